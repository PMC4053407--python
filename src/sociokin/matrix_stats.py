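"""Matrix correlation and dyad-class randomisation tests.

The Mantel test measures the Pearson correlation between two dyadic
matrices over the off-diagonal dyads, with significance from jointly
permuting rows and columns of one matrix.  The partial Mantel test
correlates the residuals of x and y after regressing each on a third
matrix z (e.g. association vs relatedness holding spatial overlap
constant) and permutes the residual matrix.  The within/between test
compares mean dyadic values inside versus across social units by
permuting unit labels over individuals.

All p-values use the add-one convention p = (1 + hits) / (1 + n_perm),
so a result more extreme than every permutation reports 1/(n_perm + 1),
never 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .matrices import DyadicMatrix, align
from .network import Partition

EXACT_MAX_N = 8


@dataclass
class MatrixTestResult:
    statistic: float
    n_dyads: int
    p: float
    n_permutations: int
    seed: int | None
    alternative: str
    extra: dict = field(default_factory=dict)


def _offdiag_vector(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    ok = np.isfinite(u) & np.isfinite(v)
    u, v = u[ok], v[ok]
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise ValueError("Mantel correlation undefined for a constant matrix")
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def _pvalue(null: np.ndarray, obs: float, alternative: str) -> float:
    if alternative == "two-sided":
        hits = np.sum(np.abs(null) >= abs(obs) - 1e-12)
    elif alternative == "greater":
        hits = np.sum(null >= obs - 1e-12)
    elif alternative == "less":
        hits = np.sum(null <= obs + 1e-12)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + hits) / (1 + len(null)))


def _permutations(n: int, n_perm: int, rng, method: str):
    if method == "exact":
        if n > EXACT_MAX_N:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_MAX_N}")
        return [np.array(p) for p in itertools.permutations(range(n))]
    return [rng.permutation(n) for _ in range(n_perm)]


def mantel(
    x: DyadicMatrix,
    y: DyadicMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    subset=None,
    alternative: str = "two-sided",
    method: str = "mc",
) -> MatrixTestResult:
    """Mantel matrix correlation test.

    ``method="exact"`` enumerates all n! joint row/column relabelings
    (n <= 8) instead of Monte-Carlo sampling.
    """
    xm, ym = align(x, y, subset=subset)
    if xm.n < 4:
        raise ValueError("need at least four individuals")
    xv = _offdiag_vector(xm.values)
    r_obs = _corr(xv, _offdiag_vector(ym.values))
    rng = np.random.default_rng(seed)
    yvals = ym.values
    null = []
    perms = _permutations(xm.n, n_perm, rng, method)
    for p in perms:
        null.append(_corr(xv, _offdiag_vector(yvals[np.ix_(p, p)])))
    null = np.array(null)
    if method == "exact":
        # the identity permutation reproduces the observed statistic, which
        # plays the add-one role exactly
        hits = {
            "two-sided": np.sum(np.abs(null) >= abs(r_obs) - 1e-12),
            "greater": np.sum(null >= r_obs - 1e-12),
            "less": np.sum(null <= r_obs + 1e-12),
        }[alternative]
        p_val = float(hits / len(null))
    else:
        p_val = _pvalue(null, r_obs, alternative)
    return MatrixTestResult(
        statistic=r_obs, n_dyads=len(xv), p=p_val,
        n_permutations=len(perms), seed=seed, alternative=alternative,
        extra={"null_mean": float(null.mean())},
    )


def _residual_matrix(target: np.ndarray, z: np.ndarray) -> np.ndarray:
    """OLS residuals of the off-diagonal dyads of ``target`` on ``z``,
    reassembled into a symmetric matrix (NaN diagonal)."""
    iu = np.triu_indices(target.shape[0], k=1)
    tv, zv = target[iu], z[iu]
    ok = np.isfinite(tv) & np.isfinite(zv)
    design = np.column_stack([np.ones(ok.sum()), zv[ok]])
    beta, *_ = np.linalg.lstsq(design, tv[ok], rcond=None)
    resid = np.full_like(tv, np.nan)
    resid[ok] = tv[ok] - design @ beta
    out = np.full_like(target, np.nan)
    out[iu] = resid
    out.T[iu] = resid
    return out


def partial_mantel(
    x: DyadicMatrix,
    y: DyadicMatrix,
    z: DyadicMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    subset=None,
    alternative: str = "two-sided",
    permute: str = "residuals",
) -> MatrixTestResult:
    """Partial Mantel test of x ~ y holding z constant.

    The statistic is the correlation of the dyadic residuals of x on z
    and y on z.  The null distribution permutes the residual matrix of x
    (``permute="residuals"``, the default) or the raw x matrix
    (``permute="raw"``), jointly over rows and columns.
    """
    xm, ym, zm = align(x, y, z, subset=subset)
    if xm.n < 4:
        raise ValueError("need at least four individuals")
    rx = _residual_matrix(xm.values, zm.values)
    ry = _residual_matrix(ym.values, zm.values)
    rxv, ryv = _offdiag_vector(rx), _offdiag_vector(ry)
    tol_x = 1e-9 * (np.nanstd(_offdiag_vector(xm.values)) + 1e-30)
    tol_y = 1e-9 * (np.nanstd(_offdiag_vector(ym.values)) + 1e-30)
    if np.nanstd(rxv) <= tol_x or np.nanstd(ryv) <= tol_y:
        # a matrix collinear with z leaves no residual variation
        if np.nanstd(ryv) <= tol_y:
            return MatrixTestResult(
                statistic=0.0, n_dyads=int(np.isfinite(rxv).sum()), p=1.0,
                n_permutations=0, seed=seed, alternative=alternative,
                extra={"note": "y is collinear with z; residual correlation is 0"},
            )
        raise ValueError("x is perfectly collinear with z")
    r_obs = _corr(rxv, ryv)
    rng = np.random.default_rng(seed)
    source = rx if permute == "residuals" else xm.values
    null = []
    for _ in range(n_perm):
        p = rng.permutation(xm.n)
        perm = source[np.ix_(p, p)]
        if permute == "raw":
            perm = _residual_matrix(perm, zm.values)
        null.append(_corr(_offdiag_vector(perm), ryv))
    p_val = _pvalue(np.array(null), r_obs, alternative)
    return MatrixTestResult(
        statistic=r_obs, n_dyads=len(rxv), p=p_val, n_permutations=n_perm,
        seed=seed, alternative=alternative,
    )


# ---------------------------------------------------------------------------
# within- vs between-unit randomisation test
# ---------------------------------------------------------------------------

def _dyad_class_mask(ids, classes, dyad_filter):
    n = len(ids)
    if dyad_filter is None:
        return np.ones((n, n), dtype=bool)
    want = frozenset(dyad_filter) if len(set(dyad_filter)) > 1 else None
    c1 = dyad_filter[0]
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            pair = frozenset((classes[ids[i]], classes[ids[j]]))
            if want is None:
                mask[i, j] = pair == frozenset((c1,))
            else:
                mask[i, j] = pair == want
    return mask


def within_between_test(
    values: DyadicMatrix,
    partition: Partition,
    dyad_filter=None,
    metadata: dict | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "two-sided",
    method: str = "mc",
) -> MatrixTestResult:
    """Compare mean dyadic values within versus between social units.

    statistic = mean(within-unit dyads) - mean(between-unit dyads); the
    null permutes unit labels across individuals holding unit sizes.
    ``dyad_filter`` restricts dyads to a class pair (e.g.
    ``("adult_F", "adult_F")``) using ``metadata`` (id -> class label).
    ``method="exact"`` enumerates all distinct label assignments for
    small n.
    """
    ids = [i for i in partition.ids if i in set(values.ids)]
    if len(set(partition.labels)) < 2:
        raise ValueError("need at least two units")
    vm = values.subset(ids)
    labels = np.array([partition.membership()[i] for i in ids])
    if dyad_filter is not None and metadata is None:
        raise ValueError("dyad_filter requires metadata (id -> class)")
    cls_mask = _dyad_class_mask(ids, metadata or {}, dyad_filter)
    iu = np.triu_indices(len(ids), k=1)
    vals = vm.values[iu]
    keep = cls_mask[iu] & np.isfinite(vals)
    if not keep.any():
        raise ValueError("dyad filter leaves no dyads")

    def stat(lab):
        same = (lab[:, None] == lab[None, :])[iu]
        w = vals[keep & same]
        b = vals[keep & ~same]
        if w.size == 0 or b.size == 0:
            return None, w, b
        return float(w.mean() - b.mean()), w, b

    obs, w_obs, b_obs = stat(labels)
    if obs is None:
        raise ValueError("need at least one within and one between dyad")

    if method == "exact":
        perms = set(itertools.permutations(labels))
        null = np.array([s for s in
                         (stat(np.array(p))[0] for p in perms) if s is not None])
        hits = {
            "two-sided": np.sum(np.abs(null) >= abs(obs) - 1e-12),
            "greater": np.sum(null >= obs - 1e-12),
            "less": np.sum(null <= obs + 1e-12),
        }[alternative]
        p_val = float(hits / len(null))
        n_done = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = []
        for _ in range(n_perm):
            s, *_ = stat(labels[rng.permutation(len(labels))])
            if s is not None:
                null.append(s)
        p_val = _pvalue(np.array(null), obs, alternative)
        n_done = len(null)
    return MatrixTestResult(
        statistic=obs, n_dyads=int(keep.sum()), p=p_val,
        n_permutations=n_done, seed=seed, alternative=alternative,
        extra={
            "within_mean": float(w_obs.mean()),
            "within_se": float(w_obs.std(ddof=1) / math.sqrt(w_obs.size)) if w_obs.size > 1 else 0.0,
            "n_within": int(w_obs.size),
            "between_mean": float(b_obs.mean()),
            "between_se": float(b_obs.std(ddof=1) / math.sqrt(b_obs.size)) if b_obs.size > 1 else 0.0,
            "n_between": int(b_obs.size),
        },
    )
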