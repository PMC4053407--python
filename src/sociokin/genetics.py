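"""Microsatellite genetics: allele frequencies, Queller-Goodnight pairwise
relatedness, diversity statistics, Hardy-Weinberg exact tests, and
sequential Bonferroni (Holm) correction.

The pairwise relatedness estimator is the allele-frequency-weighted
Queller-Goodnight statistic.  For individual x with alleles (a, b) and
individual y with alleles (c, d) at a locus,

    num  = 0.5 * (d_ac + d_ad + d_bc + d_bd) - p_a - p_b
    den  = 1 + d_ab - p_a - p_b

where d is the Kronecker delta and p the population frequency of x's
alleles.  Numerators and denominators are summed over the loci typed in
both individuals; the directional estimate is the ratio of sums and the
symmetric estimate is the mean of the two directions.  Expected values are
0.5 for first-degree kin and 0 for unrelated pairs, and the estimate can
be negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matrices import DyadicMatrix

logger = logging.getLogger(__name__)

MISSING = ""

# pairs typed together at fewer loci than this are flagged low-confidence
LOW_CONFIDENCE_SHARED_LOCI = 8


class GenotypeFormatError(ValueError):
    pass


class GenotypeTable:
    """Diploid multi-locus genotypes for a set of individuals.

    Alleles are arbitrary string labels; the pair within a cell is
    unordered and is stored in sorted order so that equal genotypes
    compare equal.  A missing genotype is stored as a pair of empty
    strings.
    """

    def __init__(self, ids, loci, alleles: np.ndarray):
        self.ids = [str(i) for i in ids]
        self.loci = [str(l) for l in loci]
        arr = np.asarray(alleles, dtype=object)
        if arr.shape != (len(self.ids), len(self.loci), 2):
            raise GenotypeFormatError(
                f"allele array shape {arr.shape} != ({len(self.ids)}, {len(self.loci)}, 2)"
            )
        if len(set(self.ids)) != len(self.ids):
            raise GenotypeFormatError("individual ids are not unique")
        if not self.loci:
            raise GenotypeFormatError("at least one locus required")
        # canonicalise: sort the two alleles of each cell; missing -> ("","")
        for i in range(arr.shape[0]):
            for l in range(arr.shape[1]):
                a, b = str(arr[i, l, 0]), str(arr[i, l, 1])
                if a == MISSING or b == MISSING:
                    arr[i, l, 0] = arr[i, l, 1] = MISSING
                else:
                    arr[i, l, 0], arr[i, l, 1] = sorted((a, b))
        self.alleles = arr

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) bool: genotype present."""
        return self.alleles[:, :, 0] != MISSING

    def missing_fraction(self) -> float:
        return float(1.0 - self.typed_mask().mean())

    def locus_index(self, locus: str) -> int:
        return self.loci.index(str(locus))

    def subset(self, ids) -> "GenotypeTable":
        ids = [str(i) for i in ids]
        idx = [self.ids.index(i) for i in ids]
        return GenotypeTable(ids, self.loci, self.alleles[idx])

    # -- tabular round trip ---------------------------------------------
    def to_frame(self, missing_token: str = "0") -> pd.DataFrame:
        cells = {}
        for l, locus in enumerate(self.loci):
            col = []
            for i in range(self.n_individuals):
                a, b = self.alleles[i, l]
                col.append(missing_token if a == MISSING else f"{a}/{b}")
            cells[locus] = col
        df = pd.DataFrame(cells, index=pd.Index(self.ids, name="id"))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, missing_token: str = "0") -> "GenotypeTable":
        ids = [str(i) for i in df.index]
        loci = [str(c) for c in df.columns]
        arr = np.empty((len(ids), len(loci), 2), dtype=object)
        for l, locus in enumerate(loci):
            for i, raw in enumerate(df[locus].astype(str)):
                cell = raw.strip()
                if cell in (missing_token, f"{missing_token}/{missing_token}", "", "nan"):
                    arr[i, l, 0] = arr[i, l, 1] = MISSING
                    continue
                parts = cell.split("/")
                if len(parts) != 2 or not all(parts):
                    raise GenotypeFormatError(
                        f"cell {raw!r} for individual {ids[i]!r} at locus "
                        f"{locus!r} does not hold exactly two alleles"
                    )
                arr[i, l] = parts
        table = cls(ids, loci, arr)
        untyped = [
            table.ids[i]
            for i in range(table.n_individuals)
            if not table.typed_mask()[i].any()
        ]
        if untyped:
            warnings.warn(
                f"dropping individuals typed at zero loci: {untyped}", stacklevel=2
            )
            keep = [i for i in table.ids if i not in set(untyped)]
            if not keep:
                raise GenotypeFormatError("no individual typed at any locus")
            table = table.subset(keep)
        logger.info(
            "genotype table: %d individuals x %d loci, missing fraction %.4f",
            table.n_individuals, table.n_loci, table.missing_fraction(),
        )
        return table

    def __eq__(self, other):
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.loci == other.loci
            and (self.alleles == other.alleles).all()
        )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeTable) -> dict[str, pd.Series]:
    """Per-locus allele frequencies among non-missing genotypes.

    Loci with zero typed genotypes are excluded with a warning.
    """
    if g.n_individuals == 0:
        raise GenotypeFormatError("empty genotype table")
    freqs: dict[str, pd.Series] = {}
    for l, locus in enumerate(g.loci):
        typed = g.typed_mask()[:, l]
        if not typed.any():
            warnings.warn(f"locus {locus!r} has no typed genotypes; excluded",
                          stacklevel=2)
            continue
        copies = np.concatenate([g.alleles[typed, l, 0], g.alleles[typed, l, 1]])
        labels, counts = np.unique(copies.astype(str), return_counts=True)
        freqs[locus] = pd.Series(counts / counts.sum(), index=labels).sort_index()
    return freqs


def _encode_locus(g: GenotypeTable, l: int, freq: pd.Series):
    """Integer-code the two allele columns of one locus; -1 = missing."""
    mapping = {a: k for k, a in enumerate(freq.index)}
    a1 = np.array([mapping.get(x, -1) for x in g.alleles[:, l, 0]], dtype=int)
    a2 = np.array([mapping.get(x, -1) for x in g.alleles[:, l, 1]], dtype=int)
    p = freq.to_numpy()
    return a1, a2, p


# ---------------------------------------------------------------------------
# Queller-Goodnight relatedness
# ---------------------------------------------------------------------------

def qg_relatedness(
    g: GenotypeTable,
    frequencies: str = "full",
    combine: str = "average",
) -> DyadicMatrix:
    """Pairwise Queller-Goodnight relatedness matrix.

    Parameters
    ----------
    frequencies : {"full", "exclude-pair"}
        Whether allele frequencies include the focal pair (the default of
        widely used estimators) or exclude the pair's gene copies (the
        bias-corrected variant).
    combine : {"average", "ratio-of-sums"}
        How the two directional estimates are combined into the symmetric
        value: mean of the two ratios (default) or the ratio of summed
        numerators/denominators across both directions.

    Dyads sharing zero typed loci get NaN (flagged, never coerced to 0);
    dyads sharing fewer than 8 typed loci are listed under
    ``flags["low_confidence_pairs"]``.
    """
    if g.n_individuals < 2:
        raise GenotypeFormatError("need at least two individuals")
    if frequencies not in ("full", "exclude-pair"):
        raise ValueError(f"unknown frequencies mode {frequencies!r}")
    if combine not in ("average", "ratio-of-sums"):
        raise ValueError(f"unknown combine mode {combine!r}")

    n = g.n_individuals
    freqs = allele_frequencies(g)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)

    for locus in freqs:
        l = g.locus_index(locus)
        a1, a2, p = _encode_locus(g, l, freqs[locus])
        typed = a1 >= 0
        pair_typed = typed[:, None] & typed[None, :]
        shared += pair_typed

        if frequencies == "full":
            pa = np.where(typed, p[np.maximum(a1, 0)], np.nan)
            pb = np.where(typed, p[np.maximum(a2, 0)], np.nan)
            pa_pair = np.broadcast_to(pa[:, None], (n, n)).copy()
            pb_pair = np.broadcast_to(pb[:, None], (n, n)).copy()
        else:
            # leave-two-out: frequency of x's alleles with the focal
            # pair's four gene copies removed, per (x, y) pair
            m = int(typed.sum())
            if m < 3:
                raise GenotypeFormatError(
                    "exclude-pair frequencies need >=3 typed individuals per locus"
                )
            counts = np.round(p * 2 * m).astype(int)
            pa_pair = np.full((n, n), np.nan)
            pb_pair = np.full((n, n), np.nan)
            for i in range(n):
                if not typed[i]:
                    continue
                for j in range(n):
                    if i == j or not typed[j]:
                        continue
                    own = {a1[i]: 0, a2[i]: 0}
                    for al in (a1[i], a2[i], a1[j], a2[j]):
                        if al in own:
                            own[al] += 1
                    pa_pair[i, j] = (counts[a1[i]] - own[a1[i]]) / (2 * (m - 2))
                    pb_pair[i, j] = (counts[a2[i]] - own[a2[i]]) / (2 * (m - 2))

        # float casts matter: "+" on numpy bool arrays is logical OR
        d_ac = (a1[:, None] == a1[None, :]).astype(float)
        d_ad = (a1[:, None] == a2[None, :]).astype(float)
        d_bc = (a2[:, None] == a1[None, :]).astype(float)
        d_bd = (a2[:, None] == a2[None, :]).astype(float)
        d_ab = (a1 == a2).astype(float)

        num_l = 0.5 * (d_ac + d_ad + d_bc + d_bd) - pa_pair - pb_pair
        den_l = (1.0 + d_ab)[:, None] - pa_pair - pb_pair
        num += np.where(pair_typed, num_l, 0.0)
        den += np.where(pair_typed, den_l, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        r_dir = np.where(shared > 0, num / den, np.nan)
        if combine == "average":
            r = 0.5 * (r_dir + r_dir.T)
        else:
            r = (num + num.T) / (den + den.T)
            r = np.where(shared > 0, r, np.nan)
    np.fill_diagonal(r, np.nan)

    iu = np.triu_indices(n, k=1)
    low = [
        (g.ids[i], g.ids[j])
        for i, j in zip(*iu)
        if 0 < shared[i, j] < LOW_CONFIDENCE_SHARED_LOCI
    ]
    m = DyadicMatrix(g.ids, r, kind="relatedness")
    m.flags["low_confidence_pairs"] = low
    m.flags["no_shared_locus_pairs"] = [
        (g.ids[i], g.ids[j]) for i, j in zip(*iu) if shared[i, j] == 0
    ]
    return m


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    na: int
    allelic_richness: float
    he: float
    ho: float


def allelic_richness(counts: np.ndarray, rarefaction_n: int) -> float:
    """Rarefied allele count: expected number of distinct alleles in a
    random draw of ``rarefaction_n`` gene copies without replacement.

    richness = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]
    """
    counts = np.asarray(counts, dtype=int)
    N = int(counts.sum())
    nsub = int(rarefaction_n)
    if not (0 < nsub <= N):
        raise ValueError(f"rarefaction_n must be in (0, {N}]")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = []
    for ni in counts:
        if N - ni < nsub:
            terms.append(1.0)
        else:
            terms.append(1.0 - np.exp(log_comb(N - ni, nsub) - log_comb(N, nsub)))
    return float(np.sum(terms))


def diversity_stats(
    g: GenotypeTable, rarefaction_n: int | None = None
) -> pd.DataFrame:
    """Per-locus Na, rarefied allelic richness, expected and observed
    heterozygosity, with a mean +/- SE row appended.

    He = 1 - sum p_i^2; Ho = fraction heterozygous among typed individuals.
    ``rarefaction_n`` defaults to the smallest per-locus number of gene
    copies, the largest sample size valid at every locus.
    """
    freqs = allele_frequencies(g)
    typed = g.typed_mask()
    copies_per_locus = {
        locus: 2 * int(typed[:, g.locus_index(locus)].sum()) for locus in freqs
    }
    if rarefaction_n is None:
        rarefaction_n = min(copies_per_locus.values())
    if rarefaction_n > min(copies_per_locus.values()):
        raise ValueError(
            f"rarefaction_n={rarefaction_n} exceeds the smallest per-locus "
            f"sample of gene copies ({min(copies_per_locus.values())})"
        )
    rows = []
    for locus, f in freqs.items():
        l = g.locus_index(locus)
        t = typed[:, l]
        het = g.alleles[t, l, 0] != g.alleles[t, l, 1]
        counts = np.round(f.to_numpy() * copies_per_locus[locus]).astype(int)
        rows.append(
            LocusSummary(
                locus=locus,
                n_typed=int(t.sum()),
                na=len(f),
                allelic_richness=allelic_richness(counts, rarefaction_n),
                he=float(1.0 - (f.to_numpy() ** 2).sum()),
                ho=float(het.mean()),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("locus")
    mean = df[["na", "allelic_richness", "he", "ho"]].mean()
    se = df[["na", "allelic_richness", "he", "ho"]].sem(ddof=1)
    df.loc["mean"] = [np.nan, mean["na"], mean["allelic_richness"], mean["he"], mean["ho"]]
    df.loc["se"] = [np.nan, se["na"], se["allelic_richness"], se["he"], se["ho"]]
    return df


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte-Carlo permutation of gene copies)
# ---------------------------------------------------------------------------

def _genotype_stat(pairs: np.ndarray) -> tuple[float, int]:
    """Log conditional probability (up to an arrangement-constant) and
    heterozygote count of a diploid arrangement of fixed gene copies.

    With allele counts fixed, the conditional probability of a genotype
    array is proportional to 2^h / prod(n_genotype!), so the log statistic
    h*log(2) - sum(log n_g!) orders arrangements by probability.
    """
    a = np.minimum(pairs[:, 0], pairs[:, 1])
    b = np.maximum(pairs[:, 0], pairs[:, 1])
    h = int((a != b).sum())
    code = a * (b.max() + 1) + b
    _, counts = np.unique(code, return_counts=True)
    logp = h * np.log(2.0) - gammaln(counts + 1).sum()
    return float(logp), h


def hwe_test(
    g: GenotypeTable,
    locus: str,
    n_reps: int = 1000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> float:
    """Monte-Carlo exact test for Hardy-Weinberg proportions at one locus.

    The locus's gene copies are repeatedly shuffled into random diploid
    pairings (the exact-test null conditional on allele counts).
    ``alternative`` selects the extremity measure: "two-sided" uses the
    conditional probability of the arrangement, "deficit" / "excess" are
    one-sided on the heterozygote count (deficit = fewer heterozygotes
    than observed is extreme).
    """
    if alternative not in ("two-sided", "deficit", "excess"):
        raise ValueError(f"unknown alternative {alternative!r}")
    l = g.locus_index(locus)
    typed = g.typed_mask()[:, l]
    if typed.sum() < 5:
        raise GenotypeFormatError(
            f"need >=5 typed individuals at locus {locus!r}, have {int(typed.sum())}"
        )
    labels = np.unique(
        np.concatenate([g.alleles[typed, l, 0], g.alleles[typed, l, 1]]).astype(str)
    )
    if len(labels) < 2:
        return 1.0
    mapping = {a: k for k, a in enumerate(labels)}
    a1 = np.array([mapping[x] for x in g.alleles[typed, l, 0]])
    a2 = np.array([mapping[x] for x in g.alleles[typed, l, 1]])
    obs_pairs = np.column_stack([a1, a2])
    obs_logp, obs_h = _genotype_stat(obs_pairs)

    copies = np.concatenate([a1, a2])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_reps)):
        perm = rng.permutation(copies).reshape(-1, 2)
        logp, h = _genotype_stat(perm)
        if alternative == "two-sided":
            hits += logp <= obs_logp + 1e-12
        elif alternative == "deficit":
            hits += h <= obs_h
        else:
            hits += h >= obs_h
    return float((1 + hits) / (1 + n_reps))


# ---------------------------------------------------------------------------
# sequential Bonferroni (Holm step-down)
# ---------------------------------------------------------------------------

def sequential_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down significance flags, returned in input order.

    Sorted ascending, p_(i) is compared with alpha / (m - i + 1); testing
    stops at the first failure and all later hypotheses are retained.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags
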