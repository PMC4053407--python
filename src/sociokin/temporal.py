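"""Lagged association rates and exponential-decay social models.

The lagged association rate (LAR) g(tau) is the probability that a dyad
associated on one day is associated again tau days later, estimated over
all ordered day pairs:

    g(tau) = sum a_ij(t) * a_ij(t')  /  sum a_ij(t) * 1[i, j identified at t']

with t' - t = tau.  It is compared against the null association rate
expected under random mixing (the mean of n_i(t) / (N(t) - 1), an
individual's typical associates over possible partners), and summarised
by fitting mixtures of social components

    g(tau) = c_cc + sum_k c_k * exp(-tau / T_k)

where a constant term represents constant companionships (T = infinity),
exponential terms represent casual acquaintances of mean duration T_k
days, and any deficit 1 - sum(c) represents rapid disassociations gone
within one sampling period.  Candidate models are ranked by qAICc,
the quasi-likelihood AIC with small-sample correction, using an
overdispersion factor estimated from the most general candidate.

A variant denominator weighting by the number of associates
(``denominator="associates"``) is available; the default conditions on
both members being identified, which makes g directly comparable with
the component proportions and with the null rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .associations import DailyRecord, _identification_arrays

logger = logging.getLogger(__name__)

_T_CONSTANT = float("inf")
_EPS = 1e-6


# ---------------------------------------------------------------------------
# day bookkeeping
# ---------------------------------------------------------------------------

def _day_numbers(records: list[DailyRecord]) -> np.ndarray:
    days = [r.day for r in records]
    if hasattr(days[0], "toordinal"):
        nums = np.array([d.toordinal() for d in days], dtype=int)
    else:
        nums = np.array(days, dtype=int)
    if len(set(nums.tolist())) != len(nums):
        raise ValueError("duplicate sampling days in records")
    return nums - nums.min()


def _dyad_arrays(records: list[DailyRecord]):
    """Identification matrix plus per-dyad association/identification
    series, restricted to dyads associated at least once."""
    ids, ident, x = _identification_arrays(records)
    index = {v: k for k, v in enumerate(ids)}
    dyads = sorted({pair for r in records for pair in r.dyads})
    P = len(dyads)
    D = len(records)
    assoc = np.zeros((D, P), dtype=np.float64)
    for d, r in enumerate(records):
        for pair in r.dyads:
            assoc[d, dyads.index(pair)] = 1.0
    di = np.array([index[a] for a, _ in dyads], dtype=int)
    dj = np.array([index[b] for _, b in dyads], dtype=int)
    both_ident = (ident[:, di] & ident[:, dj]).astype(np.float64)
    return ids, ident, dyads, assoc, both_ident, di, dj


# ---------------------------------------------------------------------------
# LAR estimation
# ---------------------------------------------------------------------------

def default_lag_bins(max_lag: int, per_decade: int = 10) -> np.ndarray:
    """Logarithmically spaced integer lag-bin edges from 1 to max_lag."""
    if max_lag < 1:
        raise ValueError("need a positive maximum lag")
    n_edges = max(2, int(np.ceil(np.log10(max_lag + 1) * per_decade)) + 1)
    edges = np.unique(np.round(np.geomspace(1, max_lag + 1, n_edges)).astype(int))
    if edges[-1] <= max_lag:
        edges = np.append(edges, max_lag + 1)
    return edges


@dataclass
class LARCurve:
    bin_edges: np.ndarray
    lag_mid: np.ndarray      # denominator-weighted mean lag per bin
    g: np.ndarray
    n_pairs: np.ndarray      # denominator weight per bin
    null_rate: float
    se: np.ndarray | None = None
    bin_index: np.ndarray | None = None  # retained bin positions in bin_edges


def _lag_sums(records: list[DailyRecord], denominator: str):
    daynum = _day_numbers(records)
    order = np.argsort(daynum)
    records = [records[k] for k in order]
    daynum = daynum[order]
    ids, ident, dyads, assoc, both_ident, di, dj = _dyad_arrays(records)
    D = len(records)
    max_lag = int(daynum.max())
    num = np.zeros(max_lag + 1)
    den = np.zeros(max_lag + 1)
    if denominator == "associates":
        n_assoc = np.zeros((D, ident.shape[1]))
        for d, r in enumerate(records):
            for a, b in r.dyads:
                n_assoc[d, ids.index(a)] += 1
                n_assoc[d, ids.index(b)] += 1
    for d1 in range(D - 1):
        a1 = assoc[d1]
        if not a1.any():
            continue
        lags = daynum[d1 + 1:] - daynum[d1]
        np.add.at(num, lags, assoc[d1 + 1:] @ a1)
        if denominator == "identified":
            np.add.at(den, lags, both_ident[d1 + 1:] @ a1)
        else:
            # ordered-sum denominator: a_ij(t) * (n_i(t') + n_j(t'));
            # the numerator is doubled to stay on the same ordered scale
            contrib = (n_assoc[d1 + 1:, di] * ident[d1 + 1:, di]
                       + n_assoc[d1 + 1:, dj] * ident[d1 + 1:, dj]) @ a1
            np.add.at(den, lags, contrib)
    if denominator == "associates":
        num *= 2.0
    return num, den, max_lag


def lagged_association_rate(
    records: list[DailyRecord],
    lag_bins: np.ndarray | None = None,
    denominator: str = "identified",
    jackknife_block: int | None = None,
) -> LARCurve:
    """Binned lagged association rate with optional jackknife errors.

    ``jackknife_block`` (days) triggers delete-one-block jackknife
    standard errors per lag bin.
    """
    if denominator not in ("identified", "associates"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if len({r.day for r in records}) < 2:
        raise ValueError("need at least two distinct days")
    num, den, max_lag = _lag_sums(records, denominator)
    edges = default_lag_bins(max_lag) if lag_bins is None else np.asarray(lag_bins)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("lag bin edges must be strictly increasing")
    lags = np.arange(max_lag + 1)
    which = np.digitize(lags, edges) - 1
    nb = len(edges) - 1
    g, mid, w, kept = [], [], [], []
    for b in range(nb):
        sel = which == b
        nb_num, nb_den = num[sel].sum(), den[sel].sum()
        if nb_den > 0:
            g.append(nb_num / nb_den)
            mid.append((lags[sel] * den[sel]).sum() / nb_den)
            w.append(nb_den)
            kept.append(b)
    if not g:
        raise ValueError("no lag bin has a positive denominator")
    curve = LARCurve(
        bin_edges=edges,
        lag_mid=np.array(mid),
        g=np.array(g),
        n_pairs=np.array(w),
        null_rate=null_association_rate(records),
        bin_index=np.array(kept, dtype=int),
    )
    if jackknife_block is not None:
        def per_bin_g(sub):
            n2, d2, _ = _lag_sums(sub, denominator)
            n2 = np.pad(n2, (0, max_lag + 1 - len(n2)))
            d2 = np.pad(d2, (0, max_lag + 1 - len(d2)))
            out = np.full(nb, np.nan)
            for b in range(nb):
                sel = which == b
                if d2[sel].sum() > 0:
                    out[b] = n2[sel].sum() / d2[sel].sum()
            return out
        se_full = jackknife_se(records, per_bin_g, block=jackknife_block)
        curve.se = se_full[curve.bin_index]
    return curve


def null_association_rate(records: list[DailyRecord]) -> float:
    """Expected association rate under random mixing: the mean over
    individuals and days of n_i(t) / (N(t) - 1).  Days with fewer than
    two identified individuals are skipped."""
    vals = []
    for r in records:
        n_t = len(r.identified)
        if n_t < 2:
            continue
        counts = dict.fromkeys(r.identified, 0)
        for a, b in r.dyads:
            counts[a] += 1
            counts[b] += 1
        vals.extend(c / (n_t - 1) for c in counts.values())
    if not vals:
        raise ValueError("no day with at least two identified individuals")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# blocked jackknife
# ---------------------------------------------------------------------------

def jackknife_se(records: list[DailyRecord], statistic, block: int = 10) -> np.ndarray:
    """Delete-one-block jackknife standard error of a statistic of the
    record stream, over consecutive ``block``-day periods:

        SE = sqrt[ (G-1)/G * sum_i (theta_(i) - theta_bar)^2 ]

    The statistic must map a record list to a float or 1-d array.  Blocks
    on which it fails are flagged and dropped with a warning.
    """
    daynum = _day_numbers(records)
    block_id = daynum // int(block)
    blocks = np.unique(block_id)
    if len(blocks) < 3:
        raise ValueError("need at least three jackknife blocks")
    thetas = []
    for bid in blocks:
        sub = [r for r, b in zip(records, block_id) if b != bid]
        try:
            thetas.append(np.atleast_1d(np.asarray(statistic(sub), dtype=float)))
        except Exception as err:  # noqa: BLE001 - statistic may fail on a delete-set
            warnings.warn(f"jackknife block {bid} failed ({err}); dropped",
                          stacklevel=2)
    if len(thetas) < 3:
        raise ValueError("too few successful jackknife blocks")
    theta = np.vstack(thetas)
    g = theta.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(theta, axis=0)
        se = np.sqrt((g - 1) / g * np.nansum((theta - mean) ** 2, axis=0))
    return se


# ---------------------------------------------------------------------------
# social model family
# ---------------------------------------------------------------------------

@dataclass
class SocialModel:
    name: str
    components: list          # (kind, proportion, duration_days) tuples
    rapid_fraction: float
    k: int                    # number of fitted parameters
    qaicc: float
    delta_qaicc: float = float("nan")
    params_se: dict | None = None
    deviance: float = float("nan")
    chat: float = 1.0
    fitted: np.ndarray | None = field(default=None, repr=False)

    @property
    def component_kinds(self) -> tuple:
        return tuple(kind for kind, _, _ in self.components)

    def predict(self, tau) -> np.ndarray:
        """Model association rate at the given lags (days)."""
        tau = np.asarray(tau, dtype=float)
        g = np.zeros_like(tau)
        for _, prop, duration in self.components:
            if np.isinf(duration):
                g = g + prop
            else:
                g = g + prop * np.exp(-tau / duration)
        return g


class _Candidate:
    """One member of the exponential-decay family.

    ``n_casual`` casual components, optionally a constant-companionship
    term, with the component proportions either free (allowing a rapid-
    disassociation remainder) or pinned to sum to one.
    """

    def __init__(self, has_constant: bool, n_casual: int, pinned: bool):
        self.has_constant = has_constant
        self.n_casual = n_casual
        self.pinned = pinned
        self.n_components = int(has_constant) + n_casual
        # parameters: component proportions (one fewer when pinned) + durations
        self.k = self.n_components - int(pinned) + n_casual
        base = ("CC+" if has_constant else "") + "+".join(["CA"] * n_casual)
        self.name = base.rstrip("+") + ("" if pinned else "+RD")

    def unpack(self, theta):
        n_free_c = self.n_components - int(self.pinned)
        cs = list(theta[:n_free_c])
        if self.pinned:
            cs.append(max(0.0, 1.0 - sum(cs)))
        ts = list(np.exp(theta[n_free_c:]))  # durations fitted on log scale
        return np.array(cs), np.array(ts)

    def curve(self, tau, theta):
        cs, ts = self.unpack(theta)
        g = np.zeros_like(np.asarray(tau, dtype=float))
        k = 0
        if self.has_constant:
            g = g + cs[0]
            k = 1
        for j in range(self.n_casual):
            g = g + cs[k + j] * np.exp(-np.asarray(tau, dtype=float) / ts[j])
        return g

    def initial_points(self, g_obs):
        lo = float(np.clip(g_obs[-1], 0.05, 0.95))
        hi = float(np.clip(g_obs[0], 0.05, 0.95))
        inits = []
        for t0 in (3.0, 8.0, 30.0, 120.0):
            cs = []
            if self.has_constant:
                cs.append(lo)
            for j in range(self.n_casual):
                cs.append(max(0.05, (hi - lo) / max(1, self.n_casual)))
            n_free_c = self.n_components - int(self.pinned)
            ts = [np.log(t0 * (4.0 ** j)) for j in range(self.n_casual)]
            inits.append(np.array(cs[:n_free_c] + ts))
        return inits

    def bounds(self):
        n_free_c = self.n_components - int(self.pinned)
        lo = [0.0] * n_free_c + [np.log(1e-2)] * self.n_casual
        hi = [1.0] * n_free_c + [np.log(1e6)] * self.n_casual
        return np.array(lo), np.array(hi)


CANDIDATES = [
    _Candidate(True, 0, True), _Candidate(True, 0, False),
    _Candidate(False, 1, True), _Candidate(False, 1, False),
    _Candidate(True, 1, True), _Candidate(True, 1, False),
    _Candidate(False, 2, True), _Candidate(False, 2, False),
]


def _fit_candidate(cand: _Candidate, tau, g_obs, w, x0=None):
    def resid(theta):
        model = cand.curve(tau, theta)
        cs, _ = cand.unpack(theta)
        penalty = 1e3 * max(0.0, cs.sum() - 1.0)
        return np.append(np.sqrt(w) * (g_obs - model), penalty)

    lo, hi = cand.bounds()
    best = None
    starts = [x0] if x0 is not None else cand.initial_points(g_obs)
    for start in starts:
        start = np.clip(start, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(resid, start, bounds=(lo, hi), method="trf",
                                max_nfev=2000)
        except Exception:  # noqa: BLE001
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    return best


def _weighted_rss(g_obs, g_fit, w):
    """Weighted residual sum of squares: the quasi-deviance of the
    Gaussian working model used for fitting and ranking."""
    return float(np.sum(w * (g_obs - g_fit) ** 2))


def _fit_weights(curve: LARCurve) -> np.ndarray:
    """Inverse-variance weights from the per-bin jackknife errors.

    Day pairs within a bin are heavily serially dependent, so the raw
    denominator counts overstate precision by orders of magnitude; the
    blocked jackknife gives an honest per-bin variance.  Bins with
    unusable SEs fall back to the median weight; SEs are floored at a
    quarter of the median to keep single bins from dominating.
    """
    se = curve.se
    if se is None:
        return curve.n_pairs / curve.n_pairs.mean()
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(se) & (se > 0)
    if ok.sum() < 4:
        return curve.n_pairs / curve.n_pairs.mean()
    # smooth log SE against log lag (quadratic) so a bin's weight does not
    # depend on its own realised noise, which would bias the fit
    lx = np.log(curve.lag_mid)
    design = np.column_stack([np.ones_like(lx), lx, lx ** 2])
    beta, *_ = np.linalg.lstsq(design[ok], np.log(se[ok]), rcond=None)
    se_hat = np.exp(design @ beta)
    floor = 0.25 * np.median(se_hat)
    return 1.0 / np.maximum(se_hat, floor) ** 2


def _model_from_fit(cand: _Candidate, theta, tau, g_obs, w, chat) -> SocialModel:
    cs, ts = cand.unpack(theta)
    comps = []
    k = 0
    if cand.has_constant:
        comps.append(("constant", float(cs[0]), _T_CONSTANT))
        k = 1
    casual = sorted(
        [("casual", float(cs[k + j]), float(ts[j])) for j in range(cand.n_casual)],
        key=lambda c: -c[2],
    )
    comps.extend(casual)
    g_fit = cand.curve(tau, theta)
    dev = _weighted_rss(g_obs, g_fit, w)
    n = len(tau)
    if n - cand.k - 1 <= 0:
        qaicc = float("inf")
    else:
        qaicc = dev / chat + 2 * cand.k + 2 * cand.k * (cand.k + 1) / (n - cand.k - 1)
    return SocialModel(
        name=cand.name,
        components=comps,
        rapid_fraction=float(max(0.0, 1.0 - cs.sum())),
        k=cand.k,
        qaicc=qaicc,
        deviance=dev,
        chat=chat,
        fitted=g_fit,
    )


def fit_social_models(
    records: list[DailyRecord],
    lag_bins: np.ndarray | None = None,
    jackknife_block: int = 10,
    seed: int | None = None,
    denominator: str = "identified",
    compute_se: bool = True,
    max_lag_fraction: float = 0.5,
) -> list[SocialModel]:
    """Fit the exponential-decay social model family to the LAR and rank
    by qAICc (ascending; best first).

    Bins are weighted by inverse jackknife variance (see
    :func:`_fit_weights`).  The overdispersion factor c-hat is the
    weighted residual sum of squares of the most general candidate
    divided by its residual degrees of freedom, floored at 1.  Jackknife
    standard errors (over ``jackknife_block``-day periods) are computed
    for the best model's proportions and durations.  Candidates that
    fail to converge are dropped with a warning.
    """
    curve = lagged_association_rate(records, lag_bins=lag_bins,
                                    denominator=denominator,
                                    jackknife_block=jackknife_block)
    # lags beyond a fraction of the span rest on few effective replicates
    span = float(_day_numbers(records).max())
    use = curve.lag_mid <= max_lag_fraction * span
    if use.sum() < 5:
        use = np.ones(len(curve.lag_mid), dtype=bool)
    tau, g_obs = curve.lag_mid[use], curve.g[use]
    w_full = _fit_weights(curve)
    w = w_full[use]
    fits = {}
    for cand in CANDIDATES:
        if cand.k == 0:
            fits[cand.name] = (cand, np.empty(0))
            continue
        res = _fit_candidate(cand, tau, g_obs, w)
        if res is None:
            warnings.warn(f"candidate {cand.name} did not converge; dropped",
                          stacklevel=2)
            continue
        fits[cand.name] = (cand, res.x)
    if not fits:
        raise RuntimeError("no social model candidate converged")

    general_name = "CA+CA+RD" if "CA+CA+RD" in fits else max(
        fits, key=lambda k: fits[k][0].k)
    gc, gtheta = fits[general_name]
    dof = max(1, len(tau) - gc.k)
    chat = max(1.0, _weighted_rss(g_obs, gc.curve(tau, gtheta), w) / dof)

    models = [
        _model_from_fit(cand, theta, tau, g_obs, w, chat)
        for cand, theta in fits.values()
    ]
    models.sort(key=lambda m: (m.qaicc, m.k))
    best_q = models[0].qaicc
    for m in models:
        m.delta_qaicc = m.qaicc - best_q

    if compute_se and models[0].k > 0:
        best_cand = next(c for c, _ in fits.values() if c.name == models[0].name)
        theta_full = fits[models[0].name][1]

        # weight lookup per bin-edge position, so delete-block refits use
        # the same inverse-variance scale and lag range as the full fit
        w_by_bin = {b: w_full[k] for k, b in enumerate(curve.bin_index) if use[k]}

        def refit(sub):
            c2 = lagged_association_rate(sub, lag_bins=curve.bin_edges,
                                         denominator=denominator)
            keep = np.array([b in w_by_bin for b in c2.bin_index])
            if keep.sum() < max(3, best_cand.k + 1):
                raise RuntimeError("too few bins after block deletion")
            w2 = np.array([w_by_bin[b] for b in c2.bin_index[keep]])
            res = _fit_candidate(best_cand, c2.lag_mid[keep], c2.g[keep], w2,
                                 x0=theta_full)
            if res is None:
                raise RuntimeError("refit failed")
            cs, ts = best_cand.unpack(res.x)
            return np.concatenate([cs, ts])

        try:
            se = jackknife_se(records, refit, block=jackknife_block)
            cs, ts = best_cand.unpack(theta_full)
            names = []
            if best_cand.has_constant:
                names.append("c_constant")
            names += [f"c_casual{j + 1}" for j in range(best_cand.n_casual)]
            names += [f"T_casual{j + 1}" for j in range(best_cand.n_casual)]
            models[0].params_se = dict(zip(names, map(float, se)))
        except ValueError as err:
            logger.warning("jackknife SE unavailable: %s", err)
    return models
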