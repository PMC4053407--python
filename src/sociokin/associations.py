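"""Dyadic association detection, half-weight index matrices, and the
data-stream permutation test for preferred/avoided companions.

Two individuals are associated on a sampling day if any pair of their
fixes lies within the simultaneity window (default < 1 h) and the
distance threshold (default < 350 m).  Association strength per dyad is
the half-weight index

    HWI = x / (x + y_ab + 0.5 * (y_a + y_b))

with x = days associated, y_ab = days both identified but not associated,
y_a / y_b = days one identified without the other.  The permutation test
swaps individuals between same-day groups (keeping each day's group sizes
and each individual's identified days fixed) and compares the observed
mean / CV / non-zero statistics of the HWI distribution against the
accumulated null: an elevated CV signals long-term preferred companions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date

import networkx as nx
import numpy as np

from .config import PipelineConfig
from .matrices import DyadicMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DailyRecord:
    """Identified individuals and associated dyads of one sampling period."""

    day: date
    identified: frozenset
    dyads: frozenset  # of 2-tuples (a, b) with a < b

    def __post_init__(self):
        for a, b in self.dyads:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) in dyads")
            if a not in self.identified or b not in self.identified:
                raise ValueError(f"dyad ({a}, {b}) outside identified set")
            if not a < b:
                raise ValueError(f"dyad ({a}, {b}) not in canonical order")


def make_record(day, identified, dyads) -> DailyRecord:
    """Normalise raw id pairs into a canonical :class:`DailyRecord`."""
    canon = frozenset(tuple(sorted((str(a), str(b)))) for a, b in dyads)
    return DailyRecord(day=day, identified=frozenset(map(str, identified)),
                       dyads=canon)


# ---------------------------------------------------------------------------
# association detection
# ---------------------------------------------------------------------------

def detect_associations(
    fixes, config: PipelineConfig | None = None
) -> list[DailyRecord]:
    """Detect daily dyadic associations from simultaneous fixes.

    ``fixes`` is a DataFrame with columns individual_id, timestamp, x, y.
    For each sampling period (default one calendar day) the identified set
    is every individual with at least one fix; a dyad is associated if any
    of its fix pairs is closer than ``association_distance_m`` with a time
    difference below ``simultaneity_window_h``.
    """
    config = config or PipelineConfig()
    if fixes.empty:
        raise ValueError("no fixes")
    ts = fixes["timestamp"].to_numpy().astype("datetime64[s]")
    days_since = (ts.astype("datetime64[D]") - ts.min().astype("datetime64[D]")).astype(int)
    period = days_since // int(config.sampling_period_days)
    base_day = ts.min().astype("datetime64[D]")

    window_s = config.simultaneity_window_h * 3600.0
    dist = config.association_distance_m
    ids_all = fixes["individual_id"].astype(str).to_numpy()
    xs = fixes["x"].to_numpy(float)
    ys = fixes["y"].to_numpy(float)
    tsec = ts.astype("int64").astype(float)

    records = []
    n_pairs_total = 0
    for p in np.unique(period):
        sel = period == p
        pid, px, py, pt = ids_all[sel], xs[sel], ys[sel], tsec[sel]
        identified = set(pid)
        dyads = set()
        if len(identified) >= 2:
            dt = np.abs(pt[:, None] - pt[None, :]) < window_s
            dd = (px[:, None] - px[None, :]) ** 2 + (py[:, None] - py[None, :]) ** 2 < dist ** 2
            hit = dt & dd
            for i, j in zip(*np.nonzero(np.triu(hit, k=1))):
                if pid[i] != pid[j]:
                    dyads.add(tuple(sorted((pid[i], pid[j]))))
        day = (base_day + int(p) * int(config.sampling_period_days)).astype(object)
        records.append(DailyRecord(day=day, identified=frozenset(identified),
                                   dyads=frozenset(dyads)))
        n_pairs_total += len(dyads)
    logger.info("detected %d associated dyad-days over %d sampling periods",
                n_pairs_total, len(records))
    return records


# ---------------------------------------------------------------------------
# half-weight index
# ---------------------------------------------------------------------------

def _identification_arrays(records, ids=None):
    if ids is None:
        ids = sorted(set().union(*(r.identified for r in records)))
    else:
        ids = [str(i) for i in ids]
    index = {v: k for k, v in enumerate(ids)}
    D, n = len(records), len(ids)
    ident = np.zeros((D, n), dtype=bool)
    x = np.zeros((n, n))
    for d, r in enumerate(records):
        for i in r.identified:
            if i in index:
                ident[d, index[i]] = True
        for a, b in r.dyads:
            if a in index and b in index:
                ia, ib = index[a], index[b]
                x[ia, ib] += 1
                x[ib, ia] += 1
    return ids, ident, x


def hwi_matrix(records: list[DailyRecord], ids=None) -> DyadicMatrix:
    """Half-weight association index matrix from daily records.

    Individuals identified on zero days are excluded with a warning.
    Dyads never identified on a common day get HWI = 0 and are listed in
    ``flags["never_co_identified"]``.
    """
    if not records:
        raise ValueError("need at least one daily record")
    ids, ident, x = _identification_arrays(records, ids)
    days = ident.sum(axis=0)
    if (days == 0).any():
        dead = [ids[i] for i in np.flatnonzero(days == 0)]
        warnings.warn(f"excluding individuals identified on zero days: {dead}",
                      stacklevel=2)
        keep = days > 0
        ids = [v for v, k in zip(ids, keep) if k]
        ident = ident[:, keep]
        x = x[np.ix_(keep, keep)]
        days = days[keep]
    both = (ident.astype(int).T @ ident.astype(int)).astype(float)
    yab = both - x
    ya = days[:, None] - both
    yb = days[None, :] - both
    denom = x + yab + 0.5 * (ya + yb)
    with np.errstate(divide="ignore", invalid="ignore"):
        hwi = np.where(denom > 0, x / denom, 0.0)
    m = DyadicMatrix(ids, hwi, kind="association")
    iu = np.triu_indices(len(ids), k=1)
    m.flags["never_co_identified"] = [
        (ids[i], ids[j]) for i, j in zip(*iu) if both[i, j] == 0
    ]
    return m


@dataclass
class HWISummary:
    mean: float
    cv: float
    mean_nonzero: float
    prop_nonzero: float
    mean_max: float
    n_dyads: int

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.cv, self.mean_nonzero,
                         self.prop_nonzero, self.mean_max])


def _summary_from_values(vals: np.ndarray, row_max: np.ndarray) -> HWISummary:
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    cv = sd / mean if mean > 0 else float("nan")
    nz = vals[vals > 0]
    return HWISummary(
        mean=mean,
        cv=cv,
        mean_nonzero=float(nz.mean()) if nz.size else 0.0,
        prop_nonzero=float((vals > 0).mean()),
        mean_max=float(row_max.mean()),
        n_dyads=int(vals.size),
    )


def association_summary(m: DyadicMatrix) -> HWISummary:
    """Mean, CV (sd/mean), non-zero mean/proportion, and mean of each
    individual's maximum HWI, over all off-diagonal dyads.

    An all-zero matrix has an undefined CV, reported as NaN.
    """
    if m.n < 2:
        raise ValueError("need at least two individuals")
    vals = m.dyad_vector()
    row_max = np.nanmax(np.where(np.isnan(m.values), -np.inf, m.values), axis=1)
    return _summary_from_values(vals, row_max)


# ---------------------------------------------------------------------------
# data-stream permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationReport:
    observed: HWISummary
    null_mean: dict
    p_values: dict
    n_perm: int
    flips_per_perm: int
    burn_in: int
    seed: int | None
    informative: bool = True
    notes: str = ""
    null_samples: np.ndarray | None = field(default=None, repr=False)
    # final chain state (per-day group label per individual), for
    # diagnostics and invariant checks
    final_state: np.ndarray | None = field(default=None, repr=False)
    state_ids: list | None = field(default=None, repr=False)


def day_groups(record: DailyRecord) -> list[set]:
    """Groups of one day: connected components of the day's association
    graph (chain rule), plus singleton groups for unassociated
    identified individuals."""
    gr = nx.Graph()
    gr.add_nodes_from(record.identified)
    gr.add_edges_from(record.dyads)
    return [set(c) for c in nx.connected_components(gr)]


def _group_state(records, index):
    """Per-day integer group label per individual (-1 = not identified)."""
    D, n = len(records), len(index)
    state = np.full((D, n), -1, dtype=np.int32)
    for d, r in enumerate(records):
        for gid, grp in enumerate(day_groups(r)):
            for v in grp:
                state[d, index[v]] = gid
    return state


def _summary_from_state(state: np.ndarray, days: np.ndarray) -> HWISummary:
    ident = state >= 0
    same = (state[:, :, None] == state[:, None, :]) & ident[:, :, None] & ident[:, None, :]
    x = same.sum(axis=0).astype(float)
    np.fill_diagonal(x, 0.0)
    both = (ident.astype(np.int32).T @ ident.astype(np.int32)).astype(float)
    ya = days[:, None] - both
    yb = days[None, :] - both
    denom = x + (both - x) + 0.5 * (ya + yb)
    with np.errstate(divide="ignore", invalid="ignore"):
        hwi = np.where(denom > 0, x / denom, 0.0)
    np.fill_diagonal(hwi, -np.inf)
    row_max = hwi.max(axis=1)
    np.fill_diagonal(hwi, 0.0)
    iu = np.triu_indices(hwi.shape[0], k=1)
    return _summary_from_values(hwi[iu], row_max)


def permutation_test(
    records: list[DailyRecord],
    n_perm: int = 1000,
    flips_per_perm: int = 100,
    burn_in: int = 1000,
    seed: int | None = None,
) -> PermutationReport:
    """Preferred/avoided-companion test by sequential within-day swaps.

    Day-level groups are the connected components of each day's
    association graph.  The null chain swaps two individuals between two
    groups of the same day, which preserves exactly each day's group-size
    multiset and each individual's number of identified days.  After
    ``burn_in`` accepted swaps, one null dataset is scored every
    ``flips_per_perm`` accepted swaps, ``n_perm`` times.

    p-values follow the directional logic of preferred companionship:
    CV and mean non-zero use P(null >= observed); mean and proportion
    non-zero use P(null <= observed).  All use the add-one convention.
    """
    if len(records) < 2:
        raise ValueError("need at least two sampling periods")
    ids = sorted(set().union(*(r.identified for r in records)))
    if len(ids) < 3:
        raise ValueError("need at least three individuals")
    index = {v: k for k, v in enumerate(ids)}
    state = _group_state(records, index)
    days = (state >= 0).sum(axis=0).astype(float)
    observed = _summary_from_state(state, days)

    # days with at least two groups admit swaps
    n_groups = np.array([len({g for g in row if g >= 0}) for row in state])
    swappable = np.flatnonzero(n_groups >= 2)
    if swappable.size == 0:
        warnings.warn("no swappable day: permutation test is non-informative",
                      stacklevel=2)
        p1 = {k: 1.0 for k in ("mean", "cv", "mean_nonzero", "prop_nonzero")}
        return PermutationReport(
            observed=observed, null_mean={}, p_values=p1, n_perm=0,
            flips_per_perm=flips_per_perm, burn_in=burn_in, seed=seed,
            informative=False, notes="no degrees of freedom for swaps",
        )

    # members-per-(day, group) bookkeeping for O(1) swap proposals
    members = []  # per day: list of lists of individual indices
    for d in range(state.shape[0]):
        gids = sorted({g for g in state[d] if g >= 0})
        remap = {g: k for k, g in enumerate(gids)}
        row = [[] for _ in gids]
        for i in np.flatnonzero(state[d] >= 0):
            row[remap[state[d, i]]].append(int(i))
        state[d, state[d] >= 0] = [remap[g] for g in state[d][state[d] >= 0]]
        members.append(row)

    rng = np.random.default_rng(seed)

    def accepted_swap():
        d = int(swappable[rng.integers(swappable.size)])
        row = members[d]
        g1, g2 = rng.choice(len(row), size=2, replace=False)
        m1, m2 = row[g1], row[g2]
        k1 = int(rng.integers(len(m1)))
        k2 = int(rng.integers(len(m2)))
        i1, i2 = m1[k1], m2[k2]
        m1[k1], m2[k2] = i2, i1
        state[d, i1], state[d, i2] = g2, g1

    for _ in range(burn_in):
        accepted_swap()

    nulls = np.empty((n_perm, 5))
    for s in range(n_perm):
        for _ in range(flips_per_perm):
            accepted_swap()
        nulls[s] = _summary_from_state(state, days).as_array()

    obs = observed.as_array()
    names = ["mean", "cv", "mean_nonzero", "prop_nonzero", "mean_max"]
    ge = {"cv", "mean_nonzero", "mean_max"}
    p_values = {}
    null_mean = {}
    for k, name in enumerate(names):
        null_mean[name] = float(np.nanmean(nulls[:, k]))
        if name in ge:
            hits = int(np.sum(nulls[:, k] >= obs[k] - 1e-12))
        else:
            hits = int(np.sum(nulls[:, k] <= obs[k] + 1e-12))
        p_values[name] = (1 + hits) / (1 + n_perm)
    return PermutationReport(
        observed=observed, null_mean=null_mean, p_values=p_values,
        n_perm=n_perm, flips_per_perm=flips_per_perm, burn_in=burn_in,
        seed=seed, null_samples=nulls, final_state=state, state_ids=ids,
    )
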