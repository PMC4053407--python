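"""Ground-truthed synthetic populations: matrilineal social units with
pedigreed microsatellite genotypes, two-level correlated movement,
telemetry-like sampling, and dyadic association series with known
social-component mixtures.

The generator emulates the statistical structure of a boar-like study
population: spatially separated matrilineal units (philopatric females,
unaffiliated adult males), roughly 7 locations per individual per month,
16-locus genotypes with ~5% missing cells, and dyadic association time
series mixing constant companionships, casual acquaintances of finite
mean duration, and rapid (single-day) disassociations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .associations import DailyRecord, make_record
from .genetics import GenotypeTable
from .matrices import DyadicMatrix

SEXES = ("F", "M")
AGE_CLASSES = ("yearling", "subadult", "adult")


class SeedRequiredError(ValueError):
    pass


def _require_seed(seed):
    if seed is None:
        raise SeedRequiredError("an explicit integer seed is required; "
                                "simulated data must be reproducible")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# population / pedigree / genotypes
# ---------------------------------------------------------------------------

@dataclass
class AssociationMixture:
    """Proportions of association instances by social component.

    c_cc: constant companionships (permanent), c_ca: casual acquaintances
    with mean duration ``t_ca`` days; the remainder 1 - c_cc - c_ca are
    rapid disassociations lasting a single sampling day.
    """

    c_cc: float = 0.81
    c_ca: float = 0.10
    t_ca: float = 7.1

    def __post_init__(self):
        if not (0 <= self.c_cc <= 1 and 0 <= self.c_ca <= 1):
            raise ValueError("component proportions must be in [0, 1]")
        if self.c_cc + self.c_ca > 1 + 1e-12:
            raise ValueError("c_cc + c_ca must not exceed 1")
        if self.t_ca <= 0:
            raise ValueError("casual duration must be positive")

    @property
    def c_rd(self) -> float:
        return max(0.0, 1.0 - self.c_cc - self.c_ca)


@dataclass
class TruePopulation:
    individuals: pd.DataFrame      # id, sex, age_class, unit, mother, father
    pedigree: pd.DataFrame         # id, mother, father (includes hidden sires)
    unit_homes: np.ndarray         # (n_units, 2) home centres, metres
    allele_freqs: list             # per locus: np.ndarray of frequencies
    genotypes: GenotypeTable
    mixture: AssociationMixture = field(default_factory=AssociationMixture)
    movement: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.individuals["id"])

    @property
    def n_units(self) -> int:
        return int(self.unit_homes.shape[0])

    def unit_members(self, unit: int) -> list[str]:
        df = self.individuals
        return list(df.loc[df["unit"] == unit, "id"])

    def metadata(self) -> pd.DataFrame:
        return self.individuals[["id", "sex", "age_class"]].copy()

    def true_labels(self) -> dict:
        """Unit membership of affiliated individuals (solitary males are
        excluded; they carry unit -1)."""
        df = self.individuals
        return {r.id: int(r.unit) for r in df.itertuples() if r.unit >= 0}

    def write_truth(self, path: str | Path) -> None:
        truth = {
            "seed": self.seed,
            "units": {str(u): self.unit_members(u) for u in range(self.n_units)},
            "solitary_males": list(
                self.individuals.loc[self.individuals["unit"] < 0, "id"]),
            "pedigree": self.pedigree.where(pd.notna(self.pedigree), None)
                            .to_dict(orient="records"),
            "mixture": {"c_cc": self.mixture.c_cc, "c_ca": self.mixture.c_ca,
                        "t_ca": self.mixture.t_ca, "c_rd": self.mixture.c_rd},
            "movement": self.movement,
        }
        Path(path).write_text(json.dumps(truth, indent=2))


DEFAULT_MOVEMENT = {
    "range_sd_m": 800.0,          # stationary sd of the unit centroid
    "ar_phi": 0.9,                # day-to-day centroid autocorrelation
    "dispersion_sd_m": 100.0,     # member scatter around the centroid
    "male_range_sd_m": 1200.0,
    "unit_spacing_m": 3000.0,
    "fixes_per_month": 7.0,
    "co_obs_prob": 0.9,           # member observed near the unit's survey time
    "co_obs_time_sd_min": 10.0,
    "kin_preference": 0.0,        # mother-offspring displacement correlation
}


def gen_population(
    n_units: int = 6,
    mean_unit_size: float = 4.6,
    n_loci: int = 16,
    seed: int | None = None,
    n_solitary_males: int = 3,
    missing_rate: float = 0.054,
    allele_range: tuple = (3, 15),
    mixture: AssociationMixture | None = None,
    movement: dict | None = None,
    kin_structure: bool = True,
) -> TruePopulation:
    """Generate a matrilineal population with pedigree and genotypes.

    Each unit is founded by one adult female; further members are
    offspring of females already in the unit (mothers precede offspring),
    with hidden, unsampled sires (one or two mates per mother), so units
    contain mother-offspring, full-sib and half-sib dyads.  Founders'
    alleles are drawn from per-locus frequency tables (uniform over 3-15
    alleles by default); offspring inherit Mendelianly; about
    ``missing_rate`` of genotype cells are masked as missing.

    ``kin_structure=False`` keeps the same unit/sex/age composition but
    makes every individual an unrelated founder, so social units carry no
    kin signal - the null scenario in which any association structure is
    driven purely by shared space.
    """
    rng = _require_seed(seed)
    if n_units < 1 or mean_unit_size < 1:
        raise ValueError("need n_units >= 1 and mean_unit_size >= 1")

    lo, hi = allele_range
    allele_freqs = []
    for _ in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        allele_freqs.append(np.full(k, 1.0 / k))
    loci = [f"L{l + 1:02d}" for l in range(n_loci)]

    rows = []      # sampled individuals
    ped = []       # full pedigree incl. hidden sires
    hidden = []

    def new_sire(tag):
        sid = f"S{tag}"
        hidden.append(sid)
        ped.append({"id": sid, "mother": None, "father": None})
        return sid

    sizes = 1 + rng.poisson(max(0.0, mean_unit_size - 1), n_units)
    for u in range(n_units):
        founder = f"U{u + 1}F0"
        rows.append({"id": founder, "sex": "F", "age_class": "adult",
                     "unit": u, "mother": None, "father": None})
        ped.append({"id": founder, "mother": None, "father": None})
        mothers = [founder]
        mates: dict[str, list[str]] = {}
        for m in range(int(sizes[u]) - 1):
            mother = mothers[int(rng.integers(len(mothers)))]
            if mother not in mates:
                n_mates = 1 + int(rng.random() < 0.3)
                mates[mother] = [new_sire(f"{mother}x{j}") for j in range(n_mates)]
            father = mates[mother][int(rng.integers(len(mates[mother])))]
            sex = SEXES[int(rng.random() < 0.5)]
            age = AGE_CLASSES[int(rng.choice(3, p=[0.55, 0.25, 0.20]))]
            iid = f"U{u + 1}I{m + 1}"
            if not kin_structure:
                mother, father = None, None
            rows.append({"id": iid, "sex": sex, "age_class": age,
                         "unit": u, "mother": mother, "father": father})
            ped.append({"id": iid, "mother": mother, "father": father})
            if sex == "F" and age != "yearling":
                mothers.append(iid)
    for j in range(n_solitary_males):
        iid = f"M{j + 1}"
        rows.append({"id": iid, "sex": "M", "age_class": "adult",
                     "unit": -1, "mother": None, "father": None})
        ped.append({"id": iid, "mother": None, "father": None})

    individuals = pd.DataFrame(rows)
    pedigree = pd.DataFrame(ped)

    # genotypes over the full pedigree; parents precede offspring by build order
    geno: dict[str, np.ndarray] = {}
    for rec in ped:
        arr = np.empty((n_loci, 2), dtype=object)
        for l, freqs in enumerate(allele_freqs):
            labels = [str(100 + 2 * a) for a in range(len(freqs))]
            if rec["mother"] is None:
                arr[l] = rng.choice(labels, size=2, p=freqs)
            else:
                arr[l, 0] = geno[rec["mother"]][l, int(rng.integers(2))]
                arr[l, 1] = geno[rec["father"]][l, int(rng.integers(2))]
        geno[rec["id"]] = arr

    sampled = list(individuals["id"])
    alleles = np.stack([geno[i] for i in sampled])
    mask = rng.random((len(sampled), n_loci)) < missing_rate
    alleles[mask] = ""
    genotypes = GenotypeTable(sampled, loci, alleles)

    mv = dict(DEFAULT_MOVEMENT)
    mv.update(movement or {})
    # jittered grid of unit home centres guarantees spatial separation
    side = int(np.ceil(np.sqrt(n_units)))
    cells = [(i, j) for i in range(side) for j in range(side)]
    order = rng.permutation(len(cells))[:n_units]
    spacing = mv["unit_spacing_m"]
    homes = np.array([
        (cells[k][0] * spacing + rng.uniform(-0.15, 0.15) * spacing,
         cells[k][1] * spacing + rng.uniform(-0.15, 0.15) * spacing)
        for k in order
    ])

    return TruePopulation(
        individuals=individuals, pedigree=pedigree, unit_homes=homes,
        allele_freqs=allele_freqs, genotypes=genotypes,
        mixture=mixture or AssociationMixture(), movement=mv, seed=seed,
    )


def pedigree_relatedness(pop: TruePopulation) -> DyadicMatrix:
    """Expected (pedigree) relatedness between sampled individuals.

    Additive-relationship (tabular) computation over the full pedigree
    including hidden sires; founders are unrelated and non-inbred, so the
    values are the classical coefficients (parent-offspring and full sibs
    0.5, half sibs 0.25, unrelated 0).
    """
    ped = pop.pedigree
    ids = list(ped["id"])
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    parents = {
        r.id: (r.mother if isinstance(r.mother, str) else None,
               r.father if isinstance(r.father, str) else None)
        for r in ped.itertuples()
    }
    for j, jid in enumerate(ids):
        mo, fa = parents[jid]
        a[j, j] = 1.0  # founders are non-inbred; parents precede offspring
        for i in range(j):
            contrib = 0.0
            if mo is not None:
                contrib += 0.5 * a[i, idx[mo]]
            if fa is not None:
                contrib += 0.5 * a[i, idx[fa]]
            a[i, j] = a[j, i] = contrib
    sampled = pop.ids
    sub = np.array([[a[idx[i], idx[j]] for j in sampled] for i in sampled])
    np.fill_diagonal(sub, np.nan)
    return DyadicMatrix(sampled, sub, kind="relatedness")


# ---------------------------------------------------------------------------
# movement and telemetry sampling
# ---------------------------------------------------------------------------

def gen_movement(
    pop: TruePopulation,
    months: int = 8,
    seed: int | None = None,
    start: datetime = datetime(2008, 1, 1),
) -> pd.DataFrame:
    """Simulate daily movement and telemetry-like observation.

    Unit centroids follow a mean-reverting AR(1) around fixed home
    centres (stationary sd ``range_sd_m``); members scatter around the
    centroid with sd ``dispersion_sd_m``, offspring displacements
    correlated with their mother's by ``kin_preference``; solitary males
    range independently and more widely.  Each individual is observed on
    a day with probability fixes_per_month / 30, unit-mates near a shared
    survey time (so they fall inside the 1-h simultaneity window), with
    probability ``co_obs_prob``.
    """
    rng = _require_seed(seed)
    if months < 1:
        raise ValueError("months must be >= 1")
    mv = pop.movement
    phi = mv["ar_phi"]
    innov = mv["range_sd_m"] * np.sqrt(1 - phi ** 2)
    disp_sd = mv["dispersion_sd_m"]
    rho = float(mv.get("kin_preference", 0.0))
    if not (0 <= rho < 1):
        raise ValueError("kin_preference must be in [0, 1)")
    p_obs = mv["fixes_per_month"] / 30.0
    n_days = int(months * 30)

    df = pop.individuals
    units = {u: pop.unit_members(u) for u in range(pop.n_units)}
    males = list(df.loc[df["unit"] < 0, "id"])
    mother_of = {r.id: r.mother for r in df.itertuples()}
    unit_of = {r.id: int(r.unit) for r in df.itertuples()}

    centroids = {u: pop.unit_homes[u].astype(float).copy() for u in units}
    male_home = {m: pop.unit_homes[int(rng.integers(pop.n_units))]
                 + rng.normal(0, mv["unit_spacing_m"], 2) for m in males}
    male_pos = {m: male_home[m].astype(float).copy() for m in males}

    rows = []
    t_sd_s = mv["co_obs_time_sd_min"] * 60.0
    for d in range(n_days):
        day0 = start + timedelta(days=d)
        for u, members in units.items():
            centroids[u] = (pop.unit_homes[u]
                            + phi * (centroids[u] - pop.unit_homes[u])
                            + rng.normal(0, innov, 2))
            t_unit = rng.uniform(0, 86400)
            disp: dict[str, np.ndarray] = {}
            for ind in members:  # mothers precede offspring by build order
                eps = rng.normal(0, disp_sd, 2)
                mo = mother_of[ind]
                if rho > 0 and isinstance(mo, str) and unit_of.get(mo) == u and mo in disp:
                    disp[ind] = rho * disp[mo] + np.sqrt(1 - rho ** 2) * eps
                else:
                    disp[ind] = eps
                if rng.random() >= p_obs:
                    continue
                if rng.random() < mv["co_obs_prob"]:
                    t = t_unit + rng.normal(0, t_sd_s)
                else:
                    t = rng.uniform(0, 86400)
                x, y = centroids[u] + disp[ind]
                rows.append((ind, day0 + timedelta(seconds=float(np.clip(t, 0, 86399))),
                             x, y))
        for m in males:
            male_pos[m] = (male_home[m] + phi * (male_pos[m] - male_home[m])
                           + rng.normal(0, mv["male_range_sd_m"] * np.sqrt(1 - phi ** 2), 2))
            if rng.random() < p_obs:
                t = rng.uniform(0, 86400)
                x, y = male_pos[m] + rng.normal(0, disp_sd, 2)
                rows.append((m, day0 + timedelta(seconds=float(t)), x, y))
    fixes = pd.DataFrame(rows, columns=["individual_id", "timestamp", "x", "y"])
    return fixes.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# direct dyadic association series
# ---------------------------------------------------------------------------

def _allocate_counts(shares: dict, rates: dict, n_dyads: int) -> dict:
    """Integer dyad counts proportional to share_k / per-dyad rate_k
    (largest-remainder rounding; classes with positive share get >= 1)."""
    weights = {k: (shares[k] / rates[k] if rates[k] > 0 else 0.0) for k in shares}
    total = sum(weights.values())
    if total == 0:
        raise ValueError("mixture has no mass")
    frac = {k: w / total * n_dyads for k, w in weights.items()}
    counts = {k: int(np.floor(v)) for k, v in frac.items()}
    rem = sorted(frac, key=lambda k: frac[k] - counts[k], reverse=True)
    i = 0
    while sum(counts.values()) < n_dyads:
        counts[rem[i % len(rem)]] += 1
        i += 1
    for k in counts:
        if shares[k] > 0 and counts[k] == 0 and n_dyads >= 3:
            donor = max(counts, key=counts.get)
            counts[donor] -= 1
            counts[k] += 1
    return counts


def _series_design(mixture: AssociationMixture, n_dyads: int,
                   casual_gap_days: float, rapid_rate: float) -> tuple:
    """Dyad allocation and calibrated per-class rates.

    The mixture proportions are the component proportions an
    exponential-decay model fit should recover.  Casual and rapid dyads
    re-associate with small stationary probability (u_ca ~ t_ca / gap,
    u_rd = rapid rate), which feeds a little of their mass into the
    model's constant term; the instance-share targets are therefore
    s_ca = c_ca / (1 - u_ca), s_rd = c_rd / (1 - u_rd), s_cc the
    remainder.  After integer allocation the rates are recalibrated so
    the expected instance shares hit the targets exactly; one fixed-point
    sweep suffices because the u's are small.
    """
    u_ca = min(0.5, mixture.t_ca / casual_gap_days)
    u_rd = min(0.5, rapid_rate)
    counts = None
    for _ in range(3):
        s_ca = mixture.c_ca / (1.0 - u_ca)
        s_rd = mixture.c_rd / (1.0 - u_rd)
        s_cc = max(0.0, 1.0 - s_ca - s_rd)
        tot = s_cc + s_ca + s_rd
        shares = {"cc": s_cc / tot, "ca": s_ca / tot, "rd": s_rd / tot}
        counts = _allocate_counts(shares, {"cc": 1.0, "ca": u_ca, "rd": u_rd},
                                  n_dyads)
        # recalibrate rates so realised expected shares equal the targets
        if counts["cc"] > 0 and shares["cc"] > 0:
            base = counts["cc"] / shares["cc"]
        elif counts["ca"] > 0 and shares["ca"] > 0:
            base = counts["ca"] * u_ca / shares["ca"]
        else:
            break
        if counts["ca"] > 0 and shares["ca"] > 0:
            u_ca = min(0.9, shares["ca"] * base / counts["ca"])
        if counts["rd"] > 0 and shares["rd"] > 0:
            u_rd = min(0.5, shares["rd"] * base / counts["rd"])
    return counts, mixture.t_ca / u_ca if u_ca > 0 else casual_gap_days, u_rd


def gen_association_series(
    n_dyads: int = 30,
    mixture: AssociationMixture | tuple | None = None,
    n_days: int = 400,
    seed: int | None = None,
    sampling_prob: float = 0.9,
    casual_gap_days: float | None = None,
    rapid_rate: float = 0.05,
) -> list[DailyRecord]:
    """Daily association records for independent dyads with a known
    social-component mixture.

    Dyads are disjoint pairs.  Constant dyads associate on every
    co-sampled day.  Casual dyads associate in bouts whose start times
    are a Poisson process (mean gap ``casual_gap_days``) and whose
    durations are exponential with the mixture's mean duration - the
    memoryless bout makes the dyad's lagged association decay exactly
    exponentially.  Rapid dyads associate on scattered single days
    (rate ``rapid_rate``).  Both members are sampled each day with
    probability ``sampling_prob``.
    """
    rng = _require_seed(seed)
    if mixture is None:
        mixture = AssociationMixture()
    elif isinstance(mixture, tuple):
        mixture = AssociationMixture(*mixture)
    if n_dyads < 1 or n_days < 2:
        raise ValueError("need n_dyads >= 1 and n_days >= 2")
    if casual_gap_days is None:
        # gaps one order of magnitude longer than the bout duration:
        # "long" relative to an acquaintance, several bouts per study
        casual_gap_days = 10.0 * mixture.t_ca
    counts, casual_gap_days, rapid_rate = _series_design(
        mixture, n_dyads, casual_gap_days, rapid_rate)

    classes = ["cc"] * counts["cc"] + ["ca"] * counts["ca"] + ["rd"] * counts["rd"]
    on = np.zeros((n_days, n_dyads), dtype=bool)
    t_eval = np.arange(n_days, dtype=float)
    horizon = 8.0 * mixture.t_ca
    for p, cls in enumerate(classes):
        if cls == "cc":
            on[:, p] = True
        elif cls == "ca":
            span = n_days + horizon
            n_bouts = rng.poisson(span / casual_gap_days)
            starts = rng.uniform(-horizon, n_days, size=n_bouts)
            durs = rng.exponential(mixture.t_ca, size=n_bouts)
            for s, du in zip(starts, durs):
                on[:, p] |= (t_eval >= s) & (t_eval < s + du)
        else:
            raw = rng.random(n_days) < rapid_rate
            # rapid disassociations are single scattered days: suppress the
            # second of any consecutive run
            for t in range(1, n_days):
                raw[t] = raw[t] and not raw[t - 1]
            on[:, p] = raw

    sampled = rng.random((n_days, 2 * n_dyads)) < sampling_prob
    width = len(str(n_dyads))
    names = [(f"d{p + 1:0{width}d}a", f"d{p + 1:0{width}d}b")
             for p in range(n_dyads)]
    records = []
    for d in range(n_days):
        identified = [names[p][s] for p in range(n_dyads) for s in (0, 1)
                      if sampled[d, 2 * p + s]]
        dyads = [names[p] for p in range(n_dyads)
                 if on[d, p] and sampled[d, 2 * p] and sampled[d, 2 * p + 1]]
        records.append(make_record(d, identified, dyads))
    return records
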