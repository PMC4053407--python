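import itertools

import numpy as np
import pytest

from sociokin.associations import DailyRecord, make_record
from sociokin.genetics import GenotypeTable
from sociokin.matrices import DyadicMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_genotypes(rng, n=12, n_loci=5, n_alleles=6, missing=0.0):
    labels = [str(100 + 2 * a) for a in range(n_alleles)]
    arr = np.empty((n, n_loci, 2), dtype=object)
    for i in range(n):
        for l in range(n_loci):
            arr[i, l] = rng.choice(labels, 2)
    if missing > 0:
        mask = rng.random((n, n_loci)) < missing
        arr[mask] = ""
    return GenotypeTable([f"i{i:02d}" for i in range(n)],
                         [f"L{l}" for l in range(n_loci)], arr)


def random_daily_records(rng, n_ind=8, n_days=12, p_present=0.8, p_group=0.5):
    """Random group-structured daily records (no preference)."""
    ids = [f"i{k:02d}" for k in range(n_ind)]
    records = []
    for d in range(n_days):
        present = [i for i in ids if rng.random() < p_present]
        rng.shuffle(present)
        groups, cur = [], []
        for m in present:
            cur.append(m)
            if rng.random() < p_group:
                groups.append(cur)
                cur = []
        if cur:
            groups.append(cur)
        dyads = [pair for g in groups for pair in itertools.combinations(g, 2)]
        records.append(make_record(d, present, dyads))
    return records


def random_dyadic(rng, n=8, kind="relatedness", ids=None):
    a = rng.normal(0, 1, (n, n))
    a = (a + a.T) / 2
    if kind in ("association", "overlap"):
        a = 1 / (1 + np.exp(-a))
    np.fill_diagonal(a, np.nan)
    return DyadicMatrix(ids or [f"i{k:02d}" for k in range(n)], a, kind)


def clique_records(n_days=30, size=4, n_cliques=2):
    """Two (or more) fixed cliques observed every day: maximal
    companion preference."""
    records = []
    for d in range(n_days):
        ids, dyads = [], []
        for c in range(n_cliques):
            members = [f"c{c}m{k}" for k in range(size)]
            ids += members
            dyads += list(itertools.combinations(members, 2))
        records.append(make_record(d, ids, dyads))
    return records


# brute-force HWI oracle used by associations and acceptance tests
def hwi_brute(records):
    ids = sorted(set().union(*(r.identified for r in records)))
    vals = {}
    for a, b in itertools.combinations(ids, 2):
        x = ya = yb = yab = 0
        for r in records:
            ia, ib = a in r.identified, b in r.identified
            assoc = tuple(sorted((a, b))) in r.dyads
            if assoc:
                x += 1
            elif ia and ib:
                yab += 1
            elif ia:
                ya += 1
            elif ib:
                yb += 1
        denom = x + yab + 0.5 * (ya + yb)
        vals[(a, b)] = x / denom if denom > 0 else 0.0
    return ids, vals


# brute-force LAR oracle: literal triple loop over the definition
def lar_brute(records, denominator="identified"):
    days = sorted(records, key=lambda r: r.day)
    num, den = {}, {}
    for i1, r1 in enumerate(days):
        for r2 in days[i1 + 1:]:
            lag = (r2.day - r1.day) if isinstance(r1.day, int) else (r2.day - r1.day).days
            for a, b in r1.dyads:
                n = 1 if tuple(sorted((a, b))) in r2.dyads else 0
                if denominator == "identified":
                    d = 1 if (a in r2.identified and b in r2.identified) else 0
                    num[lag] = num.get(lag, 0) + n
                    den[lag] = den.get(lag, 0) + d
                else:
                    na = sum(1 for x, y in r2.dyads if a in (x, y)) if a in r2.identified else 0
                    nb = sum(1 for x, y in r2.dyads if b in (x, y)) if b in r2.identified else 0
                    num[lag] = num.get(lag, 0) + 2 * n
                    den[lag] = den.get(lag, 0) + na + nb
    return num, den
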