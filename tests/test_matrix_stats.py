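import itertools

import numpy as np
import pytest

from sociokin.matrices import DyadicMatrix
from sociokin.matrix_stats import mantel, partial_mantel, within_between_test
from sociokin.network import Partition
from tests.conftest import random_dyadic


def mantel_exhaustive_p(x, y, alternative="two-sided"):
    """Oracle: enumerate all joint relabelings of y directly."""
    n = x.n
    iu = np.triu_indices(n, 1)
    xv = x.values[iu]

    def corr(v):
        return np.corrcoef(xv, v)[0, 1]

    obs = corr(y.values[iu])
    null = [corr(y.values[np.ix_(p, p)][iu])
            for p in itertools.permutations(range(n))]
    null = np.array(null)
    if alternative == "two-sided":
        return np.mean(np.abs(null) >= abs(obs) - 1e-12)
    return np.mean(null >= obs - 1e-12)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        m = random_dyadic(rng, 6)
        assert mantel(m, m, n_perm=49, seed=0).statistic == pytest.approx(1.0)

    def test_exact_mode_equals_exhaustive_oracle(self, rng):
        for seed in range(5):
            x = random_dyadic(np.random.default_rng(seed), 4)
            y = random_dyadic(np.random.default_rng(seed + 100), 4)
            res = mantel(x, y, seed=0, method="exact")
            assert res.p == pytest.approx(mantel_exhaustive_p(x, y))
            assert res.n_permutations == 24

    def test_monte_carlo_approaches_exact(self, rng):
        x, y = random_dyadic(rng, 5), random_dyadic(rng, 5)
        exact = mantel(x, y, method="exact").p
        mc = mantel(x, y, n_perm=4000, seed=1).p
        assert mc == pytest.approx(exact, abs=0.03)

    def test_statistic_symmetric_in_arguments(self, rng):
        x, y = random_dyadic(rng, 7), random_dyadic(rng, 7)
        assert mantel(x, y, n_perm=9, seed=0).statistic == pytest.approx(
            mantel(y, x, n_perm=9, seed=0).statistic)

    def test_constant_matrix_rejected(self):
        ids = list("abcd")
        const = DyadicMatrix(ids, np.where(np.eye(4, dtype=bool), np.nan, 0.3),
                             "association")
        with pytest.raises(ValueError, match="constant"):
            mantel(const, const, n_perm=9, seed=0)

    def test_subset_and_alignment(self, rng):
        x = random_dyadic(rng, 8)
        y = random_dyadic(rng, 8, ids=x.ids[::-1])
        res = mantel(x, y, n_perm=9, seed=0, subset=x.ids[:5])
        assert res.n_dyads == 10

    def test_seed_reproducibility(self, rng):
        x, y = random_dyadic(rng, 6), random_dyadic(rng, 6)
        a = mantel(x, y, n_perm=200, seed=42)
        b = mantel(x, y, n_perm=200, seed=42)
        assert a.p == b.p and a.statistic == b.statistic


class TestPartialMantel:
    def test_control_equal_to_y_gives_zero(self, rng):
        x, z = random_dyadic(rng, 6), random_dyadic(rng, 6)
        res = partial_mantel(x, z, z, n_perm=9, seed=0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_uncorrelated_control_matches_plain_mantel(self):
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(20):
            x = random_dyadic(rng, 50)
            y = random_dyadic(rng, 50, ids=x.ids)
            z = random_dyadic(rng, 50, ids=x.ids)
            r_plain = mantel(x, y, n_perm=9, seed=0).statistic
            r_part = partial_mantel(x, y, z, n_perm=9, seed=0).statistic
            diffs.append(r_part - r_plain)
        assert abs(np.mean(diffs)) < 0.02

    def test_collinear_x_rejected(self, rng):
        z = random_dyadic(rng, 6)
        y = random_dyadic(rng, 6, ids=z.ids)
        with pytest.raises(ValueError, match="collinear"):
            partial_mantel(z, y, z, n_perm=9, seed=0)

    def test_raw_permutation_variant_agrees_roughly(self, rng):
        z = random_dyadic(rng, 12)
        x = DyadicMatrix(z.ids, 0.6 * z.values + 0.4 * random_dyadic(rng, 12).values,
                         "relatedness")
        y = random_dyadic(rng, 12, ids=z.ids)
        p_res = partial_mantel(x, y, z, n_perm=999, seed=0).p
        p_raw = partial_mantel(x, y, z, n_perm=999, seed=0, permute="raw").p
        assert abs(p_res - p_raw) < 0.2


class TestWithinBetween:
    def _partition(self, labels):
        ids = [f"i{k}" for k in range(len(labels))]
        return ids, Partition(ids=ids, labels=np.array(labels), q=0.0)

    def test_identical_values_give_zero_and_p_one(self):
        ids, part = self._partition([0, 0, 1, 1])
        vals = DyadicMatrix(ids, np.where(np.eye(4, dtype=bool), np.nan, 0.7),
                            "overlap")
        res = within_between_test(vals, part, n_perm=99, seed=0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_statistic_and_exact_p(self, rng):
        ids, part = self._partition([0, 0, 0, 1, 1, 1])
        m = random_dyadic(rng, 6, ids=ids)
        res = within_between_test(m, part, method="exact")
        # brute statistic
        iu = np.triu_indices(6, 1)
        labels = np.array([0, 0, 0, 1, 1, 1])
        same = (labels[:, None] == labels[None, :])[iu]
        vals = m.values[iu]
        assert res.statistic == pytest.approx(
            vals[same].mean() - vals[~same].mean())
        # exact p by enumerating all distinct labelings
        null = []
        for perm in set(itertools.permutations(labels)):
            s = (np.array(perm)[:, None] == np.array(perm)[None, :])[iu]
            null.append(vals[s].mean() - vals[~s].mean())
        expected_p = np.mean(np.abs(null) >= abs(res.statistic) - 1e-12)
        assert res.p == pytest.approx(expected_p)

    def test_monte_carlo_matches_exact(self, rng):
        ids, part = self._partition([0, 0, 1, 1, 1])
        m = random_dyadic(rng, 5, ids=ids)
        exact = within_between_test(m, part, method="exact").p
        mc = within_between_test(m, part, n_perm=4000, seed=1).p
        assert mc == pytest.approx(exact, abs=0.03)

    def test_dyad_class_filter(self, rng):
        ids, part = self._partition([0, 0, 0, 1, 1, 1])
        m = random_dyadic(rng, 6, ids=ids)
        meta = {i: ("adult_F" if k % 2 == 0 else "adult_M")
                for k, i in enumerate(ids)}
        res = within_between_test(m, part, dyad_filter=("adult_F", "adult_F"),
                                  metadata=meta, n_perm=99, seed=0)
        assert res.n_dyads == 3  # C(3,2) female-female dyads
        with pytest.raises(ValueError, match="metadata"):
            within_between_test(m, part, dyad_filter=("adult_F", "adult_F"))

    def test_single_unit_rejected(self):
        ids, part = self._partition([0, 0, 0])
        m = DyadicMatrix(ids, np.where(np.eye(3, dtype=bool), np.nan, 0.5),
                         "overlap")
        with pytest.raises(ValueError, match="two units"):
            within_between_test(m, part, n_perm=9, seed=0)
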