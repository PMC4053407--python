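import collections
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sociokin.genetics import (
    GenotypeFormatError,
    GenotypeTable,
    allele_frequencies,
    allelic_richness,
    diversity_stats,
    hwe_test,
    qg_relatedness,
    sequential_bonferroni,
)
from tests.conftest import random_genotypes


def table(cells, loci=None):
    """cells: list per individual of list per locus of 'a/b' or ''."""
    n, L = len(cells), len(cells[0])
    arr = np.empty((n, L, 2), dtype=object)
    for i, row in enumerate(cells):
        for l, cell in enumerate(row):
            arr[i, l] = cell.split("/") if cell else ["", ""]
    return GenotypeTable([f"i{i}" for i in range(n)],
                         loci or [f"L{l}" for l in range(L)], arr)


class TestAlleleFrequencies:
    def test_fixed_allele(self):
        f = allele_frequencies(table([["a/a"], ["a/a"]]))
        assert f["L0"]["a"] == 1.0

    def test_even_counting(self):
        f = allele_frequencies(table([["a/a"], ["a/b"], ["b/b"]]))["L0"]
        assert f["a"] == 0.5 and f["b"] == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_tally(self, seed):
        g = random_genotypes(np.random.default_rng(seed), n=15, n_loci=4, missing=0.1)
        freqs = allele_frequencies(g)
        for l, locus in enumerate(g.loci):
            tally = collections.Counter()
            for i in range(g.n_individuals):
                a, b = g.alleles[i, l]
                if a:
                    tally[a] += 1
                    tally[b] += 1
            total = sum(tally.values())
            for allele, count in tally.items():
                assert freqs[locus][allele] == pytest.approx(count / total)

    def test_untyped_locus_excluded_with_warning(self):
        g = table([["a/a", ""], ["a/b", ""]])
        with pytest.warns(UserWarning, match="excluded"):
            f = allele_frequencies(g)
        assert list(f) == ["L0"]


def qg_brute(g, freqs):
    """Literal per-pair evaluation of the directional estimator."""
    n = g.n_individuals
    out = np.full((n, n), np.nan)
    for i, j in itertools.permutations(range(n), 2):
        sn = sd = 0.0
        shared = 0
        for l, locus in enumerate(g.loci):
            a, b = g.alleles[i, l]
            c, d = g.alleles[j, l]
            if not a or not c:
                continue
            shared += 1
            p = freqs[locus]
            sn += 0.5 * ((a == c) + (a == d) + (b == c) + (b == d)) - p[a] - p[b]
            sd += 1 + (a == b) - p[a] - p[b]
        if shared:
            out[i, j] = sn / sd
    return 0.5 * (out + out.T)


class TestQGRelatedness:
    def test_identical_homozygotes_are_fully_related(self):
        # third individual keeps p_a below 1
        g = table([["a/a"], ["a/a"], ["a/b"]])
        r = qg_relatedness(g)
        assert r.values[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_at_even_frequencies(self):
        g = table([["a/a"], ["b/b"]])
        r = qg_relatedness(g)
        assert r.values[0, 1] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        g = random_genotypes(np.random.default_rng(seed), n=10, n_loci=6, missing=0.1)
        r = qg_relatedness(g)
        expected = qg_brute(g, allele_frequencies(g))
        np.testing.assert_allclose(r.values, expected, atol=1e-10)

    def test_symmetric_and_relabel_invariant(self, rng):
        g = random_genotypes(rng, n=8, n_loci=5)
        r = qg_relatedness(g)
        np.testing.assert_allclose(r.values, r.values.T, atol=1e-12)
        # bijective allele relabeling leaves the estimate unchanged
        relabeled = g.alleles.copy()
        mapping = {str(100 + 2 * a): f"X{a}" for a in range(6)}
        for idx, v in np.ndenumerate(relabeled):
            relabeled[idx] = mapping.get(v, v)
        g2 = GenotypeTable(g.ids, g.loci, relabeled)
        np.testing.assert_allclose(qg_relatedness(g2).values, r.values, atol=1e-12)

    def test_unrelated_population_mean_near_zero(self):
        g = random_genotypes(np.random.default_rng(11), n=200, n_loci=16, n_alleles=8)
        r = qg_relatedness(g)
        iu = np.triu_indices(200, 1)
        assert abs(np.nanmean(r.values[iu])) < 0.01

    def test_pair_sharing_no_locus_is_nan(self):
        g = table([["a/b", ""], ["", "c/d"], ["a/a", "c/c"]])
        r = qg_relatedness(g)
        assert np.isnan(r.values[0, 1])
        assert ("i0", "i1") in r.flags["no_shared_locus_pairs"]

    def test_exclude_pair_frequencies_differ_but_agree_in_sign(self):
        g = random_genotypes(np.random.default_rng(2), n=30, n_loci=8)
        r_full = qg_relatedness(g, frequencies="full")
        r_ex = qg_relatedness(g, frequencies="exclude-pair")
        assert not np.allclose(r_full.values, r_ex.values, equal_nan=True)
        # both should agree closely at this sample size
        iu = np.triu_indices(30, 1)
        assert np.corrcoef(r_full.values[iu], r_ex.values[iu])[0, 1] > 0.98


class TestDiversity:
    def test_rarefaction_hand_example(self):
        # counts {a:3, b:1}, N=4, n=2: [1 - C(1,2)/C(4,2)] + [1 - C(3,2)/C(4,2)]
        assert allelic_richness(np.array([3, 1]), 2) == pytest.approx(1.5)

    def test_all_heterozygous_sample(self):
        g = table([["a/b"], ["a/b"], ["a/b"], ["a/b"]])
        d = diversity_stats(g)
        assert d.loc["L0", "ho"] == 1.0
        assert d.loc["L0", "he"] == pytest.approx(0.5)

    def test_uniform_four_alleles_he_converges(self):
        g = random_genotypes(np.random.default_rng(4), n=400, n_loci=1, n_alleles=4)
        assert diversity_stats(g).loc["L0", "he"] == pytest.approx(0.75, abs=0.01)

    def test_monomorphic_locus_reported_not_errored(self):
        g = table([["a/a", "a/b"], ["a/a", "b/b"]])
        d = diversity_stats(g)
        assert d.loc["L0", "he"] == 0.0 and d.loc["L0", "na"] == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_recount(self, seed):
        g = random_genotypes(np.random.default_rng(seed), n=20, n_loci=5, missing=0.08)
        d = diversity_stats(g)
        for l, locus in enumerate(g.loci):
            typed = [tuple(g.alleles[i, l]) for i in range(20) if g.alleles[i, l][0]]
            alleles = [a for pair in typed for a in pair]
            counts = collections.Counter(alleles)
            n = len(alleles)
            assert d.loc[locus, "na"] == len(counts)
            he = 1 - sum((c / n) ** 2 for c in counts.values())
            assert d.loc[locus, "he"] == pytest.approx(he)
            ho = np.mean([a != b for a, b in typed])
            assert d.loc[locus, "ho"] == pytest.approx(ho)

    def test_rarefaction_n_validated(self, rng):
        g = random_genotypes(rng, n=5, n_loci=2)
        with pytest.raises(ValueError, match="rarefaction"):
            diversity_stats(g, rarefaction_n=100)


class TestHWE:
    def test_proportions_at_equilibrium_not_rejected(self):
        # 25 aa / 50 ab / 25 bb: exactly Hardy-Weinberg
        g = table([["a/a"]] * 25 + [["a/b"]] * 50 + [["b/b"]] * 25)
        assert hwe_test(g, "L0", n_reps=400, seed=1) >= 0.5

    def test_extreme_homozygote_excess_rejected(self):
        g = table([["a/a"]] * 25 + [["b/b"]] * 25)
        assert hwe_test(g, "L0", n_reps=400, seed=1) < 0.01
        assert hwe_test(g, "L0", n_reps=400, seed=1, alternative="deficit") < 0.01

    def test_monomorphic_locus_p_one(self):
        g = table([["a/a"]] * 6)
        assert hwe_test(g, "L0", n_reps=100, seed=0) == 1.0

    def test_too_few_individuals_rejected(self):
        g = table([["a/b"]] * 4)
        with pytest.raises(GenotypeFormatError, match=">=5"):
            hwe_test(g, "L0")

    def test_type_one_error_near_nominal(self):
        # 1000 loci simulated under Hardy-Weinberg: rejection at 0.05
        # should land near the nominal rate
        rng = np.random.default_rng(123)
        labels = ["a", "b", "c", "d"]
        rej = 0
        n_sim = 1000
        for _ in range(n_sim):
            copies = rng.choice(labels, size=(50, 2))
            g = GenotypeTable([f"i{k}" for k in range(50)], ["L"],
                              copies.reshape(50, 1, 2).astype(object))
            rej += hwe_test(g, "L", n_reps=200, seed=int(rng.integers(2 ** 31))) <= 0.05
        assert 0.03 <= rej / n_sim <= 0.07


class TestSequentialBonferroni:
    def test_single_test_is_raw_comparison(self):
        assert sequential_bonferroni([0.04], 0.05).tolist() == [True]
        assert sequential_bonferroni([0.06], 0.05).tolist() == [False]

    def test_holm_hand_example(self):
        # 0.001 < 0.05/2 then 0.04 < 0.05/1
        assert sequential_bonferroni([0.001, 0.04], 0.05).tolist() == [True, True]

    def test_stops_at_first_failure(self):
        # sorted: 0.001 < 0.05/3; 0.03 >= 0.05/2 stops; 0.04 retained too
        assert sequential_bonferroni([0.03, 0.001, 0.04], 0.05).tolist() == \
            [False, True, False]

    def test_all_ones_and_empty(self):
        assert not sequential_bonferroni([1.0, 1.0, 1.0]).any()
        assert sequential_bonferroni([]).size == 0

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_holm_flags_are_monotone_in_p(self, pvals):
        """If a hypothesis is rejected, every hypothesis with a smaller
        or equal p-value is rejected too."""
        flags = sequential_bonferroni(pvals, 0.05)
        for i, fi in enumerate(flags):
            if fi:
                for j in range(len(pvals)):
                    if pvals[j] <= pvals[i]:
                        assert flags[j]
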