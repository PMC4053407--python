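import numpy as np
import pandas as pd
import pytest

import sociokin as sk
from sociokin.simulate import (
    AssociationMixture,
    SeedRequiredError,
    _series_design,
    gen_association_series,
    gen_movement,
    gen_population,
    pedigree_relatedness,
)


class TestMixture:
    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            AssociationMixture(0.7, 0.5, 3.0)
        with pytest.raises(ValueError):
            AssociationMixture(0.5, 0.1, -1.0)

    def test_rapid_is_remainder(self):
        assert AssociationMixture(0.81, 0.10, 7.1).c_rd == pytest.approx(0.09)


class TestPopulation:
    def test_seed_is_mandatory(self):
        with pytest.raises(SeedRequiredError):
            gen_population()

    def test_identical_seeds_identical_outputs(self):
        a = gen_population(seed=3)
        b = gen_population(seed=3)
        pd.testing.assert_frame_equal(a.individuals, b.individuals)
        assert a.genotypes == b.genotypes
        np.testing.assert_array_equal(a.unit_homes, b.unit_homes)
        c = gen_population(seed=4)
        assert not a.individuals.equals(c.individuals) or a.genotypes != c.genotypes

    def test_single_founder_unit(self):
        pop = gen_population(n_units=1, mean_unit_size=1, seed=1,
                             n_solitary_males=0)
        assert len(pop.ids) == 1
        assert pop.individuals.iloc[0]["mother"] is None

    def test_matriline_structure(self):
        pop = gen_population(seed=7)
        df = pop.individuals
        for row in df.dropna(subset=["mother"]).itertuples():
            mother = df.set_index("id").loc[row.mother]
            assert mother["unit"] == row.unit
            assert mother["sex"] == "F"
        # solitary males unaffiliated
        assert (df.loc[df["unit"] < 0, "sex"] == "M").all()

    def test_missingness_matches_configuration(self):
        pop = gen_population(n_units=14, mean_unit_size=5, n_loci=16, seed=11)
        n_cells = pop.genotypes.n_individuals * 16
        assert n_cells >= 1000
        assert pop.genotypes.missing_fraction() == pytest.approx(0.054, abs=0.01)

    def test_pedigree_relatedness_expectation_classes(self):
        pop = gen_population(seed=5)
        ped = pedigree_relatedness(pop)
        df = pop.individuals.set_index("id")
        idx = {v: k for k, v in enumerate(ped.ids)}
        for row in df.dropna(subset=["mother"]).itertuples():
            assert ped.values[idx[row.Index], idx[row.mother]] == pytest.approx(0.5)
        founders = [i for i in pop.ids if i.endswith("F0")]
        for a in founders:
            for b in founders:
                if a != b:
                    assert ped.values[idx[a], idx[b]] == 0.0

    def test_no_kin_structure_mode(self):
        pop = gen_population(seed=5, kin_structure=False)
        ped = pedigree_relatedness(pop)
        off = ped.values[np.triu_indices(len(ped.ids), 1)]
        assert np.nanmax(off) == 0.0


class TestMovement:
    def test_seed_required_and_deterministic(self):
        pop = gen_population(seed=1)
        with pytest.raises(SeedRequiredError):
            gen_movement(pop, months=1)
        a = gen_movement(pop, months=1, seed=2)
        b = gen_movement(pop, months=1, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_fix_rate_matches_target(self):
        # mean fixes per individual per month within +-1 of 7 over 20 seeds
        rates = []
        for s in range(20):
            pop = gen_population(n_units=3, mean_unit_size=4, seed=100 + s,
                                 n_solitary_males=1)
            fx = gen_movement(pop, months=2, seed=200 + s)
            rates.append(len(fx) / len(pop.ids) / 2)
        assert abs(np.mean(rates) - 7.0) <= 1.0

    def test_zero_dispersion_unit_mates_always_associated(self):
        pop = gen_population(n_units=1, mean_unit_size=6, seed=3,
                             n_solitary_males=0,
                             movement={"dispersion_sd_m": 1e-6,
                                       "co_obs_prob": 1.0,
                                       "co_obs_time_sd_min": 1.0})
        fx = gen_movement(pop, months=3, seed=4)
        recs = sk.detect_associations(fx)
        for r in recs:
            # every co-identified pair is associated (same place, same survey)
            n = len(r.identified)
            assert len(r.dyads) == n * (n - 1) // 2

    def test_distant_units_never_associate(self):
        pop = gen_population(n_units=2, mean_unit_size=4, seed=5,
                             n_solitary_males=0,
                             movement={"unit_spacing_m": 10000.0,
                                       "range_sd_m": 200.0,
                                       "dispersion_sd_m": 200.0})
        fx = gen_movement(pop, months=3, seed=6)
        unit_of = dict(zip(pop.individuals["id"], pop.individuals["unit"]))
        for r in sk.detect_associations(fx):
            for a, b in r.dyads:
                assert unit_of[a] == unit_of[b]


class TestAssociationSeries:
    def test_all_constant_mixture(self):
        recs = gen_association_series(8, AssociationMixture(1.0, 0.0, 1.0),
                                      30, seed=1, sampling_prob=1.0)
        for r in recs:
            assert len(r.dyads) == 8

    def test_all_rapid_mixture_single_day_runs(self):
        recs = gen_association_series(10, AssociationMixture(0.0, 0.0, 1.0),
                                      200, seed=2, sampling_prob=1.0)
        prev = set()
        for r in recs:
            assert not (r.dyads & prev), "association lasted more than one day"
            prev = r.dyads

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            gen_association_series(10, (0.7, 0.5, 3.0), 50, seed=1)

    def test_allocation_sums_and_respects_zero_classes(self):
        counts, gap, rr = _series_design(AssociationMixture(0.81, 0.10, 7.1),
                                         30, 71.0, 0.05)
        assert sum(counts.values()) == 30
        assert min(counts.values()) >= 1
        counts2, _, _ = _series_design(AssociationMixture(1.0, 0.0, 1.0),
                                       10, 10.0, 0.05)
        assert counts2 == {"cc": 10, "ca": 0, "rd": 0}

    def test_deterministic_with_seed(self):
        a = gen_association_series(12, AssociationMixture(0.5, 0.3, 5.0), 60, seed=9)
        b = gen_association_series(12, AssociationMixture(0.5, 0.3, 5.0), 60, seed=9)
        assert a == b
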