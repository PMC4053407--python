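import numpy as np
import pytest

from sociokin.associations import make_record
from sociokin.simulate import AssociationMixture, gen_association_series
from sociokin.temporal import (
    default_lag_bins,
    fit_social_models,
    jackknife_se,
    lagged_association_rate,
    null_association_rate,
)
from tests.conftest import lar_brute, random_daily_records


def constant_dyad_records(n_days=12):
    return [make_record(d, ["a", "b"], [("a", "b")]) for d in range(n_days)]


class TestLAR:
    def test_constant_dyad_rate_is_one(self):
        curve = lagged_association_rate(constant_dyad_records())
        assert np.allclose(curve.g, 1.0)

    def test_hand_worked_three_individuals(self):
        # days 0-3, dyad ab on days 0,1,3; c present throughout
        recs = [
            make_record(0, ["a", "b", "c"], [("a", "b")]),
            make_record(1, ["a", "b", "c"], [("a", "b"), ("b", "c")]),
            make_record(2, ["a", "b"], []),
            make_record(3, ["a", "b", "c"], [("a", "b")]),
        ]
        # lag 1: pairs (0,1),(1,2),(2,3): num = ab0*ab1 + ab1*ab2 + bc1*bc2
        #        = 1 + 0 + 0; den = both-identified pairs with a(t)=1:
        #        ab0->1, ab1->1, bc1->0 (c absent day 2) => 2
        curve = lagged_association_rate(recs, lag_bins=np.array([1, 2, 3, 4]))
        assert curve.g[0] == pytest.approx(1 / 2)
        # lag 2: (0,2),(1,3): ab0*ab2=0 den 1; ab1*ab3=1 den 1; bc1*bc3=0 den 1
        assert curve.g[1] == pytest.approx(1 / 3)
        # lag 3: (0,3): ab0*ab3=1 den 1
        assert curve.g[2] == pytest.approx(1.0)

    @pytest.mark.parametrize("denominator", ["identified", "associates"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_triple_loop(self, seed, denominator):
        recs = random_daily_records(np.random.default_rng(seed), n_ind=7, n_days=10)
        num, den = lar_brute(recs, denominator)
        edges = np.arange(1, 11)
        curve = lagged_association_rate(recs, lag_bins=edges,
                                        denominator=denominator)
        expected = {lag: num[lag] / den[lag] for lag in sorted(den)
                    if den[lag] > 0}
        got = dict(zip(np.round(curve.lag_mid).astype(int), curve.g))
        for lag, val in expected.items():
            assert got[lag] == pytest.approx(val)

    def test_random_mixing_matches_null_rate(self):
        # associations independent across days: LAR ~ null association rate
        rng = np.random.default_rng(42)
        gs, nulls = [], []
        for _ in range(30):
            recs = random_daily_records(rng, n_ind=10, n_days=30, p_group=0.6)
            curve = lagged_association_rate(recs)
            w = curve.n_pairs / curve.n_pairs.sum()
            gs.append(float(np.sum(w * curve.g)))
            nulls.append(curve.null_rate)
        assert np.mean(gs) == pytest.approx(np.mean(nulls), abs=0.02)

    def test_needs_two_days(self):
        with pytest.raises(ValueError, match="two distinct days"):
            lagged_association_rate([make_record(0, ["a", "b"], [("a", "b")])])


class TestNullRate:
    def test_everyone_in_one_group(self):
        recs = [make_record(d, list("abc"),
                            [("a", "b"), ("a", "c"), ("b", "c")]) for d in range(3)]
        assert null_association_rate(recs) == 1.0

    def test_no_associations(self):
        recs = [make_record(d, list("abc"), []) for d in range(3)]
        assert null_association_rate(recs) == 0.0

    def test_days_with_one_individual_skipped(self):
        recs = [make_record(0, ["a"], []),
                make_record(1, ["a", "b"], [("a", "b")])]
        assert null_association_rate(recs) == 1.0


class TestJackknife:
    def test_constant_statistic_zero_se(self):
        recs = constant_dyad_records(60)
        se = jackknife_se(recs, lambda rs: 3.14, block=10)
        assert se[0] == 0.0

    def test_iid_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        values = dict(enumerate(rng.normal(0, 2.0, 500)))
        recs = [make_record(d, ["a", "b"], []) for d in range(500)]

        def stat(rs):
            return np.mean([values[r.day] for r in rs])

        se = jackknife_se(recs, stat, block=10)[0]
        x = np.array(list(values.values()))
        block_means = x.reshape(50, 10).mean(axis=1)
        expected = block_means.std(ddof=1) / np.sqrt(50)
        assert se == pytest.approx(expected, rel=0.1)

    def test_needs_three_blocks(self):
        with pytest.raises(ValueError, match="three"):
            jackknife_se(constant_dyad_records(12), lambda rs: 0.0, block=10)


class TestSocialModels:
    def test_pure_constant_companionship(self):
        recs = gen_association_series(10, AssociationMixture(1.0, 0.0, 1.0),
                                      120, seed=5)
        models = fit_social_models(recs, compute_se=False)
        best = models[0]
        assert best.component_kinds == ("constant",)
        assert best.components[0][1] == pytest.approx(1.0, abs=0.01)

    def test_two_casual_timescales_need_two_components(self):
        from sociokin.associations import DailyRecord
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            ra = gen_association_series(20, AssociationMixture(0.0, 1.0, 1.0),
                                        250, seed=100 + s)
            rb = gen_association_series(20, AssociationMixture(0.0, 1.0, 100.0),
                                        250, seed=500 + s)
            rb = [DailyRecord(day=r.day,
                              identified=frozenset("B" + i for i in r.identified),
                              dyads=frozenset(tuple(sorted(("B" + x, "B" + y)))
                                              for x, y in r.dyads))
                  for r in rb]
            merged = [DailyRecord(day=a.day, identified=a.identified | b.identified,
                                  dyads=a.dyads | b.dyads)
                      for a, b in zip(ra, rb)]
            q = {m.name: m.qaicc for m in fit_social_models(merged, compute_se=False)}
            two = min(q.get("CA+CA", np.inf), q.get("CA+CA+RD", np.inf))
            one = min(q.get("CA", np.inf), q.get("CA+RD", np.inf))
            wins += two < one
        assert wins > n_rep / 2

    def test_ranking_invariant_to_lag_units(self):
        recs = gen_association_series(20, AssociationMixture(0.6, 0.3, 5.0),
                                      200, seed=9)
        models_days = fit_social_models(recs, compute_se=False)
        hours = [make_record(r.day * 24, r.identified, r.dyads) for r in recs]
        day_edges = default_lag_bins(199)
        models_hours = fit_social_models(
            hours, lag_bins=day_edges * 24, jackknife_block=240,
            compute_se=False)
        assert [m.name for m in models_days] == [m.name for m in models_hours]

    def test_components_sorted_by_duration_and_proportions_sum(self):
        recs = gen_association_series(30, AssociationMixture(0.5, 0.4, 6.0),
                                      300, seed=2)
        best = fit_social_models(recs, compute_se=False)[0]
        durations = [t for _, _, t in best.components]
        assert durations == sorted(durations, reverse=True)
        total = sum(p for _, p, _ in best.components) + best.rapid_fraction
        assert total <= 1 + 1e-9

    def test_jackknife_se_reported_for_best_model(self):
        recs = gen_association_series(30, AssociationMixture(0.81, 0.10, 7.1),
                                      300, seed=1)
        best = fit_social_models(recs, jackknife_block=10)[0]
        assert best.params_se is not None
        assert all(v >= 0 for v in best.params_se.values())
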