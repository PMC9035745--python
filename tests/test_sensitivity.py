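"""PSA distributions, Monte Carlo mechanics, CEAC, and tornado analysis."""

import numpy as np
import pandas as pd
import pytest

from afcea.codes import EVENTS
from afcea.markov import ModelSettings, run_strategy
from afcea.params import ModelParameters, demo_parameters
from afcea.sensitivity import (
    DistributionError,
    ParameterDistribution,
    build_distributions,
    ceac,
    draw_parameters,
    one_way_dsa,
    run_psa,
)


def fixed_distributions(mp):
    return [
        ParameterDistribution(d.name, "fixed", d.value)
        for d in build_distributions(mp)
    ]


class TestDistributions:
    def test_fixed_family_returns_point_value(self):
        d = ParameterDistribution("x", "fixed", 3.14)
        rng = np.random.default_rng(0)
        assert d.draw(rng) == 3.14
        assert np.all(d.draw(rng, size=10) == 3.14)

    def test_beta_counts_use_jeffreys_posterior(self):
        d = ParameterDistribution("fatality:IS", "beta", 2 / 92, events=2, n=92)
        assert d.analytic_mean() == pytest.approx(2.5 / 93, rel=1e-12)
        rng = np.random.default_rng(1)
        sample = d.draw(rng, size=20_000)
        se = sample.std(ddof=1) / np.sqrt(sample.size)
        assert abs(sample.mean() - 2.5 / 93) < 3 * se

    def test_gamma_moment_fit_recovers_mean_and_cv(self):
        d = ParameterDistribution("event_cost:HF", "gamma", 2964.92, mean=2964.92, cv=0.2)
        rng = np.random.default_rng(2)
        sample = d.draw(rng, size=20_000)
        se = sample.std(ddof=1) / np.sqrt(sample.size)
        assert abs(sample.mean() - 2964.92) < 3 * se
        assert sample.std(ddof=1) / sample.mean() == pytest.approx(0.2, rel=0.05)

    def test_utility_draws_capped_at_one(self):
        d = ParameterDistribution("drug_utility:apixaban", "gamma", 0.998,
                                  mean=0.998, cv=0.05, cap=1.0)
        sample = d.draw(np.random.default_rng(3), size=5_000)
        assert sample.max() <= 1.0

    def test_invalid_parameterizations_rejected(self):
        with pytest.raises(DistributionError):
            ParameterDistribution("x", "gamma", 1.0, mean=1.0, cv=0.0)
        with pytest.raises(DistributionError):
            ParameterDistribution("x", "beta", 0.5, events=5, n=2)
        with pytest.raises(DistributionError):
            ParameterDistribution("x", "lognormal", 1.0)

    def test_fixed_interval_defaults_to_quarter_span(self):
        d = ParameterDistribution("x", "fixed", 100.0)
        assert d.interval() == (75.0, 125.0)


class TestPsa:
    def test_all_fixed_distributions_reproduce_base_case(self, demo_mp):
        psa = run_psa(demo_mp, fixed_distributions(demo_mp), n_iter=20, seed=0)
        base = {
            d: run_strategy(demo_mp.strategy(d), demo_mp.settings) for d in demo_mp.drugs
        }
        # every iteration is bitwise identical to the base case
        for drug in demo_mp.drugs:
            sub = psa.iterations[psa.iterations.strategy == drug]
            assert (sub["cost"] == base[drug].total_cost).all()
            assert (sub["qaly"] == base[drug].total_qaly).all()
        for _, row in psa.summary.iterrows():
            expected = (
                base[row["strategy"]].total_cost
                if row["measure"] == "cost"
                else base[row["strategy"]].total_qaly
            )
            # identical samples: SD is zero up to the epsilon of the
            # mean-subtraction in the sample-SD formula
            assert row["sd"] == pytest.approx(0.0, abs=1e-8 * max(1.0, expected))
            assert row["mean"] == pytest.approx(expected, rel=1e-12)

    def test_same_seed_reproduces_summary(self, demo_mp):
        dists = build_distributions(demo_mp)
        a = run_psa(demo_mp, dists, n_iter=50, seed=9)
        b = run_psa(demo_mp, dists, n_iter=50, seed=9)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_summary_size_matches_iterations(self, demo_mp):
        psa = run_psa(demo_mp, build_distributions(demo_mp), n_iter=40, seed=2)
        assert (psa.summary["size"] == 40).all()
        assert np.allclose(psa.summary["variance"], psa.summary["sd"] ** 2)

    def test_infeasible_draws_are_rejected_and_counted(self):
        settings = ModelSettings()
        incidence = {("warfarin", e): 0.0 for e in EVENTS} | {("warfarin", "HF"): 0.01}
        incidence |= {("apixaban", e): 0.0 for e in EVENTS} | {
            ("apixaban", "HF"): 0.55, ("apixaban", "GI"): 0.40,
        }
        mp = ModelParameters(settings=settings, incidence=incidence,
                             fatality={e: 0.0 for e in EVENTS})
        dists = [
            ParameterDistribution("incidence:apixaban:HF", "beta", 0.55, mean=0.55, cv=0.3),
            ParameterDistribution("incidence:apixaban:GI", "beta", 0.40, mean=0.40, cv=0.3),
        ]
        psa = run_psa(mp, dists, n_iter=200, seed=4)
        assert psa.rejected_draws > 0
        assert len(psa.iterations) == 200 * 2


class TestCeac:
    def _iterations(self):
        # hand-built 4-iteration table for exact enumeration
        rows = []
        data = {
            "A": [(100, 1.0), (100, 1.0), (100, 1.0), (100, 1.0)],
            "B": [(150, 1.1), (90, 0.9), (150, 0.9), (90, 1.1)],
        }
        for s, pairs in data.items():
            for i, (c, q) in enumerate(pairs):
                rows.append({"iteration": i, "strategy": s, "cost": c, "qaly": q})
        return pd.DataFrame(rows)

    def test_hand_enumerated_probabilities(self):
        table = ceac(self._iterations(), wtp_grid=[0.0, 1000.0], reference="A")
        b = table[table.strategy == "B"].set_index("wtp")
        # WTP 0: NMB = -cost; B cheaper in iterations 2 and 4
        assert b.loc[0.0, "p_cost_effective_vs_reference"] == 0.5
        # WTP 1000: iteration NMBs B vs A: 950 vs 900 (win), 810 vs 900,
        # 750 vs 900, 1010 vs 900 (win) -> 0.5
        assert b.loc[1000.0, "p_cost_effective_vs_reference"] == 0.5

    def test_multiway_probabilities_sum_to_one(self, demo_mp):
        psa = run_psa(demo_mp, build_distributions(demo_mp), n_iter=50, seed=6)
        table = ceac(psa.iterations, wtp_grid=[0, 32_000, 80_000], reference="warfarin")
        sums = table.groupby("wtp")["p_optimal"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_zero_wtp_means_probability_of_being_cheaper(self, demo_mp):
        psa = run_psa(demo_mp, build_distributions(demo_mp), n_iter=80, seed=7)
        table = ceac(psa.iterations, wtp_grid=[0.0], reference="warfarin")
        cost = psa.iterations.pivot(index="iteration", columns="strategy", values="cost")
        for s in demo_mp.drugs:
            if s == "warfarin":
                continue
            expect = (cost[s] < cost["warfarin"]).mean()
            got = table[(table.strategy == s)]["p_cost_effective_vs_reference"].iloc[0]
            assert got == pytest.approx(expect)

    def test_large_wtp_follows_qaly_ordering(self, demo_mp):
        psa = run_psa(demo_mp, build_distributions(demo_mp), n_iter=80, seed=8)
        table = ceac(psa.iterations, wtp_grid=[1e12], reference="warfarin")
        qaly = psa.iterations.pivot(index="iteration", columns="strategy", values="qaly")
        for s in demo_mp.drugs:
            if s == "warfarin":
                continue
            expect = (qaly[s] > qaly["warfarin"]).mean()
            got = table[table.strategy == s]["p_cost_effective_vs_reference"].iloc[0]
            assert got == pytest.approx(expect)

    def test_empty_grid_rejected(self, demo_mp):
        psa = run_psa(demo_mp, fixed_distributions(demo_mp), n_iter=2, seed=0)
        with pytest.raises(ValueError):
            ceac(psa.iterations, wtp_grid=[], reference="warfarin")


class TestDsa:
    def test_zero_width_bounds_give_zero_bar(self, demo_mp):
        d = ParameterDistribution("med_cost:apixaban", "fixed",
                                  demo_mp.medication_costs["apixaban"],
                                  low=demo_mp.medication_costs["apixaban"],
                                  high=demo_mp.medication_costs["apixaban"])
        table = one_way_dsa(demo_mp, [d])
        assert np.allclose(table["icer_range"], 0.0)
        assert np.allclose(table["inmb_range"], 0.0)

    def test_widening_a_bound_widens_the_bar(self, demo_mp):
        base_cost = demo_mp.medication_costs["apixaban"]
        narrow = ParameterDistribution("med_cost:apixaban", "fixed", base_cost,
                                       low=base_cost * 0.9, high=base_cost * 1.1)
        wide = ParameterDistribution("med_cost:apixaban", "fixed", base_cost,
                                     low=base_cost * 0.8, high=base_cost * 1.2)
        t_narrow = one_way_dsa(demo_mp, [narrow])
        t_wide = one_way_dsa(demo_mp, [wide])
        sel = lambda t: t[t.comparator == "apixaban"]["icer_range"].iloc[0]
        assert sel(t_wide) > sel(t_narrow)

    def test_common_draws_within_iteration(self, demo_mp):
        """Shared event-cost draws cancel in pairwise comparisons of equal-rate events."""
        dists = [d for d in build_distributions(demo_mp) if d.name == "event_cost:HF"]
        psa = run_psa(demo_mp, dists, n_iter=30, seed=10)
        cost = psa.iterations.pivot(index="iteration", columns="strategy", values="cost")
        # HF rates are identical across drugs, so the HF-cost draw moves all
        # strategies almost in lockstep: incremental cost varies far less
        # than absolute cost (independent draws would make it ~sqrt(2) larger).
        assert (cost["apixaban"] - cost["warfarin"]).std() < 0.1 * cost["apixaban"].std()
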