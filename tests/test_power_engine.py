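"""Closed-form sample sizes, Monte-Carlo power, probit power-curve fitting
and the adaptive sample-size search."""

import math

import numpy as np
import pytest
from scipy import stats

from distrand import (
    AnalysisSpec,
    ClosedFormInput,
    DesignSpec,
    EffectSpec,
    adaptive_search_from_fn,
    adaptive_sample_size_search,
    annotate_table,
    build_allocation_table,
    closed_form_from_table,
    closed_form_power,
    closed_form_sample_size,
    fit_probit_powercurve,
    fwer_by_simulation,
    jeffreys_interval,
    mc_se,
    power_by_simulation,
    two_stage_se,
)
from distrand.errors import NonIdentifiableFitError, SearchFailureError

ONE_EFFECTIVE = EffectSpec(rules=((frozenset({1}), 0.7),))


class TestClosedForm:
    def test_balanced_reference(self):
        n_I, N = closed_form_sample_size(ClosedFormInput(0.7, 0.5, 1.0, 0.05, 0.10))
        assert (n_I, N) == (124, 248)

    def test_bonferroni_twenty_arms(self):
        n_I, _ = closed_form_sample_size(
            ClosedFormInput(0.7, 0.5, 1.0, 0.05 / 20, 0.10)
        )
        assert n_I == 220

    def test_as_printed_variant_differs(self):
        inp = ClosedFormInput(0.7, 0.5, 1.0, 0.05, 0.10)
        n_std, _ = closed_form_sample_size(inp)
        n_ap, _ = closed_form_sample_size(inp, as_printed=True)
        assert n_ap != n_std

    def test_effect_size_scaling(self):
        # doubling the contrast shrinks n roughly fourfold
        small, _ = closed_form_sample_size(ClosedFormInput(0.55, 0.5, 1.0))
        large, _ = closed_form_sample_size(ClosedFormInput(0.60, 0.5, 1.0))
        assert small / large == pytest.approx(4.0, rel=0.15)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            ClosedFormInput(0.5, 0.5, 1.0)

    def test_power_inverts_sample_size(self):
        inp = ClosedFormInput(0.7, 0.5, 2.0, 0.01, 0.10)
        n_I, N = closed_form_sample_size(inp)
        assert closed_form_power(N, inp) == pytest.approx(0.90, abs=0.01)

    def test_design_implied_inputs(self):
        table = annotate_table(
            build_allocation_table(
                DesignSpec("distributive", K=4, k=2), effects=ONE_EFFECTIVE
            ),
            ONE_EFFECTIVE,
        )
        inp = closed_form_from_table(table, 1, alpha=0.05 / 4)
        assert inp.r == pytest.approx(1.0)
        assert (inp.p_I, inp.p_C) == (pytest.approx(0.7), pytest.approx(0.5))


class TestMonteCarloErrors:
    def test_power_se(self):
        assert mc_se(0.9, 5000) == pytest.approx(0.0042426, abs=1e-6)

    def test_two_stage_se(self):
        assert two_stage_se(0.9, 5400, 5000) == pytest.approx(
            math.sqrt(0.09 / 5400 + 0.09 / 5000), abs=1e-12
        )

    def test_jeffreys_width_at_1000_sims(self):
        lo, hi = jeffreys_interval(50, 1000)
        assert 0.01 < hi - lo < 0.03


class TestSimulatedPower:
    def test_closed_form_consistency(self):
        # pooled analysis at the closed-form N recovers the target power
        spec = DesignSpec("distributive", K=4, k=2)
        table = annotate_table(
            build_allocation_table(spec, effects=ONE_EFFECTIVE), ONE_EFFECTIVE
        )
        inp = closed_form_from_table(table, 1, alpha=0.05 / 4)
        _, N = closed_form_sample_size(inp)
        p, se = power_by_simulation(
            spec, None, ONE_EFFECTIVE,
            AnalysisSpec(test="pooled_prop_diff"),
            N, 2000, 1, np.random.default_rng(42),
        )
        assert p == pytest.approx(0.90, abs=3 * se + 0.01)

    def test_uninformative_at_n_one(self):
        spec = DesignSpec("distributive", K=4, k=2)
        p, _ = power_by_simulation(
            spec, None, ONE_EFFECTIVE, AnalysisSpec(test="pooled_prop_diff"),
            2, 500, 1, np.random.default_rng(3),
        )
        assert p < 0.05

    def test_monotone_in_n(self):
        spec = DesignSpec("distributive", K=4, k=2)
        aspec = AnalysisSpec()
        rng = np.random.default_rng(9)
        powers = []
        for N in (200, 500, 1000):
            p, se = power_by_simulation(
                spec, None, ONE_EFFECTIVE, aspec, N, 2000, 1, rng
            )
            powers.append((p, se))
        for (p1, s1), (p2, s2) in zip(powers, powers[1:]):
            assert p2 >= p1 - 2 * math.hypot(s1, s2)


class TestFwer:
    def test_global_null_controlled(self):
        spec = DesignSpec("distributive", K=6, k=3)
        out = fwer_by_simulation(
            spec, None, EffectSpec(), AnalysisSpec(), 500, 1000,
            np.random.default_rng(5),
        )
        se = mc_se(max(out["fwer"], 0.01), 1000)
        assert out["fwer"] <= 0.05 + 2 * se

    def test_unadjusted_alpha_inflates(self):
        spec = DesignSpec("distributive", K=6, k=3)
        out = fwer_by_simulation(
            spec, None, EffectSpec(), AnalysisSpec(n_tests=1), 500, 400,
            np.random.default_rng(6),
        )
        # roughly 1 - (1 - alpha)^tests >> alpha
        assert out["fwer"] > 0.10

    def test_pooled_one_sided_conservative(self):
        # a single effective intervention biases pooled contrasts of null
        # interventions toward harm: one-sided (benefit) FWER stays low
        spec = DesignSpec("distributive", K=4, k=2)
        one = fwer_by_simulation(
            spec, None, ONE_EFFECTIVE,
            AnalysisSpec(test="pooled_prop_diff", sidedness="one_sided"),
            800, 400, np.random.default_rng(7),
        )
        two = fwer_by_simulation(
            spec, None, ONE_EFFECTIVE,
            AnalysisSpec(test="pooled_prop_diff", sidedness="two_sided"),
            800, 400, np.random.default_rng(7),
        )
        assert one["fwer"] <= 0.05 + 2 * mc_se(0.05, 400)
        assert two["fwer"] >= one["fwer"]


class TestProbitFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(100)
        z09 = stats.norm.ppf(0.9)
        X = rng.uniform(10, 50, size=5000)
        d = rng.random(5000) < stats.norm.cdf(z09 + 0.05 * (X - 30))
        fit = fit_probit_powercurve(X, d, z09)
        assert fit.X0 == pytest.approx(30, abs=1.0)
        assert fit.b == pytest.approx(0.05, abs=0.01)
        assert fit.se_X0 < 1.0

    def test_curve_passes_target_power_at_x0(self):
        rng = np.random.default_rng(101)
        z09 = stats.norm.ppf(0.9)
        X = rng.uniform(10, 50, size=4000)
        d = rng.random(4000) < stats.norm.cdf(z09 + 0.05 * (X - 30))
        fit = fit_probit_powercurve(X, d, z09)
        power_at_x0 = stats.norm.cdf(z09 + fit.b * (fit.X0 - fit.X0))
        assert power_at_x0 == pytest.approx(0.9, abs=1e-12)

    def test_two_anchor_history_huge_se(self):
        fit = fit_probit_powercurve(
            [1.0, 1000.0], [False, True], stats.norm.ppf(0.9)
        )
        assert fit.se_X0 > 10 or not fit.converged

    def test_all_same_outcome_non_identifiable(self):
        with pytest.raises(NonIdentifiableFitError):
            fit_probit_powercurve([10, 20, 30], [True, True, True],
                                  stats.norm.ppf(0.9))


class TestAdaptiveSearch:
    def test_oracle_recovery_within_three_percent(self):
        inp = ClosedFormInput(0.7, 0.5, 1.0, 0.05, 0.10)
        _, N_true = closed_form_sample_size(inp)
        rng = np.random.default_rng(11)

        def oracle(N):
            return rng.random() < closed_form_power(N, inp)

        res = adaptive_search_from_fn(oracle, min_sims=5000)
        assert abs(res.N_required - N_true) / N_true < 0.03
        assert res.n_sims >= 5000

    def test_rerun_on_certain_discovery(self):
        # a huge effect: every initial trial is significant, forcing re-runs
        calls = {"n": 0}

        def always(N):
            calls["n"] += 1
            return True

        with pytest.raises(SearchFailureError):
            adaptive_search_from_fn(always, min_sims=100, max_reruns=3)
        assert calls["n"] >= 3 * 40

    def test_batch_schedule_grows(self):
        inp = ClosedFormInput(0.7, 0.5, 1.0, 0.05, 0.10)
        rng = np.random.default_rng(13)

        def oracle(N):
            return rng.random() < closed_form_power(N, inp)

        res = adaptive_search_from_fn(oracle, min_sims=1000)
        totals = [e["total"] for e in res.log]
        increments = np.diff(totals)
        assert (increments >= 50).all()
        assert res.N_required >= 1

    def test_end_to_end_logistic(self):
        # scaled-down search + fresh re-check lands near the target power
        spec = DesignSpec("distributive", K=6, k=2)
        aspec = AnalysisSpec()
        res = adaptive_sample_size_search(
            spec, None, ONE_EFFECTIVE, aspec, np.random.default_rng(17),
            min_sims=1500,
        )
        p, se = power_by_simulation(
            spec, None, ONE_EFFECTIVE, aspec, res.N_required, 1500, 1,
            np.random.default_rng(18),
        )
        assert p == pytest.approx(0.90, abs=0.045)
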