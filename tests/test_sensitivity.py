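"""Tornado DSA, distribution fitting, PSA and CEAC behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afecon.analysis import evaluate_strategy, run_base_case
from afecon.errors import DistributionFitError, InvalidParameterError
from afecon.sensitivity import (
    CEACCurve,
    DSASpec,
    PSADistribution,
    PSAResult,
    TornadoEntry,
    ce_probability,
    ceac,
    ci_to_distribution,
    default_psa_distributions,
    distribution_from_moments,
    dsa_one_way,
    make_dsa_specs,
    run_psa,
)


class TestDSASpecs:
    def test_ranges_follow_category_rules(self, bundle):
        specs = {s.param_id: s for s in make_dsa_specs(bundle)}
        cost = specs["treatment_cost:vka"]
        assert cost.low == pytest.approx(0.8 * cost.base)
        assert cost.high == pytest.approx(1.2 * cost.base)
        rate = specs["rate:apixaban:ischemic_stroke"]
        assert rate.low == pytest.approx(0.9 * 0.950)
        assert rate.high == pytest.approx(1.1 * 0.950)
        util = specs["utility:AF"]
        assert util.high <= 1.0

    def test_utility_clamped_to_one(self, bundle):
        b = bundle.set("utility:AF", 0.98)
        specs = {s.param_id: s for s in make_dsa_specs(b)}
        assert specs["utility:AF"].high == 1.0


class TestDSAOneWay:
    def test_irrelevant_parameter_swings_nothing(self, bundle):
        # rivaroxaban's own rate cannot move the apixaban-vs-warfarin ICER
        spec = DSASpec("rate:rivaroxaban:ich", 1.73, 1.557, 1.903, "probability")
        entry = dsa_one_way(bundle, spec, ("apixaban", "vka"))
        assert entry.swing == pytest.approx(0.0, abs=1e-9)

    def test_influential_parameter_moves_icer(self, bundle):
        spec = DSASpec("treatment_cost:vka", 19.0, 0.8 * 19.0, 1.2 * 19.0, "cost")
        entry = dsa_one_way(bundle, spec, ("apixaban", "vka"))
        assert entry.swing > 0

    def test_swing_invariant_to_label_swap(self, bundle):
        spec = DSASpec("treatment_cost:apixaban", 11.0, 9.0, 13.0, "cost")
        e = dsa_one_way(bundle, spec, ("apixaban", "vka"))
        swapped = TornadoEntry(e.param_id, e.icer_at_high, e.icer_at_low)
        assert swapped.swing == e.swing


class TestDistributionFitting:
    def test_beta_method_of_moments(self):
        d = ci_to_distribution(0.5, 0.3, 0.7, "beta")
        sd = 0.4 / 3.919928
        assert d.family == "beta"
        alpha, beta = d.params
        assert alpha == pytest.approx(11.50, abs=0.01)
        assert beta == pytest.approx(alpha, rel=1e-12)  # symmetric
        assert d.mean == pytest.approx(0.5, rel=1e-9)
        var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-9)

    def test_gamma_method_of_moments(self):
        d = distribution_from_moments(100.0, 20.0, "gamma")
        assert d.params[0] == pytest.approx(25.0, rel=1e-12)  # shape
        assert d.params[1] == pytest.approx(4.0, rel=1e-12)   # scale

    def test_lognormal_reproduces_mean(self):
        d = distribution_from_moments(1.52, 2.22, "lognormal")
        assert d.mean == pytest.approx(1.52, rel=1e-9)

    def test_degenerate_ci_rejected(self):
        with pytest.raises(InvalidParameterError):
            ci_to_distribution(0.5, 0.5, 0.5, "beta")

    def test_infeasible_beta_suggests_lognormal(self):
        with pytest.raises(DistributionFitError, match="lognormal"):
            distribution_from_moments(0.5, 0.6, "beta")

    def test_mean_outside_ci_warns(self):
        with pytest.warns(UserWarning):
            ci_to_distribution(0.582, 0.612, 1.176, "lognormal")

    @given(
        mean=st.floats(0.05, 0.95),
        rel=st.floats(0.05, 0.4),
        family=st.sampled_from(["beta", "gamma", "lognormal"]),
    )
    @settings(max_examples=100)
    def test_fit_reproduces_mean(self, mean, rel, family):
        d = distribution_from_moments(mean, rel * mean * (1 - mean), family)
        assert d.mean == pytest.approx(mean, rel=1e-6)


class TestPSA:
    def test_point_masses_reproduce_base_case_bitwise(self, bundle):
        base = {s: evaluate_strategy(bundle, s) for s in bundle.strategies}
        points = [
            PSADistribution(pid, "point", (value,))
            for pid, value, _ in bundle.parameter_items()
        ]
        psa = run_psa(bundle, points, n_iter=3, seed=0)
        for j, s in enumerate(psa.strategies):
            assert (psa.costs[:, j] == base[s].total_cost).all()
            assert (psa.qalys[:, j] == base[s].total_qaly).all()

    def test_same_seed_is_bit_identical(self, bundle):
        a = run_psa(bundle, n_iter=40, seed=123)
        b = run_psa(bundle, n_iter=40, seed=123)
        assert (a.costs == b.costs).all()
        assert (a.qalys == b.qalys).all()

    def test_different_seed_differs(self, bundle):
        a = run_psa(bundle, n_iter=40, seed=1)
        b = run_psa(bundle, n_iter=40, seed=2)
        assert not (a.costs == b.costs).all()

    def test_shared_printed_rate_is_one_parameter(self, bundle):
        ids = [d.param_id for d in default_psa_distributions(bundle)]
        # apixaban and VKA print the identical CV-hospitalisation entry
        assert "rate:apixaban+vka:cv_hosp" in ids
        assert "rate:apixaban:cv_hosp" not in ids
        # distinct entries stay independent
        assert "rate:apixaban:ischemic_stroke" in ids
        assert "rate:vka:ischemic_stroke" in ids


def _toy_psa():
    costs = np.array([[100.0, 120.0], [110.0, 100.0], [90.0, 95.0], [100.0, 100.0]])
    qalys = np.array([[1.0, 0.9], [1.0, 1.1], [1.0, 1.0], [1.2, 1.0]])
    return PSAResult(["a", "b"], costs, qalys, seed=0)


class TestCEProbability:
    def test_counts_positive_incremental_nmb(self):
        psa = _toy_psa()
        # dc = [-20, 10, -5, 0]; dq = [0.1, -0.1, 0.0, 0.2]
        assert ce_probability(psa, ("a", "b"), 0.0) == 0.5
        assert ce_probability(psa, ("a", "b"), 1000.0) == 0.75

    def test_infinite_threshold_counts_positive_dq(self):
        psa = _toy_psa()
        assert ce_probability(psa, ("a", "b"), math.inf) == 0.5

    def test_identical_favourable_points_give_one(self):
        costs = np.array([[50.0, 100.0]] * 5)
        qalys = np.array([[1.0, 1.0]] * 5)
        psa = PSAResult(["a", "b"], costs, qalys, seed=0)
        assert ce_probability(psa, ("a", "b"), 0.0) == 1.0

    @given(lam=st.floats(0, 1e5), lam2=st.floats(0, 1e5))
    @settings(max_examples=60)
    def test_monotone_in_threshold_when_dq_positive(self, lam, lam2):
        rng = np.random.default_rng(7)
        costs = rng.normal(100, 10, (50, 2))
        qalys = np.column_stack([rng.uniform(1.1, 2.0, 50), rng.uniform(0.1, 1.0, 50)])
        psa = PSAResult(["a", "b"], costs, qalys, seed=0)
        lo, hi = sorted((lam, lam2))
        assert ce_probability(psa, ("a", "b"), hi) >= ce_probability(psa, ("a", "b"), lo)


class TestCEAC:
    def test_probabilities_sum_to_one_everywhere(self, bundle):
        psa = run_psa(bundle, n_iter=60, seed=5)
        curve = ceac(psa, np.linspace(0, 40000, 21))
        np.testing.assert_allclose(curve.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_threshold_selects_cheapest(self):
        psa = _toy_psa()
        curve = ceac(psa, [0.0])
        cheaper = (psa.costs[:, 0] < psa.costs[:, 1]).mean()
        ties = (psa.costs[:, 0] == psa.costs[:, 1]).mean()
        assert curve.probabilities[0, 0] == pytest.approx(cheaper + ties / 2)

    def test_single_strategy_probability_one(self):
        psa = PSAResult(["only"], np.full((4, 1), 10.0), np.full((4, 1), 1.0), seed=0)
        curve = ceac(psa, [0.0, 1e4])
        assert (curve.probabilities == 1.0).all()

    def test_ties_split_equally(self):
        costs = np.array([[100.0, 100.0]])
        qalys = np.array([[1.0, 1.0]])
        psa = PSAResult(["a", "b"], costs, qalys, seed=0)
        curve = ceac(psa, [5000.0])
        assert curve.probabilities[0, 0] == 0.5
        assert curve.probabilities[0, 1] == 0.5
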