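"""Posterior functionals: WAIC, weights, derived posteriors, evidence ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpflow.inference import (DerivedPosterior, compare,
                               difference_in_improvement, differentiation,
                               differentiation_change, evidence_ratio,
                               label_strength, mean_improvement, model_weights,
                               waic)
from scpflow.study import ValidationError


def brute_force_waic(ll: np.ndarray):
    """Literal two-loop implementation from the definition."""
    S, n = ll.shape
    elpd = 0.0
    p_eff = 0.0
    for i in range(n):
        acc = 0.0
        for s in range(S):
            acc += np.exp(ll[s, i])
        lppd_i = np.log(acc / S)
        mean_ll = sum(ll[s, i] for s in range(S)) / S
        var_ll = sum((ll[s, i] - mean_ll) ** 2 for s in range(S)) / (S - 1)
        elpd += lppd_i - var_ll
        p_eff += var_ll
    return elpd, p_eff, -2 * elpd


class TestWAIC:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-1.0, 0.3, size=(4, 3))
        res = waic(ll)
        elpd, p_eff, w = brute_force_waic(ll)
        assert res.elpd_waic == pytest.approx(elpd, abs=1e-12)
        assert res.p_waic == pytest.approx(p_eff, abs=1e-12)
        assert res.waic == pytest.approx(w, abs=1e-12)

    def test_identical_draws_zero_penalty(self):
        ll = np.tile(np.array([-1.0, -2.0, -0.5]), (6, 1))
        assert waic(ll).p_waic == 0.0

    def test_translation_property(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-1.0, 0.3, size=(8, 5))
        c = 0.37
        base = waic(ll)
        shifted = waic(ll + c)
        assert shifted.elpd_waic == pytest.approx(base.elpd_waic + c * 5, abs=1e-9)

    def test_accepts_chain_shaped_input(self, srs_fit):
        res3 = waic(srs_fit.loglik_)
        res2 = waic(srs_fit.loglik_.reshape(-1, srs_fit.n_obs_))
        assert res3.waic == res2.waic

    def test_non_finite_error(self):
        ll = np.array([[0.0, -np.inf], [0.0, -1.0]])
        with pytest.raises(ValidationError):
            waic(ll)


class TestModelWeights:
    def test_equal_waics(self):
        np.testing.assert_allclose(model_weights([10.0, 10.0]), [0.5, 0.5])

    def test_delta_two_closed_form(self):
        w = model_weights([100.0, 102.0])
        expected = 1.0 / (1.0 + np.exp(-1.0))
        assert w[0] == pytest.approx(expected, abs=1e-12)
        assert w[1] == pytest.approx(1.0 - expected, abs=1e-12)

    def test_delta_twenty_decisive(self):
        w = model_weights([50.0, 70.0])
        assert w[0] > 0.999

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            w = model_weights(rng.uniform(0, 100, size=4))
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_compare_table(self, srs_fit, scp_fit):
        class Stub:
            def __init__(self, ll):
                self.loglik_ = ll

        rng = np.random.default_rng(3)
        fits = {"a": Stub(rng.normal(-1, 0.1, (10, 7))),
                "b": Stub(rng.normal(-2, 0.1, (10, 7)))}
        tab = compare(fits)
        assert tab["delta"].iloc[0] == 0.0
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert tab.index[0] == "a"

    def test_mismatched_observation_counts(self):
        class Stub:
            def __init__(self, n):
                self.loglik_ = np.zeros((4, n))

        with pytest.raises(ValidationError, match="observation counts"):
            compare({"a": Stub(5), "b": Stub(6)})


class TestImprovement:
    def test_flat_trajectory_zero(self, point_predictor):
        fit = point_predictor(lambda row: 42.0)
        imp = mean_improvement(fit, "control")
        assert np.all(imp.draws == 0.0)

    def test_linear_slope_closed_form(self, point_predictor):
        b = -1.3
        fit = point_predictor(lambda row: 100.0 + b * row["Time"])
        imp = mean_improvement(fit, "experimental")
        np.testing.assert_allclose(imp.draws, -5 * b)

    def test_quadratic_truth_recovered(self, srs_fit, small_truth):
        # analytic t1 - t6 difference of the generating quadratic
        truth_imp = -5 * small_truth.srs_linear.sum()
        imp = mean_improvement(srs_fit, "control")
        lo, hi = imp.ci()
        spread = hi - lo
        assert lo - spread < truth_imp < hi + spread

    def test_unknown_group_error(self, point_predictor):
        with pytest.raises(ValidationError):
            mean_improvement(point_predictor(lambda r: 0.0), "placebo")


class TestDifferenceInImprovement:
    def test_identical_groups_centered_at_zero(self, point_predictor):
        fit = point_predictor(lambda row: 90.0 - 2.0 * row["Time"])
        d = difference_in_improvement(fit)
        np.testing.assert_allclose(d.draws, 0.0)

    def test_printed_group_improvements(self, point_predictor):
        # experimental improves 21.38 points, control 13.5 -> D = 7.88
        def surface(row):
            slope = -21.38 / 5 if row["Group"] == "experimental" else -13.5 / 5
            return 100.0 + slope * row["Time"]

        d = difference_in_improvement(point_predictor(surface))
        np.testing.assert_allclose(d.draws, 7.88, atol=1e-12)

    def test_group_time_effect_recovered(self, srs_fit, small_truth):
        truth_d = -5 * small_truth.srs_group_time_effect
        d = difference_in_improvement(srs_fit)
        lo, hi = d.ci()
        spread = hi - lo
        assert lo - spread < truth_d < hi + spread

    def test_single_group_error(self, point_predictor):
        fit = point_predictor(lambda r: 0.0, groups=("experimental",))
        with pytest.raises(ValidationError, match="both groups"):
            difference_in_improvement(fit)


class TestDifferentiation:
    def test_zero_task_effect(self, point_predictor):
        fit = point_predictor(lambda row: -1.0 + 0.1 * row["Session"])
        diff = differentiation(fit, "feedback1", 12)
        np.testing.assert_allclose(diff.draws, 0.0)

    def test_compositional_oracle(self, scp_fit):
        # equals predict(neg) - predict(pos) draw by draw
        cond, sess = "feedback1", 4
        diff = differentiation(scp_fit, cond, sess)
        neg = scp_fit.predict_draws(pd.DataFrame(
            {"Condition": [cond], "Task": ["negativity"], "Session": [sess]}))[:, 0]
        pos = scp_fit.predict_draws(pd.DataFrame(
            {"Condition": [cond], "Task": ["positivity"], "Session": [sess]}))[:, 0]
        np.testing.assert_allclose(diff.draws, neg - pos, atol=1e-12)

    def test_truth_within_interval(self, scp_fit, small_design):
        from scpflow.study import scp_truth_surface

        s = small_design.n_sessions
        truth = (scp_truth_surface("feedback1", "negativity", np.array([s]), small_design)
                 - scp_truth_surface("feedback1", "positivity", np.array([s]), small_design))[0]
        diff = differentiation(scp_fit, "feedback1", s)
        lo, hi = diff.ci()
        spread = hi - lo
        assert lo - spread < truth < hi + spread


class TestDifferentiationChange:
    def test_time_constant_effect_zero(self, point_predictor):
        fit = point_predictor(
            lambda row: -3.0 if row["Task"] == "negativity" else 0.0)
        ch = differentiation_change(fit, "feedback1", sessions=(1, 24))
        np.testing.assert_allclose(ch.draws, 0.0)

    def test_printed_endpoints(self, point_predictor):
        # endpoints -2.28 (session 1) and -5.54 (session 24) imply -3.26
        def surface(row):
            gap = -2.28 if row["Session"] == 1 else -5.54
            return gap if row["Task"] == "negativity" else 0.0

        ch = differentiation_change(point_predictor(surface), "feedback1",
                                    sessions=(1, 24))
        np.testing.assert_allclose(ch.draws, -3.26, atol=1e-12)

    def test_drawwise_composition(self, scp_fit, small_design):
        n = small_design.n_sessions
        ch = differentiation_change(scp_fit, "transfer", sessions=(1, n))
        end = differentiation(scp_fit, "transfer", n)
        start = differentiation(scp_fit, "transfer", 1)
        np.testing.assert_allclose(ch.draws, end.draws - start.draws, atol=1e-12)


class TestEvidenceRatio:
    def _dp(self, draws):
        return DerivedPosterior(name="D", draws=np.asarray(draws, dtype=float))

    def test_half_positive_gives_er_one(self):
        draws = np.concatenate([np.ones(500), -np.ones(500)])
        rep = evidence_ratio(self._dp(draws), ">0")
        assert rep.evidence_ratio == pytest.approx(1.0)
        assert rep.posterior_probability == 0.5

    def test_850_of_1000(self):
        draws = np.concatenate([np.ones(850), -np.ones(150)])
        rep = evidence_ratio(self._dp(draws), ">0")
        assert rep.evidence_ratio == pytest.approx(850 / 150, abs=1e-12)

    @given(st.integers(min_value=1, max_value=999))
    @settings(max_examples=30, deadline=None)
    def test_inverse_identity(self, k):
        draws = np.concatenate([np.ones(k), -np.ones(1000 - k)])
        dp = self._dp(draws)
        er_pos = evidence_ratio(dp, ">0").evidence_ratio
        er_neg = evidence_ratio(dp, "<0").evidence_ratio
        assert er_pos * er_neg == pytest.approx(1.0, rel=1e-9)

    def test_p_one_reported_as_bound(self):
        with pytest.warns(UserWarning):
            rep = evidence_ratio(self._dp(np.ones(200)), ">0")
        assert rep.er_is_bound
        assert rep.evidence_ratio == 200
        assert np.isfinite(rep.evidence_ratio)

    def test_p_zero_reported_as_bound(self):
        with pytest.warns(UserWarning):
            rep = evidence_ratio(self._dp(np.ones(200)), "<0")
        assert rep.er_is_bound
        assert rep.evidence_ratio == pytest.approx(1 / 200)

    def test_empty_draws_error(self):
        with pytest.raises(ValidationError):
            DerivedPosterior(name="D", draws=np.array([]))


class TestLabelStrength:
    # every printed (ER, label) pair from the reported result tables
    PRINTED_PAIRS = [
        (5.79, "substantial"),
        (12.51, "strong"),
        (10.68, "strong"),
        (8.86, "substantial"),
        (5.53, "substantial"),
        (4.46, "substantial"),
        (13.2, "strong"),
        (1.19, "barely worth mentioning"),
        (0.84, "negative"),
    ]

    @pytest.mark.parametrize("er,label", PRINTED_PAIRS)
    def test_printed_pairs(self, er, label):
        assert label_strength(er) == label

    @pytest.mark.parametrize("er,label", [
        (0.0, "negative"),
        (1.0, "barely worth mentioning"),
        (3.2, "substantial"),
        (10.0, "strong"),
        (100.0, "decisive"),
        (1e6, "decisive"),
    ])
    def test_boundaries(self, er, label):
        assert label_strength(er) == label

    def test_negative_er_error(self):
        with pytest.raises(ValidationError):
            label_strength(-0.1)


class TestDerivedPosterior:
    def test_interval_is_central(self):
        rng = np.random.default_rng(7)
        dp = DerivedPosterior(name="x", draws=rng.standard_normal(20000))
        lo, hi = dp.ci(0.95)
        assert lo == pytest.approx(-1.96, abs=0.06)
        assert hi == pytest.approx(1.96, abs=0.06)
        assert lo < hi

    def test_subtraction_requires_matching_draws(self):
        a = DerivedPosterior(name="a", draws=np.ones(10))
        b = DerivedPosterior(name="b", draws=np.ones(5))
        with pytest.raises(ValidationError):
            a - b
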