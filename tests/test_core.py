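"""Deterministic mathematics: probit link, fluency variants, curves, scales."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import ndtr, ndtri

from truthfx import (
    LinkSpec,
    ModelVariant,
    default_grid,
    fluency_shift,
    prob_true_new,
    prob_true_rep,
    transform_scale,
    truth_effect_curve,
)

# Phi(1) via numerical integration of the standard normal density (independent oracle)
PHI_1 = 0.5 + quad(lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi), 0, 1)[0]
PHI_08 = 0.5 + quad(lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi), 0, 0.8)[0]


class TestLinkSpec:
    def test_defaults(self):
        link = LinkSpec()
        assert link.sigma == 0.5 and link.threshold == 0.5

    @pytest.mark.parametrize("sigma", [0.0, -1.0, np.inf, np.nan])
    def test_invalid_sigma_rejected(self, sigma):
        with pytest.raises(ValueError):
            LinkSpec(sigma=sigma)


class TestProbTrueNew:
    def test_at_threshold_is_half(self):
        assert prob_true_new(0.5) == pytest.approx(0.5, abs=1e-15)

    def test_matches_integration_oracle(self):
        # p = 1.0 with sigma 0.5 -> Phi((1 - 0.5)/0.5) = Phi(1)
        assert prob_true_new(1.0) == pytest.approx(PHI_1, abs=1e-12)

    def test_symmetric_about_half(self):
        eps = 0.37
        lo, hi = prob_true_new(0.5 - eps), prob_true_new(0.5 + eps)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_p_rejected(self):
        with pytest.raises(ValueError):
            prob_true_new(np.nan)

    @given(st.floats(-3, 3), st.floats(1e-3, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing(self, p, dp):
        assert prob_true_new(p + dp) > prob_true_new(p)


class TestFluencyShift:
    @pytest.mark.parametrize(
        "variant, m, p, expected",
        [
            ("M1", 0.1, -0.7, 0.1),   # constant, even for implausible statements
            ("M3", 0.3, 1.0, 0.0),
            ("M4", 0.4, 0.5, 0.4),
            ("M2", 0.2, -0.5, -0.1),  # literal application below p = 0
        ],
    )
    def test_examples(self, variant, m, p, expected):
        assert fluency_shift(variant, m, p) == pytest.approx(expected, abs=1e-15)

    def test_unknown_variant_rejected(self):
        with pytest.raises((ValueError, KeyError)):
            fluency_shift("M5", 0.1, 0.5)

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            fluency_shift("M1", -0.1, 0.5)


class TestProbTrueRep:
    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_reduces_to_new_at_m_zero(self, variant):
        grid = default_grid()
        np.testing.assert_allclose(
            prob_true_rep(variant, grid, 0.0), prob_true_new(grid), atol=1e-15
        )

    def test_m1_shift_oracle(self):
        # M1, p = 0.5, m = 0.4 -> Phi(0.4 / 0.5) = Phi(0.8)
        assert prob_true_rep("M1", 0.5, 0.4) == pytest.approx(PHI_08, abs=1e-12)

    def test_negative_shift_below_zero_plausibility(self):
        assert prob_true_rep("M2", -0.5, 0.2) < prob_true_new(-0.5)

    def test_item_residual_enters_numerator(self):
        base = prob_true_rep("M1", 0.5, 0.1)
        assert prob_true_rep("M1", 0.5, 0.1, item_residual=0.2) == pytest.approx(
            ndtr((0.5 + 0.1 + 0.2 - 0.5) / 0.5), abs=1e-14
        ) and prob_true_rep("M1", 0.5, 0.1, item_residual=0.2) > base


class TestTruthEffectCurve:
    def test_default_grid_matches_simulation_span(self):
        grid = default_grid()
        assert grid.size == 301
        assert grid[0] == -1.0 and grid[-1] == 2.0
        assert np.allclose(np.diff(grid), 0.01)

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_zero_m_means_zero_effect(self, variant):
        curve = truth_effect_curve(variant, 0.0)
        assert np.all(curve["truth_effect"] == 0.0)

    def test_m1_effect_peaks_at_mid_plausibility(self):
        curve = truth_effect_curve("M1", 0.4)
        eff = curve.set_index("p")["truth_effect"]
        assert eff.loc[0.5] > eff.loc[-1.0] and eff.loc[0.5] > eff.loc[2.0]

    def test_m1_max_against_dense_grid_oracle(self):
        # brute force on a 10x finer grid bounds the coarse-grid maximum
        m = 0.1
        dense = np.arange(-1, 2.0001, 0.001)
        oracle = np.max(prob_true_rep("M1", dense, m) - prob_true_new(dense))
        coarse = truth_effect_curve("M1", m)["truth_effect"].max()
        assert coarse == pytest.approx(oracle, abs=1e-6)
        assert coarse <= oracle + 1e-15

    def test_curve_identities(self):
        curve = truth_effect_curve("M3", 0.2)
        np.testing.assert_allclose(
            curve["truth_effect"], curve["theta_rep"] - curve["theta_new"], atol=1e-15
        )
        np.testing.assert_allclose(
            curve["perceived_truth_mean"], (curve["theta_rep"] + curve["theta_new"]) / 2, atol=1e-15
        )
        np.testing.assert_allclose(curve["perceived_truth_N"], curve["theta_new"], atol=0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            truth_effect_curve("M1", 0.1, p_grid=[])

    @pytest.mark.parametrize(
        "variant, lo, hi",
        [
            ("M1", 0.49, 0.51),   # inverted U centered at .5
            ("M2", 0.52, 0.78),   # right-skewed
            ("M3", 0.22, 0.48),   # left-skewed
            ("M4", 0.50, 0.66),   # peaked right of .5 on the (R+N)/2 axis
        ],
    )
    @pytest.mark.parametrize("m", [0.1, 0.2, 0.4])
    def test_curve_shapes_by_peak_location(self, variant, lo, hi, m):
        curve = truth_effect_curve(variant, m)
        x_at_max = curve.loc[curve["truth_effect"].idxmax(), "perceived_truth_mean"]
        assert lo <= x_at_max <= hi


class TestProbitAdditivity:
    @given(st.floats(0.01, 0.8))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_constant_fluency_is_additive_on_probit_scale(self, m):
        """The constant-shift variant moves every statement by m/sigma probits."""
        curve = truth_effect_curve("M1", m)
        gap = ndtri(curve["theta_rep"]) - ndtri(curve["theta_new"])
        np.testing.assert_allclose(gap, m / 0.5, atol=1e-10)


class TestSignStructure:
    @given(st.floats(-1, 2), st.floats(0.001, 0.8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_effect_sign_by_variant(self, p, m):
        # at p ~ 0 or p ~ 1 the M2-M4 shifts vanish and the sign comparison
        # degenerates to float-precision ties
        assume(min(abs(p), abs(p - 1.0)) > 1e-6)
        new = prob_true_new(p)
        assert (prob_true_rep("M1", p, m) >= new)
        assert (prob_true_rep("M2", p, m) >= new) == (p >= 0)
        assert (prob_true_rep("M3", p, m) >= new) == (p <= 1)
        assert (prob_true_rep("M4", p, m) >= new) == (0 <= p <= 1)

    @given(st.floats(0.01, 0.99), st.floats(0.0, 0.7), st.floats(0.001, 0.1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_effect_nondecreasing_in_m(self, p, m, dm):
        for variant in ModelVariant:
            assert prob_true_rep(variant, p, m + dm) >= prob_true_rep(variant, p, m) - 1e-15


class TestTransformScale:
    def test_probit_of_half_is_zero(self):
        assert transform_scale(0.5, "probit") == pytest.approx(0.0, abs=1e-15)

    def test_equal_probit_gaps_shrink_in_the_tail(self):
        # equal 0.4-probit differences translate to unequal probability gaps
        near = ndtr(1.00) - ndtr(0.60)
        far = ndtr(2.14) - ndtr(1.74)
        assert near > far
        assert transform_scale(ndtr(1.0), "probit") == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(1e-6, 1 - 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_probit_round_trip(self, theta):
        back = ndtr(transform_scale(theta, "probit"))
        assert back == pytest.approx(theta, abs=1e-12)

    @given(st.floats(1e-6, 1 - 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_logit_round_trip(self, theta):
        from scipy.special import expit

        assert expit(transform_scale(theta, "logit")) == pytest.approx(theta, abs=1e-12)

    def test_identity_target(self):
        assert transform_scale(0.0, "probability") == 0.0

    @pytest.mark.parametrize("theta", [0.0, 1.0])
    @pytest.mark.parametrize("target", ["probit", "logit"])
    def test_boundary_rejected(self, theta, target):
        with pytest.raises(ValueError):
            transform_scale(theta, target)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            transform_scale(0.5, "log")
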