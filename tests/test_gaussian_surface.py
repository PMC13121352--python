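import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootstress import (
    FIELD_SURFACE,
    PACKED_SURFACE,
    compare_structures,
    fit_gaussian_surface,
    normalize_elongation,
    relative_elongation,
    stress_reduction,
)
from rootstress.gaussian_surface import GaussianSurfaceParams
from rootstress.errors import (
    DegenerateDesignError,
    DegenerateInputError,
    InvalidInputError,
)

surface_params = st.builds(
    GaussianSurfaceParams,
    a=st.floats(0.5, 5.0),
    b=st.floats(10.0, 60.0),
    c=st.floats(2.0, 10.0),
    x0=st.floats(-50.0, 120.0),
    y0=st.floats(-30.0, 5.0),
)


class TestEvaluate:
    def test_peak_value_is_amplitude(self, field_surface, packed_surface):
        for p in (field_surface, packed_surface):
            assert relative_elongation(p, p.y0, p.x0) == pytest.approx(p.a)

    @pytest.mark.parametrize(
        "which, qp, s, expected",
        [
            ("field", 0.3, 60.0, 0.74),
            ("field", 0.3, 90.0, 0.43),
            ("packed", 0.3, 60.0, 0.97),
            ("packed", 0.3, 90.0, 0.35),
            ("field", 1.0, 60.0, 0.62),
            ("packed", 1.0, 60.0, 0.68),
            ("field", 3.5, 60.0, 0.30),
            ("packed", 3.5, 60.0, 0.18),
        ],
    )
    def test_published_point_values(self, which, qp, s, expected, field_surface, packed_surface):
        p = field_surface if which == "field" else packed_surface
        assert round(relative_elongation(p, qp, s), 2) == expected

    def test_clamp_mode(self, packed_surface):
        # near its optimum the Packed surface exceeds 1
        raw = relative_elongation(packed_surface, -5.0, 52.0)
        assert raw > 1
        assert relative_elongation(packed_surface, -5.0, 52.0, clamp=True) == 1.0

    def test_nonfinite_rejected(self, field_surface):
        with pytest.raises(InvalidInputError):
            relative_elongation(field_surface, np.nan, 60.0)

    @given(params=surface_params, s=st.floats(0, 100), qp=st.floats(0, 8), step=st.floats(0.1, 5))
    @settings(max_examples=60, deadline=None)
    def test_radial_monotonicity(self, params, s, qp, step):
        """Re strictly decreases moving away from the optimum along either axis."""
        s_out = params.x0 + (abs(s - params.x0) + step) * np.sign(s - params.x0 or 1)
        assert relative_elongation(params, qp, s_out) < relative_elongation(params, qp, s) + 1e-15
        q_out = params.y0 + (abs(qp - params.y0) + step) * np.sign(qp - params.y0 or 1)
        assert relative_elongation(params, q_out, s) < relative_elongation(params, qp, s) + 1e-15

    @given(params=surface_params, s=st.floats(0, 100), qp=st.floats(0, 8))
    @settings(max_examples=60, deadline=None)
    def test_separability(self, params, s, qp):
        """Re factorises into a * g(s) * h(qp) with unit-peak Gaussians."""
        g = np.exp(-0.5 * ((s - params.x0) / params.b) ** 2)
        h = np.exp(-0.5 * ((qp - params.y0) / params.c) ** 2)
        assert relative_elongation(params, qp, s) == pytest.approx(params.a * g * h, rel=1e-12)


class TestNormalize:
    def test_max_mode(self):
        np.testing.assert_allclose(normalize_elongation([2.0, 4.0]), [0.5, 1.0])

    def test_reference_mode_matches_published_pairing(self):
        # (relative 0.69; absolute 3.33 cm/d) implies a reference near 4.83
        assert round(float(normalize_elongation([3.33], reference=4.8261)[0]), 2) == 0.69

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_elongation([])

    def test_all_zero_without_reference_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_elongation([0.0, 0.0])


class TestFit:
    @pytest.mark.parametrize("truth", [FIELD_SURFACE, PACKED_SURFACE], ids=["field", "packed"])
    def test_noise_free_grid_recovery(self, truth):
        """Exact data on a 9 x 8 grid identifies all five parameters."""
        from conftest import surface_grid_obs

        s, q, re = surface_grid_obs(truth)
        df = pd.DataFrame({"saturation_pct": s, "qp": q, "relative": re})
        fitted = fit_gaussian_surface(df, seed=0)
        truth_vec = np.array([truth.a, truth.b, truth.c, truth.x0, truth.y0])
        est = np.array([fitted.a, fitted.b, fitted.c, fitted.x0, fitted.y0])
        np.testing.assert_allclose(est, truth_vec, rtol=1e-4)

    def test_single_s_level_degenerate(self):
        df = pd.DataFrame(
            {"saturation_pct": np.full(12, 60.0), "qp": np.linspace(0.5, 4, 12), "relative": np.ones(12)}
        )
        with pytest.raises(DegenerateDesignError):
            fit_gaussian_surface(df)

    def test_too_few_observations(self):
        df = pd.DataFrame({"saturation_pct": [50, 60, 70], "qp": [1, 2, 3], "relative": [0.5, 0.6, 0.4]})
        with pytest.raises(DegenerateDesignError):
            fit_gaussian_surface(df)

    def test_fit_idempotence(self, field_surface):
        """Refitting on a fit's own predictions returns the same surface."""
        from conftest import surface_grid_obs

        s, q, re = surface_grid_obs(field_surface)
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"saturation_pct": s, "qp": q, "relative": np.clip(re + rng.normal(0, 0.05, re.size), 0, None)}
        )
        first = fit_gaussian_surface(df, seed=1)
        df2 = df.assign(relative=relative_elongation(first, df["qp"], df["saturation_pct"]))
        second = fit_gaussian_surface(df2, seed=1)
        pred1 = relative_elongation(first, df["qp"], df["saturation_pct"])
        pred2 = relative_elongation(second, df["qp"], df["saturation_pct"])
        np.testing.assert_allclose(pred2, pred1, atol=1e-6)


class TestStressReduction:
    def test_published_mechanical_contrasts(self, field_surface, packed_surface):
        assert round(stress_reduction(field_surface, "s", 60.0, 1.0, 3.5)) == 52
        assert round(stress_reduction(packed_surface, "s", 60.0, 1.0, 3.5)) == 74

    def test_published_hydric_contrasts(self, field_surface, packed_surface):
        assert round(stress_reduction(field_surface, "qp", 0.3, 60.0, 90.0)) == 42
        assert round(stress_reduction(packed_surface, "qp", 0.3, 60.0, 90.0)) == 64

    def test_no_change_is_zero(self, field_surface):
        assert stress_reduction(field_surface, "s", 60.0, 2.0, 2.0) == 0.0

    def test_sign_preserved_for_increase(self, field_surface):
        # moving toward the optimum raises Re, so the reduction is negative
        assert stress_reduction(field_surface, "s", 60.0, 3.5, 1.0) < 0

    def test_bad_axis_rejected(self, field_surface):
        with pytest.raises(InvalidInputError):
            stress_reduction(field_surface, "z", 60.0, 1.0, 3.5)


class TestCompare:
    def test_identical_params_ratio_one(self, field_surface):
        df = compare_structures(field_surface, field_surface, ((0.5, 4, 8), (50, 90, 9)))
        np.testing.assert_allclose(df["ratio"], 1.0)
        assert df.attrs["mean_pct_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_saturated_high_resistance_node(self, field_surface, packed_surface):
        """At Qp = 4, S = 90 the intact-structure surface sits ~3x higher."""
        df = compare_structures(field_surface, packed_surface)
        node = df[(df["qp"] == 4.0) & (df["s"] == 90.0)].iloc[0]
        assert node["ratio"] == pytest.approx(3.0, abs=0.1)

    def test_low_stress_node_favours_packed(self, field_surface, packed_surface):
        df = compare_structures(field_surface, packed_surface, ((0.3, 0.3, 1), (60, 60, 1)))
        assert df["ratio"].iloc[0] < 1

    def test_empty_grid_rejected(self, field_surface, packed_surface):
        with pytest.raises(InvalidInputError):
            compare_structures(field_surface, packed_surface, ((0.5, 4, 0), (50, 90, 5)))
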