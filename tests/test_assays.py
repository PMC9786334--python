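"""Assay math: standard curve, amine contents, DoF, swelling, plateau modulus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelmaquant import (
    FrequencySweep,
    amine_content,
    degree_of_functionalization,
    fit_standard_curve,
    generate_tnbs_dataset,
    plateau_modulus,
    swelling_ratio,
    tnbs_pipeline,
)
from gelmaquant.assays import AmineMeasurement, CalibrationError


class TestStandardCurve:
    def test_exact_line_recovered(self):
        pts = [(c, 0.05 * c) for c in (3, 5, 8, 10, 20)]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(0.05, rel=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_duplicated_points_do_not_change_fit(self):
        pts = [(3, 0.2), (10, 0.5), (20, 1.2)]
        c1 = fit_standard_curve(pts)
        c2 = fit_standard_curve(pts + pts)
        assert c1.slope == pytest.approx(c2.slope, rel=1e-12)
        assert c1.intercept == pytest.approx(c2.intercept, rel=1e-12)

    def test_generator_round_trip_zero_noise(self):
        t = generate_tnbs_dataset(true_slope=0.04, true_intercept=0.03, noise_sd=0.0)
        std = t[(t.batch == 1) & (t.sample_type == "glycine_standard")]
        curve = fit_standard_curve(zip(std.concentration, std.absorbance))
        assert curve.slope == pytest.approx(0.04, rel=1e-12)
        assert curve.intercept == pytest.approx(0.03, rel=1e-12)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(CalibrationError):
            fit_standard_curve([(5, 0.1), (5, 0.2), (5, 0.3)])

    def test_negative_slope_rejected(self):
        with pytest.raises(CalibrationError, match="slope"):
            fit_standard_curve([(3, 1.0), (10, 0.5), (20, 0.1)])

    def test_through_origin_mode(self):
        pts = [(2.0, 0.21), (4.0, 0.39), (8.0, 0.82)]
        curve = fit_standard_curve(pts, through_origin=True)
        assert curve.intercept == 0.0
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        assert curve.slope == pytest.approx(float(x @ y / (x @ x)), rel=1e-12)


class TestAmineContent:
    def test_direct_arithmetic(self):
        curve = fit_standard_curve([(c, 0.05 * c) for c in (3, 5, 8, 10, 20)])
        m = [AmineMeasurement("s", 0.5, 0.25)]
        out = amine_content(m, curve)
        # 0.25 absorbance -> 5 ug/mL amine -> 10 ug per mg protein
        assert out.loc["s", "mean"] == pytest.approx(10.0, rel=1e-12)
        assert m[0].normalized_amine_content == pytest.approx(10.0, rel=1e-12)

    def test_absorbance_at_intercept_gives_zero(self):
        curve = fit_standard_curve([(c, 0.05 * c + 0.1) for c in (3, 5, 8, 10, 20)])
        out = amine_content([AmineMeasurement("s", 1.0, 0.1)], curve)
        assert out.loc["s", "mean"] == pytest.approx(0.0, abs=1e-10)

    def test_below_intercept_warns_negative(self):
        curve = fit_standard_curve([(c, 0.05 * c + 0.2) for c in (3, 5, 8, 10, 20)])
        with pytest.warns(UserWarning, match="negative"):
            out = amine_content([AmineMeasurement("s", 1.0, 0.05)], curve)
        assert out.loc["s", "mean"] < 0

    def test_replicate_dilutions_averaged_per_sample(self):
        curve = fit_standard_curve([(c, 0.05 * c) for c in (3, 5, 8, 10, 20)])
        meas = [AmineMeasurement("s", p, 0.05 * (p * 10.0)) for p in (0.1, 0.3, 0.5, 0.8)]
        out = amine_content(meas, curve)
        assert out.loc["s", "n"] == 4
        assert out.loc["s", "mean"] == pytest.approx(10.0, rel=1e-12)
        assert out.loc["s", "sd"] == pytest.approx(0.0, abs=1e-10)


class TestDoF:
    @pytest.mark.parametrize(
        "cg,cm,expected", [(0.3, 0.3, 0.0), (0.3, 0.0, 1.0), (0.30, 0.012, 0.96)]
    )
    def test_direct_arithmetic(self, cg, cm, expected):
        assert degree_of_functionalization(cg, cm).dof == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        d=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_dof_of_scaled_content_recovers_fraction(self, c, d):
        res = degree_of_functionalization(c, c * (1.0 - d))
        assert res.dof == pytest.approx(d, abs=1e-9)

    def test_nonpositive_gelatin_content_rejected(self):
        with pytest.raises(ValueError):
            degree_of_functionalization(0.0, 0.1)

    def test_negative_dof_warns_not_clips(self):
        with pytest.warns(UserWarning, match="negative"):
            res = degree_of_functionalization(0.1, 0.2)
        assert res.dof == pytest.approx(-1.0)

    def test_first_order_error_propagation(self):
        res = degree_of_functionalization(10.0, 2.0, sd_gelatin=0.5, sd_gelma=0.3)
        expected = np.sqrt((2.0 / 100.0) ** 2 * 0.25 + (1.0 / 10.0) ** 2 * 0.09)
        assert res.dof_sd == pytest.approx(expected, rel=1e-12)


class TestSwelling:
    @pytest.mark.parametrize("ms,md,expected", [(10.0, 10.0, 1.0), (150.0, 10.0, 15.0)])
    def test_ratio(self, ms, md, expected):
        assert swelling_ratio(ms, md) == pytest.approx(expected)

    def test_nonpositive_dry_mass_rejected(self):
        with pytest.raises(ValueError):
            swelling_ratio(10.0, 0.0)

    def test_vectorized(self):
        r = swelling_ratio(np.array([10.0, 30.0]), np.array([2.0, 3.0]))
        assert np.allclose(r, [5.0, 10.0])


class TestPlateauModulus:
    def _sweep(self, g):
        w = np.logspace(np.log10(0.5), np.log10(50.0), len(g))
        return FrequencySweep(w, np.asarray(g, float), np.asarray(g, float) * 0.1)

    def test_constant_modulus(self):
        res = plateau_modulus(self._sweep([11200.0] * 11))
        assert res.modulus_pa == pytest.approx(11200.0)
        assert res.flatness == pytest.approx(1.0)

    def test_rising_sweep_bounded_by_extremes(self):
        g = np.linspace(10000, 11000, 11)
        res = plateau_modulus(self._sweep(g))
        assert g.min() < res.modulus_pa < g.max()
        assert res.flatness == pytest.approx(1.1)

    def test_power_law_matches_closed_form(self):
        # G' = a * w^n sampled log-uniformly: geometric mean -> a * (w_lo * w_hi)^(n/2)
        a, n = 5000.0, 0.02
        w = np.logspace(np.log10(0.5), np.log10(50.0), 41)
        sweep = FrequencySweep(w, a * w**n, a * w**n * 0.1)
        res = plateau_modulus(sweep, (0.5, 50.0))
        closed = a * (0.5 * 50.0) ** (n / 2)
        assert res.modulus_pa == pytest.approx(closed, rel=0.01)

    def test_not_a_plateau_warns(self):
        with pytest.warns(UserWarning, match="plateau"):
            plateau_modulus(self._sweep(np.linspace(1000, 2000, 11)))

    def test_window_outside_data_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            plateau_modulus(self._sweep([1.0] * 11), (0.01, 50.0))


class TestTnbsPipeline:
    def test_zero_noise_recovers_true_dof_exactly(self):
        t = generate_tnbs_dataset(noise_sd=0.0, rng_seed=3)
        res = tnbs_pipeline(t)
        assert res.attrs["dof_mean"] == pytest.approx(t.attrs["true_dof"], rel=1e-12)
        assert res.attrs["dof_sd"] == pytest.approx(0.0, abs=1e-12)
        assert (res.r_squared > 0.999999).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="column"):
            tnbs_pipeline(pd.DataFrame({"batch": [1]}))
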