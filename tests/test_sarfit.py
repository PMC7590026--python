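import math

import numpy as np
import pytest

from magnetherm.config import DEFAULTS, MU0
from magnetherm.sar_models import SarModelParams
from magnetherm.sarfit import (FitConfig, SarCurve, SarSaturationFit,
                               compare_conditions, correlate_sar_gamma,
                               fit_sar_curve, quadratic_region_fit,
                               sar_vs_ms_regression, saturation_sar)
from magnetherm.synthetic import SyntheticSpec, _study_particle, gen_sar_curve

MS_VOL = 93.4 * DEFAULTS.density
GAMMA_PHYS = math.pi * MU0 * 355e3 * MS_VOL / DEFAULTS.density
TRUTH = dict(D=18e-9, C=3.0, tau_N0=3e-5)


def study_curve(seed=0, noise=0.0, condition="water"):
    model = "gaussian-multiplicative" if noise else "none"
    spec = SyntheticSpec(seed=seed, noise_model=model, noise_level=noise)
    p = _study_particle(MS_VOL, condition)
    params = SarModelParams(particle=p, tau_N0=TRUTH["tau_N0"],
                            C=TRUTH["C"])
    return gen_sar_curve(spec, params, condition=condition)


class TestSarSaturationFit:
    @pytest.mark.parametrize("c_mode", ["strict", "fixed_h3"])
    def test_noiseless_recovery(self, c_mode):
        curve = study_curve()
        est = SarSaturationFit(Ms_vol=MS_VOL, c_mode=c_mode)
        est.fit(curve.H, curve.SAR)
        assert est.D_ == pytest.approx(TRUTH["D"], rel=0.01)
        assert est.C_ == pytest.approx(TRUTH["C"], rel=0.01)
        assert est.tau_N0_ == pytest.approx(TRUTH["tau_N0"], rel=0.01)
        assert est.gamma_per_field_ == pytest.approx(GAMMA_PHYS, rel=0.01)
        assert est.r_squared_ > 0.999

    def test_solid_surrogate_equals_disabled_flag(self):
        curve = study_curve(condition="solid_random")
        a = SarSaturationFit(Ms_vol=MS_VOL, eta=1e100).fit(curve.H, curve.SAR)
        b = SarSaturationFit(Ms_vol=MS_VOL, brown_disabled=True,
                             eta=1e-3).fit(curve.H, curve.SAR)
        assert a.D_ == b.D_
        assert a.C_ == b.C_
        assert a.gamma_per_field_ == b.gamma_per_field_

    def test_noisy_recovery_median_bias_under_5pct(self):
        # reduced-size version of the recovery study (10 seeds, 3% noise)
        d_err, c_err, g_err = [], [], []
        for seed in range(10):
            curve = study_curve(seed=seed, noise=0.03)
            est = SarSaturationFit(Ms_vol=MS_VOL, c_mode="strict",
                                   seed=seed).fit(curve.H, curve.SAR)
            d_err.append(est.D_ / TRUTH["D"] - 1)
            c_err.append(est.C_ / TRUTH["C"] - 1)
            g_err.append(est.gamma_per_field_ / GAMMA_PHYS - 1)
        assert abs(np.median(d_err)) < 0.05
        assert abs(np.median(c_err)) < 0.05
        assert abs(np.median(g_err)) < 0.05

    def test_gamma_constrained_mode(self):
        curve = study_curve()
        est = SarSaturationFit(Ms_vol=MS_VOL, gamma_free=False)
        est.fit(curve.H, curve.SAR)
        assert est.gamma_per_field_ == GAMMA_PHYS
        assert est.D_ == pytest.approx(TRUTH["D"], rel=0.01)

    def test_functional_wrapper_and_config(self):
        curve = study_curve(condition="solid_random")
        config = FitConfig.for_condition("solid_random", Ms_vol=MS_VOL)
        assert config.brown_disabled
        res = fit_sar_curve(curve, config)
        assert res.condition == "solid_random"
        assert res.r_squared > 0.999
        assert res.Gamma == pytest.approx(res.gamma_per_field * 65e3,
                                          rel=1e-12)

    def test_input_validation(self):
        est = SarSaturationFit()
        with pytest.raises(ValueError):
            est.fit(np.arange(1.0, 4.0), np.ones(3))
        with pytest.raises(ValueError):
            est.fit(np.array([0.0, 1, 2, 3, 4]), np.ones(5))


class TestQuadraticRegionFit:
    def test_exact_quadratic(self):
        H = np.linspace(5e3, 35e3, 7)
        curve = SarCurve(H=H, SAR=2e-6 * H ** 2)
        a = quadratic_region_fit(curve)
        assert a == pytest.approx(2e-6, rel=1e-12)
        assert np.allclose(a * H ** 2, curve.SAR)

    def test_low_field_model_data_nearly_quadratic(self):
        # in the genuinely linear-response regime the saturation model obeys
        # SAR = a H^2 to better than 2%
        p = _study_particle(MS_VOL, "water")
        params = SarModelParams(particle=p, tau_N0=3e-5)
        H = np.linspace(50.0, 500.0, 10)
        curve = gen_sar_curve(SyntheticSpec(), params, H_grid=H)
        a = quadratic_region_fit(curve, h_cut=500.0)
        resid = np.linalg.norm(curve.SAR - a * H ** 2) / \
            np.linalg.norm(curve.SAR)
        assert resid < 0.02

    def test_saturating_points_degrade_fit(self):
        curve = study_curve()
        def rel_resid(h_cut):
            mask = curve.H <= h_cut
            a = quadratic_region_fit(curve, h_cut)
            return (np.linalg.norm(curve.SAR[mask] - a * curve.H[mask] ** 2)
                    / np.linalg.norm(curve.SAR[mask]))
        assert rel_resid(65e3) > 2 * rel_resid(20e3)

    def test_insufficient_points(self):
        curve = study_curve()
        with pytest.raises(ValueError):
            quadratic_region_fit(curve, h_cut=8e3)


class TestSaturationSar:
    def test_constant_tail(self):
        H = np.arange(5e3, 70e3, 5e3)
        sar = np.where(H >= 50e3, 1000.0, H / 100.0)
        assert saturation_sar(SarCurve(H=H, SAR=sar)) == 1000.0

    def test_close_to_model_value_at_top_field(self):
        curve = study_curve()
        top = curve.SAR[-1]
        assert saturation_sar(curve) == pytest.approx(top, rel=0.03)

    def test_invariant_to_duplicated_plateau_points(self):
        H = np.array([5e3, 20e3, 40e3, 55e3, 55e3, 60e3, 60e3])
        sar = np.array([10.0, 160.0, 600.0, 900.0, 900.0, 910.0, 910.0])
        a = saturation_sar(SarCurve(H=H[:5], SAR=sar[:5]))
        # duplicating an existing plateau level leaves the mean of levels
        b = saturation_sar(SarCurve(H=H, SAR=sar))
        assert b == pytest.approx(np.mean([900, 900, 910, 910]))
        assert a == pytest.approx(900.0)

    def test_no_plateau_error(self):
        H = np.linspace(5e3, 45e3, 9)
        with pytest.raises(ValueError):
            saturation_sar(SarCurve(H=H, SAR=np.ones(9)))


class TestComparativeStatistics:
    def test_compare_conditions_by_construction(self):
        sats = {"water": 1000.0, "solid_random": 700.0,
                "solid_aligned": 980.0}
        out = compare_conditions(sats)
        assert out["immobilization_change_pct"] == pytest.approx(-30.0)
        assert out["alignment_change_pct"] == pytest.approx(40.0)

    def test_equal_conditions_give_zero(self):
        out = compare_conditions({"water": 5.0, "solid_random": 5.0})
        assert out["immobilization_change_pct"] == 0.0

    def test_missing_condition(self):
        with pytest.raises(ValueError):
            compare_conditions({"water": 1.0})

    def test_collinear_correlation(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        out = correlate_sar_gamma(g, 5 + 2 * g)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_correlation_permutation_invariant(self):
        g = np.array([1.0, 3.0, 2.0, 5.0])
        s = np.array([2.0, 7.0, 4.0, 9.0])
        a = correlate_sar_gamma(g, s)
        order = [2, 0, 3, 1]
        b = correlate_sar_gamma(g[order], s[order])
        assert a == pytest.approx(b)

    def test_degenerate_gamma_spread(self):
        with pytest.raises(ValueError):
            correlate_sar_gamma([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_sar_ms_regression_exact_line(self):
        ms = np.array([65.9, 78.5, 82.1, 93.4])
        out = sar_vs_ms_regression(ms, 12.0 * ms)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(12.0)
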