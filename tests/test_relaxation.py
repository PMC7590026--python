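import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magnetherm.config import KB
from magnetherm.magnetometry import langevin_argument
from magnetherm.relaxation import (ParticleModel, anisotropy_field,
                                   brown_time_field, brown_time_zero_field,
                                   effective_time, neel_time_field_brown,
                                   neel_time_field_empirical,
                                   neel_time_zero_field, relaxation_map)


def particle(**kw):
    base = dict(D=16e-9, Ms_vol=4.5e5, K=2.0e4, shell=2e-9, tau0=1e-9,
                T=300.0, eta=1e-3)
    base.update(kw)
    return ParticleModel(**base)


class TestBrownTime:
    def test_hand_computed(self):
        p = particle(shell=10e-9, T=310.0)   # D_h = 36 nm
        assert brown_time_zero_field(p) == pytest.approx(1.7123e-5, rel=1e-3)

    def test_cubic_in_hydrodynamic_diameter(self):
        p1 = particle(D=16e-9, shell=2e-9)     # D_h = 20 nm
        p2 = particle(D=36e-9, shell=2e-9)     # D_h = 40 nm
        assert brown_time_zero_field(p2) == \
            pytest.approx(8 * brown_time_zero_field(p1), rel=1e-12)

    def test_viscosity_surrogate_disables_brown(self):
        # eta = 1e100 Pa s and the explicit flag must be interchangeable
        surrogate = particle(eta=1e100)
        flagged = particle(brown_disabled=True)
        tn = neel_time_zero_field(surrogate)
        assert math.isinf(brown_time_zero_field(flagged))
        assert effective_time(tn, brown_time_zero_field(surrogate)) == \
            pytest.approx(tn, rel=1e-15)
        assert effective_time(tn, brown_time_zero_field(flagged)) == tn

    def test_field_dependence(self):
        p = particle()
        tb0 = brown_time_zero_field(p)
        assert brown_time_field(p, 0.0) == tb0
        # xi = sqrt(1/0.07) makes the root factor sqrt(2)
        xi_target = math.sqrt(1 / 0.07)
        H = xi_target / langevin_argument(p.Ms_vol, p.D, 1.0, p.T)
        assert brown_time_field(p, H) == pytest.approx(tb0 / math.sqrt(2),
                                                       rel=1e-9)

    def test_high_field_slope_minus_one(self):
        p = particle()
        H = np.geomspace(1e5, 1e7, 40)
        tb = np.array([brown_time_field(p, h) for h in H])
        slope = np.polyfit(np.log(H), np.log(tb), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.02)


class TestNeelTime:
    def test_zero_field_hand_computed(self):
        p = particle()
        assert p.sigma_a == pytest.approx(10.3558, rel=1e-4)
        assert neel_time_zero_field(p) == pytest.approx(1.5720e-5, rel=1e-3)

    def test_vanishing_barrier_limit(self):
        p = particle(K=1e-12)
        assert neel_time_zero_field(p) == pytest.approx(p.tau0 / 2, rel=1e-9)

    def test_increasing_in_diameter(self):
        taus = [neel_time_zero_field(particle(D=d))
                for d in np.linspace(8e-9, 20e-9, 10)]
        assert all(a < b for a, b in zip(taus, taus[1:]))

    def test_blocked_particle_overflows_to_inf(self):
        with pytest.warns(RuntimeWarning):
            assert math.isinf(neel_time_zero_field(particle(D=60e-9, K=2e5)))

    def test_field_form_reduces_to_zero_field(self):
        p = particle()
        assert neel_time_field_brown(p, 0.0) == \
            pytest.approx(neel_time_zero_field(p), rel=1e-12)

    def test_field_form_term_by_term(self):
        # independent arithmetic oracle at h = 0.2
        p = particle()
        hk = anisotropy_field(p)
        h = 0.2
        s = p.sigma_a
        rate = (1 / p.tau0) * (1 - h ** 2) * (
            (1 + h) * math.exp(-s * (1 + h) ** 2)
            + (1 - h) * math.exp(-s * (1 - h) ** 2))
        assert neel_time_field_brown(p, h * hk) == \
            pytest.approx(1 / rate, rel=1e-12)

    def test_field_form_monotone_below_validity_edge(self):
        p = particle()
        hk = anisotropy_field(p)
        hs = np.linspace(0, 0.399, 100)
        taus = [neel_time_field_brown(p, h * hk) for h in hs]
        assert all(a >= b for a, b in zip(taus, taus[1:]))

    def test_singularity_and_validity_guards(self):
        p = particle()
        hk = anisotropy_field(p)
        with pytest.raises(ValueError):
            neel_time_field_brown(p, hk)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            with pytest.raises(RuntimeWarning):
                neel_time_field_brown(p, 0.5 * hk)


class TestNeelEmpirical:
    def test_zero_field(self):
        assert neel_time_field_empirical(1e-5, 0.0) == 1e-5

    def test_dieckhoff_parameters(self):
        assert neel_time_field_empirical(1e-5, 1.0, A=1.97, C=3.18) == \
            pytest.approx(1e-5 / math.sqrt(2.97), rel=1e-12)

    def test_asymptotic_slope_minus_1p5(self):
        xi = np.geomspace(1e2, 1e4, 40)
        tau = neel_time_field_empirical(1e-5, xi, A=2.0, C=3.0)
        slope = np.polyfit(np.log(xi), np.log(tau), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.02)

    def test_literal_printed_form_increases(self):
        assert neel_time_field_empirical(1e-5, 2.0, form="literal") > 1e-5

    def test_monotone_decreasing_in_field(self):
        xi = np.linspace(0, 50, 200)
        tau = neel_time_field_empirical(1e-5, xi)
        assert np.all(np.diff(tau) < 0)


class TestEffectiveTime:
    def test_infinite_partner(self):
        assert effective_time(3.0, math.inf) == 3.0
        assert effective_time(math.inf, 7.0) == 7.0

    def test_equal_inputs(self):
        assert effective_time(2.0, 2.0) == 1.0

    @given(st.floats(min_value=1e-12, max_value=1e6),
           st.floats(min_value=1e-12, max_value=1e6))
    @settings(max_examples=100, deadline=None)
    def test_harmonic_combination(self, a, b):
        tau = effective_time(a, b)
        assert tau == pytest.approx(a * b / (a + b), rel=1e-12)
        assert tau <= min(a, b)


class TestAnisotropyField:
    def test_study_keff(self):
        assert anisotropy_field(particle(K=1.6e4)) == \
            pytest.approx(56.6e3, rel=1e-3)

    def test_fig8_keff(self):
        # with K = 2e4 the anisotropy field is ~71 kA/m, i.e. the quoted
        # "around 60 kA/m" is approximate
        assert anisotropy_field(particle(K=2.0e4)) == \
            pytest.approx(70.74e3, rel=1e-3)

    def test_linear_in_K(self):
        assert anisotropy_field(particle(K=3.2e4)) == \
            pytest.approx(2 * anisotropy_field(particle(K=1.6e4)), rel=1e-12)


class TestRelaxationMap:
    def test_zero_field_size_crossover(self, fig8_particle):
        df = relaxation_map(fig8_particle,
                            D_grid=np.linspace(5e-9, 40e-9, 36),
                            H_grid=[0.0])
        small = df[df.D_m <= 10e-9]
        large = df[df.D_m >= 30e-9]
        assert (small.tau_N_s < small.tau_B_s).all()
        assert (large.tau_B_s < large.tau_N_s).all()

    def test_neel_dominates_large_particles_at_high_field(self, fig8_particle):
        # within the 65 kA/m experimental range, the Neel branch overtakes
        # the Brownian one above 30 kA/m even for 35 nm particles
        H = np.linspace(30e3, 65e3, 36)
        df = relaxation_map(fig8_particle, D_grid=[35e-9], H_grid=H)
        dominant = df[df.tau_N_s < df.tau_B_s]
        assert not dominant.empty
        assert (df.iloc[-1].tau_N_s < df.iloc[-1].tau_B_s)

    def test_effective_time_invariant(self, fig8_particle):
        df = relaxation_map(fig8_particle,
                            D_grid=np.linspace(6e-9, 35e-9, 8),
                            H_grid=np.linspace(0, 60e3, 7))
        finite = df[np.isfinite(df.tau_N_s) & np.isfinite(df.tau_B_s)]
        assert (finite.tau_eff_s <= np.minimum(finite.tau_N_s,
                                               finite.tau_B_s) + 1e-30).all()

    def test_empirical_form_option(self, fig8_particle):
        df = relaxation_map(fig8_particle, D_grid=[10e-9],
                            H_grid=[0.0, 30e3], neel_form="empirical")
        assert df.tau_N_s.iloc[1] < df.tau_N_s.iloc[0]

    def test_empty_grid_rejected(self, fig8_particle):
        with pytest.raises(ValueError):
            relaxation_map(fig8_particle, D_grid=[], H_grid=[0.0])
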