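"""Modified HCH-1 rate law, enzyme decay, and batch integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacchsim.kinetics import (BatchState, KineticParameters,
                               enzyme_decay_fixed_point, enzyme_decay_rate,
                               free_sites_fraction, hydrolysis_rate,
                               inhibition_fraction, lumped_adsorption,
                               lumped_kinetic_constant, simulate_batch)


class TestRateLawPieces:
    @pytest.mark.parametrize("g1, expected", [
        (0.0, 1.0),
        (93.0, 0.200),          # ~20% of enzyme active at 93 g/L glucose
        (1.0 / 0.043, 0.5),     # half-inhibition at G1 = 1/beta1
    ])
    def test_inhibition_fraction(self, g1, expected, kp):
        assert inhibition_fraction(g1, kp) == pytest.approx(expected,
                                                            abs=5e-4)

    @pytest.mark.parametrize("x, expected", [
        (0.0, 123.25),          # k3 + k6
        (0.5, 39.938098),
        (1.0, 38.50),           # k3/2^k5 is ~1e-6, negligible
    ])
    def test_lumped_kinetic_constant(self, x, expected, kp):
        assert lumped_kinetic_constant(x, kp) == pytest.approx(expected,
                                                               abs=1e-4)

    def test_kappa_monotone_and_bounded(self, kp):
        xs = np.linspace(0, 1, 201)
        k = lumped_kinetic_constant(xs, kp)
        assert np.all(np.diff(k) <= 1e-12)
        assert np.all((k >= kp.k6 - 1e-12) & (k <= kp.k3 + kp.k6 + 1e-12))

    @pytest.mark.parametrize("g1, e, x, expected", [
        (0.0, 1.0, 0.3, 0.0),
        (50.0, 1.0, 0.0, 4.593231),   # 84/(1 + e^2.85)
    ])
    def test_lumped_adsorption(self, g1, e, x, expected, kp):
        assert lumped_adsorption(g1, e, x, kp) == pytest.approx(expected,
                                                                abs=1e-5)

    def test_lumped_adsorption_high_conversion_limit(self, kp):
        # once a2*x >> a3 the sigmoid saturates and alpha -> a1*G1/E
        assert lumped_adsorption(80.0, 0.5, 1.0, kp) == pytest.approx(
            kp.a1 * 80.0 / 0.5, rel=1e-8)

    def test_free_sites_no_coverage(self):
        assert free_sites_fraction(50.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_free_sites_alpha_equals_substrate(self):
        # b = -eps*E = 0, sqrt(4*alpha*Gx) = 2*Gx -> phi = 1
        assert free_sites_fraction(30.0, 30.0, 0.0) == pytest.approx(1.0)

    def test_free_sites_solves_site_balance(self):
        gx, alpha, eps_e = 100.0, 10.0, 1.0
        phi = free_sites_fraction(gx, alpha, eps_e)
        assert 0.0 < phi < 1.0
        # phi is the positive root of Gx*phi^2 + (alpha + eps*E - Gx)*phi
        # - alpha = 0
        resid = gx * phi ** 2 + (alpha + eps_e - gx) * phi - alpha
        assert resid == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("gx, g1, e, x, expected", [
        (100.0, 10.0, 0.0, 0.0, 0.0),   # no enzyme
        (0.0, 10.0, 0.5, 1.0, 0.0),     # substrate exhausted
        (100.0, 0.0, 0.1, 0.0, 12.325),  # alpha=0, phi~1, kappa=123.25
    ])
    def test_hydrolysis_rate(self, gx, g1, e, x, expected, kp):
        assert hydrolysis_rate(gx, g1, e, x, kp) == pytest.approx(
            expected, rel=1e-4, abs=1e-12)

    def test_rate_decreasing_in_glucose(self, kp):
        rates = [hydrolysis_rate(80.0, g1, 0.2, 0.3, kp)
                 for g1 in (0.0, 20.0, 60.0, 120.0)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    @given(g1=st.floats(0, 300), e=st.floats(1e-6, 2.0),
           x=st.floats(0, 1), gx=st.floats(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_rate_always_nonnegative(self, g1, e, x, gx):
        assert hydrolysis_rate(gx, g1, e, x) >= 0.0

    @pytest.mark.parametrize("bad_call", [
        lambda: inhibition_fraction(-1.0),
        lambda: lumped_kinetic_constant(1.5),
        lambda: lumped_adsorption(10.0, 0.0, 0.5),
        lambda: free_sites_fraction(0.0, 1.0, 0.0),
        lambda: enzyme_decay_rate(1.2, 1.0),
    ])
    def test_domain_errors(self, bad_call):
        with pytest.raises(ValueError):
            bad_call()


class TestEnzymeDecay:
    def test_fresh_enzyme_decays_first_order(self, kp):
        e0 = 0.8
        assert enzyme_decay_rate(e0, e0, kp) == pytest.approx(
            -kp.decay_k1 * e0)

    def test_fixed_point_is_stationary(self, kp):
        e0 = 0.5
        e_star = enzyme_decay_fixed_point(e0, kp)
        assert e_star == pytest.approx(0.174 * 0.25 / (0.023 + 0.174 * 0.5))
        assert enzyme_decay_rate(e_star, e0, kp) == pytest.approx(0.0,
                                                                  abs=1e-14)

    def test_no_enzyme_no_decay(self, kp):
        assert enzyme_decay_rate(0.0, 0.0, kp) == 0.0

    def test_trajectory_converges_monotonically_to_fixed_point(self, kp):
        # decay ODE alone: track E along a substrate-free batch
        state = BatchState(Gx=1e-9, G1=0.0, E=0.6)
        traj = simulate_batch(state, 2000.0, kp, n_out=60)
        e_star = enzyme_decay_fixed_point(0.6, kp)
        diffs = traj.E.to_numpy() - e_star
        assert np.all(np.diff(np.abs(diffs)) <= 1e-12)
        assert traj.E.iloc[-1] == pytest.approx(e_star, rel=1e-5)


class TestBatchSimulation:
    def test_no_enzyme_means_no_reaction(self, kp):
        traj = simulate_batch(BatchState(Gx=100.0, G1=5.0, E=0.0), 240.0, kp)
        assert np.allclose(traj.G1, 5.0, atol=1e-9)
        assert np.allclose(traj.Gx, 100.0, atol=1e-9)

    def test_mass_conservation_and_monotone_product(self, kp):
        traj = simulate_batch(BatchState(Gx=108.0, E=0.62), 48.0 * 10, kp)
        total = traj.Gx + traj.G1
        assert np.max(np.abs(total - total.iloc[0])) / total.iloc[0] < 1e-6
        assert np.all(np.diff(traj.G1) >= -1e-9)
        assert np.all(np.diff(traj.x) >= -1e-12)

    def test_exhaustion_limit(self, kp):
        # generous enzyme, long duration: substrate fully converts
        traj = simulate_batch(BatchState(Gx=50.0, E=2.0), 24.0 * 400, kp)
        assert traj.x.iloc[-1] > 0.999
        assert traj.G1.iloc[-1] == pytest.approx(50.0, rel=1e-3)

    def test_convergence_under_tolerance_refinement(self, kp):
        state = BatchState(Gx=108.0, E=0.3)
        a = simulate_batch(state, 480.0, kp, rtol=1e-8, atol=1e-10)
        b = simulate_batch(state, 480.0, kp, rtol=5e-9, atol=5e-11)
        assert b.G1.iloc[-1] == pytest.approx(a.G1.iloc[-1], rel=1e-3)

    def test_time_unit_rescales_trajectory(self):
        # per-hour constants over t hours == per-day constants over t days
        kp_h = KineticParameters(time_unit="h")
        kp_d = KineticParameters(time_unit="d")
        fast = simulate_batch(BatchState(Gx=80.0, E=0.4), 10.0, kp_h)
        slow = simulate_batch(BatchState(Gx=80.0, E=0.4), 240.0, kp_d)
        assert slow.G1.iloc[-1] == pytest.approx(fast.G1.iloc[-1], rel=1e-6)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            KineticParameters(beta1=0.0)
        with pytest.raises(ValueError):
            KineticParameters(k3=-1.0)
        with pytest.raises(ValueError):
            BatchState(Gx=10.0, E=0.5, E0=0.2)
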