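"""Core dynamics: rate map, derivatives, integration invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canoncircuit import (
    GIPulse,
    Pulse,
    StimulusProtocol,
    build_network,
    baseline_state,
    default_protocol,
    derivatives,
    firing_rate,
    integrate,
    reference_params,
)

DT = 1e-3


class TestFiringRate:
    @pytest.mark.parametrize(
        "v_offset,expected", [(0.0, 0.0), (-5.0, 0.0), (1.5, 1.5)]
    )
    def test_threshold_linear_values(self, v_offset, expected):
        gamma = 0.7
        assert firing_rate(gamma + v_offset, gamma) == pytest.approx(expected)

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_and_monotone(self, v1, v2, gamma):
        r1, r2 = firing_rate(v1, gamma), firing_rate(v2, gamma)
        assert r1 >= 0 and r2 >= 0
        if v1 <= v2:
            assert r1 <= r2

    @given(st.floats(0.01, 20), st.floats(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_unit_slope_above_threshold(self, dv, gamma):
        assert firing_rate(gamma + dv, gamma) == pytest.approx(dv)


class TestDerivatives:
    def test_rest_is_fixed_point_of_passive_system(self):
        # no couplings, no tonic drive, V = 0 -> dV/dt = 0
        p = reference_params(R=0.0, W_exc=0.0, W_inh=0.0, eta_exc=0.0, eta_inh=0.0)
        net = build_network(p)
        V = np.zeros(4)
        g = np.ones(net.n_gains)
        dV, dg = derivatives(V, g, 0.0, net, StimulusProtocol.empty(1.0))
        assert np.allclose(dV, 0.0)
        assert np.allclose(dg, 0.0)

    def test_zero_eta_pins_gain_at_one(self):
        p = reference_params(eta_exc=0.0, eta_inh=0.0)
        net = build_network(p)
        proto = default_protocol(net, t_end=8.0, onset=2.0)
        res = integrate(net, proto, dt=DT, seed=None)
        assert np.allclose(res.gains, 1.0)

    def test_isolated_cell_fixed_point_matches_scalar_algebra(self):
        # Decoupled cell under constant drive E: the shunting balance
        #   0 = -A V + (B - V) E  has the closed form V* = B E / (A + E).
        p = reference_params(W_exc=0.0, W_inh=0.0, eta_exc=0.0, eta_inh=0.0,
                             R=1.7)
        net = build_network(p)
        V_star = p.upper_bound * p.R / (p.decay_exc + p.R)
        V = np.full(4, V_star)
        # interneurons have their own decay rate
        V_star_inh = p.upper_bound * p.R / (p.decay_inh + p.R)
        V[2:] = V_star_inh
        dV, _ = derivatives(V, np.ones(net.n_gains), 0.0, net,
                            StimulusProtocol.empty(1.0))
        assert np.max(np.abs(dV)) < 1e-12


class TestIntegrate:
    def test_rejects_nonpositive_dt(self, ref_net):
        with pytest.raises(ValueError, match="dt"):
            integrate(ref_net, StimulusProtocol.empty(1.0), dt=0.0)

    def test_rejects_bad_protocol(self, ref_net):
        with pytest.raises(ValueError, match="duration"):
            StimulusProtocol(10.0, (Pulse(ref_net.cells[0], 1.0, -0.5, 1.0),))
        with pytest.raises(ValueError, match="t_end"):
            StimulusProtocol(1.0, (), (GIPulse(0.9, 0.5, 1.0),))

    def test_equilibrium_persists(self, ref_net, ref_baseline):
        V0, g0 = ref_baseline
        res = integrate(ref_net, StimulusProtocol.empty(5.0), dt=DT, seed=None,
                        V0=V0, gains0=g0)
        assert np.max(np.abs(res.V - V0)) < 1e-6
        assert np.max(np.abs(res.gains - g0)) < 1e-6

    def test_deterministic_without_noise(self, ref_net):
        proto = default_protocol(ref_net, t_end=8.0)
        r1 = integrate(ref_net, proto, dt=DT, seed=1)
        r2 = integrate(ref_net, proto, dt=DT, seed=2)
        assert np.array_equal(r1.V, r2.V)

    def test_noise_seed_reproducibility(self, ref_params):
        net = build_network(ref_params.replace(noise_amp=0.3))
        proto = default_protocol(net, t_end=6.0)
        r1 = integrate(net, proto, dt=DT, seed=42)
        r2 = integrate(net, proto, dt=DT, seed=42)
        r3 = integrate(net, proto, dt=DT, seed=43)
        assert np.array_equal(r1.V, r2.V)
        assert not np.array_equal(r1.V, r3.V)

    def test_noise_seeds_share_baseline_statistics(self, ref_params, ref_baseline):
        # different seeds: trajectories differ but time-averaged baseline
        # rates agree within 3 standard errors.  The reference point sits
        # near the regime boundary, so noise excites a slow mode with a
        # correlation time of ~15 s; the SE therefore comes from block
        # means with 15 s blocks over a long run.
        net = build_network(ref_params.replace(noise_amp=0.3))
        V0, g0 = ref_baseline
        block = 15.0
        means, sems = [], []
        for seed in (11, 12):
            res = integrate(net, StimulusProtocol.empty(95.0), dt=DT, seed=seed,
                            V0=V0, gains0=g0)
            r = res.rate("exc_a")[int(5.0 / DT):]
            nb = int(r.size * DT / block)
            blocks = r[: nb * int(block / DT)].reshape(nb, -1).mean(axis=1)
            means.append(blocks.mean())
            sems.append(blocks.std(ddof=1) / np.sqrt(nb))
        assert abs(means[0] - means[1]) < 3 * np.hypot(*sems)

    def test_membrane_bounded_and_rates_nonnegative(self, ref_net, ref_baseline):
        p = ref_net.params
        V0, g0 = ref_baseline
        proto = StimulusProtocol(
            10.0,
            (Pulse(ref_net.cells[0], 1.0, 0.2, 3 * p.I_exc_on),),
            (GIPulse(5.0, 0.5, 10.0),),
        )
        res = integrate(ref_net, proto, dt=DT, seed=None, V0=V0, gains0=g0)
        assert res.V.max() <= p.upper_bound + 1e-9
        assert res.V.min() >= -p.lower_bound - 1e-9
        assert res.rates.min() >= 0.0
        assert res.gains.min() >= 0.0 and res.gains.max() <= 1.0

    def test_rates_are_thresholded_membranes(self, ref_pulse_result):
        res = ref_pulse_result
        gamma = res.net.params.gamma
        assert np.array_equal(res.rates, np.maximum(0.0, res.V - gamma))

    def test_stimulus_swap_symmetry(self, ref_net, ref_baseline):
        # stimulating exc_b instead of exc_a mirrors every trace exactly
        V0, g0 = ref_baseline
        ra = integrate(ref_net, default_protocol(ref_net, t_end=10.0, target="exc_a"),
                       dt=DT, seed=None, V0=V0, gains0=g0)
        rb = integrate(ref_net, default_protocol(ref_net, t_end=10.0, target="exc_b"),
                       dt=DT, seed=None, V0=V0, gains0=g0)
        swap = [1, 0, 3, 2]
        assert np.array_equal(ra.V, rb.V[:, swap])

    def test_step_halving_convergence(self, ref_net, ref_baseline):
        V0, g0 = ref_baseline
        proto = default_protocol(ref_net, t_end=12.0)
        r1 = integrate(ref_net, proto, dt=1e-3, seed=None, V0=V0, gains0=g0)
        r2 = integrate(ref_net, proto, dt=5e-4, seed=None, V0=V0, gains0=g0)
        diff = np.max(np.abs(r1.rates - r2.rates[::2]))
        assert diff < 0.05
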