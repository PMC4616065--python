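"""Activity measurement, fixed points, regime classification, bisection."""

import numpy as np
import pytest

from canoncircuit import (
    BracketError,
    MeasurementWindows,
    StimulusProtocol,
    build_network,
    critical_parameter,
    default_protocol,
    find_equilibria,
    integrate,
    measure_activity,
    reference_params,
)
from canoncircuit.simulate import SimResult, firing_rate


def _synthetic_result(net, t, rates_by_cell):
    """Wrap hand-written rate traces in a SimResult (membrane = rate + gamma)."""
    gamma = net.params.gamma
    n = net.n_cells
    V = np.zeros((t.size, n))
    for cell, r in rates_by_cell.items():
        V[:, net.index(cell)] = np.asarray(r) + gamma
    rates = firing_rate(V, gamma)
    gains = np.ones((t.size, net.n_gains))
    return SimResult(t, V, gains, rates, net,
                     StimulusProtocol.empty(float(t[-1])), float(t[1] - t[0]), None)


class TestMeasureActivity:
    def test_flat_trace_has_zero_maintained(self, ref_net):
        t = np.arange(0, 16.0, 0.01)
        res = _synthetic_result(ref_net, t, {"exc_a": np.full(t.size, 3.0),
                                             "exc_b": np.full(t.size, 3.0)})
        s = measure_activity(res)["exc_a"]
        assert s.baseline_activity == pytest.approx(3.0)
        assert s.short_maintained == pytest.approx(0.0)
        assert s.long_maintained == pytest.approx(0.0)

    def test_step_trace_measures_the_step(self, ref_net):
        t = np.arange(0, 16.0, 0.01)
        r = np.where(t < 6.0, 1.0, 3.0)  # step of +2 after 6 s
        res = _synthetic_result(ref_net, t, {"exc_a": r})
        s = measure_activity(res)["exc_a"]
        assert s.long_maintained == pytest.approx(2.0)

    def test_window_outside_simulation_names_window(self, ref_net):
        t = np.arange(0, 10.0, 0.01)
        res = _synthetic_result(ref_net, t, {"exc_a": np.ones(t.size)})
        with pytest.raises(ValueError, match="long_term"):
            measure_activity(res, MeasurementWindows(long_term=(12.0, 15.0)))

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            MeasurementWindows(baseline=(2.0, 6.0), short_term=(5.5, 8.5))

    def test_reference_run_signs(self, ref_summary):
        # stimulated cell keeps memory; competitor's late mean sits below its baseline
        a = ref_summary["exc_a"]
        b = ref_summary["exc_b"]
        assert a.long_maintained > 0
        assert b.short_maintained < 0


class TestFindEquilibria:
    def test_decoupled_network_matches_scalar_balance(self):
        p = reference_params(W_exc=0.0, W_inh=0.0, eta_exc=0.0, eta_inh=0.0)
        net = build_network(p)
        rep = find_equilibria(net)
        assert len(rep.fixed_points) == 1
        fp = rep.fixed_points[0]
        assert fp.is_stable
        v_exc = p.upper_bound * p.R / (p.decay_exc + p.R)
        v_inh = p.upper_bound * p.R / (p.decay_inh + p.R)
        expect = np.array([v_exc, v_exc, v_inh, v_inh])
        assert np.allclose(fp.V, expect, atol=1e-8)
        assert rep.regime == "single"

    def test_reference_network_single_regime(self, ref_net):
        rep = find_equilibria(ref_net)
        assert rep.baseline.is_stable
        assert rep.regime == "single"

    def test_high_inhibition_dual_regime(self, ref_params):
        net = build_network(ref_params.replace(W_inh=0.7))
        rep = find_equilibria(net)
        assert rep.regime == "dual"
        exc_idx = [0, 1]
        elev = [fp for fp in rep.stable_points
                if fp.V[exc_idx].max() > rep.baseline.V[exc_idx].max() + 1e-3]
        assert elev, "expected a stable fixed point with elevated shape-cell activity"

    def test_relaxation_lands_on_a_listed_fixed_point(self, ref_params):
        # perturbed baseline relaxes onto one of the report's fixed points
        net = build_network(ref_params.replace(W_inh=0.7))
        rep = find_equilibria(net)
        V0 = rep.baseline.V.copy()
        V0[0] += 0.01 * ref_params.upper_bound
        res = integrate(net, StimulusProtocol.empty(60.0), dt=1e-3, seed=None,
                        V0=V0, gains0=rep.baseline.gains.copy())
        dists = [np.max(np.abs(res.V[-1] - fp.V)) for fp in rep.fixed_points]
        assert min(dists) < 1e-3


class TestCriticalParameter:
    def test_synthetic_classifier_bisection(self, ref_net):
        crit = critical_parameter(
            ref_net, "W_inh", 0.0, 1.0, tol=1e-3,
            classifier=lambda x: "single" if x < 0.6 else "dual",
        )
        assert crit == pytest.approx(0.6, abs=1e-3)

    def test_same_label_everywhere_raises(self, ref_net):
        with pytest.raises(BracketError):
            critical_parameter(ref_net, "W_inh", 0.0, 1.0, tol=1e-2,
                               classifier=lambda x: "single")

    def test_bad_interval_rejected(self, ref_net):
        with pytest.raises(ValueError):
            critical_parameter(ref_net, "W_inh", 1.0, 0.5)
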