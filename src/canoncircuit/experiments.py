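"""Scripted experiment drivers.

Each driver reproduces one of the model's signature protocols and returns
both the raw trajectories and the derived summary quantities; the derived
quantities are exactly the phenomena the circuit is known for (maintained
activity and its origin, reset by global inhibition, priming, proactive
interference, masking, and the cueing time course), so a driver run doubles
as an integration test of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import MeasurementWindows, measure_activity, parameter_sweep
from .network import NetworkConfig, build_network
from .params import CellId, ModelParams, reference_params
from .protocol import GIPulse, Pulse, StimulusProtocol
from .simulate import SimResult, integrate
from .analysis import baseline_state

__all__ = [
    "Fig1Result", "Fig5ResetResult", "Fig5NoveltyResult", "CueingResult",
    "run_fig1", "run_fig2", "run_fig3", "run_fig4",
    "run_fig5_reset", "run_fig5_novelty", "run_cueing",
]

_PULSE_DUR = 0.2


def _single_pulse(net, onset=5.0, t_end=16.0, amplitude=None, target="exc_a"):
    amp = net.params.I_exc_on if amplitude is None else amplitude
    cell = net.cells[net.index(target)]
    return StimulusProtocol(t_end, (Pulse(cell, onset, _PULSE_DUR, amp),))


def _run(net, protocol, dt, seed=None):
    V0, g0 = baseline_state(net)
    return integrate(net, protocol, dt=dt, seed=seed, V0=V0, gains0=g0)


# ---------------------------------------------------------------------------
# maintained activity and its origin
# ---------------------------------------------------------------------------

@dataclass
class Fig1Result:
    isolation: SimResult
    network_noisy: SimResult
    by_strength: dict            # input amplitude -> SimResult
    iso_long: float              # long-term maintained, isolated cells
    net_long: float              # long-term maintained, intact network (noise off run)
    strength_long: dict          # input amplitude -> long-term maintained


def run_fig1(
    params: ModelParams | None = None,
    input_strengths=(2.0, 4.0, 8.0),
    noise_amp: float = 0.2,
    noise_seed: int = 7,
    dt: float = 5e-4,
    windows: MeasurementWindows = MeasurementWindows(),
) -> Fig1Result:
    """Maintained activity needs the network, scales with input strength.

    Three conditions: the shape cells in isolation (inhibition removed), the
    intact network with additive membrane noise, and the intact noise-free
    network at several stimulus amplitudes.
    """
    p = params or reference_params()
    iso_net = build_network(p.replace(noise_amp=0.0), isolation=True)
    iso = _run(iso_net, _single_pulse(iso_net), dt)
    iso_long = measure_activity(iso, windows)["exc_a"].long_maintained

    noisy_net = build_network(p.replace(noise_amp=noise_amp))
    noisy = _run(noisy_net, _single_pulse(noisy_net), dt, seed=noise_seed)

    net = build_network(p.replace(noise_amp=0.0))
    by_strength, strength_long = {}, {}
    for amp in input_strengths:
        res = _run(net, _single_pulse(net, amplitude=amp), dt)
        by_strength[amp] = res
        strength_long[amp] = measure_activity(res, windows)["exc_a"].long_maintained
    net_long = strength_long.get(p.I_exc_on) or measure_activity(
        _run(net, _single_pulse(net), dt), windows)["exc_a"].long_maintained
    return Fig1Result(iso, noisy, by_strength, iso_long, net_long, strength_long)


# ---------------------------------------------------------------------------
# parameter sweeps (thin drivers)
# ---------------------------------------------------------------------------

def run_fig2(params: ModelParams | None = None, values=None, dt: float = 5e-4) -> pd.DataFrame:
    """Mutual-inhibition sweep: maintained activity vs W_inh."""
    p = params or reference_params()
    if values is None:
        values = np.round(np.arange(0.40, 0.70001, 0.025), 4)
    return parameter_sweep(build_network(p), "W_inh", values, dt=dt)


def run_fig3(params: ModelParams | None = None, values=None, dt: float = 5e-4) -> pd.DataFrame:
    """Repetition-suppression sweep: maintained activity vs eta_exc."""
    p = params or reference_params()
    if values is None:
        values = np.round(np.linspace(0.0, 2.0 * p.eta_exc, 9), 6)
    return parameter_sweep(build_network(p), "eta_exc", values, dt=dt)


def run_fig4(params: ModelParams | None = None, values=None, dt: float = 5e-4) -> pd.DataFrame:
    """Baseline-drive sweep: maintained activity vs R."""
    p = params or reference_params()
    if values is None:
        values = np.round(np.linspace(0.0, 1.5, 13), 6)
    return parameter_sweep(build_network(p), "R", values, dt=dt)


# ---------------------------------------------------------------------------
# voluntary reset (global inhibition)
# ---------------------------------------------------------------------------

@dataclass
class Fig5ResetResult:
    runs: dict                   # GI strength -> SimResult
    baseline: float
    transient_first: float
    transient_second: float
    maintained_after_first: float
    maintained_after_second: float
    reset_time: dict             # GI strength -> s after GI offset (inf if never)


def _maintained_after(res, cell, t0, t1, base):
    return res.window_mean(cell, t0, t1) - base


def _reset_time(res, cell, base, gi_off, tol_frac=0.05, hold=1.0):
    """Time after GI offset until the rate stays within tol of baseline for
    ``hold`` seconds; inf if that never happens before t_end."""
    r = res.rate(cell)
    t = res.t
    tol = max(tol_frac * base, 1e-3)
    ok = np.abs(r - base) <= tol
    idx = np.where(t >= gi_off)[0]
    need = int(round(hold / res.dt))
    run = 0
    for i in idx:
        run = run + 1 if ok[i] else 0
        if run >= need:
            return float(t[i - need + 1] - gi_off)
    return float("inf")


def run_fig5_reset(
    params: ModelParams | None = None,
    gi_strengths=(0.0, 0.3, 0.35, 0.45),
    dt: float = 5e-4,
) -> Fig5ResetResult:
    """Two repeated same-shape pulses, then a 200 ms global-inhibition pulse.

    Shows repetition suppression of the second transient, memory priming
    (higher maintained activity after the repeat), and voluntary reset whose
    speed grows with GI strength.
    """
    p = (params or reference_params()).replace(noise_amp=0.0)
    net = build_network(p)
    cell = net.cells[net.index("exc_a")]
    runs, reset = {}, {}
    first = None
    for g in gi_strengths:
        proto = StimulusProtocol(
            25.0,
            (Pulse(cell, 5.0, _PULSE_DUR, p.I_exc_on), Pulse(cell, 10.0, _PULSE_DUR, p.I_exc_on)),
            (GIPulse(20.0, _PULSE_DUR, g),) if g > 0 else (),
        )
        res = _run(net, proto, dt)
        runs[g] = res
        base = res.window_mean(cell, 2.0, 5.0)
        reset[g] = _reset_time(res, cell, base, 20.0 + _PULSE_DUR)
        if first is None:
            first = (res, base)
    res0, base = first
    summ = measure_activity(res0, MeasurementWindows((2.0, 5.0), (5.5, 8.5), (12.0, 15.0)))
    t1 = summ["exc_a"].transient_peak
    # second transient, relative to the 500 ms immediately preceding it
    r = res0.rate(cell)
    pre = r[(res0.t >= 9.5) & (res0.t < 10.0)].mean()
    t2 = float(r[(res0.t >= 10.0) & (res0.t <= 10.0 + _PULSE_DUR + 0.3)].max() - pre)
    m1 = _maintained_after(res0, cell, 7.0, 10.0, base)
    m2 = _maintained_after(res0, cell, 12.0, 15.0, base)
    return Fig5ResetResult(runs, base, t1, t2, m1, m2, reset)


# ---------------------------------------------------------------------------
# novel input: masking, proactive interference, priming
# ---------------------------------------------------------------------------

@dataclass
class Fig5NoveltyResult:
    run_ab: SimResult            # a-pulse at 5 s, b-pulse at 10 s
    run_b_alone: SimResult       # b-pulse at 10 s only
    base_a: float
    base_b: float
    a_after_b: float             # exc_a mean over the late window minus its baseline
    maintained_b_with_prior_a: float
    maintained_b_alone: float


def run_fig5_novelty(params: ModelParams | None = None, dt: float = 5e-4) -> Fig5NoveltyResult:
    """A novel (different-shape) input masks the old trace and suffers
    proactive interference from it."""
    p = (params or reference_params()).replace(noise_amp=0.0)
    net = build_network(p)
    a = net.cells[net.index("exc_a")]
    b = net.cells[net.index("exc_b")]
    proto_ab = StimulusProtocol(
        20.0, (Pulse(a, 5.0, _PULSE_DUR, p.I_exc_on), Pulse(b, 10.0, _PULSE_DUR, p.I_exc_on))
    )
    proto_b = StimulusProtocol(20.0, (Pulse(b, 10.0, _PULSE_DUR, p.I_exc_on),))
    res_ab = _run(net, proto_ab, dt)
    res_b = _run(net, proto_b, dt)
    base_a = res_ab.window_mean(a, 2.0, 5.0)
    base_b = res_ab.window_mean(b, 2.0, 5.0)
    a_after_b = res_ab.window_mean(a, 12.0, 15.0) - base_a
    mb_prior = res_ab.window_mean(b, 12.0, 15.0) - base_b
    mb_alone = res_b.window_mean(b, 12.0, 15.0) - res_b.window_mean(b, 2.0, 5.0)
    return Fig5NoveltyResult(res_ab, res_b, base_a, base_b, a_after_b, mb_prior, mb_alone)


# ---------------------------------------------------------------------------
# two-location reflexive attention
# ---------------------------------------------------------------------------

@dataclass
class CueingResult:
    """Cueing effect per cue-target onset asynchrony (CTOA).

    The behavioral proxy is the target-evoked transient of the target-shape
    cell at the target location: the peak rate during the target response
    minus the mean rate over the 500 ms preceding target onset (the same
    convention as :class:`~canoncircuit.analysis.ActivitySummary`'s
    transient peak; a larger transient = faster downstream localization).
    ``cueing_effect`` is that transient when the cue was at the target
    location minus the transient when the cue was at the other location;
    positive = facilitation, negative = inhibition of return.
    """

    ctoa: tuple
    cueing_effect: dict          # ctoa -> SU
    transient_cued: dict
    transient_uncued: dict

    @property
    def sign_changes(self) -> int:
        eff = [self.cueing_effect[c] for c in self.ctoa]
        signs = np.sign(eff)
        return int(np.sum(np.abs(np.diff(signs)) > 0))


def _target_transient(res, cell, onset):
    r = res.rate(cell)
    m = (res.t >= onset) & (res.t <= onset + _PULSE_DUR + 0.3)
    mpre = (res.t >= onset - 0.5) & (res.t < onset)
    return float(r[m].max() - r[mpre].mean())


def run_cueing(
    params: ModelParams | None = None,
    ctoas=(0.1, 0.2, 0.3, 0.5, 1.0, 1.5, 2.0, 3.0),
    dt: float = 5e-4,
) -> CueingResult:
    """Two-location spatial cueing: cue and target share the shape; the cue
    appears at the target's location or at the other location."""
    p = (params or reference_params()).replace(noise_amp=0.0)
    net = build_network(p, locations=2)
    tgt = net.cells[net.index("s.exc_a")]
    cue_same = tgt
    cue_other = net.cells[net.index("s_prime.exc_a")]
    V0, g0 = baseline_state(net)
    effect, peaks_c, peaks_u = {}, {}, {}
    for ctoa in ctoas:
        t_on = 5.0 + ctoa
        t_end = t_on + 2.0
        runs = {}
        for label, cue_cell in (("cued", cue_same), ("uncued", cue_other)):
            proto = StimulusProtocol(
                t_end,
                (Pulse(cue_cell, 5.0, _PULSE_DUR, p.I_exc_on),
                 Pulse(tgt, t_on, _PULSE_DUR, p.I_exc_on)),
            )
            runs[label] = integrate(net, proto, dt=dt, seed=None, V0=V0, gains0=g0)
        peaks_c[ctoa] = _target_transient(runs["cued"], tgt, t_on)
        peaks_u[ctoa] = _target_transient(runs["uncued"], tgt, t_on)
        effect[ctoa] = peaks_c[ctoa] - peaks_u[ctoa]
    return CueingResult(tuple(ctoas), effect, peaks_c, peaks_u)
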