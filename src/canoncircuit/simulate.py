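"""Fixed-step integration of the shunting dynamics.

The membrane equation of every cell has the Grossberg shunting form

    dV/dt = -decay * V + (B - V) * E(t) - (V + D) * I(t)

where ``E`` collects all excitatory drive (habituatively gated tonic input R
plus stimulus, plus gated excitatory couplings) and ``I`` all inhibitory
drive (gated inhibitory couplings plus global inhibition).  Excitation is
gated by the distance to the ceiling ``B`` and inhibition by the distance to
the floor ``-D``, so activities stay inside ``[-D, B]``.  Each habituative
gain ``g`` recovers toward 1 with time constant ``tau_gain`` and is depleted
in proportion to ``eta * (presynaptic signal) * g``; at steady presynaptic
signal ``S`` it settles at ``1 / (1 + eta * tau_gain * S)``.

Integration is explicit Euler (Euler-Maruyama when membrane noise is on)
with a fixed step; the model's time scales (200 ms pulses, multi-second
decays) are far slower than the default 0.5 ms step.  Uniform noise of
half-width ``noise_amp`` enters each membrane equation scaled by
``sqrt(dt)`` so that trajectory statistics are step-size stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CompiledNetwork, NetworkConfig
from .protocol import StimulusProtocol

__all__ = ["firing_rate", "derivatives", "integrate", "SimResult"]


def firing_rate(V, gamma):
    """Threshold-linear rate map: ``max(0, V - gamma)``, slope 1 above threshold."""
    return np.maximum(0.0, np.asarray(V) - gamma)


def external_input(net: NetworkConfig, protocol: StimulusProtocol, t: float):
    """Per-cell stimulus amplitude and global-inhibition strength at time t."""
    ext = np.zeros(net.n_cells)
    for p in protocol.pulses:
        if p.onset <= t < p.onset + p.duration:
            ext[net.index(p.target)] += p.amplitude
    gi = 0.0
    for p in protocol.gi_pulses:
        if p.onset <= t < p.onset + p.duration:
            gi += p.strength
    return ext, gi


def derivatives(
    V: np.ndarray,
    gains: np.ndarray,
    t: float,
    net: NetworkConfig | CompiledNetwork,
    protocol: StimulusProtocol,
):
    """Pure deterministic right-hand side ``(dV/dt, dgains/dt)`` at time t."""
    comp = net if isinstance(net, CompiledNetwork) else net.compiled()
    ext, gi = external_input(comp.net, protocol, t)
    return comp.rhs(np.asarray(V, float), np.asarray(gains, float), ext, gi)


@dataclass
class SimResult:
    """A simulated trajectory on a uniform time grid.

    ``V``/``rates`` are (T, n_cells); ``gains`` is (T, n_gains) in the
    compiled layout (input gains per cell first, then coupling gains).
    """

    t: np.ndarray
    V: np.ndarray
    gains: np.ndarray
    rates: np.ndarray
    net: NetworkConfig
    protocol: StimulusProtocol
    dt: float
    seed: int | None

    def cell_index(self, cell) -> int:
        return self.net.index(cell)

    def rate(self, cell) -> np.ndarray:
        return self.rates[:, self.cell_index(cell)]

    def membrane(self, cell) -> np.ndarray:
        return self.V[:, self.cell_index(cell)]

    def window_mean(self, cell, t0: float, t1: float) -> float:
        m = (self.t >= t0) & (self.t <= t1)
        if not m.any():
            raise ValueError(f"window [{t0}, {t1}] outside simulated time")
        return float(self.rate(cell)[m].mean())

    def to_dataframe(self, stride: int = 1) -> pd.DataFrame:
        """Tidy long table: one row per cell per (strided) time step."""
        comp = self.net.compiled()
        sl = slice(None, None, max(1, int(stride)))
        t = self.t[sl]
        frames = []
        # incoming inhibitory gain per cell (1.0 where the cell receives none)
        gain_inh_col = {}
        for k in range(comp.i_post.size):
            gain_inh_col[int(comp.i_post[k])] = int(comp.i_gain[k])
        for j, cell in enumerate(self.net.cells):
            gi = self.gains[sl, gain_inh_col[j]] if j in gain_inh_col else np.ones_like(t)
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "location": cell.location,
                        "cell": cell.role,
                        "membrane": self.V[sl, j],
                        "rate": self.rates[sl, j],
                        "gain_exc": self.gains[sl, j],
                        "gain_inh": gi,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _pulse_schedule(net, protocol, t):
    """Precompute per-step stimulus array (T, n) and GI vector (T,)."""
    n = net.n_cells
    ext = np.zeros((t.size, n))
    gi = np.zeros(t.size)
    for p in protocol.pulses:
        j = net.index(p.target)
        m = (t >= p.onset) & (t < p.onset + p.duration)
        ext[m, j] += p.amplitude
    for p in protocol.gi_pulses:
        m = (t >= p.onset) & (t < p.onset + p.duration)
        gi[m] += p.strength
    return ext, gi


def integrate(
    net: NetworkConfig,
    protocol: StimulusProtocol,
    dt: float = 5e-4,
    seed: int | None = 0,
    V0: np.ndarray | None = None,
    gains0: np.ndarray | None = None,
) -> SimResult:
    """Integrate the network under a protocol over ``[0, t_end]``.

    With ``noise_amp == 0`` the result is deterministic (seed-independent);
    with noise on, identical seeds give bit-identical trajectories.  Gains
    are clamped to [0, 1] after every step.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    comp = net.compiled()
    n, ng = comp.n, net.n_gains
    nsteps = int(round(protocol.t_end / dt))
    t = np.arange(nsteps + 1) * dt

    V = np.zeros(n) if V0 is None else np.array(V0, float)
    g = np.ones(ng) if gains0 is None else np.array(gains0, float)
    if V.shape != (n,) or g.shape != (ng,):
        raise ValueError("initial state has wrong shape for this network")

    ext_sched, gi_sched = _pulse_schedule(net, protocol, t)
    amp = net.params.noise_amp
    noisy = amp > 0
    rng = np.random.default_rng(seed) if noisy else None
    sq = np.sqrt(dt)

    Vtraj = np.empty((nsteps + 1, n))
    gtraj = np.empty((nsteps + 1, ng))
    Vtraj[0], gtraj[0] = V, g
    for k in range(nsteps):
        dV, dg = comp.rhs(V, g, ext_sched[k], gi_sched[k])
        V = V + dt * dV
        if noisy:
            V = V + sq * rng.uniform(-amp, amp, n)
        g = np.clip(g + dt * dg, 0.0, 1.0)
        Vtraj[k + 1], gtraj[k + 1] = V, g

    rates = firing_rate(Vtraj, comp.gamma)
    return SimResult(t, Vtraj, gtraj, rates, net, protocol, dt, seed if noisy else None)
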