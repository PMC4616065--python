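"""Dynamical analysis: activity measurement over the standard windows,
fixed-point location and stability, regime classification, critical-parameter
bisection, and parameter sweeps.

Regimes
-------
single
    The baseline (spontaneous-activity) fixed point is stable and is the
    only stable fixed point: any maintained activity eventually decays back
    to baseline at a parameter-controlled rate.
dual
    A second stable fixed point with elevated shape-cell activity exists
    (and the baseline point is typically unstable): a perturbation latches
    the network into the elevated state and maintained activity becomes
    input-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import root

from .network import NetworkConfig
from .protocol import StimulusProtocol
from .simulate import SimResult, firing_rate, integrate

__all__ = [
    "MeasurementWindows",
    "ActivitySummary",
    "CellActivity",
    "FixedPoint",
    "EquilibriumReport",
    "measure_activity",
    "find_equilibria",
    "baseline_state",
    "classify_regime",
    "critical_parameter",
    "parameter_sweep",
    "RegimeInconsistencyError",
    "BracketError",
]


# ---------------------------------------------------------------------------
# activity measurement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementWindows:
    """Averaging windows (s): baseline before the first pulse, a short-term
    window soon after offset, and a longer-term window well after offset."""

    baseline: tuple[float, float] = (2.0, 5.0)
    short_term: tuple[float, float] = (5.5, 8.5)
    long_term: tuple[float, float] = (12.0, 15.0)

    def __post_init__(self) -> None:
        b, s, l = self.baseline, self.short_term, self.long_term
        for name, (t0, t1) in (("baseline", b), ("short_term", s), ("long_term", l)):
            if not (0 <= t0 < t1):
                raise ValueError(f"window {name} must satisfy 0 <= t0 < t1")
        if not (b[1] <= s[0] and s[1] <= l[0]):
            raise ValueError("windows must be ordered baseline < short_term < long_term")


@dataclass(frozen=True)
class CellActivity:
    baseline_activity: float
    short_maintained: float
    long_maintained: float
    transient_peak: float


@dataclass(frozen=True)
class ActivitySummary:
    """Window-averaged activity per excitatory cell.

    Maintained values are window means minus the baseline-window mean;
    ``transient_peak`` is the peak rate during/shortly after the cell's
    first pulse minus the mean rate over the 500 ms preceding the pulse.
    """

    cells: dict

    def __getitem__(self, key) -> CellActivity:
        if key in self.cells:
            return self.cells[key]
        # bare role lookup
        for cell, v in self.cells.items():
            if cell.role == key:
                return v
        raise KeyError(key)


def _check_window(name, win, t_end):
    if win[1] > t_end + 1e-9:
        raise ValueError(f"window {name!r} [{win[0]}, {win[1]}] extends past simulated t_end={t_end}")


def measure_activity(
    result: SimResult,
    windows: MeasurementWindows = MeasurementWindows(),
    transient_tail: float = 0.3,
) -> ActivitySummary:
    """Summarise a simulation into baseline / maintained / transient values."""
    t_end = float(result.t[-1])
    for name in ("baseline", "short_term", "long_term"):
        _check_window(name, getattr(windows, name), t_end)
    out = {}
    for cell in result.net.cells:
        if not cell.is_excitatory:
            continue
        r = result.rate(cell)
        base = result.window_mean(cell, *windows.baseline)
        short = result.window_mean(cell, *windows.short_term) - base
        long_ = result.window_mean(cell, *windows.long_term) - base
        pulses = [p for p in result.protocol.pulses if p.target == cell]
        peak = float("nan")
        if pulses:
            p = min(pulses, key=lambda q: q.onset)
            pre0, pre1 = max(0.0, p.onset - 0.5), p.onset
            mpre = (result.t >= pre0) & (result.t < pre1)
            pre = float(r[mpre].mean()) if mpre.any() else 0.0
            mdur = (result.t >= p.onset) & (result.t <= p.onset + p.duration + transient_tail)
            peak = float(r[mdur].max()) - pre
        out[cell] = CellActivity(base, short, long_, peak)
    return ActivitySummary(out)


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint:
    V: np.ndarray
    gains: np.ndarray
    stability: str           # "stable" | "unstable"
    method: str              # "constrained_solve" | "multistart_root"
    eigenvalues: np.ndarray = field(repr=False, default=None)

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class EquilibriumReport:
    fixed_points: tuple[FixedPoint, ...]
    baseline: FixedPoint
    regime: str              # "single" | "dual"

    @property
    def stable_points(self) -> tuple[FixedPoint, ...]:
        return tuple(fp for fp in self.fixed_points if fp.is_stable)


def _steady_gains(comp, V, rectified=True):
    """Gain states at steady state given membrane activities."""
    f = firing_rate(V, comp.gamma) if rectified else (V - comp.gamma)
    g = np.empty(comp.n + comp.coupling_eta.size)
    g[: comp.n] = 1.0 / (1.0 + comp.input_eta * comp.tau * comp.R)
    g[comp.n :] = 1.0 / (1.0 + comp.coupling_eta * comp.tau * f[comp.coupling_pre])
    return g


def _residual(comp, V, rectified=True):
    """Membrane derivatives with gains at their steady-state values."""
    f = firing_rate(V, comp.gamma) if rectified else (V - comp.gamma)
    g = _steady_gains(comp, V, rectified)
    exc = g[: comp.n] * comp.R
    if comp.e_pre.size:
        np.add.at(exc, comp.e_post, comp.e_w * g[comp.e_gain] * f[comp.e_pre])
    inh = np.zeros(comp.n)
    if comp.i_pre.size:
        np.add.at(inh, comp.i_post, comp.i_w * g[comp.i_gain] * f[comp.i_pre])
    return -comp.decay * V + (comp.B - V) * exc - (V + comp.D) * inh


def _full_jacobian(comp, V, gains, h=1e-6):
    """Central-difference Jacobian of the full (V, gains) system at rest input."""
    n, ng = comp.n, gains.size
    x0 = np.concatenate([V, gains])
    ext = np.zeros(n)

    def F(x):
        dV, dg = comp.rhs(x[:n], x[n:], ext, 0.0)
        return np.concatenate([dV, dg])

    J = np.empty((n + ng, n + ng))
    for j in range(n + ng):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (F(xp) - F(xm)) / (2 * h)
    return J


_STABILITY_MARGIN = 1e-8
_MERGE_TOL = 1e-6


def baseline_state(net: NetworkConfig, t_relax: float = 30.0, dt: float = 1e-3):
    """The spontaneous-activity (baseline) fixed point.

    Located by relaxing the unstimulated network from rest — the dynamics
    preserve the a<->b exchange symmetry, so this converges to the symmetric
    baseline point even when it is unstable to asymmetric perturbations —
    then polishing with a root solve.
    """
    comp = net.compiled()
    res = integrate(
        net.with_params(net.params.replace(noise_amp=0.0)),
        StimulusProtocol.empty(t_relax), dt=dt, seed=None,
    )
    V_guess = res.V[-1]
    sol = root(lambda v: _residual(comp, v), V_guess, method="hybr", tol=1e-12)
    V = sol.x if sol.success else V_guess
    return V, _steady_gains(comp, V)


def _label_stability(comp, V):
    g = _steady_gains(comp, V)
    J = _full_jacobian(comp, V, g)
    eig = np.linalg.eigvals(J)
    stab = "unstable" if eig.real.max() > _STABILITY_MARGIN else "stable"
    return g, stab, eig


def find_equilibria(
    net: NetworkConfig,
    grid_levels: int = 5,
    max_starts: int = 800,
    seed: int = 0,
) -> EquilibriumReport:
    """Locate and classify the unstimulated network's fixed points.

    Two routes: (i) a constrained solve assuming every cell is above the
    firing threshold, which removes the rate rectification and leaves a
    smooth algebraic system (solutions inconsistent with the all-active
    assumption are discarded); (ii) a multistart rectified root search from
    a grid over [0, upper_bound] per cell, which catches fixed points with
    silent cells.  Duplicates are merged within 1e-6 SU; stability comes
    from the eigenvalues of the full-system Jacobian (membranes + gains).
    """
    comp = net.compiled()
    n = comp.n
    found: list[tuple[np.ndarray, str]] = []

    def push(V, method):
        if not np.all(np.isfinite(V)):
            return
        if np.max(np.abs(_residual(comp, V))) > 1e-8:
            return
        if V.min() < -comp.D - 1e-6 or V.max() > comp.B + 1e-6:
            return
        for Vk, _ in found:
            if np.max(np.abs(Vk - V)) < _MERGE_TOL:
                return
        found.append((V.copy(), method))

    # (i) constrained solve, all cells active
    base_guess, _ = baseline_state(net)
    starts = [base_guess, np.full(n, comp.gamma + 0.5), np.full(n, 0.5 * comp.B)]
    for s in starts:
        sol = root(lambda v: _residual(comp, v, rectified=False), s, method="hybr", tol=1e-12)
        if sol.success and np.all(sol.x >= comp.gamma - 1e-9):
            push(sol.x, "constrained_solve")

    # (ii) multistart rectified search
    levels = np.linspace(0.0, comp.B, grid_levels)
    if grid_levels ** n <= max_starts:
        grid = np.stack(np.meshgrid(*([levels] * n), indexing="ij"), -1).reshape(-1, n)
    else:
        rng = np.random.default_rng(seed)
        grid = levels[rng.integers(0, grid_levels, size=(max_starts, n))]
    grid = np.vstack([grid, base_guess])
    tried = []
    for s in grid:
        sol = root(lambda v: _residual(comp, v), s, method="hybr", tol=1e-12)
        tried.append(s)
        if sol.success:
            push(sol.x, "multistart_root")
    if not found:
        raise RuntimeError(
            f"fixed-point search failed to converge from {len(tried)} starts"
        )

    fps = []
    for V, method in found:
        g, stab, eig = _label_stability(comp, V)
        fps.append(FixedPoint(V, g, stab, method, eig))

    # the baseline point is the symmetric one nearest the rest relaxation
    base_fp = min(fps, key=lambda fp: np.max(np.abs(fp.V - base_guess)))
    regime = _regime_from_points(net, fps, base_fp)
    return EquilibriumReport(tuple(fps), base_fp, regime)


def _regime_from_points(net, fps, base_fp) -> str:
    exc_idx = [j for j, c in enumerate(net.cells) if c.is_excitatory]
    base_exc = base_fp.V[exc_idx].max()
    elevated_stable = any(
        fp.is_stable
        and fp is not base_fp
        and fp.V[exc_idx].max() > base_exc + 1e-3
        for fp in fps
    )
    if elevated_stable:
        return "dual"
    return "single" if base_fp.is_stable else "dual"


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

class RegimeInconsistencyError(RuntimeError):
    """Jacobian stability label and perturbation simulation disagree strongly."""


class BracketError(ValueError):
    """No regime change found inside the requested parameter interval."""


def classify_regime(
    net: NetworkConfig,
    cross_check: bool = True,
    t_relax: float = 60.0,
    dt: float = 1e-3,
    report: EquilibriumReport | None = None,
) -> str:
    """Classify the operating regime as ``"single"`` or ``"dual"``.

    With ``cross_check`` the eigenvalue label of the baseline point is
    verified by a small-perturbation simulation (+1% of upper_bound on one
    shape cell, 60 s relaxation, noise off).  Only a strong disagreement —
    the perturbed trajectory settling on a different fixed point despite a
    stable label, or returning essentially exactly to baseline despite an
    unstable label — raises :class:`RegimeInconsistencyError`; slow
    near-critical relaxations are left to the eigenvalue verdict.
    """
    rep = report if report is not None else find_equilibria(net)
    if not cross_check:
        return rep.regime

    quiet = net.with_params(net.params.replace(noise_amp=0.0))
    pert = 0.01 * net.params.upper_bound
    V0 = rep.baseline.V.copy()
    V0[net.index(f"{net.cells[0].location}.exc_a")] += pert
    res = integrate(quiet, StimulusProtocol.empty(t_relax), dt=dt, seed=None,
                    V0=V0, gains0=rep.baseline.gains.copy())
    dev_end = np.max(np.abs(res.V[-1] - rep.baseline.V))
    if rep.baseline.is_stable:
        others = [fp for fp in rep.fixed_points if fp is not rep.baseline and fp.is_stable]
        if dev_end > 10 * pert and any(
            np.max(np.abs(res.V[-1] - fp.V)) < pert for fp in others
        ):
            raise RegimeInconsistencyError(
                "baseline labeled stable but a small perturbation settled on "
                "another fixed point (stiff/tolerance problem?)"
            )
    else:
        if dev_end < 0.1 * pert:
            raise RegimeInconsistencyError(
                "baseline labeled unstable but a small perturbation returned "
                "to baseline (stiff/tolerance problem?)"
            )
    return rep.regime


def critical_parameter(
    net: NetworkConfig,
    param: str,
    lo: float,
    hi: float,
    tol: float = 1e-3,
    cross_check: bool = False,
    scan_points: int = 16,
    classifier=None,
) -> float:
    """Bisect ``classify_regime`` over a parameter to locate the regime boundary.

    Returns the midpoint of the final bracket.  If the two endpoints share a
    regime, a coarse scan locates the rightmost regime flip inside the
    interval and that bracket is bisected; if the regime never changes a
    :class:`BracketError` is raised.  ``classifier`` (value -> label)
    replaces the regime classifier when given.
    """
    if not hi > lo:
        raise ValueError("need hi > lo")

    def regime_at(x: float) -> str:
        if classifier is not None:
            return classifier(float(x))
        p = net.params.replace(**{param: float(x)})
        return classify_regime(net.with_params(p), cross_check=cross_check)

    r_lo, r_hi = regime_at(lo), regime_at(hi)
    if r_lo == r_hi:
        xs = np.linspace(lo, hi, scan_points + 1)
        rs = [r_lo] + [regime_at(x) for x in xs[1:-1]] + [r_hi]
        flips = [k for k in range(len(xs) - 1) if rs[k] != rs[k + 1]]
        if not flips:
            raise BracketError(
                f"regime is {r_lo!r} at both ends of [{lo}, {hi}] and no "
                f"transition was found on a {scan_points + 1}-point scan"
            )
        k = flips[-1]
        lo, hi, r_lo = float(xs[k]), float(xs[k + 1]), rs[k]
    while hi - lo > 2 * tol:
        mid = 0.5 * (lo + hi)
        if regime_at(mid) == r_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def default_protocol(net: NetworkConfig, t_end: float = 16.0,
                     onset: float = 5.0, duration: float = 0.2,
                     amplitude: float | None = None,
                     target: str = "exc_a") -> StimulusProtocol:
    """The standard single-pulse protocol: one 200 ms pulse to one shape cell."""
    from .protocol import Pulse
    amp = net.params.I_exc_on if amplitude is None else amplitude
    cell = net.cells[net.index(target)]
    return StimulusProtocol(t_end, (Pulse(cell, onset, duration, amp),))


def parameter_sweep(
    net: NetworkConfig,
    param: str,
    values,
    protocol: StimulusProtocol | None = None,
    windows: MeasurementWindows = MeasurementWindows(),
    stim_cell: str = "exc_a",
    classify: bool = True,
    dt: float = 5e-4,
) -> pd.DataFrame:
    """One row per parameter value: regime plus the activity summary of the
    stimulated cell under the standard single-pulse protocol."""
    values = np.asarray(list(values), float)
    if not np.all(np.isfinite(values)):
        raise ValueError("sweep values must be finite")
    if not np.all(np.diff(values) >= 0):
        raise ValueError("sweep values must be sorted ascending")
    rows = []
    for v in values:
        try:
            p = net.params.replace(**{param: float(v)}, noise_amp=0.0)
            swept = net.with_params(p)
            regime = classify_regime(swept, cross_check=False) if classify else ""
            proto = protocol if protocol is not None else default_protocol(swept)
            V0, g0 = baseline_state(swept)
            res = integrate(swept, proto, dt=dt, seed=None, V0=V0, gains0=g0)
            summ = measure_activity(res, windows)[stim_cell]
        except Exception as exc:
            raise RuntimeError(f"sweep of {param!r} failed at value {v}") from exc
        rows.append(
            {
                "param": param,
                "value": float(v),
                "regime": regime,
                "baseline": summ.baseline_activity,
                "short_maintained": summ.short_maintained,
                "long_maintained": summ.long_maintained,
                "transient_peak": summ.transient_peak,
            }
        )
    return pd.DataFrame(rows)
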