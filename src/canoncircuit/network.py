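"""Network wiring: cells, couplings, and the compiled index arrays the
integrator and equilibrium solver share."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import LOCATIONS, ROLES, CellId, ModelParams

__all__ = ["Coupling", "NetworkConfig", "build_network"]


@dataclass(frozen=True)
class Coupling:
    """A directed synapse between two cells.

    ``kind`` is "excitatory" (enters the shunting excitatory term, gated by
    ceiling distance) or "inhibitory" (enters the inhibitory term, gated by
    floor distance).  ``eta`` is the peak adaptive-gain-change parameter of
    the synapse's habituative gate; 0 pins the gate at 1.
    """

    pre: CellId
    post: CellId
    weight: float
    kind: str
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("excitatory", "inhibitory"):
            raise ValueError(f"coupling kind must be excitatory|inhibitory, got {self.kind!r}")
        if self.weight < 0 or self.eta < 0:
            raise ValueError("coupling weight and eta must be >= 0")


@dataclass(frozen=True)
class NetworkConfig:
    """A wired network: parameters, ordered cells, and couplings.

    Every cell additionally owns an external-input excitatory synapse that
    carries the tonic drive R plus any stimulus pulse addressed to the cell;
    input synapses are non-adaptive.  The habituative excitatory synapses
    are the shape cell -> interneuron couplings (parameter ``eta_exc``,
    depleted by the presynaptic shape-cell rate), so their gain falls when
    baseline or stimulus-evoked activity rises - the circuit's repetition
    suppression.  The interneuron -> shape cell couplings adapt with
    ``eta_inh``.
    """

    params: ModelParams
    cells: tuple[CellId, ...]
    couplings: tuple[Coupling, ...]
    isolation: bool = False

    # -- lookups -----------------------------------------------------------
    def index(self, cell: CellId | str) -> int:
        if isinstance(cell, str):
            labels = [c.label for c in self.cells]
            # allow bare role for single-location networks
            if cell not in labels and "." not in cell:
                cell = f"{self.cells[0].location}.{cell}"
            return labels.index(cell)
        return self.cells.index(cell)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_gains(self) -> int:
        """One gain state per external-input synapse plus one per coupling."""
        return self.n_cells + len(self.couplings)

    def with_params(self, params: ModelParams) -> "NetworkConfig":
        """Rebuild this network's wiring from new parameters."""
        locations = len({c.location for c in self.cells})
        return build_network(params, locations=locations, isolation=self.isolation)

    # -- compiled view -----------------------------------------------------
    def compiled(self) -> "CompiledNetwork":
        return CompiledNetwork(self)


class CompiledNetwork:
    """Index arrays for fast vectorised evaluation of the dynamics.

    Gain-state layout: ``[input gains (one per cell)] + [coupling gains]``,
    couplings in :attr:`NetworkConfig.couplings` order.
    """

    def __init__(self, net: NetworkConfig) -> None:
        p = net.params
        self.net = net
        self.n = net.n_cells
        self.decay = np.array(
            [p.decay_exc if c.is_excitatory else p.decay_inh for c in net.cells]
        )
        # external-input synapses are non-adaptive
        self.input_eta = np.zeros(self.n)
        self.B = p.upper_bound
        self.D = p.lower_bound
        self.R = p.R
        self.tau = p.tau_gain
        self.gamma = p.gamma

        exc = [c for c in net.couplings if c.kind == "excitatory"]
        inh = [c for c in net.couplings if c.kind == "inhibitory"]
        order = list(net.couplings)
        self.e_pre = np.array([net.index(c.pre) for c in exc], dtype=int)
        self.e_post = np.array([net.index(c.post) for c in exc], dtype=int)
        self.e_w = np.array([c.weight for c in exc])
        self.e_eta = np.array([c.eta for c in exc])
        self.e_gain = np.array([self.n + order.index(c) for c in exc], dtype=int)
        self.i_pre = np.array([net.index(c.pre) for c in inh], dtype=int)
        self.i_post = np.array([net.index(c.post) for c in inh], dtype=int)
        self.i_w = np.array([c.weight for c in inh])
        self.i_eta = np.array([c.eta for c in inh])
        self.i_gain = np.array([self.n + order.index(c) for c in inh], dtype=int)
        self.coupling_eta = np.array([c.eta for c in order])
        self.coupling_pre = np.array([net.index(c.pre) for c in order], dtype=int)

    def rhs(self, V: np.ndarray, gains: np.ndarray, ext: np.ndarray, gi: float):
        """Time derivatives of membrane activities and gain states."""
        f = np.maximum(0.0, V - self.gamma)
        s_in = self.R + ext
        exc_drive = gains[: self.n] * s_in
        if self.e_pre.size:
            np.add.at(exc_drive, self.e_post, self.e_w * gains[self.e_gain] * f[self.e_pre])
        inh_drive = np.full(self.n, gi)
        if self.i_pre.size:
            np.add.at(inh_drive, self.i_post, self.i_w * gains[self.i_gain] * f[self.i_pre])
        dV = -self.decay * V + (self.B - V) * exc_drive - (V + self.D) * inh_drive
        dg = np.empty_like(gains)
        g_in = gains[: self.n]
        dg[: self.n] = (1.0 - g_in) / self.tau - self.input_eta * s_in * g_in
        g_c = gains[self.n :]
        dg[self.n :] = (1.0 - g_c) / self.tau - self.coupling_eta * f[self.coupling_pre] * g_c
        return dV, dg


def build_network(
    params: ModelParams, locations: int = 1, isolation: bool = False
) -> NetworkConfig:
    """Wire the canonical circuit at one or two spatial locations.

    Each location holds two shape-selective cells and two interneurons:
    exc_a excites inh_ab which inhibits exc_b, and symmetrically exc_b
    excites inh_ba which inhibits exc_a.  Two-location networks are two
    disjoint copies (no cross-location couplings).  ``isolation`` removes
    the interneuron->cell inhibitory couplings, leaving everything else
    unchanged.
    """
    if locations not in (1, 2):
        raise ValueError(f"locations must be 1 or 2, got {locations!r}")
    cells: list[CellId] = []
    couplings: list[Coupling] = []
    for loc in LOCATIONS[:locations]:
        loc_cells = {role: CellId(loc, role) for role in ROLES}
        cells.extend(loc_cells[role] for role in ROLES)
        couplings.append(
            Coupling(loc_cells["exc_a"], loc_cells["inh_ab"], params.W_exc,
                     "excitatory", params.eta_exc)
        )
        couplings.append(
            Coupling(loc_cells["exc_b"], loc_cells["inh_ba"], params.W_exc,
                     "excitatory", params.eta_exc)
        )
        if not isolation:
            couplings.append(
                Coupling(loc_cells["inh_ab"], loc_cells["exc_b"], params.W_inh,
                         "inhibitory", params.eta_inh)
            )
            couplings.append(
                Coupling(loc_cells["inh_ba"], loc_cells["exc_a"], params.W_inh,
                         "inhibitory", params.eta_inh)
            )
    return NetworkConfig(params, tuple(cells), tuple(couplings), isolation)
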