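"""Model parameters for the 4-cell shunting circuit.

The circuit couples two shape-selective excitatory cells through a pair of
inhibitory interneurons (mutual inhibition).  All coefficients live in
:class:`ModelParams`; the reference set reproduces the phenomena the model
is known for: non-zero baseline firing, stimulus-strength-dependent
maintained activity in the single-equilibrium regime, a transition to a
dual-equilibrium (runaway) regime at high mutual inhibition or low tonic
drive, and repetition suppression through habituative synaptic gains.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["ModelParams", "CellId", "ROLES", "LOCATIONS", "reference_params"]

#: canonical cell ordering within one location
ROLES = ("exc_a", "exc_b", "inh_ab", "inh_ba")

#: canonical location ordering
LOCATIONS = ("s", "s_prime")


@dataclass(frozen=True)
class ModelParams:
    """Fixed coefficients of the circuit.

    Units: time in seconds, activities and drives in arbitrary simulation
    units (SU).  Rate "constants" (``decay_*``) are 1/s.
    """

    decay_exc: float = 0.2     # passive decay rate of shape-selective cells (1/s)
    decay_inh: float = 0.76    # passive decay rate of interneurons (1/s)
    upper_bound: float = 8.0   # shunting ceiling B (SU)
    lower_bound: float = 1.0   # shunting floor magnitude D (SU); V >= -D
    R: float = 1.0             # tonic baseline drive to every cell (SU)
    W_exc: float = 0.23        # shape cell -> its interneuron weight
    W_inh: float = 0.55        # interneuron -> opposing shape cell weight
    I_exc_on: float = 4.0      # external stimulus amplitude while a pulse is on (SU)
    eta_exc: float = 0.25      # peak adaptive-gain change, shape->interneuron synapse
    eta_inh: float = 0.205     # peak adaptive-gain change, interneuron->shape synapse
    tau_gain: float = 0.15     # recovery time constant of adaptive gains (s)
    gamma: float = 5.0         # firing threshold (SU); rate = max(0, V - gamma)
    noise_amp: float = 0.0     # half-width of uniform membrane noise (SU)

    def __post_init__(self) -> None:
        nonneg = (
            "decay_exc", "decay_inh", "upper_bound", "lower_bound", "R",
            "W_exc", "W_inh", "I_exc_on", "eta_exc", "eta_inh",
            "tau_gain", "noise_amp",
        )
        for name in nonneg:
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"ModelParams.{name} must be >= 0, got {v!r}")
        if self.upper_bound <= 0:
            raise ValueError("upper_bound must be positive")
        if self.tau_gain <= 0:
            raise ValueError("tau_gain must be positive")

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True, order=True)
class CellId:
    """A cell is identified by its spatial location and its role.

    Roles: ``exc_a``/``exc_b`` are the shape-selective cells preferring
    shapes 'a' and 'b'; ``inh_ab`` is driven by ``exc_a`` and inhibits
    ``exc_b``; ``inh_ba`` is driven by ``exc_b`` and inhibits ``exc_a``.
    """

    location: str
    role: str

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}; expected one of {LOCATIONS}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    @property
    def is_excitatory(self) -> bool:
        return self.role.startswith("exc")

    @property
    def label(self) -> str:
        return f"{self.location}.{self.role}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def reference_params(**overrides: float) -> ModelParams:
    """The reference parameter set, optionally with overrides."""
    return ModelParams(**overrides)
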