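"""Stimulation protocols: timed excitatory pulses to named cells plus
global-inhibition (GI) pulses delivered to every cell."""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import CellId

__all__ = ["Pulse", "GIPulse", "StimulusProtocol"]


@dataclass(frozen=True)
class Pulse:
    target: CellId
    onset: float      # s
    duration: float   # s
    amplitude: float  # SU, added to the target's external-input signal


@dataclass(frozen=True)
class GIPulse:
    onset: float      # s
    duration: float   # s
    strength: float   # SU, added to every cell's shunting inhibitory term


@dataclass(frozen=True)
class StimulusProtocol:
    """Pulse trains over a simulated interval [0, t_end]."""

    t_end: float
    pulses: tuple[Pulse, ...] = ()
    gi_pulses: tuple[GIPulse, ...] = ()

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("protocol.t_end must be positive")
        for i, p in enumerate(self.pulses):
            if p.onset < 0:
                raise ValueError(f"protocol.pulses[{i}].onset must be >= 0")
            if p.duration < 0:
                raise ValueError(f"protocol.pulses[{i}].duration must be >= 0")
            if p.amplitude < 0:
                raise ValueError(f"protocol.pulses[{i}].amplitude must be >= 0")
            if p.onset + p.duration > self.t_end + 1e-12:
                raise ValueError(f"protocol.pulses[{i}] extends past t_end")
        for i, p in enumerate(self.gi_pulses):
            if p.onset < 0:
                raise ValueError(f"protocol.gi_pulses[{i}].onset must be >= 0")
            if p.duration < 0:
                raise ValueError(f"protocol.gi_pulses[{i}].duration must be >= 0")
            if p.strength < 0:
                raise ValueError(f"protocol.gi_pulses[{i}].strength must be >= 0")
            if p.onset + p.duration > self.t_end + 1e-12:
                raise ValueError(f"protocol.gi_pulses[{i}] extends past t_end")

    @staticmethod
    def empty(t_end: float) -> "StimulusProtocol":
        return StimulusProtocol(t_end=t_end)

    def with_pulses(self, *pulses: Pulse) -> "StimulusProtocol":
        return StimulusProtocol(self.t_end, self.pulses + tuple(pulses), self.gi_pulses)
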