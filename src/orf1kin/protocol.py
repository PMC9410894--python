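"""Protocol specification: ordered clamp segments with a concentration schedule.

A protocol is a contiguous sequence of instrument segments.  Each segment
clamps one control variable:

* ``force``      - force clamp at ``setpoint`` pN for ``duration`` s,
  with free-trimer concentration ``concentration`` nM (0 = protein-free
  buffer; the buffer swap is instantaneous).  ``hold_dissolution`` marks
  the high-force hold during which locked compacted blocks dissolve
  stepwise.
* ``extension``  - extension clamp at ``setpoint`` nm (end-to-end) for
  ``duration`` s in protein-free buffer.
* ``velocity``   - constant-velocity ramp at ``velocity`` nm/s until the
  tension reaches ``setpoint`` pN; ``release=True`` ramps downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["Segment", "ProtocolSpec"]

_KINDS = ("force", "extension", "velocity")


@dataclass(frozen=True)
class Segment:
    kind: str
    setpoint: float                   # pN (force/velocity target) or nm (extension)
    duration: float = 0.0             # s; ramps derive duration from velocity
    concentration: float = 0.0        # nM free trimer during the segment
    velocity: float = 450.0           # nm/s, ramps only
    release: bool = False             # downward ramp
    hold_dissolution: bool = False    # stepwise block dissolution during hold
    label: str = ""

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"segment kind must be one of {_KINDS}, "
                             f"got {self.kind!r}")
        if self.kind != "velocity" and self.duration <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if self.kind == "velocity" and self.velocity <= 0:
            raise ValueError("ramp velocity must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered, contiguous instrument segments plus sampling and replication."""

    segments: tuple
    sample_rate: float = 10.0         # Hz
    name: str = "protocol"
    replicates: int = 3
    seeds: Optional[Sequence[int]] = None
    initial_state: object = None      # optional LatticeState to start from

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        for seg in self.segments:
            seg.validate()

    # -- canned protocols --------------------------------------------------
    @staticmethod
    def force_clamp(force: float, duration: float, concentration: float = 30.0,
                    sample_rate: float = 10.0, name: str = "binding",
                    initial_state=None) -> "ProtocolSpec":
        return ProtocolSpec(
            (Segment("force", force, duration, concentration, label="clamp"),),
            sample_rate=sample_rate, name=name, initial_state=initial_state)

    @staticmethod
    def dissociation(force: float, duration: float, sample_rate: float = 10.0,
                     initial_state=None) -> "ProtocolSpec":
        """Protein-free force clamp starting from a pre-formed complex."""
        return ProtocolSpec(
            (Segment("force", force, duration, 0.0, label="dissociation"),),
            sample_rate=sample_rate, name="dissociation",
            initial_state=initial_state)

    @staticmethod
    def stretch_release_cycle(incubation_s: float, clamp_nm: float,
                              stretch_force: float = 75.0,
                              hold_s: float = 100.0,
                              velocity: float = 450.0,
                              sample_rate: float = 10.0,
                              initial_state=None) -> "ProtocolSpec":
        """Low-extension incubation, 450 nm/s stretch to 75 pN, 100 s hold
        with stepwise dissolution, then release back down."""
        return ProtocolSpec((
            Segment("extension", clamp_nm, incubation_s, 0.0,
                    label="incubation"),
            Segment("velocity", stretch_force, velocity=velocity,
                    label="stretch"),
            Segment("force", stretch_force, hold_s, 0.0,
                    hold_dissolution=True, label="hold"),
            Segment("velocity", 1.0, velocity=velocity, release=True,
                    label="release"),
        ), sample_rate=sample_rate, name=f"cycle_{incubation_s:g}s",
            initial_state=initial_state)
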