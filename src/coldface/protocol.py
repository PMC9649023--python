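"""Study timeline model for the MIST / Cold Face Test protocol.

The session clock starts at the beginning of the 15-min seated Global
Baseline (``BL_Glo``); all event times are stored in seconds on that clock.
The Montreal Imaging Stress Task (MIST) follows as three phases, each made
of four subphases:

    BL (1 min)  ->  RP or CFI (2 min)  ->  AT (4 min)  ->  FB (2-3 min)

where the second subphase is a Resting Period (RP) for the Control
condition and the Cold Face Intervention (CFI) for the CFT condition.
Saliva samples S1..S6 are scheduled at fixed offsets relative to MIST
start (0, 30, 40, 50, 60, 70 min); S0 is a pre-protocol screening sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

SUBPHASE_NAMES = ("BL", "RP_CFI", "AT", "FB")

#: Aliases accepted when naming the second subphase.
_SUBPHASE_ALIASES = {"RP": "RP_CFI", "CFI": "RP_CFI", "RP/CFI": "RP_CFI"}

CONDITIONS = ("Control", "CFT")


class ProtocolError(ValueError):
    """Raised for invalid protocol configurations."""


@dataclass(frozen=True)
class Segment:
    """A named half-open time interval [start_s, end_s) on the session clock."""

    name: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ProtocolError(
                f"segment {self.name!r}: end ({self.end_s}) must exceed start ({self.start_s})"
            )


@dataclass(frozen=True)
class MistPhase:
    """One MIST phase (1..3) with its four timed subphases."""

    index: int
    subphases: tuple[Segment, ...]

    def __post_init__(self) -> None:
        names = tuple(s.name for s in self.subphases)
        if names != SUBPHASE_NAMES:
            raise ProtocolError(f"subphase order must be {SUBPHASE_NAMES}, got {names}")

    @property
    def start_s(self) -> float:
        return self.subphases[0].start_s

    @property
    def end_s(self) -> float:
        return self.subphases[-1].end_s

    def subphase(self, name: str) -> Segment:
        name = _SUBPHASE_ALIASES.get(name, name)
        for seg in self.subphases:
            if seg.name == name:
                return seg
        raise KeyError(f"unknown subphase {name!r}; expected one of {SUBPHASE_NAMES}")


@dataclass(frozen=True)
class StudyProtocol:
    """Fully timed study protocol: Global Baseline, 3 MIST phases, saliva schedule."""

    global_baseline: Segment
    mist_phases: tuple[MistPhase, ...]
    saliva_times_min: tuple[float, ...]  # S0..S6 offsets relative to MIST start
    resting_duration_min: float = 45.0

    def __post_init__(self) -> None:
        if len(self.mist_phases) != 3:
            raise ProtocolError("protocol requires exactly 3 MIST phases")
        offs = np.asarray(self.saliva_times_min, dtype=float)
        if len(offs) != 7:
            raise ProtocolError("expected 7 saliva offsets (S0 plus S1..S6)")
        if np.any(np.diff(offs) <= 0):
            raise ProtocolError("saliva offsets must be strictly increasing")
        if offs[1] != 0:
            raise ProtocolError("S1 must be scheduled at MIST start (offset 0)")

    @property
    def mist_start_s(self) -> float:
        return self.mist_phases[0].start_s

    @property
    def mist_end_s(self) -> float:
        return self.mist_phases[-1].end_s

    @property
    def saliva_times_s(self) -> np.ndarray:
        """Absolute saliva sampling times (S0..S6) on the session clock."""
        return self.mist_start_s + 60.0 * np.asarray(self.saliva_times_min, float)

    def phase(self, index: int) -> MistPhase:
        if index not in (1, 2, 3):
            raise KeyError(f"MIST phase index must be 1..3, got {index}")
        return self.mist_phases[index - 1]

    def subphase(self, phase: int, name: str) -> Segment:
        return self.phase(phase).subphase(name)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "global_baseline": {"start_s": self.global_baseline.start_s,
                                "end_s": self.global_baseline.end_s},
            "mist_phases": [
                {"index": p.index,
                 "subphases": [{"name": s.name, "start_s": s.start_s, "end_s": s.end_s}
                               for s in p.subphases]}
                for p in self.mist_phases
            ],
            "saliva_times_min": list(self.saliva_times_min),
            "resting_duration_min": self.resting_duration_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyProtocol":
        gb = d["global_baseline"]
        phases = tuple(
            MistPhase(
                index=p["index"],
                subphases=tuple(Segment(s["name"], s["start_s"], s["end_s"])
                                for s in p["subphases"]),
            )
            for p in d["mist_phases"]
        )
        return cls(
            global_baseline=Segment("BL_Glo", gb["start_s"], gb["end_s"]),
            mist_phases=phases,
            saliva_times_min=tuple(d["saliva_times_min"]),
            resting_duration_min=d.get("resting_duration_min", 45.0),
        )

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "StudyProtocol":
        path = str(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
        return cls.from_dict(d)


def build_mist_protocol(
    *,
    global_baseline_min: float = 15.0,
    bl_min: float = 1.0,
    rp_cfi_min: float = 2.0,
    at_min: float = 4.0,
    fb_min: float = 2.5,
    saliva_offsets_min: tuple[float, ...] = (-20.0, 0.0, 30.0, 40.0, 50.0, 60.0, 70.0),
    resting_duration_min: float = 45.0,
    mist_start_min: float | None = None,
) -> StudyProtocol:
    """Build the default study protocol.

    Phases are contiguous (the protocol does not define gaps between FB end
    and the next BL start).  The FB subphase defaults to 2.5 min, the middle
    of its 2-3 min range; any positive duration is accepted as an explicit
    override.

    Parameters
    ----------
    mist_start_min:
        Start of MIST1 on the session clock; defaults to the end of the
        Global Baseline.
    saliva_offsets_min:
        Offsets of S0..S6 relative to MIST start.  S0 is the pre-protocol
        screening sample and must precede S1 = 0.
    """
    for name, dur in [("global_baseline", global_baseline_min), ("BL", bl_min),
                      ("RP_CFI", rp_cfi_min), ("AT", at_min), ("FB", fb_min),
                      ("resting", resting_duration_min)]:
        if dur <= 0:
            raise ProtocolError(f"duration of {name} must be positive, got {dur}")

    if mist_start_min is None:
        mist_start_min = global_baseline_min

    phases = []
    t = mist_start_min * 60.0
    for idx in (1, 2, 3):
        segs = []
        for name, dur in zip(SUBPHASE_NAMES, (bl_min, rp_cfi_min, at_min, fb_min)):
            segs.append(Segment(name, t, t + dur * 60.0))
            t += dur * 60.0
        phases.append(MistPhase(index=idx, subphases=tuple(segs)))

    return StudyProtocol(
        global_baseline=Segment("BL_Glo", 0.0, global_baseline_min * 60.0),
        mist_phases=tuple(phases),
        saliva_times_min=tuple(saliva_offsets_min),
        resting_duration_min=resting_duration_min,
    )


def segment_mask(times_s: np.ndarray, segment: Segment) -> np.ndarray:
    """Boolean mask of timestamps inside ``[start, end)`` of a segment."""
    t = np.asarray(times_s, dtype=float)
    return (t >= segment.start_s) & (t < segment.end_s)


def slice_by_subphase(times_s: np.ndarray, protocol: StudyProtocol,
                      phase: int, subphase: str) -> np.ndarray:
    """Indices of samples falling in the named subphase (half-open interval).

    Timestamps must share the protocol's session clock.  An empty overlap
    yields an empty index array with a warning rather than an error, so a
    truncated recording degrades gracefully.
    """
    seg = protocol.subphase(phase, subphase)
    idx = np.nonzero(segment_mask(times_s, seg))[0]
    if idx.size == 0:
        warnings.warn(
            f"series does not overlap MIST{phase} {subphase} "
            f"[{seg.start_s:.0f}, {seg.end_s:.0f}) s", stacklevel=2)
    return idx
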