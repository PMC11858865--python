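"""Biorelevant dissolution media and the sequential open-loop protocol.

The flow-through (USP apparatus IV) experiment perfuses the sample cell with a
gradient of five fasted-state biorelevant media, each run for a physiologically
relevant residence time: FaSSGF (stomach), FaSSIF-V2 (proximal gut), FaSSIF-V2
midgut, SIF Ileum-V2 (distal ileum) and FaSSCoF (ascending colon).  Each medium
also stands proxy for the gastrointestinal regions whose luminal fluid it
mimics, which is what lets a per-medium dissolution scalar be carried over to
the corresponding in vivo compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "GI_REGIONS",
    "Medium",
    "ProtocolSegment",
    "DissolutionProtocol",
    "default_media",
    "build_default_protocol",
    "medium_at",
    "validate_protocol",
]

#: The nine GI compartments of the absorption model, in anatomical order.
GI_REGIONS: tuple[str, ...] = (
    "Stomach",
    "Duodenum",
    "Jejunum I",
    "Jejunum II",
    "Ileum I",
    "Ileum II",
    "Ileum III",
    "Ileum IV",
    "Colon",
)

#: Maleic acid pKa values (diprotic buffer of the level-II intestinal media).
MALEATE_PKA1 = 1.83
MALEATE_PKA2 = 5.99

#: Default apparent (amorphous) drug solubility per medium, mg/mL.
#: Low-µg/mL values typical of a poorly soluble (BCS II) lipophilic drug,
#: scaling with bile-salt content; the dose/fluid ratio then exceeds
#: solubility and absorption is dissolution/solubility-limited, which is the
#: premise of the whole extrapolation.  Configurable.
DEFAULT_SOLUBILITY: dict[str, float] = {
    "FaSSGF": 0.002,
    "FaSSIF-V2": 0.008,
    "FaSSIF-V2 midgut": 0.008,
    "SIF Ileum-V2": 0.006,
    "FaSSCoF": 0.004,
}


@dataclass(frozen=True)
class Medium:
    """One biorelevant dissolution medium.

    Parameters
    ----------
    name : str
        Medium identifier (e.g. ``"FaSSIF-V2 midgut"``).
    pH : float
        Bulk pH; must lie in [1, 9].
    buffer_total : float
        Total buffer concentration, mM.
    buffer_pka1, buffer_pka2 : float or None
        pKa values of the buffer species (None when unbuffered, e.g. FaSSGF).
    bile_salt : float
        Sodium-taurocholate-equivalent surfactant concentration, mM.
    solubility : float
        Apparent drug solubility in this medium, mg/mL.
    """

    name: str
    pH: float
    buffer_total: float
    buffer_pka1: float | None
    buffer_pka2: float | None
    bile_salt: float
    solubility: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.pH <= 9.0):
            raise ValueError(f"{self.name}: pH {self.pH} outside [1, 9]")
        if self.buffer_total < 0:
            raise ValueError(f"{self.name}: negative buffer_total")
        if self.bile_salt < 0:
            raise ValueError(f"{self.name}: negative bile_salt")
        if self.solubility <= 0:
            raise ValueError(f"{self.name}: solubility must be > 0")


@dataclass(frozen=True)
class ProtocolSegment:
    """A timed exposure to one medium at a fixed pump flow rate.

    Times are minutes; flow in mL/min.  Media switches follow a half-open
    convention: the segment is active on ``[start, start + duration)``.
    """

    medium: Medium
    start: float
    duration: float
    flow_rate: float

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class DissolutionProtocol:
    """The sequential media gradient of the open-loop flow-through experiment.

    ``region_map`` records which GI regions each medium stands for; it is how a
    per-medium dissolution scalar fitted in vitro is assigned to in vivo
    compartments (FaSSGF -> Stomach, FaSSIF-V2 -> Duodenum, midgut -> Jejunum
    I/II, SIF Ileum-V2 -> Ileum I-IV, FaSSCoF -> Colon).
    """

    segments: list[ProtocolSegment]
    cell_volume: float = 20.0  # mL; flow-through cell working volume
    region_map: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def start_time(self) -> float:
        return self.segments[0].start

    @property
    def end_time(self) -> float:
        return self.segments[-1].end

    @property
    def media(self) -> list[Medium]:
        """Distinct media in protocol order."""
        seen: dict[str, Medium] = {}
        for seg in self.segments:
            seen.setdefault(seg.medium.name, seg.medium)
        return list(seen.values())

    def medium_names(self) -> list[str]:
        return [m.name for m in self.media]

    def with_solubility(self, solubility: Mapping[str, float]) -> "DissolutionProtocol":
        """Return a copy with per-medium solubilities replaced."""
        segs = [
            replace(seg, medium=replace(seg.medium, solubility=solubility.get(seg.medium.name, seg.medium.solubility)))
            for seg in self.segments
        ]
        return DissolutionProtocol(segs, self.cell_volume, dict(self.region_map))


DEFAULT_REGION_MAP: dict[str, tuple[str, ...]] = {
    "FaSSGF": ("Stomach",),
    "FaSSIF-V2": ("Duodenum",),
    "FaSSIF-V2 midgut": ("Jejunum I", "Jejunum II"),
    "SIF Ileum-V2": ("Ileum I", "Ileum II", "Ileum III", "Ileum IV"),
    "FaSSCoF": ("Colon",),
}


def default_media(solubility: Mapping[str, float] | None = None) -> dict[str, Medium]:
    """The five fasted-state media with their default properties.

    The three level-II lower-intestinal media use a maleate buffer (pKa 1.83 /
    5.99) at 19.3, 52.8 and 75.8 mM with pH 6.8, 7.5, 7.8 and taurocholate
    1.5, 0.8 and 0 mM respectively.  FaSSGF and FaSSIF-V2 use standard
    literature compositions (pH 1.6 / 80 uM bile; pH 6.5 / 3 mM taurocholate,
    maleate ~19.1 mM).
    """
    sol = dict(DEFAULT_SOLUBILITY)
    if solubility:
        sol.update(solubility)
    media = [
        Medium("FaSSGF", pH=1.6, buffer_total=0.0, buffer_pka1=None,
               buffer_pka2=None, bile_salt=0.08, solubility=sol["FaSSGF"]),
        Medium("FaSSIF-V2", pH=6.5, buffer_total=19.1, buffer_pka1=MALEATE_PKA1,
               buffer_pka2=MALEATE_PKA2, bile_salt=3.0, solubility=sol["FaSSIF-V2"]),
        Medium("FaSSIF-V2 midgut", pH=6.8, buffer_total=19.3, buffer_pka1=MALEATE_PKA1,
               buffer_pka2=MALEATE_PKA2, bile_salt=1.5, solubility=sol["FaSSIF-V2 midgut"]),
        Medium("SIF Ileum-V2", pH=7.5, buffer_total=52.8, buffer_pka1=MALEATE_PKA1,
               buffer_pka2=MALEATE_PKA2, bile_salt=0.8, solubility=sol["SIF Ileum-V2"]),
        Medium("FaSSCoF", pH=7.8, buffer_total=75.8, buffer_pka1=MALEATE_PKA1,
               buffer_pka2=MALEATE_PKA2, bile_salt=0.0, solubility=sol["FaSSCoF"]),
    ]
    return {m.name: m for m in media}


#: (medium name, start min, duration min, flow mL/min) of the media gradient.
DEFAULT_GRADIENT: tuple[tuple[str, float, float, float], ...] = (
    ("FaSSGF", 0.0, 30.0, 8.0),
    ("FaSSIF-V2", 30.0, 40.0, 4.0),
    ("FaSSIF-V2 midgut", 70.0, 80.0, 4.0),
    ("SIF Ileum-V2", 150.0, 60.0, 4.0),
    ("FaSSCoF", 210.0, 150.0, 4.0),
)


def build_default_protocol(
    solubility: Mapping[str, float] | None = None,
    cell_volume: float = 20.0,
) -> DissolutionProtocol:
    """The default five-medium gradient: FaSSGF 0-30 min at 8 mL/min, then
    FaSSIF-V2 (30-70), midgut (70-150), SIF Ileum-V2 (150-210) and FaSSCoF
    (210-360) at 4 mL/min, ending at 6 h."""
    media = default_media(solubility)
    segments = [
        ProtocolSegment(media[name], start, duration, flow)
        for name, start, duration, flow in DEFAULT_GRADIENT
    ]
    return DissolutionProtocol(segments, cell_volume=cell_volume,
                               region_map=dict(DEFAULT_REGION_MAP))


def medium_at(protocol: DissolutionProtocol, t: float) -> Medium:
    """Medium active at time ``t`` (minutes).

    Each segment owns the half-open interval ``[start, end)`` so switch times
    belong to the incoming medium; exactly at the protocol end the last medium
    is returned.  ``t`` outside the protocol raises ``ValueError``.
    """
    if t < protocol.start_time or t > protocol.end_time:
        raise ValueError(
            f"t={t} min outside protocol span "
            f"[{protocol.start_time}, {protocol.end_time}] min"
        )
    for seg in protocol.segments:
        if seg.start <= t < seg.end:
            return seg.medium
    return protocol.segments[-1].medium


def validate_protocol(protocol: DissolutionProtocol) -> list[str]:
    """Check protocol invariants; violations are returned as data, not raised."""
    v: list[str] = []
    if not protocol.segments:
        return ["protocol has no segments"]
    if protocol.segments[0].start != 0:
        v.append(f"segment 0: start is {protocol.segments[0].start}, expected 0")
    for i, seg in enumerate(protocol.segments):
        if seg.duration <= 0:
            v.append(f"segment {i} ({seg.medium.name}): duration must be > 0")
        if seg.flow_rate <= 0:
            v.append(f"segment {i} ({seg.medium.name}): flow_rate must be > 0")
        if i > 0:
            prev = protocol.segments[i - 1]
            if seg.start < prev.end:
                v.append(f"segment {i} ({seg.medium.name}): overlap with segment {i - 1}")
            elif seg.start > prev.end:
                v.append(f"segment {i} ({seg.medium.name}): gap after segment {i - 1}")
    if protocol.cell_volume <= 0:
        v.append("cell_volume must be > 0")
    if protocol.region_map:
        covered = {r for regions in protocol.region_map.values() for r in regions}
        missing = [r for r in GI_REGIONS if r not in covered]
        if missing:
            v.append(f"region_map does not cover: {', '.join(missing)}")
    return v
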