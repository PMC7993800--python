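"""Chothia-convention structural regions of the antibody variable fragment.

The variable fragment (Fv) is partitioned into six complementarity
determining regions (CDR L1-L3 on the light chain, H1-H3 on the heavy
chain), the light and heavy framework regions (FRL, FRH), and an
"Orientation" span used to describe the relative placement of the two
variable domains.  All residue numbers follow the Chothia convention, in
which loop-length variation is absorbed by insertion codes (e.g. H100A)
rather than renumbering.

Region boundaries used here:

======== ====== =================================================
region   chain  inclusive Chothia ranges
======== ====== =================================================
CDR_L1   light  24-34
CDR_L2   light  50-56
CDR_L3   light  89-97
FRL      light  10-23, 35-39, 46-49, 57-66, 71-88, 98-104
CDR_H1   heavy  26-35
CDR_H2   heavy  50-65
CDR_H3   heavy  95-102
FRH      heavy  10-25, 36-39, 46-49, 66-94, 103-109
Orient.  both   L5-L104 and H5-H109
======== ====== =================================================

The framework definitions deliberately do not complement the CDRs:
non-CDR loops between the listed framework ranges belong to no region
("unassigned").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

from .errors import MissingRegionError, RegionError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class ChainKind(str, enum.Enum):
    LIGHT = "light"
    HEAVY = "heavy"
    ANTIGEN = "antigen"


@dataclass(frozen=True, slots=True)
class ResidueID:
    """A Chothia-numbered residue identifier.

    Ordering is by (number, insertion_code), with a blank insertion code
    sorting before 'A' < 'B' < ... so that e.g. H100 < H100A < H100B < H101.
    """

    chain_kind: ChainKind
    number: int
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"Chothia numbers start at 1, got {self.number}")
        if len(self.insertion_code) > 1:
            raise ValueError(f"insertion code must be one character: {self.insertion_code!r}")

    def sort_key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def __lt__(self, other: "ResidueID") -> bool:
        if self.chain_kind != other.chain_kind:
            raise TypeError("cannot order residues across chains")
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        prefix = {ChainKind.LIGHT: "L", ChainKind.HEAVY: "H", ChainKind.ANTIGEN: "X"}[self.chain_kind]
        return f"{prefix}{self.number}{self.insertion_code}"


@dataclass(frozen=True)
class Span:
    """An inclusive Chothia number range on one chain."""

    chain_kind: ChainKind
    start: int
    end: int

    def __contains__(self, residue: ResidueID) -> bool:
        # insertion-coded residues inherit the region of their parent number
        return residue.chain_kind == self.chain_kind and self.start <= residue.number <= self.end


@dataclass(frozen=True)
class RegionDefinition:
    name: str
    spans: tuple[Span, ...]

    @property
    def chain_kind(self) -> ChainKind | None:
        """The single chain this region lives on, or None if it spans both."""
        kinds = {s.chain_kind for s in self.spans}
        return kinds.pop() if len(kinds) == 1 else None

    def contains(self, residue: ResidueID) -> bool:
        return any(residue in s for s in self.spans)


@dataclass(frozen=True)
class RegionSequence:
    region_name: str
    sequence: str
    source_id: str = ""
    residue_ids: tuple[ResidueID, ...] = field(default=(), compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _spans(kind: ChainKind, ranges: Iterable[tuple[int, int]]) -> tuple[Span, ...]:
    return tuple(Span(kind, a, b) for a, b in ranges)


REGION_DEFINITIONS: dict[str, RegionDefinition] = {
    "CDR_L1": RegionDefinition("CDR_L1", _spans(ChainKind.LIGHT, [(24, 34)])),
    "CDR_L2": RegionDefinition("CDR_L2", _spans(ChainKind.LIGHT, [(50, 56)])),
    "CDR_L3": RegionDefinition("CDR_L3", _spans(ChainKind.LIGHT, [(89, 97)])),
    "FRL": RegionDefinition(
        "FRL",
        _spans(ChainKind.LIGHT, [(10, 23), (35, 39), (46, 49), (57, 66), (71, 88), (98, 104)]),
    ),
    "CDR_H1": RegionDefinition("CDR_H1", _spans(ChainKind.HEAVY, [(26, 35)])),
    "CDR_H2": RegionDefinition("CDR_H2", _spans(ChainKind.HEAVY, [(50, 65)])),
    "CDR_H3": RegionDefinition("CDR_H3", _spans(ChainKind.HEAVY, [(95, 102)])),
    "FRH": RegionDefinition(
        "FRH",
        _spans(ChainKind.HEAVY, [(10, 25), (36, 39), (46, 49), (66, 94), (103, 109)]),
    ),
    "Orientation": RegionDefinition(
        "Orientation",
        (Span(ChainKind.LIGHT, 5, 104), Span(ChainKind.HEAVY, 5, 109)),
    ),
}

CDR_NAMES = ("CDR_L1", "CDR_L2", "CDR_L3", "CDR_H1", "CDR_H2", "CDR_H3")
FRAMEWORK_NAMES = ("FRL", "FRH")

#: Short names used in database file naming, e.g. ``database.L1.11``.
SHORT_NAMES = {
    "CDR_L1": "L1",
    "CDR_L2": "L2",
    "CDR_L3": "L3",
    "CDR_H1": "H1",
    "CDR_H2": "H2",
    "CDR_H3": "H3",
    "FRL": "FRL",
    "FRH": "FRH",
}

#: Chothia positions whose presence identifies the structural regions:
#: every CDR/framework range boundary plus the Orientation span anchors.
ANCHOR_POSITIONS: dict[ChainKind, tuple[int, ...]] = {}
for _kind in (ChainKind.LIGHT, ChainKind.HEAVY):
    _pos: set[int] = set()
    for _rd in REGION_DEFINITIONS.values():
        for _s in _rd.spans:
            if _s.chain_kind == _kind:
                _pos.update((_s.start, _s.end))
    ANCHOR_POSITIONS[_kind] = tuple(sorted(_pos))
del _kind, _pos, _rd, _s


def region_ranges(name: str) -> RegionDefinition:
    """Return the definition (chain + inclusive Chothia ranges) of a region."""
    try:
        return REGION_DEFINITIONS[name]
    except KeyError:
        raise RegionError(f"unknown region {name!r}; expected one of {sorted(REGION_DEFINITIONS)}") from None


def assign_region(residue: ResidueID) -> str:
    """Map a residue to its CDR or framework region, or ``"unassigned"``.

    Antigen residues and positions outside every CDR/framework range
    (including the non-CDR loops excluded from the frameworks) are
    unassigned.  The Orientation span is a measurement window, not a
    partition member, and is never returned here.
    """
    if residue.chain_kind is ChainKind.ANTIGEN:
        return "unassigned"
    for name in CDR_NAMES + FRAMEWORK_NAMES:
        if REGION_DEFINITIONS[name].contains(residue):
            return name
    return "unassigned"


def extract_region_sequence(structure, region: str | RegionDefinition) -> RegionSequence:
    """Concatenate one-letter codes of the residues falling in a region.

    Residues are taken in Chothia order including insertion-coded
    positions, so loop insertions lengthen the sequence and absent
    numbers shorten it.  Raises :class:`MissingRegionError` when the
    structure has no residue in any of the region's ranges.
    """
    definition = region if isinstance(region, RegionDefinition) else region_ranges(region)
    letters: list[str] = []
    ids: list[ResidueID] = []
    for residue in structure.iter_residues():
        if definition.contains(residue.id):
            letters.append(residue.aa)
            ids.append(residue.id)
    if not letters:
        raise MissingRegionError(
            f"structure {structure.pdb_id!r} has no residues in region {definition.name}"
        )
    return RegionSequence(
        region_name=definition.name,
        sequence="".join(letters),
        source_id=structure.pdb_id,
        residue_ids=tuple(ids),
    )


def export_region_table() -> str:
    """Region definitions as a TSV table: region, chain, start, end."""
    lines = ["region\tchain\tstart\tend"]
    for rd in REGION_DEFINITIONS.values():
        for s in rd.spans:
            lines.append(f"{rd.name}\t{s.chain_kind.value}\t{s.start}\t{s.end}")
    return "\n".join(lines) + "\n"
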