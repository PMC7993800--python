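"""Chothia-numbered antibody structure I/O and quality control.

Reads pre-numbered (SAbDab-style) PDB coordinate files, selects the
light/heavy chains named in a tab-delimited summary record, truncates to
the variable fragment, and applies the template-database quality
criteria:

* crystallographic resolution strictly below a cutoff (default 3 A);
* the file is loadable: chains parse and every residue carries a
  complete N/CA/C/O backbone;
* peptide-link geometry: no C-N bond longer than 2 A, CA-C-N angles
  within [89.5, 144.5] degrees and C-N-CA angles within [95, 151]
  degrees;
* no zero-occupancy atoms;
* none of the conserved region-anchor residues is missing.

Geometry violations inside a CDR do not reject the whole structure;
they mark that CDR as chain-broken so it can be omitted from template
pools (see :func:`detect_cdr_chainbreaks`).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import MissingChainError, MissingRegionError, ParseError, ScFvError
from .regions import (
    ANCHOR_POSITIONS,
    CDR_NAMES,
    REGION_DEFINITIONS,
    ChainKind,
    ResidueID,
    assign_region,
)

# Fv truncation bounds (Chothia numbering, inclusive).
LIGHT_FV_LAST = 109
HEAVY_FV_LAST = 112

# Peptide-link quality windows.
MAX_C_N_BOND = 2.0  # Angstrom
CA_C_N_WINDOW = (89.5, 144.5)  # degrees
C_N_CA_WINDOW = (95.0, 151.0)  # degrees

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


@dataclass(frozen=True)
class Atom:
    name: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0

    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Residue:
    id: ResidueID
    aa: str  # one-letter code, 'X' for non-standard
    name: str  # three-letter PDB residue name
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names: Sequence[str]) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)


@dataclass(frozen=True)
class SummaryRecord:
    pdb_id: str
    heavy_chain_id: str | None
    light_chain_id: str | None
    resolution: float | None
    method: str = ""

    @property
    def is_scfv(self) -> bool:
        return (
            self.heavy_chain_id is not None
            and self.light_chain_id is not None
            and self.heavy_chain_id == self.light_chain_id
        )


@dataclass
class AntibodyStructure:
    pdb_id: str
    light_residues: list[Residue] = field(default_factory=list)
    heavy_residues: list[Residue] = field(default_factory=list)
    resolution: float | None = None
    method: str = ""

    def chain(self, kind: ChainKind) -> list[Residue]:
        if kind is ChainKind.LIGHT:
            return self.light_residues
        if kind is ChainKind.HEAVY:
            return self.heavy_residues
        raise ValueError("antigen chains are not stored on AntibodyStructure")

    def iter_residues(self) -> Iterator[Residue]:
        yield from self.light_residues
        yield from self.heavy_residues

    def find_residue(self, rid: ResidueID) -> Residue | None:
        for r in self.chain(rid.chain_kind):
            if r.id == rid:
                return r
        return None

    @property
    def chains_present(self) -> tuple[ChainKind, ...]:
        kinds = []
        if self.light_residues:
            kinds.append(ChainKind.LIGHT)
        if self.heavy_residues:
            kinds.append(ChainKind.HEAVY)
        return tuple(kinds)

    def fv_sequence(self) -> str:
        """Concatenated light+heavy one-letter sequence (redundancy key)."""
        return "".join(r.aa for r in self.iter_residues())


@dataclass(frozen=True)
class CriterionResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class QualityReport:
    pdb_id: str
    checks: list[CriterionResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed_criteria(self) -> list[str]:
        return [c.name for c in self.checks if not c.passed]

    def to_tsv(self) -> str:
        lines = ["criterion\tstatus\tdetail"]
        for c in self.checks:
            lines.append(f"{c.name}\t{'pass' if c.passed else 'fail'}\t{c.detail}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class LinkViolation:
    """A peptide link that breaks the geometry criteria."""

    chain_kind: ChainKind
    from_residue: ResidueID
    to_residue: ResidueID
    kind: str  # "bond_length" | "ca_c_n_angle" | "c_n_ca_angle" | "missing_atom"
    value: float
    region: str

    def describe(self) -> str:
        return (
            f"{self.from_residue}-{self.to_residue} {self.kind}={self.value:.2f} ({self.region})"
        )


# ---------------------------------------------------------------------------
# Parsing


def _residues_from_biopdb_chain(chain, kind: ChainKind) -> list[Residue]:
    out: list[Residue] = []
    for res in chain:
        het, number, icode = res.get_id()
        if het.strip():
            continue  # skip waters / heteroatoms
        rid = ResidueID(kind, number, icode.strip())
        atoms: list[Atom] = []
        for atom in res.get_unpacked_list():
            if atom.get_altloc() not in (" ", "", "A"):
                continue  # deterministic parse: keep blank/'A' altlocs only
            x, y, z = (float(v) for v in atom.get_coord())
            occ = atom.get_occupancy()
            bf = atom.get_bfactor()
            atoms.append(
                Atom(
                    name=atom.get_name(),
                    position=(x, y, z),
                    occupancy=1.0 if occ is None else float(occ),
                    b_factor=0.0 if bf is None else float(bf),
                )
            )
        aa = _3TO1.get(res.get_resname().strip().upper(), "X")
        out.append(Residue(id=rid, aa=aa, name=res.get_resname().strip(), atoms=atoms))
    out.sort(key=lambda r: r.id.sort_key())
    return out


def read_pdb_chains(coordinate_text: str, kind: ChainKind = ChainKind.ANTIGEN) -> dict[str, list[Residue]]:
    """Parse PDB text into ``{chain_id: [Residue, ...]}`` (all chains)."""
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = next(parser.get_structure("x", io.StringIO(coordinate_text)).get_models())
    except (PDBConstructionException, ValueError, StopIteration) as exc:
        raise ParseError(f"malformed PDB input: {exc}") from exc
    return {chain.id: _residues_from_biopdb_chain(chain, kind) for chain in model}


def read_chothia_structure(coordinate_text: str, summary: SummaryRecord) -> AntibodyStructure:
    """Extract the summary-named heavy/light chains from PDB text.

    Chains not named in the summary are treated as antigen and dropped.
    scFv entries (heavy and light ids equal) are rejected outright to
    avoid mis-assigned chains downstream.
    """
    if summary.is_scfv:
        raise ScFvError(f"{summary.pdb_id}: heavy and light share chain id {summary.heavy_chain_id!r} (scFv)")
    chains = read_pdb_chains(coordinate_text)
    structure = AntibodyStructure(
        pdb_id=summary.pdb_id, resolution=summary.resolution, method=summary.method
    )
    for cid, attr, kind in (
        (summary.light_chain_id, "light_residues", ChainKind.LIGHT),
        (summary.heavy_chain_id, "heavy_residues", ChainKind.HEAVY),
    ):
        if cid is None:
            continue
        if cid not in chains:
            raise MissingChainError(f"{summary.pdb_id}: chain {cid!r} named in summary is absent")
        residues = [
            Residue(ResidueID(kind, r.id.number, r.id.insertion_code), r.aa, r.name, r.atoms)
            for r in chains[cid]
        ]
        setattr(structure, attr, residues)
    if not structure.light_residues and not structure.heavy_residues:
        raise MissingChainError(f"{summary.pdb_id}: summary names no chains")
    return structure


def truncate_fv(structure: AntibodyStructure) -> AntibodyStructure:
    """Keep light residues 1-109 and heavy residues 1-112 (idempotent)."""
    return AntibodyStructure(
        pdb_id=structure.pdb_id,
        light_residues=[r for r in structure.light_residues if r.id.number <= LIGHT_FV_LAST],
        heavy_residues=[r for r in structure.heavy_residues if r.id.number <= HEAVY_FV_LAST],
        resolution=structure.resolution,
        method=structure.method,
    )


# ---------------------------------------------------------------------------
# Quality criteria


def check_resolution(structure: AntibodyStructure, cutoff: float = 3.0) -> CriterionResult:
    """Pass iff resolution is present and strictly below the cutoff.

    Records without a resolution (NMR, low-resolution EM) fail.
    """
    res = structure.resolution
    if res is None or math.isnan(res):
        return CriterionResult("resolution", False, "no resolution recorded")
    if res < cutoff:
        return CriterionResult("resolution", True, f"{res:.2f} A < {cutoff:g} A")
    return CriterionResult("resolution", False, f"{res:.2f} A >= {cutoff:g} A")


def check_loadability(structure: AntibodyStructure) -> CriterionResult:
    """Pass iff every residue carries a complete N/CA/C/O backbone."""
    missing = [
        f"{r.id}:{n}"
        for r in structure.iter_residues()
        for n in BACKBONE_ATOMS
        if r.atom(n) is None
    ]
    if missing:
        return CriterionResult("loadability", False, "missing backbone atoms: " + ", ".join(missing[:8]))
    return CriterionResult("loadability", True, "all residues have complete backbones")


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u = a - b
    v = c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _link_region(a: ResidueID, b: ResidueID) -> str:
    """Region label for a peptide link: a CDR wins over framework."""
    ra, rb = assign_region(a), assign_region(b)
    for r in (ra, rb):
        if r in CDR_NAMES:
            return r
    return ra if ra != "unassigned" else rb


def backbone_link_violations(residues: Sequence[Residue], kind: ChainKind) -> list[LinkViolation]:
    """Check every consecutive-residue peptide link in one chain."""
    violations: list[LinkViolation] = []
    for prev, curr in zip(residues, residues[1:]):
        region = _link_region(prev.id, curr.id)
        needed = (prev.atom("CA"), prev.atom("C"), curr.atom("N"), curr.atom("CA"))
        if any(a is None for a in needed):
            violations.append(
                LinkViolation(kind, prev.id, curr.id, "missing_atom", math.nan, region)
            )
            continue
        ca1, c1, n2, ca2 = (a.xyz() for a in needed)
        d = float(np.linalg.norm(n2 - c1))
        if d > MAX_C_N_BOND:
            violations.append(LinkViolation(kind, prev.id, curr.id, "bond_length", d, region))
            continue
        ang1 = _angle_deg(ca1, c1, n2)
        if not (CA_C_N_WINDOW[0] <= ang1 <= CA_C_N_WINDOW[1]):
            violations.append(LinkViolation(kind, prev.id, curr.id, "ca_c_n_angle", ang1, region))
        ang2 = _angle_deg(c1, n2, ca2)
        if not (C_N_CA_WINDOW[0] <= ang2 <= C_N_CA_WINDOW[1]):
            violations.append(LinkViolation(kind, prev.id, curr.id, "c_n_ca_angle", ang2, region))
    return violations


def all_link_violations(structure: AntibodyStructure) -> list[LinkViolation]:
    out = backbone_link_violations(structure.light_residues, ChainKind.LIGHT)
    out += backbone_link_violations(structure.heavy_residues, ChainKind.HEAVY)
    return out


def check_backbone_geometry(structure: AntibodyStructure) -> CriterionResult:
    """Pass iff no peptide-link violation occurs outside the CDR loops.

    CDR-internal violations are tolerated here: those loops are dropped
    individually via :func:`detect_cdr_chainbreaks` instead of rejecting
    the whole structure.
    """
    violations = all_link_violations(structure)
    outside = [v for v in violations if v.region not in CDR_NAMES]
    if outside:
        return CriterionResult(
            "geometry", False, "; ".join(v.describe() for v in outside[:5])
        )
    detail = "all links within windows" if not violations else (
        f"CDR-only violations in {{{', '.join(sorted({v.region for v in violations}))}}}"
    )
    return CriterionResult("geometry", True, detail)


def check_occupancy(structure: AntibodyStructure) -> CriterionResult:
    """Pass iff no atom has exactly zero occupancy."""
    zeros = [
        f"{r.id}:{a.name}"
        for r in structure.iter_residues()
        for a in r.atoms
        if a.occupancy == 0.0
    ]
    if zeros:
        return CriterionResult("occupancy", False, "zero-occupancy atoms: " + ", ".join(zeros[:8]))
    return CriterionResult("occupancy", True, "no zero-occupancy atoms")


def check_anchor_residues(structure: AntibodyStructure) -> CriterionResult:
    """Pass iff every conserved region-anchor position exists.

    The anchors are the Table-style region boundary positions plus the
    Orientation span endpoints, restricted to the chains actually
    present (a heavy-only nanobody is not penalised for lacking light
    anchors).
    """
    missing: list[str] = []
    for kind in structure.chains_present:
        present = {r.id.number for r in structure.chain(kind)}
        for pos in ANCHOR_POSITIONS[kind]:
            if pos not in present:
                missing.append(str(ResidueID(kind, pos)))
    if missing:
        return CriterionResult("anchors", False, "missing anchors: " + ", ".join(missing))
    return CriterionResult("anchors", True, "all anchor residues present")


def run_quality_control(structure: AntibodyStructure, resolution_cutoff: float = 3.0) -> QualityReport:
    """Apply every configured criterion; all appear in the report."""
    report = QualityReport(pdb_id=structure.pdb_id)
    report.checks.append(check_resolution(structure, resolution_cutoff))
    report.checks.append(check_loadability(structure))
    report.checks.append(check_backbone_geometry(structure))
    report.checks.append(check_occupancy(structure))
    report.checks.append(check_anchor_residues(structure))
    return report


def detect_cdr_chainbreaks(structure: AntibodyStructure) -> set[str]:
    """CDR regions containing chain breaks.

    A CDR is flagged when a peptide link touching any of its residues
    violates the geometry criteria, or when a Chothia number in its
    range is absent while the chain continues on both sides (terminal
    absences are truncation, not breaks).
    """
    broken: set[str] = set()
    for v in all_link_violations(structure):
        if v.region in CDR_NAMES:
            broken.add(v.region)
    for name in CDR_NAMES:
        rd = REGION_DEFINITIONS[name]
        kind = rd.chain_kind
        if kind not in structure.chains_present:
            continue
        numbers = {r.id.number for r in structure.chain(kind)}
        if not numbers:
            continue
        lo, hi = min(numbers), max(numbers)
        (span,) = rd.spans
        for pos in range(span.start, span.end + 1):
            if pos not in numbers and lo < pos < hi:
                broken.add(name)
                break
    return broken


def average_cdr_bfactor(structure: AntibodyStructure, region: str) -> float:
    """Arithmetic mean B-factor over all atoms of all residues in a CDR."""
    if region not in CDR_NAMES:
        raise MissingRegionError(f"{region} is not a CDR region")
    rd = REGION_DEFINITIONS[region]
    values = [
        a.b_factor
        for r in structure.iter_residues()
        if rd.contains(r.id)
        for a in r.atoms
    ]
    if not values:
        raise MissingRegionError(f"structure {structure.pdb_id!r} has no atoms in {region}")
    return float(np.mean(values))
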