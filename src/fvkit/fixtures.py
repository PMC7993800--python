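"""Synthetic Chothia-numbered antibody structures for testing and demos.

Every other module in the package can be exercised without downloading
real crystal structures: this module writes PDB-format coordinate
files, SAbDab-style summary tables, and dihedral fragment sets, all
deterministically from a seed.

The generated chains are idealized poly-peptide traces built from
standard internal coordinates (C-N ~1.33 A, canonical bond angles, a
lightly jittered extended backbone), not realistic immunoglobulin
folds.  Quality control, region extraction, constraint generation,
kinematics and RMSD arithmetic only require correct local geometry and
numbering, which the traces provide; anything sensitive to global fold
realism is out of scope here.  Light chains carry Chothia numbers
1-109, heavy chains 1-112, with loop-length variation expressed via
insertion codes at the canonical insertion position of each CDR
(e.g. H100A, H100B for a long CDR-H3).  When both chains are present a
glutamine pair is placed at light 38 / heavy 39 with side-chain amide
atoms at a configurable donor-acceptor distance, so the automatic Q-Q
constraint machinery has something real to find.

Defects can be injected one at a time (over-long C-N bond, out-of-window
bond angle, zero-occupancy atom, missing residue, poor resolution,
scFv summary row), each constructed to trip exactly one quality
criterion: for example a deleted residue leaves the backbone
geometrically continuous (the trace is built after the deletion) so
only the anchor/chainbreak bookkeeping notices it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .errors import FixtureSpecError
from .metrics import FragmentWindow, wrap_angle
from .regions import CDR_NAMES, REGION_DEFINITIONS, ChainKind, ResidueID
from .structure import Atom, Residue, SummaryRecord

#: Default seed for reproducible corpora.
DEFAULT_SEED = 20190215

# Idealized backbone internal coordinates.
_N_CA = 1.458
_CA_C = 1.525
_C_N = 1.329
_C_O = 1.231
_ANGLE_N_CA_C = 111.0
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5
_PHI0, _PSI0 = -139.0, 135.0  # extended-strand base dihedrals

#: Canonical insertion-code position inside each CDR loop.
INSERTION_POSITIONS = {
    "CDR_L1": 30,
    "CDR_L2": 54,
    "CDR_L3": 95,
    "CDR_H1": 31,
    "CDR_H2": 52,
    "CDR_H3": 100,
}

#: Span length of each CDR when every Chothia number is present.
DEFAULT_CDR_LENGTHS = {
    "CDR_L1": 11,
    "CDR_L2": 7,
    "CDR_L3": 9,
    "CDR_H1": 10,
    "CDR_H2": 16,
    "CDR_H3": 8,
}

_AA_ALPHABET = "ACDEFGHIKLMNQRSTVWY"  # no proline: keeps link geometry simple
_1TO3 = {k: v.upper() for k, v in protein_letters_1to3.items()}


# ---------------------------------------------------------------------------
# Defect specifications


@dataclass(frozen=True)
class LongBond:
    """Stretch the C-N link following a residue to ``length`` Angstrom."""

    chain: ChainKind
    after_number: int
    insertion_code: str = ""
    length: float = 2.5


@dataclass(frozen=True)
class BadAngle:
    """Set the CA-C-N angle of the link following a residue to ``angle`` deg."""

    chain: ChainKind
    after_number: int
    insertion_code: str = ""
    angle: float = 150.0


@dataclass(frozen=True)
class ZeroOccupancy:
    chain: ChainKind
    number: int
    insertion_code: str = ""
    atom: str = "CA"


@dataclass(frozen=True)
class MissingResidue:
    chain: ChainKind
    number: int
    insertion_code: str = ""


@dataclass(frozen=True)
class BadResolution:
    value: float = 3.4


@dataclass(frozen=True)
class ScFv:
    """Emit a summary row with identical heavy and light chain ids."""


Defect = LongBond | BadAngle | ZeroOccupancy | MissingResidue | BadResolution | ScFv


@dataclass
class FixtureSpec:
    seed: int = DEFAULT_SEED
    pdb_id: str = "fx00"
    chains: tuple[ChainKind, ...] = (ChainKind.LIGHT, ChainKind.HEAVY)
    cdr_lengths: dict[str, int] = field(default_factory=dict)
    antigen_chains: int = 0
    antigen_length: int = 20
    resolution: float = 2.0
    method: str = "X-RAY DIFFRACTION"
    qq_glutamines: bool = True
    qq_distance: float = 2.91
    defects: tuple[Defect, ...] = ()


# ---------------------------------------------------------------------------
# Geometry helpers


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta_deg: float, chi_deg: float
) -> np.ndarray:
    """NeRF placement: position d with |cd| = r, angle(b,c,d) = theta,
    torsion(a,b,c,d) = chi."""
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(theta), -r * math.sin(theta) * math.cos(chi), -r * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


# ---------------------------------------------------------------------------
# Roster construction (which Chothia positions exist, and their amino acids)


def _loop_positions(name: str, length: int) -> list[tuple[int, str]]:
    """Chothia (number, icode) pairs for one CDR at the requested length."""
    (span,) = REGION_DEFINITIONS[name].spans
    span_len = span.end - span.start + 1
    ins_at = INSERTION_POSITIONS[name]
    if length < 1:
        raise FixtureSpecError(f"{name} length must be >= 1, got {length}")
    if length >= span_len:
        positions = [(n, "") for n in range(span.start, span.end + 1)]
        extra = length - span_len
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        if extra > len(letters):
            raise FixtureSpecError(f"{name} length {length} exceeds insertion capacity")
        inserts = [(ins_at, letters[i]) for i in range(extra)]
        idx = positions.index((ins_at, "")) + 1
        return positions[:idx] + inserts + positions[idx:]
    # shorter than the reference span: delete numbers after the canonical
    # insertion point, keeping both boundary anchors
    n_delete = span_len - length
    deletable = [n for n in range(ins_at + 1, span.end)]
    if n_delete > len(deletable):
        raise FixtureSpecError(f"{name} length {length} is too short to represent")
    deleted = set(deletable[:n_delete])
    return [(n, "") for n in range(span.start, span.end + 1) if n not in deleted]


def _chain_roster(kind: ChainKind, spec: FixtureSpec, rng: np.random.Generator) -> list[Residue]:
    """Residue roster (ids + amino acids, no atoms yet) for one chain."""
    if kind is ChainKind.ANTIGEN:
        positions = [(n, "") for n in range(1, spec.antigen_length + 1)]
    else:
        last = 109 if kind is ChainKind.LIGHT else 112
        positions = [(n, "") for n in range(1, last + 1)]
        for name in CDR_NAMES:
            rd = REGION_DEFINITIONS[name]
            if rd.chain_kind is not kind:
                continue
            length = spec.cdr_lengths.get(name, DEFAULT_CDR_LENGTHS[name])
            (span,) = rd.spans
            loop = _loop_positions(name, length)
            idx0 = positions.index((span.start, ""))
            idx1 = positions.index((span.end, ""))
            positions = positions[:idx0] + loop + positions[idx1 + 1 :]
    residues = []
    for number, icode in positions:
        aa = _AA_ALPHABET[int(rng.integers(len(_AA_ALPHABET)))]
        residues.append(Residue(ResidueID(kind, number, icode), aa, _1TO3[aa], atoms=[]))
    # conserved glutamines for the V_H-V_L hydrogen-bond pair
    if spec.qq_glutamines:
        target = {ChainKind.LIGHT: 38, ChainKind.HEAVY: 39}.get(kind)
        for r in residues:
            if target is not None and r.id.number == target and r.id.insertion_code == "":
                r.aa, r.name = "Q", "GLN"
    return residues


# ---------------------------------------------------------------------------
# Backbone building and defect application


def _build_backbone(residues: list[Residue], rng: np.random.Generator, origin: np.ndarray) -> None:
    """Attach idealized N/CA/C/O atoms to a residue roster in place."""
    n = len(residues)
    phis = _PHI0 + rng.uniform(-8.0, 8.0, size=n)
    psis = _PSI0 + rng.uniform(-8.0, 8.0, size=n)
    coords: list[dict[str, np.ndarray]] = []
    N = origin.copy()
    CA = N + np.array([_N_CA, 0.0, 0.0])
    th = math.radians(180.0 - _ANGLE_N_CA_C)
    C = CA + _CA_C * np.array([math.cos(th), math.sin(th), 0.0])
    for i in range(n):
        entry = {"N": N, "CA": CA, "C": C}
        entry["O"] = _place_atom(N, CA, C, _C_O, _ANGLE_CA_C_O, psis[i] + 180.0)
        coords.append(entry)
        if i + 1 < n:
            N_next = _place_atom(N, CA, C, _C_N, _ANGLE_CA_C_N, psis[i])
            CA_next = _place_atom(CA, C, N_next, _N_CA, _ANGLE_C_N_CA, 180.0)
            C_next = _place_atom(C, N_next, CA_next, _CA_C, _ANGLE_N_CA_C, phis[i + 1])
            N, CA, C = N_next, CA_next, C_next
    for res, entry in zip(residues, coords):
        res.atoms = [
            Atom(name, tuple(float(v) for v in pos)) for name, pos in entry.items()
        ]


def _find_index(residues: list[Residue], number: int, icode: str) -> int:
    for i, r in enumerate(residues):
        if r.id.number == number and r.id.insertion_code == icode:
            return i
    raise FixtureSpecError(f"no residue numbered {number}{icode} in chain")


def _translate_tail(residues: list[Residue], start: int, shift: np.ndarray) -> None:
    for r in residues[start:]:
        r.atoms = [Atom(a.name, tuple(a.xyz() + shift), a.occupancy, a.b_factor) for a in r.atoms]


def _apply_long_bond(residues: list[Residue], defect: LongBond) -> None:
    i = _find_index(residues, defect.after_number, defect.insertion_code)
    if i + 1 >= len(residues):
        raise FixtureSpecError("long-bond defect needs a following residue")
    c = residues[i].atom("C").xyz()
    n = residues[i + 1].atom("N").xyz()
    u = (n - c) / np.linalg.norm(n - c)
    delta = defect.length - float(np.linalg.norm(n - c))
    _translate_tail(residues, i + 1, delta * u)


def _apply_bad_angle(residues: list[Residue], defect: BadAngle) -> None:
    i = _find_index(residues, defect.after_number, defect.insertion_code)
    if i + 1 >= len(residues):
        raise FixtureSpecError("bad-angle defect needs a following residue")
    ca = residues[i].atom("CA").xyz()
    c = residues[i].atom("C").xyz()
    n = residues[i + 1].atom("N").xyz()
    current = _angle_deg(ca, c, n)
    axis = np.cross(ca - c, n - c)
    for sign in (1.0, -1.0):
        rot = _rotation_about_axis(axis, sign * (defect.angle - current))
        if abs(_angle_deg(ca, c, rot @ (n - c) + c) - defect.angle) < 1e-6:
            for r in residues[i + 1 :]:
                r.atoms = [
                    Atom(a.name, tuple(rot @ (a.xyz() - c) + c), a.occupancy, a.b_factor)
                    for a in r.atoms
                ]
            return
    raise FixtureSpecError("could not realise requested bond angle")


def _apply_zero_occupancy(residues: list[Residue], defect: ZeroOccupancy) -> None:
    i = _find_index(residues, defect.number, defect.insertion_code)
    res = residues[i]
    if res.atom(defect.atom) is None:
        raise FixtureSpecError(f"residue {res.id} has no atom {defect.atom!r}")
    res.atoms = [
        Atom(a.name, a.position, 0.0 if a.name == defect.atom else a.occupancy, a.b_factor)
        for a in res.atoms
    ]


def _place_qq_sidechains(
    light: list[Residue], heavy: list[Residue], distance: float
) -> None:
    """Build Gln side-chain amides at L38/H39 at the requested N-O distance."""
    li = _find_index(light, 38, "")
    hi = _find_index(heavy, 39, "")
    ca_l = light[li].atom("CA").xyz()
    ca_h = heavy[hi].atom("CA").xyz()
    mid = (ca_l + ca_h) / 2.0
    u = (ca_h - ca_l) / np.linalg.norm(ca_h - ca_l)
    # a perpendicular offset separates the two candidate hydrogen bonds
    p = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(p) < 1e-6:
        p = np.cross(u, np.array([0.0, 1.0, 0.0]))
    p = 1.75 * p / np.linalg.norm(p)
    oe1_l = mid + p - (distance / 2.0) * u
    ne2_h = oe1_l + distance * u
    ne2_l = mid - p - (distance / 2.0) * u
    oe1_h = ne2_l + distance * u
    for res, ca, oe1, ne2 in ((light[li], ca_l, oe1_l, ne2_l), (heavy[hi], ca_h, oe1_h, ne2_h)):
        cd = (oe1 + ne2) / 2.0
        cb = ca + 0.25 * (cd - ca)
        cg = ca + 0.60 * (cd - ca)
        res.atoms = res.atoms + [
            Atom("CB", tuple(cb)),
            Atom("CG", tuple(cg)),
            Atom("CD", tuple(cd)),
            Atom("OE1", tuple(oe1)),
            Atom("NE2", tuple(ne2)),
        ]


def _assign_bfactors(residues: list[Residue], rng: np.random.Generator) -> None:
    for r in residues:
        r.atoms = [
            Atom(a.name, a.position, a.occupancy, round(float(rng.uniform(10.0, 50.0)), 2))
            for a in r.atoms
        ]


# ---------------------------------------------------------------------------
# PDB emission


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    return "C"


def _format_atom_line(
    serial: int, atom: Atom, res: Residue, chain_id: str
) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name}"
    x, y, z = atom.position
    return (
        f"ATOM  {serial:5d} {name:<4s} {res.name:>3s} {chain_id:1s}"
        f"{res.id.number:4d}{res.id.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {_element_of(atom.name):>2s}"
    )


def render_pdb(chains: Sequence[tuple[str, Sequence[Residue]]]) -> str:
    lines: list[str] = []
    serial = 1
    for chain_id, residues in chains:
        for res in residues:
            for atom in res.atoms:
                lines.append(_format_atom_line(serial, atom, res, chain_id))
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Public builders

_CHAIN_IDS = {ChainKind.LIGHT: "L", ChainKind.HEAVY: "H"}
_CHAIN_ORIGINS = {
    ChainKind.LIGHT: np.array([0.0, 0.0, 0.0]),
    ChainKind.HEAVY: np.array([40.0, 0.0, 0.0]),
}


def make_fixture_antibody(spec: FixtureSpec) -> tuple[str, SummaryRecord]:
    """Build one synthetic antibody entry: PDB text plus its summary row."""
    rng = np.random.default_rng(spec.seed)
    chains: dict[ChainKind, list[Residue]] = {}
    for kind in spec.chains:
        if kind is ChainKind.ANTIGEN:
            continue
        chains[kind] = _chain_roster(kind, spec, rng)
    for defect in spec.defects:
        if isinstance(defect, MissingResidue):
            if defect.chain not in chains:
                raise FixtureSpecError(f"missing-residue defect on absent chain {defect.chain}")
            i = _find_index(chains[defect.chain], defect.number, defect.insertion_code)
            del chains[defect.chain][i]
    for kind, residues in chains.items():
        _build_backbone(residues, rng, _CHAIN_ORIGINS[kind])
    for defect in spec.defects:
        if isinstance(defect, LongBond):
            _apply_long_bond(chains[defect.chain], defect)
        elif isinstance(defect, BadAngle):
            _apply_bad_angle(chains[defect.chain], defect)
    if (
        spec.qq_glutamines
        and ChainKind.LIGHT in chains
        and ChainKind.HEAVY in chains
        and not any(
            isinstance(d, MissingResidue) and (d.chain, d.number) in ((ChainKind.LIGHT, 38), (ChainKind.HEAVY, 39))
            for d in spec.defects
        )
    ):
        _place_qq_sidechains(chains[ChainKind.LIGHT], chains[ChainKind.HEAVY], spec.qq_distance)
    for residues in chains.values():
        _assign_bfactors(residues, rng)
    for defect in spec.defects:
        if isinstance(defect, ZeroOccupancy):
            _apply_zero_occupancy(chains[defect.chain], defect)

    antigen_blocks: list[tuple[str, list[Residue]]] = []
    for ai in range(spec.antigen_chains):
        roster = _chain_roster(ChainKind.ANTIGEN, spec, rng)
        _build_backbone(roster, rng, np.array([20.0, 40.0 + 30.0 * ai, 0.0]))
        _assign_bfactors(roster, rng)
        antigen_blocks.append((chr(ord("A") + ai), roster))

    ordered: list[tuple[str, Sequence[Residue]]] = []
    for kind in (ChainKind.LIGHT, ChainKind.HEAVY):
        if kind in chains:
            ordered.append((_CHAIN_IDS[kind], chains[kind]))
    ordered.extend(antigen_blocks)
    pdb_text = render_pdb(ordered)

    resolution = spec.resolution
    for defect in spec.defects:
        if isinstance(defect, BadResolution):
            resolution = defect.value
    scfv = any(isinstance(d, ScFv) for d in spec.defects)
    heavy_id = _CHAIN_IDS[ChainKind.HEAVY] if ChainKind.HEAVY in chains else None
    light_id = _CHAIN_IDS[ChainKind.LIGHT] if ChainKind.LIGHT in chains else None
    if scfv:
        heavy_id = light_id = heavy_id or light_id or "H"
    summary = SummaryRecord(
        pdb_id=spec.pdb_id,
        heavy_chain_id=heavy_id,
        light_chain_id=light_id,
        resolution=resolution,
        method=spec.method,
    )
    return pdb_text, summary


def write_summary_tsv(records: Sequence[SummaryRecord], path: Path) -> None:
    lines = ["pdb\tHchain\tLchain\tresolution\tmethod"]
    for rec in records:
        res = "" if rec.resolution is None else f"{rec.resolution:.2f}"
        lines.append(
            f"{rec.pdb_id}\t{rec.heavy_chain_id or ''}\t{rec.light_chain_id or ''}\t{res}\t{rec.method}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def make_fixture_corpus(
    n: int,
    seed: int = DEFAULT_SEED,
    out_dir: Path | str | None = None,
    duplicate_of: dict[int, int] | None = None,
    defects: dict[int, tuple[Defect, ...]] | None = None,
    h3_lengths: Sequence[int] = (8, 9, 10, 11),
) -> tuple[dict[str, str], list[SummaryRecord]]:
    """Generate a corpus of n entries with controlled diversity.

    ``duplicate_of`` maps an entry index to an earlier index whose
    sequences (and coordinates) it replicates under a new PDB id, for
    redundancy-filter assertions.  ``defects`` injects per-entry defect
    tuples.  Returns ({pdb_id: pdb_text}, summary rows) and, if
    ``out_dir`` is given, also writes ``<pdb_id>.pdb`` files plus a
    ``summary.tsv``.
    """
    if n < 1:
        raise FixtureSpecError("corpus size must be >= 1")
    duplicate_of = duplicate_of or {}
    defects = defects or {}
    child_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]
    files: dict[str, str] = {}
    summaries: list[SummaryRecord] = []
    for i in range(n):
        source = duplicate_of.get(i, i)
        spec = FixtureSpec(
            seed=child_seeds[source],
            pdb_id=f"f{i:03d}",
            cdr_lengths={"CDR_H3": h3_lengths[source % len(h3_lengths)]},
            defects=defects.get(i, ()),
        )
        pdb_text, summary = make_fixture_antibody(spec)
        files[spec.pdb_id] = pdb_text
        summaries.append(summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pdb_id, text in files.items():
            (out / f"{pdb_id}.pdb").write_text(text)
        write_summary_tsv(summaries, out / "summary.tsv")
    return files, summaries


def make_fragment_set(
    loop: FragmentWindow, offsets: Sequence[float | Sequence[tuple[float, float]]]
) -> list[FragmentWindow]:
    """Fragments equal to the loop with shifted dihedrals.

    Each entry of ``offsets`` describes one fragment: either a scalar
    shift applied to every phi and psi, or a per-position list of
    (dphi, dpsi) pairs.  Shifts wrap into (-180, 180].
    """
    fragments: list[FragmentWindow] = []
    for off in offsets:
        if np.isscalar(off):
            dphi = [float(off)] * loop.n
            dpsi = [float(off)] * loop.n
        else:
            pairs = list(off)  # type: ignore[arg-type]
            if len(pairs) != loop.n:
                raise FixtureSpecError(
                    f"offset list length {len(pairs)} != window length {loop.n}"
                )
            dphi = [float(p) for p, _ in pairs]
            dpsi = [float(s) for _, s in pairs]
        fragments.append(
            FragmentWindow(
                tuple(wrap_angle(a + d) for a, d in zip(loop.phi, dphi)),
                tuple(wrap_angle(a + d) for a, d in zip(loop.psi, dpsi)),
            )
        )
    return fragments
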