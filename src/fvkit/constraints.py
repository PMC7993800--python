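"""Flat-harmonic distance constraints and K-of-N composites.

The conserved glutamine pair at the V_H-V_L interface (light-chain Gln
38 and heavy-chain Gln 39) can form two side-chain hydrogen bonds, each
between the amide nitrogen (NE2) of one glutamine and the amide oxygen
(OE1) of the other.  These bonds are restrained with a flat-harmonic
penalty on the donor-acceptor heavy-atom distance x:

    f(x) = ((|x - x0| - dm) / sigma)^2   if |x - x0| > dm
    f(x) = 0                             otherwise

with x0 the mean observed distance, sigma the observed standard
deviation, and dm the half-width of the penalty-free flat bottom.  The
shipped defaults, fitted on a curated antibody template database, are
x0 = 2.91 A and sigma = 0.23 A with dm = 0.5 * sigma.  Note that with
dm = 0.5 sigma the formula above evaluates to 0.25 (not 0.5) at
|x - x0| = sigma; the formula is implemented as stated.

A ``KofNConstraint`` scores only the K lowest-penalty members of a set
of N flat-harmonic constraints, which lets ambiguous experimental
restraints (e.g. one epitope residue that must be near *some* CDR
residue) reward any satisfying arrangement without over-penalising the
rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConstraintConfigError, ConstraintFitError, ParseError
from .regions import ChainKind, ResidueID
from .structure import AntibodyStructure

DEFAULT_QQ_X0 = 2.91  # Angstrom, mean N-O donor-acceptor distance
DEFAULT_QQ_SIGMA = 0.23  # Angstrom
DEFAULT_QQ_DM = 0.5 * DEFAULT_QQ_SIGMA

LIGHT_QQ_POSITION = 38
HEAVY_QQ_POSITION = 39

#: Heavy atoms of the glutamine side-chain amide.
GLN_AMIDE_N = "NE2"
GLN_AMIDE_O = "OE1"

#: Donor-acceptor N-O distance treated as a formed hydrogen bond (reporting only).
HBOND_DISTANCE_CUTOFF = 3.5


@dataclass(frozen=True)
class AtomRef:
    atom_name: str
    residue: ResidueID


@dataclass(frozen=True)
class FlatHarmonicConstraint:
    x0: float
    sigma: float
    dm: float
    atom_pair: tuple[AtomRef, AtomRef] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConstraintConfigError(f"sigma must be positive, got {self.sigma}")
        if self.dm < 0:
            raise ConstraintConfigError(f"dm must be non-negative, got {self.dm}")

    def evaluate(self, x: float) -> float:
        return eval_flat_harmonic(self, x)


def eval_flat_harmonic(constraint: FlatHarmonicConstraint, x: float) -> float:
    """Flat-harmonic penalty at distance x (zero on the flat bottom).

    The boundary |x - x0| = dm lies in the zero branch (the penalised
    condition is strictly ``> dm``).
    """
    dev = abs(x - constraint.x0)
    if dev > constraint.dm:
        return ((dev - constraint.dm) / constraint.sigma) ** 2
    return 0.0


@dataclass(frozen=True)
class KofNConstraint:
    k: int
    members: tuple[FlatHarmonicConstraint, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.members):
            raise ConstraintConfigError(
                f"K must satisfy 1 <= K <= N, got K={self.k}, N={len(self.members)}"
            )


def eval_kofn(kofn: KofNConstraint, distances: Sequence[float]) -> float:
    """Sum of the K lowest member penalties, one distance per member."""
    if len(distances) != len(kofn.members):
        raise ConstraintConfigError(
            f"expected {len(kofn.members)} distances, got {len(distances)}"
        )
    penalties = sorted(m.evaluate(x) for m, x in zip(kofn.members, distances))
    return float(sum(penalties[: kofn.k]))


def fit_qq_parameters(distances: Sequence[float]) -> tuple[float, float, float]:
    """Fit (x0, sigma, dm) from observed donor-acceptor distances.

    x0 is the sample mean, sigma the sample (n-1) standard deviation,
    and dm = 0.5 * sigma.  Degenerate inputs (fewer than two values or
    zero variance) are rejected.
    """
    if len(distances) < 2:
        raise ConstraintFitError(f"need at least 2 distances, got {len(distances)}")
    arr = np.asarray(distances, dtype=float)
    x0 = float(np.mean(arr))
    sigma = float(np.std(arr, ddof=1))
    if sigma == 0.0:
        raise ConstraintFitError("zero variance in observed distances; cannot fit sigma")
    return x0, sigma, 0.5 * sigma


@dataclass(frozen=True)
class QQGeometry:
    """The two candidate hydrogen bonds across the V_H-V_L interface."""

    light_gln: ResidueID
    heavy_gln: ResidueID
    pairs: tuple[tuple[AtomRef, AtomRef], ...]


def find_qq_pairs(structure: AntibodyStructure) -> QQGeometry | None:
    """Locate the glutamine-glutamine donor-acceptor atom pairings.

    Returns None (constraint disabled) unless light residue 38 and
    heavy residue 39 are both glutamines carrying their side-chain
    amide atoms; otherwise returns the two N-to-O pairings.
    """
    light = structure.find_residue(ResidueID(ChainKind.LIGHT, LIGHT_QQ_POSITION))
    heavy = structure.find_residue(ResidueID(ChainKind.HEAVY, HEAVY_QQ_POSITION))
    if light is None or heavy is None:
        return None
    if light.aa != "Q" or heavy.aa != "Q":
        return None
    for res in (light, heavy):
        if not res.has_atoms((GLN_AMIDE_N, GLN_AMIDE_O)):
            return None
    return QQGeometry(
        light_gln=light.id,
        heavy_gln=heavy.id,
        pairs=(
            (AtomRef(GLN_AMIDE_N, light.id), AtomRef(GLN_AMIDE_O, heavy.id)),
            (AtomRef(GLN_AMIDE_N, heavy.id), AtomRef(GLN_AMIDE_O, light.id)),
        ),
    )


def measure_pair_distances(structure: AntibodyStructure, geometry: QQGeometry) -> list[float]:
    """Donor-acceptor distances (A) for each Q-Q atom pairing."""
    out: list[float] = []
    for donor, acceptor in geometry.pairs:
        dres = structure.find_residue(donor.residue)
        ares = structure.find_residue(acceptor.residue)
        datom = dres.atom(donor.atom_name) if dres else None
        aatom = ares.atom(acceptor.atom_name) if ares else None
        if datom is None or aatom is None:
            raise ConstraintConfigError(f"missing atom for pair {donor} - {acceptor}")
        out.append(float(np.linalg.norm(datom.xyz() - aatom.xyz())))
    return out


def qq_constraints(
    structure: AntibodyStructure,
    x0: float = DEFAULT_QQ_X0,
    sigma: float = DEFAULT_QQ_SIGMA,
    dm: float | None = None,
) -> list[FlatHarmonicConstraint]:
    """Automatic Q-Q constraints for a structure (empty if not applicable)."""
    geometry = find_qq_pairs(structure)
    if geometry is None:
        return []
    if dm is None:
        dm = 0.5 * sigma
    return [
        FlatHarmonicConstraint(x0=x0, sigma=sigma, dm=dm, atom_pair=pair)
        for pair in geometry.pairs
    ]


def hydrogen_bond_formed(distance: float) -> bool:
    """Geometric hydrogen-bond call on a donor-acceptor N-O distance."""
    return distance <= HBOND_DISTANCE_CUTOFF


# ---------------------------------------------------------------------------
# Serialization (Rosetta-style atom-pair constraint grammar)

_CHAIN_LETTER = {ChainKind.LIGHT: "L", ChainKind.HEAVY: "H", ChainKind.ANTIGEN: "A"}
_LETTER_CHAIN = {v: k for k, v in _CHAIN_LETTER.items()}


def _residue_token(rid: ResidueID) -> str:
    return f"{rid.number}{rid.insertion_code}{_CHAIN_LETTER[rid.chain_kind]}"


def _parse_residue_token(token: str) -> ResidueID:
    chain = _LETTER_CHAIN.get(token[-1])
    if chain is None:
        raise ParseError(f"unknown chain letter in residue token {token!r}")
    body = token[:-1]
    icode = ""
    if body and body[-1].isalpha():
        icode = body[-1]
        body = body[:-1]
    try:
        number = int(body)
    except ValueError:
        raise ParseError(f"malformed residue token {token!r}") from None
    return ResidueID(chain, number, icode)


def _atom_pair_line(c: FlatHarmonicConstraint) -> str:
    if c.atom_pair is None:
        raise ConstraintConfigError("constraint has no atom pair; cannot serialise")
    a, b = c.atom_pair
    return (
        f"AtomPair {a.atom_name} {_residue_token(a.residue)} "
        f"{b.atom_name} {_residue_token(b.residue)} "
        f"FLAT_HARMONIC {c.x0:.3f} {c.sigma:.3f} {c.dm:.3f}"
    )


def serialize_constraints(
    constraints: Iterable[FlatHarmonicConstraint | KofNConstraint],
) -> str:
    """Plain-text constraint file: one AtomPair record per line,
    K-of-N blocks wrapped in ``KofNConstraint <K> ... End``."""
    lines: list[str] = []
    for c in constraints:
        if isinstance(c, KofNConstraint):
            lines.append(f"KofNConstraint {c.k}")
            lines.extend(_atom_pair_line(m) for m in c.members)
            lines.append("End")
        else:
            lines.append(_atom_pair_line(c))
    return "\n".join(lines) + ("\n" if lines else "")


def write_constraint_file(
    constraints: Sequence[FlatHarmonicConstraint | KofNConstraint], path
) -> None:
    text = serialize_constraints(constraints)
    with open(path, "w") as fh:
        fh.write(text)


def _parse_atom_pair_line(line: str) -> FlatHarmonicConstraint:
    fields = line.split()
    if len(fields) != 9 or fields[0] != "AtomPair" or fields[5] != "FLAT_HARMONIC":
        raise ParseError(f"malformed AtomPair record: {line!r}")
    a = AtomRef(fields[1], _parse_residue_token(fields[2]))
    b = AtomRef(fields[3], _parse_residue_token(fields[4]))
    x0, sigma, dm = (float(v) for v in fields[6:9])
    return FlatHarmonicConstraint(x0=x0, sigma=sigma, dm=dm, atom_pair=(a, b))


def parse_constraints(text: str) -> list[FlatHarmonicConstraint | KofNConstraint]:
    """Inverse of :func:`serialize_constraints` (``#`` comments allowed)."""
    out: list[FlatHarmonicConstraint | KofNConstraint] = []
    block_k: int | None = None
    block_members: list[FlatHarmonicConstraint] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("KofNConstraint"):
            if block_k is not None:
                raise ParseError("nested KofNConstraint blocks are not supported")
            try:
                block_k = int(line.split()[1])
            except (IndexError, ValueError):
                raise ParseError(f"malformed KofNConstraint header: {line!r}") from None
            block_members = []
        elif line == "End":
            if block_k is None:
                raise ParseError("'End' outside a KofNConstraint block")
            out.append(KofNConstraint(k=block_k, members=tuple(block_members)))
            block_k = None
        else:
            c = _parse_atom_pair_line(line)
            if block_k is None:
                out.append(c)
            else:
                block_members.append(c)
    if block_k is not None:
        raise ParseError("unterminated KofNConstraint block")
    return out


def gauss_negative_log_likelihood(distances: Sequence[float], x0: float, sigma: float) -> float:
    """Mean negative log-likelihood of distances under Normal(x0, sigma)."""
    arr = np.asarray(distances, dtype=float)
    return float(
        np.mean(0.5 * ((arr - x0) / sigma) ** 2 + math.log(sigma * math.sqrt(2 * math.pi)))
    )
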