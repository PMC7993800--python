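"""Per-region template selection by local sequence alignment.

Framework queries are scored against framework pools with BLOSUM62 and
affine gaps (a gap of length k costs open + k * extend); CDR queries
search only the pool of matching length with PAM30 in an ungapped
full-length mode, mirroring the length-partitioned database layout.
Candidate templates can then be filtered: by PDB id (to exclude a
query's own known structure during benchmarking) and by the proline
rule, which removes CDR templates with a proline in the template or
query but not both, since prolines occupy their own region of
Ramachandran space and substitution matrices under-penalise the
mismatch.

Ranking ties are broken deterministically: higher score, then lower
template resolution, then lower average CDR B-factor, then PDB id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlignmentInputError, FilterNotApplicableError
from .regions import CDR_NAMES, FRAMEWORK_NAMES, STANDARD_AA
from .database import TemplateDatabase, TemplateRecord
from .structure import AntibodyStructure
from .regions import extract_region_sequence
from .errors import MissingRegionError

#: Conventional gap-penalty pairings for the two matrices.
DEFAULT_SCHEMES = {
    "BLOSUM62": (11, 1),
    "PAM30": (9, 1),
}


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


def default_scheme(matrix_name: str) -> ScoringScheme:
    gap_open, gap_extend = DEFAULT_SCHEMES[matrix_name]
    return ScoringScheme(matrix_name, gap_open, gap_extend)


FRAMEWORK_SCHEME = default_scheme("BLOSUM62")
CDR_SCHEME = default_scheme("PAM30")


@dataclass(frozen=True)
class TemplateHit:
    pdb_id: str
    region_name: str
    alignment_score: float
    template_sequence: str
    resolution: float | None = None
    avg_bfactor: float | None = None
    filter_flags: frozenset[str] = field(default_factory=frozenset)


def _validate(sequence: str) -> None:
    bad = set(sequence) - STANDARD_AA
    if bad or not sequence:
        raise AlignmentInputError(
            f"sequence must be non-empty standard residues; offending: {sorted(bad)!r}"
        )


def local_align_score(
    query: str, template: str, scheme: ScoringScheme, ungapped: bool = False
) -> float:
    """Best local (Smith-Waterman) alignment score under the scheme.

    With ``ungapped=True`` the sequences must be equal length and the
    score is the straight sum of substitution-matrix entries, the mode
    used for length-partitioned CDR pools.
    """
    _validate(query)
    _validate(template)
    matrix = scheme.matrix
    if ungapped:
        if len(query) != len(template):
            raise AlignmentInputError("ungapped scoring requires equal-length sequences")
        return float(sum(matrix[q, t] for q, t in zip(query, template)))
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # first gapped position costs open+extend, each further position extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return float(aligner.score(query, template))


def filter_exclude_pdb(
    hits: Sequence[TemplateHit], excluded_ids: Sequence[str]
) -> tuple[list[TemplateHit], list[TemplateHit]]:
    """Split hits into (kept, flagged) by case-insensitive PDB id."""
    excluded = {e.lower() for e in excluded_ids}
    kept: list[TemplateHit] = []
    flagged: list[TemplateHit] = []
    for hit in hits:
        if hit.pdb_id.lower() in excluded:
            flagged.append(replace(hit, filter_flags=hit.filter_flags | {"excluded_pdb"}))
        else:
            kept.append(hit)
    return kept, flagged


def proline_mismatch_positions(query: str, template: str) -> list[int]:
    """0-based positions where exactly one sequence has a proline."""
    if len(query) != len(template):
        raise FilterNotApplicableError(
            "proline filter compares equal-length CDR sequences only"
        )
    return [i for i, (q, t) in enumerate(zip(query, template)) if (q == "P") != (t == "P")]


def filter_proline_mismatch(
    query: str, hits: Sequence[TemplateHit]
) -> tuple[list[TemplateHit], list[TemplateHit]]:
    """Drop hits with proline/non-proline mismatches against the query."""
    kept: list[TemplateHit] = []
    flagged: list[TemplateHit] = []
    for hit in hits:
        if proline_mismatch_positions(query, hit.template_sequence):
            flagged.append(replace(hit, filter_flags=hit.filter_flags | {"proline_mismatch"}))
        else:
            kept.append(hit)
    return kept, flagged


def _rank_key(hit: TemplateHit):
    return (
        -hit.alignment_score,
        float("inf") if hit.resolution is None else hit.resolution,
        float("inf") if hit.avg_bfactor is None else hit.avg_bfactor,
        hit.pdb_id,
    )


def _score_pool(
    query: str, records: Sequence[TemplateRecord], scheme: ScoringScheme, ungapped: bool
) -> list[TemplateHit]:
    return [
        TemplateHit(
            pdb_id=rec.pdb_id,
            region_name=rec.region_name,
            alignment_score=local_align_score(query, rec.sequence, scheme, ungapped=ungapped),
            template_sequence=rec.sequence,
            resolution=rec.resolution,
            avg_bfactor=rec.avg_bfactor,
        )
        for rec in records
    ]


@dataclass
class RegionRanking:
    region_name: str
    hits: list[TemplateHit] = field(default_factory=list)
    flagged: list[TemplateHit] = field(default_factory=list)
    warning: str = ""


def query_regions_from_structure(structure: AntibodyStructure) -> dict[str, str]:
    """Per-region query sequences from a Chothia-numbered structure."""
    out: dict[str, str] = {}
    for name in CDR_NAMES + FRAMEWORK_NAMES:
        try:
            out[name] = extract_region_sequence(structure, name).sequence
        except MissingRegionError:
            continue
    return out


def select_templates(
    region_sequences: Mapping[str, str],
    db: TemplateDatabase,
    exclude_pdbs: Sequence[str] = (),
    proline_filter: bool = True,
    top_n: int | None = None,
) -> dict[str, RegionRanking]:
    """Rank template hits per region, applying the configured filters.

    CDR regions search only the pool of the query's length (ungapped,
    PAM30); frameworks search all framework pools of their region with
    gapped BLOSUM62.  Hard-removed hits stay available in ``flagged``.
    """
    rankings: dict[str, RegionRanking] = {}
    for region, query in region_sequences.items():
        ranking = RegionRanking(region_name=region)
        rankings[region] = ranking
        is_cdr = region in CDR_NAMES
        if is_cdr:
            pool = db.pools.get((region, len(query)), [])
            if not pool:
                available = sorted(db.region_pools(region))
                nearest = sorted(available, key=lambda n: abs(n - len(query)))[:3]
                ranking.warning = (
                    f"no {region} pool of length {len(query)}; nearest available: {nearest}"
                )
                warnings.warn(ranking.warning, stacklevel=2)
                continue
            hits = _score_pool(query, pool, CDR_SCHEME, ungapped=True)
        else:
            pool = [rec for recs in db.region_pools(region).values() for rec in recs]
            hits = _score_pool(query, pool, FRAMEWORK_SCHEME, ungapped=False)
        hits, flagged = filter_exclude_pdb(hits, exclude_pdbs)
        ranking.flagged.extend(flagged)
        if proline_filter and is_cdr:
            hits, flagged = filter_proline_mismatch(query, hits)
            ranking.flagged.extend(flagged)
        hits.sort(key=_rank_key)
        if not hits:
            ranking.warning = ranking.warning or f"all {region} candidates were filtered out"
            warnings.warn(ranking.warning, stacklevel=2)
        ranking.hits = hits if top_n is None else hits[:top_n]
    return rankings


def rankings_to_tsv(rankings: Mapping[str, RegionRanking], verbose: bool = False) -> str:
    lines = ["region\trank\tpdb_id\tscore\ttemplate_sequence\tflags"]
    for region in rankings:
        ranking = rankings[region]
        for rank, hit in enumerate(ranking.hits, start=1):
            lines.append(
                f"{region}\t{rank}\t{hit.pdb_id}\t{hit.alignment_score:g}\t"
                f"{hit.template_sequence}\t"
            )
        if verbose:
            for hit in ranking.flagged:
                flags = ",".join(sorted(hit.filter_flags))
                lines.append(
                    f"{region}\t-\t{hit.pdb_id}\t{hit.alignment_score:g}\t"
                    f"{hit.template_sequence}\t{flags}"
                )
    return "\n".join(lines) + "\n"
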