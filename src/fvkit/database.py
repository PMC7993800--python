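"""Template-database construction from Chothia-numbered structures.

Given a directory of SAbDab-style pre-numbered PDB files and a
tab-delimited summary table (``pdb  Hchain  Lchain  resolution
method``), the builder runs each entry through a fixed pipeline:

1. entry selection — the first summary row per PDB id wins; rows whose
   heavy and light ids coincide (scFv) are skipped;
2. parse + truncate to the Fv (light 1-109, heavy 1-112);
3. quality control — resolution < cutoff, loadability, peptide-link
   geometry, non-zero occupancy, conserved anchor residues;
4. redundancy — entries whose full Fv sequence duplicates an earlier
   accepted entry are dropped (first in summary order wins);
5. region extraction — per-region sequences, omitting CDRs with chain
   breaks and regions containing non-standard ('X') residues;
6. pooling by (region, length), with per-CDR average B-factors and
   orientation-anchor coordinates recorded for later filters.

Pools are written as one FASTA file per (region, length), e.g.
``database.L1.11`` for all length-11 CDR-L1 sequences, with headers
carrying the source PDB id; per-region info tables and a rejection log
accompany them.  Rebuilding from the same inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FvkitError, MissingRegionError, ParseError, ScFvError
from .regions import (
    CDR_NAMES,
    FRAMEWORK_NAMES,
    SHORT_NAMES,
    STANDARD_AA,
    ChainKind,
    ResidueID,
    extract_region_sequence,
)
from .structure import (
    AntibodyStructure,
    SummaryRecord,
    average_cdr_bfactor,
    detect_cdr_chainbreaks,
    read_chothia_structure,
    run_quality_control,
    truncate_fv,
)

#: Orientation anchor positions whose CA coordinates are stored raw, so
#: that V_H-V_L orientation measures can be computed downstream.
ORIENTATION_ANCHORS = (
    (ChainKind.LIGHT, 5),
    (ChainKind.LIGHT, 104),
    (ChainKind.HEAVY, 5),
    (ChainKind.HEAVY, 109),
)


@dataclass(frozen=True)
class TemplateRecord:
    pdb_id: str
    region_name: str
    sequence: str
    avg_bfactor: float | None
    resolution: float | None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class BuildConfig:
    resolution_cutoff: float = 3.0


@dataclass
class Provenance:
    n_summary_rows: int = 0
    n_entries: int = 0
    accepted: list[str] = field(default_factory=list)
    rejections: list[tuple[str, str, str]] = field(default_factory=list)  # pdb, criterion, detail
    region_notes: list[tuple[str, str, str]] = field(default_factory=list)  # pdb, region, reason

    def reject(self, pdb_id: str, criterion: str, detail: str = "") -> None:
        self.rejections.append((pdb_id, criterion, detail))


@dataclass
class TemplateDatabase:
    pools: dict[tuple[str, int], list[TemplateRecord]] = field(default_factory=dict)
    info_tables: dict[str, list[dict]] = field(default_factory=dict)
    orientation_coords: dict[str, dict[str, tuple[float, float, float]]] = field(default_factory=dict)
    provenance: Provenance = field(default_factory=Provenance)
    config: BuildConfig = field(default_factory=BuildConfig)

    def add_record(self, record: TemplateRecord) -> None:
        self.pools.setdefault((record.region_name, record.length), []).append(record)
        self.info_tables.setdefault(record.region_name, []).append(
            {
                "pdb": record.pdb_id,
                "sequence": record.sequence,
                "length": record.length,
                "avg_bfactor": record.avg_bfactor,
                "resolution": record.resolution,
            }
        )

    def region_pools(self, region_name: str) -> dict[int, list[TemplateRecord]]:
        return {
            length: records
            for (name, length), records in self.pools.items()
            if name == region_name
        }


def read_summary(path: Path | str) -> list[SummaryRecord]:
    """Read a SAbDab-style summary TSV preserving file order."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"pdb": str, "Hchain": str, "Lchain": str})
    except Exception as exc:  # noqa: BLE001 - normalise into our error type
        raise ParseError(f"unreadable summary table {path}: {exc}") from exc
    required = {"pdb", "Hchain", "Lchain", "resolution"}
    if not required.issubset(frame.columns):
        raise ParseError(f"summary table missing columns {sorted(required - set(frame.columns))}")
    records: list[SummaryRecord] = []
    for row in frame.itertuples(index=False):
        heavy = getattr(row, "Hchain", None)
        light = getattr(row, "Lchain", None)
        resolution = getattr(row, "resolution", None)
        records.append(
            SummaryRecord(
                pdb_id=str(row.pdb),
                heavy_chain_id=None if pd.isna(heavy) or heavy == "" else str(heavy),
                light_chain_id=None if pd.isna(light) or light == "" else str(light),
                resolution=None if pd.isna(resolution) else float(resolution),
                method=str(getattr(row, "method", "") or ""),
            )
        )
    return records


def select_antibody_from_entry(rows: list[SummaryRecord]) -> SummaryRecord | None:
    """First non-scFv summary row for one PDB entry, or None if all scFv."""
    if not rows:
        raise FvkitError("entry selection requires at least one summary row")
    for row in rows:
        if not row.is_scfv:
            return row
    return None


def _extract_records(
    structure: AntibodyStructure, db: TemplateDatabase
) -> list[TemplateRecord]:
    broken = detect_cdr_chainbreaks(structure)
    records: list[TemplateRecord] = []
    for name in CDR_NAMES + FRAMEWORK_NAMES:
        try:
            region_seq = extract_region_sequence(structure, name)
        except MissingRegionError:
            continue  # e.g. light-chain regions of a nanobody
        if name in broken:
            db.provenance.region_notes.append((structure.pdb_id, name, "chainbreak"))
            continue
        if not set(region_seq.sequence) <= STANDARD_AA:
            db.provenance.region_notes.append((structure.pdb_id, name, "nonstandard_residue"))
            continue
        bfactor = average_cdr_bfactor(structure, name) if name in CDR_NAMES else None
        records.append(
            TemplateRecord(
                pdb_id=structure.pdb_id,
                region_name=name,
                sequence=region_seq.sequence,
                avg_bfactor=bfactor,
                resolution=structure.resolution,
            )
        )
    return records


def _store_orientation_coords(structure: AntibodyStructure, db: TemplateDatabase) -> None:
    coords: dict[str, tuple[float, float, float]] = {}
    for kind, number in ORIENTATION_ANCHORS:
        res = structure.find_residue(ResidueID(kind, number))
        atom = res.atom("CA") if res else None
        if atom is not None:
            coords[str(res.id)] = atom.position
    if coords:
        db.orientation_coords[structure.pdb_id] = coords


def build_database(
    structures_dir: Path | str,
    summary_path: Path | str,
    config: BuildConfig | None = None,
) -> TemplateDatabase:
    """Run the full curation pipeline over a structure directory."""
    config = config or BuildConfig()
    structures_dir = Path(structures_dir)
    summary_rows = read_summary(summary_path)
    db = TemplateDatabase(config=config)
    db.provenance.n_summary_rows = len(summary_rows)

    by_pdb: dict[str, list[SummaryRecord]] = {}
    for row in summary_rows:
        by_pdb.setdefault(row.pdb_id, []).append(row)
    db.provenance.n_entries = len(by_pdb)

    seen_fv: set[str] = set()
    for pdb_id, rows in by_pdb.items():
        summary = select_antibody_from_entry(rows)
        if summary is None:
            db.provenance.reject(pdb_id, "scfv", "all summary rows are single-chain Fv")
            continue
        pdb_path = structures_dir / f"{pdb_id}.pdb"
        if not pdb_path.exists():
            db.provenance.reject(pdb_id, "missing_file", str(pdb_path))
            continue
        try:
            structure = read_chothia_structure(pdb_path.read_text(), summary)
        except (ParseError, ScFvError, FvkitError) as exc:
            db.provenance.reject(pdb_id, "loadability", str(exc))
            continue
        structure = truncate_fv(structure)
        report = run_quality_control(structure, config.resolution_cutoff)
        if not report.passed:
            failed = report.failed_criteria()
            detail = "; ".join(c.detail for c in report.checks if not c.passed)
            db.provenance.reject(pdb_id, failed[0], detail)
            continue
        fv = structure.fv_sequence()
        if fv in seen_fv:
            db.provenance.reject(pdb_id, "redundant", "identical Fv sequence already accepted")
            continue
        seen_fv.add(fv)
        for record in _extract_records(structure, db):
            db.add_record(record)
        _store_orientation_coords(structure, db)
        db.provenance.accepted.append(pdb_id)
    return db


# ---------------------------------------------------------------------------
# Output


def write_pools(db: TemplateDatabase, out_dir: Path | str) -> list[Path]:
    """Write pool FASTAs, per-region info tables, rejection log, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (region, length) in sorted(db.pools):
        records = db.pools[(region, length)]
        if not records:
            continue
        path = out / f"database.{SHORT_NAMES[region]}.{length}"
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f">{rec.pdb_id}\n{rec.sequence}\n")
        written.append(path)
    for region in sorted(db.info_tables):
        rows = db.info_tables[region]
        path = out / f"{SHORT_NAMES[region]}.info"
        with open(path, "w") as fh:
            fh.write("pdb\tsequence\tlength\tavg_bfactor\tresolution\n")
            for row in rows:
                bf = "" if row["avg_bfactor"] is None else f"{row['avg_bfactor']:.2f}"
                res = "" if row["resolution"] is None else f"{row['resolution']:.2f}"
                fh.write(f"{row['pdb']}\t{row['sequence']}\t{row['length']}\t{bf}\t{res}\n")
        written.append(path)
    rej_path = out / "rejections.tsv"
    with open(rej_path, "w") as fh:
        fh.write("pdb\tcriterion\tdetail\n")
        for pdb_id, criterion, detail in db.provenance.rejections:
            fh.write(f"{pdb_id}\t{criterion}\t{detail}\n")
    written.append(rej_path)
    manifest = {
        "summary_rows": db.provenance.n_summary_rows,
        "entries": db.provenance.n_entries,
        "accepted": db.provenance.accepted,
        "rejected": [
            {"pdb": p, "criterion": c, "detail": d} for p, c, d in db.provenance.rejections
        ],
        "region_notes": [
            {"pdb": p, "region": r, "reason": why} for p, r, why in db.provenance.region_notes
        ],
        "resolution_cutoff": db.config.resolution_cutoff,
        "orientation_coords": db.orientation_coords,
    }
    man_path = out / "provenance.json"
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    written.append(man_path)
    return written


def load_pools(db_dir: Path | str) -> TemplateDatabase:
    """Reconstruct pools and info tables from a written database directory."""
    db = TemplateDatabase()
    long_names = {v: k for k, v in SHORT_NAMES.items()}
    info: dict[str, dict[str, dict]] = {}
    for path in sorted(Path(db_dir).glob("*.info")):
        region = long_names.get(path.stem)
        if region is None:
            continue
        frame = pd.read_csv(path, sep="\t", dtype={"pdb": str})
        info[region] = {
            str(row.pdb): {
                "avg_bfactor": None if pd.isna(row.avg_bfactor) else float(row.avg_bfactor),
                "resolution": None if pd.isna(row.resolution) else float(row.resolution),
            }
            for row in frame.itertuples(index=False)
        }
    for path in sorted(Path(db_dir).glob("database.*")):
        parts = path.name.split(".")
        if len(parts) != 3:
            continue
        region = long_names.get(parts[1])
        if region is None:
            continue
        pdb_id = None
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                pdb_id = line[1:].strip()
            elif line and pdb_id is not None:
                meta = info.get(region, {}).get(pdb_id, {})
                db.add_record(
                    TemplateRecord(
                        pdb_id=pdb_id,
                        region_name=region,
                        sequence=line.strip(),
                        avg_bfactor=meta.get("avg_bfactor"),
                        resolution=meta.get("resolution"),
                    )
                )
                pdb_id = None
    return db
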