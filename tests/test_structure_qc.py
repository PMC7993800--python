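"""PDB parsing, Fv truncation, and the template quality-control criteria."""

import math

import numpy as np
import pytest

from fvkit.errors import MissingChainError, MissingRegionError, ScFvError
from fvkit.fixtures import (
    BadAngle,
    BadResolution,
    FixtureSpec,
    LongBond,
    MissingResidue,
    ZeroOccupancy,
    make_fixture_antibody,
)
from fvkit.regions import ChainKind, ResidueID
from fvkit.structure import (
    AntibodyStructure,
    Atom,
    Residue,
    SummaryRecord,
    average_cdr_bfactor,
    check_anchor_residues,
    check_backbone_geometry,
    check_occupancy,
    check_resolution,
    detect_cdr_chainbreaks,
    read_chothia_structure,
    run_quality_control,
    truncate_fv,
)


def build(spec: FixtureSpec) -> AntibodyStructure:
    text, summary = make_fixture_antibody(spec)
    return truncate_fv(read_chothia_structure(text, summary))


# ---------------------------------------------------------------------------
# Parsing and chain selection


def test_antigen_chains_dropped():
    text, summary = make_fixture_antibody(FixtureSpec(seed=3, pdb_id="ag01", antigen_chains=1))
    structure = read_chothia_structure(text, summary)
    assert structure.light_residues and structure.heavy_residues
    assert all(
        r.id.chain_kind in (ChainKind.LIGHT, ChainKind.HEAVY)
        for r in structure.iter_residues()
    )


def test_nanobody_parses_without_light_chain(nanobody_structure):
    assert nanobody_structure.light_residues == []
    assert nanobody_structure.heavy_residues


def test_scfv_summary_rejected(clean_entry):
    text, _ = clean_entry
    scfv = SummaryRecord("sc01", heavy_chain_id="H", light_chain_id="H", resolution=2.0)
    with pytest.raises(ScFvError):
        read_chothia_structure(text, scfv)


def test_missing_named_chain_errors(clean_entry):
    text, _ = clean_entry
    summary = SummaryRecord("xx01", heavy_chain_id="Z", light_chain_id="L", resolution=2.0)
    with pytest.raises(MissingChainError):
        read_chothia_structure(text, summary)


# ---------------------------------------------------------------------------
# Fv truncation


def _residue(kind: ChainKind, number: int) -> Residue:
    return Residue(ResidueID(kind, number), "A", "ALA", [Atom("CA", (float(number), 0.0, 0.0))])


def test_truncate_fv_bounds():
    structure = AntibodyStructure(
        pdb_id="tr01",
        light_residues=[_residue(ChainKind.LIGHT, n) for n in range(1, 215)],
        heavy_residues=[_residue(ChainKind.HEAVY, n) for n in range(1, 131)],
    )
    fv = truncate_fv(structure)
    assert [r.id.number for r in fv.light_residues] == list(range(1, 110))
    assert fv.heavy_residues[-1].id.number == 112
    assert all(r.id.number <= 112 for r in fv.heavy_residues)


def test_truncate_fv_idempotent_and_never_grows(clean_structure):
    once = truncate_fv(clean_structure)
    twice = truncate_fv(once)
    assert [r.id for r in twice.iter_residues()] == [r.id for r in once.iter_residues()]
    assert len(list(once.iter_residues())) <= len(list(clean_structure.iter_residues()))


# ---------------------------------------------------------------------------
# Individual criteria


@pytest.mark.parametrize(
    "resolution, expected",
    [(2.5, True), (3.0, False), (None, False), (2.999, True)],
)
def test_resolution_criterion_strictly_below_cutoff(resolution, expected):
    s = AntibodyStructure("rs01", resolution=resolution)
    assert check_resolution(s).passed is expected


def test_occupancy_criterion_zero_only():
    def structure_with_occupancy(value):
        res = Residue(ResidueID(ChainKind.LIGHT, 1), "A", "ALA", [Atom("CA", (0, 0, 0), value)])
        return AntibodyStructure("oc01", light_residues=[res])

    assert check_occupancy(structure_with_occupancy(1.0)).passed
    assert check_occupancy(structure_with_occupancy(0.5)).passed
    assert not check_occupancy(structure_with_occupancy(0.0)).passed


def test_anchor_criterion_flags_deleted_anchor():
    s = build(FixtureSpec(seed=3, pdb_id="an01", defects=(MissingResidue(ChainKind.HEAVY, 95),)))
    result = check_anchor_residues(s)
    assert not result.passed
    assert "H95" in result.detail


def test_nanobody_skips_light_anchors(nanobody_structure):
    assert check_anchor_residues(nanobody_structure).passed


def test_geometry_violation_detected_by_kind():
    long_bond = build(FixtureSpec(seed=3, pdb_id="gb01", defects=(LongBond(ChainKind.LIGHT, 15, length=2.5),)))
    result = check_backbone_geometry(long_bond)
    assert not result.passed and "bond_length" in result.detail

    bad_angle = build(FixtureSpec(seed=3, pdb_id="ga01", defects=(BadAngle(ChainKind.HEAVY, 80, angle=150.0),)))
    result = check_backbone_geometry(bad_angle)
    assert not result.passed and "ca_c_n_angle" in result.detail


def test_geometry_agrees_with_bruteforce_recomputation():
    s = build(FixtureSpec(seed=13, pdb_id="gg01", defects=(LongBond(ChainKind.LIGHT, 77, length=2.2),)))

    def brute_force_bad_links(residues):
        bad = []
        for a, b in zip(residues, residues[1:]):
            c = np.array(a.atom("C").position)
            n = np.array(b.atom("N").position)
            ca1 = np.array(a.atom("CA").position)
            ca2 = np.array(b.atom("CA").position)
            d = float(np.linalg.norm(n - c))
            ang1 = math.degrees(
                math.acos(np.dot(ca1 - c, n - c) / (np.linalg.norm(ca1 - c) * np.linalg.norm(n - c)))
            )
            ang2 = math.degrees(
                math.acos(np.dot(c - n, ca2 - n) / (np.linalg.norm(c - n) * np.linalg.norm(ca2 - n)))
            )
            if d > 2.0 or not (89.5 <= ang1 <= 144.5) or not (95 <= ang2 <= 151):
                bad.append((a.id, b.id))
        return bad

    expected = brute_force_bad_links(s.light_residues) + brute_force_bad_links(s.heavy_residues)
    from fvkit.structure import all_link_violations

    observed = [(v.from_residue, v.to_residue) for v in all_link_violations(s)]
    assert observed == expected
    assert expected  # the injected defect is actually there


# ---------------------------------------------------------------------------
# Chain breaks and B-factors


def test_cdr_chainbreak_from_geometry():
    s = build(FixtureSpec(seed=3, pdb_id="cb01", defects=(LongBond(ChainKind.LIGHT, 28, length=4.0),)))
    assert detect_cdr_chainbreaks(s) == {"CDR_L1"}
    # a CDR-internal break does not reject the whole structure
    assert check_backbone_geometry(s).passed


def test_framework_break_not_reported_as_cdr_break():
    s = build(FixtureSpec(seed=3, pdb_id="cb02", defects=(LongBond(ChainKind.LIGHT, 15, length=4.0),)))
    assert detect_cdr_chainbreaks(s) == set()
    assert not check_backbone_geometry(s).passed


def test_missing_interior_number_flags_cdr():
    s = build(FixtureSpec(seed=3, pdb_id="cb03", defects=(MissingResidue(ChainKind.LIGHT, 28),)))
    assert "CDR_L1" in detect_cdr_chainbreaks(s)


def test_clean_structure_has_no_breaks(clean_structure):
    assert detect_cdr_chainbreaks(clean_structure) == set()


def test_average_bfactor_matches_bruteforce(clean_structure):
    from fvkit.regions import REGION_DEFINITIONS

    rd = REGION_DEFINITIONS["CDR_H2"]
    values = [
        a.b_factor
        for r in clean_structure.iter_residues()
        if rd.contains(r.id)
        for a in r.atoms
    ]
    expected = sum(values) / len(values)
    assert average_cdr_bfactor(clean_structure, "CDR_H2") == pytest.approx(expected)


def test_average_bfactor_rejects_framework_and_empty(nanobody_structure):
    with pytest.raises(MissingRegionError):
        average_cdr_bfactor(nanobody_structure, "FRH")
    with pytest.raises(MissingRegionError):
        average_cdr_bfactor(nanobody_structure, "CDR_L1")


# ---------------------------------------------------------------------------
# Whole-report behaviour


def test_report_contains_every_criterion_pass_or_fail(clean_structure):
    report = run_quality_control(clean_structure)
    assert [c.name for c in report.checks] == [
        "resolution", "loadability", "geometry", "occupancy", "anchors",
    ]
    assert report.passed

    bad = build(FixtureSpec(seed=3, pdb_id="qr01", defects=(BadResolution(3.4),)))
    report = run_quality_control(bad)
    assert [c.name for c in report.checks] == [
        "resolution", "loadability", "geometry", "occupancy", "anchors",
    ]
    assert report.failed_criteria() == ["resolution"]


def test_defects_fail_exactly_their_criterion():
    cases = {
        "geometry": (LongBond(ChainKind.LIGHT, 15, length=2.5),),
        "occupancy": (ZeroOccupancy(ChainKind.LIGHT, 60, atom="CA"),),
        "anchors": (MissingResidue(ChainKind.HEAVY, 95),),
        "resolution": (BadResolution(3.4),),
    }
    for criterion, defects in cases.items():
        s = build(FixtureSpec(seed=21, pdb_id="df01", defects=defects))
        assert run_quality_control(s).failed_criteria() == [criterion], criterion
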