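"""Fold-tree construction, rigid-body jump propagation, and validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_chain
from fvkit.errors import FoldTreeError
from fvkit.foldtree import (
    apply_jump,
    center_of_mass,
    hierarchical_foldtree,
    linear_foldtree,
    parse_foldtree,
    serialize_foldtree,
    validate_foldtree,
)
from fvkit.regions import ChainKind, ResidueID
from fvkit.structure import Atom, Residue


def rotation_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array(
        [[math.cos(t), -math.sin(t), 0.0], [math.sin(t), math.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )


def atom_cloud(tree) -> dict[str, np.ndarray]:
    """Every atom position in the tree, keyed by node id + atom name."""
    out = {}
    for node in tree.residue_nodes():
        for atom in node.residue.atoms:
            out[f"{node.id}:{atom.name}"] = atom.xyz()
    return out


# ---------------------------------------------------------------------------
# Centre of mass


def test_com_single_atom():
    res = Residue(ResidueID(ChainKind.ANTIGEN, 1), "A", "ALA", [Atom("CA", (1.0, 2.0, 3.0))])
    assert np.allclose(center_of_mass([res]), [1.0, 2.0, 3.0])


def test_com_symmetric_pair_is_origin():
    res = Residue(
        ResidueID(ChainKind.ANTIGEN, 1),
        "A",
        "ALA",
        [Atom("CA", (1.0, 0.0, 0.0)), Atom("CB", (-1.0, 0.0, 0.0))],
    )
    assert np.allclose(center_of_mass([res]), [0.0, 0.0, 0.0])


def test_com_matches_bruteforce_mean():
    chain = make_chain("A", 15, seed=3)
    coords = np.array([a.xyz() for r in chain.residues for a in r.atoms])
    assert np.allclose(center_of_mass(chain.residues), coords.mean(axis=0))


def test_com_requires_atoms():
    with pytest.raises(FoldTreeError):
        center_of_mass([])


# ---------------------------------------------------------------------------
# Builders


def four_chains():
    return [make_chain(c, 10, seed=i, origin=(25.0 * i, 0.0, 0.0)) for i, c in enumerate("ABCD")]


def test_linear_tree_has_chains_minus_one_jumps():
    tree = linear_foldtree(four_chains())
    assert len(tree.jumps) == 3
    assert validate_foldtree(tree).passed
    single = linear_foldtree([make_chain("A", 8, seed=1)])
    assert len(single.jumps) == 0


def test_linear_jump_anchors_are_com_proximal():
    chains = four_chains()
    tree = linear_foldtree(chains)
    for chain in chains:
        com = center_of_mass(chain.residues)
        best = min(
            chain.residues,
            key=lambda r: np.linalg.norm(r.atom("CA").xyz() - com),
        )
        anchor_ids = {tree.jumps[j].upstream for j in tree.jumps} | {
            tree.jumps[j].downstream for j in tree.jumps
        }
        assert f"res:{chain.id}:{best.id.number}" in anchor_ids


def test_hierarchical_node_counts_for_antibody_antigen():
    h, l, a = make_chain("H", 10, 1), make_chain("L", 10, 2, (25, 0, 0)), make_chain("A", 10, 3, (0, 25, 0))
    tree = hierarchical_foldtree([[h, l], [a]])
    virtuals = [n for n in tree.nodes.values() if n.kind == "virtual"]
    assert len(virtuals) == 1 + 2 + 3  # root + two groups + three chains
    assert validate_foldtree(tree).passed
    # virtual nodes sit at the relevant centres of mass
    assert np.allclose(
        tree.nodes["vrt:group1"].position, center_of_mass(h.residues + l.residues)
    )


def test_hierarchical_heavy_only_group_is_valid():
    tree = hierarchical_foldtree([[make_chain("H", 12, 5)], [make_chain("A", 8, 6, (30, 0, 0))]])
    assert validate_foldtree(tree).passed
    assert not any("L" == n.id.split(".")[-1] for n in tree.nodes.values() if n.kind == "virtual")


def test_hierarchical_single_group_single_chain():
    tree = hierarchical_foldtree([[make_chain("H", 6, 9)]])
    virtuals = [n for n in tree.nodes.values() if n.kind == "virtual"]
    assert len(virtuals) == 3  # complex + group + chain
    assert validate_foldtree(tree).passed


# ---------------------------------------------------------------------------
# Jump application


def test_identity_update_leaves_coordinates_unchanged():
    tree = linear_foldtree(four_chains())
    before = atom_cloud(tree)
    apply_jump(tree, 1)
    after = atom_cloud(tree)
    assert all(np.allclose(before[k], after[k]) for k in before)


def test_linear_perturbation_propagates_downstream():
    tree = linear_foldtree(four_chains())
    before = atom_cloud(tree)
    apply_jump(tree, 1, rotation_z(20.0), [3.0, 0.0, 0.0])
    after = atom_cloud(tree)
    moved = {k.split(":")[1] for k in before if np.linalg.norm(after[k] - before[k]) > 1e-6}
    still = {k.split(":")[1] for k in before if np.linalg.norm(after[k] - before[k]) <= 1e-6}
    assert moved == {"B", "C", "D"}
    assert still == {"A"}
    # relative geometry among moved chains is preserved
    for pair in (("B", "C"), ("C", "D")):
        keys0 = [k for k in before if k.split(":")[1] == pair[0]][:5]
        keys1 = [k for k in before if k.split(":")[1] == pair[1]][:5]
        for k0 in keys0:
            for k1 in keys1:
                d_before = np.linalg.norm(before[k0] - before[k1])
                d_after = np.linalg.norm(after[k0] - after[k1])
                assert d_after == pytest.approx(d_before, abs=1e-6)


def test_hierarchical_intergroup_jump_preserves_intra_antibody_geometry():
    h, l, a = make_chain("H", 10, 1), make_chain("L", 10, 2, (25, 0, 0)), make_chain("A", 10, 3, (0, 25, 0))
    tree = hierarchical_foldtree([[h, l], [a]])
    before = atom_cloud(tree)
    # jump 1 is root -> antibody group
    apply_jump(tree, 1, rotation_z(35.0), [4.0, -2.0, 1.0])
    after = atom_cloud(tree)
    ab_keys = [k for k in before if k.split(":")[1] in ("H", "L")]
    for i in range(0, len(ab_keys), 7):
        for j in range(i + 1, len(ab_keys), 11):
            d_before = np.linalg.norm(before[ab_keys[i]] - before[ab_keys[j]])
            d_after = np.linalg.norm(after[ab_keys[i]] - after[ab_keys[j]])
            assert d_after == pytest.approx(d_before, abs=1e-6)
    # the antigen group did not move
    ag_keys = [k for k in before if k.split(":")[1] == "A"]
    assert all(np.allclose(before[k], after[k]) for k in ag_keys)


def test_hl_jump_leaves_antigen_untouched():
    h, l, a = make_chain("H", 10, 1), make_chain("L", 10, 2, (25, 0, 0)), make_chain("A", 10, 3, (0, 25, 0))
    tree = hierarchical_foldtree([[h, l], [a]])
    # find the jump from the antibody group to the L chain virtual
    (jump_id,) = [
        j for j, jump in tree.jumps.items() if jump.downstream == "vrt:chain.L"
    ]
    before = atom_cloud(tree)
    apply_jump(tree, jump_id, rotation_z(25.0), [0.0, 3.0, 0.0])
    after = atom_cloud(tree)
    for k in before:
        chain = k.split(":")[1]
        if chain in ("A", "H"):
            assert np.allclose(before[k], after[k], atol=1e-12)


def test_repeated_updates_preserve_subtree_rigidity():
    tree = linear_foldtree(four_chains())
    before = atom_cloud(tree)
    rng = np.random.default_rng(8)
    for _ in range(5):
        jump_id = int(rng.integers(1, 4))
        apply_jump(tree, jump_id, rotation_z(float(rng.uniform(-40, 40))), rng.uniform(-3, 3, 3))
    after = atom_cloud(tree)
    # distances within one chain never change
    for chain in "ABCD":
        keys = [k for k in before if k.split(":")[1] == chain][:8]
        for i, k0 in enumerate(keys):
            for k1 in keys[i + 1 :]:
                assert np.linalg.norm(after[k0] - after[k1]) == pytest.approx(
                    np.linalg.norm(before[k0] - before[k1]), abs=1e-6
                )


def test_invalid_jump_updates_rejected():
    tree = linear_foldtree(four_chains())
    with pytest.raises(FoldTreeError):
        apply_jump(tree, 99)
    with pytest.raises(FoldTreeError):
        apply_jump(tree, 1, np.eye(3) * 2.0)  # not orthonormal
    with pytest.raises(FoldTreeError):
        apply_jump(tree, 1, np.diag([1.0, 1.0, -1.0]))  # improper rotation


# ---------------------------------------------------------------------------
# Validation and serialization


@settings(deadline=None, derandomize=True, max_examples=20)
@given(
    n_chains=st.integers(min_value=1, max_value=6),
    split=st.integers(min_value=0, max_value=5),
    linear=st.booleans(),
)
def test_randomized_groupings_yield_valid_trees(n_chains, split, linear):
    chains = [
        make_chain(chr(ord("A") + i), 6, seed=i + 1, origin=(20.0 * i, 0.0, 0.0))
        for i in range(n_chains)
    ]
    if linear:
        tree = linear_foldtree(chains)
    else:
        cut = min(split, n_chains - 1)
        groups = [chains[: cut + 1], chains[cut + 1 :]] if cut + 1 < n_chains else [chains]
        tree = hierarchical_foldtree(groups)
    expected = [
        f"res:{c.id}:{r.id.number}{r.id.insertion_code}" for c in chains for r in c.residues
    ]
    assert validate_foldtree(tree, expected).passed


def test_back_edge_detected_as_cycle():
    tree = linear_foldtree(four_chains())
    child = tree.children(tree.root)[0]
    tree.edges.append((child, tree.root, "peptide"))
    report = validate_foldtree(tree)
    assert not report.passed


def test_missing_residue_coverage_failure():
    tree = linear_foldtree(four_chains())
    report = validate_foldtree(tree, ["res:A:1", "res:Z:999"])
    assert not report.passed
    assert any("res:Z:999" in p for p in report.problems)


def test_serialization_roundtrip_exact():
    tree = hierarchical_foldtree(
        [[make_chain("H", 8, 1), make_chain("L", 8, 2, (25, 0, 0))], [make_chain("A", 8, 3, (0, 25, 0))]]
    )
    text = serialize_foldtree(tree)
    assert serialize_foldtree(parse_foldtree(text)) == text
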