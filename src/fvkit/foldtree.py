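"""Fold-tree kinematics for multi-chain complexes.

A fold tree is a directed acyclic graph over residues that dictates how
coordinate changes propagate: peptide edges connect consecutive
residues within a chain, and "jump" edges carry rigid-body transforms
(rotation + translation) between non-bonded anchors.  Perturbing a jump
moves everything downstream of it rigidly and leaves the upstream part
untouched.

Two builders are provided:

* :func:`linear_foldtree` — the conventional layout for an N-chain
  complex: jumps daisy-chain the chains in file order (A->B->C->D), so
  perturbing an early jump drags every later chain along.

* :func:`hierarchical_foldtree` — virtual residues (position-only
  nodes, invisible to any energy or quality computation) are placed at
  the centre of mass of each chain, each chain group (e.g. the two
  antibody chains, or all antigen chains), and the whole complex.
  Jumps connect complex -> group -> chain -> anchor residue, so a group
  can be docked as one rigid body without disturbing the internal
  geometry of any other group.  Nothing in the construction assumes a
  light chain exists, so heavy-chain-only antibodies are handled
  naturally.

Jump anchors within a chain are the residues closest to the chain's
centre of mass, and peptide edges fan outward from the anchor in both
directions, which keeps every residue single-parented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import FoldTreeError
from .structure import Atom, Residue

PEPTIDE = "peptide"


@dataclass
class Chain:
    id: str
    residues: list[Residue]


def center_of_mass(residues: Iterable[Residue]) -> np.ndarray:
    """Unweighted centroid of all heavy atoms in the residues."""
    coords = [a.xyz() for r in residues for a in r.atoms]
    if not coords:
        raise FoldTreeError("cannot compute a centre of mass without atoms")
    return np.mean(np.array(coords), axis=0)


def _anchor_index(chain: Chain) -> int:
    """Index of the residue whose CA (or first atom) is nearest the chain COM."""
    com = center_of_mass(chain.residues)
    best, best_d = 0, np.inf
    for i, res in enumerate(chain.residues):
        atom = res.atom("CA") or (res.atoms[0] if res.atoms else None)
        if atom is None:
            continue
        d = float(np.linalg.norm(atom.xyz() - com))
        if d < best_d:
            best, best_d = i, d
    return best


@dataclass
class KinematicNode:
    id: str
    kind: str  # "residue" | "virtual"
    position: np.ndarray
    residue: Residue | None = field(default=None, repr=False)


@dataclass
class Jump:
    id: int
    upstream: str
    downstream: str
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class FoldTree:
    nodes: dict[str, KinematicNode] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)  # (parent, child, label)
    jumps: dict[int, Jump] = field(default_factory=dict)
    root: str = ""

    # -- construction helpers -------------------------------------------------

    def _add_node(self, node: KinematicNode) -> None:
        if node.id in self.nodes:
            raise FoldTreeError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def _add_peptide_edge(self, parent: str, child: str) -> None:
        self.edges.append((parent, child, PEPTIDE))

    def _add_jump(self, parent: str, child: str) -> Jump:
        jump = Jump(id=len(self.jumps) + 1, upstream=parent, downstream=child)
        self.jumps[jump.id] = jump
        self.edges.append((parent, child, f"jump{jump.id}"))
        return jump

    # -- queries --------------------------------------------------------------

    def children(self, node_id: str) -> list[str]:
        return [c for p, c, _ in self.edges if p == node_id]

    def subtree(self, node_id: str) -> list[str]:
        """Node ids reachable from (and including) ``node_id``."""
        seen: list[str] = []
        stack = [node_id]
        visited: set[str] = set()
        while stack:
            nid = stack.pop()
            if nid in visited:
                raise FoldTreeError(f"cycle detected at node {nid!r}")
            visited.add(nid)
            seen.append(nid)
            stack.extend(self.children(nid))
        return seen

    def residue_nodes(self) -> list[KinematicNode]:
        return [n for n in self.nodes.values() if n.kind == "residue"]

    def coordinates(self) -> dict[str, np.ndarray]:
        return {nid: n.position.copy() for nid, n in self.nodes.items()}


def _residue_node_id(chain_id: str, res: Residue) -> str:
    return f"res:{chain_id}:{res.id.number}{res.id.insertion_code}"


def _add_chain_residues(tree: FoldTree, chain: Chain, entry_index: int) -> str:
    """Add a chain's residues with peptide edges fanning out from the entry.

    Returns the entry residue's node id.
    """
    ids: list[str] = []
    for res in chain.residues:
        nid = _residue_node_id(chain.id, res)
        atom = res.atom("CA") or (res.atoms[0] if res.atoms else None)
        if atom is None:
            raise FoldTreeError(f"residue {res.id} has no atoms to anchor")
        tree._add_node(KinematicNode(nid, "residue", atom.xyz(), residue=res))
        ids.append(nid)
    for i in range(entry_index, 0, -1):
        tree._add_peptide_edge(ids[i], ids[i - 1])
    for i in range(entry_index, len(ids) - 1):
        tree._add_peptide_edge(ids[i], ids[i + 1])
    return ids[entry_index]


def linear_foldtree(chains: Sequence[Chain]) -> FoldTree:
    """Daisy-chained fold tree over chains in file order.

    Jumps connect the COM-proximal residues of consecutive chains, so a
    complex of N chains has N - 1 jumps and perturbing jump i moves
    every chain after it.
    """
    if not chains:
        raise FoldTreeError("cannot build a fold tree over zero chains")
    tree = FoldTree()
    anchors: list[str] = []
    for chain in chains:
        if not chain.residues:
            raise FoldTreeError(f"chain {chain.id!r} has no residues")
        anchors.append(_add_chain_residues(tree, chain, _anchor_index(chain)))
    tree.root = anchors[0]
    for up, down in zip(anchors, anchors[1:]):
        tree._add_jump(up, down)
    return tree


def hierarchical_foldtree(groups: Sequence[Sequence[Chain]]) -> FoldTree:
    """Virtual-residue fold tree for independent sub-complex docking.

    Layout: a root virtual node at the complex COM jumps to one virtual
    node per group (at the group COM), which jumps to one virtual node
    per member chain (at the chain COM), which jumps to the chain's
    COM-proximal residue.  Single-chain groups (e.g. a nanobody) are
    valid; no chain identity is assumed.
    """
    if not groups or any(len(g) == 0 for g in groups):
        raise FoldTreeError("each group must contain at least one chain")
    tree = FoldTree()
    all_residues = [r for group in groups for chain in group for r in chain.residues]
    tree._add_node(KinematicNode("vrt:complex", "virtual", center_of_mass(all_residues)))
    tree.root = "vrt:complex"
    for gi, group in enumerate(groups, start=1):
        group_residues = [r for chain in group for r in chain.residues]
        gid = f"vrt:group{gi}"
        tree._add_node(KinematicNode(gid, "virtual", center_of_mass(group_residues)))
        tree._add_jump("vrt:complex", gid)
        for chain in group:
            if not chain.residues:
                raise FoldTreeError(f"chain {chain.id!r} has no residues")
            cid = f"vrt:chain.{chain.id}"
            tree._add_node(KinematicNode(cid, "virtual", center_of_mass(chain.residues)))
            tree._add_jump(gid, cid)
            anchor = _add_chain_residues(tree, chain, _anchor_index(chain))
            tree._add_jump(cid, anchor)
    return tree


def apply_jump(
    tree: FoldTree,
    jump_id: int,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | Sequence[float] | None = None,
) -> None:
    """Rigidly move the subtree downstream of a jump.

    The rotation pivots about the jump's upstream node position; the
    translation is applied afterwards.  Residue atoms move together
    with their nodes, so all pairwise distances within the moved
    subtree (and among unmoved nodes) are preserved.
    """
    if jump_id not in tree.jumps:
        raise FoldTreeError(f"no jump with id {jump_id}")
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    trans = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
        raise FoldTreeError("rotation must be a 3x3 orthonormal matrix")
    if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
        raise FoldTreeError("rotation must be proper (determinant +1)")
    jump = tree.jumps[jump_id]
    pivot = tree.nodes[jump.upstream].position.copy()

    def move(p: np.ndarray) -> np.ndarray:
        return rot @ (p - pivot) + pivot + trans

    for nid in tree.subtree(jump.downstream):
        node = tree.nodes[nid]
        node.position = move(node.position)
        if node.residue is not None:
            node.residue.atoms = [
                Atom(a.name, tuple(move(a.xyz())), a.occupancy, a.b_factor)
                for a in node.residue.atoms
            ]
    jump.rotation = rot @ jump.rotation
    jump.translation = rot @ jump.translation + trans


@dataclass(frozen=True)
class FoldTreeValidation:
    passed: bool
    problems: tuple[str, ...]


def validate_foldtree(
    tree: FoldTree, expected_residue_ids: Sequence[str] | None = None
) -> FoldTreeValidation:
    """Check acyclicity, connectivity, single-parenting, and coverage."""
    problems: list[str] = []
    parents: dict[str, int] = {nid: 0 for nid in tree.nodes}
    for parent, child, _ in tree.edges:
        if parent not in tree.nodes or child not in tree.nodes:
            problems.append(f"edge references unknown node: {parent} -> {child}")
            continue
        parents[child] += 1
    for nid, count in parents.items():
        if nid == tree.root:
            if count != 0:
                problems.append(f"root {nid} has an incoming edge")
        elif count != 1:
            problems.append(f"node {nid} has {count} parents (expected 1)")
    try:
        reachable = set(tree.subtree(tree.root))
    except FoldTreeError as exc:
        problems.append(str(exc))
        reachable = set()
    unreachable = set(tree.nodes) - reachable
    if unreachable and not problems:
        problems.extend(f"node {nid} unreachable from root" for nid in sorted(unreachable))
    elif unreachable:
        problems.append(f"{len(unreachable)} nodes unreachable from root")
    if expected_residue_ids is not None:
        present = {n.id for n in tree.residue_nodes()}
        for rid in expected_residue_ids:
            if rid not in present:
                problems.append(f"residue {rid} missing from tree (coverage)")
    return FoldTreeValidation(passed=not problems, problems=tuple(problems))


# ---------------------------------------------------------------------------
# Serialization: plain-text node/edge list


def serialize_foldtree(tree: FoldTree) -> str:
    lines = [f"ROOT {tree.root}"]
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        x, y, z = n.position
        lines.append(f"NODE {nid} {n.kind} {x:.6f} {y:.6f} {z:.6f}")
    for parent, child, label in tree.edges:
        lines.append(f"EDGE {parent} {child} {label}")
    return "\n".join(lines) + "\n"


def parse_foldtree(text: str) -> FoldTree:
    """Inverse of :func:`serialize_foldtree` (topology + node positions)."""
    tree = FoldTree()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "ROOT" and len(fields) == 2:
            tree.root = fields[1]
        elif fields[0] == "NODE" and len(fields) == 6:
            nid, kind = fields[1], fields[2]
            pos = np.array([float(v) for v in fields[3:6]])
            tree._add_node(KinematicNode(nid, kind, pos))
        elif fields[0] == "EDGE" and len(fields) == 4:
            parent, child, label = fields[1], fields[2], fields[3]
            if label.startswith("jump"):
                jump = Jump(id=int(label[4:]), upstream=parent, downstream=child)
                tree.jumps[jump.id] = jump
                tree.edges.append((parent, child, label))
            else:
                tree._add_peptide_edge(parent, child)
        else:
            raise FoldTreeError(f"malformed fold-tree line: {raw!r}")
    if not tree.root:
        raise FoldTreeError("fold-tree text has no ROOT line")
    return tree
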