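"""Body-bar constraint networks and (6,6) pebble-game rigidity.

A protein is modelled as a multigraph: heavy atoms are rigid bodies with
six degrees of freedom, constraints are bars between them.  Bar counts per
constraint class follow the body-bar convention: a locked covalent bond
(peptide, resonance-stabilised or ring bond) contributes 6 bars, a
rotatable single bond 5, a hydrogen bond or salt bridge 5, a hydrophobic
tether 2.  Hydrogens are merged into their parent bodies, and terminal
single-bonded heavy atoms (e.g. the carbonyl oxygen) are merged into their
neighbour, since their only internal motion is a spin about the bond axis
that moves no atom.

Rigidity is decided by the (k=6, l=6) pebble game: a bar is independent
iff seven pebbles can be gathered on its endpoints.  The number of
degrees of freedom of the network is ``6 n_bodies - n_independent`` (the
six trivial rigid-body motions included), and two bodies share a rigid
cluster iff one more bar between them would be redundant.  A brute-force
count-matroid oracle validates the game on small networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .interactions import KIND_HBOND, KIND_HYDROPHOBIC, KIND_SALT, Interaction
from .structio import ResKey, Structure, atom_key, covalent_bonds

SOURCE_COVALENT_LOCKED = "covalent_locked"
SOURCE_COVALENT_ROTATABLE = "covalent_rotatable"

#: Bars per constraint class; config-exposed (pass ``multiplicities=`` to
#: :func:`build_network` to override).
DEFAULT_MULTIPLICITIES = {
    SOURCE_COVALENT_LOCKED: 6,
    SOURCE_COVALENT_ROTATABLE: 5,
    KIND_HBOND: 5,
    KIND_SALT: 5,
    KIND_HYDROPHOBIC: 2,
}

K_DOF = 6  # degrees of freedom per body
L_TRIVIAL = 6  # trivial motions subtracted in the sparsity count


@dataclass(frozen=True)
class Bar:
    a: int
    b: int
    multiplicity: int
    source: str
    energy: float | None = None


@dataclass
class ConstraintNetwork:
    """Multigraph of bodies and bars, with optional residue bookkeeping."""

    n_bodies: int
    bars: list[Bar] = field(default_factory=list)
    body_residue: list[ResKey | None] = field(default_factory=list)
    ca_body: dict[ResKey, int] = field(default_factory=dict)
    backbone_bodies: dict[ResKey, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_bodies < 1:
            raise ValueError("network must have at least one body")
        for bar in self.bars:
            if not (0 <= bar.a < self.n_bodies and 0 <= bar.b < self.n_bodies):
                raise ValueError(f"bar {bar} references unknown body")
            if bar.a == bar.b:
                raise ValueError("self-loop bars are not allowed")

    @property
    def n_bars(self) -> int:
        return sum(b.multiplicity for b in self.bars)

    def dilutable_energies(self) -> list[float]:
        return sorted({b.energy for b in self.bars
                       if b.source in (KIND_HBOND, KIND_SALT) and b.energy is not None})

    def filtered(self, e_cut: float, strict: bool = False) -> "ConstraintNetwork":
        """Copy keeping dilutable bars with energy <= e_cut (or < if strict)."""
        keep = []
        for bar in self.bars:
            if bar.source in (KIND_HBOND, KIND_SALT):
                e = bar.energy if bar.energy is not None else 0.0
                if (e < e_cut) if strict else (e <= e_cut):
                    keep.append(bar)
            else:
                keep.append(bar)
        return ConstraintNetwork(self.n_bodies, keep, self.body_residue,
                                 self.ca_body, self.backbone_bodies)


@dataclass
class RigidDecomposition:
    """Partition of bodies into rigid clusters plus global counts.

    Clusters are numbered from 1 by descending size (ties: smallest
    contained body index first).  ``p_inf`` is the fraction of bodies in
    the largest cluster; ``dof`` counts all degrees of freedom including
    the six trivial rigid-body motions.
    """

    cluster_of: np.ndarray
    cluster_sizes: list[int]
    dof: int
    n_independent: int

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def p_inf(self) -> float:
        return self.cluster_sizes[0] / len(self.cluster_of)

    def same_cluster(self, a: int, b: int) -> bool:
        return self.cluster_of[a] == self.cluster_of[b]


# --------------------------------------------------------------------------
# pebble game
# --------------------------------------------------------------------------

class _PebbleGame:
    """Directed-graph state of the (6,6) pebble game."""

    def __init__(self, n: int) -> None:
        self.n = n
        self.pebbles = np.full(n, K_DOF, dtype=np.int64)
        self.succ: list[dict[int, int]] = [dict() for _ in range(n)]

    def _pull_pebble(self, root: int, blocked: tuple[int, int]) -> bool:
        """Move one pebble to ``root`` by reversing a path, if possible."""
        parent = {root: -1}
        stack = [root]
        target = -1
        while stack:
            u = stack.pop()
            for v in self.succ[u]:
                if v in parent:
                    continue
                parent[v] = u
                if self.pebbles[v] > 0 and v not in blocked:
                    target = v
                    stack.clear()
                    break
                stack.append(v)
        if target < 0:
            return False
        v = target
        while v != root:
            u = parent[v]
            # reverse edge u -> v
            self.succ[u][v] -= 1
            if self.succ[u][v] == 0:
                del self.succ[u][v]
            self.succ[v][u] = self.succ[v].get(u, 0) + 1
            v = u
        self.pebbles[target] -= 1
        self.pebbles[root] += 1
        return True

    def collect(self, u: int, v: int, target: int = L_TRIVIAL + 1) -> bool:
        """Try to gather ``target`` pebbles on {u, v}."""
        while self.pebbles[u] + self.pebbles[v] < target:
            if not (self._pull_pebble(u, (u, v)) or self._pull_pebble(v, (u, v))):
                return False
        return True

    def add_bar(self, u: int, v: int) -> bool:
        """Insert one unit bar; returns True iff independent."""
        if not self.collect(u, v):
            return False
        if self.pebbles[u] == 0:
            u, v = v, u
        self.pebbles[u] -= 1
        self.succ[u][v] = self.succ[u].get(v, 0) + 1
        return True


def pebble_game(network: ConstraintNetwork) -> RigidDecomposition:
    """Rigid cluster decomposition of a body-bar network.

    The result is independent of bar insertion order (matroid property);
    rigid clusters are the equivalence classes of the mutual-rigidity
    relation "an extra bar between the pair would be redundant", which is
    transitive in the body-bar model because two rigid clusters sharing a
    body are jointly rigid.
    """
    n = network.n_bodies
    game = _PebbleGame(n)
    independent = 0
    for bar in network.bars:
        for _ in range(bar.multiplicity):
            if game.add_bar(bar.a, bar.b):
                independent += 1
    dof = K_DOF * n - independent

    unassigned = list(range(n))
    clusters: list[list[int]] = []
    adjacency: list[set[int]] = [set() for _ in range(n)]
    for bar in network.bars:
        adjacency[bar.a].add(bar.b)
        adjacency[bar.b].add(bar.a)
    while unassigned:
        u = unassigned.pop(0)
        members = [u]
        # only bodies connected to u's component can possibly be rigid with it
        component = _component_of(adjacency, u)
        rest = []
        for v in unassigned:
            if v in component and not game.collect(u, v):
                members.append(v)
            else:
                rest.append(v)
        unassigned = rest
        clusters.append(members)

    clusters.sort(key=lambda c: (-len(c), min(c)))
    cluster_of = np.zeros(n, dtype=np.int64)
    for cid, members in enumerate(clusters, start=1):
        for m in members:
            cluster_of[m] = cid
    return RigidDecomposition(cluster_of, [len(c) for c in clusters], dof, independent)


def _component_of(adjacency: list[set[int]], u: int) -> set[int]:
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in adjacency[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


# --------------------------------------------------------------------------
# brute-force count-matroid oracle
# --------------------------------------------------------------------------

BRUTE_FORCE_MAX_BODIES = 8


def _count_independent(unit_pairs: Sequence[tuple[int, int]], n: int) -> bool:
    """Is a unit-bar multiset independent in the (6,6) count matroid?

    Independence requires every sub-multiset spanning n' >= 2 bodies to
    have at most 6 n' - 6 bars; by maximality it suffices to check, for
    every body subset S, the bars fully inside S.
    """
    from itertools import combinations

    bodies = sorted({b for pair in unit_pairs for b in pair})
    for size in range(2, len(bodies) + 1):
        for subset in combinations(bodies, size):
            s = set(subset)
            inside = sum(1 for a, b in unit_pairs if a in s and b in s)
            if inside > K_DOF * size - L_TRIVIAL:
                return False
    return True


def brute_force_decomposition(network: ConstraintNetwork) -> RigidDecomposition:
    """Exponential-time reference decomposition for tiny networks (n <= 8).

    Rank is computed by greedy growth with full subset verification (valid
    because the sparsity counts form a matroid); two bodies share a
    cluster iff a trial bar between them is dependent on the basis.
    """
    n = network.n_bodies
    if n > BRUTE_FORCE_MAX_BODIES:
        raise ValueError(f"brute force limited to {BRUTE_FORCE_MAX_BODIES} bodies")
    unit_bars: list[tuple[int, int]] = []
    for bar in network.bars:
        unit_bars.extend([(bar.a, bar.b)] * bar.multiplicity)

    basis: list[tuple[int, int]] = []
    for bar in unit_bars:
        candidate = basis + [bar]
        if _count_independent(candidate, n):
            basis = candidate
    rank = len(basis)
    dof = K_DOF * n - rank

    same = nx.Graph()
    same.add_nodes_from(range(n))
    for u in range(n):
        for v in range(u + 1, n):
            if not _count_independent(basis + [(u, v)], n):
                same.add_edge(u, v)
    clusters = [sorted(c) for c in nx.connected_components(same)]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    cluster_of = np.zeros(n, dtype=np.int64)
    for cid, members in enumerate(clusters, start=1):
        for m in members:
            cluster_of[m] = cid
    return RigidDecomposition(cluster_of, [len(c) for c in clusters], dof, rank)


# --------------------------------------------------------------------------
# network construction from a structure
# --------------------------------------------------------------------------

#: Side-chain bonds locked by resonance/planarity (unordered name pairs).
_LOCKED_SIDECHAIN: dict[str, frozenset[frozenset[str]]] = {
    "ARG": frozenset({frozenset(p) for p in
                      [("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")]}),
    "ASP": frozenset({frozenset(p) for p in [("CG", "OD1"), ("CG", "OD2")]}),
    "GLU": frozenset({frozenset(p) for p in [("CD", "OE1"), ("CD", "OE2")]}),
    "ASN": frozenset({frozenset(p) for p in [("CG", "OD1"), ("CG", "ND2")]}),
    "GLN": frozenset({frozenset(p) for p in [("CD", "OE1"), ("CD", "NE2")]}),
    "PHE": frozenset({frozenset(p) for p in
                      [("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
                       ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")]}),
    "TYR": frozenset({frozenset(p) for p in
                      [("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
                       ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")]}),
    "TRP": frozenset({frozenset(p) for p in
                      [("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
                       ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
                       ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"),
                       ("CZ2", "CE2")]}),
    "HIS": frozenset({frozenset(p) for p in
                      [("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
                       ("CD2", "NE2"), ("CE1", "NE2")]}),
    "PRO": frozenset({frozenset(p) for p in
                      [("N", "CA"), ("CA", "CB"), ("CB", "CG"),
                       ("CG", "CD"), ("CD", "N")]}),
}


def _bond_source(res_a: str, name_a: str, res_b: str, name_b: str,
                 same_residue: bool) -> str:
    if not same_residue:
        if {name_a, name_b} == {"C", "N"}:
            return SOURCE_COVALENT_LOCKED  # peptide bond (partial double)
        return SOURCE_COVALENT_ROTATABLE  # e.g. disulfide
    pair = frozenset((name_a, name_b))
    if pair in ({"C", "O"}, {"C", "OXT"}) or pair in (frozenset(("C", "O")), frozenset(("C", "OXT"))):
        return SOURCE_COVALENT_LOCKED  # carbonyl / carboxylate
    locked = _LOCKED_SIDECHAIN.get(res_a)
    if locked and pair in locked:
        return SOURCE_COVALENT_LOCKED
    return SOURCE_COVALENT_ROTATABLE


def build_network(
    structure: Structure,
    interactions: Sequence[Interaction],
    e_cut: float = 0.0,
    multiplicities: dict[str, int] | None = None,
    merge_terminal: bool = True,
) -> ConstraintNetwork:
    """Assemble the body-bar network for one structure.

    Bodies are heavy atoms (hydrogens merge into their parents, and with
    ``merge_terminal`` singly-bonded heavy atoms merge into their
    neighbour).  Hydrogen bonds and salt bridges enter iff their energy is
    <= ``e_cut``; hydrophobic tethers always enter.
    """
    mult = dict(DEFAULT_MULTIPLICITIES)
    if multiplicities:
        mult.update(multiplicities)

    atom_index: dict[tuple, int] = {}
    resname: dict[tuple, str] = {}
    order = []
    for chain, res, atom in structure.iter_atoms():
        if atom.element == "H" or atom.is_hetatm:
            continue
        key = atom_key(chain, res, atom)
        atom_index[key] = len(order)
        resname[key] = res.name
        order.append(key)
    if not order:
        raise ValueError("structure has no heavy atoms")

    bonds = covalent_bonds(structure)
    bond_idx = [(atom_index[a], atom_index[b], a, b) for a, b in bonds
                if a in atom_index and b in atom_index]
    degree = np.zeros(len(order), dtype=int)
    for ia, ib, _, _ in bond_idx:
        degree[ia] += 1
        degree[ib] += 1

    # terminal merge: an atom with a single covalent bond joins its neighbour
    merge_into = np.arange(len(order))
    if merge_terminal:
        for ia, ib, _, _ in bond_idx:
            if degree[ia] == 1 and degree[ib] > 1:
                merge_into[ia] = ib
            elif degree[ib] == 1 and degree[ia] > 1:
                merge_into[ib] = ia

    body_of = {}
    bodies: list[tuple] = []
    for i, key in enumerate(order):
        root = int(merge_into[i])
        if root == i:
            body_of[i] = len(bodies)
            bodies.append(key)
    for i in range(len(order)):
        root = int(merge_into[i])
        if root != i:
            body_of[i] = body_of[root]

    bars: list[Bar] = []
    for ia, ib, ka, kb in bond_idx:
        ba, bb = body_of[ia], body_of[ib]
        if ba == bb:
            continue
        source = _bond_source(resname[ka], ka[3], resname[kb], kb[3],
                              ka[:3] == kb[:3])
        bars.append(Bar(min(ba, bb), max(ba, bb), mult[source], source))

    unknown = [key for key in order
               if resname[key] not in _sidechain_known() and degree[atom_index[key]] == 0
               and len(order) > 1]
    if unknown:
        names = sorted({f"{k[0]}/{k[1]}{k[2]} {resname[k]}" for k in unknown})
        raise ValueError(f"cannot derive covalent topology for: {', '.join(names)}")

    for inter in interactions:
        if inter.kind in (KIND_HBOND, KIND_SALT):
            if inter.energy is None or inter.energy > e_cut:
                continue
        ia, ib = atom_index.get(inter.a), atom_index.get(inter.b)
        if ia is None or ib is None:
            continue
        ba, bb = body_of[ia], body_of[ib]
        if ba == bb:
            continue
        bars.append(Bar(min(ba, bb), max(ba, bb), mult[inter.kind],
                        inter.kind, inter.energy))

    body_residue: list[ResKey | None] = [key[:3] for key in bodies]
    ca_body: dict[ResKey, int] = {}
    backbone_bodies: dict[ResKey, list[int]] = {}
    for i, key in enumerate(order):
        rk = key[:3]
        if key[3] == "CA":
            ca_body[rk] = body_of[i]
        if key[3] in ("N", "CA", "C", "O"):
            backbone_bodies.setdefault(rk, []).append(body_of[i])
    return ConstraintNetwork(len(bodies), bars, body_residue, ca_body, backbone_bodies)


def _sidechain_known() -> set[str]:
    from .structio import _SIDECHAIN_BONDS

    return set(_SIDECHAIN_BONDS)


def residue_cluster_membership(
    decomposition: RigidDecomposition,
    network: ConstraintNetwork,
) -> dict[ResKey, int]:
    """Residue -> rigid cluster id, judged at the C-alpha body.

    Residues without a C-alpha fall back to the majority cluster of their
    backbone bodies.
    """
    import warnings

    out: dict[ResKey, int] = {}
    residues = {rk for rk in network.ca_body} | {rk for rk in network.backbone_bodies}
    for rk in sorted(residues):
        body = network.ca_body.get(rk)
        if body is not None:
            out[rk] = int(decomposition.cluster_of[body])
        else:
            members = network.backbone_bodies.get(rk, [])
            if not members:
                continue
            warnings.warn(f"residue {rk} lacks CA; using backbone majority")
            ids, counts = np.unique(
                [decomposition.cluster_of[b] for b in members], return_counts=True)
            out[rk] = int(ids[np.argmax(counts)])
    return out


def network_to_frame(network: ConstraintNetwork):
    """Edge-list export (bodyA, bodyB, bars, source, energy)."""
    import pandas as pd

    return pd.DataFrame(
        [{"bodyA": b.a, "bodyB": b.b, "bars": b.multiplicity,
          "source": b.source, "energy": b.energy} for b in network.bars],
        columns=["bodyA", "bodyB", "bars", "source", "energy"])


def random_body_bar_graph(n_bodies: int, n_bars: int, seed: int) -> ConstraintNetwork:
    """Uniform random multigraph with exactly ``n_bars`` unit bars.

    Bars are distributed uniformly over the 6-slot capacity of every body
    pair (at most 6 bars per pair, matching the (6,6) count); the result
    is a pure function of the arguments.
    """
    if n_bodies < 1:
        raise ValueError("n_bodies must be >= 1")
    n_pairs = n_bodies * (n_bodies - 1) // 2
    capacity = 6 * n_pairs
    if not 0 <= n_bars <= capacity:
        raise ValueError(f"n_bars must be in [0, {capacity}] for {n_bodies} bodies")
    rng = np.random.default_rng(seed)
    pairs = [(a, b) for a in range(n_bodies) for b in range(a + 1, n_bodies)]
    slots = np.repeat(np.arange(n_pairs), 6)
    chosen = rng.choice(slots, size=n_bars, replace=False) if n_bars else np.array([], dtype=int)
    counts = np.bincount(chosen, minlength=n_pairs)
    bars = [Bar(pairs[i][0], pairs[i][1], int(c), KIND_HBOND, energy=-1.0)
            for i, c in enumerate(counts) if c > 0]
    return ConstraintNetwork(n_bodies, bars)
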