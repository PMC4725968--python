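"""Protein structure container, PDB input/output, and per-residue annotations.

The in-memory model is deliberately small: chains hold residues, residues
hold atoms, and an optional stack of coordinate sets turns a single
:class:`Structure` into a conformational ensemble (one coordinate set per
PDB ``MODEL``).  Reading and writing go through :mod:`gemmi`, which also
supplies ``HELIX``/``SHEET`` records and ``REMARK 350`` assembly operators.

Distances are in Angstrom, B-factors in Angstrom^2, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

SSE_HELIX = "H"
SSE_STRAND = "E"
SSE_COIL = "C"

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

#: Dihedral windows of the fallback secondary-structure heuristic (degrees).
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -40.0)
STRAND_PSI_A = (60.0, 180.0)
STRAND_PSI_B = (-180.0, -170.0)
HELIX_MIN_RUN = 4
STRAND_MIN_RUN = 3


# --------------------------------------------------------------------------
# container types
# --------------------------------------------------------------------------

ResKey = tuple[str, int, str]  # (chain id, author seq number, insertion code)


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    name: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    sse: str = SSE_COIL

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_protein(self) -> bool:
        return self.atom("CA") is not None and not all(a.is_hetatm for a in self.atoms)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class SSEElement:
    """One secondary-structure element (a helix or strand) of a chain."""

    label: str
    kind: str  # "helix" | "strand"
    chain_id: str
    start: int
    end: int  # inclusive author numbering

    def contains(self, key: ResKey) -> bool:
        return key[0] == self.chain_id and self.start <= key[1] <= self.end


@dataclass
class AssemblyOp:
    """One REMARK 350 BIOMT operator: ``x' = R x + t`` applied to chains."""

    chain_ids: tuple[str, ...]
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)


@dataclass
class Structure:
    """Chains of residues plus an optional ensemble of coordinate sets.

    ``model_coords`` has shape ``(n_models, n_atoms, 3)`` in flat atom order
    (chain -> residue -> atom); the atoms' own ``coord`` attributes always
    mirror model 0.
    """

    chains: list[Chain] = field(default_factory=list)
    model_coords: np.ndarray | None = None
    elements: list[SSEElement] = field(default_factory=list)
    record_sse: list[tuple[str, str, int, int]] = field(default_factory=list)
    assembly_ops: list[AssemblyOp] = field(default_factory=list)
    name: str = ""

    # -- iteration -----------------------------------------------------
    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain, res, atom

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    @property
    def n_models(self) -> int:
        return 1 if self.model_coords is None else int(self.model_coords.shape[0])

    def coords(self) -> np.ndarray:
        return np.array([a.coord for _, _, a in self.iter_atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        atoms = [a for _, _, a in self.iter_atoms()]
        if xyz.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        for atom, row in zip(atoms, xyz):
            atom.coord = row.copy()

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}; available: {[c.id for c in self.chains]}")

    def residue(self, key: ResKey) -> Residue:
        chain = self.chain(key[0])
        for res in chain.residues:
            if res.seqnum == key[1] and res.icode == (key[2] or ""):
                return res
        raise KeyError(f"no residue {key} in chain {key[0]}")

    def copy(self) -> "Structure":
        new_chains = []
        for chain in self.chains:
            new_res = [
                Residue(r.name, r.seqnum, r.icode,
                        [replace(a, coord=a.coord.copy()) for a in r.atoms], r.sse)
                for r in chain.residues
            ]
            new_chains.append(Chain(chain.id, new_res))
        return Structure(
            chains=new_chains,
            model_coords=None if self.model_coords is None else self.model_coords.copy(),
            elements=list(self.elements),
            record_sse=list(self.record_sse),
            assembly_ops=list(self.assembly_ops),
            name=self.name,
        )

    def get_model(self, index: int) -> "Structure":
        """Single-model copy carrying the coordinates of ensemble member ``index``."""
        if index < 0 or index >= self.n_models:
            raise IndexError(f"model {index} out of range (n_models={self.n_models})")
        out = self.copy()
        out.model_coords = None
        if self.model_coords is not None:
            out.set_coords(self.model_coords[index])
        return out

    def ca_coords(self, chain_ids: Sequence[str] | None = None) -> np.ndarray:
        rows = []
        for chain, res in self.iter_residues():
            if chain_ids is not None and chain.id not in chain_ids:
                continue
            ca = res.atom("CA")
            if ca is not None:
                rows.append(ca.coord)
        return np.array(rows, dtype=float)


# --------------------------------------------------------------------------
# vector geometry
# --------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry: zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    u, w = _unit(a - b), _unit(c - b)
    return math.degrees(math.acos(np.clip(np.dot(u, w), -1.0, 1.0)))


def dihedral_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion angle of the a-b-c-d chain in degrees, in (-180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement: position D with |CD| = length, angle(B,C,D) = angle
    and torsion(A,B,C,D) = dihedral (both in degrees)."""
    ang, tor = math.radians(angle), math.radians(dihedral)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(tor),
        -length * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# --------------------------------------------------------------------------
# covalent topology
# --------------------------------------------------------------------------

#: Side-chain bonds of the 20 standard amino acids (backbone N-CA, CA-C,
#: C-O, C-OXT and CA-CB are implied and added for every residue type).
_SIDECHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "GLY": (),
    "ALA": (),
    "SER": (("CB", "OG"),),
    "CYS": (("CB", "SG"),),
    "THR": (("CB", "OG1"), ("CB", "CG2")),
    "VAL": (("CB", "CG1"), ("CB", "CG2")),
    "LEU": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "ILE": (("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "MET": (("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PRO": (("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "PHE": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "TYR": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")),
    "TRP": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE3", "CZ3"),
            ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")),
    "ASP": (("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "GLU": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "ASN": (("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "GLN": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "LYS": (("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "ARG": (("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")),
    "HIS": (("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")),
}

_BACKBONE_BONDS = (("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT"), ("CA", "CB"))

#: Fallback distance cutoffs for atoms not covered by the templates.
HEAVY_BOND_CUTOFF = 1.9
HYDROGEN_BOND_CUTOFF = 1.25


AtomKey = tuple[str, int, str, str]  # (chain, seqnum, icode, atom name)


def atom_key(chain: Chain, res: Residue, atom: Atom) -> AtomKey:
    return (chain.id, res.seqnum, res.icode, atom.name)


def covalent_bonds(structure: Structure) -> list[tuple[AtomKey, AtomKey]]:
    """Covalent bonds between heavy atoms (hydrogens excluded).

    Bonds come from amino-acid templates plus the inter-residue peptide
    bond; atoms with no template match fall back to a distance criterion
    (<= 1.9 A).  Disulfides (SG-SG <= 2.5 A) are included.
    """
    bonds: list[tuple[AtomKey, AtomKey]] = []
    bonded: set[frozenset[AtomKey]] = set()

    def add(ka: AtomKey, kb: AtomKey) -> None:
        pair = frozenset((ka, kb))
        if ka != kb and pair not in bonded:
            bonded.add(pair)
            bonds.append((ka, kb))

    matched: set[AtomKey] = set()
    sg_atoms: list[tuple[AtomKey, np.ndarray]] = []
    for chain in structure.chains:
        prev: tuple[Residue, Atom] | None = None
        for res in chain.residues:
            template = _SIDECHAIN_BONDS.get(res.name)
            pairs = _BACKBONE_BONDS + (template or ())
            atoms = {a.name: a for a in res.atoms if a.element != "H"}
            if template is not None:
                for n1, n2 in pairs:
                    if n1 in atoms and n2 in atoms:
                        add((chain.id, res.seqnum, res.icode, n1),
                            (chain.id, res.seqnum, res.icode, n2))
                        matched.add((chain.id, res.seqnum, res.icode, n1))
                        matched.add((chain.id, res.seqnum, res.icode, n2))
            sg = atoms.get("SG")
            if sg is not None:
                sg_atoms.append(((chain.id, res.seqnum, res.icode, "SG"), sg.coord))
            # peptide bond to the previous residue of the chain
            n = res.atom("N")
            if prev is not None and n is not None:
                prev_res, prev_c = prev
                if np.linalg.norm(prev_c.coord - n.coord) <= 2.0:
                    add((chain.id, prev_res.seqnum, prev_res.icode, "C"),
                        (chain.id, res.seqnum, res.icode, "N"))
            c = res.atom("C")
            prev = (res, c) if c is not None else None

    # distance fallback for heavy atoms the templates did not cover
    keys, coords = [], []
    for chain, res, atom in structure.iter_atoms():
        if atom.element != "H":
            keys.append(atom_key(chain, res, atom))
            coords.append(atom.coord)
    unmatched_idx = [i for i, k in enumerate(keys) if k not in matched]
    if unmatched_idx and len(keys) > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(np.asarray(coords))
        for i in unmatched_idx:
            for j in tree.query_ball_point(coords[i], HEAVY_BOND_CUTOFF):
                if j != i:
                    add(keys[i], keys[j])

    for i in range(len(sg_atoms)):
        for j in range(i + 1, len(sg_atoms)):
            if np.linalg.norm(sg_atoms[i][1] - sg_atoms[j][1]) <= 2.5:
                add(sg_atoms[i][0], sg_atoms[j][0])
    return bonds


def hydrogen_parents(structure: Structure) -> dict[AtomKey, AtomKey]:
    """Map each hydrogen to the closest heavy atom of the same residue."""
    parents: dict[AtomKey, AtomKey] = {}
    for chain, res in structure.iter_residues():
        heavies = [a for a in res.atoms if a.element != "H"]
        for atom in res.atoms:
            if atom.element != "H" or not heavies:
                continue
            best = min(heavies, key=lambda h: np.linalg.norm(h.coord - atom.coord))
            if np.linalg.norm(best.coord - atom.coord) <= HYDROGEN_BOND_CUTOFF:
                parents[atom_key(chain, res, atom)] = atom_key(chain, res, best)
    return parents


# --------------------------------------------------------------------------
# PDB input / output (via gemmi)
# --------------------------------------------------------------------------

def _element_of(atom: gemmi.Atom) -> str:
    name = atom.element.name.upper()
    return "H" if name in ("H", "D") else name


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken alphabetically by altloc id).  HETATM records are kept but
    flagged; hydrogens are kept if present.  Multiple ``MODEL`` blocks
    become the ensemble coordinate stack; every model must list the same
    atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no coordinate models found")

    def convert_model(model: gemmi.Model) -> list[Chain]:
        chains = []
        for gch in model:
            chain = Chain(gch.name)
            for gres in gch:
                res = Residue(gres.name, gres.seqid.num, gres.seqid.icode.strip())
                chosen: dict[str, gemmi.Atom] = {}
                for ga in gres:
                    cur = chosen.get(ga.name)
                    if cur is None:
                        chosen[ga.name] = ga
                    elif (ga.occ, -ord(ga.altloc or "~")) > (cur.occ, -ord(cur.altloc or "~")):
                        chosen[ga.name] = ga
                for ga in chosen.values():
                    res.atoms.append(Atom(
                        name=ga.name, element=_element_of(ga),
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        b_factor=ga.b_iso, occupancy=ga.occ,
                        is_hetatm=gres.het_flag == "H",
                    ))
                if res.atoms:
                    chain.residues.append(res)
            if chain.residues:
                chain.residues.sort(key=lambda r: (r.seqnum, r.icode))
                chains.append(chain)
        return chains

    structure = Structure(chains=convert_model(st[0]), name=st.name.lower())
    n_protein = sum(1 for _, r in structure.iter_residues() if r.is_protein)
    if n_protein == 0:
        raise ValueError(f"{path}: no protein atoms")

    if len(st) > 1:
        ident = [(c.id, r.seqnum, r.icode, a.name)
                 for c, r, a in structure.iter_atoms()]
        stack = [structure.coords()]
        for model in list(st)[1:]:
            other = Structure(chains=convert_model(model))
            other_ident = [(c.id, r.seqnum, r.icode, a.name)
                           for c, r, a in other.iter_atoms()]
            if other_ident != ident:
                raise ValueError(f"{path}: MODEL blocks list different atoms")
            stack.append(other.coords())
        structure.model_coords = np.stack(stack)

    for h in st.helices:
        structure.record_sse.append(
            ("helix", h.start.chain_name, h.start.res_id.seqid.num, h.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            structure.record_sse.append(
                ("strand", strand.start.chain_name,
                 strand.start.res_id.seqid.num, strand.end.res_id.seqid.num))
    for asm in st.assemblies:
        for gen in asm.generators:
            chains = tuple(gen.chains) if gen.chains else tuple(c.id for c in structure.chains)
            for op in gen.operators:
                tr = op.transform
                rot = np.array(tr.mat.tolist(), dtype=float)
                trans = np.array([tr.vec.x, tr.vec.y, tr.vec.z])
                structure.assembly_ops.append(AssemblyOp(chains, rot, trans))
    return structure


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.name or "rigidnet"
    n_models = structure.n_models
    for k in range(n_models):
        model = gemmi.Model(str(k + 1))
        coords = (structure.coords() if structure.model_coords is None
                  else structure.model_coords[k])
        i = 0
        for chain in structure.chains:
            gch = gemmi.Chain(chain.id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
                gres.het_flag = "H" if all(a.is_hetatm for a in res.atoms) else "A"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*coords[i])
                    ga.occ = atom.occupancy
                    ga.b_iso = atom.b_factor
                    gres.add_atom(ga)
                    i += 1
                gch.add_residue(gres)
            model.add_chain(gch)
        st.add_model(model)
    for kind, chain_id, start, end in structure.record_sse:
        if kind == "helix":
            h = gemmi.Helix()
            h.start = gemmi.AtomAddress(chain_id, gemmi.SeqId(start, " "), "", "")
            h.end = gemmi.AtomAddress(chain_id, gemmi.SeqId(end, " "), "", "")
            h.length = end - start + 1
            st.helices.append(h)
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure (and its ensemble, if any) as a PDB file."""
    st = _to_gemmi(structure)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# assemblies and chain selection
# --------------------------------------------------------------------------

def select_assembly(structure: Structure, chain_ids: Sequence[str]) -> Structure:
    """Restrict a structure to the given chains (order preserved)."""
    available = [c.id for c in structure.chains]
    missing = [cid for cid in chain_ids if cid not in available]
    if missing:
        raise KeyError(f"chain(s) {missing} not present; available: {available}")
    out = structure.copy()
    keep = []
    index = 0
    atom_idx: list[int] = []
    for chain in out.chains:
        n = sum(len(r.atoms) for r in chain.residues)
        if chain.id in chain_ids:
            keep.append(chain)
            atom_idx.extend(range(index, index + n))
        index += n
    keep.sort(key=lambda c: list(chain_ids).index(c.id))
    out.chains = keep
    if out.model_coords is not None:
        out.model_coords = out.model_coords[:, atom_idx, :]
    out.elements = [e for e in out.elements if e.chain_id in chain_ids]
    out.record_sse = [r for r in out.record_sse if r[1] in chain_ids]
    return out


def apply_assembly(structure: Structure) -> Structure:
    """Expand the stored REMARK 350 operators into an explicit assembly.

    Identity operators keep the original chain ids; transformed copies get
    fresh single-character ids.  Without stored operators the structure is
    returned unchanged (the file already deposits the assembly).
    """
    if not structure.assembly_ops:
        return structure.copy()
    out = Structure(name=structure.name)
    used: set[str] = set()

    def fresh_id(preferred: str) -> str:
        if preferred not in used:
            return preferred
        for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789":
            if c not in used:
                return c
        raise ValueError("too many assembly chains")

    for op in structure.assembly_ops:
        identity = np.allclose(op.rotation, np.eye(3)) and np.allclose(op.translation, 0)
        for cid in op.chain_ids:
            src = structure.chain(cid)
            new_id = fresh_id(cid if identity else "?")
            used.add(new_id)
            chain = Chain(new_id)
            for res in src.residues:
                atoms = [replace(a, coord=op.rotation @ a.coord + op.translation)
                         for a in res.atoms]
                chain.residues.append(Residue(res.name, res.seqnum, res.icode, atoms, res.sse))
            out.chains.append(chain)
    return out


# --------------------------------------------------------------------------
# secondary structure
# --------------------------------------------------------------------------

def backbone_dihedrals(chain: Chain) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue; ``None`` where a neighbour or atom is missing."""
    out: list[tuple[float | None, float | None]] = []
    residues = chain.residues
    for i, res in enumerate(residues):
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = None
        if n is not None and ca is not None and c is not None:
            if i > 0:
                prev_c = residues[i - 1].atom("C")
                if prev_c is not None and np.linalg.norm(prev_c.coord - n.coord) <= 2.0:
                    phi = dihedral_deg(prev_c.coord, n.coord, ca.coord, c.coord)
            if i + 1 < len(residues):
                next_n = residues[i + 1].atom("N")
                if next_n is not None and np.linalg.norm(c.coord - next_n.coord) <= 2.0:
                    psi = dihedral_deg(n.coord, ca.coord, c.coord, next_n.coord)
        out.append((phi, psi))
    return out


def _in(x: float, window: tuple[float, float]) -> bool:
    return window[0] <= x <= window[1]


def assign_secondary_structure(structure: Structure) -> Structure:
    """Annotate residues H/E/C and group runs into labelled elements.

    HELIX/SHEET records take precedence where present; all other residues
    are classified by a phi/psi window heuristic (helix runs >= 4, strand
    runs >= 3; a terminal residue with only one defined dihedral counts if
    that dihedral is in the window).
    """
    out = structure.copy()
    for chain in out.chains:
        dihedrals = backbone_dihedrals(chain)
        labels = []
        for (phi, psi), res in zip(dihedrals, chain.residues):
            defined = [d for d in (phi, psi) if d is not None]
            if not defined or not res.is_protein:
                labels.append(SSE_COIL)
                continue
            helix_ok = ((phi is None or _in(phi, HELIX_PHI))
                        and (psi is None or _in(psi, HELIX_PSI)))
            strand_ok = ((phi is None or _in(phi, STRAND_PHI))
                         and (psi is None or _in(psi, STRAND_PSI_A) or _in(psi, STRAND_PSI_B)))
            labels.append(SSE_HELIX if helix_ok else SSE_STRAND if strand_ok else SSE_COIL)
        # enforce minimum run lengths
        final = list(labels)
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            run = j - i
            if labels[i] == SSE_HELIX and run < HELIX_MIN_RUN:
                final[i:j] = [SSE_COIL] * run
            if labels[i] == SSE_STRAND and run < STRAND_MIN_RUN:
                final[i:j] = [SSE_COIL] * run
            i = j
        for res, lab in zip(chain.residues, final):
            res.sse = lab
        # record precedence
        for kind, chain_id, start, end in out.record_sse:
            if chain_id != chain.id:
                continue
            lab = SSE_HELIX if kind == "helix" else SSE_STRAND
            for res in chain.residues:
                if start <= res.seqnum <= end:
                    res.sse = lab

    out.elements = []
    counters = {"helix": 0, "strand": 0}
    for chain in out.chains:
        i = 0
        residues = chain.residues
        while i < len(residues):
            lab = residues[i].sse
            j = i
            while j < len(residues) and residues[j].sse == lab:
                j += 1
            if lab in (SSE_HELIX, SSE_STRAND):
                kind = "helix" if lab == SSE_HELIX else "strand"
                counters[kind] += 1
                symbol = "α" if kind == "helix" else "β"
                out.elements.append(SSEElement(
                    label=f"{symbol}{counters[kind]}", kind=kind, chain_id=chain.id,
                    start=residues[i].seqnum, end=residues[j - 1].seqnum))
            i = j
    return out


# --------------------------------------------------------------------------
# B-factors
# --------------------------------------------------------------------------

def relative_bfactors(structure: Structure, scope: str = "backbone") -> pd.DataFrame:
    """Per-residue relative B-factors (z-scores), normalised per chain.

    ``z = (B - mean) / SD`` with the population SD taken over the selected
    atoms of each chain; the residue value is the mean of its atoms'
    z-scores.  Raises on all-equal B-factors (zero SD).
    """
    if scope not in ("backbone", "all"):
        raise ValueError("scope must be 'backbone' or 'all'")
    rows = []
    for chain in structure.chains:
        values, owners = [], []
        for res in chain.residues:
            if not res.is_protein:
                continue
            for atom in res.atoms:
                if atom.element == "H":
                    continue
                if scope == "backbone" and atom.name not in BACKBONE_ATOMS:
                    continue
                values.append(atom.b_factor)
                owners.append(res)
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        sd = arr.std()  # population SD
        if sd < 1e-12:
            raise ValueError(f"chain {chain.id}: all selected B-factors equal (zero SD)")
        z = (arr - arr.mean()) / sd
        per_res: dict[int, list[float]] = {}
        meta: dict[int, Residue] = {}
        for res, zi in zip(owners, z):
            per_res.setdefault(id(res), []).append(zi)
            meta[id(res)] = res
        for rid, zs in per_res.items():
            res = meta[rid]
            rows.append({"chain": chain.id, "resnum": res.seqnum, "icode": res.icode,
                         "resname": res.name, "z": float(np.mean(zs))})
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "resname", "z"])


def sse_bfactor_profile(structure: Structure, scope: str = "backbone") -> pd.DataFrame:
    """Mean relative B-factor per secondary-structure element."""
    table = relative_bfactors(structure, scope)
    rows = []
    for element in structure.elements:
        mask = (table["chain"] == element.chain_id) & \
               (table["resnum"] >= element.start) & (table["resnum"] <= element.end)
        sub = table[mask]
        if len(sub):
            rows.append({"label": element.label, "kind": element.kind,
                         "chain": element.chain_id, "z_mean": float(sub["z"].mean()),
                         "n_residues": int(len(sub))})
    return pd.DataFrame(rows, columns=["label", "kind", "chain", "z_mean", "n_residues"])


# --------------------------------------------------------------------------
# polar hydrogen placement
# --------------------------------------------------------------------------

N_H_LENGTH = 1.01
O_H_LENGTH = 0.96

#: Side-chain hydroxyl/thiol donors: residue -> (donor, antecedent, H name).
_HYDROXYL_DONORS = {
    "SER": ("OG", "CB", "HG"),
    "THR": ("OG1", "CB", "HG1"),
    "TYR": ("OH", "CZ", "HH"),
    "CYS": ("SG", "CB", "HG"),
}


def add_polar_hydrogens(structure: Structure, hydroxyl: bool = True) -> Structure:
    """Place missing polar hydrogens needed by the H-bond detector.

    Backbone amide H sits in the peptide plane bisecting C(i-1)-N-CA.
    Hydroxyl/thiol H (optional) is placed at the ideal X-O-H angle in a
    deterministic but rotamer-arbitrary orientation.  Existing hydrogens
    are never moved or duplicated.
    """
    out = structure.copy()
    for chain in out.chains:
        prev_c = None
        for res in chain.residues:
            n, ca = res.atom("N"), res.atom("CA")
            if (res.is_protein and res.name != "PRO" and prev_c is not None
                    and n is not None and ca is not None and res.atom("H") is None
                    and np.linalg.norm(prev_c.coord - n.coord) <= 2.0):
                direction = -_unit(_unit(prev_c.coord - n.coord) + _unit(ca.coord - n.coord))
                res.atoms.append(Atom("H", "H", n.coord + N_H_LENGTH * direction))
            if hydroxyl and res.name in _HYDROXYL_DONORS:
                donor_name, ante_name, h_name = _HYDROXYL_DONORS[res.name]
                donor, ante = res.atom(donor_name), res.atom(ante_name)
                if donor is not None and ante is not None and res.atom(h_name) is None:
                    axis = _unit(donor.coord - ante.coord)
                    ref = np.array([0.0, 0.0, 1.0])
                    if abs(np.dot(axis, ref)) > 0.95:
                        ref = np.array([1.0, 0.0, 0.0])
                    perp = _unit(np.cross(axis, ref))
                    ang = math.radians(108.5)
                    direction = math.cos(ang) * (-axis) + math.sin(ang) * perp
                    length = 1.34 if donor_name == "SG" else O_H_LENGTH
                    res.atoms.append(Atom(h_name, "H", donor.coord + length * _unit(direction)))
            c = res.atom("C")
            prev_c = c if c is not None else None
    return out
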