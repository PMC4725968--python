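"""Non-covalent interaction detection and scoring.

Three detectors cover the constraint classes of the rigidity model:

* hydrogen bonds, scored with a Mayo-style 12-10 potential modulated by an
  angular factor (only these and salt bridges carry an energy and take
  part in thermal dilution);
* salt bridges between charged side-chain groups (fixed strong energy so
  they persist to high simulated temperature);
* hydrophobic tethers between carbon/sulfur atom pairs within van der
  Waals contact.

Energies are kcal/mol (negative = attractive), distances Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import (
    AtomKey,
    Structure,
    atom_key,
    covalent_bonds,
    hydrogen_parents,
)

KIND_HBOND = "hbond"
KIND_SALT = "salt_bridge"
KIND_HYDROPHOBIC = "hydrophobic"


@dataclass(frozen=True)
class Interaction:
    """One non-covalent constraint between two heavy atoms.

    ``a``/``b`` are canonically ordered atom identifiers (for hydrogen
    bonds ``a`` is reordered like the rest, the donor/acceptor roles are in
    ``donor``/``acceptor``).  ``energy`` is ``None`` for hydrophobic
    tethers, which the dilution never removes.
    """

    kind: str
    a: AtomKey
    b: AtomKey
    distance: float
    energy: float | None
    interchain: bool
    donor: AtomKey | None = None
    acceptor: AtomKey | None = None

    @property
    def residue_pair(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        ra, rb = self.a[:3], self.b[:3]
        return (ra, rb) if ra <= rb else (rb, ra)


@dataclass
class HBondParams:
    """Parameters of the 12-10 hydrogen-bond potential.

    ``E(d) = v0 * (5 (d0/d)^12 - 6 (d0/d)^10) * F`` with donor-acceptor
    distance ``d`` and angular factor ``F = cos^2(theta_dev)`` where
    ``theta_dev`` is the deviation of the D-H...A angle from linearity.
    An optional acceptor-angle term (sp2: ideal 120 deg, sp3: 109.5 deg)
    multiplies in; the default is hybridisation-agnostic (no acceptor
    term).  Candidates weaker than ``energy_cutoff`` are not bonds.
    """

    v0: float = 8.0           # well depth, kcal/mol
    d0: float = 2.8           # equilibrium donor-acceptor distance, A
    cutoff_da: float = 3.6    # donor-acceptor distance cutoff, A
    min_dha_deg: float = 100.0
    energy_cutoff: float = -0.1
    acceptor_term: str = "none"  # "none" | "sp2" | "sp3"
    salt_energy: float = -10.0   # fixed energy assigned to salt bridges
    pairing: str = "unique"      # "unique" | "all"

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.d0 <= 0 or self.cutoff_da <= 0:
            raise ValueError("v0, d0 and cutoff_da must be positive")
        if self.acceptor_term not in ("none", "sp2", "sp3"):
            raise ValueError("acceptor_term must be 'none', 'sp2' or 'sp3'")
        if self.pairing not in ("unique", "all"):
            raise ValueError("pairing must be 'unique' or 'all'")


def _radial(d: float, params: HBondParams) -> float:
    r = params.d0 / d
    return params.v0 * (5.0 * r**12 - 6.0 * r**10)


def hbond_energy(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    antecedent: np.ndarray | None = None,
    params: HBondParams | None = None,
) -> float:
    """Energy (kcal/mol) of one donor-H...acceptor geometry.

    Minimised at d = d0 with value -v0 for ideal (linear) geometry; the
    caller applies distance/angle/energy acceptance cutoffs.
    """
    params = params or HBondParams()
    d = float(np.linalg.norm(acceptor - donor))
    if d < 1e-6 or np.linalg.norm(hydrogen - donor) < 1e-6 \
            or np.linalg.norm(acceptor - hydrogen) < 1e-6:
        raise ValueError("degenerate hydrogen-bond geometry (coincident atoms)")
    hd = donor - hydrogen
    ha = acceptor - hydrogen
    cos_dha = float(np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha)))
    theta = math.degrees(math.acos(max(-1.0, min(1.0, cos_dha))))
    deviation = math.radians(180.0 - theta)
    factor = math.cos(deviation) ** 2 if deviation < math.pi / 2 else 0.0
    if params.acceptor_term != "none" and antecedent is not None:
        ideal = 120.0 if params.acceptor_term == "sp2" else 109.5
        va = hydrogen - acceptor
        vb = antecedent - acceptor
        cos_acc = float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))
        phi = math.degrees(math.acos(max(-1.0, min(1.0, cos_acc))))
        factor *= math.cos(math.radians(phi - ideal)) ** 2
    return _radial(d, params) * factor


def dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    hd, ha = donor - hydrogen, acceptor - hydrogen
    cos_t = float(np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_t))))


# --------------------------------------------------------------------------
# hydrogen-bond detection
# --------------------------------------------------------------------------

_POLAR_ELEMENTS = ("N", "O", "S")


def _canonical(kind: str, a: AtomKey, b: AtomKey, distance: float,
               energy: float | None, interchain: bool,
               donor: AtomKey | None = None, acceptor: AtomKey | None = None) -> Interaction:
    if b < a:
        a, b = b, a
    return Interaction(kind, a, b, distance, energy, interchain, donor, acceptor)


def detect_hbonds(
    structure: Structure,
    params: HBondParams | None = None,
    include_hetatm: bool = False,
) -> list[Interaction]:
    """All hydrogen bonds passing distance, angle and energy cutoffs.

    Donors are N/O/S heavy atoms with an attached hydrogen, acceptors any
    N/O/S atom.  Pairs within the same residue or within two covalent
    bonds of each other are excluded.  The default ``pairing="unique"``
    performs greedy strongest-first matching in which each donor hydrogen
    donates at most one bond and each acceptor atom accepts at most one:
    bifurcated side geometries (e.g. the weak i->i+3 flank of a helical
    i->i+4 bond) then do not double-count as constraints.  ``pairing="all"``
    keeps every geometry passing the cutoffs (deduplicated per atom pair).
    The list is sorted by energy ascending (strongest first).
    """
    params = params or HBondParams()
    atoms: dict[AtomKey, np.ndarray] = {}
    element: dict[AtomKey, str] = {}
    hetatm: dict[AtomKey, bool] = {}
    for chain, res, atom in structure.iter_atoms():
        key = atom_key(chain, res, atom)
        atoms[key] = atom.coord
        element[key] = atom.element
        hetatm[key] = atom.is_hetatm

    parents = hydrogen_parents(structure)
    donors: dict[AtomKey, list[AtomKey]] = {}
    for h_key, heavy_key in parents.items():
        if element[heavy_key] in _POLAR_ELEMENTS:
            donors.setdefault(heavy_key, []).append(h_key)

    neighbours: dict[AtomKey, set[AtomKey]] = {}
    for ka, kb in covalent_bonds(structure):
        neighbours.setdefault(ka, set()).add(kb)
        neighbours.setdefault(kb, set()).add(ka)

    def within_two_bonds(a: AtomKey, b: AtomKey) -> bool:
        na = neighbours.get(a, set())
        if b in na:
            return True
        return any(b in neighbours.get(m, set()) for m in na)

    acceptor_keys = [k for k, el in element.items()
                     if el in _POLAR_ELEMENTS and (include_hetatm or not hetatm[k])]
    if not acceptor_keys:
        return []
    acceptor_coords = np.array([atoms[k] for k in acceptor_keys])
    tree = cKDTree(acceptor_coords)

    candidates: list[tuple[float, AtomKey, Interaction]] = []
    for donor_key, h_keys in sorted(donors.items()):
        if not include_hetatm and hetatm[donor_key]:
            continue
        d_coord = atoms[donor_key]
        for j in tree.query_ball_point(d_coord, params.cutoff_da):
            acc_key = acceptor_keys[j]
            if acc_key == donor_key or acc_key[:3] == donor_key[:3]:
                continue
            if within_two_bonds(donor_key, acc_key):
                continue
            acc_coord = atoms[acc_key]
            ante_keys = [k for k in neighbours.get(acc_key, set()) if element[k] != "H"]
            ante = atoms[min(ante_keys)] if ante_keys else None
            for h_key in h_keys:
                h_coord = atoms[h_key]
                if dha_angle(d_coord, h_coord, acc_coord) < params.min_dha_deg:
                    continue
                energy = hbond_energy(d_coord, h_coord, acc_coord, ante, params)
                if energy > params.energy_cutoff:
                    continue
                inter = _canonical(
                    KIND_HBOND, donor_key, acc_key,
                    float(np.linalg.norm(acc_coord - d_coord)), energy,
                    donor_key[0] != acc_key[0], donor=donor_key, acceptor=acc_key)
                candidates.append((energy, h_key, inter))

    candidates.sort(key=lambda t: (t[0], t[2].a, t[2].b))
    found: dict[frozenset[AtomKey], Interaction] = {}
    if params.pairing == "unique":
        used_h: set[AtomKey] = set()
        used_acceptor: set[AtomKey] = set()
        for energy, h_key, inter in candidates:
            if h_key in used_h or inter.acceptor in used_acceptor:
                continue
            used_h.add(h_key)
            used_acceptor.add(inter.acceptor)
            found[frozenset((inter.a, inter.b))] = inter
    else:
        for energy, h_key, inter in candidates:
            pair = frozenset((inter.a, inter.b))
            if pair not in found:
                found[pair] = inter
    return sorted(found.values(), key=lambda i: (i.energy, i.a, i.b))


# --------------------------------------------------------------------------
# salt bridges
# --------------------------------------------------------------------------

_BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def detect_salt_bridges(
    structure: Structure,
    cutoff: float = 4.0,
    params: HBondParams | None = None,
    include_termini: bool = True,
) -> list[Interaction]:
    """Charged-group contacts (N...O <= cutoff), one per residue pair.

    Basic groups: Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 and (optionally) the
    chain N-terminus; acidic: Asp OD1/OD2, Glu OE1/OE2 and the C-terminal
    carboxylate.  Each bridge is assigned the fixed energy
    ``params.salt_energy`` so it ranks among the strongest dilutable
    constraints; the closest atom pair is reported.
    """
    params = params or HBondParams()
    basic: list[tuple[AtomKey, np.ndarray]] = []
    acidic: list[tuple[AtomKey, np.ndarray]] = []
    for chain in structure.chains:
        protein = [r for r in chain.residues if r.is_protein]
        for res in protein:
            for name in _BASIC_ATOMS.get(res.name, ()):
                a = res.atom(name)
                if a is not None:
                    basic.append(((chain.id, res.seqnum, res.icode, name), a.coord))
            for name in _ACIDIC_ATOMS.get(res.name, ()):
                a = res.atom(name)
                if a is not None:
                    acidic.append(((chain.id, res.seqnum, res.icode, name), a.coord))
        if include_termini and protein:
            n_term = protein[0].atom("N")
            if n_term is not None:
                basic.append(((chain.id, protein[0].seqnum, protein[0].icode, "N"),
                              n_term.coord))
            for name in ("OXT", "O"):
                a = protein[-1].atom(name)
                if a is not None:
                    acidic.append(((chain.id, protein[-1].seqnum, protein[-1].icode, name),
                                   a.coord))
                    break

    best: dict[tuple, tuple[float, AtomKey, AtomKey]] = {}
    for bkey, bcoord in basic:
        for akey, acoord in acidic:
            if bkey[:3] == akey[:3]:
                continue
            d = float(np.linalg.norm(bcoord - acoord))
            if d <= cutoff:
                rp = tuple(sorted((bkey[:3], akey[:3])))
                if rp not in best or d < best[rp][0]:
                    best[rp] = (d, bkey, akey)
    out = [
        _canonical(KIND_SALT, bkey, akey, d, params.salt_energy, bkey[0] != akey[0])
        for d, bkey, akey in best.values()
    ]
    return sorted(out, key=lambda i: (i.distance, i.a, i.b))


# --------------------------------------------------------------------------
# hydrophobic tethers
# --------------------------------------------------------------------------

VDW_RADII = {"C": 1.7, "S": 1.8}


def detect_hydrophobic(structure: Structure, pad: float = 0.25) -> list[Interaction]:
    """Carbon/sulfur contact tethers, at most one per residue pair.

    Two C/S atoms of different, non-adjacent residues are tethered when
    their distance is within the sum of van der Waals radii plus ``pad``.
    Tethers carry no energy: the dilution never removes them.
    """
    keys, coords, radii = [], [], []
    for chain, res, atom in structure.iter_atoms():
        if atom.element in VDW_RADII and not atom.is_hetatm:
            keys.append(atom_key(chain, res, atom))
            coords.append(atom.coord)
            radii.append(VDW_RADII[atom.element])
    if len(keys) < 2:
        return []
    coords_arr = np.asarray(coords)
    tree = cKDTree(coords_arr)
    max_cut = 2 * max(VDW_RADII.values()) + pad
    best: dict[tuple, tuple[float, AtomKey, AtomKey]] = {}
    for i, j in tree.query_pairs(max_cut):
        ka, kb = keys[i], keys[j]
        if ka[:3] == kb[:3]:
            continue
        if ka[0] == kb[0] and abs(ka[1] - kb[1]) == 1 and ka[2] == kb[2] == "":
            continue  # covalently adjacent residues
        d = float(np.linalg.norm(coords_arr[i] - coords_arr[j]))
        if d <= radii[i] + radii[j] + pad:
            rp = tuple(sorted((ka[:3], kb[:3])))
            if rp not in best or d < best[rp][0]:
                best[rp] = (d, ka, kb)
    out = [_canonical(KIND_HYDROPHOBIC, ka, kb, d, None, ka[0] != kb[0])
           for d, ka, kb in best.values()]
    return sorted(out, key=lambda i: (i.distance, i.a, i.b))


def detect_all(structure: Structure, params: HBondParams | None = None,
               salt_cutoff: float = 4.0, pad: float = 0.25) -> list[Interaction]:
    """Hydrogen bonds + salt bridges + hydrophobic tethers in one list."""
    params = params or HBondParams()
    return (detect_hbonds(structure, params)
            + detect_salt_bridges(structure, salt_cutoff, params)
            + detect_hydrophobic(structure, pad))


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def interaction_summary(interactions: Sequence[Interaction],
                        strength_percentile: float = 1.0) -> pd.DataFrame:
    """Counts per kind, total and interchain, for all interactions and for
    the strongest ``strength_percentile`` fraction by energy.

    The percentile filter applies only to energy-bearing kinds (hydrogen
    bonds, salt bridges); hydrophobic tethers have no energy and keep
    their full count in the strongest-subset columns.
    """
    if not 0.0 < strength_percentile <= 1.0:
        raise ValueError("strength_percentile must be in (0, 1]")
    kinds = (KIND_HBOND, KIND_SALT, KIND_HYDROPHOBIC)
    rows = []
    for kind in kinds:
        sub = [i for i in interactions if i.kind == kind]
        if kind == KIND_HYDROPHOBIC:
            strongest = sub
        else:
            ordered = sorted(sub, key=lambda i: i.energy)
            k = int(math.floor(strength_percentile * len(ordered) + 1e-9))
            strongest = ordered[:k]
        rows.append({
            "kind": kind,
            "count": len(sub),
            "interchain": sum(i.interchain for i in sub),
            "strongest_count": len(strongest),
            "strongest_interchain": sum(i.interchain for i in strongest),
        })
    return pd.DataFrame(rows)


def _occupancy_key(i: Interaction) -> tuple:
    return (i.kind, i.a, i.b)


def ensemble_interaction_summary(
    per_model: Sequence[Sequence[Interaction]],
    max_occupancy: float | None = None,
) -> pd.DataFrame:
    """Occupancy table over an ensemble: one row per distinct interaction.

    ``occupancy`` is the fraction of models containing the interaction
    (matched by kind and atom pair).  ``max_occupancy`` keeps only the
    least frequent interactions (occupancy <= threshold).
    """
    n_models = len(per_model)
    if n_models == 0:
        return pd.DataFrame(columns=["kind", "a", "b", "occupancy", "mean_energy"])
    counts: dict[tuple, int] = {}
    energies: dict[tuple, list[float]] = {}
    for model in per_model:
        seen = set()
        for inter in model:
            key = _occupancy_key(inter)
            if key in seen:
                continue
            seen.add(key)
            counts[key] = counts.get(key, 0) + 1
            if inter.energy is not None:
                energies.setdefault(key, []).append(inter.energy)
    rows = []
    for key, count in sorted(counts.items()):
        occ = count / n_models
        if max_occupancy is not None and occ > max_occupancy:
            continue
        es = energies.get(key)
        rows.append({"kind": key[0], "a": key[1], "b": key[2], "occupancy": occ,
                     "mean_energy": float(np.mean(es)) if es else np.nan})
    return pd.DataFrame(rows, columns=["kind", "a", "b", "occupancy", "mean_energy"])


def interactions_to_frame(interactions: Iterable[Interaction]) -> pd.DataFrame:
    """Flat export table (one row per interaction)."""
    rows = []
    for i in interactions:
        rows.append({
            "kind": i.kind,
            "chainA": i.a[0], "resA": i.a[1], "atomA": i.a[3],
            "chainB": i.b[0], "resB": i.b[1], "atomB": i.b[3],
            "distance": round(i.distance, 3),
            "energy": None if i.energy is None else round(i.energy, 4),
            "interchain": i.interchain,
        })
    return pd.DataFrame(rows, columns=["kind", "chainA", "resA", "atomA",
                                       "chainB", "resB", "atomB",
                                       "distance", "energy", "interchain"])
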