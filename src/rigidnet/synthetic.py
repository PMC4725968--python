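"""Synthetic test structures and networks with known ground truth.

Everything downstream of the detectors is validated against inputs whose
answer is known by construction: ideal poly-alanine helices with an exact
count of backbone hydrogen bonds, two-chain "toy dimers" with planted
interface interactions at prescribed energies and planted C-beta pair
distances, coordinate-perturbed ensembles, random body-bar multigraphs
for the pebble-game oracle, and two-block networks whose unfolding
transition temperature is known exactly.

All generators are pure functions of their arguments (seeded randomness
only), so fixtures are bitwise reproducible.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .interactions import KIND_HBOND, KIND_HYDROPHOBIC, KIND_SALT, HBondParams
from .rigidity import Bar, ConstraintNetwork
from .rigidity import random_body_bar_graph  # re-exported: it is a generator
from .structio import (
    SSE_HELIX,
    Atom,
    Chain,
    Residue,
    SSEElement,
    Structure,
    add_polar_hydrogens,
    place_atom,
)

__all__ = [
    "make_helix",
    "make_toy_dimer",
    "make_ensemble",
    "random_body_bar_graph",
    "two_block_network",
    "two_block_ensemble",
    "ca_distance",
]

# ideal backbone geometry (lengths in A, angles in degrees)
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
CA_CB = 1.53
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA = 180.0


def _helix_backbone(n_residues: int) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helical backbone (N, CA, C, O per residue) via NeRF."""
    res: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([N_CA, 0.0, 0.0])
    c = place_atom(np.array([0.0, -1.0, 0.0]), n, ca, CA_C, ANGLE_N_CA_C, 120.0)
    res.append({"N": n, "CA": ca, "C": c})
    for _ in range(n_residues - 1):
        prev = res[-1]
        n_next = place_atom(prev["N"], prev["CA"], prev["C"], C_N, ANGLE_CA_C_N, HELIX_PSI)
        ca_next = place_atom(prev["CA"], prev["C"], n_next, N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = place_atom(prev["C"], n_next, ca_next, CA_C, ANGLE_N_CA_C, HELIX_PHI)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, r in enumerate(res):
        # carbonyl O anti to the next amide N (dihedral psi + 180)
        r["O"] = place_atom(r["N"], r["CA"], r["C"], C_O, ANGLE_CA_C_O, HELIX_PSI + 180.0)
        if i == n_residues - 1:
            r["OXT"] = place_atom(r["N"], r["CA"], r["C"], C_O, ANGLE_CA_C_O, HELIX_PSI)
    return res


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral C-beta from the backbone frame."""
    return place_atom(n, c, ca, CA_CB, 110.5, 123.0)


def _align_to_z(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/centroid putting the principal axis of ``coords`` on z."""
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(np.dot(axis, z))
    if s < 1e-9:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return rot, centroid


def make_helix(n_residues: int, seed: int = 0, chain_id: str = "A",
               start_seqnum: int = 1, with_hydrogens: bool = True) -> Structure:
    """Ideal poly-alanine alpha-helix (phi=-57, psi=-47, omega=180).

    By construction the backbone forms exactly ``n_residues - 4``
    i -> i+4 hydrogen bonds, which the detector recovers.  The helix is
    centred at the origin with its axis along z.  ``seed`` is accepted for
    interface uniformity; the construction is deterministic.
    """
    del seed  # deterministic by construction
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5 (no i -> i+4 contact otherwise)")
    backbone = _helix_backbone(n_residues)
    chain = Chain(chain_id)
    for i, atoms in enumerate(backbone):
        res = Residue("ALA", start_seqnum + i, "", sse=SSE_HELIX)
        order = ["N", "CA", "C", "O"] + (["OXT"] if "OXT" in atoms else [])
        for name in order:
            res.atoms.append(Atom(name, name[0], atoms[name]))
        res.atoms.append(Atom("CB", "C", _ideal_cb(atoms["N"], atoms["CA"], atoms["C"])))
        chain.residues.append(res)
    structure = Structure(chains=[chain], name=f"helix{n_residues}")
    ca = structure.ca_coords()
    rot, centroid = _align_to_z(ca)
    structure.set_coords((structure.coords() - centroid) @ rot.T)
    end = start_seqnum + n_residues - 1
    structure.record_sse.append(("helix", chain_id, start_seqnum, end))
    structure.elements.append(SSEElement("α1", "helix", chain_id, start_seqnum, end))
    if with_hydrogens:
        structure = add_polar_hydrogens(structure, hydroxyl=False)
    return structure


# --------------------------------------------------------------------------
# toy dimers with planted interactions
# --------------------------------------------------------------------------

def ca_distance(structure: Structure, res_a: tuple[str, int], res_b: tuple[str, int]) -> float:
    """C-alpha distance between two residues given as (chain, seqnum)."""
    a = structure.residue((res_a[0], res_a[1], "")).atom("CA")
    b = structure.residue((res_b[0], res_b[1], "")).atom("CA")
    return float(np.linalg.norm(a.coord - b.coord))


def _perp(m_hat: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(m_hat, ref))) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(m_hat, ref)
    return p / np.linalg.norm(p)


def _solve_hbond_geometry(energy: float, params: HBondParams) -> tuple[float, float]:
    """Donor-acceptor distance and D-H...A angle realising ``energy``.

    Prefers ideal linear geometry with the distance carrying the energy;
    bonds weaker than the radial term at 3.0 A are realised by bending
    the donor angle instead.
    """
    if energy >= params.energy_cutoff or energy < -params.v0:
        raise ValueError(
            f"plantable H-bond energies lie in [{-params.v0}, {params.energy_cutoff})")

    def radial(d: float) -> float:
        r = params.d0 / d
        return params.v0 * (5.0 * r**12 - 6.0 * r**10)

    e_at_3 = radial(3.0)
    if energy <= e_at_3:
        d = brentq(lambda x: radial(x) - energy, params.d0, 3.0)
        return float(d), 180.0
    factor = energy / e_at_3  # in (0, 1)
    theta = 180.0 - math.degrees(math.acos(math.sqrt(factor)))
    if theta < params.min_dha_deg + 2.0:
        raise ValueError(f"energy {energy} needs a donor angle below the detection cutoff")
    return 3.0, float(theta)


def _donor_h_position(donor: np.ndarray, acceptor: np.ndarray,
                      theta_deg: float, p_hat: np.ndarray) -> np.ndarray:
    """Hydrogen on the donor such that the D-H...A angle equals theta."""
    m_hat = (acceptor - donor) / np.linalg.norm(acceptor - donor)
    if theta_deg >= 179.99:
        return donor + 1.01 * m_hat

    def angle_at_h(beta: float) -> float:
        h = donor + 1.01 * (math.cos(beta) * m_hat + math.sin(beta) * p_hat)
        hd, ha = donor - h, acceptor - h
        cos_t = float(np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha)))
        return math.degrees(math.acos(max(-1.0, min(1.0, cos_t))))

    beta = brentq(lambda b: angle_at_h(b) - theta_deg, 1e-6, math.radians(89.0))
    return donor + 1.01 * (math.cos(beta) * m_hat + math.sin(beta) * p_hat)


def _replace_atom(res: Residue, name: str, element: str, coord: np.ndarray) -> None:
    atom = res.atom(name)
    if atom is None:
        res.atoms.append(Atom(name, element, coord))
    else:
        atom.coord = np.asarray(coord, dtype=float)


def make_toy_dimer(
    n_residues: int = 12,
    seed: int = 0,
    axis_separation: float = 10.0,
    planted_interactions: Sequence[tuple[tuple[int, int], str, float]] = (),
    planted_cb_pairs: Sequence[tuple[tuple[int, int], float]] = (),
    c2_symmetric: bool = True,
    chain_ids: tuple[str, str] = ("A", "B"),
    start_seqnum: int = 1,
    params: HBondParams | None = None,
) -> Structure:
    """Two-helix dimer with planted interface features.

    Chain A is an ideal helix at x = -separation/2; chain B is its copy at
    +separation/2 (a 180-degree rotation about z when ``c2_symmetric``, so
    residue i of A faces residue i of B near the two-fold axis).

    ``planted_interactions`` is a list of ``((seq_a, seq_b), kind, energy)``
    with kind in {hbond, salt_bridge, hydrophobic}; ``planted_cb_pairs``
    is ``((seq_a, seq_b), distance)``.  Plants are realised by stub
    side-chain geometry solved exactly, so the corresponding detector or
    screen recovers them; a geometrically unreachable plant raises with a
    diagnostic.  Planted C-beta distances are exact to < 0.01 A.
    """
    del seed  # deterministic; accepted for interface uniformity
    params = params or HBondParams()
    base = make_helix(n_residues, chain_id=chain_ids[0],
                      start_seqnum=start_seqnum, with_hydrogens=False)
    shift = np.array([axis_separation / 2.0, 0.0, 0.0])
    chain_a = base.chains[0]
    for res in chain_a.residues:
        for atom in res.atoms:
            atom.coord = atom.coord - shift

    chain_b = Chain(chain_ids[1])
    flip = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z (the C2 axis)
    for res in chain_a.residues:
        atoms = []
        for a in res.atoms:
            coord = flip @ a.coord if c2_symmetric else a.coord + 2.0 * shift
            atoms.append(Atom(a.name, a.element, coord))
        chain_b.residues.append(Residue(res.name, res.seqnum, res.icode, atoms, res.sse))

    structure = Structure(chains=[chain_a, chain_b], name="toy_dimer")
    end = start_seqnum + n_residues - 1
    for cid in chain_ids:
        structure.record_sse.append(("helix", cid, start_seqnum, end))
    structure.elements = [
        SSEElement("α1", "helix", chain_ids[0], start_seqnum, end),
        SSEElement("α2", "helix", chain_ids[1], start_seqnum, end),
    ]

    used_sites: set[tuple[str, int]] = set()

    def claim(chain_id: str, seq: int, what: str) -> Residue:
        site = (chain_id, seq)
        if site in used_sites:
            raise ValueError(f"residue {site} used by more than one plant ({what})")
        used_sites.add(site)
        return structure.residue((chain_id, seq, ""))

    def anchors(seq_a: int, seq_b: int, what: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        ca_a = structure.residue((chain_ids[0], seq_a, "")).atom("CA").coord
        ca_b = structure.residue((chain_ids[1], seq_b, "")).atom("CA").coord
        w = ca_b - ca_a
        length = float(np.linalg.norm(w))
        if length < 1e-6:
            raise ValueError(f"{what}: coincident C-alpha anchors")
        return ca_a, ca_b, w / length, _perp(w / length)

    for (seq_a, seq_b), target in planted_cb_pairs:
        res_a = claim(chain_ids[0], seq_a, "cb pair")
        res_b = claim(chain_ids[1], seq_b, "cb pair")
        ca_a, ca_b, m_hat, p_hat = anchors(seq_a, seq_b, "cb pair")
        length = float(np.linalg.norm(ca_b - ca_a))
        a = (length - target) / 2.0
        if abs(a) > CA_CB:
            raise ValueError(
                f"unrealizable C-beta plant ({seq_a},{seq_b}): CA-CA distance "
                f"{length:.2f} A cannot host a {target:.2f} A C-beta pair "
                f"(needs CA-CA within {target - 2*CA_CB:.2f}..{target + 2*CA_CB:.2f} A)")
        b = math.sqrt(CA_CB**2 - a**2)
        _replace_atom(res_a, "CB", "C", ca_a + a * m_hat + b * p_hat)
        _replace_atom(res_b, "CB", "C", ca_b - a * m_hat + b * p_hat)

    for (seq_a, seq_b), kind, energy in planted_interactions:
        if kind == KIND_HBOND:
            res_a = claim(chain_ids[0], seq_a, "hbond")
            res_b = claim(chain_ids[1], seq_b, "hbond")
            ca_a, ca_b, m_hat, p_hat = anchors(seq_a, seq_b, "hbond")
            length = float(np.linalg.norm(ca_b - ca_a))
            d, theta = _solve_hbond_geometry(energy, params)
            reach = (length - d) / 2.0
            if not 1.8 <= reach <= 3.2:
                raise ValueError(
                    f"unrealizable H-bond plant ({seq_a},{seq_b}): CA-CA distance "
                    f"{length:.2f} A incompatible with donor-acceptor {d:.2f} A")
            res_a.name = res_b.name = "SER"
            og_a = ca_a + reach * m_hat
            og_b = ca_b - reach * m_hat
            _replace_atom(res_a, "CB", "C", ca_a + (reach - 1.43) * m_hat)
            _replace_atom(res_a, "OG", "O", og_a)
            _replace_atom(res_b, "CB", "C", ca_b - (reach - 1.43) * m_hat)
            _replace_atom(res_b, "OG", "O", og_b)
            _replace_atom(res_a, "HG", "H", _donor_h_position(og_a, og_b, theta, p_hat))
            # acceptor hydroxyl H deliberately omitted: the planted bond has
            # a unique donor side, so the detector sees exactly one geometry
        elif kind == KIND_SALT:
            res_a = claim(chain_ids[0], seq_a, "salt bridge")
            res_b = claim(chain_ids[1], seq_b, "salt bridge")
            ca_a, ca_b, m_hat, p_hat = anchors(seq_a, seq_b, "salt bridge")
            length = float(np.linalg.norm(ca_b - ca_a))
            target = 3.5  # N...O distance inside the default 4.0 A cutoff
            r_glu = 4.3
            r_lys = length - target - r_glu
            if not 3.0 <= r_lys <= 7.2:
                raise ValueError(
                    f"unrealizable salt-bridge plant ({seq_a},{seq_b}): CA-CA "
                    f"distance {length:.2f} A out of reach for Lys/Glu stubs")
            res_a.name = "LYS"
            spacing = (r_lys - CA_CB) / 4.0
            jog = 0.35 * p_hat
            for k, name in enumerate(["CB", "CG", "CD", "CE", "NZ"]):
                r = CA_CB + k * spacing
                offset = jog if k % 2 else -jog
                if name == "NZ":
                    offset = 0.0 * p_hat
                _replace_atom(res_a, name, "N" if name == "NZ" else "C",
                              ca_a + r * m_hat + offset)
            res_b.name = "GLU"
            spacing_b = (r_glu - 1.25 - CA_CB) / 2.0
            for k, name in enumerate(["CB", "CG", "CD"]):
                r = CA_CB + k * spacing_b
                offset = jog if k % 2 else -jog
                if name == "CD":
                    offset = 0.0 * p_hat
                _replace_atom(res_b, name, "C", ca_b - r * m_hat + offset)
            _replace_atom(res_b, "OE1", "O", ca_b - r_glu * m_hat)
            _replace_atom(res_b, "OE2", "O",
                          ca_b - (r_glu - 1.25) * m_hat + 1.1 * p_hat)
        elif kind == KIND_HYDROPHOBIC:
            res_a = claim(chain_ids[0], seq_a, "hydrophobic")
            res_b = claim(chain_ids[1], seq_b, "hydrophobic")
            ca_a, ca_b, m_hat, p_hat = anchors(seq_a, seq_b, "hydrophobic")
            length = float(np.linalg.norm(ca_b - ca_a))
            target = energy if energy and energy > 0 else 3.4  # contact distance
            a = (length - target) / 2.0
            if abs(a) > CA_CB:
                raise ValueError(
                    f"unrealizable hydrophobic plant ({seq_a},{seq_b}): "
                    f"CA-CA distance {length:.2f} A vs contact {target:.2f} A")
            b = math.sqrt(CA_CB**2 - a**2)
            _replace_atom(res_a, "CB", "C", ca_a + a * m_hat + b * p_hat)
            _replace_atom(res_b, "CB", "C", ca_b - a * m_hat + b * p_hat)
        else:
            raise ValueError(f"unknown planted interaction kind {kind!r}")

    return add_polar_hydrogens(structure, hydroxyl=False)


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------

def make_ensemble(base: Structure, n_models: int, noise_sd: float, seed: int) -> Structure:
    """Gaussian coordinate-perturbed ensemble of ``base``.

    Model k = base coordinates + i.i.d. isotropic Gaussian displacement
    with standard deviation ``noise_sd`` per coordinate; with zero noise
    every model equals the base.  Stands in for snapshots of a sampled
    trajectory.
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    coords = base.coords()
    stack = coords[None, :, :] + rng.normal(0.0, noise_sd, size=(n_models, *coords.shape))
    out = base.copy()
    out.model_coords = stack
    out.set_coords(stack[0])
    return out


# --------------------------------------------------------------------------
# two-block networks (known transition energy)
# --------------------------------------------------------------------------

def two_block_network(
    block_size: int = 5,
    bridge_energies: Sequence[float] = (-3.0, -3.0),
    decoy_energies: Sequence[float] = (-0.5, -1.5),
) -> ConstraintNetwork:
    """Two rigid blocks joined by dilutable hydrogen-bond bridges.

    Each block is a chain of 6-bar (locked) edges, hence internally rigid;
    ``bridge_energies`` gives one 5-bar bond per entry between distinct
    body pairs across the blocks.  With >= 2 bridges the whole network is
    one rigid cluster; once the bridges are diluted away it falls apart
    into the two blocks, so the transition happens exactly when the
    second-strongest bridge is removed (for equal energies: at that shared
    energy).  ``decoy_energies`` adds redundant intra-block bonds so the
    dilution has pre-transition states.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    if len(bridge_energies) < 1:
        raise ValueError("at least one bridge required")
    if len(bridge_energies) > block_size:
        raise ValueError("more bridges than distinct body pairs available")
    n = 2 * block_size
    bars: list[Bar] = []
    for base in (0, block_size):
        for i in range(block_size - 1):
            bars.append(Bar(base + i, base + i + 1, 6, "covalent_locked"))
    for i, e in enumerate(bridge_energies):
        bars.append(Bar(i, block_size + i, 5, KIND_HBOND, float(e)))
    for j, e in enumerate(decoy_energies):
        a = j % max(1, block_size - 2)
        bars.append(Bar(a, a + 2, 5, KIND_HBOND, float(e)) if block_size > 2
                    else Bar(0, 1, 5, KIND_HBOND, float(e)))
    return ConstraintNetwork(n, bars)


def two_block_ensemble(
    n_models: int = 50,
    mean_energy: float = -3.0,
    sd: float = 0.2,
    seed: int = 0,
    block_size: int = 5,
    n_bridges: int = 2,
    decoy_energies: Sequence[float] = (-0.5, -1.5),
) -> list[ConstraintNetwork]:
    """Ensemble of two-block networks with a Normal bridge-energy draw.

    Each model draws one bridge energy from Normal(mean, sd) shared by its
    ``n_bridges`` bridges, so the model's transition energy equals the
    draw and the ensemble-mean transition temperature is known.
    """
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean_energy, sd, size=n_models)
    draws = np.minimum(draws, -0.2)  # keep draws in the bonded regime
    return [
        two_block_network(block_size, tuple([float(e)] * n_bridges), decoy_energies)
        for e in draws
    ]
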