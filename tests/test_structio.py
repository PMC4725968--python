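"""Structure I/O, assemblies, secondary structure, B-factors."""

import numpy as np
import pandas as pd
import pytest

import rigidnet as rn
from rigidnet.structio import backbone_dihedrals

from conftest import transformed


def test_pdb_round_trip_coordinates(tmp_path, helix20):
    path = tmp_path / "helix.pdb"
    rn.write_pdb(helix20, path)
    back = rn.read_pdb(path)
    assert np.abs(back.coords() - helix20.coords()).max() < 1e-3  # PDB precision
    assert [c.id for c in back.chains] == ["A"]
    assert back.record_sse == [("helix", "A", 1, 20)]


def test_pdb_round_trip_ensemble(tmp_path, helix20):
    ens = rn.make_ensemble(helix20, 3, 0.2, seed=1)
    path = tmp_path / "ens.pdb"
    rn.write_pdb(ens, path)
    back = rn.read_pdb(path)
    assert back.n_models == 3
    assert np.abs(back.model_coords - ens.model_coords).max() < 1e-3
    idents = [(c.id, r.seqnum, a.name) for c, r, a in back.iter_atoms()]
    assert idents == [(c.id, r.seqnum, a.name) for c, r, a in ens.iter_atoms()]


def test_read_pdb_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        rn.read_pdb(tmp_path / "missing.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("")
    with pytest.raises(ValueError):
        rn.read_pdb(empty)


def test_read_pdb_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40 10.00           N",
        "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.60 10.00           N",
        "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C",
        "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00 10.00           C",
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    structure = rn.read_pdb(path)
    n = structure.chains[0].residues[0].atom("N")
    assert n.coord[0] == pytest.approx(9.0)  # the 0.60-occupancy conformer


def test_select_assembly(planted_dimer):
    mono = rn.select_assembly(planted_dimer, ["A"])
    assert [c.id for c in mono.chains] == ["A"]
    both = rn.select_assembly(planted_dimer, ["A", "B"])
    np.testing.assert_allclose(both.coords(), planted_dimer.coords())
    with pytest.raises(KeyError, match="available"):
        rn.select_assembly(planted_dimer, ["Z"])


def test_remark350_assembly_expansion(tmp_path, helix20):
    path = tmp_path / "asym.pdb"
    rn.write_pdb(helix20, path)
    text = path.read_text()
    remark = (
        "REMARK 350 BIOMOLECULE: 1\n"
        "REMARK 350 APPLY THE FOLLOWING TO CHAINS: A\n"
        "REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000\n"
        "REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000\n"
        "REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000\n"
        "REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000       20.00000\n"
        "REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000\n"
        "REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000\n"
    )
    path.write_text(remark + text)
    structure = rn.read_pdb(path)
    assert len(structure.assembly_ops) == 2
    dimer = rn.apply_assembly(structure)
    assert len(dimer.chains) == 2
    ca_a = dimer.chains[0].residues[0].atom("CA").coord
    ca_b = dimer.chains[1].residues[0].atom("CA").coord
    expected = np.array([-ca_a[0] + 20.0, -ca_a[1], ca_a[2]])
    np.testing.assert_allclose(ca_b, expected, atol=1e-3)


def test_sse_heuristic_labels_ideal_helix(helix20):
    bare = helix20.copy()
    bare.record_sse = []
    annotated = rn.assign_secondary_structure(bare)
    assert all(res.sse == "H" for _, res in annotated.iter_residues())
    assert len(annotated.elements) == 1
    element = annotated.elements[0]
    assert (element.start, element.end, element.kind) == (1, 20, "helix")


def test_sse_records_take_precedence(helix20):
    override = helix20.copy()
    override.record_sse = [("strand", "A", 3, 10)]
    annotated = rn.assign_secondary_structure(override)
    labels = {res.seqnum: res.sse for _, res in annotated.iter_residues()}
    assert all(labels[i] == "E" for i in range(3, 11))


def test_sse_rotation_invariance(helix20):
    bare = helix20.copy()
    bare.record_sse = []
    rotated = transformed(bare, seed=11)
    a = rn.assign_secondary_structure(bare)
    b = rn.assign_secondary_structure(rotated)
    assert [r.sse for _, r in a.iter_residues()] == [r.sse for _, r in b.iter_residues()]


def test_extended_chain_never_helix():
    from rigidnet.structio import Atom, Chain, Residue, Structure, place_atom

    # fully extended backbone: phi = psi = omega = 180
    residues = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = place_atom(np.array([0.0, -1.0, 0.0]), n, ca, 1.525, 111.2, 120.0)
    residues.append({"N": n, "CA": ca, "C": c})
    for _ in range(9):
        prev = residues[-1]
        n2 = place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, 180.0)
        ca2 = place_atom(prev["CA"], prev["C"], n2, 1.458, 121.7, 180.0)
        c2 = place_atom(prev["C"], n2, ca2, 1.525, 111.2, 180.0)
        residues.append({"N": n2, "CA": ca2, "C": c2})
    chain = Chain("A")
    for i, atoms in enumerate(residues):
        res = Residue("ALA", i + 1)
        for name in ("N", "CA", "C"):
            res.atoms.append(Atom(name, name[0], atoms[name]))
        chain.residues.append(res)
    annotated = rn.assign_secondary_structure(Structure(chains=[chain]))
    labels = [r.sse for _, r in annotated.iter_residues()]
    phi_psi = backbone_dihedrals(annotated.chains[0])
    assert phi_psi[5][0] == pytest.approx(180.0, abs=1e-6)
    assert "H" not in labels  # extended chain is strand or coil, never helix


def test_relative_bfactors_hand_computed():
    from rigidnet.structio import Atom, Chain, Residue, Structure

    # one backbone atom per residue, B-factors {10, 20, 30}:
    # population SD = 8.165, z = {-1.2247, 0, +1.2247}
    residues = []
    for i, b in enumerate((10.0, 20.0, 30.0), start=1):
        atom = Atom("CA", "C", np.array([float(i), 0.0, 0.0]), b_factor=b)
        residues.append(Residue("ALA", i, atoms=[atom]))
    structure = Structure(chains=[Chain("A", residues)])
    table = rn.relative_bfactors(structure, scope="backbone")
    z = dict(zip(table["resnum"], table["z"]))
    assert z[1] == pytest.approx(-1.2247, abs=1e-4)
    assert z[2] == pytest.approx(0.0, abs=1e-12)
    assert z[3] == pytest.approx(+1.2247, abs=1e-4)


def test_relative_bfactors_zero_sd_errors(helix20):
    flat = helix20.copy()
    for _, _, atom in flat.iter_atoms():
        atom.b_factor = 15.0
    with pytest.raises(ValueError, match="zero SD"):
        rn.relative_bfactors(flat)


def test_relative_bfactors_per_chain_normalisation(planted_dimer):
    rng = np.random.default_rng(0)
    structure = planted_dimer.copy()
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.b_factor = float(rng.uniform(5, 50))
    table = rn.relative_bfactors(structure, scope="all")
    assert set(table["chain"]) == {"A", "B"}
    # atom-level z-scores have per-chain mean 0 by construction; residue means stay small
    for cid in ("A", "B"):
        assert abs(table[table["chain"] == cid]["z"].mean()) < 0.5
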