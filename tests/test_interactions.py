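"""Interaction detectors: energy function, cutoffs, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rigidnet as rn
from rigidnet.interactions import (
    HBondParams,
    detect_hbonds,
    detect_hydrophobic,
    detect_salt_bridges,
    hbond_energy,
    interaction_summary,
    ensemble_interaction_summary,
)
from rigidnet.structio import Atom, Chain, Residue, Structure

from conftest import transformed


def _linear_geometry(d):
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.0, 0.0, 0.0])
    acceptor = np.array([d, 0.0, 0.0])
    return donor, hydrogen, acceptor


def test_hbond_energy_minimum_at_d0():
    donor, hydrogen, acceptor = _linear_geometry(2.8)
    assert hbond_energy(donor, hydrogen, acceptor) == pytest.approx(-8.0)


def test_hbond_energy_at_3p2_matches_direct_evaluation():
    donor, hydrogen, acceptor = _linear_geometry(3.2)
    expected = 8.0 * (5 * (2.8 / 3.2) ** 12 - 6 * (2.8 / 3.2) ** 10)
    energy = hbond_energy(donor, hydrogen, acceptor)
    assert energy == pytest.approx(expected)
    assert energy == pytest.approx(-4.57, abs=0.01)


def test_hbond_energy_angular_factor():
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.0, 0.0, 0.0])
    # D-H...A angle of 120 deg: deviation 60 deg, F = cos^2(60) = 1/4
    direction = np.array([math.cos(math.radians(60)), math.sin(math.radians(60)), 0.0])
    acceptor = hydrogen + 1.8 * direction
    d = np.linalg.norm(acceptor)
    radial = 8.0 * (5 * (2.8 / d) ** 12 - 6 * (2.8 / d) ** 10)
    assert hbond_energy(donor, hydrogen, acceptor) == pytest.approx(radial * 0.25)


def test_hbond_energy_degenerate_geometry_errors():
    p = np.zeros(3)
    with pytest.raises(ValueError):
        hbond_energy(p, p, np.array([2.8, 0, 0]))


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=2.81, max_value=5.0), st.floats(min_value=0.01, max_value=1.0))
def test_hbond_energy_monotone_beyond_d0(d, delta):
    donor, hydrogen, acceptor = _linear_geometry(d)
    e1 = hbond_energy(donor, hydrogen, acceptor)
    donor2, hydrogen2, acceptor2 = _linear_geometry(d + delta)
    e2 = hbond_energy(donor2, hydrogen2, acceptor2)
    assert e2 > e1  # strictly increasing toward zero
    assert e1 < 0 and e2 < 0


def test_detector_rejects_bent_donor_angle(helix20):
    strict = HBondParams(min_dha_deg=179.0)
    assert detect_hbonds(helix20, strict) == []


def test_helix_bonds_sorted_strongest_first(helix20):
    bonds = detect_hbonds(helix20)
    energies = [b.energy for b in bonds]
    assert energies == sorted(energies)


def test_hbond_detection_rotation_invariant(helix20):
    reference = {(b.a, b.b): b.energy for b in detect_hbonds(helix20)}
    rotated = transformed(helix20, seed=3)
    moved = {(b.a, b.b): b.energy for b in detect_hbonds(rotated)}
    assert reference.keys() == moved.keys()
    for key in reference:
        assert moved[key] == pytest.approx(reference[key], abs=1e-9)


def _two_residue_structure(res_a, atoms_a, res_b, atoms_b, chain_b="A"):
    ca_1 = Residue(res_a, 1, atoms=[Atom(n, e, c) for n, e, c in atoms_a])
    ca_2 = Residue(res_b, 10, atoms=[Atom(n, e, c) for n, e, c in atoms_b])
    if chain_b == "A":
        return Structure(chains=[Chain("A", [ca_1, ca_2])])
    return Structure(chains=[Chain("A", [ca_1]), Chain(chain_b, [ca_2])])


def _lys_glu(dist):
    lys = [("N", "N", [0, 5, 0]), ("CA", "C", [1.5, 5, 0]), ("C", "C", [2.5, 6, 0]),
           ("NZ", "N", [0.0, 0.0, 0.0])]
    glu = [("N", "N", [dist, 5, 3]), ("CA", "C", [dist + 1.5, 5, 3]),
           ("C", "C", [dist + 2.5, 6, 3]), ("OE1", "O", [dist, 0.0, 0.0])]
    return lys, glu


def test_salt_bridge_within_cutoff():
    lys, glu = _lys_glu(3.5)
    structure = _two_residue_structure("LYS", lys, "GLU", glu)
    bridges = detect_salt_bridges(structure, include_termini=False)
    assert len(bridges) == 1
    assert bridges[0].energy == pytest.approx(-10.0)
    assert bridges[0].distance == pytest.approx(3.5)


def test_salt_bridge_beyond_cutoff():
    lys, glu = _lys_glu(4.5)
    structure = _two_residue_structure("LYS", lys, "GLU", glu)
    assert detect_salt_bridges(structure, include_termini=False) == []


def test_salt_bridge_one_per_residue_pair():
    arg = [("N", "N", [0, 5, 0]), ("CA", "C", [1.5, 5, 0]), ("C", "C", [2.5, 6, 0]),
           ("NH1", "N", [0.0, 0.0, 0.0]), ("NH2", "N", [0.0, 2.0, 0.0])]
    asp = [("N", "N", [3.0, 5, 3]), ("CA", "C", [4.5, 5, 3]), ("C", "C", [5.5, 6, 3]),
           ("OD1", "O", [3.0, 0.0, 0.0]), ("OD2", "O", [3.0, 2.0, 0.0])]
    structure = _two_residue_structure("ARG", arg, "ASP", asp)
    bridges = detect_salt_bridges(structure, include_termini=False)
    assert len(bridges) == 1  # four atom pairs within cutoff, one interaction


@pytest.mark.parametrize("elements,dist,expected", [
    (("C", "C"), 3.5, 1),   # cutoff 1.7+1.7+0.25 = 3.65
    (("C", "C"), 3.8, 0),
    (("C", "S"), 3.7, 1),   # cutoff 1.7+1.8+0.25 = 3.75
])
def test_hydrophobic_cutoffs(elements, dist, expected):
    atoms_a = [("CA", "C", [0, 5, 0]), ("CB", elements[0], [0.0, 0.0, 0.0])]
    atoms_b = [("CA", "C", [dist, 5, 0]), ("CB", elements[1], [dist, 0.0, 0.0])]
    structure = _two_residue_structure("ALA", atoms_a, "ALA", atoms_b)
    assert len(detect_hydrophobic(structure)) == expected


def test_hydrophobic_excludes_adjacent_residues():
    atoms_a = [("CA", "C", [0, 5, 0]), ("CB", "C", [0.0, 0.0, 0.0])]
    atoms_b = [("CA", "C", [3.0, 5, 0]), ("CB", "C", [3.0, 0.0, 0.0])]
    r1 = Residue("ALA", 1, atoms=[Atom(n, e, c) for n, e, c in atoms_a])
    r2 = Residue("ALA", 2, atoms=[Atom(n, e, c) for n, e, c in atoms_b])
    structure = Structure(chains=[Chain("A", [r1, r2])])
    assert detect_hydrophobic(structure) == []


def test_summary_percentile_counts(helix20):
    bonds = detect_hbonds(helix20)
    # synthetic energies -1..-10 on ten bonds
    from dataclasses import replace

    ten = [replace(b, energy=-(i + 1.0)) for i, b in enumerate(bonds[:10])]
    table = interaction_summary(ten, strength_percentile=0.3)
    row = table[table["kind"] == "hbond"].iloc[0]
    assert row["count"] == 10
    assert row["strongest_count"] == 3
    full = interaction_summary(ten, strength_percentile=1.0)
    assert full[full["kind"] == "hbond"].iloc[0]["strongest_count"] == 10


def test_summary_on_helix(helix20):
    table = interaction_summary(rn.detect_all(helix20))
    by_kind = table.set_index("kind")
    assert by_kind.loc["hbond", "count"] == 16
    assert by_kind.loc["salt_bridge", "count"] == 0
    assert by_kind.loc["hydrophobic", "count"] >= 0


def test_summary_rejects_bad_percentile():
    with pytest.raises(ValueError):
        interaction_summary([], strength_percentile=0.0)


def test_ensemble_occupancy_filter(helix20):
    ens = rn.make_ensemble(helix20, 4, 0.15, seed=2)
    per_model = [detect_hbonds(ens.get_model(k)) for k in range(4)]
    table = ensemble_interaction_summary(per_model)
    assert (table["occupancy"] > 0).all() and (table["occupancy"] <= 1).all()
    rare = ensemble_interaction_summary(per_model, max_occupancy=0.5)
    assert (rare["occupancy"] <= 0.5).all()
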