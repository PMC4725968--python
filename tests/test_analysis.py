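"""Interface/element aggregation, ensemble T_p, regression, diagnostics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import rigidnet as rn
from rigidnet.analysis import superpose
from rigidnet.structio import SSEElement
from rigidnet.unfolding import StabilityMap


def _map_from(pairs):
    smap = StabilityMap()
    for (a, b), e in pairs.items():
        smap.e_rc[StabilityMap._key(a, b)] = e
    return smap


# ---------------------------------------------------------------- interface

def test_interface_pairs_requires_two_chains(helix20):
    with pytest.raises(ValueError):
        rn.interface_pairs(helix20)


def test_interface_pairs_cutoff_zero(planted_dimer):
    assert rn.interface_pairs(planted_dimer, cutoff=0.0) == []


def test_interface_pairs_contains_planted_contacts(planted_dimer):
    pairs = rn.interface_pairs(planted_dimer)
    assert (("A", 5, ""), ("B", 5, "")) in pairs
    assert (("A", 12, ""), ("B", 12, "")) in pairs


def test_interface_energy_arithmetic():
    smap = _map_from({(("A", 1, ""), ("B", 1, "")): -3.0,
                      (("A", 2, ""), ("B", 2, "")): -1.0})
    pairs = [(("A", 1, ""), ("B", 1, "")), (("A", 2, ""), ("B", 2, "")),
             (("A", 9, ""), ("B", 9, ""))]  # absent pair contributes 0
    assert rn.interface_rigidity_energy(smap, pairs) == pytest.approx(-4.0)
    assert rn.interface_rigidity_energy(smap, []) == 0.0


def test_interface_energy_additive_over_disjoint_sets():
    smap = _map_from({(("A", i, ""), ("B", i, "")): -float(i) for i in range(1, 7)})
    pairs = [(("A", i, ""), ("B", i, "")) for i in range(1, 7)]
    total = rn.interface_rigidity_energy(smap, pairs)
    split = (rn.interface_rigidity_energy(smap, pairs[:3])
             + rn.interface_rigidity_energy(smap, pairs[3:]))
    assert total == pytest.approx(split)


# ---------------------------------------------------------------- per-element

def test_sse_energy_per_residue(helix20):
    elements = [SSEElement("α1", "helix", "A", 1, 4)]
    smap = _map_from({(("A", 1, ""), ("A", 10, "")): -5.0,
                      (("A", 2, ""), ("A", 12, "")): -3.0,
                      (("A", 2, ""), ("A", 3, "")): -99.0})  # inside-inside: ignored
    table = rn.sse_rigidity_energy(smap, elements, helix20)
    assert table.iloc[0]["energy_per_residue"] == pytest.approx(-8.0 / 4)


def test_sse_energy_zero_without_cross_contacts(helix20):
    elements = [SSEElement("α1", "helix", "A", 1, 4)]
    table = rn.sse_rigidity_energy(_map_from({}), elements, helix20)
    assert table.iloc[0]["energy_per_residue"] == 0.0


def test_sse_energy_invariant_under_renumbering(planted_dimer):
    trajectory = rn.dilute(planted_dimer, rn.detect_all(planted_dimer))
    smap = rn.stability_map(trajectory)
    elements = [SSEElement("α1", "helix", "A", 1, 12)]
    before = rn.sse_rigidity_energy(smap, elements, planted_dimer)
    shifted = planted_dimer.copy()
    for chain in shifted.chains:
        for res in chain.residues:
            res.seqnum += 100
    smap_shift = StabilityMap()
    for (a, b), e in smap.items():
        key = StabilityMap._key((a[0], a[1] + 100, a[2]), (b[0], b[1] + 100, b[2]))
        smap_shift.e_rc[key] = e
    elements_shift = [SSEElement("α1", "helix", "A", 101, 112)]
    after = rn.sse_rigidity_energy(smap_shift, elements_shift, shifted)
    assert after.iloc[0]["energy_per_residue"] == pytest.approx(
        before.iloc[0]["energy_per_residue"])


# ---------------------------------------------------------------- ensembles

def test_tp_statistics_hand_computed():
    result = rn.tp_statistics([350.0, 352.0, 354.0, 356.0])
    assert result.mean == pytest.approx(353.0)
    assert result.sd == pytest.approx(np.sqrt(20.0 / 3.0))
    assert result.sem == pytest.approx(np.sqrt(20.0 / 3.0) / 2.0)


def test_ensemble_tp_zero_noise_degenerate(planted_dimer):
    ens = rn.make_ensemble(planted_dimer, 3, 0.0, seed=0)
    result = rn.ensemble_tp(ens)
    assert result.sd == 0.0 and result.sem == 0.0
    single_traj = rn.dilute(planted_dimer, rn.detect_all(planted_dimer))
    single = rn.phase_transition(single_traj)
    assert result.mean == pytest.approx(single.t_p)


def test_two_block_ensemble_recovers_planted_mean():
    tps = []
    for seed in range(5):
        for net in rn.two_block_ensemble(n_models=20, seed=seed):
            tps.append(rn.phase_transition(rn.dilute_network(net)).t_p)
    result = rn.tp_statistics(tps)
    assert abs(result.mean - rn.temperature_of(-3.0)) < 2 * result.sem + 0.5


# ---------------------------------------------------------------- regression

def test_regression_collinear_points():
    metas = [rn.OrthologMeta(str(t), t) for t in (10.0, 37.0, 80.0)]
    results = [rn.tp_statistics([0.1 * (t + 273.15) + 300.0]) for t in (10.0, 37.0, 80.0)]
    fit = rn.correlate_tp_torg(list(zip(metas, results)))
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.slope == pytest.approx(0.1)


def test_regression_matches_brute_force_oracle():
    x = np.array([0.0, 1.0, 2.0])
    y = np.array([0.0, 1.0, 0.0])
    metas = [rn.OrthologMeta(str(v), v - 273.15) for v in x]
    results = [rn.tp_statistics([v]) for v in y]
    fit = rn.correlate_tp_torg(list(zip(metas, results)))
    # independent OLS oracle: normal equations by hand
    slope_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    yhat = y.mean() + slope_oracle * (x - x.mean())
    r2_oracle = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
    assert fit.slope == pytest.approx(slope_oracle)
    assert fit.r_squared == pytest.approx(r2_oracle)
    assert fit.r_squared == pytest.approx(0.0, abs=1e-12)


def test_regression_needs_three_points():
    metas = [rn.OrthologMeta("a", 10.0), rn.OrthologMeta("b", 40.0)]
    results = [rn.tp_statistics([300.0]), rn.tp_statistics([310.0])]
    with pytest.raises(ValueError):
        rn.correlate_tp_torg(list(zip(metas, results)))


# ---------------------------------------------------------------- diagnostics

def test_rmsd_identity_and_rotation():
    coords = np.random.default_rng(0).normal(size=(12, 3))
    assert rn.ca_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-9)
    rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
    moved = coords @ rot.T + np.array([4.0, -2.0, 7.0])
    assert rn.ca_rmsd(moved, coords) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_matches_scipy_alignment_oracle():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(4, 3))
    b = rng.normal(size=(4, 3))
    ours = rn.ca_rmsd(a, b)
    # independent oracle: scipy quaternion-based alignment
    ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(bc, ac)
    oracle = rssd / np.sqrt(len(a))
    assert ours == pytest.approx(oracle, abs=1e-6)


def test_rg_values():
    assert rn.radius_of_gyration(np.zeros((1, 3))) == 0.0
    assert rn.radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]])) == pytest.approx(1.0)
    cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
    assert rn.radius_of_gyration(cube) == pytest.approx(np.sqrt(0.75))


def test_rmsip_bounds_and_symmetry(helix20):
    ens_a = rn.make_ensemble(helix20, 25, 0.3, seed=1)
    ens_b = rn.make_ensemble(helix20, 25, 0.3, seed=2)
    ab = rn.rmsip(ens_a, ens_b)
    ba = rn.rmsip(ens_b, ens_a)
    assert 0.0 <= ab <= 1.0
    assert ab == pytest.approx(ba)
    assert rn.rmsip(ens_a, ens_a) == pytest.approx(1.0, abs=1e-6)


def test_rmsip_orthogonal_subspaces():
    v = np.zeros((40, 5))
    w = np.zeros((40, 5))
    for i in range(5):
        v[i, i] = 1.0
        w[10 + i, i] = 1.0
    assert rn.rmsip_subspaces(v, w) == 0.0
    assert rn.rmsip_subspaces(v, v) == pytest.approx(1.0)


def test_rmsip_random_subspace_expectation():
    """Random 10-mode subspaces of R^300 overlap at ~ sqrt(10/300)."""
    values = []
    for seed in range(6):
        rng = np.random.default_rng(seed)
        v = np.linalg.qr(rng.normal(size=(300, 10)))[0]
        w = np.linalg.qr(rng.normal(size=(300, 10)))[0]
        values.append(rn.rmsip_subspaces(v, w))
    assert np.mean(values) == pytest.approx(np.sqrt(10 / 300), rel=0.15)


def test_superpose_removes_rigid_motion():
    rng = np.random.default_rng(3)
    fixed = rng.normal(size=(8, 3))
    rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.5]).as_matrix()
    moving = fixed @ rot.T + 3.0
    np.testing.assert_allclose(superpose(moving, fixed), fixed, atol=1e-9)


# ---------------------------------------------------------------- pipeline

def test_pipeline_discriminates_interface_strength():
    """Stronger planted interfaces give lower energy sums and higher T_p."""
    energies, tps = [], []
    for strength in (-1.5, -3.0, -4.5):
        dimer = rn.make_toy_dimer(
            12, planted_interactions=[((5, 5), "hbond", strength),
                                      ((8, 8), "hbond", strength * 0.9)])
        trajectory, transition, smap = rn.unfold(dimer, rn.detect_all(dimer))
        pairs = rn.interface_pairs(dimer)
        energies.append(rn.interface_rigidity_energy(smap, pairs))
        tps.append(transition.t_p)
    assert energies[0] > energies[1] > energies[2]
    assert tps[0] < tps[1] < tps[2]
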