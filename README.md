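# rigidnet

Body-bar rigidity analysis of protein structures: constraint networks,
pebble-game rigid cluster decomposition, thermal unfolding by constraint
dilution, and dimer-interface stability screens.

## The problem

Orthologous enzymes from psychrophilic, mesophilic and (hyper)thermophilic
organisms trade catalytic activity against thermal stability. Much of that
trade-off is mechanical: how rigid is the folded structure, where are the
flexible joints, and how strongly are the subunits of an oligomer tied
together? `rigidnet` answers these questions from coordinates alone, using
rigidity theory rather than force-field energetics, which makes the analysis
fast enough to run over thousands of conformational snapshots.

## The model

A structure is mapped to a **body-bar multigraph**: each heavy atom is a
rigid body with 6 degrees of freedom (hydrogens merge into their parents),
and interactions become bars that remove relative degrees of freedom:

| constraint | bars |
|---|---|
| locked covalent bond (peptide, resonance, ring) | 6 |
| rotatable single bond | 5 |
| hydrogen bond / salt bridge | 5 |
| hydrophobic tether | 2 |

Hydrogen bonds are scored with a 12-10 potential,
`E = V0 [5 (d0/d)^12 - 6 (d0/d)^10] · cos²θ_dev` (defaults `V0 = 8`
kcal/mol, `d0 = 2.8` Å), salt bridges get a fixed strong energy, and
hydrophobic tethers carry none.

Generic rigidity of the multigraph is decided by the **(6,6) pebble game**:
a bar is independent iff 7 pebbles can be gathered on its endpoints; the
network's degrees of freedom are `6·n_bodies − n_independent`, and two
bodies share a **rigid cluster** iff one more bar between them would be
redundant. A brute-force count-matroid oracle (`6n′ − 6` sparsity counts
over all body subsets) validates the game exactly on small graphs.

**Thermal unfolding** removes hydrogen bonds in order of increasing
strength. As the energy cutoff `E_cut` sweeps downward, the order
parameter `P∞` (fraction of bodies in the largest rigid cluster) collapses
at a phase transition; a linear empirical map `T = a·E_cut + b` (defaults
`a = −20` K·mol/kcal, `b = 300` K) converts the transition cutoff into a
**phase transition temperature `T_p`** — a computational melting point.
Recording when each residue pair first stops sharing a rigid cluster gives
the **rigid-contact stability map** `E_rc`, which is summed over interface
residue pairs (interface stability) or over the contacts of each secondary
structure element (local stiffness, normalised per residue).

On top of the pipeline sit ensemble statistics (mean and SEM of per-model
`T_p`, regression against host growth temperature `T_org`), ensemble
diagnostics (Kabsch RMSD, radius of gyration, RMSIP of principal-component
subspaces), and the **interchain disulfide screen**: non-proline residue
pairs with Cβ–Cβ distances of 3.83 ± 0.18 Å across the interface, the
geometry of a native cystine.

## Worked example

Build a toy homodimer with two planted interchain hydrogen bonds (−3.0 and
−1.0 kcal/mol), unfold it, and measure the interface:

```python
import rigidnet as rn

dimer = rn.make_toy_dimer(
    12,
    planted_interactions=[((5, 5), "hbond", -3.0), ((8, 8), "hbond", -1.0)],
)
interactions = rn.detect_all(dimer)
trajectory, transition, stability = rn.unfold(dimer, interactions)
print(trajectory.to_frame().round(3).to_string(index=False))
print(f"T_p = {transition.t_p:.1f} K")
pairs = rn.interface_pairs(dimer)
energy = rn.interface_rigidity_energy(stability, pairs)
print(f"interface rigidity energy = {energy:.1f} kcal/mol over {len(pairs)} residue pairs")
```

prints

```
 state  e_cut  temperature  p_inf  n_clusters
     0  0.000       300.00  0.919           7
     1 -1.000       320.00  0.432          12
     2 -3.000       360.00  0.432          12
     3 -5.263       405.25  0.027          52
T_p = 320.0 K
interface rigidity energy = -2.0 kcal/mol over 3 residue pairs
```

Reading the trajectory: at `E_cut = 0` nearly every atom sits in one rigid
cluster (`P∞ ≈ 0.92`). Removing the −1.0 kcal/mol interchain bond leaves a
single 5-bar bridge between the chains — a hinge, not a rigid tie — so the
dimer falls apart into its two monomers (`P∞` halves; that largest drop
defines `T_p = 320 K`). The backbone helices themselves only melt once
their own −5.26 kcal/mol i→i+4 bonds are removed at 405 K. Both interface
residue pairs separate at `E_cut = −1.0`, so the interface rigidity energy
is −2.0 kcal/mol; planting stronger interchain bonds makes this sum more
negative and pushes `T_p` up.

Real structures enter the same pipeline through `rn.read_pdb(path)` (with
`rn.apply_assembly` to expand REMARK 350 operators into the biological
dimer) and multi-MODEL files become ensembles for `rn.ensemble_tp` and
`rn.rmsip`. A thin CLI mirrors the library:
`rigidnet synth helix --out h.pdb`, `rigidnet unfold --pdb h.pdb`,
`rigidnet screen --pdb dimer.pdb`.

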