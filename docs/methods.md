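# Methods

This note documents the model, the numerical conventions and the design
choices behind `rigidnet`, and states what the synthetic test inputs do and
do not establish about real structures.

## Constraint network

Bodies are heavy atoms. Hydrogens merge into the heavy atom they bond to,
and a heavy atom with exactly one covalent bond (carbonyl O, OXT, the Cβ of
alanine, a terminal amine N after its hydrogens merge) merges into its
neighbour: a point body on a bond axis has no motion of its own that moves
an atom. The merge is a single pass on the covalent graph, not recursive —
recursing would swallow whole chains across rotatable bonds and erase real
dihedral flexibility.

Covalent topology comes from bond templates of the 20 standard amino acids
plus the inter-residue peptide bond and SG–SG disulfides; atoms without a
template match fall back to a distance criterion (heavy–heavy ≤ 1.9 Å,
X–H ≤ 1.25 Å). Bond classes: peptide C–N, carbonyl/carboxylate,
amide/guanidinium, aromatic rings and the proline ring are locked (6 bars);
every other single bond is rotatable (5 bars). Hydrogen bonds and salt
bridges contribute 5 bars, hydrophobic tethers 2. All multiplicities are
arguments of `build_network`; the defaults follow the standard body-bar
convention for protein rigidity analysis. HETATM entities (waters,
ligands) are excluded from both interaction detection and the network by
default, since crystallographic waters would otherwise dominate the
hydrogen-bond constraint set.

## Interaction detectors

*Hydrogen bonds.* Donors are N/O/S atoms bearing a hydrogen (backbone
amide H and hydroxyl/thiol H are placed geometrically when absent, as
crystal structures rarely include them; the hydroxyl rotamer is arbitrary
but deterministic). Acceptors are any N/O/S atom. Candidates must pass a
donor–acceptor distance cutoff (3.6 Å), a D–H···A angle cutoff (≥ 100°)
and an energy cutoff (≤ −0.1 kcal/mol) with

    E = V0 · [5 (d0/d)^12 − 6 (d0/d)^10] · cos²(θ_dev),

where `d` is the donor–acceptor distance, `θ_dev` the deviation of
D–H···A from linearity, `V0 = 8` kcal/mol and `d0 = 2.8` Å. An optional
acceptor-angle factor (sp2: ideal 120°, sp3: 109.5°) can multiply in; the
default is hybridisation-agnostic because acceptor geometry adds a second
parameterisation with little effect on the dilution ranking.

The default pairing policy is **greedy unique matching**: candidates are
sorted strongest-first, and each donor hydrogen donates at most one bond
while each acceptor atom accepts at most one. The motivation is visible in
an ideal α-helix: besides the n−4 i→i+4 bonds (N···O ≈ 3.09 Å, D–H···A ≈
165°, E ≈ −5.3 kcal/mol) each amide H also sees the flanking i→i+3
carbonyl at ≈ 3.21 Å and ≈ 109°, worth ≈ −0.5 kcal/mol. Counting that
bifurcated flank as a second independent 5-bar constraint would
over-rigidify every helix; under unique matching the helix carries exactly
its n−4 canonical bonds. `pairing="all"` retains every geometry for users
who want the raw candidate set.

*Salt bridges.* Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 and the N-terminus
versus Asp OD1/OD2, Glu OE1/OE2 and the C-terminal carboxylate, N–O
distance ≤ 4.0 Å, one interaction per residue pair (closest atom pair
reported). Each bridge carries a fixed energy of −10 kcal/mol so that it
ranks among the strongest dilutable constraints and persists to high
simulated temperature. The value is a convention, not a physical energy;
it only needs to sit below the hydrogen-bond range.

*Hydrophobic tethers.* C/S atom pairs of non-adjacent residues within
r_vdW(i) + r_vdW(j) + 0.25 Å (C 1.7 Å, S 1.8 Å), one per residue pair.
Tethers never dilute: hydrophobic contacts are entropic and do not break
first under heating in this model.

## Pebble game and oracle

The (k=6, l=6) pebble game maintains 6 pebbles per body and a directed
graph of accepted bars. A bar is accepted iff 7 pebbles can be gathered on
its endpoints (pebble searches reverse paths); the count of accepted bars
is the rank of the constraint multiset in the (6,6) count matroid, so DOF
= 6·n − rank is insertion-order independent. Rigid clusters partition the
bodies: a pair is co-rigid iff a trial bar between them would be redundant
(gathering 7 pebbles fails). In the body-bar model with l = k this
relation is transitive — two rigid clusters sharing a body satisfy
(6n₁−6) + (6n₂−6) = 6(n₁+n₂−1)−6 and are jointly isostatic — which the
cluster search exploits by testing each unassigned body only against one
representative per cluster. Clusters are numbered by descending size, ties
by smallest body index, so outputs diff cleanly.

The brute-force oracle computes the rank by greedy growth with full subset
verification (every body subset S must contain ≤ 6|S|−6 bars), valid
because sparsity counts form a matroid, and decides co-rigidity by testing
whether a trial bar extends the basis. It is exponential and restricted to
n ≤ 8; the test suite and the acceptance script compare it against the
pebble game on hundreds of seed-indexed random multigraphs.

## Dilution and T_p

Dilution removes hydrogen bonds and salt bridges in order of increasing
strength. The default grid places one state at `E_cut = 0` and one at each
distinct dilutable energy; a state's network keeps dilutable bars
**strictly stronger** than its `E_cut`. The state labelled `E_cut = E` is
therefore the first state in which bonds of energy `E` are gone, and the
energy at which a residue pair separates is exact (no ±ε bookkeeping in
reported numbers). Energies equal to within 1e-6 kcal/mol are grouped into
one state — geometrically identical bonds produce float-level noise.
Covalent and hydrophobic bars are never removed. A fixed-step grid
(default 0.1 kcal/mol) is available; the per-bond default avoids step-size
artefacts.

Temperature map: `T = a·E_cut + b`, defaults `a = −20` K·mol/kcal,
`b = 300` K, both configurable. The published calibrations of this map
were fitted on meso-/thermophilic protein pairs and are not printed in a
form usable here; the defaults are an explicit placeholder. Every
comparative quantity in the package (rank orders, R², energy differences)
is invariant to the affine choice; absolute Kelvin values are not and
should be read as relative.

`T_p` estimation: `max_drop` (default) takes the temperature of the state
with the largest single-step decrease of P∞, ties resolved to the lowest
temperature; it is deterministic and exact on per-bond grids.
`sigmoid_fit` fits a two-state logistic to P∞(T) and reports the midpoint,
matching the melting-point reading of the transition; it needs several
pre- and post-transition states to be well conditioned. A trajectory
qualifies as having a transition only if it has ≥ 3 states and P∞ drops
by ≥ 0.2 overall; otherwise the result is flagged rather than numeric.

The stability map assigns each initially co-rigid residue pair the E_cut
of the first state where its residues (judged at their Cα bodies) land in
different clusters; pairs co-rigid through the final state are marked
persistent at the final cutoff. Interface stability is the sum of E_rc
over interchain residue pairs within 5.0 Å heavy-atom contact; per-element
stiffness sums E_rc over pairs crossing the element boundary and divides
by the element's residue count (standard error from the per-residue sums).

## Ensembles and statistics

Ensemble T_p uses the full pipeline per model; models without a detectable
transition are excluded and counted. Moments use the sample SD (n−1);
SEM = SD/√M. The T_p–T_org regression is ordinary least squares on
ensemble means with both variables in Kelvin (a 1/SEM² weighted variant is
provided); R² and the two-sided slope p-value come with it.

Diagnostics: Kabsch superposition (SVD with determinant correction) for
Cα RMSD; unweighted Cα radius of gyration; RMSIP between the top-10
eigenvector subspaces of the Cα covariance matrices of two ensembles.
Covariances are built after a two-pass superposition: fit all models on
all residues, rank residues by RMSF, refit on the least-mobile 80%
(configurable). Mass weighting is not applied.

## Synthetic inputs

The generators provide ground truth by construction, with ideal-geometry
backbones (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231, N–H 1.01 Å;
helix φ = −57°, ψ = −47°, ω = 180°; amide H in-plane bisecting C–N–Cα):

* `make_helix(n)` — poly-alanine α-helix with exactly n−4 backbone
  hydrogen bonds; detector round-trips are exact.
* `make_toy_dimer` — two helices, C2-symmetric about z by default, axis
  separation 10 Å (chosen so that un-planted chains have no incidental
  interchain contacts while facing residues remain within stub reach).
  Plants are solved exactly: Cβ pairs by symmetric tilting of the two Cβ
  vectors (realised to < 0.01 Å), hydrogen bonds by serine hydroxyl stubs
  whose distance carries the target energy (bent at the donor when the
  radial term alone cannot be weak enough), salt bridges by extended
  Lys/Glu stubs at 3.5 Å N–O. Geometrically unreachable plants raise with
  a diagnostic rather than being silently approximated.
* `make_ensemble` — i.i.d. isotropic Gaussian coordinate noise per atom.
  The independence gives analytic expectations for displacement and
  subspace-overlap tests; it deliberately lacks the collective modes of
  physical ensembles.
* `random_body_bar_graph` — uniform bars over the 6-slot pair capacities,
  for the oracle comparison.
* `two_block_network` — two chains of 6-bar edges joined by ≥ 2 five-bar
  bridges: rigid while two bridges stand, two clusters after, so the
  transition energy equals the (second-)strongest bridge energy exactly.
  `two_block_ensemble` draws one shared bridge energy per model from
  Normal(−3.0, 0.2), making the planted ensemble-mean T_p exact (360 K
  under the default map).

What passing on these inputs shows: the combinatorics (pebble game,
dilution bookkeeping, screens, statistics) are exact, and the detectors
invert the generator's geometry. What it does not show: agreement with any
particular force field or experiment on real structures — the energy
function constants, the salt-bridge convention and the temperature map are
field-standard but deliberately simple, and real ensembles have correlated
fluctuations the Gaussian generator does not emulate.

## Numerical conventions and edge cases

* Distances in Å, energies in kcal/mol (negative attractive), B-factors in
  Å², temperatures in K (T_org input in °C, converted internally).
* PDB I/O via gemmi; altlocs resolve to highest occupancy (ties:
  alphabetical), residues sort by (seqnum, icode), multi-MODEL files must
  list identical atoms. Coordinates round-trip to PDB precision (10⁻³ Å).
* Secondary structure: HELIX/SHEET records take precedence; otherwise a
  φ/ψ window heuristic (helix φ∈[−100,−30], ψ∈[−80,−5], runs ≥ 4; strand
  φ∈[−180,−40], ψ∈[60,180]∪[−180,−170], runs ≥ 3). Terminal residues with
  one defined dihedral join an adjacent run if that dihedral qualifies.
  This is a deliberate lightweight heuristic, not a DSSP reimplementation.
* Relative B-factors are z-scores normalised per chain (population SD)
  so that chains of a crystal with different overall mobility are
  comparable; all-equal B-factors raise.
* Terminal residues of a helix hang off single rotatable bonds after the
  merges and are genuinely flexible: a 20-residue ideal helix decomposes
  into one 18-residue rigid cluster plus two terminal singletons.
* The disulfide screen uses a closed window [center − halfwidth,
  center + halfwidth], excludes prolines, skips glycine unless a virtual
  Cβ is requested (ideal tetrahedral reconstruction from N, Cα, C), and
  screens the first model of an ensemble. No C2-axis proximity filter is
  applied: near-axis positions are reported via the symmetric flag, not
  used as a criterion.

## Problem sizes

The shipped tests and the acceptance script run on 12-residue-per-chain
dimers, 20-residue helices, ≤ 6-body oracle graphs (200 of them), 10-body
two-block networks (5 × 50-model ensembles) and 15–25-model coordinate
ensembles. These sizes were chosen so that every quantity has an exact or
analytic reference; the pipeline itself is polynomial (pebble searches
dominate) and handles full-size dimeric structures.

## Known limitations

* No π-stacking, cation–π or metal coordination; electrostatics beyond the
  fixed salt-bridge rule are out of scope.
* mmCIF input is not supported (PDB only).
* The absolute T_p scale depends on the placeholder temperature map and on
  the architecture and size of the protein; only comparisons within a
  structural family are meaningful.
* The sigmoid T_p method degrades on trajectories with few states; the
  default max_drop method is preferred on per-bond grids.
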