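# Methods

## The mixed-resolution elastic network

The package models a protein as a network of point masses connected by
harmonic springs at their equilibrium (crystallographic) separations — an
anisotropic network model (ANM) — with two resolutions mixed in one
network. Inside the high-resolution (HR) region every heavy atom is a
node with its atomic mass; every low-resolution (LR) residue is a single
node, placed at its Cα atom or its heavy-atom mass centroid, carrying the
residue's summed heavy-atom mass. Hydrogens are parsed but never enter
the network; waters, ions and ligand records are likewise excluded from
the node set by default (an `include_hetero` flag adds ligand heavy atoms
as HR nodes when the ligand's own flexibility matters).

The underlying assumptions are the standard ENM ones: the crystal
structure is the energy minimum, fluctuations are harmonic around it, and
the slow (low-frequency) end of the spectrum — which is insensitive to
the fine details of the force field — captures the functionally relevant
collective motions. Mixing resolutions preserves that slow end while
keeping the node count far below an all-atom model.

### Springs and the contact-count rule

Two nodes are connected when they have at least one heavy-atom contact
within the cutoff r_c, and the spring constant is

  γ_ij = γ₀ × #{(a, b) : a ∈ atoms(i), b ∈ atoms(j), |r_a − r_b| ≤ r_c}.

This single rule covers all node-kind combinations: an atom–atom pair has
contact count 0 or 1 (a plain uniform-γ ANM spring), an atom–residue or
residue–residue pair is weighted by the inter-residue contact count. Two
desirable degenerate limits follow: with every residue HR the model *is*
a conventional heavy-atom ANM (verified in the tests against an
independent all-pairs oracle to 1e-8 on the spectrum), and with no HR
residues it is a contact-weighted residue-level ENM. Springs between
atoms of the same HR residue are included when within r_c — excluding
them would disconnect side chains. Contacts are found with a k-d tree, so
network construction is O(n log n) rather than all-pairs.

### Hessian, mass weighting, modes

Each spring contributes the standard ANM superblock
H_ij = −(γ_ij/R_ij²)·d_ij d_ijᵀ with d_ij the equilibrium inter-node
vector; diagonal superblocks are the negative row sums, which makes the
superblock rows of the unweighted Hessian vanish identically
(translational invariance, asserted to 1e-10 in the tests). The Hessian
is mass-weighted as M^(−1/2) H M^(−1/2), with each node's mass repeated
over x, y, z, and symmetrised exactly before diagonalisation.

Eigenpairs come from a dense symmetric solver up to 1500 degrees of
freedom (where dense is faster and exact) and otherwise from a
shift-inverted Lanczos solve at σ = −1e-6 — the matrix is positive
semidefinite, so H − σI is safely factorizable — returning the requested
lowest eigenpairs under the same ascending-order contract. Zero modes are
classified by λ < 1e-8 × max(diag), a scale that is identical for dense
and partial solves of the same matrix; a connected network must produce
exactly six (translations and rotations — the tests check the computed
zero-mode subspace against the analytic rigid-body basis to < 1e-4 rad of
principal angle), and the API can be told to fail loudly when it does
not, which is the practical symptom of a disconnected network or
coincident nodes.

Solver eigenvector signs are arbitrary, so every eigenvector is oriented
with its largest-magnitude component positive. This fixes what "positive
direction" means for conformer labels across solvers and platforms.

### Fluctuations and B-factor validation

Mean-square fluctuations per node are the mode sums
⟨ΔR_i²⟩ = Σ_k u_ik²/(m_i λ_k) over nonzero modes; the 1/m_i
back-transforms the mass-weighted eigenvectors into Cartesian space.
Per-residue values take the Cα atom node for HR residues and the single
node for LR residues. Validation is the Pearson correlation between the
per-residue MSF and the experimental Cα B-factor column; the statistic is
invariant under positive affine maps of either side, which is why neither
γ₀ nor the conventional 8π²/3 conversion constant appears anywhere — both
would cancel.

For uniform masses the all-mode MSF equals the diagonal-block traces of
the Moore–Penrose pseudoinverse of the Cartesian Hessian, and the tests
assert exactly that; with non-uniform masses the two differ, because the
pseudoinverse does not commute with the mass transform when the null
space is mass-skewed, so the mass-weighted mode sum is the defining
quantity and the pinv identity is only used as an oracle in the uniform
case.

## Conformer generation

A conformer displaces *all* nodes along one mode's Cartesian field
u_k/√m (one mode at a time; no mode mixing). Because the construction is
linear, the signed scale s = ±target/RMSD(unit displacement) hits any
Cα-RMSD target exactly (tolerance 1e-6 Å is asserted, achieved at
machine precision); RMSD is computed with no superposition, in the common
frame, matching how the deformation is built. The RMSD selection is the
Cα-bearing node set — HR Cα atom nodes plus LR nodes; under centroid
placement the residue node stands in for the Cα with a warning. The
default schedule (modes 1–3, both directions, 1.0/1.5/2.0/2.5/3.0/4.0 Å)
produces 36 conformers in a fixed (mode, direction, target) order with
labels mXa (positive) and mXb (negative). No minimization happens here;
the restraint machinery below generates the inputs for that external
step.

## Truncation and zoned restraints

The HR residues of a conformer are extracted (heavy atoms, identifiers
preserved, TER records at sequence discontinuities) and each atom is
assigned to a concentric shell by its minimum distance to any ligand
heavy atom (or to an explicit point). Shell intervals are half-open
[low, high): an atom exactly on a boundary belongs to the outer, stiffer
shell — a deterministic, conservative convention. Assignment is per-atom
by default; a per-residue mode assigns whole residues by their Cα
distance, since restraint wordings in the literature alternate between
the two granularities.

Four presets ship (constants in kcal/mol·Å²): `minimization` 0 (<15 Å) /
50; `case1` 0/10 (15–20 Å)/50; `case2` 0 (<10 Å)/25/35/50; `case3`
0 (<15 Å)/10/25/50 (shell edges at 20 and 25 Å). None is wired in as the
default — the appropriate scheme differs between the minimization and MD
stages and between published variants of the zone constants, so the CLI
requires an explicit scheme name. Output dialects: a constraint PDB with
the force constant in the occupancy column (the NAMD consref/conskfile
convention) and a flat TSV; both are byte-stable.

## Synthetic fixtures: what they do and do not show

`mcganm.fixtures` generates toy structures (idealised helix, extended or
random-walk backbones with N/CA/C/O plus seeded pseudo-side-chain atoms,
optional two-chain split and a HETATM ligand cluster placed at the last
chain's centroid) and guaranteed-rigid random spring networks (a banded
chain — each node bonded to three predecessors — plus random extra edges;
a bare chain of central-force springs would have floppy hinge mechanisms
and spurious zero modes). The toy B-factor column is a low-frequency
sinusoid plus seeded noise, so correlation code has a non-degenerate,
reproducible target.

These fixtures exercise every code path deterministically and offline:
geometry-dependent selection, contact counting, spectra, RMSD targeting,
shell partitioning. What they cannot show is *agreement with experiment*:
the toy B column is arbitrary, so the Pearson r computed on a toy says
the machinery is correct, not that the model reproduces crystallographic
temperature factors. That check needs real structures —
`examples/validate_bfactors.py` runs the identical protocol (30 Å
ligand-centred HR sphere, chain promotion, r_c = 10 Å, all modes) on any
PDB file the user supplies.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| r_c (cutoff) | 10 Å | heavy-atom contact distance; 6–10 Å is the physically sensible band, values outside warn |
| HR radius | 30 Å | sphere around the ligand modeled at atomic resolution; large enough to hold a 15 Å flexible core for truncated simulations |
| chain promotion | > 50 % | a chain with most residues selected becomes wholly HR, avoiding split subunits |
| LR placement | calpha | residue node at Cα; `centroid` uses the heavy-atom mass centroid |
| γ₀ | 1 | base spring constant; every published statistic here is scale-free, so it has no unit |
| zero tolerance | 1e-8 | relative eigenvalue threshold for rigid-body modes |
| RMSD targets | 1.0–4.0 Å | deformation levels of the conformer schedule |

## Problem sizes

The test suite and the acceptance script run on toys of 40–50 residues
(≈ 200–300 nodes, ≤ 900 degrees of freedom), where dense
eigendecomposition is exact and takes seconds; these sizes exercise every
branch, including mixed HR/LR models with both node kinds. Real
structures at a few thousand nodes go through the same API with the
partial eigensolver.

## Known limitations

- No loop or gap rebuilding: chain continuity is validated and gaps are
  reported (`Structure.chain_gaps`), but externally completed models are
  expected as input.
- Harmonicity: large deformation levels (3–4 Å) extrapolate a linear
  mode far beyond the harmonic basin; the resulting conformers are
  starting points for minimization, not equilibrium structures.
- Single-mode deformation only; combined-mode or iterative
  (minimize-then-deform) schemes are out of scope.
- The network has no solvent, no distance-dependent force constants and
  no isotropic (GNM) variant.
- mmCIF input is not parsed; fixed-column PDB only.
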