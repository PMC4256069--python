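# Methods

This note records the models, conventions and numerical choices behind
`gasmap`, in the order a user meets them: the insertion free-energy estimator,
the explicit-ligand sampler, the landscape analysis, the synthetic
ground-truth systems, and the error model. It states no empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## Probe model and interaction

The probe is a rigid homonuclear diatomic with two identical Lennard-Jones
sites and zero charges; the default mimics O₂ (ε = 0.40 kJ·mol⁻¹, σ = 3.0 Å
per site, bond length 1.21 Å). Treating the gas as apolar is standard for
O₂-class ligands: dispersion and steric repulsion dominate, and no
electrostatic insertion term is included. Cross interactions use
Lorentz-Berthelot combination (arithmetic σ, geometric ε) by default; the
all-geometric rule used by GROMOS-family force fields is available via
`combining_rule="geometric"`. The pair potential is plainly truncated at
`lj_cutoff` (default 14 Å, a typical long-range MD cutoff); no switching or
tail correction, because insertion free-energy differences between voxels are
insensitive to a constant far-field term at these densities.

## Implicit ligand sampling

For each voxel the estimator evaluates

ΔG(r) = −k_B T · ln [ Σ_f w_f ⟨ exp(−E_f(r_i, ω_i)/k_B T) ⟩_i / Σ_f w_f ],

where f runs over ensemble frames with weights w_f (uniform by default — an
evenly pooled set of replicates) and i over `n_insertions_per_voxel` probe
placements drawn inside the voxel cube (the cube variant; an
inscribed-sphere mode is kept for comparison with older insertion schemes).
Implementation details that matter:

* **Placement scheme.** Each voxel owns an RNG stream derived from
  `(seed, voxel index)`, so maps are bit-reproducible and independent of
  evaluation order. The default placements are *scrambled-Sobol* points over
  the joint (position, cos θ, φ) space. Plain independent sampling is
  unbiased but converges slowly in voxels straddling a steric wall, where the
  Boltzmann factor spans many decades across the cube; low-discrepancy
  placement cuts the worst-voxel standard error several-fold at identical
  cost while remaining unbiased (the scrambling is random) and still
  converging at least as fast as n^(−1/2). `sampling="stratified"` (jittered
  position sub-grid) and `sampling="uniform"` are provided for comparison and
  for variance studies.
* **One placement set per voxel, shared across frames.** The same insertion
  set is evaluated in every frame. This is a correlated-sampling variance
  reduction, and it makes frame pooling exact: the map of a concatenated
  ensemble equals the Boltzmann-factor-weighted combination of the
  per-ensemble maps, a property the tests assert to 1e−10.
* **Numerical safety.** Per-voxel averages are computed with a max-shifted
  exponential sum; a voxel whose average Boltzmann factor underflows, or
  whose ΔG exceeds `value_cap` (default 100 kJ·mol⁻¹), is written as the cap.
  The cap is far above the 20 kJ·mol⁻¹ network cutoff, so capping can never
  alter network topology. When every insertion energy is exactly zero the
  estimator returns exactly 0.0 — the ideal-gas limit holds to the bit, not
  to a tolerance.
* **Periodicity.** Off by default: after rigid-body superposition of frames a
  periodic lattice is no longer meaningful. Minimum-image interactions are
  supported (`periodic=True`) for bulk-reference estimation in an intact box.

Maps are vacuum-referenced; `convert_reference` subtracts a vacuum→water
offset so that bulk-water-like regions read ≈ 0. The offset is either
supplied or measured by `estimate_bulk_offset`, which inserts the probe
throughout a homogeneous reference ensemble and reports a bootstrap-over-
frames standard error.

## Quadrature reference

`gasmap.quadrature` recomputes the same insertion integral by deterministic
quadrature — a midpoint product rule over positions (default 12³ per voxel)
and Gauss-Legendre × midpoint orientation nodes (12 × 12) — with its own LJ
code, sharing nothing with the stochastic engine. It is the independent
oracle for the engine on frozen one- and two-site systems, and is priced for
exactly that role: cost per voxel grows as positions × orientations × matrix
sites, so it is not a production path.

## Explicit-ligand sampling

`sample_explicit_ligand` runs Metropolis Monte Carlo of the rigid diatomic:
each sweep draws a frame (by frame weight), proposes a joint Gaussian
translation (default step 0.6 Å) and small random rotation (0.5 rad), and
accepts by the Metropolis criterion in that frame's field; the box boundary
is a hard wall. For a frozen single-frame system the stationary distribution
is exactly exp(−βE(r, ω)) — this is the regime the quantitative
implicit↔explicit consistency checks use. For fluctuating ensembles the
frame-mixture kernel only approximates the frame-averaged Boltzmann density
(the approximation is good when the matrix relaxes slowly relative to probe
moves, the physically intended regime); no quantitative test relies on it.
Only the stationary distribution matters for density-map validation, which is
why Monte Carlo was chosen over Langevin dynamics. A window with zero
acceptances (default 2000 sweeps) aborts with a diagnostic, catching
pathological step sizes early.

## Density maps

Density is a raw histogram: each present ligand centre is assigned to its
nearest voxel centre, and voxel values are counts/(frames × voxel volume), so
Σ values × voxel volume equals the mean in-grid ligand count exactly;
positions outside the grid are tallied, not silently dropped. No kernel
smoothing is applied by default (an option exists upstream of the tests but
all validation uses raw histograms). The default iso-level for reports,
1.5 × 10⁻⁴ Å⁻³, is the contour conventionally used to display high-affinity
gas regions; components are counted with 26-connectivity.

## Landscape analysis

* **Tessellation.** Voxels with value above the cutoff are excluded. Every
  remaining voxel repeatedly moves to its lexicographically smallest
  (value, linearized index) neighbour while that is smaller than its own
  pair; the terminus is the basin minimum. The index tie-break is a stated
  convention (the underlying method leaves plateaus undefined); it makes the
  whole analysis deterministic, including on exactly flat grids, where the
  single basin's minimum is the smallest-index voxel.
* **Connectivity.** 26-neighbour by default — diagonal moves give smoother
  descent on ~1 Å grids; 6 and 18 are available for sensitivity checks, and
  all oracle tests run at every connectivity.
* **Saddles.** The boundary of a basin pair is the set of neighbouring voxel
  pairs with different labels; the saddle value is min over the boundary of
  max(value(a), value(b)), attained at the higher-valued voxel (ties toward
  the smaller index). With this convention the saddle provably equals the
  minimax path energy between the two minima *over paths confined to the
  union of the two basins* — the restriction matters: a path detouring
  through a third basin can cross lower, and the network as a whole
  represents such routes by its other edges. The oracle tests check the
  within-union identity exhaustively.
* **Network cutoff.** The construction cutoff (default 20 kJ·mol⁻¹) is
  interpreted, by default, as the maximum energy a voxel may have to
  participate at all (`cutoff_mode="voxel"`); the alternative reading — keep
  all voxels, admit only edges whose saddle is below the cutoff
  (`cutoff_mode="saddle"`) — is implemented behind the same flag, since the
  underlying method statement does not disambiguate. Both directional
  barriers (saddle − each minimum) are stored per edge; basins touching any
  grid face are flagged exterior.
* **Profiles.** A route of connected minima yields the alternating
  minimum/saddle sequence; the forward barrier at step i is saddle_i −
  minimum_i (the barrier climbed when moving forward), so forward and reverse
  barriers differ exactly by the free-energy difference of the flanking
  minima.
* **Block errors.** The analysis is run independently on maps from two
  disjoint data blocks; minima and saddles are matched greedily by nearest
  position within a matching radius (default 2 Å ≈ two voxels), and each
  matched feature's uncertainty is half the absolute inter-block difference.
  A feature present in only one block is reported as error-uncomputable —
  never as zero.

## Synthetic ground-truth systems

The generator stands in for unavailable real trajectory data, so its defaults
are the study conditions of every test:

* **Fluctuating matrix.** Sites jitter independently and isotropically with
  Gaussian displacements (`thermal_sigma`, default 0.25 Å for channel
  systems — side-chain-scale thermal motion). Independence keeps the ground
  truth analytically tractable; real matrices have correlated motions, so
  passing tests demonstrate estimator correctness, not conformational realism.
* **Channel system.** Two radius-5 Å cavity shells (64-point Fibonacci
  spheres, facing polar caps removed to form a neck, ε = 0.45 kJ·mol⁻¹,
  σ = 3 Å sites) on the z-axis of a 24 × 24 × 36 Å box; the lower cavity
  opens to the exterior through a permanent mouth; a six-site gate ring at
  the neck midplane has radius 0.8 Å (occluding) to 7 Å (clear) as
  `open_fraction` goes 0 → 1, interpolated geometrically so that at
  intermediate openness the ring still engages the channel sterically. This
  keeps the exterior→cavity pass height monotone in openness at the tested
  fractions — with soft LJ gates, strict monotonicity can fail once a gate
  has fully left the channel, because its attractive tail then only deepens
  the open pass.
* **Two-cavity box.** Two eight-site attractive pockets of different depths
  (ε = 2.0 vs 0.9 kJ·mol⁻¹) in a deliberately small 14 × 14 × 22 Å box, so a
  Monte Carlo walker revisits both pockets often and the occupancy-ratio
  comparison against exp(−βΔΔG) has useful statistical power.
* **Frozen-atom oracle system.** A single site with ε = 0.4 kJ·mol⁻¹ and a
  narrow σ = 0.2 Å core (combined wall with the O₂ probe at ≈ 1.6 Å), so the
  repulsive wall falls inside the first voxel shell of a 1 Å grid and the
  voxels entering the quadrature comparison sit on the well-resolved side of
  the wall. This choice came from an a-priori variance analysis of the
  insertion estimator (wall-straddling voxels dominate the error budget), not
  from adjusting to test outcomes.

## Problem sizes and error model

The validation suite uses desk-scale sizes chosen to keep each property
statistically decisive: 11³ voxels × 10⁴ insertions against a 12³ × 144-node
quadrature for the oracle comparison; 4 × 10⁵ Monte Carlo sweeps (first 10%
discarded as burn-in, 12-block standard errors) for occupancy consistency;
9 × 9 × 20 voxels × 192 insertions × 6 frames per channel map; 100 random
8³ grids per connectivity for the exhaustive watershed oracle. Statistical
comparisons are made in combined-standard-error units (3σ); exact claims
(ideal-gas zero, normalisation, pooling, oracle equality) are asserted
exactly or at float-roundoff tolerance.

## Known limitations

* No electrostatics, polarizability, flexible probes or grand-canonical
  occupancy prediction; the probe is a rigid LJ diatomic.
* The explicit-ligand sampler is exact only for frozen fields; its
  frame-mixture stationary distribution is an approximation for fluctuating
  ensembles.
* Basin adjacency, tie-breaking and the cutoff interpretation are stated
  package conventions where the underlying methods literature is silent;
  sensitivity to them can be probed via the connectivity and cutoff-mode
  options.
* Binary trajectory formats are out of scope for core I/O (multi-model
  PDB/XYZ plus sidecar tables; OpenDX for grids).
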