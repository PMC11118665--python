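# Methods

This note records the models, conventions and numerical choices behind
`fretrest`, in enough detail to reproduce or audit any number the package
prints.

## Geometry and RMSD conventions

Structures are Cα traces indexed by `(chain, residue id)`; two structures are
compared over the intersection of those keys in chain order, with no sequence
alignment (the intended inputs are same-sequence conformers). Superposition
is Kabsch via SVD with the determinant sign correction, so the reported RMSD
is the exact global minimum over proper rigid motions. `ca_rmsd` accepts two
shared residues (the minimum is well-defined even though the rotation is
not unique); `kabsch_superpose` demands at least three because it returns the
rotation itself. The radius of gyration is the unweighted RMS Cα distance
from the Cα centroid — the whole method operates in Cα space, so no mass or
heavy-atom weighting is used anywhere.

Relative solvent accessibility divides per-residue Shrake–Rupley areas
(probe 1.4 Å, 960 Fibonacci sphere points per atom, element radii C 1.70 /
N 1.55 / O 1.52 / S 1.80 Å) by fixed theoretical maximum-exposure values per
residue type; values are not clamped and may slightly exceed 1 for terminal
residues. Synthetic fixtures carry annotated rSASA instead, so filter tests
are exact.

## Candidate pool

A pair survives iff its separation on the initial structure is at least the
radius of gyration and both residues have rSASA ≥ 0.1. Both thresholds are
experimental constraints (Förster radii of common dye pairs exceed R_g for
these proteins; buried residues cannot be labelled), not tunables of the
selection problem. The pool records, per pair, the separation and both rSASA
values that passed.

## Selection methods

*Random.* Uniform without-replacement draws of N_r pairs; the benchmark runs
one trajectory per drawn set and averages over sets, mirroring the protocol
of many sets rather than many replicates.

*Normal-mode (target-free).* The anisotropic network model uses a uniform
spring constant and a 12 Å cutoff — the standard choice that reproduces
low-frequency domain motions; masses are unit (only frequency ratios enter).
Rigid-body modes are those with eigenvalue below 1e-8 times the spectral
radius; a connected, non-collinear trace has exactly six. The sampler
displaces by Σ_m ξ_m (a/ω_m) v̂_m with fresh ξ_m ~ U(−1, 1) per iteration and
modes recomputed on the displaced structure each time; no re-centring is done
between iterations (rigid drift is removed only at analysis time by
superposition). The overall scale `a` is calibrated in closed form so one
iteration moves the trace by 0.35 Å RMSD in expectation — successive
structures overlap strongly while a 10³-iteration run explores several Å.
Defaults are ten runs of 10³ structures (10⁴ total); tests and the
acceptance script sample hundreds, which is ample for an 80-residue fixture.

Scoring uses the χ²-weighted mean pairwise RMSD. The per-pair χ² term is the
squared fractional deviation (ΔR/R̄)² with R̄ the mean of the two
separations; the alternative reading ΔR²/(Rⁱ+Rʲ)² (a factor 4 smaller per
pair, which shifts the tail probabilities) is available as
`convention="sum"`. Self terms j = i enter the average as written (P = 1,
RMSD = 0), which also guarantees a non-zero denominator. Greedy selection
caches the fixed pairs' χ² matrix so each candidate costs one rank-one
update; a seeded subsample caps the number of ensemble structures (default
100 → at most 10⁴ structure pairs), identical across candidates and steps so
the ranking is unbiased. Ties break to the lexicographically smallest pair —
pool order makes the first strict minimum the winner.

*Largest separation (target-free).* Static ranking on the initial structure;
a candidate is dropped if its pair-distance series over an unrestrained
trajectory has |Pearson ρ| ≥ 0.9 with any selected pair, or shares a residue
with one. If the admissible pairs run out the result is shorter than
requested, with a warning.

*Largest change (target-aware, engine in the loop).* Each iteration runs the
engine with the accumulated restraints, averages every pool pair's
separation over production frames, and adds the residue-disjoint pair with
the largest absolute deviation from its target separation. The trajectory
*mean* is used as the most stable reading of "largest deviation in the
simulations". Deviations are averaged over 3 replicate runs per iteration
(the full protocol runs tens of replicates per restraint set); single-run
estimates are noticeably noisier and can let a thermal-drift pair into the
late picks.

*Linear discriminant analysis (target-aware).* Features are the pool pair
separations of frames sampled around the initial and target structures
(unrestrained engine runs by default; any ensembles are accepted). The
between-class scatter is the rank-one outer product of the ensemble-mean
difference, so the leading eigenvector of (S_w + εI)⁻¹S_b is computed in
closed form as the normalised (S_w + εI)⁻¹(mean_A − mean_B); ε defaults to
1e-6·trace(S_w)/dim, which regularises the generic features ≫ frames case.
Identical ensemble means raise a dedicated no-discriminant error. Pairs are
ranked by |weight| with lexicographic tie-break.

## The coarse-grained engine (a deliberate physics substitution)

The published protocol runs explicit-solvent all-atom MD; reproducing it is
out of scope here. The stand-in keeps the two properties the method actually
relies on — the starting structure is metastable, and the restraints supply
the driving force — by integrating overdamped (Brownian) Langevin dynamics
on the potential

    U = ANM(starting structure) + Σ (k_r/2)(R_βδ − R⁰_βδ)²

Units: Å, kJ mol⁻¹, ps, K; k_B = 0.008314463 kJ mol⁻¹ K⁻¹; stiffnesses are
accepted in kJ mol⁻¹ nm⁻² and converted internally. The update is
x ← x + (F/γ)dt + √(2k_BT dt/γ)·η with independent standard-normal η, so
"different initial velocities" of the source protocol map to independent
noise streams per replicate. There are no velocities and no thermostat; the
scheme samples the canonical ensemble of U in the small-dt limit. A
construction-time check rejects timesteps above half the stiffest spring's
relaxation scale; any non-finite coordinate aborts the run with its frame
index. The inner loop is numba-jitted with a pure-numpy reference fallback;
both are deterministic given the seed.

Engine defaults (temperature 300 K, friction 50 kJ mol⁻¹ ps Å⁻², dt 0.02 ps,
ANM cutoff 12 Å and stiffness 2000 kJ mol⁻¹ nm⁻², runs of 400 000 steps
= 8 ns with frames every 10 ps and the first half discarded) were calibrated
once, on physical grounds: the network stiffness keeps unrestrained runs
within ~2 Å of their start over the full run (metastability at the thermal
scale of solvated proteins) while the prescribed restraint stiffness
k_r = 5000 kJ mol⁻¹ nm⁻² (which holds a restrained distance to
√(k_BT/k_r) ≈ 0.22 Å) can still drive the hinge transition; the run length
is set by the slowest collective modes, which need nanoseconds both for a
restrained transition to complete and for unrestrained reference runs to
spread over the target basin — a shorter protocol systematically
underestimates the reference RMSD. One protocol is used for restrained,
unrestrained and reference runs alike. The equilibration fraction (0.5)
reflects this engine's relaxation times, not the all-atom protocol's.

## Reference RMSD and the benchmark

For a single target model, RMSD_r is the aligned RMSD between the target and
the central structure (most neighbours within 1 Å) of pooled production
frames from unrestrained runs started at the target; the pool is thinned to
at most 150 frames so the O(n²) neighbour count stays cheap. For NMR-bundle
targets, RMSD_r is the mean pairwise aligned RMSD over distinct models. The
variant is chosen automatically from the target type. Note that in a
high-dimensional thermal ensemble every sample sits near the shell radius,
so the central-structure RMSD_r is close to the basin's thermal radius
rather than to zero. For broad, soft target basins the statistic has
substantial replicate-to-replicate variance — which dense clump of pooled
frames wins the neighbour count depends on where individual runs lingered —
and this is precisely the regime in which the bundle-mean-pairwise variant
is the better-behaved reference; the benchmark reports whichever variant the
target type selects and treats the value as part of the seeded protocol.

The benchmark averages aligned RMSD-to-target over production frames within
each replicate first, then over replicates; the standard error is over
replicate means. Success per row means the mean is below RMSD_r. Normalized
RMSD is exactly 1 at N_r = 0 by construction and 0 when the mean equals
RMSD_r; it can be negative when restrained runs get closer than the
reference fluctuation scale. Per-cell failures are recorded in the table
rather than raised. Everything is bitwise reproducible given the config
seed.

## Synthetic fixtures

The hinge generator emulates an open↔closed two-lobe protein at Cα
resolution: two compact serpentine lattice-walk lobes (spacing 3.8 Å,
jitter 0.25 Å) joined by a ten-residue ribbon linker that zig-zags in one
plane (amplitude 1.7 Å). The ribbon's width stiffens out-of-plane bending
and torsion, so the soft collective direction of an elastic network built on
the fixture is the in-plane elbow bend — the closing motion, as in real
hinge proteins. A perfectly straight linker instead leaves torsion and
bending about its axis as spurious near-zero modes. The initial conformation
is pre-bent 35° (lobes in contact near the elbow → metastable under the
engine); the target opens a further 30° about the hinge axis through the
linker start, by default — the direction in which the target basin is soft,
mirroring a bound→unbound transition. Domain-internal distance matrices are
exactly identical between conformers, so every changed separation spans the
hinge and the brute-force largest-|ΔR| pair is a known ground truth for
parameter-recovery tests. Clash-free construction is checked (non-local
cross-domain pairs ≥ 3 Å) with bounded seeded retries.

What the fixture does *not* emulate: side chains, sequence, anharmonic
force-field frustration, solvent, or a target that is a genuine second
minimum of the baseline potential. Passing benchmarks on the fixture shows
the machinery is correct and that the selection logic recovers known ground
truth at realistic geometry scales; it does not certify performance on real
force fields. Because the baseline network has a single minimum at the
initial structure, late restraints can compete with it and the RMSD-versus-
N_r curve can show a small (≲0.1 Å) non-monotonic wiggle once the genuinely
informative pairs are exhausted — the same regime the restrained-MD
literature reports when the target is not a minimum of the force field.

NMR-like bundles add chain-smoothed Gaussian displacements (kernel σ = 3
residues) rescaled to an exact per-residue RMS amplitude, so bundle spread
is monotone in the noise scale by construction. Correlation-engineered
trajectories realise a requested pair-distance correlation matrix via a
Cholesky factor of latent Gaussian series, displacing each pair's second
residue along the pair axis; infeasible (non-PSD) matrices and residue-
sharing pairs are rejected.

## Problem sizes

Tests and the acceptance script use the 80-residue, 30° fixture; ensembles
of 10²–10³ structures for sampling checks; 8 ns engine runs with 10
replicates per benchmark cell and 3 replicates per selection iteration; toy
systems of ≤ 10 residues wherever an exhaustive or analytic oracle is
compared. The full-scale protocol (10⁴ normal-mode structures, 50–100
replicates, real PDB inputs) is available through the same interfaces.

## Known limitations

- The engine is a Cα elastic-network surrogate: no force-field realism, no
  explicit solvent, single-basin baseline (see above).
- Residue correspondence is by identifier intersection; conformer pairs with
  different numbering need pre-renumbering.
- mmCIF input is not supported; altloc handling keeps the highest-occupancy
  conformer only.
- The LDA method inherits the linearity limitation discussed in the
  literature: for large proteins the leading discriminant direction need not
  capture the transition coordinate.
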