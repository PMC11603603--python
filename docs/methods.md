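# Methods

## Scope and model

`nohcg` implements a bottom-up coarse-graining workflow for protein-like
systems built around four ideas:

1. **A no-hydrogen (noh) map.** Every heavy atom becomes one bead; hydrogens
   (and solvent) are removed. The map on coordinates is a pure selection
   `R = Ξ r`. Each bead is labelled by an integer embedding derived from
   `(element, number of bonded hydrogens)`; over the 20 standard amino acids
   at standard protonation (ASP/GLU deprotonated, LYS/ARG protonated, neutral
   His) exactly 12 classes occur: C0–C3, N0–N3, O0, O1, S0, S1. Bead masses
   are the heavy-atom mass plus the masses of its bonded hydrogens, so the
   CG system carries the full fine-grained mass.

2. **Basic force aggregation.** The reference force on bead *i* is the force
   on its heavy atom plus the forces on the hydrogens bonded to it,
   `F_i = f_i + Σ_{h∈H_i} f_h`. Because the hydrogen sets partition the
   hydrogens, the total force is conserved identically — a property the test
   suite asserts to machine precision rather than to a tolerance.

3. **Variational force matching.** The CG potential `U(R, z; θ)` is fitted by
   minimizing the mean squared deviation between its negative coordinate
   gradient and the aggregated forces,

       L(θ) = (1/K) Σ_k 1/(3 N_k) Σ_{i,α} ( -∂U/∂R_{k,iα} - F_{k,iα} )²,

   with `K` conformations per batch and `N_k` beads in conformation `k`.
   The normalization is per force *component* (the factor `3 N_k`), making
   the loss an expected squared error in (kcal/mol/Å)² independent of system
   size; a per-bead convention would only rescale the learning rate. No
   energy labels are used (none exist at CG resolution) and the model has no
   prior terms: at `θ = 0` the predicted forces are identically zero, which a
   test asserts.

4. **Thermodynamic-consistency analysis.** Simulated CG trajectories are
   validated against the free-energy landscape they were trained to
   represent, via Cα-distance features, TICA projection, k-means
   microstates, a reversible MSM and weighted free-energy surfaces.

## The potential

The trainable potential is a sum of type-pair radial terms,

    U(R, z; θ) = Σ_{i<j, r_ij<r_c} θ[p(z_i,z_j), :] · φ(r_ij),

with `φ` a bank of Gaussian radial basis functions (default 32, centres
uniform on (0, r_c), width equal to the spacing) under a cosine cutoff
envelope that takes the energy and its gradient smoothly to zero at the
receptive field `r_c` (default 10 Å). `p` indexes unordered embedding pairs.
Because the energy depends on interatomic distances only, translation,
rotation and reflection invariance of the energy — and the corresponding
equivariance of the forces — hold exactly, not approximately; a scalar
CG energy requires nothing stronger than invariance. The analytic forces are
the exact negative gradient; a central-difference check is part of the test
suite.

The model is deliberately linear in θ. That buys three things: the
force-matching problem has a closed-form normal-equations solution
(`fit_least_squares`) that serves as an independent oracle for the
mini-batch Adam trainer; the per-batch loss reduces to cached quadratic
forms `(A, b, c)`, so epochs cost `O(P²)` regardless of dataset size; and
training to data generated by a model in the hypothesis class provably
recovers it. Parameter columns belonging to type pairs never seen in the
data are frozen at zero (the loss is flat along them). Nonlinear
message-passing architectures would slot in behind the same
`energy/forces/force_features` surface but are not part of this package.

Neighbor search is an exact all-pairs cutoff list. Every system in scope
(toy molecules, sub-1000-bead domains) is far below the size where a cell
list pays for itself, so none is provided.

## Dynamics

CG beads are propagated with BAOAB-split Langevin dynamics: half kick, half
drift, exact Ornstein–Uhlenbeck velocity refresh, half drift, half kick.
BAOAB was chosen for its configurational accuracy at large timesteps; with
zero friction and zero temperature it reduces exactly to velocity Verlet,
which the energy-conservation test exploits. Defaults follow the package's
simulation protocol: 4 fs timestep, 1 ps⁻¹ friction, 350 K, aggregated bead
masses. One force evaluation per step (forces are cached across the B
sub-steps). Units are Å, fs, a.m.u., kcal/mol throughout, with
k_B = 0.0019872041 kcal/(mol·K) and the single conversion constant
4.184·10⁻⁴ (Å/fs)² per (kcal/mol)/a.m.u. centralized in `nohcg.units`.
Simulations are vacuum and unconstrained: all interactions, including
anything long-range, live inside the potential's receptive field.

## Dataset curation

Training data live in per-domain HDF5 groups with one subgroup per
simulation temperature (an mdCATH-like layout at reduced complexity;
float32 coordinates/forces, int64 embeddings, metadata as group
attributes). Curation keeps domains with **at most** 150 residues, **at
most** 1000 noh atoms and **at least** 50 % combined helix+sheet content —
boundaries inclusive, reading the exclusion rules literally ("more than
150" excludes only strictly larger domains). A band-pass variant
(150–250 residues, ≥50 % structure) selects the scale-up evaluation set.
Helix/sheet fractions are read from metadata; no secondary-structure
assignment is implemented. The five temperatures 320/348/379/413/450 K are
pooled as a flat frame list — multiple temperatures broaden the sampled
configuration space; temperature is carried as metadata, not as a model
input. Frames are subsampled with a stride (default 25) and split
train/validation/test by a seeded shuffle at frame granularity (a
domain-level split is available via grouping by `domain_ids`).

Relative shape anisotropy is computed from the gyration-tensor eigenvalues,
κ² = 1 − 3(λ₁λ₂+λ₂λ₃+λ₃λ₁)/(λ₁+λ₂+λ₃)²: 0 for spherically symmetric
arrangements, 1 for collinear ones, invariant under similarity transforms.

## Synthetic systems: what they emulate and what they do not

The toy generator produces chains of heavy "carbon" sites carrying 0–4
satellite hydrogens on stiff harmonic bonds (k = 340 kcal/mol/Å²,
r₀ = 1.09 Å), harmonic heavy–heavy bonds and angles, and Lennard-Jones
contacts between heavy sites three or more bonds apart. Hydrogens are
light and stiffly bonded so their fluctuations are fast, making the
aggregated force labels a low-noise estimator of the CG mean force — the
same premise that justifies absorbing constrained hydrogens into beads.
Gaussian force noise of known width can be injected to emulate the noisy
labels of real CG force matching and to give trainer tests a known noise
floor.

The reference system is the **CG-solvable dimer**: two CH₃-like beads whose
heavy–heavy bond is a tilted quartic double well
`a((r−r₀)²−w²)² + t(r−r₀)` with r₀ = 4 Å, w = 0.5 Å and a = 32 kcal/mol/Å⁴
(2 kcal/mol barrier). The tilt is solved by root finding so that the basin
free-energy difference is exactly 1 kcal/mol at 350 K. Because the
hydrogens interact only with their own heavy site, their forces cancel
exactly within each bead and the exact CG free energy along the bond length
reduces to one dimension: `G(r) = U_b(r) − 2 k_B T ln r`, normalized by
quadrature. This is the analytic oracle for the flagship end-to-end
property.

These fixtures are statistical stand-ins: they have no secondary structure,
no electrostatics, no solvent and no real protein energetics. Passing the
end-to-end test shows the *machinery* (mapping, aggregation, training,
integration, analysis) is consistent; it says nothing about force-field
accuracy on real proteins, which would require training at dataset scale.

## The end-to-end benchmark

`synthetic_systems.dimer_pmf_recovery` runs the whole pipeline under fixed
study conditions: 10 000 all-atom frames sampled at each of the five pooled
temperatures (50 000 coordinate–force pairs; 0.5 fs sampling timestep to
resolve the stiff hydrogen bonds, 10 ps⁻¹ friction, frames every 10 steps
after 4 000 steps of burn-in), label noise σ = 1 kcal/mol/Å, force-matching
training (Adam, 800 epochs, batch 512, learning rate 5·10⁻² with 0.997
per-epoch decay), then a 10⁶-step CG Langevin run at 4 fs / 1 ps⁻¹ / 350 K
from the deeper well. The simulated bond-length free energy — histogram
bins of the analytic PMF grid (80 bins over r₀ ± 1 Å) with at least 25
samples — is compared to the quadrature result after min-shifting both.
The multi-temperature pool matters for more than variability: the hottest
replicas sample the repulsive walls a 350 K run rarely visits, so the
learned potential is anchored over the whole region the CG simulation can
reach and the run cannot drift into unlearned, spuriously flat territory.

## Numerical choices

- **TICA** uses the symmetrized covariance estimators, which keep the
  generalized eigenvalues real and ≤ 1; a relative ridge (10⁻¹⁰ of the mean
  covariance trace) is added only when the instantaneous covariance is not
  positive definite, and is reported on the model (strict mode raises
  instead). Components: 4 for fitting, 2 for surfaces, 3 when projecting CG
  data with the all-atom basis; all are arguments.
- **MSM**: sliding-window counts at the chosen lag after discarding the
  leading 10 % of each trajectory (5 % is an argument for long runs);
  largest strongly connected state set, weighted by transition counts so an
  isolated self-looping state cannot win; reversible maximum-likelihood
  estimation by the standard fixed-point iteration on the symmetric flux
  matrix (tolerance 10⁻¹² on the stationary vector), with a non-reversible
  row-normalized fallback.
- **Free-energy surfaces** weight each frame by stationary probability of
  its microstate divided by the microstate's frame count, bin the first two
  projection columns on an 80×80 grid spanning the data range, and report
  `−ln p` in k_B T units min-shifted to exactly 0; empty bins are NaN and
  flagged.
- **Macrostates** are a lightweight spectral lumping (k-means on the leading
  right eigenvectors of the transition matrix); the native macrostate is the
  one containing the minimum-RMSD frame under Kabsch superposition with a
  proper-rotation determinant correction.
- **Degenerate inputs**: unbonded or multiply-bonded hydrogens, unknown
  `(element, n_H)` pairs, non-finite forces mid-simulation, empty batches,
  singular covariances and disconnected chains all raise typed errors
  naming the offending object; a permissive typing mode extends the bead
  table instead for nonstandard chemistry (terminal OXT, unusual
  protonation), since the `(element, n_H)` rule generalizes beyond the
  canonical 12.
- **Precision**: float32 on disk for trajectories and datasets, float64 for
  all oracles and analysis.

## Design choices that were genuinely open

- **Loss normalization.** Mean over components (`3 N_k`) rather than beads;
  either convention differs by a constant factor and rescales the learning
  rate only. Documented above and frozen in `force_matching_loss`.
- **Split granularity.** Frame-level seeded splits by default (matching the
  granularity at which conformation counts are quoted); domain-level
  splitting is achievable through the recorded `domain_ids`.
- **Stride placement.** The stride is applied to the stored frame order,
  which is per-domain/per-temperature contiguous — i.e. per-trajectory for
  single-trajectory inputs. The count identity |train|+|val|+|test| =
  ⌈N/stride⌉ holds regardless.
- **Integrator.** Any Langevin discretization would satisfy "a Langevin
  thermostat"; BAOAB was picked for its configurational accuracy at the
  4 fs default timestep, and its exact velocity-Verlet limit gives a sharp
  correctness test.
- **Bead-type ids.** Assigned by sorting `(element, n_H)`; the ids are a
  package convention, stable across runs and machines.
- **Bond inference.** When a structure file lacks connectivity, each
  hydrogen is attached to its nearest heavy atom within 1.2 Å — covalent
  X–H bonds are 0.96–1.09 Å while hydrogen-bond contacts start near 1.5 Å,
  so the cutoff is unambiguous for chemically sound structures.

## Problem sizes

The shipped tests and the acceptance script use the sizes quoted above
(50 000 training frames, 10⁶ CG steps for the dimer benchmark; 1.2·10⁵
thermostat steps; 2·10⁵-step telegraph chains; 3·10⁵-sample Gaussian
surfaces; three pooled 3·10⁵-step replicas for the MSM pipeline check).
These were chosen as the smallest sizes at which the statistical error of
each estimate sits comfortably inside the assertion tolerance, so the tests
probe correctness rather than luck.

## Known limitations

- The trainable potential is pairwise; it cannot represent genuinely
  many-body CG free-energy contributions. For the toy systems this is exact
  by construction; for real proteins it would be a modelling error.
- The reversible MLE assumes the largest connected set dominates; weakly
  connected fringe states are silently dropped (reported via `connected`).
- `estimate_msm`'s discard fraction assumes trajectories are passed whole;
  pre-sliced label arrays would be discarded again.
- The PDB reader handles single-model protein files with {C,N,O,S,H}
  chemistry; ligands, ions and waters must be stripped beforehand.
- Macrostate lumping by eigenvector k-means is a heuristic stand-in for
  PCCA+; for well-separated metastable basins (the use case here) they
  agree.
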