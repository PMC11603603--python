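# nohcg

No-hydrogen coarse-graining for protein-like systems: a heavy-atom bead
representation with force aggregation, a force-matched pair potential,
BAOAB Langevin dynamics, and MSM/TICA free-energy analysis — exercisable
end to end on synthetic toy systems with closed-form reference physics.

## Who this is for

All-atom molecular dynamics resolves protein motion in detail but at a cost
that makes slow conformational processes expensive to sample. A common
remedy is coarse-graining (CG): simulate fewer interaction sites under an
effective potential that reproduces the fine-grained thermodynamics. This
package is for people building and validating *bottom-up* CG models of
proteins — it provides the mapping, data curation, training, simulation and
analysis layers, each testable against exact oracles on toy systems.

## The model

**Mapping.** One bead per heavy atom; hydrogens are deleted and solvent is
implicit. Each bead gets an integer embedding from
`(element, n bonded hydrogens)` — exactly 12 classes over the 20 standard
amino acids — and a mass equal to heavy atom plus bonded hydrogens. The
reference force on bead *i* aggregates its hydrogens:

    F_i = f_i + Σ_{h ∈ H_i} f_h

which conserves total force exactly.

**Force matching.** The CG potential `U(R, z; θ)` (a type-pair radial-basis
expansion inside a 10 Å receptive field, exactly invariant under rigid
motions, with no prior energy terms) is trained by minimizing

    L(θ) = (1/K) Σ_k 1/(3 N_k) || −∂U/∂R_k − F_k ||²

over coordinate–force pairs. Predicted forces are the analytic negative
gradient. Because the model is linear in θ, a closed-form least-squares
solution exists and cross-checks the mini-batch trainer.

**Dynamics.** BAOAB-discretized Langevin dynamics (default 4 fs, 1 ps⁻¹,
350 K) with aggregated bead masses.

**Analysis.** Cα-distance features → TICA projection → k-means microstates
→ reversible MSM → equilibrium-weighted free-energy surfaces (80×80 grid,
k_B T units) and native-macrostate RMSD statistics via Kabsch
superposition.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

The solvable reference system is a two-bead "dimer": two CH₃-like heavy
sites on a tilted double-well bond, each carrying three stiff satellite
hydrogens. Its exact CG free energy along the bond length is known by
quadrature, so the whole pipeline can be scored against ground truth:

```python
from nohcg.synthetic_systems import dimer_pmf_recovery

result = dimer_pmf_recovery(seed=1)
print(f"training frames : {result['n_training_frames']}")
print(f"final loss      : {result['history']['train_loss'][-1]:.3f} (kcal/mol/A)^2")
print(f"populated bins  : {int(result['populated'].sum())}")
print(f"max PMF error   : {result['pmf_max_error']:.3f} kcal/mol")
```

Output (about five minutes on one CPU core):

```
training frames : 50000
final loss      : 3.997
populated bins  : 61
max PMF error   : 0.139 kcal/mol
```

What the numbers mean: 50 000 coordinate–force pairs are sampled from the
all-atom toy force field across five pooled temperatures (320–450 K) and
aggregated onto beads. The converged force-matching loss of ≈4 (kcal/mol/Å)²
is the injected label-noise floor — σ = 1 kcal/mol/Å per atom and four atoms
per bead — so the model has extracted all learnable signal. A 10⁶-step
Langevin run under the learned potential then reproduces the analytic
bond-length free energy to 0.14 kcal/mol (about k_BT/5) across all 61
populated histogram bins, including the 2 kcal/mol barrier and the designed
1 kcal/mol basin asymmetry.

The same machinery is exposed as a CLI for file-based workflows:

```sh
nohcg make-fixtures --out fixtures/ --seed 7
nohcg build-dataset --in fixtures/fixtures.h5 --out cg --stride 25 --seed 1234
nohcg train --data cg.train.h5 --val cg.val.h5 --out model.npz --epochs 100
nohcg simulate --model model.npz --data cg.train.h5 --steps 100000 --out traj.h5
nohcg analyze --traj traj.h5 --lag 20 --clusters 50
```

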