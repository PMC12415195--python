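# dimerpath

Committor-guided transition path sampling (TPS) and ensemble analysis for
transmembrane-helix dimerization, with synthetic systems carrying known
ground truth.

## The problem

The association of two transmembrane (TM) helices — e.g. the dimerization of
the STIM1 TM domain that relays calcium-store depletion across the ER
membrane — is a rare event: unbiased simulation spends almost all of its time
in the separated or dimerized basins and almost never on the transitions
between them. Transition path sampling concentrates the computation on the
transitions themselves, and the *committor*

    pB(x) = P(trajectory from x reaches the dimerized state B before the separated state A)

is the ideal reaction coordinate for analyzing them. This package implements
the AI-guided variant of that workflow: a neural network learns pB(x) on the
fly from two-way-shooting outcomes, the learned committor steers the choice of
shooting points toward the transition state ensemble (TSE, pB ≈ 0.5), and the
resulting path ensemble is dissected into transition channels, bound-state
clusters, flow matrices, per-residue importance scores and a distilled
two-contact committor formula. A three-cube sensitized-emission FRET module
quantifies dimerization propensity on the experimental side.

Because the original atomistic data are out of reach at desk scale, the
package ships two synthetic systems with computable ground truth:

* a **2D Brownian-dynamics landscape** with one reactant basin, two transition
  channels and three product basins, plus a brute-force committor oracle;
* a **pseudo-helix-pair generator** (37 residues, 206–242) producing
  parallel (‖), X, Λ and separated archetypes with planted labels.

## Core definitions

* Switching function: σ(d) = 1 / (1 + (d/r0)^12), the algebraically
  simplified form of (1 − (d/r0)^12)/(1 − (d/r0)^24).
* Descriptors (77): 37 backbone and 37 sidechain equivalent-residue distances
  switched at r0 = 1.7 nm, the switched helix–helix center-of-mass distance,
  and both tilt angles divided by π.
* States: *separated* if every interhelical point distance exceeds 1.4 nm;
  *dimerized* if the contact count NC > 25 (contacts at 0.45 nm) or the
  contact function Σ = Σ_{211 ≤ r = r′ ≤ 226} σ(d_SC(r,r′); r0 = 1 nm)
  exceeds 8.5.
* Committor model: pyramidal stack of 5 self-normalizing (SELU) layers
  tapering 77 → 11, then 3 residual blocks of 4 layers at width 11, scalar
  logit q, pB = logistic(q); trained with Adam on the binomial shooting loss
  at lr = 0.001 · min(1, (1 − nTPgen/nTPpred)²) every 10th MC step for 5
  epochs (skipped below lr = 1e−5).
* Two-way shooting: two trials with independent noise from a shooting point
  selected with weight ∝ exp(−q²); a path is generated when the trials reach
  different states and accepted with min{1, p_sel(x|new)/p_sel(x|old)}.
* Distilled two-contact committor:
  pB2D = σ_G225 · exp(−5.9 · (σ_G225 σ_V217 − 0.04) · (σ_V217 − 1)).
* FRET: Eapp = (IFRET − a·IYFP − b·ICFP) / (IFRET − a·IYFP + (G − b)·ICFP)
  per pixel, with a, b calibrated from single-fluorophore samples and
  G = 2.75.

## Worked example

```python
import numpy as np
from dimerpath import ToyLandscapeSpec, learn_toy_committor, brute_force_committor
from dimerpath.pipeline import transition_region_grid, committor_grid_rmse

spec = ToyLandscapeSpec()
run, model, dynamics = learn_toy_committor(spec, seed=1, n_steps=60,
                                           n_preliminary=100, k_models=2)
print(f"MC steps: {len(run.results)}, transition paths generated: {run.n_generated}")
sw = [c.switches / (c.accepted - 1) for c in run.chains if c.accepted > 1]
print(f"mean bound-state switch fraction: {np.mean(sw):.2f}")

grid = transition_region_grid(spec, n=7)
oracle = brute_force_committor(spec, grid, 200, seed=2)
print(f"committor RMSE vs brute-force oracle on {len(grid)} grid points: "
      f"{committor_grid_rmse(model, dynamics, oracle):.3f}")
```

Output (a couple of minutes on one core):

```
MC steps: 900, transition paths generated: 313
mean bound-state switch fraction: 0.51
committor RMSE vs brute-force oracle on 37 grid points: 0.046
```

313 of 900 two-way shots produced a transition path — the committor-guided
shooting-point selection is doing its job (blind shooting from the basins
would produce essentially none). A switch fraction of 0.51 means every second
accepted path terminated in a different product basin, i.e. the Monte Carlo
chains mix well across dimerization pathways. The learned committor agrees
with the 200-shot brute-force oracle to 0.046 RMSE across the transition
region; the default, longer pipeline (`n_steps=300`, `k_models=5`) brings
this to ≈ 0.03.

A command-line layer mirrors the library (`dimerpath toy simulate`,
`dimerpath toy committor-grid`, `dimerpath toy archetypes`, `dimerpath tps
run`, `dimerpath tps validate`, `dimerpath fret calibrate`, `dimerpath fret
eapp`).

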