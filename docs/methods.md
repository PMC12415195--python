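# Methods

## Scope and design

The package implements a committor-guided transition-path-sampling (TPS)
workflow for two-state association processes, specialized to
transmembrane-helix dimerization: featurization and state definitions for a
two-helix system, a neural committor model trained on shooting outcomes,
two-way-shooting TPS in parallel Monte Carlo chains, path-ensemble analytics,
permutation-based input importance with symbolic distillation, and three-cube
sensitized-emission FRET quantification. Everything is exercised on synthetic
systems with computable ground truth; no force field, membrane or solvent is
modeled, and no atomistic fidelity is claimed.

## The toy dynamical system

**Model.** Overdamped Langevin dynamics (Euler–Maruyama),
x' = x − (dt/γ)∇V + √(2kT dt/γ)·ξ, on a 2D potential: a quadratic confining
background (coefficient 0.5), four inverted Gaussian wells (reactant A at
(−1.2, 0); products B1/B2/B3 at x = 1.2, y = 0.9/0/−0.9; depth 4 kT, widths
0.30–0.35), and a Gaussian barrier ridge along x = 0 (height 6 kT, width
0.25) pierced by two channel gaps at y = ±0.5 (gap depths 4.8 and 4.2, widths
0.4). Units: kT = 1, γ = 1, dt = 5·10⁻⁴ (dt × maximum curvature ≈ 0.05,
comfortably stable). States are discs of radius 0.3 around the well centers.
The domain is the box [−3, 3]² with reflecting edges; the confinement makes
boundary visits rare, so the reflection is a numerical guard, not a feature
of the dynamics.

**Why these numbers.** Barrier heights of ≈ 4.8–5.4 kT above the A minimum
give mean first-passage times of order 10⁴–10⁵ steps, so that committor
oracles, validation shots and direct transition-path harvesting all run at
desk scale while transitions remain genuinely rare on the step scale. The
two gap depths differ so the two reaction channels carry asymmetric weight
(≈ 60/40 in direct simulation) — controllable ground truth for
channel-population tests. The channel gaps overlap enough (separation 1.0,
width 0.4) that sampled paths can cross between channels; with well-separated
channels each MC chain froze in one channel, contradicting the behavior of
the system being emulated, whose two transition-state clusters are strongly
connected and whose chains switch bound states roughly every second accepted
path. The revised geometry reproduces that switching rate (≈ 0.5).

**Velocity randomization.** The dynamics are overdamped, so the "two-way"
character of a shot comes entirely from independent noise streams; there are
no velocities to randomize. The committor and the TPS machinery are agnostic
to this choice.

**Channel and basin labels.** A transition path's channel is the sign of y
at its last crossing of x = 0 (interpolated); its bound-state label is the
product basin entered. The brute-force committor of any point is the
fraction of independent trajectories reaching any B basin before A, with a
Wilson 95% CI; shots exhausting the step cap are counted separately and a
warning is raised if they exceed 10%.

## Pseudo-helix pairs

Backbone anchors lie on an ideal α-helical curve (rise 0.15 nm/residue,
radius 0.23 nm, twist 100°/residue, 37 residues = 206–242); sidechain tips
sit 0.25 nm radially outward. A pair is parameterized by inter-axis distance,
crossing angle (split symmetrically about the pivot), pivot position along
the axis, per-helix phase, axial offset and isotropic positional noise.
Archetypes: parallel (d = 1.05 nm, facing phases), X (d = 0.85 nm, crossing
angle 45°, pivot mid-helix — closest approach near residue 224), Λ (d = 0.90
nm at the C-terminal pivot, 30°, matched phases — the per-residue distance
profile decreases monotonically from N- to C-terminus), separated (d = 6 nm).
"Heavy atoms" are approximated by the union of anchors and tips. Planted
archetype labels are stored in each configuration's metadata as clustering
ground truth.

## Featurization and states

Distances are mapped to [0, 1] by σ(d) = 1/(1 + (d/r0)^12), implemented in
the simplified form to avoid the removable 0/0 of the literal
(1 − x¹²)/(1 − x²⁴) at d = r0 (the two agree to 10⁻¹² elsewhere; the
simplified form underflows to exactly 1.0 for d ≲ 0.3·r0 in float64, which is
the correct limit). The 77-entry descriptor vector is ordered: backbone
206→242, sidechain 206→242 (glycines substitute the backbone anchor), switched
center-of-mass distance, tilt1/π, tilt2/π. Tilt is the angle between the
N→C-oriented principal component of the backbone anchors and +z; for a finite
helix with a non-integer number of turns this axis deviates from the
geometric axis by a fraction of a degree, which is below any threshold used
here. The descriptor ordering is frozen and hashed; model checkpoints carry
the hash and refuse to load against a different ordering.

States: separated iff the minimum interhelical point distance exceeds 1.4 nm;
dimerized iff NC > 25 or Σ > 8.5, where Σ sums σ(d_SC; r0 = 1 nm) over the 16
equivalent-residue pairs 211–226. A "contact" for NC is an interhelical
residue pair with minimum point-to-point distance below 0.45 nm — the same
contact scale used by the contact-frequency map; the counting unit (residue
pairs, not atom pairs) is a package choice since no finer convention is
available for the anchor/tip representation. The two state criteria cannot
hold simultaneously (sub-nm contacts versus all distances > 1.4 nm); the
classifier asserts this.

## Committor model and training

Architecture: 5 self-normalizing layers (SELU, LeCun-normal initialization)
tapering geometrically 77 → 47 → 29 → 18 → 11, then 3 residual blocks of 4
SELU layers at width 11 with identity skips, then a zero-initialized linear
head — an untrained model predicts pB = 0.5 everywhere, the correct
uninformed prior. The taper between the printed end widths is geometric
because no intermediate widths are prescribed; the widths are recorded in
every checkpoint. For the 2D toy system the same architecture is built on a
2-wide input.

Loss: the binomial negative log-likelihood of shooting outcomes,
L = −Σᵢ [nAᵢ log(1 − p(xᵢ)) + nBᵢ log p(xᵢ)], the standard likelihood for
two-way shooting; results whose trials both hit the step cap are excluded
from the counts (censored) but retained in the record. Optimization is Adam
(β = 0.9/0.999) on minibatches of 128 (256 in postprocessing). On-the-fly
schedule: training after every 10th MC step for 5 epochs at
lr = 0.001 · min(1, (1 − nTPgen/nTPpred)²) counted over the trailing 100 MC
steps, skipped when lr < 10⁻⁵; on a cold window with no predicted paths the
base rate is used with a warning. All recorded shooting results (accepted
and rejected moves alike) form the training set.

The network, backpropagation and Adam are implemented directly in numpy; at
these widths a framework would add nothing but a dependency. Gradients are
verified against finite differences in the test suite.

## TPS engine

Shooting points are drawn from the current path's intermediate frames with
weight w ∝ exp(−q²) (no extra temperature parameter; logits clipped at
|q| = 18 for the weight only); if all weights vanish, selection falls back to
uniform with a warning. Two trials are launched with independent seeds and
propagated until a state is hit or the trial cap (default 4·10⁵ steps, two
to three orders of magnitude above typical commitment times) is reached. A
generated path (trials in different states) is assembled as the reversed
A-trial plus the B-trial and accepted with
min{1, p_sel(x_sp | new)/p_sel(x_sp | old)} — the standard detailed-balance
correction for selection biased along the current path. Chains share the
model but own their RNG streams; training uses the pooled result store. Runs
are exactly reproducible given the seed.

The estimator for path-ensemble populations weights each chain's current path
at every MC step (rejected moves repeat the old path). For statistical
comparisons the package uses the number of *accepted* moves as the effective
sample size, because per-step occupancy within a chain is autocorrelated.
Correctness is validated empirically: occupancy channel weights and
terminal-basin populations agree with a brute-force transition-path ensemble
harvested from long direct simulation, under both uniform and
committor-guided selection.

Diagnostics mirror standard practice: the cumulative generated path count
N_generated against the on-the-fly expectation N_expected = Σ 2p(1−p), their
flattening difference after burn-in, per-chain bound-state switching
fractions, and predicted-versus-sampled validation committor scatter.

## The learning pipeline

`learn_toy_committor` chains: (1) harvest a handful of initial transition
paths from direct simulation (steered seeding is MD-specific and out of
scope); (2) 300 preliminary two-way shots with *uniform* selection along the
initial paths — before a model exists nothing justifies biased selection, and
these shots give the data set coverage of the near-state regions that guided
selection later avoids; (3) a guided run of 15 chains × 300 sweeps with
on-the-fly training; (4) retrain-and-select: 5 fresh models are trained for
250 epochs on the pooled data and the one agreeing best (RMSE) with
independent validation committor shots — 20 points stratified across the
predicted-pB range, 40 one-way shots each — is selected as the analysis
model. Selection against independent committor shots, rather than a held-out
slice of the shooting data, directly probes calibration across the whole
transition and is markedly more reliable; single retrained models vary by
roughly a factor of two in oracle RMSE, the selected one lands at ≈ 0.03–0.04
against a 500-shot oracle (whose own sampling noise contributes ≈ 0.02).

The "transition region" grid for oracle comparisons spans the rectangle
between the state boundaries, restricted to thermally accessible points
(potential at most 1 kT above the higher channel saddle) — i.e. the support
of the shooting-point distribution, which is where a committor model is
constrained by data and meaningful.

## Ensemble analytics

TSE extraction takes frames with pB ∈ [0.45, 0.55] (configurable band; a
path's nearest-to-0.5 frame as fallback). BSE extraction takes each path's
first dimerized frame (paths terminate on state entry, so this is the final
frame for the toy system). BSE clustering is k-means (k = 3 by default,
10 restarts) on sidechain-distance vectors; TSE clustering is k-medoids
(k = 2, alternating Voronoi updates, 10 restarts, best cost) so every
representative is an actual ensemble member — the in-package PAM-style
implementation is small and deterministic under its seed. k is configurable
and a silhouette scan can be run when the cluster count is unknown.
Committor–distance correlations are Pearson coefficients of each
equivalent-residue sidechain distance against pB, pooled over path frames
(per-path averaging available); the sign convention makes contact formation
during the transition *negative*. Zero-variance distances report NaN, not 0.
Isocommittor profiles average sidechain distances over frames within ±0.05
of each level per channel. Contact frequency is the frame-average of
σ(d; 0.45 nm) on minimum interresidue distances. Binding initiative: for
each contact, the earliest formation time after which the contact persists
in > 90% of the remaining frames; the remaining-runtime fraction is min–max
normalized across contacts, so the earliest persistent contact scores 1 and
the latest 0 (never-persistent contacts report NaN; if all persistent
contacts tie — including the single-contact case — they score 1 as joint
"first").

## Importance and distillation

Permutation importance: on the subsets {pB ≤ 0.2}, {pB ≥ 0.2} (model-predicted)
and the full set, the reference shooting loss is compared with the loss after
permuting one descriptor column within the subset, 100 permutations by
default; the score is the mean relative increase (l_perm − l_ref)/l_ref with
its SD. Permutations are within-subset, matching the subset-wise reference
loss.

The distilled two-contact committor is
pB2D = σ_G225 · exp(−5.9 · (σ_G225 σ_V217 − 0.04) · (σ_V217 − 1)), clipped to
[0, 1] for reporting. **Caveat:** the printed source of this expression is
typographically flattened and its exponent grouping is ambiguous; the parse
above is the only grouping found consistent with both documented qualitative
properties (pB2D exceeds 0.5 with the V217 contact absent — its maximum there
is e^(−0.236) ≈ 0.79 — and the G225 contact has the larger impact on a grid).
Any reading against the originally deposited code should revisit this parse;
it must not be silently substituted.

The distillation fitter evolves small expression trees over
{+, −, ×, ÷, exp, pow} (guarded division, clipped exponents) with a
(1+λ) strategy for up to 500 generations, minimizing the mean binomial
shooting loss plus 0.001 per elementary operation. A parametric family
σ₁·exp(−a(σ₁σ₂ − b)(σ₂ − c)) is always fitted by maximum likelihood
(Nelder–Mead) as a deterministic fallback, and the better of the two by
penalized loss is returned; if neither beats the constant model, the constant
is returned with a warning.

## Proportion statistics

The two-proportion z-test uses the pooled standard error with a normal
two-sided p-value; a pooled proportion of exactly 0 or 1 is degenerate and
returns (z, p) = (0, 1) with a warning. Binomial CIs default to the Wilson
score interval (Clopper–Pearson via `method="beta"`). Pointwise coverage of
any discrete-data interval oscillates with (n, p) — at n = 20, p = 0.3 the
Wilson interval covers with probability 0.9752, identical to Clopper–Pearson
and Agresti–Coull there — so coverage is assessed averaged over p (exact mean
0.9575 over a uniform grid at n = 20), the standard practice for discrete
intervals.

## FRET quantification

Eapp = (IFRET − a·IYFP − b·ICFP)/(IFRET − a·IYFP + (G − b)·ICFP) per pixel.
Background is a per-channel scalar subtraction clipped at zero. Masking keeps
pixels with both channels above background and donor:acceptor ratio in
[0.01, 100] (the reading of "0.1:10 to 10:0.1"); masking never alters
per-pixel values, only inclusion, and non-positive denominators are excluded
and counted. Calibration factors a and b are Siegel repeated-median slopes of
the FRET channel against the acceptor (acceptor-only sample) and donor
(donor-only sample) channels — robust to a minority of aberrant pixels; G is
instrument-specific (default 2.75). The synthetic generator inverts the same
model (ICFP = D(1−E), sensitized emission G·D·E plus cross-excitation and
bleed-through, optional Poisson shot noise), so the quantification chain
recovers the planted efficiency exactly in the noise-free case for any
(a, b, G) — a round-trip identity the tests rely on.

## What the synthetic systems do and do not show

The toy landscape reproduces the *topology* of the studied transition
(one reactant, two channels, three products, asymmetric weights, connected
channels) and supplies exact oracles, so it validates the sampling and
learning machinery: acceptance bias would show up as ensemble-population
disagreement, a miscalibrated committor as N_expected drift or validation
scatter. It does not probe high-dimensional descriptor spaces, metastable
intermediates, memory effects of inertial dynamics, or force-field physics.
The pseudo-helix generator validates featurization, state logic and
clustering against planted geometry; it says nothing about real sidechain
packing. Passing tests therefore certify the method implementation, not any
biological claim about a particular protein.

## Problem sizes and determinism

Default study sizes: 15 chains × 300 sweeps (plus 300 preliminary shots) for
the learning pipeline; 500 shots/point on a 15×15 transition-region grid for
the oracle; 400 harvested paths for the reference ensemble; 20 × 40
validation shots. All generators, the sampler and both fitters are pure
functions of their seeds (a root seed fans out through independent
SeedSequence streams); the Langevin kernels are numba-compiled and seeded per
trajectory. Known limitations: the committor model is unconstrained outside
the sampled region (predictions there are extrapolation); k-medoids uses the
alternating heuristic, not exhaustive PAM swaps; the symbolic-regression
engine is a compact evolutionary search and is not guaranteed to rediscover
any particular expression string — the parametric fallback provides the
deterministic target.
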