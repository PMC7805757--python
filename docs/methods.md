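# Methods

## Model

`hvgh` treats a multivariate time series `s = x_1 .. x_T` (one frame per row,
D dimensions) as a concatenation of segments, each generated by one of a
countably infinite set of classes. The generative story is:

1. **Class inventory and transitions (HDP).** Global class popularities
   `β ~ GEM(γ)` by stick breaking; each class c' has a transition distribution
   `π_{c'} ~ DP(η, β)`. With transition counts collapsed, the probability of
   moving from c' to c is `(N_{c'c} + η β_c) / (N_{c'} + η)`, where `N_{c'}`
   counts segments of class c' and `N_{c'c}` observed c'→c transitions.
   Sequence-initial transitions use a dedicated start pseudo-class row.
2. **Durations.** Segment lengths are `Poisson(λ)`, evaluated on 1..K without
   renormalization; K is the lattice depth (default `ceil(2.5 λ)`, beyond
   99.9% of the Poisson mass at practical λ). Length-0 segments are
   unreachable because the lattice enumerates k = 1..K.
3. **Emissions (GP).** Each class keeps the latent values of all its segments,
   indexed by within-segment position i = 1, 2, ... (positions restart at 1
   every segment). A new segment is scored point-by-point against the class's
   GP predictive `N(kᵀC⁻¹t_c, ρ − kᵀC⁻¹k)` with kernel
   `θ₀ exp(−θ₁ d²/2) + θ₂ + θ₃ i_p i_q` and Gram matrix
   `C = K + ω⁻¹ I`. Latent dimensions are modeled independently, so one
   Cholesky factor of C serves all d dimensions. An empty class scores
   against the prior predictive (mean 0, variance `k(i, i)`), which is what
   lets new classes be born during sampling.
4. **Observation (VAE decoder).** Latent frames map to observed frames
   through a decoder network with unit-variance Gaussian likelihood.

## Inference

**Blocked Gibbs over sequences.** Each sweep removes one sequence's segments
from the transition counts and GP stores, then resamples its entire
segmentation exactly given everything else: slice variables
`u_j ~ U(0, π_{c_{j-1}, c_j})` are drawn for the sequence's old transitions,
fresh classes are broken off the stick remainder until the largest possible
fresh-class transition probability falls below `min_j u_j` (so the candidate
set is finite but can grow), a forward lattice `α[t][k][c]` is filled in the
log domain, and a segmentation is drawn by backward sampling (the final
segment ∝ `α[T][k][c]`, earlier segments ∝ `α[t][k][c] · P(ĉ | c)` with ĉ the
already-sampled following class). Global sticks β are resampled after each
sequence via the auxiliary table-count (Chinese-restaurant) scheme, and atoms
no segmentation uses are folded back into the remainder.

Two deliberate readings of ambiguous constructions, both surfaced as flags or
documented behavior: the transition prior uses the **destination** class's
stick weight (the source-indexed variant does not normalize over destinations;
`source_class_beta=True` exposes it for comparison), and the backward-sampling
transition factor is taken **into the already-sampled following segment**.
The segment likelihood in the lattice scores candidate points against stored
class data only — no sequential conditioning within the candidate — keeping
each lattice cell O(1) after per-class precomputation.

**VAE.** Encoder D→64→32→(μ, log σ²), mirrored decoder, ReLU; one
reparameterized sample per frame per step; Adam (lr 1e-3) on mini-batches of
¼ of all frames, 150 steps per round. The ELBO's KL term is taken against
`N(0, I)` in the first round and against the per-frame GP predictives
`(μ_c(i), Σ_c(i))` of the current segmentation afterwards. The network is
plain numpy with hand-derived reverse-mode gradients (there is no autodiff
framework among the dependencies); the gradients are checked against central
finite differences in the test suite. Latent sequences passed to the
segmenter are the encoder **means** (a `latent_from_samples` flag switches to
sampled latents).

**Mutual-learning loop.** Train VAE → encode all frames → 10 Gibbs sweeps →
recompute per-frame GP priors → repeat until the relative change of the
deterministic full-data ELBO drops below `tol` (default 1e-3) or `max_loops`
(default 20) is reached; non-convergence returns the final state with a
warning. `max_loops=0` disables the feedback (VAE once with the standard
prior, one segmentation phase) — the "compress then segment" baseline.
`compression="identity"` skips the VAE entirely, giving the plain
HDP-GP-HSMM on z-scored input.

## Parameters that matter

| Parameter | Default | Meaning |
| --- | --- | --- |
| `lam` | 14.0 frames | Poisson mean segment duration (at 4 fps ≈ 3.5 s); halve it for short recordings |
| `theta0..theta3` | 1, 1, 0, 16 | kernel coefficients (RBF + constant + linear-in-position) |
| `omega` | 10.0 | GP noise precision. Not specified by the modeling convention we follow; 0.1 noise variance is of the right order for z-scored / VAE latents, configurable |
| `gamma`, `eta` | 1.0 | HDP concentrations; larger values admit more classes |
| `latent_dim` | 3 | VAE latent dimension d |
| `max_len` | `ceil(2.5 λ)` | lattice depth K |
| `gibbs_iters` | 10 | sweeps per round |
| `vae_steps`, `batch_fraction` | 150, 0.25 | Adam steps and mini-batch share per round |
| `max_class_points` | 150 | per-class GP training-set cap (uniform subsample, seeded) bounding the O(N³) factorization; set `None` to disable (oracle tests do) |
| `tol`, `max_loops` | 1e-3, 20 | loop convergence; neither is pinned by the modeling convention, both are logged |

Predictive variances are floored at 1e-10 after rounding; observation noise
ω⁻¹ is *not* added to the predictive variance when scoring data (the
posterior-variance form is taken literally) unless
`include_noise_in_predictive=True`.

## Synthetic data generator

`hvgh.simulate` samples from the model's own generative process so that
parameter recovery is a well-posed self-consistency check: per class a latent
template drawn once from the GP prior over positions 1..K (so repeated
segments of a class share a pattern), a Markov chain over classes with
Dirichlet(1)-sampled rows, Poisson segment lengths clipped to ≥ 1 (negligible
bias at λ ≥ 5), white noise of sd 0.1 on latents, and a seeded linear lift
with orthonormal columns (optionally tanh-squashed) plus white observation
noise into D dimensions. Defaults are the scaled-down recovery conditions: 4
classes, d = 2, D = 30, 4 sequences × 200 frames, λ = 10.

What it does **not** emulate: skeletal kinematics, Euler-angle wrap-around,
inter-dimension correlation structure of real mocap, time warping, or
segments whose content depends on context. Passing recovery tests therefore
demonstrates the correctness and self-consistency of the implementation, not
segmentation quality on real recordings.

## Numerical choices

* All lattice arithmetic is in the log domain with logsumexp; 93→3-dim
  likelihood products underflow linear-domain arithmetic.
* Gram factors are cached per class (shared across latent dimensions) and
  invalidated on segment add/remove; the blocked sweep removes and re-adds
  whole sequences, so lazy rebuild-per-sequence is the cheapest consistent
  policy. A non-positive-definite Gram raises a degeneracy error naming the
  class.
* Initialization: each sequence is cut into segments of roughly mean length λ
  with classes uniform over an initial pool of one class plus one fresh
  class; sticks start from a GEM draw.
* Every random draw flows from a single seed through per-purpose
  `SeedSequence` children (VAE init, VAE training, Gibbs, prediction), so
  fits are bit-reproducible.
* Evaluation: the normalized Hamming distance aligns estimated to true labels
  by an exact maximum-agreement assignment on the contingency table
  (estimated labels carry no identity); boundary precision/recall/F uses a
  ±ψ% window (`round(ψ/100·T)`, default ψ = 5) with greedy nearest-first
  one-to-one matching, endpoints excluded. Dataset-level reports pool
  boundary counts per sequence so each sequence's window refers to its own
  length and concatenation seams are not boundaries.

## Problem sizes used in the shipped studies

The recovery study runs the full pipeline on the generator defaults (2400
frames total per seed, three seeds) plus the single-pass variant and the
100-trial random baselines; the oracle comparisons use instances small enough
for exhaustive enumeration (T ≤ 8, K ≤ 3, C = 2; ≤ 50 GP training points) and
2×10⁴ posterior draws for the total-variation check.

## Known limitations

* **Mixing.** Blocked-by-sequence Gibbs can linger on label-splitting
  plateaus: two classes holding the same template, each kept alive by several
  sequences, with correct boundaries. Such duplicates usually merge within a
  few tens of sweeps but occasionally persist; the estimated class count is
  accordingly an upper-biased point estimate (visible as 5–7 classes on
  4-class synthetic data). Split–merge moves would address this and are not
  implemented.
* **Cost.** GP training cost is O(N³) per class; the per-class point cap
  trades fidelity for bounded cost on long recordings. No sparse/inducing
  approximations are provided.
* The duration model is a raw Poisson truncated to 1..K by construction (no
  renormalization); extremely long true segments (> K) are split by design.
* Per-dimension GP independence ignores cross-dimension covariance;
  multi-output GPs are out of scope.
* No handling of time warping: the same motion at a clearly different speed
  will be assigned a different class.
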