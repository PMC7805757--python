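# hvgh — unsupervised segmentation of high-dimensional time series

`hvgh` discovers recurring temporal patterns ("unit motions", behavioral
syllables) in high-dimensional multivariate time series — e.g. 93-dimensional
joint-angle recordings from motion capture — without any labels. It jointly
learns

* a **variational autoencoder (VAE)** that compresses each D-dimensional frame
  `x_t` into a low-dimensional latent Gaussian `q(z_t) = N(μ_enc(x_t), Σ_enc(x_t))`, and
* a **hierarchical-Dirichlet-process Gaussian-process hidden semi-Markov model
  (HDP-GP-HSMM)** that tiles the latent sequence `z_1..z_T` into segments:
  segment classes `c_j` follow an HDP-coupled Markov chain
  (`β ~ GEM(γ)`, `π_c ~ DP(η, β)`, transition probability
  `P(c | c') = (N_{c'c} + η β_c) / (N_{c'} + η)`), segment lengths follow
  `Poisson(λ)`, and each class emits its segment through a Gaussian-process
  posterior over within-segment position `i` with kernel
  `k(i_p, i_q) = θ₀ exp(−θ₁‖i_p − i_q‖²/2) + θ₂ + θ₃ i_p i_q`.

The two halves are trained in a **mutual-learning loop**: after each round of
blocked Gibbs sampling (slice-sampled class truncation + forward
filtering–backward sampling over the segment lattice `α[t][k][c]`), the GP
predictive distribution `(μ_c(i), Σ_c(i))` of every frame's class and position
replaces the VAE's `N(0, I)` prior in the ELBO, so the latent space itself is
shaped to make segments temporally smooth and class-separable.

Who it is for: anyone segmenting smooth, high-dimensional behavioral or sensor
time series into an unknown number of recurring units — the model estimates
the class inventory nonparametrically.

## Worked example (CLI)

```bash
hvgh simulate --n-classes 3 --lam 8 --n-sequences 2 --frames 120 \
    --latent-dim 2 --observed-dim 20 --seed 7 --out data
hvgh fit --input data --latent-dim 2 --lam 8 --loops 10 --seed 7 \
    --out model.npz --segmentation-out seg.csv
hvgh segment --model model.npz --input data --out seg2.csv --labels-out labels
hvgh evaluate --pred labels/seq_000.labels.csv \
    --truth data/seq_000.labels.csv --psi 5
```

The `fit` log shows the per-round trace, e.g.

```
loop 9: elbo=-18.9538 joint_loglik=-3898.20 n_classes=3 (atoms=3)
model written to model.npz (3 classes)
```

and the final evaluation prints

```json
{
  "f_measure": 1.0,
  "hamming": 0.0,
  "n_classes": 3,
  "precision": 1.0,
  "psi": 5.0,
  "recall": 1.0,
  "seed": 0
}
```

i.e. on this 20-dimensional synthetic dance of three unit motions, the model
recovers the number of classes (3), every boundary within the ±5% window
(precision = recall = 1), and labels every frame correctly (normalized Hamming
distance 0, after optimal one-to-one label matching).

## Worked example (Python API)

The estimator follows scikit-learn conventions (`fit`, `predict`,
`get_params`, fitted attributes with trailing underscores):

```python
import numpy as np
from hvgh import HVGH, SyntheticConfig, generate, evaluate_dataset

cfg = SyntheticConfig(seed=1)              # 4 classes, 4 sequences x 200 frames, D=30
ds = generate(cfg, np.random.default_rng(1))
model = HVGH(latent_dim=2, lam=10.0, random_state=1).fit(ds.sequences)
print(model.n_classes_, model.converged_)  # 5 True
print(evaluate_dataset(model.labels_, ds.labels, psi=5.0))
# EvalReport(hamming=0.21375, precision=0.4348, recall=1.0,
#            f_measure=0.6061, n_classes=5, psi=5.0)
```

`model.labels_` holds per-frame class ids per sequence, `model.segmentation_`
the `(start, end, class)` tiles, and `model.trace_` the per-round ELBO /
joint-log-likelihood / class-count history. A Hamming distance of 0.21 means
79% of frames carry the right class after optimal label alignment; random
segmentations with the true segment count score about 0.64 on the same data.

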