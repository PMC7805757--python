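"""Sampling datasets from the model's own generative process.

Each class owns a smooth latent template drawn from the GP prior over
within-segment positions; sequences are built by a Markov chain over
classes with Poisson segment lengths, each segment being its class
template plus white noise, and frames are lifted to high dimension
through a seeded linear (optionally tanh-squashed) map with orthonormal
columns.  Ground-truth labels, boundaries and latents are recorded so
parameter recovery is a well-posed self-consistency check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky

from .gp import KernelParams, build_gram
from .hsmm import default_max_len

#: jitter added to template covariances before factorization
_TEMPLATE_JITTER = 1e-8


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the scaled-down recovery setting: 4 classes in a
    2-dimensional latent space lifted to 30 observed dimensions, 4
    sequences of ~200 frames, Poisson(10) segment lengths and white
    noise of standard deviation 0.1 on both latents and observations.
    """

    n_classes: int = 4
    lam_true: float = 10.0
    n_sequences: int = 4
    target_frames: int = 200
    latent_dim: int = 2
    observed_dim: int = 30
    noise_sd: float = 0.1
    transition_concentration: float = 1.0
    lift: str = "linear"  # or "tanh"
    kernel: KernelParams = field(default_factory=KernelParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.observed_dim < self.latent_dim:
            raise ValueError("observed_dim must be >= latent_dim")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.lift not in ("linear", "tanh"):
            raise ValueError("lift must be 'linear' or 'tanh'")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = asdict(self.kernel)
        return d


@dataclass
class SyntheticDataset:
    sequences: list  # (T, D) arrays
    labels: list  # per-frame class ids, (T,) arrays
    boundaries: list  # interior boundary frames per sequence
    latents: list  # (T, d) true latent trajectories
    templates: np.ndarray  # (n_classes, K_max, d)
    lift_matrix: np.ndarray  # (D, d), orthonormal columns
    transition_matrix: np.ndarray  # (n_classes, n_classes)
    config: SyntheticConfig


def sample_class_templates(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean GP draws over positions 1..K_max, one per class and
    latent dimension; shape (n_classes, K_max, d).

    Repeated segments of a class reuse its template, so a class is a
    reproducible temporal pattern rather than a fresh GP draw per
    segment.
    """
    K_max = default_max_len(config.lam_true)
    idx = np.arange(1, K_max + 1)
    # prior covariance of the latent function (no observation noise term)
    C = build_gram(idx, config.kernel)
    C -= np.eye(K_max) / config.kernel.omega
    L = cholesky(C + _TEMPLATE_JITTER * np.eye(K_max), lower=True)
    draws = rng.standard_normal((config.n_classes, K_max, config.latent_dim))
    return np.einsum("pq,cqd->cpd", L, draws)


def make_lift(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded (D, d) matrix with orthonormal columns."""
    A = rng.standard_normal((config.observed_dim, config.latent_dim))
    Q, _ = np.linalg.qr(A)
    return Q[:, : config.latent_dim]


def lift(Z: np.ndarray, W: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Map latent frames (T, d) to observed frames (T, D), noise-free."""
    X = np.atleast_2d(np.asarray(Z, dtype=float)) @ W.T
    if mode == "tanh":
        X = np.tanh(X)
    return X


def generate(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SyntheticDataset:
    """Sample a full dataset under the generative process.

    Segment classes follow a Markov chain with Dirichlet-sampled rows;
    segment lengths are Poisson(lam_true) clipped to >= 1; the last
    segment of each sequence is truncated so the sequence has exactly
    ``target_frames`` frames.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    templates = sample_class_templates(config, rng)
    K_max = templates.shape[1]
    W = make_lift(config, rng)
    n = config.n_classes
    conc = config.transition_concentration
    P = rng.dirichlet(np.full(n, conc), size=n)
    start = rng.dirichlet(np.full(n, conc))

    sequences, labels, boundaries, latents = [], [], [], []
    for _ in range(config.n_sequences):
        T = config.target_frames
        frames = np.empty((T, config.latent_dim))
        lab = np.empty(T, dtype=int)
        bnds = []
        t = 0
        c = int(rng.choice(n, p=start))
        while t < T:
            if t > 0:
                c = int(rng.choice(n, p=P[c]))
                bnds.append(t)
            k = max(1, int(rng.poisson(config.lam_true)))
            k = min(k, K_max, T - t)
            seg = templates[c, :k] + rng.normal(0.0, config.noise_sd, (k, config.latent_dim))
            frames[t : t + k] = seg
            lab[t : t + k] = c
            t += k
        obs = lift(frames, W, config.lift)
        if config.noise_sd > 0:
            obs = obs + rng.normal(0.0, config.noise_sd, obs.shape)
        sequences.append(obs)
        labels.append(lab)
        boundaries.append(bnds)
        latents.append(frames)
    return SyntheticDataset(
        sequences=sequences,
        labels=labels,
        boundaries=boundaries,
        latents=latents,
        templates=templates,
        lift_matrix=W,
        transition_matrix=P,
        config=config,
    )


def segment_lengths(dataset: SyntheticDataset) -> np.ndarray:
    """All segment lengths in the dataset (diagnostic)."""
    out = []
    for lab, bnds in zip(dataset.labels, dataset.boundaries):
        edges = [0] + list(bnds) + [len(lab)]
        out.extend(np.diff(edges))
    return np.asarray(out)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write per-sequence CSVs, truth labels and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (seq, lab) in enumerate(zip(dataset.sequences, dataset.labels)):
        np.savetxt(outdir / f"seq_{i:03d}.csv", seq, delimiter=",", fmt="%.10g")
        np.savetxt(outdir / f"seq_{i:03d}.labels.csv", lab, fmt="%d")
    manifest = {
        "n_sequences": len(dataset.sequences),
        "observed_dim": dataset.config.observed_dim,
        "config": dataset.config.as_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
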