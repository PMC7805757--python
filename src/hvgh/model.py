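"""The HVGH estimator: mutual learning of a VAE and an HDP-GP-HSMM.

Each round trains the VAE (standard N(0, I) prior in the first round,
per-frame GP predictive priors afterwards), encodes every frame to its
latent mean, runs a fixed number of blocked Gibbs sweeps of the
HDP-GP-HSMM on the latent sequences, and feeds the per-class GP
predictive distributions back as the next round's VAE priors.  Rounds
repeat until the full-data ELBO converges.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import hdp, hsmm
from .gp import KernelParams
from .hdp import START
from .hsmm import GibbsConfig, GibbsState, Tile
from .vae import VAE, LOG_2PI

#: floor for the per-dimension scale of constant input columns
SCALE_FLOOR = 1e-8


class PriorCoverageError(RuntimeError):
    """Raised when a frame has no segment (hence no GP prior)."""


def _as_sequence_list(X):
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return [np.asarray(X, dtype=float)]
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in X]
    if not seqs:
        raise ValueError("need at least one sequence")
    D = seqs[0].shape[1]
    for s in seqs:
        if s.shape[1] != D:
            raise ValueError("all sequences must share the same dimension")
        if s.shape[0] < 2:
            raise ValueError("each sequence needs at least 2 frames")
    return seqs


def assign_priors(state: GibbsState, latent_lengths):
    """Per-frame GP predictive (mean, variance) tables from a segmentation.

    The frame at offset o of a class-c tile receives the class-c
    predictive at position o + 1.  Returns (means, variances), each a
    list of (T, d) arrays aligned with the sequences.
    """
    means, variances = [], []
    for n, T in enumerate(latent_lengths):
        tiles = state.segmentations[n]
        mu = np.empty((T, state.latent_dim))
        var = np.empty((T, state.latent_dim))
        covered = 0
        for tile in tiles:
            m, v = state.gp_models[tile.cls].predict_many(
                np.arange(1, tile.length + 1)
            )
            mu[tile.start : tile.end] = m
            var[tile.start : tile.end] = v[:, None]
            covered += tile.length
        if covered != T:
            raise PriorCoverageError(
                f"sequence {n}: segmentation covers {covered} of {T} frames"
            )
        means.append(mu)
        variances.append(var)
    return means, variances


class HVGH(BaseEstimator):
    """Unsupervised segmenter for high-dimensional time series.

    Parameters
    ----------
    latent_dim : int, default 3
        Dimension d of the VAE latent space the HSMM segments.
    lam : float, default 14.0
        Poisson mean segment duration, in frames.
    gamma, eta : float, default 1.0
        HDP concentrations (global sticks, per-row transition DP).
    omega : float, default 10.0
        GP observation-noise precision (noise variance 1/omega).
    theta0, theta1, theta2, theta3 : float
        Kernel coefficients of the RBF + constant + linear GP kernel.
    max_len : int or None
        Maximum segment length K; None means ceil(2.5 * lam).
    gibbs_iters : int, default 10
        Blocked Gibbs sweeps per mutual-learning round.
    vae_steps : int, default 150
        Adam steps per round; each uses a mini-batch of
        ``batch_fraction`` of all frames.
    max_loops : int, default 20
        Maximum mutual-learning rounds; 0 disables the feedback loop
        (VAE with standard prior, then one segmentation phase).
    tol : float, default 1e-3
        Relative full-data-ELBO change that counts as converged.
    compression : {"vae", "identity"}
        "identity" skips the VAE and segments the (normalized) input
        directly: the plain HDP-GP-HSMM mode.
    max_class_points : int or None, default 150
        Per-class GP training-set cap (uniform subsample).
    include_noise_in_predictive : bool, default False
        Add 1/omega to GP predictive variances when scoring data.
    latent_from_samples : bool, default False
        Build latent sequences from reparameterized samples instead of
        encoder means.
    random_state : int or None
        Seed for every source of randomness.

    Attributes
    ----------
    labels_ : list of (T,) int arrays, per-frame class ids per sequence.
    segmentation_ : list of lists of Tile(start, end, cls).
    n_classes_ : number of distinct classes in the final segmentation.
    trace_ : per-round dicts (elbo, joint_loglik, n_atoms, n_classes).
    converged_ : whether the ELBO tolerance was met.
    """

    def __init__(
        self,
        latent_dim: int = 3,
        lam: float = 14.0,
        gamma: float = 1.0,
        eta: float = 1.0,
        omega: float = 10.0,
        theta0: float = 1.0,
        theta1: float = 1.0,
        theta2: float = 0.0,
        theta3: float = 16.0,
        max_len: int | None = None,
        gibbs_iters: int = 10,
        vae_steps: int = 150,
        batch_fraction: float = 0.25,
        hidden: tuple = (64, 32),
        learning_rate: float = 1e-3,
        max_loops: int = 20,
        tol: float = 1e-3,
        compression: str = "vae",
        max_class_points: int | None = 150,
        include_noise_in_predictive: bool = False,
        latent_from_samples: bool = False,
        random_state: int | None = None,
    ):
        self.latent_dim = latent_dim
        self.lam = lam
        self.gamma = gamma
        self.eta = eta
        self.omega = omega
        self.theta0 = theta0
        self.theta1 = theta1
        self.theta2 = theta2
        self.theta3 = theta3
        self.max_len = max_len
        self.gibbs_iters = gibbs_iters
        self.vae_steps = vae_steps
        self.batch_fraction = batch_fraction
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.max_loops = max_loops
        self.tol = tol
        self.compression = compression
        self.max_class_points = max_class_points
        self.include_noise_in_predictive = include_noise_in_predictive
        self.latent_from_samples = latent_from_samples
        self.random_state = random_state

    # ------------------------------------------------------------------ api
    def _kernel_params(self) -> KernelParams:
        return KernelParams(
            theta0=self.theta0,
            theta1=self.theta1,
            theta2=self.theta2,
            theta3=self.theta3,
            omega=self.omega,
        )

    def _gibbs_config(self) -> GibbsConfig:
        return GibbsConfig(
            lam=self.lam,
            K=self.max_len,
            gamma=self.gamma,
            eta=self.eta,
            kernel=self._kernel_params(),
            max_class_points=self.max_class_points,
            include_noise_in_predictive=self.include_noise_in_predictive,
        )

    def _rngs(self):
        """Deterministic per-purpose streams derived from random_state:
        (vae-init seed, vae-train rng, gibbs rng, predict rng)."""
        ss = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        init_ss, train_ss, gibbs_ss, pred_ss = ss.spawn(4)
        return (
            int(init_ss.generate_state(1)[0] % (2**31)),
            np.random.default_rng(train_ss),
            np.random.default_rng(gibbs_ss),
            np.random.default_rng(pred_ss),
        )

    def _encode_sequences(self, seqs_norm, rng):
        if self.compression == "identity":
            return [s.copy() for s in seqs_norm]
        out = []
        for s in seqs_norm:
            mu, var = self.vae_.encode(s)
            if self.latent_from_samples:
                out.append(VAE.reparam_sample(mu, var, rng))
            else:
                out.append(mu)
        return out

    def _reseat(self, state: GibbsState, latent_seqs) -> None:
        """Re-add segment data to fresh GP stores after the latent space
        moved (segmentation, counts and sticks are kept)."""
        state.gp_models = {}
        for n, tiles in enumerate(state.segmentations):
            hs = []
            for tile in tiles:
                h = state.model_for(tile.cls).add_segment(
                    latent_seqs[n][tile.start : tile.end]
                )
                hs.append((tile.cls, h))
            state.handles[n] = hs

    def fit(self, X, y=None):
        """Fit the model to one or more (T, D) sequences."""
        if self.compression not in ("vae", "identity"):
            raise ValueError("compression must be 'vae' or 'identity'")
        seqs = _as_sequence_list(X)
        frames = np.vstack(seqs)
        self.mean_ = frames.mean(axis=0)
        self.scale_ = np.maximum(frames.std(axis=0), SCALE_FLOOR)
        seqs_norm = [(s - self.mean_) / self.scale_ for s in seqs]
        self._seqs_norm = seqs_norm
        frames_norm = np.vstack(seqs_norm)
        lengths = [s.shape[0] for s in seqs_norm]
        offsets = np.concatenate([[0], np.cumsum(lengths)])

        vae_seed, rng_train, rng_gibbs, self._rng_predict = self._rngs()
        use_vae = self.compression == "vae"
        if use_vae:
            self.vae_ = VAE(
                input_dim=frames.shape[1],
                latent_dim=self.latent_dim,
                hidden=self.hidden,
                learning_rate=self.learning_rate,
                seed=vae_seed,
            )
        else:
            self.vae_ = None

        cfg = self._gibbs_config()
        state = None
        priors = None
        self.trace_ = []
        self.converged_ = False
        prev_elbo = None
        n_rounds = max(1, self.max_loops)
        for loop in range(n_rounds):
            if use_vae:
                self.vae_.train(
                    frames_norm,
                    priors=priors,
                    steps=self.vae_steps,
                    batch_fraction=self.batch_fraction,
                    rng=rng_train,
                )
            latents = self._encode_sequences(seqs_norm, rng_train)
            if state is None:
                state = hsmm.init_state(latents, cfg, rng_gibbs)
            else:
                self._reseat(state, latents)
            for _ in range(self.gibbs_iters):
                hsmm.blocked_gibbs_sweep(latents, state, rng_gibbs)
            state.audit(latents)
            mu_table, var_table = assign_priors(state, lengths)
            if use_vae:
                priors = (np.vstack(mu_table), np.vstack(var_table))
                elbo = self.vae_.elbo(frames_norm, priors=priors)
            else:
                elbo = float("nan")
            self._state = state
            self._latents = latents
            self.trace_.append(
                {
                    "loop": loop,
                    "elbo": elbo,
                    "joint_loglik": self.joint_loglik(),
                    "n_atoms": state.beta.n_atoms,
                    "n_classes": len(state.classes_in_use()),
                }
            )
            if use_vae and prev_elbo is not None:
                if abs(elbo - prev_elbo) < self.tol * (abs(prev_elbo) + 1e-12):
                    self.converged_ = True
                    break
            prev_elbo = elbo
            if self.max_loops == 0 or not use_vae:
                break
        else:
            if use_vae and self.max_loops > 1:
                warnings.warn(
                    "mutual-learning loop reached max_loops without ELBO "
                    "convergence; returning the final state",
                    RuntimeWarning,
                )

        self.segmentation_ = [list(tiles) for tiles in state.segmentations]
        self.labels_ = [self._tiles_to_labels(tiles, T) for tiles, T in zip(state.segmentations, lengths)]
        self.n_classes_ = len(state.classes_in_use())
        self.prior_means_, self.prior_vars_ = mu_table, var_table
        self.offsets_ = offsets
        return self

    @staticmethod
    def _tiles_to_labels(tiles, T):
        lab = np.empty(T, dtype=int)
        for tile in tiles:
            lab[tile.start : tile.end] = tile.cls
        return lab

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        """Segment new sequences with the frozen model (one posterior
        draw of the segmentation per sequence); returns frame labels."""
        check_is_fitted(self, "segmentation_")
        seqs = _as_sequence_list(X)
        seqs_norm = [(s - self.mean_) / self.scale_ for s in seqs]
        latents = self._encode_sequences(seqs_norm, self._rng_predict)
        state = self._state
        cfg = state.config
        C = state.beta.n_atoms
        classes = list(range(C))
        with np.errstate(divide="ignore"):
            log_trans = np.log(
                hdp.trans_matrix(classes, classes, state.counts, state.beta, cfg.eta)
            )
            log_start = np.log(
                np.array(
                    [hdp.trans_prob(START, c, state.counts, state.beta, cfg.eta) for c in classes]
                )
            )
        models = [state.model_for(c) for c in classes]
        out = []
        for seq in latents:
            lattice = hsmm.forward_filter(
                seq, models, log_trans, log_start, cfg.lam, cfg.max_len
            )
            tiles = hsmm.backward_sample(lattice, self._rng_predict)
            out.append(self._tiles_to_labels(tiles, seq.shape[0]))
        return out

    # ----------------------------------------------------------- diagnostics
    def joint_loglik(self) -> float:
        """Point estimate of the joint log-likelihood of the current state:
        GP segment terms + transition terms + decoder reconstruction terms
        evaluated at the encoder means."""
        state = self._state
        if not any(state.segmentations):
            return 0.0
        cfg = state.config
        total = 0.0
        for n, tiles in enumerate(state.segmentations):
            prev = START
            for tile in tiles:
                seg = self._latents[n][tile.start : tile.end]
                total += state.gp_models[tile.cls].segment_loglik(seg)
                total += np.log(
                    hdp.trans_prob(prev, tile.cls, state.counts, state.beta, cfg.eta)
                )
                prev = tile.cls
        if self.vae_ is not None:
            lat = np.vstack(self._latents)
            rec = self.vae_.decode(lat)
            norm = np.vstack(self._seqs_norm)
            total += float(
                -0.5 * ((norm - rec) ** 2).sum() - 0.5 * norm.size * LOG_2PI
            )
        return float(total)
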