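"""Variational autoencoder with a per-frame structured Gaussian prior.

A small fully-connected encoder maps each D-dimensional frame to the
mean and diagonal variance of a d-dimensional Gaussian; a mirrored
decoder maps latents back to frame space under a unit-variance Gaussian
likelihood.  The ELBO's KL term is taken either against N(0, I)
(standard mode) or against per-frame Gaussian priors supplied by the
segmentation model's GP predictives (structured mode).

The network is implemented directly on numpy arrays with hand-written
reverse-mode gradients and an Adam optimizer; gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))


class TrainingDivergenceError(RuntimeError):
    """Raised when activations or the loss become non-finite."""


def kl_diag_gaussian(q_mean, q_var, p_mean, p_var) -> float:
    """KL( N(q_mean, diag q_var) || N(p_mean, diag p_var) ), summed over
    dimensions.  Closed form:

        0.5 * sum[ log(p_var/q_var) + (q_var + (q_mean-p_mean)^2)/p_var - 1 ]
    """
    q_mean = np.asarray(q_mean, dtype=float)
    q_var = np.asarray(q_var, dtype=float)
    p_mean = np.asarray(p_mean, dtype=float)
    p_var = np.asarray(p_var, dtype=float)
    if np.any(q_var <= 0) or np.any(p_var <= 0):
        raise ValueError("variances must be strictly positive")
    val = 0.5 * (
        np.log(p_var / q_var) + (q_var + (q_mean - p_mean) ** 2) / p_var - 1.0
    )
    return float(val.sum())


def _kl_batch(q_mean, q_lv, p_mean, p_var):
    """Per-sample KL for batched arrays; q given as (mean, log-variance)."""
    q_var = np.exp(q_lv)
    val = 0.5 * (
        np.log(p_var) - q_lv + (q_var + (q_mean - p_mean) ** 2) / p_var - 1.0
    )
    return val.sum(axis=1)


def _relu(x):
    return np.maximum(x, 0.0)


@dataclass
class AdamOptimizer:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class VAE:
    """Encoder/decoder pair for frame-wise compression.

    Parameters
    ----------
    input_dim : D, observed frame dimension.
    latent_dim : d, latent dimension (3 in the motion experiments).
    hidden : sizes of the two hidden layers (mirrored in the decoder).
    learning_rate : Adam step size.
    seed : weight-initialization seed.
    """

    def __init__(
        self,
        input_dim: int,
        latent_dim: int = 3,
        hidden: tuple[int, int] = (64, 32),
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        self.hidden = tuple(hidden)
        rng = np.random.default_rng(seed)
        h1, h2 = self.hidden
        d = latent_dim

        def glorot(fan_in, fan_out):
            s = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.normal(0.0, s, size=(fan_in, fan_out))

        self.params = {
            "enc_W1": glorot(input_dim, h1),
            "enc_b1": np.zeros(h1),
            "enc_W2": glorot(h1, h2),
            "enc_b2": np.zeros(h2),
            "enc_Wmu": glorot(h2, d),
            "enc_bmu": np.zeros(d),
            "enc_Wlv": glorot(h2, d),
            "enc_blv": np.zeros(d),
            "dec_W1": glorot(d, h2),
            "dec_b1": np.zeros(h2),
            "dec_W2": glorot(h2, h1),
            "dec_b2": np.zeros(h1),
            "dec_W3": glorot(h1, input_dim),
            "dec_b3": np.zeros(input_dim),
        }
        self.opt = AdamOptimizer(lr=learning_rate)
        self.loss_trace: list[float] = []

    # ----------------------------------------------------------- inference
    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Encoder mean and variance for a batch of frames.

        Returns (mu, var), each (N, d); the variance comes from an
        exponentiated log-variance head and is strictly positive.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = self.params
        h1 = _relu(X @ p["enc_W1"] + p["enc_b1"])
        h2 = _relu(h1 @ p["enc_W2"] + p["enc_b2"])
        mu = h2 @ p["enc_Wmu"] + p["enc_bmu"]
        lv = h2 @ p["enc_Wlv"] + p["enc_blv"]
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
            raise TrainingDivergenceError("non-finite encoder activations")
        return mu, np.exp(lv)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Decoder reconstruction for a batch of latents; (N, D)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        p = self.params
        g1 = _relu(Z @ p["dec_W1"] + p["dec_b1"])
        g2 = _relu(g1 @ p["dec_W2"] + p["dec_b2"])
        xr = g2 @ p["dec_W3"] + p["dec_b3"]
        if not np.all(np.isfinite(xr)):
            raise TrainingDivergenceError("non-finite decoder activations")
        return xr

    @staticmethod
    def reparam_sample(mu, var, rng: np.random.Generator):
        """z = mu + sqrt(var) * eps with eps ~ N(0, I)."""
        mu = np.asarray(mu, dtype=float)
        var = np.asarray(var, dtype=float)
        return mu + np.sqrt(var) * rng.standard_normal(mu.shape)

    # ----------------------------------------------------------- objective
    def _forward_backward(self, X, prior_mean, prior_var, eps):
        """Mean negative ELBO over the batch and its parameter gradients.

        ``eps`` is the reparameterization noise, (N, d); pass zeros for
        a deterministic (mean-latent) evaluation.
        """
        p = self.params
        N = X.shape[0]
        a1 = X @ p["enc_W1"] + p["enc_b1"]
        h1 = _relu(a1)
        a2 = h1 @ p["enc_W2"] + p["enc_b2"]
        h2 = _relu(a2)
        mu = h2 @ p["enc_Wmu"] + p["enc_bmu"]
        lv = h2 @ p["enc_Wlv"] + p["enc_blv"]
        z = mu + np.exp(0.5 * lv) * eps
        q1 = z @ p["dec_W1"] + p["dec_b1"]
        g1 = _relu(q1)
        q2 = g1 @ p["dec_W2"] + p["dec_b2"]
        g2 = _relu(q2)
        xr = g2 @ p["dec_W3"] + p["dec_b3"]

        recon = 0.5 * ((X - xr) ** 2).sum(axis=1)
        kl = _kl_batch(mu, lv, prior_mean, prior_var)
        loss = float((recon + kl).mean())
        if not np.isfinite(loss):
            raise TrainingDivergenceError("non-finite loss")

        # reverse pass (gradients of the mean loss)
        dxr = (xr - X) / N
        grads = {
            "dec_W3": g2.T @ dxr,
            "dec_b3": dxr.sum(axis=0),
        }
        dg2 = dxr @ p["dec_W3"].T
        dq2 = dg2 * (q2 > 0)
        grads["dec_W2"] = g1.T @ dq2
        grads["dec_b2"] = dq2.sum(axis=0)
        dg1 = dq2 @ p["dec_W2"].T
        dq1 = dg1 * (q1 > 0)
        grads["dec_W1"] = z.T @ dq1
        grads["dec_b1"] = dq1.sum(axis=0)
        dz = dq1 @ p["dec_W1"].T

        q_var = np.exp(lv)
        dmu = dz + (mu - prior_mean) / prior_var / N
        dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + 0.5 * (q_var / prior_var - 1.0) / N
        grads["enc_Wmu"] = h2.T @ dmu
        grads["enc_bmu"] = dmu.sum(axis=0)
        grads["enc_Wlv"] = h2.T @ dlv
        grads["enc_blv"] = dlv.sum(axis=0)
        dh2 = dmu @ p["enc_Wmu"].T + dlv @ p["enc_Wlv"].T
        da2 = dh2 * (a2 > 0)
        grads["enc_W2"] = h1.T @ da2
        grads["enc_b2"] = da2.sum(axis=0)
        dh1 = da2 @ p["enc_W2"].T
        da1 = dh1 * (a1 > 0)
        grads["enc_W1"] = X.T @ da1
        grads["enc_b1"] = da1.sum(axis=0)
        return loss, grads

    @staticmethod
    def _resolve_priors(priors, N, d):
        if priors is None:
            return np.zeros((N, d)), np.ones((N, d))
        pm, pv = priors
        pm = np.asarray(pm, dtype=float)
        pv = np.asarray(pv, dtype=float)
        if pm.shape != (N, d) or pv.shape != (N, d):
            raise ValueError(
                f"prior table shape {pm.shape}/{pv.shape} does not cover "
                f"{N} frames x {d} dims"
            )
        return pm, pv

    def elbo(self, X, priors=None, rng=None) -> float:
        """Mean per-frame ELBO (up to no constants: the -D/2 log 2pi of the
        unit-variance Gaussian likelihood is included).

        With ``rng`` the reconstruction uses one reparameterized sample;
        without, the encoder mean (deterministic evaluation, used for
        convergence monitoring).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pm, pv = self._resolve_priors(priors, X.shape[0], self.latent_dim)
        if rng is None:
            eps = np.zeros((X.shape[0], self.latent_dim))
        else:
            eps = rng.standard_normal((X.shape[0], self.latent_dim))
        loss, _ = self._forward_backward(X, pm, pv, eps)
        return -loss - 0.5 * self.input_dim * LOG_2PI

    def train(
        self,
        X,
        priors=None,
        steps: int = 150,
        batch_fraction: float = 0.25,
        rng: np.random.Generator | None = None,
    ) -> None:
        """Run ``steps`` Adam updates on random mini-batches.

        Batch size is ceil(batch_fraction * N); one reparameterized
        sample per frame per step.
        """
        if not 0 < batch_fraction <= 1:
            raise ValueError("batch_fraction must be in (0, 1]")
        if steps < 1:
            raise ValueError("steps must be >= 1")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rng = rng if rng is not None else np.random.default_rng(0)
        N = X.shape[0]
        pm, pv = self._resolve_priors(priors, N, self.latent_dim)
        B = int(np.ceil(batch_fraction * N))
        for _ in range(steps):
            idx = rng.choice(N, size=B, replace=False)
            eps = rng.standard_normal((B, self.latent_dim))
            loss, grads = self._forward_backward(X[idx], pm[idx], pv[idx], eps)
            self.opt.step(self.params, grads)
            self.loss_trace.append(loss)
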