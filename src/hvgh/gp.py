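"""Gaussian-process emission model for segment classes.

Each segment class c keeps the latent values of all segments assigned to
it, indexed by within-segment position i = 1, 2, ... (positions restart
at 1 for every segment).  The class emits a new value at position i from
the GP predictive distribution given that training set; every latent
dimension is modelled independently, so a single Gram factor serves all
dimensions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

logger = logging.getLogger(__name__)

#: smallest predictive variance returned after rounding
VARIANCE_FLOOR = 1e-10


class NumericalDegeneracyError(RuntimeError):
    """Raised when a class Gram matrix cannot be factorized."""


class UnknownSegmentError(KeyError):
    """Raised when removing a segment handle that was never added."""


@dataclass(frozen=True)
class KernelParams:
    """Coefficients of the RBF + constant + linear kernel, plus noise.

    k(ip, iq) = theta0 * exp(-theta1 * |ip - iq|^2 / 2) + theta2 + theta3 * ip * iq

    omega is the observation-noise *precision*: the Gram matrix adds
    1/omega on its diagonal.
    """

    theta0: float = 1.0
    theta1: float = 1.0
    theta2: float = 0.0
    theta3: float = 16.0
    omega: float = 10.0

    def __post_init__(self):
        if self.theta0 < 0 or self.theta1 < 0 or self.theta3 < 0:
            raise ValueError("theta0, theta1, theta3 must be nonnegative")
        if self.omega <= 0:
            raise ValueError("omega (noise precision) must be positive")


def kernel(ip, iq, params: KernelParams):
    """Kernel value(s) between within-segment positions ``ip`` and ``iq``.

    Accepts scalars or broadcastable arrays of positive integers.
    """
    ip = np.asarray(ip, dtype=float)
    iq = np.asarray(iq, dtype=float)
    sq = (ip - iq) ** 2
    val = params.theta0 * np.exp(-0.5 * params.theta1 * sq) + params.theta2 + params.theta3 * ip * iq
    return val if val.shape else float(val)


def build_gram(indices, params: KernelParams, *, class_id=None) -> np.ndarray:
    """Gram matrix C(p,q) = k(i_p, i_q) + delta_pq / omega for a position vector."""
    idx = np.asarray(indices, dtype=float)
    if idx.size == 0:
        raise ValueError("indices must be nonempty")
    C = kernel(idx[:, None], idx[None, :], params)
    C = C + np.eye(idx.size) / params.omega
    return C


def _factorize(C: np.ndarray, class_id):
    try:
        return cho_factor(C, lower=True)
    except LinAlgError as exc:  # pragma: no cover - only degenerate params
        raise NumericalDegeneracyError(
            f"Gram matrix of class {class_id!r} is not positive definite"
        ) from exc


@dataclass
class GPPredictive:
    """Per-dimension predictive mean and variance at one position."""

    mean: np.ndarray  # (d,)
    variance: np.ndarray  # (d,), all > 0


class GPClassModel:
    """Training data and cached Gram factor for one segment class.

    Parameters
    ----------
    class_id : int
        Identifier used in error messages.
    latent_dim : int
        Number of latent dimensions d.
    params : KernelParams
        Kernel coefficients and noise precision, shared by all classes.
    max_points : int or None
        Optional cap on the training-set size; when exceeded, a uniform
        subsample (drawn with ``rng``) is used to build the Gram matrix.
        Bounds the O(N^3) factorization cost on long recordings.
    include_noise_in_predictive : bool
        If True, add 1/omega to the predictive variance when scoring
        data (off by default: the predictive is the noise-free posterior).
    """

    def __init__(
        self,
        class_id: int,
        latent_dim: int,
        params: KernelParams,
        max_points: int | None = 150,
        rng: np.random.Generator | None = None,
        include_noise_in_predictive: bool = False,
    ):
        self.class_id = class_id
        self.latent_dim = latent_dim
        self.params = params
        self.max_points = max_points
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.include_noise_in_predictive = include_noise_in_predictive
        self._segments: dict[int, np.ndarray] = {}
        self._next_handle = 0
        self.dirty = True
        self._chol = None
        self._i_c = np.empty(0)
        self._t_c = np.empty((0, latent_dim))
        self._alpha = None  # C^{-1} t_c, (N, d)

    # ------------------------------------------------------------------ data
    @property
    def n_segments(self) -> int:
        return len(self._segments)

    @property
    def n_points(self) -> int:
        return int(sum(seg.shape[0] for seg in self._segments.values()))

    @property
    def index_vector(self) -> np.ndarray:
        """1-based within-segment positions of every stored point (i_c)."""
        if self._segments:
            return np.concatenate(
                [np.arange(1, seg.shape[0] + 1) for seg in self._segments.values()]
            )
        return np.empty(0, dtype=int)

    @property
    def value_matrix(self) -> np.ndarray:
        """Stored latent values, one row per point (t_c)."""
        if self._segments:
            return np.vstack(list(self._segments.values()))
        return np.empty((0, self.latent_dim))

    def add_segment(self, segment: np.ndarray) -> int:
        """Store a (T_seg, d) segment; returns a handle for later removal."""
        seg = np.atleast_2d(np.asarray(segment, dtype=float))
        if seg.shape[1] != self.latent_dim:
            raise ValueError(
                f"segment has {seg.shape[1]} dims, class model expects {self.latent_dim}"
            )
        handle = self._next_handle
        self._next_handle += 1
        self._segments[handle] = seg
        self.dirty = True
        return handle

    def remove_segment(self, handle: int) -> None:
        if handle not in self._segments:
            raise UnknownSegmentError(
                f"class {self.class_id}: no stored segment with handle {handle}"
            )
        del self._segments[handle]
        self.dirty = True

    # ------------------------------------------------------------- factorize
    def refresh(self) -> None:
        """Rebuild the (possibly subsampled) training set and its Gram factor."""
        if not self.dirty:
            return
        i_c = self.index_vector
        t_c = self.value_matrix
        if self.max_points is not None and i_c.size > self.max_points:
            keep = np.sort(self.rng.choice(i_c.size, size=self.max_points, replace=False))
            i_c = i_c[keep]
            t_c = t_c[keep]
        self._i_c = i_c
        self._t_c = t_c
        if i_c.size:
            C = build_gram(i_c, self.params, class_id=self.class_id)
            self._chol = _factorize(C, self.class_id)
            self._alpha = cho_solve(self._chol, t_c)
        else:
            self._chol = None
            self._alpha = None
        self.dirty = False

    # ------------------------------------------------------------- predictive
    def predict_many(self, positions) -> tuple[np.ndarray, np.ndarray]:
        """Predictive means and variances at several 1-based positions.

        Returns ``(means, variances)`` with shapes (P, d) and (P,): the
        variance is shared by all dimensions because the Gram matrix
        depends only on the position vector.
        """
        self.refresh()
        pos = np.asarray(positions, dtype=float)
        rho = kernel(pos, pos, self.params)
        rho = np.atleast_1d(np.asarray(rho, dtype=float))
        if self._i_c.size == 0:
            means = np.zeros((pos.size, self.latent_dim))
            var = rho.copy()
        else:
            Kx = kernel(self._i_c[:, None], pos[None, :], self.params)  # (N, P)
            means = Kx.T @ self._alpha
            v = cho_solve(self._chol, Kx)
            var = rho - np.einsum("np,np->p", Kx, v)
        if self.include_noise_in_predictive:
            var = var + 1.0 / self.params.omega
        if np.any(var < VARIANCE_FLOOR):
            logger.warning(
                "class %s: predictive variance clamped to floor %.1e",
                self.class_id,
                VARIANCE_FLOOR,
            )
            var = np.maximum(var, VARIANCE_FLOOR)
        return means, var

    def predict(self, i_hat: int) -> GPPredictive:
        """Predictive distribution at one within-segment position (1-based)."""
        means, var = self.predict_many([i_hat])
        return GPPredictive(
            mean=means[0], variance=np.full(self.latent_dim, var[0])
        )

    def segment_loglik(self, segment: np.ndarray) -> float:
        """Log-probability of a candidate (T_seg, d) segment under this class.

        Each point is scored against the stored class data only (no
        conditioning on the other points of the candidate), position i of
        the candidate against the predictive at i.
        """
        seg = np.asarray(segment, dtype=float)
        if seg.size == 0:
            return 0.0
        seg = np.atleast_2d(seg)
        T_seg = seg.shape[0]
        means, var = self.predict_many(np.arange(1, T_seg + 1))
        resid = seg - means
        ll = -0.5 * (
            np.log(2.0 * np.pi * var)[:, None] * np.ones_like(resid)
            + resid**2 / var[:, None]
        )
        return float(ll.sum())
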