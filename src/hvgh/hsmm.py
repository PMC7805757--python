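"""Explicit-duration semi-Markov segmentation of latent sequences.

The forward lattice alpha[t][k][c] holds the (log) probability that the
k frames ending at t form a segment of class c, marginalized over
everything before; segment lengths follow a Poisson duration model and
class transitions follow the HDP prior.  Backward sampling then draws a
segmentation exactly from the lattice posterior, and the blocked Gibbs
sweep resamples one whole sequence at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .gp import GPClassModel, KernelParams
from . import hdp
from .hdp import START, StickWeights, TransitionCounts

NEG_INF = -np.inf


class InfeasibleLatticeError(RuntimeError):
    """Raised when no segmentation can reach some frame."""


@dataclass(frozen=True)
class Tile:
    """One segment: frames [start, end) of one class; within-segment GP
    position of frame ``start + o`` is ``o + 1`` (1-based)."""

    start: int
    end: int  # exclusive
    cls: int

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_tiles(tiles, T: int, max_len: int | None = None) -> None:
    """Check that tiles are contiguous, nonempty and cover [0, T)."""
    if not tiles:
        raise ValueError("empty segmentation")
    pos = 0
    for tile in tiles:
        if tile.start != pos or tile.end <= tile.start:
            raise ValueError(f"tiles must tile [0, T) contiguously, got {tile}")
        if max_len is not None and tile.length > max_len:
            raise ValueError(f"tile longer than max length {max_len}: {tile}")
        pos = tile.end
    if pos != T:
        raise ValueError(f"tiles cover [0, {pos}), expected [0, {T})")


def duration_logpmf(k, lam: float):
    """Poisson(lam) log-pmf at segment length k (no truncation or
    renormalization over the admissible range)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    k_arr = np.asarray(k, dtype=float)
    out = k_arr * np.log(lam) - lam - gammaln(k_arr + 1.0)
    return out if out.shape else float(out)


def default_max_len(lam: float) -> int:
    """Default lattice depth K = ceil(2.5 * lam): beyond 99.9% of the
    Poisson duration mass at the lambdas in practical use."""
    return int(np.ceil(2.5 * lam))


@dataclass
class ForwardLattice:
    """Log-domain forward probabilities.

    ``log_alpha[t, k, c]`` is indexed by end frame t in 1..T (slot t),
    length k in 1..K (slot k-1) and class c in 0..C-1; slot 0 of the t
    axis is unused.  ``log_start[c]`` holds the START-row transition
    log-probabilities used at t - k = 0.
    """

    log_alpha: np.ndarray  # (T+1, K, C)
    log_trans: np.ndarray  # (C, C) rows source, cols destination
    log_start: np.ndarray  # (C,)

    @property
    def T(self) -> int:
        return self.log_alpha.shape[0] - 1

    @property
    def K(self) -> int:
        return self.log_alpha.shape[1]

    @property
    def n_classes(self) -> int:
        return self.log_alpha.shape[2]

    def log_marginal(self) -> float:
        return float(logsumexp(self.log_alpha[self.T]))


def _pointwise_logliks(latent_seq, gp_models, K):
    """M[c][a, p]: log-density of frame a under class c at position p+1."""
    T = latent_seq.shape[0]
    Kp = min(K, T)
    pos = np.arange(1, Kp + 1)
    Ms = []
    for model in gp_models:
        means, var = model.predict_many(pos)  # (Kp, d), (Kp,)
        resid = latent_seq[:, None, :] - means[None, :, :]  # (T, Kp, d)
        ll = -0.5 * (
            np.log(2.0 * np.pi * var)[None, :, None] + resid**2 / var[None, :, None]
        )
        Ms.append(ll.sum(axis=2))
    return Ms


def _segment_scores(M, T, K):
    """G[s, k]: summed log-density of frames s..s+k-1 at positions 1..k."""
    Kp = min(K, T)
    G = np.full((T + 1, Kp + 1), NEG_INF)
    G[:, 0] = 0.0
    for k in range(1, Kp + 1):
        s = np.arange(0, T - k + 1)
        G[s, k] = G[s, k - 1] + M[s + k - 1, k - 1]
    return G


def forward_filter(
    latent_seq: np.ndarray,
    gp_models,
    log_trans: np.ndarray,
    log_start: np.ndarray,
    lam: float,
    K: int,
) -> ForwardLattice:
    """Fill the forward lattice for one latent sequence.

    Parameters
    ----------
    latent_seq : (T, d) array
    gp_models : sequence of GPClassModel, one per candidate class
    log_trans : (C, C) log transition matrix between candidate classes
    log_start : (C,) log probabilities of the sequence-initial class
    lam : Poisson duration mean
    K : maximum segment length
    """
    latent_seq = np.atleast_2d(np.asarray(latent_seq, dtype=float))
    T = latent_seq.shape[0]
    C = len(gp_models)
    if C < 1 or K < 1:
        raise ValueError("need at least one class and K >= 1")
    Kp = min(K, T)
    Ms = _pointwise_logliks(latent_seq, gp_models, K)
    Gs = [_segment_scores(M, T, K) for M in Ms]
    dur = duration_logpmf(np.arange(1, Kp + 1), lam)

    log_alpha = np.full((T + 1, Kp, C), NEG_INF)
    incoming = np.empty((T + 1, C))  # logsumexp_{c'} alpha-mass * trans into c
    incoming[0] = log_start
    for t in range(1, T + 1):
        ks = np.arange(1, min(Kp, t) + 1)
        for c in range(C):
            seg = Gs[c][t - ks, ks]
            log_alpha[t, ks - 1, c] = seg + dur[ks - 1] + incoming[t - ks, c]
        m_t = logsumexp(log_alpha[t], axis=0)  # (C,) mass per class ending at t
        if not np.any(np.isfinite(m_t)):
            raise InfeasibleLatticeError(f"no admissible segmentation reaches frame {t}")
        incoming[t] = logsumexp(m_t[:, None] + log_trans, axis=0)
    return ForwardLattice(log_alpha=log_alpha, log_trans=log_trans, log_start=log_start)


def _sample_cell(logw: np.ndarray, rng) -> tuple[int, int]:
    flat = logw.reshape(-1)
    mx = flat.max()
    if not np.isfinite(mx):
        raise InfeasibleLatticeError("no admissible cell to sample")
    p = np.exp(flat - mx)
    p /= p.sum()
    idx = rng.choice(flat.size, p=p)
    return np.unravel_index(idx, logw.shape)


def backward_sample(lattice: ForwardLattice, rng: np.random.Generator):
    """Draw one segmentation exactly from the lattice posterior.

    The final segment is sampled proportionally to alpha[T][k][c]; each
    earlier segment proportionally to alpha[t][k][c] times the
    transition probability into the already-sampled following class.
    Returns tiles in temporal order.
    """
    t = lattice.T
    tiles: list[Tile] = []
    next_cls: int | None = None
    while t > 0:
        logw = lattice.log_alpha[t].copy()
        if next_cls is not None:
            logw = logw + lattice.log_trans[None, :, next_cls]
        k_idx, c = _sample_cell(logw, rng)
        k = k_idx + 1
        tiles.append(Tile(start=t - k, end=t, cls=int(c)))
        next_cls = int(c)
        t -= k
    tiles.reverse()
    validate_tiles(tiles, lattice.T)
    return tiles


# --------------------------------------------------------------------------
# Blocked Gibbs state and sweep
# --------------------------------------------------------------------------


@dataclass
class GibbsConfig:
    lam: float = 14.0
    K: int | None = None  # default ceil(2.5 * lam)
    gamma: float = 1.0
    eta: float = 1.0
    kernel: KernelParams = field(default_factory=KernelParams)
    max_class_points: int | None = 150
    include_noise_in_predictive: bool = False

    @property
    def max_len(self) -> int:
        return self.K if self.K is not None else default_max_len(self.lam)


@dataclass
class GibbsState:
    """Segmentations, per-class GP stores, HDP counts and sticks.

    ``handles[n]`` keeps, per tile of sequence n, the (class, handle)
    pair naming the tile's rows inside the class GP store so a sweep can
    remove exactly what it added.
    """

    config: GibbsConfig
    latent_dim: int
    rng: np.random.Generator
    beta: StickWeights
    counts: TransitionCounts = field(default_factory=TransitionCounts)
    segmentations: list = field(default_factory=list)  # list[list[Tile]]
    gp_models: dict = field(default_factory=dict)  # class id -> GPClassModel
    handles: list = field(default_factory=list)  # list[list[(cls, handle)]]

    def model_for(self, c: int) -> GPClassModel:
        if c not in self.gp_models:
            self.gp_models[c] = GPClassModel(
                class_id=c,
                latent_dim=self.latent_dim,
                params=self.config.kernel,
                max_points=self.config.max_class_points,
                rng=self.rng,
                include_noise_in_predictive=self.config.include_noise_in_predictive,
            )
        return self.gp_models[c]

    # ------------------------------------------------------------- plumbing
    def _add_sequence(self, n: int, latent_seq: np.ndarray, tiles) -> None:
        self.segmentations[n] = list(tiles)
        hs = []
        prev = START
        for tile in tiles:
            h = self.model_for(tile.cls).add_segment(latent_seq[tile.start : tile.end])
            hs.append((tile.cls, h))
            self.counts.add_segment_of(tile.cls)
            self.counts.add_transition(prev, tile.cls)
            prev = tile.cls
        self.counts.n_class[START] = self.counts.n_class.get(START, 0) + 1
        self.handles[n] = hs

    def _remove_sequence(self, n: int) -> None:
        tiles = self.segmentations[n]
        prev = START
        for tile, (cls, h) in zip(tiles, self.handles[n]):
            self.gp_models[cls].remove_segment(h)
            self.counts.remove_segment_of(tile.cls)
            self.counts.remove_transition(prev, tile.cls)
            prev = tile.cls
        self.counts.n_class[START] -= 1
        if self.counts.n_class[START] < 0:
            raise hdp.CountUnderflowError("START count underflow")
        self.segmentations[n] = []
        self.handles[n] = []

    def classes_in_use(self) -> set:
        return {tile.cls for tiles in self.segmentations for tile in tiles}

    def prune_unused(self) -> None:
        """Drop atoms no segmentation uses; their stick mass rejoins the
        remainder and remaining classes are relabelled contiguously."""
        used = sorted(self.classes_in_use())
        if len(used) == self.beta.n_atoms and used == list(range(len(used))):
            return
        mapping = {c: i for i, c in enumerate(used)}
        keep = np.zeros(self.beta.n_atoms, dtype=bool)
        for c in used:
            keep[c] = True
        self.beta.drop_atoms(keep)
        self.counts = self.counts.remap(mapping)
        self.gp_models = {
            mapping[c]: m for c, m in self.gp_models.items() if c in mapping
        }
        for c, m in self.gp_models.items():
            m.class_id = c
        self.segmentations = [
            [Tile(t.start, t.end, mapping[t.cls]) for t in tiles]
            for tiles in self.segmentations
        ]
        self.handles = [
            [(mapping[c], h) for c, h in hs] for hs in self.handles
        ]

    def audit(self, latent_seqs) -> None:
        """Recompute counts and GP stores from the segmentation and
        verify they match the incremental state (consistency check)."""
        fresh = TransitionCounts()
        points = {}
        for n, tiles in enumerate(self.segmentations):
            validate_tiles(tiles, latent_seqs[n].shape[0], self.config.max_len)
            prev = START
            for tile in tiles:
                fresh.add_segment_of(tile.cls)
                fresh.add_transition(prev, tile.cls)
                points[tile.cls] = points.get(tile.cls, 0) + tile.length
                prev = tile.cls
            fresh.n_class[START] = fresh.n_class.get(START, 0) + 1
        clean = lambda d: {k: v for k, v in d.items() if v > 0}
        if clean(fresh.n_class) != clean(self.counts.n_class):
            raise RuntimeError("segment counts inconsistent with segmentation")
        if clean(fresh.n_trans) != clean(self.counts.n_trans):
            raise RuntimeError("transition counts inconsistent with segmentation")
        for c, npts in points.items():
            if self.gp_models[c].n_points != npts:
                raise RuntimeError(f"GP store of class {c} inconsistent")


def random_initial_tiles(T: int, lam: float, K: int, n_classes: int, rng) -> list:
    """Random initialization: segments of roughly mean length lam,
    classes uniform over a small initial pool."""
    tiles = []
    t = 0
    while t < T:
        k = int(np.clip(rng.poisson(lam), 1, min(K, T - t)))
        c = int(rng.integers(n_classes))
        tiles.append(Tile(t, t + k, c))
        t += k
    return tiles


def init_state(latent_seqs, config: GibbsConfig, rng: np.random.Generator) -> GibbsState:
    """Random segmentation with an initial pool of one class plus one
    fresh class, and sticks drawn from the GEM prior."""
    beta = hdp.sample_gem(config.gamma, 2, rng)
    state = GibbsState(
        config=config,
        latent_dim=latent_seqs[0].shape[1],
        rng=rng,
        beta=beta,
    )
    state.segmentations = [[] for _ in latent_seqs]
    state.handles = [[] for _ in latent_seqs]
    for n, seq in enumerate(latent_seqs):
        tiles = random_initial_tiles(
            seq.shape[0], config.lam, config.max_len, beta.n_atoms, rng
        )
        state._add_sequence(n, seq, tiles)
    state.prune_unused()
    return state


def blocked_gibbs_sweep(latent_seqs, state: GibbsState, rng: np.random.Generator) -> GibbsState:
    """One blocked Gibbs sweep: resample every sequence's segmentation.

    Per sequence: remove its segments and counts, slice-sample the
    truncation, forward filter, backward sample, re-add, then resample
    the stick weights and prune unused classes.
    """
    cfg = state.config
    for n, seq in enumerate(latent_seqs):
        old_classes = [t.cls for t in state.segmentations[n]]
        state._remove_sequence(n)
        us = hdp.slice_variables(old_classes, state.counts, state.beta, cfg.eta, rng)
        hdp.expand_sticks_to_slice(
            state.beta, state.counts, cfg.eta, cfg.gamma, min(us), rng
        )
        C = state.beta.n_atoms
        models = [state.model_for(c) for c in range(C)]
        classes = list(range(C))
        with np.errstate(divide="ignore"):
            log_trans = np.log(
                hdp.trans_matrix(classes, classes, state.counts, state.beta, cfg.eta)
            )
            log_start = np.log(
                np.array(
                    [
                        hdp.trans_prob(START, c, state.counts, state.beta, cfg.eta)
                        for c in classes
                    ]
                )
            )
        lattice = forward_filter(seq, models, log_trans, log_start, cfg.lam, cfg.max_len)
        tiles = backward_sample(lattice, rng)
        state._add_sequence(n, seq, tiles)
        state.beta = hdp.update_beta(state.counts, state.beta, cfg.gamma, cfg.eta, rng)
        state.prune_unused()
    return state
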