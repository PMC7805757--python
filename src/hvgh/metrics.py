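"""Segmentation accuracy metrics and random baselines.

Frame-level accuracy is the normalized Hamming distance after an
optimal one-to-one matching between estimated and true label sets
(estimated labels carry no intrinsic identity).  Boundary accuracy is
precision/recall/F over segment boundaries, counting an estimated
boundary correct when it lies within +-psi% of the sequence length of
an unmatched true boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class EvalReport:
    hamming: float
    precision: float
    recall: float
    f_measure: float
    n_classes: int
    psi: float

    def as_dict(self) -> dict:
        return asdict(self)


def labels_to_boundaries(labels) -> list[int]:
    """Interior change points of a frame-label sequence (endpoints 0 and
    T are not boundaries)."""
    labels = np.asarray(labels)
    return [int(i) for i in np.flatnonzero(labels[1:] != labels[:-1]) + 1]


def labels_to_segments(labels):
    """(start, end, class) runs of a frame-label sequence."""
    labels = np.asarray(labels)
    bounds = [0] + labels_to_boundaries(labels) + [len(labels)]
    return [(bounds[i], bounds[i + 1], int(labels[bounds[i]])) for i in range(len(bounds) - 1)]


def normalized_hamming(est, truth) -> float:
    """Mismatch fraction after maximum-agreement one-to-one label matching.

    The matching is solved exactly on the contingency table (Hungarian
    assignment); estimated labels left unmatched count all their frames
    as errors.  Ranges over [0, 1]; 0 means identical partitions.
    """
    est = np.asarray(est)
    truth = np.asarray(truth)
    if est.shape != truth.shape:
        raise ValueError(f"label length mismatch: {est.shape} vs {truth.shape}")
    T = est.size
    if T == 0:
        return 0.0
    e_ids, e_inv = np.unique(est, return_inverse=True)
    t_ids, t_inv = np.unique(truth, return_inverse=True)
    table = np.zeros((e_ids.size, t_ids.size), dtype=int)
    np.add.at(table, (e_inv, t_inv), 1)
    rows, cols = linear_sum_assignment(table, maximize=True)
    agree = int(table[rows, cols].sum())
    return 1.0 - agree / T


def boundary_prf(est_bounds, true_bounds, T: int, psi: float = 5.0):
    """Boundary precision, recall and F-measure at a +-psi% window.

    The window is round(psi/100 * T) frames.  Estimated and true
    boundaries are matched greedily nearest-first, each usable once;
    matches are true positives, unmatched estimated boundaries false
    positives, unmatched true boundaries false negatives.  A zero
    denominator yields 0 by convention.
    """
    if not 0 < psi <= 100:
        raise ValueError("psi must be in (0, 100]")
    est = sorted(int(b) for b in est_bounds)
    tru = sorted(int(b) for b in true_bounds)
    for b in est + tru:
        if not 0 < b < T:
            raise ValueError(f"boundary {b} outside (0, {T})")
    w = int(round(psi / 100.0 * T))
    pairs = sorted(
        ((abs(e - t), ei, ti) for ei, e in enumerate(est) for ti, t in enumerate(tru)
         if abs(e - t) <= w),
        key=lambda x: (x[0], x[1], x[2]),
    )
    used_e, used_t = set(), set()
    tp = 0
    for _, ei, ti in pairs:
        if ei in used_e or ti in used_t:
            continue
        used_e.add(ei)
        used_t.add(ti)
        tp += 1
    fp = len(est) - tp
    fn = len(tru) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def count_classes(labels_or_tiles) -> int:
    """Distinct class ids used by a labeling or a list of (s, e, c) tiles."""
    items = list(labels_or_tiles) if not isinstance(labels_or_tiles, np.ndarray) else labels_or_tiles
    if len(items) == 0:
        return 0
    first = items[0]
    if np.isscalar(first) or isinstance(first, (int, np.integer)):
        return int(np.unique(np.asarray(items)).size)
    return len({getattr(t, "cls", t[2] if isinstance(t, tuple) else None) for t in items})


def evaluate_labels(est, truth, psi: float = 5.0) -> EvalReport:
    """Full report (Hamming + boundary PRF + class count) from frame labels."""
    est = np.asarray(est)
    truth = np.asarray(truth)
    p, r, f = boundary_prf(
        labels_to_boundaries(est), labels_to_boundaries(truth), truth.size, psi
    )
    return EvalReport(
        hamming=normalized_hamming(est, truth),
        precision=p,
        recall=r,
        f_measure=f,
        n_classes=count_classes(est),
        psi=psi,
    )


def _boundary_counts(est_bounds, true_bounds, T, psi):
    p, r, _ = boundary_prf(est_bounds, true_bounds, T, psi)
    tp = int(round(r * len(list(true_bounds))))
    return tp, len(list(est_bounds)) - tp, len(list(true_bounds)) - tp


def evaluate_dataset(est_labels, true_labels, psi: float = 5.0) -> EvalReport:
    """Dataset-level report over several sequences.

    The Hamming distance uses one global label matching on the
    concatenated frames (class ids are shared across sequences);
    boundary TP/FP/FN are pooled per sequence, so each sequence's
    +-psi% window refers to its own length and concatenation seams do
    not count as boundaries.
    """
    tp = fp = fn = 0
    for est, tru in zip(est_labels, true_labels):
        a, b, c = _boundary_counts(
            labels_to_boundaries(est), labels_to_boundaries(tru), len(tru), psi
        )
        tp, fp, fn = tp + a, fp + b, fn + c
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    cat_est = np.concatenate([np.asarray(e) for e in est_labels])
    cat_tru = np.concatenate([np.asarray(t) for t in true_labels])
    return EvalReport(
        hamming=normalized_hamming(cat_est, cat_tru),
        precision=precision,
        recall=recall,
        f_measure=f,
        n_classes=count_classes(cat_est),
        psi=psi,
    )


def _random_labels(truth, mode, rng):
    truth = np.asarray(truth)
    T = truth.size
    J_true = len(labels_to_segments(truth))
    n_cls = count_classes(truth)
    if mode == "A":
        J = J_true
    elif mode == "B":
        J = 2 * J_true
    elif mode == "C":
        J = max(1, int(round(J_true / 2)))
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    J = min(J, T)
    if J > 1:
        cuts = np.sort(rng.choice(np.arange(1, T), size=J - 1, replace=False))
    else:
        cuts = np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [T]]).astype(int)
    labels = np.empty(T, dtype=int)
    for s, e in zip(bounds[:-1], bounds[1:]):
        labels[s:e] = rng.integers(n_cls)
    return labels


def random_baseline_dataset(
    true_labels,
    mode: str = "A",
    trials: int = 100,
    psi: float = 5.0,
    rng: np.random.Generator | None = None,
) -> EvalReport:
    """Dataset-level random baseline: per trial, every sequence gets an
    independent uniform segmentation; the pooled report is averaged
    over trials."""
    rng = rng if rng is not None else np.random.default_rng(0)
    accum = np.zeros(5)
    for _ in range(trials):
        est = [_random_labels(t, mode, rng) for t in true_labels]
        rep = evaluate_dataset(est, true_labels, psi)
        accum += [rep.hamming, rep.precision, rep.recall, rep.f_measure, rep.n_classes]
    accum /= trials
    return EvalReport(
        hamming=float(accum[0]),
        precision=float(accum[1]),
        recall=float(accum[2]),
        f_measure=float(accum[3]),
        n_classes=int(round(accum[4])),
        psi=psi,
    )


def random_baseline(
    truth,
    mode: str = "A",
    trials: int = 100,
    psi: float = 5.0,
    rng: np.random.Generator | None = None,
) -> EvalReport:
    """Average metrics of uniformly random segmentations.

    The sequence is cut at J-1 interior boundaries drawn uniformly
    without replacement, J being the true segment count (mode A), twice
    it (mode B) or half of it (mode C, at least one segment); segment
    classes are uniform over the true class inventory.  Metrics are
    averaged over ``trials`` draws.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    truth = np.asarray(truth)
    accum = np.zeros(5)
    for _ in range(trials):
        labels = _random_labels(truth, mode, rng)
        rep = evaluate_labels(labels, truth, psi)
        accum += [rep.hamming, rep.precision, rep.recall, rep.f_measure, rep.n_classes]
    accum /= trials
    return EvalReport(
        hamming=float(accum[0]),
        precision=float(accum[1]),
        recall=float(accum[2]),
        f_measure=float(accum[3]),
        n_classes=int(round(accum[4])),
        psi=psi,
    )
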