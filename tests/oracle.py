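"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from the definitions (explicit
matrix inverses, exhaustive enumeration, math.factorial) and shares no
code with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def oracle_kernel(ip, iq, theta):
    t0, t1, t2, t3 = theta
    return t0 * math.exp(-0.5 * t1 * (ip - iq) ** 2) + t2 + t3 * ip * iq


def oracle_gram(indices, theta, omega):
    n = len(indices)
    C = np.empty((n, n))
    for p in range(n):
        for q in range(n):
            C[p, q] = oracle_kernel(indices[p], indices[q], theta)
            if p == q:
                C[p, q] += 1.0 / omega
    return C


def oracle_predict(train_idx, train_vals, i_hat, theta, omega):
    """Predictive (mean-vector, variance) at position i_hat via an
    explicit matrix inverse; train_vals is (N, d)."""
    rho = oracle_kernel(i_hat, i_hat, theta)
    if len(train_idx) == 0:
        return np.zeros(np.atleast_2d(train_vals).shape[1] if np.size(train_vals) else 1), rho
    Cinv = np.linalg.inv(oracle_gram(train_idx, theta, omega))
    k = np.array([oracle_kernel(i, i_hat, theta) for i in train_idx])
    mean = k @ Cinv @ np.atleast_2d(train_vals)
    var = rho - k @ Cinv @ k
    return mean, var


def oracle_segment_loglik(train_idx, train_vals, segment, theta, omega):
    """Sum of per-point Gaussian log densities, position i of the
    candidate against the predictive at i."""
    total = 0.0
    segment = np.atleast_2d(segment)
    for i in range(segment.shape[0]):
        mean, var = oracle_predict(train_idx, train_vals, i + 1, theta, omega)
        for d in range(segment.shape[1]):
            total += -0.5 * math.log(2 * math.pi * var) - (
                segment[i, d] - mean[d]
            ) ** 2 / (2 * var)
    return total


def oracle_poisson_logpmf(k, lam):
    return k * math.log(lam) - lam - math.log(math.factorial(k))


def compositions(T, K):
    """All ordered compositions of T into parts in 1..K."""
    if T == 0:
        yield ()
        return
    for first in range(1, min(K, T) + 1):
        for rest in compositions(T - first, K):
            yield (first,) + rest


def enumerate_segmentations(T, K, C):
    """All (lengths, classes) segmentations of T frames."""
    for comp in compositions(T, K):
        for classes in product(range(C), repeat=len(comp)):
            yield comp, classes


def oracle_log_joint(latent_seq, comp, classes, class_data, theta, omega, lam,
                     trans, start):
    """Log-probability of one segmentation.

    class_data[c] = (train_idx, train_vals); trans[c', c] and start[c]
    are linear-domain transition probabilities.
    """
    logp = 0.0
    t = 0
    prev = None
    for k, c in zip(comp, classes):
        seg = latent_seq[t : t + k]
        idx, vals = class_data[c]
        logp += oracle_segment_loglik(idx, vals, seg, theta, omega)
        logp += oracle_poisson_logpmf(k, lam)
        logp += math.log(start[c] if prev is None else trans[prev, c])
        prev = c
        t += k
    return logp


def oracle_log_marginal(latent_seq, K, C, class_data, theta, omega, lam, trans, start):
    """Log of the sum over all segmentations (exhaustive enumeration)."""
    T = latent_seq.shape[0]
    logs = [
        oracle_log_joint(latent_seq, comp, cls, class_data, theta, omega, lam, trans, start)
        for comp, cls in enumerate_segmentations(T, K, C)
    ]
    m = max(logs)
    return m + math.log(sum(math.exp(v - m) for v in logs))


def oracle_posterior(latent_seq, K, C, class_data, theta, omega, lam, trans, start):
    """Exact posterior over segmentations as {(comp, classes): prob}."""
    items = {}
    for comp, cls in enumerate_segmentations(latent_seq.shape[0], K, C):
        items[(comp, cls)] = oracle_log_joint(
            latent_seq, comp, cls, class_data, theta, omega, lam, trans, start
        )
    m = max(items.values())
    weights = {k: math.exp(v - m) for k, v in items.items()}
    Z = sum(weights.values())
    return {k: w / Z for k, w in weights.items()}
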