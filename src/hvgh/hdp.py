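"""Hierarchical Dirichlet process prior over segment classes.

A GEM (stick-breaking) draw beta gives the global popularity of an
unbounded class inventory; each source class c' transitions to class c
with probability (N_{c'c} + eta * beta_c) / (N_{c'} + eta), mixing
observed transition counts with the shared base measure.  Slice
variables sampled per transition truncate the inventory to the finitely
many classes a blocked Gibbs sweep has to consider.

Sequence-initial transitions are booked under a dedicated start
pseudo-class (``START``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: pseudo-class id for the sequence-initial transition row
START = -1

#: hard cap on instantiated atoms (safety valve for the stick-breaking loop)
MAX_ATOMS = 512


class ZeroProbabilityTransitionError(ValueError):
    """Raised when slicing a transition whose current probability is zero."""


class CountUnderflowError(RuntimeError):
    """Raised when a transition/segment count would go negative."""


@dataclass
class StickWeights:
    """Stick-breaking weights: instantiated atoms plus unbroken remainder."""

    atoms: np.ndarray
    remainder: float

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        total = self.atoms.sum() + self.remainder
        if np.any(self.atoms < 0) or self.remainder < 0:
            raise ValueError("stick weights must be nonnegative")
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"stick weights must sum to 1, got {total!r}")

    @property
    def n_atoms(self) -> int:
        return int(self.atoms.size)

    def break_atom(self, gamma: float, rng: np.random.Generator) -> int:
        """Split a new atom off the remainder with a Beta(1, gamma) fraction.

        Returns the index of the new atom.
        """
        v = rng.beta(1.0, gamma)
        new = v * self.remainder
        self.atoms = np.append(self.atoms, new)
        self.remainder *= 1.0 - v
        return self.atoms.size - 1

    def drop_atoms(self, keep: np.ndarray) -> None:
        """Keep only the atoms flagged in the boolean mask; mass of the
        dropped atoms returns to the remainder."""
        keep = np.asarray(keep, dtype=bool)
        self.remainder += float(self.atoms[~keep].sum())
        self.atoms = self.atoms[keep]


def sample_gem(gamma: float, max_atoms: int, rng: np.random.Generator) -> StickWeights:
    """Draw the first ``max_atoms`` stick-breaking weights of GEM(gamma)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    v = rng.beta(1.0, gamma, size=max_atoms)
    v = np.minimum(v, 1.0 - 1e-16)  # beta() can round to exactly 1 at tiny gamma
    log_rem = np.concatenate([[0.0], np.cumsum(np.log1p(-v))])
    atoms = v * np.exp(log_rem[:-1])
    return StickWeights(atoms=atoms, remainder=float(np.exp(log_rem[-1])))


@dataclass
class TransitionCounts:
    """Segment and transition counts over instantiated classes.

    ``n_class[c]`` counts segments of class c (START counts sequences);
    ``n_trans[(c', c)]`` counts observed transitions c' -> c, including
    the START -> first-segment transition.  Final segments of a sequence
    have no outgoing transition, so sum_c n_trans[(c', c)] <= n_class[c'].
    """

    n_class: dict = field(default_factory=dict)
    n_trans: dict = field(default_factory=dict)

    def add_segment_of(self, c: int) -> None:
        """Book one segment of class c with no outgoing transition yet."""
        self.n_class[c] = self.n_class.get(c, 0) + 1

    def remove_segment_of(self, c: int) -> None:
        if self.n_class.get(c, 0) <= 0:
            raise CountUnderflowError(f"removing segment of absent class {c}")
        self.n_class[c] -= 1

    def add_transition(self, c_prev: int, c: int) -> None:
        self.n_trans[(c_prev, c)] = self.n_trans.get((c_prev, c), 0) + 1

    def remove_transition(self, c_prev: int, c: int) -> None:
        if self.n_trans.get((c_prev, c), 0) <= 0:
            raise CountUnderflowError(
                f"removing absent transition {c_prev} -> {c}"
            )
        self.n_trans[(c_prev, c)] -= 1

    def out_count(self, c_prev: int) -> int:
        return self.n_class.get(c_prev, 0)

    def remap(self, mapping: dict) -> "TransitionCounts":
        """Relabel classes (START maps to itself); drops unmapped classes."""
        m = dict(mapping)
        m[START] = START
        n_class = {
            m[c]: n for c, n in self.n_class.items() if c in m and n > 0
        }
        n_trans = {
            (m[a], m[b]): n
            for (a, b), n in self.n_trans.items()
            if a in m and b in m and n > 0
        }
        return TransitionCounts(n_class=n_class, n_trans=n_trans)


def trans_prob(
    c_prev: int,
    c: int,
    counts: TransitionCounts,
    beta: StickWeights,
    eta: float,
    source_class_beta: bool = False,
) -> float:
    """Transition probability c_prev -> c under the HDP.

    ``c`` may be an atom index or ``beta.n_atoms`` to denote the fresh
    (not yet instantiated) slot, whose base mass is the stick remainder.
    With ``source_class_beta`` the base-measure weight of the *source*
    class is used instead of the destination's; that variant does not
    normalize over destinations and exists only for comparison.
    """
    if c == beta.n_atoms:
        beta_c = beta.remainder
    else:
        beta_c = float(beta.atoms[c])
    if source_class_beta:
        beta_c = 1.0 if c_prev == START else float(beta.atoms[c_prev])
    n_out = counts.out_count(c_prev)
    n_cc = counts.n_trans.get((c_prev, c), 0)
    return (n_cc + eta * beta_c) / (n_out + eta)


def trans_matrix(
    row_classes,
    col_classes,
    counts: TransitionCounts,
    beta: StickWeights,
    eta: float,
) -> np.ndarray:
    """Matrix of trans_prob over given source rows and destination columns."""
    return np.array(
        [[trans_prob(a, b, counts, beta, eta) for b in col_classes] for a in row_classes]
    )


def slice_variables(
    class_sequence,
    counts: TransitionCounts,
    beta: StickWeights,
    eta: float,
    rng: np.random.Generator,
):
    """Auxiliary slice variables, one per transition of a class sequence.

    ``class_sequence`` is the ordered classes (c_1 .. c_J) of one
    sequence's segments; the initial transition is START -> c_1.  Each
    u_j ~ Uniform(0, pi_{c_{j-1}, c_j}).
    """
    cs = list(class_sequence)
    if not cs:
        raise ValueError("need at least one segment to slice")
    us = []
    prev = START
    for c in cs:
        p = trans_prob(prev, c, counts, beta, eta)
        if p <= 0.0:
            raise ZeroProbabilityTransitionError(
                f"transition {prev} -> {c} has zero probability"
            )
        us.append(rng.uniform(0.0, p))
        prev = c
    return us


def expand_sticks_to_slice(
    beta: StickWeights,
    counts: TransitionCounts,
    eta: float,
    gamma: float,
    u_min: float,
    rng: np.random.Generator,
) -> None:
    """Break fresh atoms off the remainder until the largest possible
    fresh-slot transition probability falls below ``u_min``.

    The bound max_{c'} eta*beta_rest/(N_{c'} + eta) is achieved at the
    smallest outgoing count (>= 0), so eta*beta_rest/eta = beta_rest
    upper-bounds every row.
    """
    while beta.remainder >= u_min and beta.n_atoms < MAX_ATOMS:
        beta.break_atom(gamma, rng)


def truncation_level(
    u,
    class_sequence,
    counts: TransitionCounts,
    beta: StickWeights,
    eta: float,
    classes_in_use: int = 0,
) -> int:
    """Number of candidate classes surviving the slice thresholds.

    For each transition j the candidates are the instantiated atoms with
    pi_{c_{j-1}, c} > u_j; the level is the max over transitions,
    floored at the number of classes the current segmentation uses.
    """
    cs = list(class_sequence)
    level = 0
    prev = START
    for u_j, c in zip(u, cs):
        cnt = sum(
            1
            for cand in range(beta.n_atoms)
            if trans_prob(prev, cand, counts, beta, eta) > u_j
        )
        level = max(level, cnt)
        prev = c
    return max(level, classes_in_use)


def _antoniak_tables(n: int, alpha: float, rng: np.random.Generator) -> int:
    """Number of occupied tables when n customers sit under CRP(alpha)."""
    if n <= 0:
        return 0
    i = np.arange(n, dtype=float)
    return int(np.sum(rng.random(n) < alpha / (alpha + i)))


def update_beta(
    counts: TransitionCounts,
    beta: StickWeights,
    gamma: float,
    eta: float,
    rng: np.random.Generator,
) -> StickWeights:
    """Resample the global stick weights given the transition counts.

    Auxiliary table counts m_{c'c} are drawn via the Chinese-restaurant
    construction from (N_{c'c}, eta * beta_c); beta is then a Dirichlet
    draw on (sum_{c'} m_{c'1}, ..., sum_{c'} m_{c'C}, gamma), the last
    slot becoming the new remainder.
    """
    C = beta.n_atoms
    if not any(n > 0 for n in counts.n_trans.values()):
        return sample_gem(gamma, max(C, 1), rng)
    m = np.zeros(C)
    for (c_prev, c), n in counts.n_trans.items():
        if n <= 0 or c < 0 or c >= C:
            continue
        m[c] += _antoniak_tables(n, eta * float(beta.atoms[c]), rng)
    # every instantiated class keeps at least one table so its weight
    # cannot collapse to an exact zero while it is still in use
    used = np.array([counts.n_class.get(c, 0) > 0 for c in range(C)])
    m[used] = np.maximum(m[used], 1.0)
    draw = rng.dirichlet(np.concatenate([m + 1e-12, [gamma]]))
    return StickWeights(atoms=draw[:-1], remainder=float(draw[-1]))
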