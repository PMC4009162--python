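"""Noise-perturbed state-transition kernel and simpler barrier measures.

Expression noise is modeled as independent per-gene bit flips: at each
synchronous update step every gene flips with probability ``p``.  Under the
standard perturbed-Boolean-network convention, flips preempt the update:
with probability ``(1-p)^n`` no gene flips and the deterministic map D
fires; otherwise the state jumps to the flipped state.  The resulting
one-step transition probability from x to z (Hamming distance h) is

    P(x, z) = [h >= 1] * p^h * (1-p)^(n-h) + [z = D(x)] * (1-p)^n

which is row-stochastic by construction.

Two cheaper barrier measures are also provided: the Hamming distance
between states, and the single-bit-flip measure (perturb one bit of an
attractor state, relax deterministically, record the receiving attractor).
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Iterable

import numpy as np

from .network_model import BooleanNetwork, NetworkState
from .dynamics import AttractorSet, successor_table

__all__ = [
    "TransitionKernel",
    "hamming",
    "flip_probability",
    "transition_prob",
    "single_bit_flip_counts",
    "single_bit_flip_matrix",
]

DENSE_LIMIT = 14  # genes; above this rows are generated lazily


def hamming(x, y, n: int | None = None) -> int:
    """Number of differing bits between two states.

    Accepts integer state indices (with ``n`` optional) or equal-length bit
    sequences / :class:`NetworkState` objects.
    """
    if isinstance(x, NetworkState):
        x = x.bits
    if isinstance(y, NetworkState):
        y = y.bits
    if isinstance(x, (int, np.integer)) and isinstance(y, (int, np.integer)):
        return int(np.bitwise_count(np.int64(x) ^ np.int64(y)))
    xb = [int(bool(b)) for b in x]
    yb = [int(bool(b)) for b in y]
    if len(xb) != len(yb):
        raise ValueError(f"length mismatch: {len(xb)} vs {len(yb)}")
    return sum(a != b for a, b in zip(xb, yb))


def flip_probability(n: int, r: int, p: float) -> float:
    """Binomial probability of exactly ``r`` of ``n`` bits flipping."""
    if not 0 <= r <= n:
        raise ValueError(f"r={r} out of range [0, {n}]")
    if not 0 < p < 1:
        raise ValueError(f"flip probability p={p} must be in (0, 1)")
    return comb(n, r) * p**r * (1 - p) ** (n - r)


class TransitionKernel:
    """Row-stochastic one-step transition kernel under flip noise.

    Dense (2^n x 2^n) for small networks, lazy row generation above
    ``dense_limit``.  Entries depend only on D(x), Hamming(x, z), n and p.
    """

    def __init__(
        self,
        net: BooleanNetwork,
        p: float,
        dense_limit: int = DENSE_LIMIT,
    ):
        if not 0 < p < 1:
            raise ValueError(f"flip probability p={p} must be in (0, 1)")
        self.net = net
        self.n = net.n
        self.p = float(p)
        self.n_states = 2**net.n
        self.successors = successor_table(net)
        self._dense: np.ndarray | None = None
        if net.n <= dense_limit:
            self._dense = self._build_dense()

    def _row_values(self, x: int) -> np.ndarray:
        z = np.arange(self.n_states, dtype=np.int64)
        h = np.bitwise_count(np.int64(x) ^ z).astype(np.int64)
        row = self.p**h * (1 - self.p) ** (self.n - h)
        row[x] = 0.0  # the h=0 term exists only through the deterministic route
        row[int(self.successors[x])] += (1 - self.p) ** self.n
        return row

    def _build_dense(self) -> np.ndarray:
        mat = np.empty((self.n_states, self.n_states), dtype=np.float64)
        for x in range(self.n_states):
            mat[x] = self._row_values(x)
        return mat

    @property
    def matrix(self) -> np.ndarray:
        """Dense kernel; raises for networks above the dense limit."""
        if self._dense is None:
            raise ValueError(
                f"{self.n}-gene kernel is lazy; use row() or lower dense_limit"
            )
        return self._dense

    def row(self, x: int) -> np.ndarray:
        if self._dense is not None:
            return self._dense[x]
        return self._row_values(int(x))

    def prob(self, x: int, z: int) -> float:
        x, z = int(x), int(z)
        h = hamming(x, z)
        val = 0.0
        if h >= 1:
            val += self.p**h * (1 - self.p) ** (self.n - h)
        if z == int(self.successors[x]):
            val += (1 - self.p) ** self.n
        return val


def transition_prob(net: BooleanNetwork, p: float, x: int, z: int) -> float:
    """One-step probability of moving from state ``x`` to state ``z``."""
    return TransitionKernel(net, p, dense_limit=0).prob(x, z)


def single_bit_flip_counts(net: BooleanNetwork, aset: AttractorSet) -> np.ndarray:
    """Count matrix c[i, j]: single-bit perturbations of attractor i's cycle
    states whose deterministic relaxation lands in attractor j.  Row i sums
    to period_i * n exactly."""
    m = aset.m
    counts = np.zeros((m, m), dtype=np.int64)
    for a in aset.attractors:
        for s in a.states:
            for bit in range(net.n):
                target = int(aset.basin_map[s ^ (1 << bit)])
                counts[a.id, target] += 1
    return counts

def single_bit_flip_matrix(net: BooleanNetwork, aset: AttractorSet) -> np.ndarray:
    """Single-bit-flip transition measure between attractors.

    Entry (i, j) is the fraction of the period_i * n one-off single-bit
    perturbations of attractor i's states whose noise-free trajectory ends
    in attractor j.  Rows sum to 1 exactly (the entries are ratios of
    integer counts with a common denominator).
    """
    counts = single_bit_flip_counts(net, aset)
    mat = np.zeros(counts.shape, dtype=np.float64)
    for i, a in enumerate(aset.attractors):
        denom = a.period * net.n
        mat[i] = [float(Fraction(int(c), denom)) for c in counts[i]]
    return mat


def kernel_tsv(kernel: TransitionKernel, threshold: float = 0.0) -> str:
    """Diagnostic export of nonzero kernel entries as TSV."""
    lines = [f"# p={kernel.p} n={kernel.n}", "from\tto\tprobability"]
    for x in range(kernel.n_states):
        row = kernel.row(x)
        for z in np.nonzero(row > threshold)[0]:
            lines.append(f"{x}\t{int(z)}\t{row[z]:.12g}")
    return "\n".join(lines) + "\n"
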