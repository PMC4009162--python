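"""Mean first passage times between attractors under flip noise.

The MFPT from a source state x to a target state set T is the expected
number of synchronous update steps until the perturbed chain first visits
any state of T.  Three independent routes are provided:

* ``hitting_times`` — exact first-step analysis: solve (I - Q) k = 1 on the
  transient block of the kernel.
* ``fk_series`` / ``series_mfpt`` — the first-passage probability series
  F_k (probability that the first visit to T happens at step k) summed as
  sum_k k * F_k, with an explicit truncation tail.
* ``estimate_mfpt_mc`` — seeded Monte-Carlo simulation of noisy walks.

Between attractors, the target is treated as a state *set* (first arrival
at any state of the target cycle) and the source average is uniform over
the source cycle's states.  The diagonal is 0 by the first-passage
convention (not the mean recurrence time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .network_model import BooleanNetwork
from .dynamics import Attractor, AttractorSet, successor_table
from .noise_kernel import TransitionKernel

__all__ = [
    "MfptMatrix",
    "FkSeries",
    "McEstimate",
    "hitting_times",
    "mfpt_attractors",
    "fk_series",
    "series_mfpt",
    "estimate_mfpt_mc",
    "mfpt_tsv",
]


@dataclass(frozen=True)
class MfptMatrix:
    """m x m mean first passage times between attractors (diagonal 0)."""

    values: np.ndarray
    p: float
    method: str
    labels: tuple[str, ...]
    params: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FkSeries:
    """Truncated first-passage distribution from one source state.

    ``F[k-1]`` is the probability that the first visit to the target set
    happens exactly at step k.  ``partial_mfpt`` is sum_{k<=K} k * F_k and
    ``tail_mass`` is 1 - sum F_k; the exact MFPT lies above
    ``partial_mfpt + (K+1) * tail_mass`` minus nothing, i.e. the partial sum
    plus ``K * tail_mass`` is a lower bound on the exact value.
    """

    F: np.ndarray
    partial_mfpt: float
    tail_mass: float

    @property
    def K(self) -> int:
        return len(self.F)


@dataclass(frozen=True)
class McEstimate:
    mean: float
    se: float
    n_censored: int
    n_walks: int
    max_steps: int


def _target_array(target) -> np.ndarray:
    if isinstance(target, Attractor):
        target = target.states
    arr = np.asarray(sorted({int(t) for t in target}), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("target state set is empty")
    return arr


def hitting_times(kernel: TransitionKernel, target) -> np.ndarray:
    """Expected steps to first reach any target state, for every state.

    Solves the first-step equations k(y) = 0 for y in the target and
    k(x) = 1 + sum_z P(x, z) k(z) otherwise, as a dense linear system on
    the transient block (iterative solve above the dense kernel limit).
    """
    tgt = _target_array(target)
    n_states = kernel.n_states
    is_target = np.zeros(n_states, dtype=bool)
    is_target[tgt] = True
    trans = np.nonzero(~is_target)[0]
    out = np.zeros(n_states, dtype=np.float64)
    if trans.size == 0:
        return out
    if kernel._dense is not None:
        Q = kernel.matrix[np.ix_(trans, trans)]
        A = np.eye(trans.size) - Q
        k = scipy.linalg.solve(A, np.ones(trans.size))
    else:  # matrix-free path for large state spaces
        def matvec(v):
            full = np.zeros(n_states)
            full[trans] = v
            out_v = np.empty(trans.size)
            for i, x in enumerate(trans):
                out_v[i] = v[i] - float(kernel.row(int(x)) @ full)
            return out_v

        op = scipy.sparse.linalg.LinearOperator(
            (trans.size, trans.size), matvec=matvec
        )
        k, info = scipy.sparse.linalg.gmres(
            op, np.ones(trans.size), rtol=1e-10, atol=0.0
        )
        if info != 0:
            raise RuntimeError(f"iterative hitting-time solve failed (info={info})")
    if np.any(k < -1e-9):
        raise RuntimeError("hitting-time solve produced negative expectations")
    out[trans] = np.maximum(k, 0.0)
    return out


def mfpt_attractors(
    kernel: TransitionKernel, aset: AttractorSet
) -> MfptMatrix:
    """Exact MFPT between every ordered attractor pair.

    The target is the full state set of the destination cycle; the source
    side is averaged uniformly over the source cycle's states (for a point
    attractor this is just its single state).  Diagonal entries are 0.
    """
    m = aset.m
    values = np.zeros((m, m), dtype=np.float64)
    for j, target in enumerate(aset.attractors):
        k = hitting_times(kernel, target.states)
        for i, source in enumerate(aset.attractors):
            if i == j:
                continue
            values[i, j] = float(np.mean([k[s] for s in source.states]))
    return MfptMatrix(values, kernel.p, "exact", tuple(aset.labels()))


def _transient_blocks(kernel: TransitionKernel, tgt: np.ndarray):
    n_states = kernel.n_states
    is_target = np.zeros(n_states, dtype=bool)
    is_target[tgt] = True
    trans = np.nonzero(~is_target)[0]
    P = kernel.matrix
    Q = P[np.ix_(trans, trans)]
    b = P[np.ix_(trans, tgt)].sum(axis=1)  # one-step absorption probability
    pos = {int(x): i for i, x in enumerate(trans)}
    return trans, pos, Q, b


def fk_series(kernel: TransitionKernel, source: int, target, K: int) -> FkSeries:
    """First K terms of the first-passage distribution from one state.

    F_1(x) is the one-step probability of entering the target; deeper terms
    follow the recursion F_k(x) = sum_{z not in T} P(x, z) F_{k-1}(z).  A
    source already inside the target has F_k = 0 for all k (hitting time 0).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    tgt = _target_array(target)
    src = int(source)
    if src in set(int(t) for t in tgt):
        return FkSeries(np.zeros(K), 0.0, 0.0)
    trans, pos, Q, b = _transient_blocks(kernel, tgt)
    F = np.empty(K, dtype=np.float64)
    f = b.copy()
    F[0] = f[pos[src]]
    for k in range(1, K):
        f = Q @ f
        F[k] = f[pos[src]]
    partial = float(np.sum(np.arange(1, K + 1) * F))
    tail = float(max(0.0, 1.0 - F.sum()))
    return FkSeries(F, partial, tail)


def series_mfpt(
    kernel: TransitionKernel,
    target,
    tail_tol: float = 1e-6,
    max_doublings: int = 60,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Truncated sum_k k * F_k for every source state, by block doubling.

    Evaluates the same F_k recursion as :func:`fk_series` but accumulates
    the partial sums with matrix doubling (A_K = sum Q^{k-1}, W_K = sum
    k Q^{k-1}), doubling K until the largest transient-state tail mass
    falls below ``tail_tol``.  Returns (partial MFPT per state, tail mass
    per state, K).  Independent of the linear-solve route.
    """
    tgt = _target_array(target)
    trans, pos, Q, b = _transient_blocks(kernel, tgt)
    n_states = kernel.n_states
    if trans.size == 0:
        return np.zeros(n_states), np.zeros(n_states), 1
    QK = Q.copy()          # Q^K
    A = np.eye(trans.size)  # sum_{k=1..K} Q^{k-1}
    W = np.eye(trans.size)  # sum_{k=1..K} k Q^{k-1}
    K = 1
    for _ in range(max_doublings):
        tail = 1.0 - A @ b
        if float(np.max(tail)) < tail_tol:
            break
        A, W = A + QK @ A, W + QK @ (W + K * A)
        QK = QK @ QK
        K *= 2
    partial_t = W @ b
    tail_t = np.maximum(0.0, 1.0 - A @ b)
    partial = np.zeros(n_states)
    tail = np.zeros(n_states)
    partial[trans] = partial_t
    tail[trans] = tail_t
    return partial, tail, K


def estimate_mfpt_mc(
    net: BooleanNetwork,
    p: float,
    source,
    target,
    n_walks: int = 10_000,
    max_steps: int | None = None,
    seed: int | np.random.Generator = 0,
) -> McEstimate:
    """Monte-Carlo MFPT estimate by simulating noisy trajectories.

    Each walk starts from a uniformly chosen source state.  Per step every
    gene flips independently with probability ``p``; if no gene flips the
    deterministic update fires.  The walk stops on first arrival at any
    target state.  Walks still running at ``max_steps`` are censored and
    excluded from the mean but reported.
    """
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    if not 0 < p < 1:
        raise ValueError(f"flip probability p={p} must be in (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    src_states = _target_array(source)  # same normalization: sorted unique
    tgt = _target_array(target)
    if max_steps is None:
        max_steps = 1_000_000
    n = net.n
    succ = successor_table(net)
    is_target = np.zeros(2**n, dtype=bool)
    is_target[tgt] = True
    states = rng.choice(src_states, size=n_walks)
    times = np.zeros(n_walks, dtype=np.int64)
    active = ~is_target[states]  # a source already in the target hits at 0
    bit_weights = (1 << np.arange(n)).astype(np.int64)
    step_count = 0
    while np.any(active) and step_count < max_steps:
        step_count += 1
        idx = np.nonzero(active)[0]
        cur = states[idx]
        flips = (rng.random((idx.size, n)) < p) @ bit_weights
        nxt = np.where(flips > 0, cur ^ flips, succ[cur])
        states[idx] = nxt
        times[idx] = step_count
        active[idx] = ~is_target[nxt]
    n_censored = int(np.count_nonzero(active))
    if n_censored == n_walks:
        raise RuntimeError(
            f"all {n_walks} walks censored at max_steps={max_steps}"
        )
    hit = times[~active].astype(np.float64)
    mean = float(hit.mean())
    se = float(hit.std(ddof=1) / np.sqrt(hit.size)) if hit.size > 1 else float("inf")
    return McEstimate(mean, se, n_censored, n_walks, int(max_steps))


def mfpt_tsv(mfpt: MfptMatrix, extra_meta: dict | None = None) -> str:
    """MFPT matrix as TSV with a key-value metadata header comment."""
    meta = {"p": mfpt.p, "method": mfpt.method, **mfpt.params, **(extra_meta or {})}
    lines = [f"# {k}={v}" for k, v in meta.items()]
    lines.append("\t".join(["source\\target"] + list(mfpt.labels)))
    for i, lab in enumerate(mfpt.labels):
        lines.append(
            "\t".join([lab] + [f"{mfpt.values[i, j]:.10g}" for j in range(mfpt.m)])
        )
    return "\n".join(lines) + "\n"
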