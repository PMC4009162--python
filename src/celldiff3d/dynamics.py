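"""Deterministic synchronous dynamics and exhaustive attractor enumeration.

The synchronous update map D sends every state to a unique successor, so
the state space is a functional graph: every trajectory ends on a cycle
(an attractor).  Point attractors are fixed points; cyclic attractors have
period > 1.  Enumeration walks every one of the 2^n start states once,
sharing a visited-state memo, which is linear in the state-space size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .network_model import BooleanNetwork, evaluate_gene

__all__ = [
    "Attractor",
    "AttractorSet",
    "successor_table",
    "step",
    "find_attractors",
    "label_attractors",
    "attractor_report",
    "AmbiguousPatternError",
]

MAX_GENES_EXHAUSTIVE = 24


class AmbiguousPatternError(ValueError):
    """An expression pattern matched more than one attractor."""


@dataclass(frozen=True)
class Attractor:
    """A cycle of states closed under the deterministic update.

    ``states`` is in successor order and canonically rotated to start at
    the smallest state index.  ``basin_size`` counts all states whose
    noise-free trajectory ends on this cycle (cycle states included).
    """

    id: int
    states: tuple[int, ...]
    basin_size: int
    label: str | None = None

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_point(self) -> bool:
        return len(self.states) == 1


@dataclass(frozen=True)
class AttractorSet:
    """All attractors of a network plus the basin membership of every state."""

    attractors: tuple[Attractor, ...]
    n: int
    basin_map: np.ndarray  # state index -> attractor id

    @property
    def m(self) -> int:
        return len(self.attractors)

    @property
    def n_states(self) -> int:
        return 2**self.n

    def labels(self) -> list[str]:
        return [
            a.label if a.label is not None else f"attractor-{a.id}"
            for a in self.attractors
        ]

    def by_label(self, label: str) -> Attractor:
        for a in self.attractors:
            if a.label == label:
                return a
        raise KeyError(f"no attractor labeled {label!r}")


def successor_table(net: BooleanNetwork) -> np.ndarray:
    """The full map D as an integer array: ``table[x]`` is the successor of
    state ``x``.  Vectorized over all 2^n states via per-gene truth tables."""
    n = net.n
    states = np.arange(2**n, dtype=np.int64)
    nxt = np.zeros(2**n, dtype=np.int64)
    for pos, gene in enumerate(net.genes):
        inp = net.inputs(gene)
        table = net.truth_table(gene)
        key = np.zeros(2**n, dtype=np.int64)
        for j, src in enumerate(inp):
            src_pos = net.gene_index(src)
            key |= ((states >> src_pos) & 1) << j
        nxt |= table[key].astype(np.int64) << pos
    return nxt


def step(net: BooleanNetwork, state: int) -> int:
    """One synchronous update: every gene evaluated on the pre-update state."""
    bits = [(int(state) >> k) & 1 for k in range(net.n)]
    out = 0
    for pos, gene in enumerate(net.genes):
        if evaluate_gene(net, gene, bits):
            out |= 1 << pos
    return out


def find_attractors(
    net: BooleanNetwork, max_genes: int = MAX_GENES_EXHAUSTIVE
) -> AttractorSet:
    """Enumerate every attractor and basin by exhausting all start states.

    Attractors are ordered (and numbered) by their smallest contained state
    index, so ids are stable across runs.
    """
    if net.n > max_genes:
        raise ValueError(
            f"{net.n} genes exceeds the exhaustive-enumeration guard "
            f"({max_genes}); raise max_genes explicitly if intended"
        )
    nxt = successor_table(net)
    n_states = 2**net.n
    color = np.full(n_states, -1, dtype=np.int64)  # -1 unvisited, -2 on path
    cycles: list[list[int]] = []
    for s in range(n_states):
        if color[s] != -1:
            continue
        path: list[int] = []
        x = s
        while color[x] == -1:
            color[x] = -2
            path.append(x)
            x = int(nxt[x])
        if color[x] == -2:  # closed a brand-new cycle on the current path
            start = path.index(x)
            cycles.append(path[start:])
            aid = len(cycles) - 1
        else:
            aid = int(color[x])
        for y in path:
            color[y] = aid
    # canonical rotation + stable ordering by smallest state index
    order = sorted(range(len(cycles)), key=lambda i: min(cycles[i]))
    remap = {old: new for new, old in enumerate(order)}
    basin_map = np.array([remap[int(c)] for c in color], dtype=np.int64)
    counts = np.bincount(basin_map, minlength=len(cycles))
    attractors = []
    for new_id, old_id in enumerate(order):
        cyc = cycles[old_id]
        rot = cyc.index(min(cyc))
        states = tuple(cyc[rot:] + cyc[:rot])
        attractors.append(Attractor(new_id, states, int(counts[new_id])))
    return AttractorSet(tuple(attractors), net.n, basin_map)


def _matches(state: int, pattern: Mapping[str, object], net: BooleanNetwork) -> bool:
    for gene, want in pattern.items():
        if want in ("*", None):
            continue
        bit = (state >> net.gene_index(gene)) & 1
        if bit != int(want):
            return False
    return True


def label_attractors(
    aset: AttractorSet,
    expected: Mapping[str, Mapping[str, object]],
    net: BooleanNetwork,
) -> AttractorSet:
    """Assign cell-type labels by matching expression patterns.

    ``expected`` maps a label to a per-gene pattern (values 0, 1, or ``"*"``
    for wildcard; omitted genes are wildcards).  A point attractor must
    match the pattern exactly; a cyclic attractor is labeled only if every
    state on the cycle matches.  A pattern matching two or more attractors,
    or two patterns claiming the same attractor, is an error.  Unmatched
    attractors receive ``unassigned-<id>``.
    """
    for label, pattern in expected.items():
        for gene in pattern:
            net.gene_index(gene)  # raises on unknown gene
    assigned: dict[int, str] = {}
    for label, pattern in expected.items():
        hits = [
            a.id
            for a in aset.attractors
            if all(_matches(s, pattern, net) for s in a.states)
        ]
        if len(hits) > 1:
            raise AmbiguousPatternError(
                f"pattern for {label!r} matches attractors {hits}"
            )
        if hits:
            aid = hits[0]
            if aid in assigned:
                raise AmbiguousPatternError(
                    f"attractor {aid} matches both {assigned[aid]!r} and {label!r}"
                )
            assigned[aid] = label
    new = tuple(
        replace(a, label=assigned.get(a.id, f"unassigned-{a.id}"))
        for a in aset.attractors
    )
    return AttractorSet(new, aset.n, aset.basin_map)


def attractor_report(aset: AttractorSet, net: BooleanNetwork) -> str:
    """TSV report: one row per cycle state with per-gene bits."""
    header = ["attractor", "period", "basin_size", "label", "state_index"] + list(
        net.genes
    )
    lines = ["\t".join(header)]
    for a in aset.attractors:
        label = a.label if a.label is not None else ""
        for s in a.states:
            bits = [(s >> k) & 1 for k in range(net.n)]
            lines.append(
                "\t".join(
                    [str(a.id), str(a.period), str(a.basin_size), label, str(s)]
                    + [str(b) for b in bits]
                )
            )
    return "\n".join(lines) + "\n"
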