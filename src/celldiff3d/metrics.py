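"""Separation, flux, landscape capacity, and lineage-tree classification.

From the directional MFPT matrix two derived barrier measures are formed:

* separation(i, j) = min(MFPT(i, j), MFPT(j, i)) — symmetric barrier height;
* flux(i, j) = MFPT(i, j) - MFPT(j, i) — antisymmetric; its sign gives the
  favored transition direction (the edge points i -> j when
  MFPT(i, j) < MFPT(j, i)), its magnitude the directionality strength.

Transitions between labeled attractors are classified against a reference
lineage tree (rooted at the multipotent progenitor, terminal cell types at
the leaves) into five kinds: spontaneous-differentiation (sink is a
descendant of source), spontaneous-dedifferentiation (sink is an ancestor),
transdifferentiation (off-path, both leaves), off-differentiation
(off-path, sink at least as deep), and off-dedifferentiation (off-path,
sink shallower).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .mfpt import MfptMatrix

__all__ = [
    "MetricsTable",
    "LineageTree",
    "separation",
    "flux",
    "edge_direction",
    "landscape_capacity",
    "classify_transition",
    "build_metrics",
    "metrics_frame",
    "metrics_tsv",
    "TRANSITION_KINDS",
]

TRANSITION_KINDS = (
    "spontaneous-differentiation",
    "spontaneous-dedifferentiation",
    "transdifferentiation",
    "off-differentiation",
    "off-dedifferentiation",
)


def separation(mfpt: MfptMatrix | np.ndarray, i: int, j: int) -> float:
    """Symmetric barrier: the smaller of the two directional MFPTs."""
    values = mfpt.values if isinstance(mfpt, MfptMatrix) else np.asarray(mfpt)
    if i == j:
        raise ValueError("separation is defined between distinct attractors")
    return float(min(values[i, j], values[j, i]))


def flux(mfpt: MfptMatrix | np.ndarray, i: int, j: int) -> float:
    """Antisymmetric directionality: MFPT(i, j) - MFPT(j, i)."""
    values = mfpt.values if isinstance(mfpt, MfptMatrix) else np.asarray(mfpt)
    if i == j:
        raise ValueError("flux is defined between distinct attractors")
    return float(values[i, j] - values[j, i])


#: Relative tolerance below which two directional MFPTs count as tied.
#: Exact ties (e.g. by network symmetry) reach the linear solver as
#: permuted systems and come back differing at rounding level, so "exact"
#: is judged at solver precision rather than bit-for-bit.
TIE_RTOL = 1e-9


def edge_direction(mfpt: MfptMatrix | np.ndarray, i: int, j: int):
    """Favored transition direction for the unordered pair {i, j}.

    Returns ``(i, j)`` when MFPT(i, j) < MFPT(j, i) (the transition into j
    is the faster one, so the edge points i -> j), ``(j, i)`` for the
    reverse, and ``None`` on a tie (no arrow); ties are judged at relative
    solver precision :data:`TIE_RTOL`.
    """
    values = mfpt.values if isinstance(mfpt, MfptMatrix) else np.asarray(mfpt)
    if i == j:
        raise ValueError("edge direction is defined between distinct attractors")
    fwd, rev = float(values[i, j]), float(values[j, i])
    if abs(fwd - rev) <= TIE_RTOL * max(fwd, rev, 1.0):
        return None
    return (i, j) if fwd < rev else (j, i)


def landscape_capacity(m: int) -> int:
    """Maximum number of cell-type transitions a classic ridge-and-valley
    epigenetic landscape can depict for ``m`` cell types:
    2m - log2(m+1) - 1.  Exact when m+1 is a power of two (a perfect binary
    lineage tree); the log term is floored otherwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 2 * m - int(math.floor(math.log2(m + 1))) - 1


# ---------------------------------------------------------------------------
# Lineage tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineageTree:
    """Rooted cell-type tree: multipotent root, terminal types at leaves."""

    parent: Mapping[str, str | None]

    def __post_init__(self):
        object.__setattr__(self, "parent", dict(self.parent))
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"lineage tree must have exactly one root, got {roots}")
        for child, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValueError(f"parent {par!r} of {child!r} is not a node")
            seen = {child}
            node = par
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle in lineage tree at {node!r}")
                seen.add(node)
                node = self.parent[node]

    @property
    def root(self) -> str:
        return next(c for c, p in self.parent.items() if p is None)

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def depth(self, node: str) -> int:
        self._check(node)
        d = 0
        while self.parent[node] is not None:
            node = self.parent[node]
            d += 1
        return d

    def ancestors(self, node: str) -> list[str]:
        self._check(node)
        out = []
        node = self.parent[node]
        while node is not None:
            out.append(node)
            node = self.parent[node]
        return out

    def is_leaf(self, node: str) -> bool:
        self._check(node)
        return all(p != node for p in self.parent.values())

    def _check(self, node: str) -> None:
        if node not in self.parent:
            raise KeyError(f"unknown cell type {node!r}")

    @classmethod
    def from_newick(cls, text: str) -> "LineageTree":
        """Parse a newick string with named internal nodes."""
        from Bio import Phylo

        tree = Phylo.read(io.StringIO(text), "newick")
        parent: dict[str, str | None] = {}

        def walk(clade, par_name):
            name = clade.name
            if name is None:
                raise ValueError("every lineage-tree node needs a name")
            if name in parent:
                raise ValueError(f"duplicate node name {name!r}")
            parent[name] = par_name
            for child in clade.clades:
                walk(child, name)

        walk(tree.root, None)
        return cls(parent)

    @classmethod
    def from_parent_tsv(cls, text: str) -> "LineageTree":
        """Two-column TSV (child <tab> parent); the root's parent is empty,
        '-' or 'root'."""
        parent: dict[str, str | None] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            child = parts[0].strip()
            par = parts[1].strip() if len(parts) > 1 else ""
            parent[child] = None if par in ("", "-", "root", "NA") else par
        return cls(parent)

    def to_newick(self) -> str:
        children: dict[str, list[str]] = {n: [] for n in self.parent}
        for c, p in self.parent.items():
            if p is not None:
                children[p].append(c)

        def render(node: str) -> str:
            kids = children[node]
            if not kids:
                return node
            return "(" + ",".join(render(k) for k in kids) + ")" + node

        return render(self.root) + ";"


def classify_transition(tree: LineageTree, source: str, sink: str) -> str:
    """Classify a cell-type switch by the relative tree positions.

    On-path transitions are spontaneous (differentiation toward a
    descendant, dedifferentiation toward an ancestor).  Off-path switches
    between two leaves are transdifferentiation; otherwise the sink's depth
    relative to the source distinguishes off-differentiation (equal or
    deeper) from off-dedifferentiation (shallower).
    """
    if source == sink:
        raise ValueError("source and sink cell types must differ")
    if sink in tree.ancestors(source):
        return "spontaneous-dedifferentiation"
    if source in tree.ancestors(sink):
        return "spontaneous-differentiation"
    if tree.is_leaf(source) and tree.is_leaf(sink):
        return "transdifferentiation"
    if tree.depth(sink) >= tree.depth(source):
        return "off-differentiation"
    return "off-dedifferentiation"


# ---------------------------------------------------------------------------
# Metrics table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsTable:
    """Separation / flux / direction for every attractor pair."""

    labels: tuple[str, ...]
    mfpt: np.ndarray
    separation: np.ndarray
    flux: np.ndarray
    p: float

    @property
    def m(self) -> int:
        return len(self.labels)

    def direction(self, i: int, j: int):
        return edge_direction(self.mfpt, i, j)


def build_metrics(mfpt: MfptMatrix) -> MetricsTable:
    """Derive the symmetric separation and antisymmetric flux matrices."""
    v = mfpt.values
    sep = np.minimum(v, v.T)
    np.fill_diagonal(sep, 0.0)
    flx = v - v.T
    return MetricsTable(tuple(mfpt.labels), v.copy(), sep, flx, mfpt.p)


def metrics_frame(
    table: MetricsTable, tree: LineageTree | None = None
) -> pd.DataFrame:
    """All m(m-1) ordered pairs as a tidy frame.

    The direction column marks whether this row's orientation is the
    favored one; classification needs a lineage tree and is
    'unclassified' for labels absent from it.
    """
    rows = []
    for i in range(table.m):
        for j in range(table.m):
            if i == j:
                continue
            d = table.direction(i, j)
            if d is None:
                direction = "none"
            elif d == (i, j):
                direction = "forward"
            else:
                direction = "reverse"
            src, snk = table.labels[i], table.labels[j]
            if tree is not None and src in tree.parent and snk in tree.parent:
                kind = classify_transition(tree, src, snk)
            else:
                kind = "unclassified"
            rows.append(
                {
                    "source": src,
                    "sink": snk,
                    "mfpt": table.mfpt[i, j],
                    "separation": table.separation[i, j],
                    "flux": table.flux[i, j],
                    "direction": direction,
                    "classification": kind,
                }
            )
    return pd.DataFrame(rows)


def metrics_tsv(table: MetricsTable, tree: LineageTree | None = None) -> str:
    frame = metrics_frame(table, tree)
    header = f"# p={table.p}\n"
    return header + frame.to_csv(sep="\t", index=False)
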