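"""Bundled example networks and a seeded random-network generator.

``random_network`` draws Kauffman-style NK random Boolean networks (each
gene reads k distinct inputs; truth-table outputs are true with a given
bias), which drive the property tests.  ``example_networks`` bundles the
micro networks used throughout the test-suite plus an 11-gene myeloid
differentiation demonstration network.

The demonstration network is a synthetic stand-in: its eleven
transcription factors and interaction topology follow the well-known
myeloid regulators (GATA-2, GATA-1, FOG-1, EKLF, Fli-1, SCL, C/EBPa,
PU.1, cJun, EgrNab, Gfi-1) with author-chosen Boolean logic tuned so the
synchronous dynamics yield seven point attractors matching the simplified
myeloid lineage: CMP at the root, MEP and GMP progenitors, and terminal
ERY, MEG, MON, GRA.  It demonstrates the full pipeline at realistic scale
(2^11 states); it is not a literature-inferred regulatory model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import BooleanNetwork, parse_expression, parse_network
from .metrics import LineageTree

__all__ = [
    "RandomNetSpec",
    "random_network",
    "example_networks",
    "myeloid_demo_network",
    "myeloid_lineage_tree",
    "myeloid_expression_patterns",
]


@dataclass(frozen=True)
class RandomNetSpec:
    """Kauffman NK ensemble parameters: n genes, fan-in k, output bias."""

    n: int
    k: int
    bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.k <= self.n:
            raise ValueError(f"fan-in k={self.k} must be in [1, n={self.n}]")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError(f"bias={self.bias} must be in [0, 1]")


def _minterm_expression(inputs: tuple[str, ...], outputs: np.ndarray) -> str:
    """Render a truth table as a sum-of-minterms expression string."""
    if not outputs.any():
        return "0"
    if outputs.all():
        return "1"
    terms = []
    for row in np.nonzero(outputs)[0]:
        lits = []
        for j, name in enumerate(inputs):
            lits.append(name if (row >> j) & 1 else f"!{name}")
        terms.append("(" + " & ".join(lits) + ")")
    return " | ".join(terms)


def random_network(spec: RandomNetSpec) -> BooleanNetwork:
    """Draw one seeded NK random Boolean network.

    Each gene reads ``k`` distinct inputs chosen uniformly; each of the
    2^k truth-table outputs is true independently with probability
    ``bias``.  Identical specs produce identical networks, and the rule
    expressions round-trip through the text dialect.
    """
    rng = np.random.default_rng(spec.seed)
    genes = tuple(f"g{i}" for i in range(spec.n))
    rules = {}
    for gene in genes:
        inputs = tuple(
            genes[i] for i in sorted(rng.choice(spec.n, size=spec.k, replace=False))
        )
        outputs = rng.random(2**spec.k) < spec.bias
        rules[gene] = parse_expression(_minterm_expression(inputs, outputs))
    return BooleanNetwork(genes, rules)


# ---------------------------------------------------------------------------
# Bundled examples
# ---------------------------------------------------------------------------

_MYELOID_DEMO = """\
targets, factors
# Synthetic 11-gene myeloid differentiation demo (author-chosen logic).
GATA2,  GATA2 & !PU1 & !EKLF & !FLI1
GATA1,  (GATA1 | GATA2) & !PU1
FOG1,   GATA1
EKLF,   GATA1 & !GATA2 & (EKLF | !FLI1)
FLI1,   GATA1 & !GATA2 & !EKLF
SCL,    GATA1 & !PU1
CEBPA,  CEBPA & !(GATA1 & FOG1 & SCL)
PU1,    (CEBPA | PU1) & !(GATA1 | GATA2)
CJUN,   PU1 & !GFI1 & !CEBPA
EGRNAB, PU1 & CJUN & !GFI1
GFI1,   CEBPA & GFI1 & !EGRNAB
"""

#: Simplified myeloid lineage: CMP root, MEP/GMP progenitors, four
#: terminally differentiated leaves.
_MYELOID_NEWICK = "((ERY,MEG)MEP,(MON,GRA)GMP)CMP;"

#: Expected expression pattern of each cell type in the demo network.
_MYELOID_PATTERNS: dict[str, dict[str, int]] = {
    "CMP": {g: 0 for g in (
        "GATA2 GATA1 FOG1 EKLF FLI1 SCL CEBPA PU1 CJUN EGRNAB GFI1".split()
    )},
    "MEP": {"GATA2": 1, "GATA1": 1, "FOG1": 1, "SCL": 1,
            "EKLF": 0, "FLI1": 0, "CEBPA": 0, "PU1": 0,
            "CJUN": 0, "EGRNAB": 0, "GFI1": 0},
    "ERY": {"GATA2": 0, "GATA1": 1, "FOG1": 1, "SCL": 1,
            "EKLF": 1, "FLI1": 0, "CEBPA": 0, "PU1": 0,
            "CJUN": 0, "EGRNAB": 0, "GFI1": 0},
    "MEG": {"GATA2": 0, "GATA1": 1, "FOG1": 1, "SCL": 1,
            "EKLF": 0, "FLI1": 1, "CEBPA": 0, "PU1": 0,
            "CJUN": 0, "EGRNAB": 0, "GFI1": 0},
    "GMP": {"GATA2": 0, "GATA1": 0, "FOG1": 0, "EKLF": 0,
            "FLI1": 0, "SCL": 0, "CEBPA": 1, "PU1": 1,
            "CJUN": 0, "EGRNAB": 0, "GFI1": 0},
    "MON": {"GATA2": 0, "GATA1": 0, "FOG1": 0, "EKLF": 0,
            "FLI1": 0, "SCL": 0, "CEBPA": 0, "PU1": 1,
            "CJUN": 1, "EGRNAB": 1, "GFI1": 0},
    "GRA": {"GATA2": 0, "GATA1": 0, "FOG1": 0, "EKLF": 0,
            "FLI1": 0, "SCL": 0, "CEBPA": 1, "PU1": 1,
            "CJUN": 0, "EGRNAB": 0, "GFI1": 1},
}


def myeloid_demo_network() -> BooleanNetwork:
    """The bundled 11-gene synthetic myeloid demonstration network."""
    return parse_network(_MYELOID_DEMO)


def myeloid_lineage_tree() -> LineageTree:
    """The simplified myeloid lineage tree used to classify transitions."""
    return LineageTree.from_newick(_MYELOID_NEWICK)


def myeloid_expression_patterns() -> dict[str, dict[str, int]]:
    """Per-cell-type expression patterns for labeling demo attractors."""
    return {k: dict(v) for k, v in _MYELOID_PATTERNS.items()}


def example_networks() -> dict[str, BooleanNetwork]:
    """Named micro networks plus the 11-gene myeloid demo.

    * ``identity-1`` / ``identity-2``: every state is a fixed point.
    * ``not-1``: single period-2 cycle {0, 1}.
    * ``swap-2``: two fixed points and one period-2 cycle.
    * ``myeloid-demo``: 11 genes, seven labeled point attractors.
    """
    texts = {
        "identity-1": "targets, factors\nA, A\n",
        "identity-2": "targets, factors\nA, A\nB, B\n",
        "not-1": "targets, factors\nA, !A\n",
        "swap-2": "targets, factors\nA, B\nB, A\n",
    }
    nets = {name: parse_network(text) for name, text in texts.items()}
    nets["myeloid-demo"] = myeloid_demo_network()
    return nets
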