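"""Scene assembly and export: VRML97, GraphML, and JSON.

A :class:`SceneSpec` combines a fitted 3D layout with the pair metrics:
one colored sphere per attractor and one arrow (cylinder shaft + cone
head) per favored transition direction.  Arrow widths scale linearly with
|flux|; pairs with |flux| below the flux threshold, or with no favored
direction, are hidden — mirroring the convention of omitting low-flux
edges for legibility.  All writers are deterministic: identical inputs
produce byte-identical documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .layout3d import Layout3D
from .metrics import LineageTree, MetricsTable, metrics_frame

__all__ = [
    "SceneSpec",
    "SceneNode",
    "SceneEdge",
    "build_scene",
    "write_vrml",
    "write_graphml",
    "write_json_graph",
    "write_graph_exports",
    "DEFAULT_PALETTE",
]

#: Fixed 12-color palette (RGB in [0,1]) keyed by attractor order when no
#: user color map is given.
DEFAULT_PALETTE: tuple[tuple[float, float, float], ...] = (
    (0.122, 0.467, 0.706),
    (1.000, 0.498, 0.055),
    (0.173, 0.627, 0.173),
    (0.839, 0.153, 0.157),
    (0.580, 0.404, 0.741),
    (0.549, 0.337, 0.294),
    (0.890, 0.467, 0.761),
    (0.498, 0.498, 0.498),
    (0.737, 0.741, 0.133),
    (0.090, 0.745, 0.812),
    (0.682, 0.780, 0.910),
    (1.000, 0.733, 0.471),
)


@dataclass(frozen=True)
class SceneNode:
    label: str
    position: tuple[float, float, float]
    radius: float
    color: tuple[float, float, float]


@dataclass(frozen=True)
class SceneEdge:
    source: str
    sink: str
    width: float
    flux: float
    shown: bool


@dataclass(frozen=True)
class SceneSpec:
    nodes: tuple[SceneNode, ...]
    edges: tuple[SceneEdge, ...]
    flux_threshold: float
    metadata: dict = field(default_factory=dict)

    @property
    def shown_edges(self) -> tuple[SceneEdge, ...]:
        return tuple(e for e in self.edges if e.shown)


def build_scene(
    layout: Layout3D,
    metrics: MetricsTable,
    labels=None,
    flux_threshold: float | None = None,
    color_map: dict | None = None,
    sphere_radius: float | None = None,
) -> SceneSpec:
    """Assemble the renderable scene from layout coordinates and metrics.

    ``flux_threshold`` defaults to 10% of the maximum |flux|; arrows are
    drawn only for pairs with a favored direction and |flux| at or above
    the threshold.  Widths map |flux| linearly onto [0.2, 1.0] of the
    sphere radius.  Sphere radius defaults to 5% of the largest pairwise
    layout distance.
    """
    labels = tuple(labels) if labels is not None else tuple(metrics.labels)
    if layout.m != metrics.m or len(labels) != metrics.m:
        raise ValueError(
            f"layout has {layout.m} nodes, metrics {metrics.m}, labels {len(labels)}"
        )
    coords = layout.coordinates
    if metrics.m > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        max_dist = float(np.sqrt((diff**2).sum(-1)).max())
    else:
        max_dist = 1.0
    if max_dist <= 0:
        max_dist = 1.0
    radius = sphere_radius if sphere_radius is not None else 0.05 * max_dist
    abs_flux = np.abs(metrics.flux)
    max_flux = float(abs_flux.max()) if metrics.m > 1 else 0.0
    if flux_threshold is None:
        flux_threshold = 0.1 * max_flux
    nodes = []
    for i, lab in enumerate(labels):
        if color_map and lab in color_map:
            color = tuple(float(c) for c in color_map[lab])
        else:
            color = DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
        nodes.append(SceneNode(lab, tuple(float(c) for c in coords[i]), radius, color))
    edges = []
    for i in range(metrics.m):
        for j in range(i + 1, metrics.m):
            d = metrics.direction(i, j)
            if d is None:
                continue  # exact tie: no arrow, ever
            src, snk = d
            f = abs(float(metrics.flux[i, j]))
            shown = f >= flux_threshold
            frac = f / max_flux if max_flux > 0 else 1.0
            width = (0.2 + 0.8 * frac) * radius
            edges.append(SceneEdge(labels[src], labels[snk], width, f, shown))
    meta = {
        "flux_threshold": float(flux_threshold),
        "sphere_radius": float(radius),
        "p": metrics.p,
        "layout_stress": layout.stress,
        "layout_scale_mode": layout.scale_mode,
        "layout_seed": layout.seed,
    }
    return SceneSpec(tuple(nodes), tuple(edges), float(flux_threshold), meta)


# ---------------------------------------------------------------------------
# VRML97
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _rotation_from_y(direction: np.ndarray) -> tuple[float, float, float, float]:
    """VRML axis-angle rotating the +Y axis onto ``direction``."""
    d = direction / np.linalg.norm(direction)
    y = np.array([0.0, 1.0, 0.0])
    axis = np.cross(y, d)
    norm = np.linalg.norm(axis)
    angle = float(np.arccos(np.clip(d[1], -1.0, 1.0)))
    if norm < 1e-12:  # parallel or antiparallel to Y
        return (1.0, 0.0, 0.0, 0.0 if d[1] > 0 else np.pi)
    axis = axis / norm
    return (float(axis[0]), float(axis[1]), float(axis[2]), angle)


def write_vrml(scene: SceneSpec) -> str:
    """Render the scene as a VRML V2.0 utf8 document.

    One sphere per attractor; each shown transition as a cylinder shaft
    capped by a cone head at the sink end, pointing source -> sink.
    """
    lines = ["#VRML V2.0 utf8", ""]
    for key, val in sorted(scene.metadata.items()):
        lines.append(f"# {key}={val}")
    lines.append("")
    pos = {n.label: np.array(n.position) for n in scene.nodes}
    for node in scene.nodes:
        r, g, b = node.color
        x, y, z = node.position
        lines += [
            f"# node {node.label}",
            "Transform {",
            f"  translation {_fmt(x)} {_fmt(y)} {_fmt(z)}",
            "  children Shape {",
            "    appearance Appearance { material Material {"
            f" diffuseColor {_fmt(r)} {_fmt(g)} {_fmt(b)} }} }}",
            f"    geometry Sphere {{ radius {_fmt(node.radius)} }}",
            "  }",
            "}",
        ]
    for edge in scene.shown_edges:
        a, b = pos[edge.source], pos[edge.sink]
        vec = b - a
        length = float(np.linalg.norm(vec))
        if length < 1e-12:
            continue
        head_len = min(0.25 * length, 4.0 * edge.width)
        shaft_len = length - head_len
        ax, ay, az, angle = _rotation_from_y(vec)
        shaft_mid = a + vec * (shaft_len / (2.0 * length))
        head_mid = a + vec * ((shaft_len + head_len / 2.0) / length)
        lines += [
            f"# edge {edge.source} -> {edge.sink} (flux {edge.flux:.6g})",
            "Transform {",
            f"  translation {_fmt(shaft_mid[0])} {_fmt(shaft_mid[1])}"
            f" {_fmt(shaft_mid[2])}",
            f"  rotation {_fmt(ax)} {_fmt(ay)} {_fmt(az)} {_fmt(angle)}",
            "  children Shape {",
            "    appearance Appearance { material Material {"
            " diffuseColor 0.300000 0.300000 0.300000 } }",
            f"    geometry Cylinder {{ radius {_fmt(edge.width / 2.0)}"
            f" height {_fmt(shaft_len)} }}",
            "  }",
            "}",
            "Transform {",
            f"  translation {_fmt(head_mid[0])} {_fmt(head_mid[1])}"
            f" {_fmt(head_mid[2])}",
            f"  rotation {_fmt(ax)} {_fmt(ay)} {_fmt(az)} {_fmt(angle)}",
            "  children Shape {",
            "    appearance Appearance { material Material {"
            " diffuseColor 0.300000 0.300000 0.300000 } }",
            f"    geometry Cone {{ bottomRadius {_fmt(edge.width)}"
            f" height {_fmt(head_len)} }}",
            "  }",
            "}",
        ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Graph exports
# ---------------------------------------------------------------------------


def _scene_graph(scene: SceneSpec, metrics: MetricsTable) -> nx.DiGraph:
    index = {lab: i for i, lab in enumerate(metrics.labels)}
    g = nx.DiGraph()
    for key, val in sorted(scene.metadata.items()):
        g.graph[key] = val
    for node in scene.nodes:
        x, y, z = node.position
        g.add_node(
            node.label,
            label=node.label,
            x=float(x),
            y=float(y),
            z=float(z),
            color="#%02x%02x%02x"
            % tuple(int(round(255 * c)) for c in node.color),
        )
    for edge in scene.edges:
        i, j = index[edge.source], index[edge.sink]
        g.add_edge(
            edge.source,
            edge.sink,
            mfpt_forward=float(metrics.mfpt[i, j]),
            mfpt_reverse=float(metrics.mfpt[j, i]),
            separation=float(metrics.separation[i, j]),
            flux=float(metrics.mfpt[i, j] - metrics.mfpt[j, i]),
            width=float(edge.width),
            shown=bool(edge.shown),
        )
    return g


def write_graphml(scene: SceneSpec, metrics: MetricsTable) -> str:
    g = _scene_graph(scene, metrics)
    return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"


def write_json_graph(
    scene: SceneSpec, metrics: MetricsTable, tree: LineageTree | None = None
) -> str:
    """JSON mirror of the GraphML export, plus the full ordered-pair table."""
    g = _scene_graph(scene, metrics)
    doc = {
        "metadata": {k: g.graph[k] for k in sorted(g.graph)},
        "nodes": [
            {"id": n, **{k: v for k, v in data.items()}}
            for n, data in g.nodes(data=True)
        ],
        "edges": [
            {"source": u, "sink": v, **{k: w for k, w in data.items()}}
            for u, v, data in g.edges(data=True)
        ],
        "pairs": metrics_frame(metrics, tree).to_dict(orient="records"),
    }
    return json.dumps(doc, indent=2, sort_keys=False) + "\n"


def write_graph_exports(
    scene: SceneSpec, metrics: MetricsTable, tree: LineageTree | None = None
) -> tuple[str, str]:
    """Both machine-readable exports: (GraphML document, JSON document)."""
    return write_graphml(scene, metrics), write_json_graph(scene, metrics, tree)
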