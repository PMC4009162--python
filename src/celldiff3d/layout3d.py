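"""3D stress-minimization layout of the attractor graph.

Attractors are embedded in Euclidean 3-space so that pairwise distances
approximate pairwise separations: the objective is the raw stress

    stress(X) = sum_{i<j} (||x_i - x_j|| - sep(i, j))^2

minimized by SMACOF-style iterative majorization (Guttman transform) from
several seeded random starts.  Majorization guarantees the stress never
increases between iterations; the best restart is kept.  Because MFPT-
derived separations can span orders of magnitude, an optional log scale
mode embeds log(1 + sep) instead; the mode is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Layout3D", "stress", "fit_layout", "layout_tsv"]


@dataclass(frozen=True)
class Layout3D:
    """Embedded coordinates (m x 3, centroid at origin) with final stress."""

    coordinates: np.ndarray
    stress: float
    scale_mode: str
    seed: int
    restarts: int
    stress_history: tuple[float, ...] = field(default_factory=tuple)

    @property
    def m(self) -> int:
        return self.coordinates.shape[0]


def _check_separations(separations: np.ndarray) -> np.ndarray:
    sep = np.asarray(separations, dtype=np.float64)
    if sep.ndim != 2 or sep.shape[0] != sep.shape[1]:
        raise ValueError("separations must be a square matrix")
    if not np.allclose(sep, sep.T, rtol=0, atol=1e-9):
        raise ValueError("separations must be symmetric")
    if np.any(sep < 0):
        raise ValueError("separations must be nonnegative")
    return (sep + sep.T) / 2.0


def _distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def stress(coords: np.ndarray, separations: np.ndarray) -> float:
    """Raw stress: sum over unordered pairs of (distance - separation)^2."""
    coords = np.asarray(coords, dtype=np.float64)
    sep = _check_separations(separations)
    if coords.shape[0] != sep.shape[0]:
        raise ValueError(
            f"{coords.shape[0]} coordinate rows vs {sep.shape[0]} separations"
        )
    d = _distances(coords)
    iu = np.triu_indices(sep.shape[0], k=1)
    return float(np.sum((d[iu] - sep[iu]) ** 2))


def _guttman_step(coords: np.ndarray, sep: np.ndarray) -> np.ndarray:
    """One majorization update X' = B(X) X / m (uniform weights)."""
    m = coords.shape[0]
    d = _distances(coords)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, sep / np.where(d > 0, d, 1.0), 0.0)
    B = -ratio
    np.fill_diagonal(B, 0.0)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ coords) / m


def fit_layout(
    separations: np.ndarray,
    seed: int = 0,
    restarts: int = 8,
    tol: float = 1e-9,
    max_iter: int = 2000,
    scale_mode: str = "linear",
) -> Layout3D:
    """Fit 3D coordinates minimizing the stress objective.

    Runs ``restarts`` majorization descents from random starts drawn
    uniformly in a cube scaled to the median separation (all seeded from
    ``seed``), keeps the best, and recenters the centroid at the origin.
    ``scale_mode='log'`` embeds log(1 + sep).  The per-iteration stress
    trace of the winning restart is kept for descent diagnostics.
    """
    sep = _check_separations(separations)
    m = sep.shape[0]
    if scale_mode not in ("linear", "log"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if scale_mode == "log":
        sep = np.log1p(sep)
        np.fill_diagonal(sep, 0.0)
    if m == 1:
        return Layout3D(np.zeros((1, 3)), 0.0, scale_mode, seed, restarts, (0.0,))
    if m == 2:  # exact closed form: the pair on the x-axis
        d = sep[0, 1]
        coords = np.array([[-d / 2, 0.0, 0.0], [d / 2, 0.0, 0.0]])
        return Layout3D(coords, 0.0, scale_mode, seed, restarts, (0.0,))

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(m, k=1)
    scale = float(np.median(sep[iu]))
    if scale <= 0:
        scale = 1.0
    best_coords = None
    best_stress = np.inf
    best_history: list[float] = []
    for _ in range(max(1, restarts)):
        coords = rng.uniform(-scale, scale, size=(m, 3))
        s_prev = stress(coords, sep)
        history = [s_prev]
        for _ in range(max_iter):
            coords = _guttman_step(coords, sep)
            s = stress(coords, sep)
            if s > s_prev + 1e-9 * max(1.0, s_prev):  # majorization guarantee
                raise RuntimeError("stress increased during majorization")
            history.append(s)
            if s_prev - s <= tol * max(s_prev, 1e-300):
                s_prev = s
                break
            s_prev = s
        if s_prev < best_stress:
            best_stress = s_prev
            best_coords = coords
            best_history = history
    best_coords = best_coords - best_coords.mean(axis=0, keepdims=True)
    return Layout3D(
        best_coords,
        float(stress(best_coords, sep)),
        scale_mode,
        seed,
        restarts,
        tuple(best_history),
    )


def layout_tsv(layout: Layout3D, labels) -> str:
    """Coordinates as TSV with a metadata header."""
    lines = [
        f"# stress={layout.stress:.10g}",
        f"# scale_mode={layout.scale_mode}",
        f"# seed={layout.seed}",
        f"# restarts={layout.restarts}",
        "label\tx\ty\tz",
    ]
    for lab, (x, y, z) in zip(labels, layout.coordinates):
        lines.append(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}")
    return "\n".join(lines) + "\n"
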