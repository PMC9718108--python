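"""Generalized Procrustes alignment of 2-D landmark configurations.

Removes the similarity nuisances — translation, scale (full Procrustes, unit
centroid size) and rotation — so that only shape differences remain.
Reflections are never produced by the rotation solver; pooling of left hips
is handled explicitly by :func:`mirror_left` before alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
import numpy as np

from .io import LandmarkConfiguration


def flatten_points(points: np.ndarray) -> np.ndarray:
    """(k, 2) point matrix -> length-2k row ``[x1..xk, y1..yk]``."""
    points = np.asarray(points, dtype=float)
    return np.concatenate([points[:, 0], points[:, 1]])


def unflatten_points(row: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_points`."""
    row = np.asarray(row, dtype=float)
    k = row.size // 2
    return np.column_stack([row[:k], row[k:]])


def centroid_size(points: np.ndarray) -> float:
    """Square root of the summed squared landmark distances to the centroid."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("centroid_size requires at least 2 points")
    centered = points - points.mean(axis=0)
    ss = float(np.sum(centered**2))
    if ss < 1e-24:
        raise ValueError("degenerate shape: all landmarks coincide")
    return float(np.sqrt(ss))


def optimal_rotation(shape: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rotation aligning ``shape`` onto ``reference``.

    Both inputs must be centered (k, 2) matrices.  Returns the 2x2 rotation
    ``R`` (determinant +1, reflections excluded) minimising
    ``sum ||R p_i - q_i||^2``; apply it as ``shape @ R.T``.  A vanishing
    cross-covariance yields the identity with a warning.
    """
    shape = np.asarray(shape, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if shape.shape != reference.shape:
        raise ValueError("shape and reference must have identical dimensions")
    h = shape.T @ reference  # 2x2 cross-covariance
    if np.linalg.norm(h) < 1e-12:
        warnings.warn("zero cross-covariance; returning identity rotation")
        return np.eye(2)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, d]) @ u.T


@dataclass
class AlignedShapes:
    """GPA output: rows are flattened aligned shapes ``[x1..xk, y1..yk]``."""

    aligned: np.ndarray          # (n, 2k)
    consensus: np.ndarray        # (2k,) row mean of `aligned`
    centroid_sizes: np.ndarray   # per-shape size before unit scaling
    iterations: int
    converged: bool
    residual_history: list[float]

    @property
    def n_shapes(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_points(self) -> int:
        return self.aligned.shape[1] // 2

    def shape(self, i: int) -> np.ndarray:
        return unflatten_points(self.aligned[i])


def _stack(shapes) -> np.ndarray:
    if isinstance(shapes, np.ndarray) and shapes.ndim == 3:
        return np.asarray(shapes, dtype=float)
    mats = []
    for s in shapes:
        if isinstance(s, LandmarkConfiguration):
            mats.append(s.points)
        else:
            mats.append(np.asarray(s, dtype=float))
    counts = {m.shape for m in mats}
    if len(counts) != 1:
        raise ValueError(f"all shapes must share one point count, got {counts}")
    return np.stack(mats)


def generalized_procrustes(
    shapes, tol: float = 1e-8, max_iter: int = 100
) -> AlignedShapes:
    """Iterative GPA: center, scale to unit centroid size, rotate to the
    consensus, and re-estimate the consensus until it stabilises.

    The consensus is initialised to the first shape and re-normalised to unit
    centroid size each iteration to fix the scale gauge.  Non-convergence is
    reported (``converged=False`` plus a warning), never silent.
    """
    x = _stack(shapes)
    n, k, _ = x.shape
    if n < 2:
        raise ValueError("GPA requires at least 2 shapes")

    x = x - x.mean(axis=1, keepdims=True)
    sizes = np.sqrt((x**2).sum(axis=(1, 2)))
    if np.any(sizes < 1e-12):
        raise ValueError("degenerate shape: all landmarks coincide")
    x = x / sizes[:, None, None]

    # the first shape only fixes the rotation gauge; convergence is judged
    # on the change between successively *estimated* consensus shapes
    consensus = x[0].copy()
    prev_consensus = None
    converged = False
    residuals: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            r = optimal_rotation(x[i], consensus)
            x[i] = x[i] @ r.T
        mean = x.mean(axis=0)
        residuals.append(float(((x - mean) ** 2).sum()))
        mean = mean - mean.mean(axis=0)
        consensus = mean / np.sqrt((mean**2).sum())
        if prev_consensus is not None:
            change = float(np.sqrt(((consensus - prev_consensus) ** 2).mean()))
            if change < tol:
                converged = True
                break
        prev_consensus = consensus
    if not converged:
        warnings.warn(
            f"GPA did not converge within {max_iter} iterations "
            f"(last consensus RMS change above {tol})"
        )

    aligned = np.stack([flatten_points(s) for s in x])
    return AlignedShapes(
        aligned=aligned,
        consensus=aligned.mean(axis=0),
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        residual_history=residuals,
    )


def mirror_left(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a left hip (x -> -x) into the right-hip convention.

    Both sides are pooled into one per-sex shape model, which requires a side
    convention; mirroring must happen before GPA because the alignment itself
    never reflects.  The returned configuration is relabelled ``right``.
    """
    if config.side != "left":
        raise ValueError(f"mirror_left applies only to left hips, got side={config.side!r}")
    pts = config.points.copy()
    pts[:, 0] = -pts[:, 0]
    return replace(config, points=pts, side="right")


__all__ = [
    "AlignedShapes",
    "centroid_size",
    "optimal_rotation",
    "generalized_procrustes",
    "mirror_left",
    "flatten_points",
    "unflatten_points",
]
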