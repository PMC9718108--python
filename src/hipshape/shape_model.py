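"""PCA shape modes of Procrustes-aligned landmark configurations.

The point-distribution model: aligned shapes are decomposed about their mean
into orthonormal modes of variation ordered by explained variance.  Per-hip
mode scores are standardized in-sample to mean 0 and SD 1, so downstream
association analyses always work in units of one SD of shape-mode score.
Modes explaining at least a configurable fraction of total variance
(default 1%) are retained for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .procrustes import AlignedShapes, unflatten_points


@dataclass
class ShapeModel:
    """Point-distribution model fitted to one sex stratum.

    ``modes`` rows are orthonormal 2k-vectors in the flattened
    ``[x1..xk, y1..yk]`` convention; ``eigenvalues`` are the corresponding
    (descending) variances; ``variance_fraction`` is each eigenvalue over the
    total variance of the aligned data.  ``scores`` are raw projections of
    the centered training shapes; ``standardized_scores`` rescale each column
    to mean 0, SD 1 (n-1 denominator).
    """

    consensus: np.ndarray            # (2k,)
    modes: np.ndarray                # (m, 2k)
    eigenvalues: np.ndarray          # (m,)
    variance_fraction: np.ndarray    # (m,)
    scores: np.ndarray               # (n, m)
    score_mean: np.ndarray           # (m,)
    score_sd: np.ndarray             # (m,)
    standardized_scores: np.ndarray  # (n, m)
    sex: str | None = None

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def n_shapes(self) -> int:
        return self.scores.shape[0]


def fit_shape_model(aligned, sex: str | None = None) -> ShapeModel:
    """Eigendecompose aligned shape coordinates about their mean.

    Accepts an :class:`~hipshape.procrustes.AlignedShapes` or a plain
    ``(n, 2k)`` array of flattened aligned rows.  The rank is capped at
    ``min(n - 1, 2k - 4)``: one degree of freedom is lost to centering and
    four to the similarity constraints removed by GPA.
    """
    x = aligned.aligned if isinstance(aligned, AlignedShapes) else np.asarray(aligned, float)
    if x.ndim != 2:
        raise ValueError("aligned data must be a 2-D array of flattened shapes")
    n, p = x.shape
    if n < 3:
        raise ValueError(f"shape model requires at least 3 shapes, got {n}")

    mean = x.mean(axis=0)
    xc = x - mean
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    eig = svals**2 / (n - 1)
    total = float(eig.sum())
    rank = min(n - 1, p - 4, eig.size)
    modes = vt[:rank].copy()
    eig = eig[:rank].copy()

    # Fix each mode's sign: largest-magnitude loading positive.
    for j in range(rank):
        lead = np.argmax(np.abs(modes[j]))
        if modes[j, lead] < 0:
            modes[j] = -modes[j]

    scores = xc @ modes.T
    score_mean = scores.mean(axis=0)
    score_sd = scores.std(axis=0, ddof=1)
    safe_sd = np.where(score_sd > 0, score_sd, 1.0)
    standardized = (scores - score_mean) / safe_sd

    return ShapeModel(
        consensus=mean,
        modes=modes,
        eigenvalues=eig,
        variance_fraction=eig / total,
        scores=scores,
        score_mean=score_mean,
        score_sd=score_sd,
        standardized_scores=standardized,
        sex=sex,
    )


def modes_above_threshold(variance_fractions, threshold: float = 0.01) -> np.ndarray:
    """Indices (0-based, eigenvalue order) of fractions >= ``threshold``.

    Applied to unrounded fractions; the printed one-decimal percentages are
    for reporting only.
    """
    fractions = np.asarray(variance_fractions, dtype=float)
    return np.flatnonzero(fractions >= threshold)


def select_modes(model: ShapeModel, threshold: float = 0.01) -> np.ndarray:
    """Modes explaining at least ``threshold`` of total shape variance."""
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    return modes_above_threshold(model.variance_fraction, threshold)


def mode_shape_at(model: ShapeModel, mode_index: int, k_sd: float) -> np.ndarray:
    """The (k, 2) shape at ``k_sd`` score SDs along one mode from the mean."""
    if not 0 <= mode_index < model.n_modes:
        raise IndexError(
            f"mode index {mode_index} out of range 0..{model.n_modes - 1}"
        )
    row = model.consensus + k_sd * model.score_sd[mode_index] * model.modes[mode_index]
    return unflatten_points(row)


def project(model: ShapeModel, shape) -> np.ndarray:
    """Raw mode scores of one aligned shape (or a stack of shapes)."""
    arr = np.asarray(shape, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:  # (k, 2) point matrix
        arr = np.concatenate([arr[:, 0], arr[:, 1]])
    if arr.shape[-1] != model.consensus.size:
        raise ValueError(
            f"dimension mismatch: shape has {arr.shape[-1]} coordinates, "
            f"model expects {model.consensus.size}"
        )
    return (arr - model.consensus) @ model.modes.T


def standardize_scores(model: ShapeModel, raw_scores) -> np.ndarray:
    """Scale raw scores by the model's in-sample mean/SD (the per-SD unit)."""
    raw = np.asarray(raw_scores, dtype=float)
    safe_sd = np.where(model.score_sd > 0, model.score_sd, 1.0)
    return (raw - model.score_mean) / safe_sd


def reconstruct(model: ShapeModel, raw_scores) -> np.ndarray:
    """Map raw mode scores back to a flattened shape row."""
    raw = np.atleast_1d(np.asarray(raw_scores, dtype=float))
    return model.consensus + raw @ model.modes[: raw.shape[-1]]


def variance_table(model: ShapeModel) -> pd.DataFrame:
    """Per-mode percentage of variance explained plus cumulative percentage.

    Percentages print to one decimal; the cumulative column is computed on
    the unrounded fractions and rounded last, so it is internally consistent
    even when the rounded per-mode column would not sum to it.
    """
    pct = model.variance_fraction * 100.0
    return pd.DataFrame(
        {
            "mode": np.arange(1, model.n_modes + 1),
            "pct_variance": np.round(pct, 1),
            "cumulative_pct": np.round(np.cumsum(pct), 1),
        }
    )


__all__ = [
    "ShapeModel",
    "fit_shape_model",
    "select_modes",
    "modes_above_threshold",
    "mode_shape_at",
    "project",
    "standardize_scores",
    "reconstruct",
    "variance_table",
]
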