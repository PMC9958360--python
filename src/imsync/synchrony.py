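"""Dyadic correlation matrices of body-part velocity time series.

For each trial, every combination of participant A's and participant B's ten
body parts is correlated (Pearson), giving a 10x10 matrix per dyad/trial.
Matrices from the trials of one condition are averaged element-wise, and —
because the two participants have no assigned roles — each condition matrix
is symmetrised by averaging across the main diagonal, leaving 55 unique
body-part combinations (10 homologous + 45 heterologous).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import PART_NAMES
from .preprocess import VelocityPanel

#: Row/column indices of the 55 unique combinations (lower triangle, i >= j).
TRIL_INDICES: tuple[np.ndarray, np.ndarray] = np.tril_indices(len(PART_NAMES))

#: Labels of the 55 combinations, "<partA>-<partB>" with i >= j.
COMBO_LABELS: tuple[str, ...] = tuple(
    f"{PART_NAMES[i]}-{PART_NAMES[j]}" for i, j in zip(*TRIL_INDICES)
)

#: Index (into COMBO_LABELS) of the 10 homologous combinations.
HOMOLOGOUS_COMBOS: tuple[int, ...] = tuple(
    k for k, (i, j) in enumerate(zip(*TRIL_INDICES)) if i == j
)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series.

    Zero variance in either input is signalled with a ``ValueError`` rather
    than silently mapped to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def _aligned(a: np.ndarray, b: np.ndarray, tol: int = 2) -> tuple[np.ndarray, np.ndarray]:
    la, lb = a.shape[0], b.shape[0]
    if la == lb:
        return a, b
    if abs(la - lb) > tol:
        raise ValueError(f"partner series lengths differ by {abs(la - lb)} > {tol} frames")
    warnings.warn(f"truncating partner series to common length ({min(la, lb)})")
    n = min(la, lb)
    return a[:n], b[:n]


def corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs column correlation: ``out[i, j] = r(a[:, i], b[:, j])``.

    NaN columns (dropped parts) propagate to NaN entries.
    """
    a, b = _aligned(np.asarray(a, float), np.asarray(b, float))
    n = a.shape[0]
    az = (a - a.mean(axis=0)) / a.std(axis=0)
    bz = (b - b.mean(axis=0)) / b.std(axis=0)
    return az.T @ bz / n


def trial_matrix(panel_a: VelocityPanel, panel_b: VelocityPanel) -> np.ndarray:
    """10x10 trial correlation matrix, rows = A's parts, cols = B's parts.

    Refuses QC-flagged trials.
    """
    if panel_a.qc_flag or panel_b.qc_flag:
        raise ValueError(f"trial {panel_a.trial_id}: QC-flagged, refusing correlation")
    return corr_columns(panel_a.velocity, panel_b.velocity)


def condition_average(matrices: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of the per-trial matrices of one condition."""
    if len(matrices) == 0:
        raise ValueError("no unflagged trials to average")
    return np.mean(np.stack(matrices), axis=0)


def symmetrize(matrix: np.ndarray) -> np.ndarray:
    """Average a square matrix across its main diagonal: ``(M + M.T) / 2``.

    Idempotent; the informative entries are the lower triangle (55 values
    for 10 parts).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got {matrix.shape}")
    return (matrix + matrix.T) / 2.0


def combo_vector(matrix: np.ndarray) -> np.ndarray:
    """The 55 unique combination coefficients of a (symmetrised) matrix,
    ordered like :data:`COMBO_LABELS`."""
    return symmetrize(matrix)[TRIL_INDICES]


def tidy_table(coeffs: dict[tuple[str, tuple[str, str]], np.ndarray]) -> pd.DataFrame:
    """Tidy per-dyad condition coefficients: one row per
    dyad x condition x combination.

    ``coeffs`` maps ``(dyad_id, (proximity, vision))`` to a 55-vector.
    """
    rows = []
    ii, jj = TRIL_INDICES
    for (dyad, (prox, vis)), vec in coeffs.items():
        for k, (i, j) in enumerate(zip(ii, jj)):
            rows.append({
                "dyad": dyad, "proximity": prox, "vision": vis,
                "part_a": PART_NAMES[i], "part_b": PART_NAMES[j],
                "combo": COMBO_LABELS[k], "r": vec[k],
            })
    return pd.DataFrame(rows)
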