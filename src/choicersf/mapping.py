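"""Predicted relative-probability-of-use surfaces and map comparison.

A fitted coefficient vector turns the covariate stack into a map of
exp(beta . x) per cell, min-max rescaled to [0, 1] across the mapped
extent.  Only the relative (rank) structure of such a surface is
interpretable, so maps are compared with Spearman rank correlation, which
is invariant to the rescaling convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .design import DesignCoding
from .errors import InsufficientDataError, ShapeError
from .landscape import CovariateGrids, _write_ascii_grid
from .likelihood import Coefficients, _as_beta

#: Bin edges for the rho distribution table: closed lower bounds from 0.9
#: down to 0.0, plus a catch-all for negative correlations.
RHO_BIN_LOWER = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.0]


@dataclass
class PredictionMap:
    """Relative-use surface in [0, 1] on the geometry of its source grids."""

    values: np.ndarray
    provenance: str = ""
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("prediction map must be 2-D")

    def write(self, path: str | Path) -> None:
        _write_ascii_grid(Path(path), self.values, self.cell_size, self.origin)


def predict_map(
    beta: Coefficients | np.ndarray,
    grids: CovariateGrids,
    coding: DesignCoding,
    provenance: str = "",
) -> PredictionMap:
    """Map of min-max rescaled exp(beta . x) over every cell.

    A constant utility surface (e.g. beta = 0) carries no rank information;
    it is returned as all zeros with a warning.
    """
    b = _as_beta(beta)
    if b.shape[0] != coding.n_columns:
        raise ShapeError(f"beta has {b.size} entries, coding has {coding.n_columns} columns")
    u = np.zeros(grids.shape)
    for i, name in enumerate(coding.continuous):
        if name not in grids.layers:
            raise ShapeError(f"covariate {name!r} missing from grids")
        u += b[i] * grids.layers[name]
    offset = len(coding.continuous)
    dummy_labels = [c for c in coding.habitat_labels if c != coding.reference]
    for i, label in enumerate(dummy_labels):
        j = coding.habitat_labels.index(label)
        u += b[offset + i] * (grids.habitat == j)

    w = np.exp(u - u.max())
    lo, hi = w.min(), w.max()
    if hi == lo:
        warnings.warn("constant utility surface; returning an all-zero map", stacklevel=2)
        values = np.zeros_like(w)
    else:
        values = (w - lo) / (hi - lo)
    return PredictionMap(
        values=values, provenance=provenance, cell_size=grids.cell_size, origin=grids.origin
    )


def compare_maps(m1: PredictionMap | np.ndarray, m2: PredictionMap | np.ndarray) -> float:
    """Spearman rank correlation over all cells (average ranks for ties).

    Constant maps have no rank ordering; the comparison is then undefined
    and returned as nan with a warning.
    """
    a = (m1.values if isinstance(m1, PredictionMap) else np.asarray(m1, float)).ravel()
    b = (m2.values if isinstance(m2, PredictionMap) else np.asarray(m2, float)).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"map geometries differ: {a.shape} vs {b.shape}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant map: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho = spearmanr(a, b).statistic
    return float(rho)


def correlation_table(rhos: list[float] | np.ndarray) -> pd.DataFrame:
    """Distribution of map correlations binned the way pairwise individual-
    vs-population comparisons are conventionally reported: rho >= 0.9, then
    tenth-wide bins with closed lower bounds down to [0, 0.1), and one bin
    for negative rho.  Proportions sum to 1.
    """
    rhos = np.asarray(rhos, dtype=float)
    if rhos.size == 0:
        raise InsufficientDataError("no correlations to tabulate")
    if not np.all(np.isfinite(rhos)):
        raise InsufficientDataError("non-finite correlation in input")
    labels, counts = [], []
    for i, lo in enumerate(RHO_BIN_LOWER):
        if i == 0:
            labels.append(f"rho >= {lo}")
            counts.append(int(np.sum(rhos >= lo)))
        else:
            hi = RHO_BIN_LOWER[i - 1]
            labels.append(f"{lo} <= rho < {hi}")
            counts.append(int(np.sum((rhos >= lo) & (rhos < hi))))
    labels.append("negative rho")
    counts.append(int(np.sum(rhos < 0.0)))
    counts_arr = np.array(counts)
    return pd.DataFrame(
        {"bin": labels, "n": counts_arr, "proportion": counts_arr / rhos.size}
    )


def uncertainty_map(
    draws: np.ndarray, grids: CovariateGrids, coding: DesignCoding, thin: int = 10
) -> PredictionMap:
    """Cell-wise sd of the rescaled use surface across posterior draws."""
    draws = np.asarray(draws, dtype=float)[::thin]
    stack = np.stack([predict_map(b, grids, coding).values for b in draws])
    return PredictionMap(
        values=stack.std(axis=0),
        provenance="posterior sd of relative use",
        cell_size=grids.cell_size,
        origin=grids.origin,
    )
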