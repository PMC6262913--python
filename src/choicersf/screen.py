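"""Iterative collinearity screening of continuous covariates.

Before all-subsets model fitting, redundant covariates are removed until
every pairwise Pearson correlation among the retained continuous columns
satisfies |r| <= threshold (0.6 by default).  Categorical indicator columns
are exempt.  At each step the worst-offending pair is located and the member
with the larger mean absolute correlation to all other retained columns is
dropped (ties broken lexically), a reproducible analogue of judging which
variable is the more redundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .choices import ChoiceData
from .errors import InsufficientDataError


@dataclass
class ScreenResult:
    retained: list[str]
    dropped: list[tuple[str, float]]   # (column, max |r| at drop time; nan for zero variance)
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"column": c, "status": "retained", "max_abs_r_at_drop": np.nan} for c in self.retained]
        rows += [{"column": c, "status": "dropped", "max_abs_r_at_drop": r} for c, r in self.dropped]
        return pd.DataFrame(rows)


def _pooled_continuous_matrix(data: ChoiceData) -> tuple[np.ndarray, list[str]]:
    """Continuous columns pooled over all alternatives of all sets."""
    if data.coding is not None:
        cont = [c for c in data.column_names if c in data.coding.continuous]
    else:
        cont = [c for c in data.column_names if not c.startswith("habitat:")]
    idx = [data.column_names.index(c) for c in cont]
    n, C, _ = data.X.shape
    return data.X[:, :, idx].reshape(n * C, len(idx)), cont


def screen_collinearity(
    data: ChoiceData | pd.DataFrame | np.ndarray,
    threshold: float = 0.6,
    column_names: list[str] | None = None,
) -> ScreenResult:
    """Drop continuous covariates until all pairwise |r| <= threshold.

    Accepts a :class:`ChoiceData` (continuous columns pooled across
    alternatives), a DataFrame, or a plain matrix with ``column_names``.
    Zero-variance columns are flagged and dropped first with a warning.
    """
    if isinstance(data, ChoiceData):
        mat, names = _pooled_continuous_matrix(data)
    elif isinstance(data, pd.DataFrame):
        mat, names = data.to_numpy(dtype=float), list(data.columns)
    else:
        mat = np.asarray(data, dtype=float)
        names = column_names or [f"col{i}" for i in range(mat.shape[1])]
    if mat.shape[1] < 2:
        raise InsufficientDataError("need at least 2 continuous columns to screen")

    dropped: list[tuple[str, float]] = []
    active = list(range(mat.shape[1]))

    sds = mat.std(axis=0)
    for j in [j for j in active if sds[j] == 0]:
        warnings.warn(f"zero-variance column {names[j]!r} dropped before screening", stacklevel=2)
        dropped.append((names[j], float("nan")))
        active.remove(j)

    while len(active) >= 2:
        r = np.corrcoef(mat[:, active], rowvar=False)
        np.fill_diagonal(r, 0.0)
        absr = np.abs(r)
        worst = absr.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        # drop the member of the worst pair that is more redundant overall
        mean_i = absr[i].sum() / (len(active) - 1)
        mean_j = absr[j].sum() / (len(active) - 1)
        if mean_i > mean_j or (mean_i == mean_j and names[active[i]] > names[active[j]]):
            victim = i
        else:
            victim = j
        dropped.append((names[active[victim]], float(worst)))
        del active[victim]

    return ScreenResult(
        retained=[names[j] for j in active],
        dropped=dropped,
        threshold=threshold,
    )


def max_abs_correlation(mat: np.ndarray) -> float:
    """Maximum off-diagonal |Pearson r| of a column matrix."""
    r = np.corrcoef(np.asarray(mat, dtype=float), rowvar=False)
    np.fill_diagonal(r, 0.0)
    return float(np.abs(r).max())
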