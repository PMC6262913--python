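"""Design-vector construction from covariate grids.

A design vector for a habitat unit (a point carrying its cell's covariates)
holds the continuous layer values followed by reference-coded indicators for
the categorical habitat layer.  The conditional-logit model has no intercept
— within-set constants cancel — so one habitat class serves as the reference
and contributes no column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidConfigError, SchemaError
from .landscape import CovariateGrids


@dataclass(frozen=True)
class DesignCoding:
    """Column layout manifest: which covariates, and how habitat is coded."""

    continuous: tuple[str, ...]
    habitat_labels: tuple[str, ...] = ()
    reference: str | None = None

    def __post_init__(self):
        if self.habitat_labels:
            ref = self.reference if self.reference is not None else self.habitat_labels[0]
            if ref not in self.habitat_labels:
                raise InvalidConfigError(f"reference class {ref!r} not among habitat labels")
            object.__setattr__(self, "reference", ref)

    @classmethod
    def from_grids(
        cls,
        grids: CovariateGrids,
        continuous: list[str] | None = None,
        reference: str | None = None,
        include_habitat: bool = True,
    ) -> "DesignCoding":
        cont = tuple(continuous if continuous is not None else grids.layer_names)
        missing = set(cont) - set(grids.layer_names)
        if missing:
            raise SchemaError(f"continuous layers not in grids: {sorted(missing)}")
        labels = tuple(grids.habitat_labels) if include_habitat else ()
        return cls(continuous=cont, habitat_labels=labels, reference=reference)

    @property
    def habitat_columns(self) -> list[str]:
        return [f"habitat:{c}" for c in self.habitat_labels if c != self.reference]

    @property
    def column_names(self) -> list[str]:
        return list(self.continuous) + self.habitat_columns

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    @property
    def variables(self) -> list[str]:
        """Variable-level terms: each continuous layer, plus 'habitat' as one block."""
        out = list(self.continuous)
        if self.habitat_labels:
            out.append("habitat")
        return out

    def columns_for(self, variables: list[str]) -> list[int]:
        """Column indices realizing a subset of variable-level terms."""
        names = self.column_names
        idx: list[int] = []
        for v in variables:
            if v == "habitat":
                idx.extend(names.index(c) for c in self.habitat_columns)
            elif v in self.continuous:
                idx.append(names.index(v))
            else:
                raise SchemaError(f"unknown variable {v!r}")
        return idx

    def to_dict(self) -> dict:
        return {
            "continuous": list(self.continuous),
            "habitat_labels": list(self.habitat_labels),
            "reference": self.reference,
            "column_order": self.column_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignCoding":
        return cls(
            continuous=tuple(d["continuous"]),
            habitat_labels=tuple(d["habitat_labels"]),
            reference=d.get("reference"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignCoding":
        return cls.from_dict(json.loads(Path(path).read_text()))


def extract_design(points: np.ndarray, grids: CovariateGrids, coding: DesignCoding) -> np.ndarray:
    """Design matrix (n_points, n_columns) for planar points.

    Continuous covariates are read from the cell containing each point;
    habitat is expanded to K-1 reference-coded indicators.  Points outside
    the grid extent raise :class:`OutOfBoundsError`.
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    row, col = grids.cell_index(pts[:, 0], pts[:, 1])
    cols = [grids.layers[name][row, col] for name in coding.continuous]
    if coding.habitat_labels:
        hab = grids.habitat[row, col]
        for j, label in enumerate(coding.habitat_labels):
            if label == coding.reference:
                continue
            cols.append((hab == j).astype(float))
    X = np.column_stack(cols) if cols else np.empty((len(pts), 0))
    return X[0] if squeeze else X
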