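"""Used/available choice-set construction from telemetry.

Availability is defined per used location by the radius-of-available-habitat
rule: a buffer of radius c (a + 2 b), where a and b are the mean and
standard deviation of the hourly movement rate and c is the number of hours
between visits.  Each choice set pairs the used unit with ``n_available``
points sampled uniformly within that buffer (default 5), each carrying its
cell's design vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignCoding, extract_design
from .errors import (
    DegenerateTrackError,
    EmptyDataError,
    InsufficientDataError,
    InvalidConfigError,
    InvalidTrackError,
    SamplingFailedError,
    SchemaError,
)
from .landscape import CovariateGrids
from .track import TelemetryTrack, _sample_disc

logger = logging.getLogger(__name__)


@dataclass
class MovementStats:
    """Hourly movement-rate summary used to delimit availability.

    a: mean hourly movement rate (m/hr); b: sample SD of the rate (m/hr);
    c: hours between visits to habitat units; n_steps: steps retained.
    """

    a: float
    b: float
    c: float
    n_steps: int

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.c <= 0 or self.n_steps < 1:
            raise InvalidConfigError("invalid movement statistics")


def movement_stats(
    track: TelemetryTrack,
    nominal_interval: float = 5.0,
    max_gap_factor: float = 2.0,
    use_observed_median: bool = False,
) -> MovementStats:
    """Mean and SD of the hourly movement rate, plus the revisit interval c.

    Rates are Euclidean step length divided by actual elapsed hours, so
    missed fixes do not inflate speeds; steps whose gap exceeds
    ``max_gap_factor`` times the nominal interval are excluded (long gaps
    say little about travel rate).  c is the nominal collar schedule by
    default, or the observed median gap with ``use_observed_median``.
    """
    dt = track.elapsed_hours()
    if np.any(dt <= 0):
        raise InvalidTrackError("zero or negative elapsed time between fixes")
    dist = track.step_lengths()
    keep = dt <= max_gap_factor * nominal_interval
    if keep.sum() < 2:
        raise InsufficientDataError(
            f"only {int(keep.sum())} usable steps (need >= 2 for a rate SD)"
        )
    rates = dist[keep] / dt[keep]
    c = float(np.median(dt)) if use_observed_median else float(nominal_interval)
    return MovementStats(
        a=float(rates.mean()),
        b=float(rates.std(ddof=1)),
        c=c,
        n_steps=int(keep.sum()),
    )


def availability_radius(stats: MovementStats) -> float:
    """Radius of available habitat: c (a + 2 b) meters."""
    r = stats.c * (stats.a + 2.0 * stats.b)
    if r <= 0:
        raise DegenerateTrackError("availability radius is non-positive (stationary track?)")
    return r


def sample_available(
    used: np.ndarray,
    radius: float,
    n_available: int,
    grids: CovariateGrids,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> np.ndarray:
    """Uniform available points on the buffer disc clipped to the extent."""
    if n_available < 1:
        raise InvalidConfigError("n_available must be >= 1")
    if radius <= 0:
        raise InvalidConfigError("radius must be positive")
    used = np.asarray(used, dtype=float)
    out = np.empty((0, 2))
    for _ in range(max_rounds):
        pts = _sample_disc(rng, used, radius, max(n_available, 8))
        keep = grids.in_extent(pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
        if len(out) >= n_available:
            return out[:n_available]
    raise SamplingFailedError(
        f"buffer around {tuple(used)} (radius {radius:.1f} m) lies almost wholly outside the extent"
    )


@dataclass
class ChoiceSet:
    """One used unit plus its available alternatives (a view into ChoiceData)."""

    set_id: str
    coords: np.ndarray   # (C, 2)
    X: np.ndarray        # (C, k)
    chosen_index: int

    def __post_init__(self):
        if len(self.coords) != len(self.X) or len(self.X) < 1:
            raise SchemaError("alternatives and design rows disagree")
        if not 0 <= self.chosen_index < len(self.X):
            raise SchemaError("chosen_index out of range")


@dataclass
class ChoiceData:
    """All choice sets for one individual, as dense arrays.

    X has shape (n_sets, C, k); ``chosen`` holds the used alternative's index
    within each set.  All sets share the column layout in ``column_names``
    (recorded with the categorical coding in ``coding``).
    """

    individual_id: str
    X: np.ndarray
    chosen: np.ndarray
    column_names: list[str]
    coding: DesignCoding | None = None
    coords: np.ndarray | None = None   # (n_sets, C, 2) if available
    set_ids: list[str] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.chosen = np.asarray(self.chosen, dtype=int)
        if self.X.ndim != 3:
            raise SchemaError("X must be (n_sets, n_alternatives, n_columns)")
        if self.X.shape[2] != len(self.column_names):
            raise SchemaError("column_names length must match design columns")
        if len(self.chosen) != self.X.shape[0]:
            raise SchemaError("chosen length must match number of sets")
        if self.X.shape[0] < 1:
            raise EmptyDataError("no choice sets")
        if np.any(self.chosen < 0) or np.any(self.chosen >= self.X.shape[1]):
            raise SchemaError("chosen index out of range")

    @property
    def n_sets(self) -> int:
        return self.X.shape[0]

    @property
    def n_alternatives(self) -> int:
        return self.X.shape[1]

    @property
    def n_columns(self) -> int:
        return self.X.shape[2]

    @property
    def sets(self) -> list[ChoiceSet]:
        ids = self.set_ids or [str(i) for i in range(self.n_sets)]
        coords = (
            self.coords
            if self.coords is not None
            else np.full((self.n_sets, self.n_alternatives, 2), np.nan)
        )
        return [
            ChoiceSet(set_id=ids[i], coords=coords[i], X=self.X[i], chosen_index=int(self.chosen[i]))
            for i in range(self.n_sets)
        ]

    def subset_columns(self, columns: list[int] | list[str]) -> "ChoiceData":
        """New ChoiceData restricted to the given design columns."""
        if columns and isinstance(columns[0], str):
            idx = [self.column_names.index(c) for c in columns]
        else:
            idx = list(columns)  # type: ignore[arg-type]
        return ChoiceData(
            individual_id=self.individual_id,
            X=self.X[:, :, idx],
            chosen=self.chosen,
            column_names=[self.column_names[i] for i in idx],
            coding=None,
            coords=self.coords,
            set_ids=self.set_ids,
        )

    def subset_variables(self, variables: list[str]) -> "ChoiceData":
        """Restrict to variable-level terms (habitat enters/exits as a block)."""
        if self.coding is None:
            raise SchemaError("subset_variables requires a coding manifest")
        return self.subset_columns(self.coding.columns_for(variables))


def build_choice_sets(
    track: TelemetryTrack,
    grids: CovariateGrids,
    n_available: int = 5,
    nominal_interval: float = 5.0,
    coding: DesignCoding | None = None,
    seed: int | np.random.Generator = 0,
    stats: MovementStats | None = None,
) -> ChoiceData:
    """Assemble one choice set per fix: the used unit plus sampled alternatives.

    The availability radius is computed from the track's own movement
    statistics unless ``stats`` is supplied.  Fixes whose buffer sampling
    fails (buffer essentially outside the mapped extent) are dropped with a
    logged count; an all-dropped track raises :class:`EmptyDataError`.
    """
    if coding is None:
        coding = DesignCoding.from_grids(grids)
    rng = np.random.default_rng(seed)
    if stats is None:
        stats = movement_stats(track, nominal_interval=nominal_interval)
    radius = availability_radius(stats)

    X_rows, coords_rows, set_ids = [], [], []
    n_dropped = 0
    for i in range(track.n_fixes):
        used = track.xy[i]
        if not bool(np.all(grids.in_extent(used[0], used[1]))):
            n_dropped += 1
            continue
        try:
            avail = sample_available(used, radius, n_available, grids, rng)
        except SamplingFailedError:
            n_dropped += 1
            continue
        pts = np.vstack([used, avail])
        X_rows.append(extract_design(pts, grids, coding))
        coords_rows.append(pts)
        set_ids.append(str(i))
    if n_dropped:
        logger.info(
            "individual %s: dropped %d of %d fixes during choice-set construction",
            track.individual_id, n_dropped, track.n_fixes,
        )
    if not X_rows:
        raise EmptyDataError(f"all fixes of {track.individual_id} were dropped")
    return ChoiceData(
        individual_id=track.individual_id,
        X=np.stack(X_rows),
        chosen=np.zeros(len(X_rows), dtype=int),
        column_names=coding.column_names,
        coding=coding,
        coords=np.stack(coords_rows),
        set_ids=set_ids,
    )


def simulate_choice_data(
    beta: np.ndarray,
    n_sets: int,
    n_alternatives: int = 6,
    seed: int | np.random.Generator = 0,
    individual_id: str = "sim",
    column_names: list[str] | None = None,
    covariate_corr: np.ndarray | None = None,
) -> ChoiceData:
    """Choice data drawn directly from the conditional-logit model.

    Covariates are standard normal per alternative (optionally mixed to a
    target correlation matrix across columns); the chosen alternative is
    drawn with the softmax probabilities implied by ``beta``.  This is the
    generative twin of the likelihood, used for parameter-recovery and
    calibration experiments that do not need a spatial landscape.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    k = beta.size
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_sets, n_alternatives, k))
    if covariate_corr is not None:
        L = np.linalg.cholesky(np.asarray(covariate_corr, float) + 1e-12 * np.eye(k))
        X = X @ L.T
    u = X @ beta
    u -= u.max(axis=1, keepdims=True)
    p = np.exp(u)
    p /= p.sum(axis=1, keepdims=True)
    chosen = (rng.uniform(size=(n_sets, 1)) > np.cumsum(p, axis=1)).sum(axis=1)
    names = column_names or [f"x{i + 1}" for i in range(k)]
    return ChoiceData(
        individual_id=individual_id,
        X=X,
        chosen=chosen.astype(int),
        column_names=names,
        coding=DesignCoding(continuous=tuple(names)),
    )


# ---------------------------------------------------------------------------
# Long-format CSV round trip
# ---------------------------------------------------------------------------

def choice_data_to_frame(data: ChoiceData) -> pd.DataFrame:
    n, C, k = data.X.shape
    ids = data.set_ids or [str(i) for i in range(n)]
    df = pd.DataFrame(
        data.X.reshape(n * C, k), columns=data.column_names
    )
    df.insert(0, "chosen", (np.arange(C)[None, :] == data.chosen[:, None]).astype(int).ravel())
    df.insert(0, "alt_id", np.tile(np.arange(C), n))
    df.insert(0, "set_id", np.repeat(ids, C))
    df.insert(0, "individual_id", data.individual_id)
    if data.coords is not None:
        df["x"] = data.coords[:, :, 0].ravel()
        df["y"] = data.coords[:, :, 1].ravel()
    return df


def write_choice_csv(data: ChoiceData, path: str | Path, coding_path: str | Path | None = None) -> None:
    choice_data_to_frame(data).to_csv(path, index=False)
    if coding_path is not None and data.coding is not None:
        data.coding.to_json(coding_path)


def read_choice_csv(path: str | Path, coding_path: str | Path | None = None) -> ChoiceData:
    df = pd.read_csv(path, dtype={"set_id": str})
    coding = DesignCoding.from_json(coding_path) if coding_path else None
    meta = ["individual_id", "set_id", "alt_id", "chosen", "x", "y"]
    columns = [c for c in df.columns if c not in meta]
    groups = list(df.groupby("set_id", sort=False))
    C = len(groups[0][1])
    if any(len(g) != C for _, g in groups):
        raise SchemaError("choice sets differ in number of alternatives")
    X = np.stack([g[columns].to_numpy(dtype=float) for _, g in groups])
    chosen = np.array([int(np.argmax(g["chosen"].to_numpy())) for _, g in groups])
    coords = None
    if "x" in df.columns and "y" in df.columns:
        coords = np.stack([g[["x", "y"]].to_numpy(dtype=float) for _, g in groups])
    return ChoiceData(
        individual_id=str(df["individual_id"].iloc[0]),
        X=X,
        chosen=chosen,
        column_names=columns,
        coding=coding,
        coords=coords,
        set_ids=[sid for sid, _ in groups],
    )
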