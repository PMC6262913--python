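"""GPS telemetry tracks and the discrete-choice movement simulator.

The simulator is the generative twin of the model the pipeline fits: at
each fix it samples candidate destinations uniformly within a disc around
the current location, scores them with the linear utility of their cell
covariates, and steps to one of them with conditional-logit (softmax)
probabilities.  Fixes advance on a regular schedule (5 h by default, the
usual collar programming for large ungulates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignCoding, extract_design
from .errors import InvalidConfigError, InvalidInputError, SimulationStuckError
from .landscape import CovariateGrids

DEFAULT_START_TIME = np.datetime64("2011-06-01T00:00:00")


@dataclass
class TelemetryTrack:
    """Ordered GPS fixes for one individual."""

    individual_id: str
    times: np.ndarray  # datetime64[s], strictly increasing
    xy: np.ndarray     # (n, 2) planar meters

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.times) != len(self.xy):
            raise InvalidInputError("times and coordinates disagree in length")
        if len(self.times) < 1:
            raise InvalidInputError("a track needs at least one fix")
        if np.any(np.diff(self.times.astype("int64")) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")

    @property
    def n_fixes(self) -> int:
        return len(self.times)

    def elapsed_hours(self) -> np.ndarray:
        """Hours between consecutive fixes."""
        return np.diff(self.times.astype("int64")) / 3600.0

    def step_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.xy, axis=0).T)


@dataclass
class PopulationDistribution:
    """Normal population distribution of selection coefficients.

    Individual coefficients for covariate k are drawn Normal(mu[k],
    sigma[k]^2), the random-slopes heterogeneity model.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape:
            raise InvalidConfigError("mu and sigma must have equal length")
        if np.any(self.sigma < 0):
            raise InvalidConfigError("sigma must be non-negative")

    @property
    def n_coefficients(self) -> int:
        return len(self.mu)


def draw_individual_coefficients(
    pop: PopulationDistribution, n_individuals: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw (n_individuals, k) coefficient vectors from the population."""
    if n_individuals < 1:
        raise InvalidConfigError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(pop.mu, pop.sigma, size=(n_individuals, pop.n_coefficients))


@dataclass
class MovementConfig:
    """Step-generation settings for the simulator."""

    step_radius: float = 1000.0   # m; disc of reachable destinations per fix interval
    n_candidates: int = 30        # sampled alternatives scored per step
    fix_interval_hours: float = 5.0

    def validate(self):
        if self.step_radius <= 0:
            raise InvalidConfigError("step_radius must be positive")
        if self.n_candidates < 2:
            raise InvalidConfigError("n_candidates must be >= 2")
        if self.fix_interval_hours <= 0:
            raise InvalidConfigError("fix_interval_hours must be positive")


def _sample_disc(rng: np.random.Generator, center: np.ndarray, radius: float, n: int) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return center + np.column_stack([r * np.cos(th), r * np.sin(th)])


def sample_candidates(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    n: int,
    grids: CovariateGrids,
    max_rounds: int = 200,
) -> np.ndarray:
    """Uniform points on the disc around ``center`` clipped to the grid extent.

    Rejection sampling: out-of-extent draws are discarded and redrawn, which
    leaves the accepted points uniform on the disc-extent intersection.
    """
    out = np.empty((0, 2))
    for _ in range(max_rounds):
        pts = _sample_disc(rng, center, radius, max(n, 8))
        keep = grids.in_extent(pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
        if len(out) >= n:
            return out[:n]
    raise SimulationStuckError(
        f"could not place {n} candidates inside the extent around {center} (radius {radius} m)"
    )


def simulate_track(
    grids: CovariateGrids,
    beta: np.ndarray,
    movement: MovementConfig,
    n_fixes: int,
    start: tuple[float, float],
    seed: int | np.random.Generator,
    individual_id: str = "sim",
    coding: DesignCoding | None = None,
    start_time: np.datetime64 = DEFAULT_START_TIME,
) -> TelemetryTrack:
    """Simulate a GPS track from the discrete-choice selection model.

    Each step scores ``movement.n_candidates`` uniformly sampled reachable
    points by the utility beta . x of their cell covariates and moves to one
    with softmax probabilities.  ``beta`` must match ``coding.column_names``
    (all continuous layers plus reference-coded habitat by default).
    """
    movement.validate()
    if coding is None:
        coding = DesignCoding.from_grids(grids)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (coding.n_columns,):
        raise InvalidInputError(
            f"beta has length {beta.size}, design has {coding.n_columns} columns"
        )
    start = np.asarray(start, dtype=float)
    if not bool(np.all(grids.in_extent(start[0], start[1]))):
        raise InvalidInputError(f"start {tuple(start)} outside grid extent")
    if n_fixes < 2:
        raise InvalidInputError("n_fixes must be >= 2")

    rng = np.random.default_rng(seed)
    xy = np.empty((n_fixes, 2))
    xy[0] = start
    for i in range(1, n_fixes):
        try:
            cand = sample_candidates(rng, xy[i - 1], movement.step_radius, movement.n_candidates, grids)
        except SimulationStuckError as err:
            err.fix_index = i
            raise SimulationStuckError(f"stuck at fix {i}: {err}", fix_index=i) from None
        u = extract_design(cand, grids, coding) @ beta
        u -= u.max()
        p = np.exp(u)
        p /= p.sum()
        xy[i] = cand[rng.choice(len(cand), p=p)]

    step = np.timedelta64(int(round(movement.fix_interval_hours * 3600)), "s")
    times = start_time.astype("datetime64[s]") + step * np.arange(n_fixes)
    return TelemetryTrack(individual_id=individual_id, times=times, xy=xy)


# ---------------------------------------------------------------------------
# Movebank-style CSV I/O
# ---------------------------------------------------------------------------

def tracks_to_frame(tracks: list[TelemetryTrack]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "individual_id": t.individual_id,
                "timestamp": pd.to_datetime(t.times).strftime("%Y-%m-%dT%H:%M:%S"),
                "x": t.xy[:, 0],
                "y": t.xy[:, 1],
            }
        )
        for t in tracks
    ]
    return pd.concat(frames, ignore_index=True)


def write_tracks_csv(tracks: list[TelemetryTrack], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.6f")


def read_tracks_csv(path: str | Path) -> list[TelemetryTrack]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for ind, grp in df.groupby("individual_id", sort=False):
        grp = grp.sort_values("timestamp")
        out.append(
            TelemetryTrack(
                individual_id=str(ind),
                times=grp["timestamp"].to_numpy().astype("datetime64[s]"),
                xy=grp[["x", "y"]].to_numpy(),
            )
        )
    return out
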