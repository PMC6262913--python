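"""Synthetic covariate landscapes.

Real applications of discrete-choice resource selection functions read
co-registered 30 m environmental rasters (canopy cover, slope, distances to
roads, a categorical habitat layer, ...).  For testing and simulation this
module generates statistically controlled stand-ins: smoothed Gaussian
random fields with a user-specified cross-correlation structure, plus a
categorical habitat layer obtained by rank-slicing one extra latent field
into (near-)equal classes.

All layers share a planar, projected geometry: square cells of ``cell_size``
meters, row-major indexing with cell (0, 0) at the origin corner, and
point-in-cell membership by half-open intervals [x, x + cell_size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import InvalidConfigError, OutOfBoundsError

DEFAULT_HABITAT_LABELS = [
    "warm_season_grassland",
    "cool_season_grassland",
    "shrubland",
    "savannah",
    "woodland",
    "forest",
    "glade",
    "forage_opening",
]


@dataclass
class CovariateGrids:
    """A co-registered stack of continuous layers plus one categorical layer.

    Parameters
    ----------
    layers:
        Mapping from layer name to a float array of shape (n_rows, n_cols).
    habitat:
        Integer-coded array of the same shape; codes are indices into
        ``habitat_labels``.
    cell_size:
        Cell edge length in meters.
    origin:
        (x, y) of the lower-left grid corner in meters.
    """

    layers: dict[str, np.ndarray]
    habitat: np.ndarray
    habitat_labels: list[str]
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.layers.values()} | {self.habitat.shape}
        if len(shapes) != 1:
            raise InvalidConfigError(f"layers disagree on shape: {shapes}")
        if len(self.habitat_labels) < 2:
            raise InvalidConfigError("need at least 2 habitat classes")
        codes = np.unique(self.habitat)
        if codes.min() < 0 or codes.max() >= len(self.habitat_labels):
            raise InvalidConfigError("habitat codes outside label range")
        for name, arr in self.layers.items():
            if not np.all(np.isfinite(arr)):
                raise InvalidConfigError(f"layer {name!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.habitat.shape

    @property
    def n_rows(self) -> int:
        return self.habitat.shape[0]

    @property
    def n_cols(self) -> int:
        return self.habitat.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def in_extent(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each planar point.

        Raises :class:`OutOfBoundsError` if any point lies outside the extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.in_extent(x, y)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside))[:1]
            raise OutOfBoundsError(f"point(s) outside grid extent (first offender index {bad.ravel()})")
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y - y0) / self.cell_size).astype(int)
        return row, col


@dataclass
class LandscapeConfig:
    """Specification of a synthetic landscape.

    ``smoothing_range`` is the Gaussian kernel sd in cells; larger values give
    smoother, more spatially autocorrelated fields.  ``cross_correlation`` is
    the target cell-wise Pearson correlation matrix among continuous layers
    (symmetric, unit diagonal, positive semidefinite); identity when omitted.
    """

    n_rows: int = 64
    n_cols: int = 64
    cell_size: float = 30.0
    n_continuous: int = 9
    n_habitat_classes: int = 8
    smoothing_range: float = 3.0
    cross_correlation: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    layer_names: list[str] | None = None
    habitat_labels: list[str] | None = None

    def validate(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise InvalidConfigError("landscape dims must be at least 8x8")
        if self.n_habitat_classes < 2:
            raise InvalidConfigError("n_habitat_classes must be >= 2")
        if self.n_continuous < 1:
            raise InvalidConfigError("need at least one continuous layer")
        if self.cross_correlation is not None:
            c = np.asarray(self.cross_correlation, dtype=float)
            if c.shape != (self.n_continuous, self.n_continuous):
                raise InvalidConfigError("cross_correlation shape mismatch")
            if not np.allclose(c, c.T, atol=1e-10):
                raise InvalidConfigError("cross_correlation must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise InvalidConfigError("cross_correlation must have unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise InvalidConfigError("cross_correlation must be positive semidefinite")

    def to_dict(self) -> dict:
        d = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size": self.cell_size,
            "n_continuous": self.n_continuous,
            "n_habitat_classes": self.n_habitat_classes,
            "smoothing_range": self.smoothing_range,
            "origin": list(self.origin),
            "layer_names": self.layer_names,
            "habitat_labels": self.habitat_labels,
        }
        if self.cross_correlation is not None:
            d["cross_correlation"] = np.asarray(self.cross_correlation).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        d = dict(d)
        if d.get("cross_correlation") is not None:
            d["cross_correlation"] = np.asarray(d["cross_correlation"], dtype=float)
        if "origin" in d:
            d["origin"] = tuple(d["origin"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandscapeConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _smoothed_field(rng: np.random.Generator, shape: tuple[int, int], srange: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if srange > 0:
        z = ndimage.gaussian_filter(z, sigma=srange, mode="wrap")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_landscape(config: LandscapeConfig, seed: int) -> CovariateGrids:
    """Generate a seeded synthetic covariate stack.

    Continuous layers are Gaussian-kernel-smoothed white noise fields,
    standardized to mean 0 / sd 1 per layer, then mixed through the Cholesky
    factor of ``config.cross_correlation`` so that cell-wise correlations
    approximate the target.  The habitat layer rank-slices one additional
    independent latent field into ``n_habitat_classes`` classes of equal size
    (within one cell), emulating a patchy categorical mosaic.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    shape = (config.n_rows, config.n_cols)
    p = config.n_continuous

    fields = np.stack(
        [_smoothed_field(rng, shape, config.smoothing_range).ravel() for _ in range(p)]
    )
    if config.cross_correlation is not None:
        c = np.asarray(config.cross_correlation, dtype=float)
        # small jitter keeps Cholesky defined for merely semidefinite targets
        L = np.linalg.cholesky(c + 1e-10 * np.eye(p))
        fields = L @ fields
        fields -= fields.mean(axis=1, keepdims=True)
        fields /= fields.std(axis=1, keepdims=True)

    names = config.layer_names or [f"cov{i + 1}" for i in range(p)]
    if len(names) != p:
        raise InvalidConfigError("layer_names length must equal n_continuous")
    layers = {name: fields[i].reshape(shape) for i, name in enumerate(names)}

    latent = _smoothed_field(rng, shape, config.smoothing_range).ravel()
    ranks = np.argsort(np.argsort(latent, kind="stable"), kind="stable")
    habitat = (ranks * config.n_habitat_classes // latent.size).reshape(shape).astype(np.int64)

    labels = config.habitat_labels or (
        DEFAULT_HABITAT_LABELS
        if config.n_habitat_classes == 8
        else [f"class{i}" for i in range(config.n_habitat_classes)]
    )
    if len(labels) != config.n_habitat_classes:
        raise InvalidConfigError("habitat_labels length must equal n_habitat_classes")

    return CovariateGrids(
        layers=layers,
        habitat=habitat,
        habitat_labels=list(labels),
        cell_size=config.cell_size,
        origin=config.origin,
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O with a JSON sidecar manifest
# ---------------------------------------------------------------------------

def _write_ascii_grid(path: Path, values: np.ndarray, cell_size: float, origin: tuple[float, float]) -> None:
    n_rows, n_cols = values.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {origin[0]!r}\n"
        f"yllcorner {origin[1]!r}\n"
        f"cellsize {cell_size!r}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI convention: first data row is the TOP of the grid
        np.savetxt(fh, values[::-1], fmt="%.10g")


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1].copy()
    return values, hdr["cellsize"], (hdr["xllcorner"], hdr["yllcorner"])


def write_grids(grids: CovariateGrids, directory: str | Path) -> None:
    """Write each layer as an ESRI ASCII grid plus ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in grids.layers.items():
        _write_ascii_grid(directory / f"{name}.asc", arr, grids.cell_size, grids.origin)
    _write_ascii_grid(directory / "habitat.asc", grids.habitat.astype(float), grids.cell_size, grids.origin)
    manifest = {
        "continuous_layers": grids.layer_names,
        "habitat_layer": "habitat",
        "habitat_labels": grids.habitat_labels,
        "cell_size": grids.cell_size,
        "origin": list(grids.origin),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_grids(directory: str | Path) -> CovariateGrids:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    layers = {}
    for name in manifest["continuous_layers"]:
        arr, cell, origin = _read_ascii_grid(directory / f"{name}.asc")
        layers[name] = arr
    hab, cell, origin = _read_ascii_grid(directory / f"{manifest['habitat_layer']}.asc")
    return CovariateGrids(
        layers=layers,
        habitat=hab.astype(np.int64),
        habitat_labels=manifest["habitat_labels"],
        cell_size=manifest["cell_size"],
        origin=tuple(manifest["origin"]),
    )
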