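"""Categorical landscape rasters and telemetry fix tables.

The package works on a single raster convention, stated once:

* coordinates are metres, origin at the lower-left corner of the grid;
* ``y`` increases northward, so row ``i`` of :attr:`GridLandscape.class_grid`
  counts from the *bottom* of the map;
* the centre of cell ``(i, j)`` is ``origin + ((j + 0.5) * cell, (i + 0.5) * cell)``;
* all indices are 0-based.

Esri ASCII grids (which are written top row first) are flipped on read/write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Functional habitat classes, fixed by construction of the functional map.
FUNCTIONAL_LEGEND: dict[int, str] = {
    0: "non-usable",
    1: "breeding",
    2: "roosting",
    3: "foraging",
}

NODATA = -9999

FIX_COLUMNS = ["individual_id", "x_m", "y_m", "phase", "behavior", "true_x_m", "true_y_m"]


class LandscapeError(ValueError):
    """Invalid landscape construction or use."""


@dataclass
class GridLandscape:
    """A categorical raster with a legend.

    Parameters
    ----------
    class_grid
        2-D integer array of class codes; row 0 is the southernmost row.
    cell_size_m
        Cell edge length in metres (> 0).
    legend
        Mapping from every code present in the grid to a class name.
    level
        ``"functional"`` (codes 0-3, fixed legend) or ``"structural"``
        (cover typologies).
    origin_xy
        Coordinates in metres of the lower-left corner of the grid.
    """

    class_grid: np.ndarray
    cell_size_m: float
    legend: dict[int, str]
    level: str = "functional"
    origin_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.class_grid)
        if grid.ndim != 2 or grid.size == 0:
            raise LandscapeError("class_grid must be a non-empty 2-D array")
        if not np.issubdtype(grid.dtype, np.integer):
            if not np.all(np.mod(grid, 1) == 0):
                raise LandscapeError("class codes must be integers")
            grid = grid.astype(np.int16)
        self.class_grid = grid.astype(np.int16, copy=False)
        if not self.cell_size_m > 0:
            raise LandscapeError("cell_size_m must be > 0")
        if self.level not in ("functional", "structural"):
            raise LandscapeError(f"unknown level {self.level!r}")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        codes = set(np.unique(self.class_grid).tolist())
        missing = codes - set(self.legend)
        if missing:
            raise LandscapeError(f"codes {sorted(missing)} missing from legend")
        if self.level == "functional" and not set(self.legend) <= set(FUNCTIONAL_LEGEND):
            raise LandscapeError(
                "functional legend must use codes 0 (non-usable), 1 (breeding), "
                "2 (roosting), 3 (foraging)"
            )

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.class_grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.class_grid.shape[1]

    @property
    def area_ha(self) -> float:
        return self.n_rows * self.n_cols * self.cell_size_m**2 / 1e4

    @property
    def width_m(self) -> float:
        return self.n_cols * self.cell_size_m

    @property
    def height_m(self) -> float:
        return self.n_rows * self.cell_size_m

    def cell_index(self, x, y):
        """Row/col indices of the cells containing points ``(x, y)``.

        Points outside the grid raise :class:`LandscapeError`.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.floor((x - self.origin_xy[0]) / self.cell_size_m).astype(int)
        i = np.floor((y - self.origin_xy[1]) / self.cell_size_m).astype(int)
        # points exactly on the top/right edge belong to the last cell
        j = np.where((x - self.origin_xy[0]) == self.width_m, self.n_cols - 1, j)
        i = np.where((y - self.origin_xy[1]) == self.height_m, self.n_rows - 1, i)
        bad = (i < 0) | (i >= self.n_rows) | (j < 0) | (j >= self.n_cols)
        if np.any(bad):
            raise LandscapeError("point(s) outside the landscape extent")
        return i, j

    def contains_points(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.origin_xy[0])
            & (x < self.origin_xy[0] + self.width_m)
            & (y >= self.origin_xy[1])
            & (y < self.origin_xy[1] + self.height_m)
        )

    def class_at(self, x, y) -> np.ndarray:
        i, j = self.cell_index(x, y)
        return self.class_grid[i, j]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (same shape as the grid) of cell-centre x and y."""
        xs = self.origin_xy[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size_m
        ys = self.origin_xy[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)

    def fractions(self) -> dict[int, float]:
        """Realized areal fraction of every legend code (zeros included)."""
        n = self.class_grid.size
        counts = {code: 0 for code in self.legend}
        codes, cnt = np.unique(self.class_grid, return_counts=True)
        for c, k in zip(codes.tolist(), cnt.tolist()):
            counts[int(c)] = k
        return {code: counts[code] / n for code in sorted(counts)}


# -- Esri ASCII grid I/O ----------------------------------------------------

def _legend_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".legend.json")


def write_esri_ascii(landscape: GridLandscape, path: str | Path) -> Path:
    """Write a landscape as an Esri ASCII grid plus a JSON legend sidecar."""
    path = Path(path)
    header = (
        f"ncols {landscape.n_cols}\n"
        f"nrows {landscape.n_rows}\n"
        f"xllcorner {landscape.origin_xy[0]:.6f}\n"
        f"yllcorner {landscape.origin_xy[1]:.6f}\n"
        f"cellsize {landscape.cell_size_m:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.flipud(landscape.class_grid), fmt="%d")
    with open(_legend_path(path), "w") as fh:
        json.dump(
            {"level": landscape.level, "legend": {str(k): v for k, v in landscape.legend.items()}},
            fh,
            indent=2,
            sort_keys=True,
        )
    return path


def read_esri_ascii(
    path: str | Path,
    legend: Mapping[int, str] | None = None,
    level: str | None = None,
) -> GridLandscape:
    """Read an Esri ASCII grid; legend/level come from the sidecar unless given."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        grid = np.loadtxt(fh, dtype=np.int16, ndmin=2)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise LandscapeError(f"grid shape {grid.shape} does not match header in {path}")
    if legend is None or level is None:
        with open(_legend_path(path)) as fh:
            sidecar = json.load(fh)
        legend = legend or {int(k): v for k, v in sidecar["legend"].items()}
        level = level or sidecar["level"]
    return GridLandscape(
        class_grid=np.flipud(grid),
        cell_size_m=header["cellsize"],
        legend=dict(legend),
        level=level,
        origin_xy=(header["xllcorner"], header["yllcorner"]),
    )


# -- telemetry fixes --------------------------------------------------------

@dataclass
class FixSet:
    """Telemetry fixes for one or more individuals.

    Wraps a DataFrame with columns ``individual_id, x_m, y_m, phase,
    behavior, true_x_m, true_y_m``. Reported coordinates (``x_m, y_m``)
    include positional error; ``true_*`` carry the ground truth for
    synthetic fixes and are NaN for field data.
    """

    fixes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.fixes)
        missing = [c for c in FIX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"FixSet missing columns {missing}")
        df = df[FIX_COLUMNS].reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("FixSet must contain at least one fix")
        if not np.all(np.isfinite(df[["x_m", "y_m"]].to_numpy(float))):
            raise ValueError("fix coordinates must be finite")
        self.fixes = df

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(self.fixes["individual_id"]))

    def for_individual(self, individual_id: str) -> "FixSet":
        sub = self.fixes[self.fixes["individual_id"] == individual_id]
        if len(sub) == 0:
            raise KeyError(f"no fixes for individual {individual_id!r}")
        return FixSet(sub)

    def by_behavior(self, behavior: str) -> pd.DataFrame:
        return self.fixes[self.fixes["behavior"] == behavior]

    @property
    def xy(self) -> np.ndarray:
        """Reported coordinates, shape (n, 2)."""
        return self.fixes[["x_m", "y_m"]].to_numpy(float)

    @property
    def true_xy(self) -> np.ndarray:
        return self.fixes[["true_x_m", "true_y_m"]].to_numpy(float)

    @classmethod
    def concat(cls, parts: Iterable["FixSet"]) -> "FixSet":
        return cls(pd.concat([p.fixes for p in parts], ignore_index=True))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.fixes.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FixSet":
        return cls(pd.read_csv(path))
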