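"""Simulated nests and distance-to-habitat movement needs.

Daily movement need of a breeding pair is modelled as the summed straight-line
distances from the nest to the nearest roosting habitat and to the nearest
foraging habitat, computed on the functional raster with an exact Euclidean
distance transform (cell centre to nearest target cell centre). A
grid-geodesic cost distance (8-connected Dijkstra over a cost surface) is
provided for non-uniform landscapes; with uniform unit cost it matches the
Euclidean distance up to the 8-connectivity metric bound (factor
1/cos(pi/8) ~ 1.0824).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .grids import GridLandscape, LandscapeError
from .synthetic import EmptyClassError

__all__ = [
    "NestSet",
    "MovementNeeds",
    "NestPlacementError",
    "simulate_nests",
    "nearest_habitat_distance",
    "movement_needs",
    "cost_distance",
]


class NestPlacementError(RuntimeError):
    """Could not place the requested number of spaced nests."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(f"placed only {placed} of {requested} nests under the spacing constraint")


@dataclass
class NestSet:
    """Simulated nest locations inside breeding habitat with minimum spacing."""

    points: np.ndarray  # (n, 2) xy in metres
    n_requested: int
    min_dist_m: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def min_pairwise_distance(self) -> float:
        d = np.sqrt(((self.points[:, None, :] - self.points[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return float(d.min())


@dataclass
class MovementNeeds:
    """Per-nest distances to nearest roosting and foraging habitat."""

    table: pd.DataFrame = field(repr=False)  # nest_id,x_m,y_m,d_roost_m,d_forage_m,d_total_m,group
    group: str = ""

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {"n": int(len(self.table))}
        for col in ("d_roost_m", "d_forage_m", "d_total_m"):
            v = self.table[col].to_numpy(float)
            out[f"mean_{col}"] = float(v.mean())
            out[f"se_{col}"] = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def simulate_nests(
    functional: GridLandscape,
    n: int = 60,
    min_dist_m: float = 50.0,
    seed: int | None = None,
    max_attempts: int = 10000,
    rng: np.random.Generator | None = None,
) -> NestSet:
    """Uniform-random nest points in breeding cells, >= ``min_dist_m`` apart.

    Rejection sampling with a global restart when a point exhausts its attempt
    budget; deterministic under ``seed``.
    """
    if functional.level != "functional":
        raise LandscapeError("simulate_nests expects a functional landscape")
    breeding = np.argwhere(functional.class_grid == 1)
    if len(breeding) == 0:
        raise EmptyClassError("landscape has no breeding cells")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cell = functional.cell_size_m
    ox, oy = functional.origin_xy

    best_placed = 0
    for _restart in range(5):
        pts: list[tuple[float, float]] = []
        failed = False
        for _k in range(n):
            placed = False
            for _try in range(max_attempts):
                i, j = breeding[rng.integers(len(breeding))]
                x = ox + (j + rng.random()) * cell
                y = oy + (i + rng.random()) * cell
                if pts:
                    arr = np.asarray(pts)
                    if np.min((arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2) < min_dist_m**2:
                        continue
                pts.append((x, y))
                placed = True
                break
            if not placed:
                failed = True
                break
        best_placed = max(best_placed, len(pts))
        if not failed:
            return NestSet(points=np.asarray(pts), n_requested=n, min_dist_m=min_dist_m, seed=seed)
    raise NestPlacementError(best_placed, n)


def nearest_habitat_distance(functional: GridLandscape, target_class: int) -> np.ndarray:
    """Exact Euclidean distance (m) from every cell centre to the nearest
    target-class cell centre; zero on target cells."""
    mask = functional.class_grid == target_class
    if not mask.any():
        raise EmptyClassError(
            f"landscape has no cells of class "
            f"{functional.legend.get(target_class, target_class)}"
        )
    return ndimage.distance_transform_edt(~mask, sampling=functional.cell_size_m)


def movement_needs(
    nests: NestSet,
    d_roost: np.ndarray,
    d_forage: np.ndarray,
    functional: GridLandscape,
    group: str = "",
) -> MovementNeeds:
    """Look up per-nest distances (cell of the nest point) and sum them."""
    if d_roost.shape != functional.class_grid.shape or d_forage.shape != functional.class_grid.shape:
        raise ValueError("distance grids must share the landscape geometry")
    i, j = functional.cell_index(nests.points[:, 0], nests.points[:, 1])
    dr = np.asarray(d_roost)[i, j]
    df_ = np.asarray(d_forage)[i, j]
    table = pd.DataFrame(
        {
            "nest_id": np.arange(1, len(nests) + 1),
            "x_m": nests.points[:, 0],
            "y_m": nests.points[:, 1],
            "d_roost_m": dr,
            "d_forage_m": df_,
            "d_total_m": dr + df_,
            "group": group,
        }
    )
    return MovementNeeds(table=table, group=group)


def cost_distance(
    functional: GridLandscape,
    cost_per_class: dict[int, float],
    sources: np.ndarray,
) -> np.ndarray:
    """Geodesic distance over an 8-connected cost surface from source points.

    Step length is ``cell_size`` (orthogonal) or ``cell_size * sqrt(2)``
    (diagonal) weighted by the mean cost of the two cells; ``inf`` cost is a
    barrier. Returns the accumulated cost grid (``inf`` where unreachable).
    """
    costs = np.full(max(functional.legend) + 1, np.nan)
    for c, v in cost_per_class.items():
        if not (v > 0):
            raise ValueError("costs must be > 0 (use inf for barriers)")
        costs[c] = v
    cost_grid = costs[functional.class_grid]
    if np.any(np.isnan(cost_grid)):
        raise ValueError("cost_per_class must cover every class present")
    sources = np.asarray(sources, dtype=float).reshape(-1, 2)
    if len(sources) == 0:
        raise ValueError("need at least one source point")

    rows, cols = cost_grid.shape
    n = rows * cols
    cell = functional.cell_size_m
    idx = np.arange(n).reshape(rows, cols)

    def slc(d: int, size: int, head: bool) -> slice:
        # cells having a neighbour at offset d (head) / their neighbours (tail)
        if d == 0:
            return slice(0, size)
        if head:
            return slice(0, size - d) if d > 0 else slice(-d, size)
        return slice(d, size) if d > 0 else slice(0, size + d)

    def edges(di: int, dj: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = idx[slc(di, rows, True), slc(dj, cols, True)].ravel()
        b = idx[slc(di, rows, False), slc(dj, cols, False)].ravel()
        step = cell * (np.sqrt(2.0) if di and dj else 1.0)
        w = step * 0.5 * (cost_grid.ravel()[a] + cost_grid.ravel()[b])
        return a, b, w

    rows_l, cols_l, w_l = [], [], []
    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a, b, w = edges(di, dj)
        finite = np.isfinite(w)
        rows_l.append(a[finite])
        cols_l.append(b[finite])
        w_l.append(w[finite])
    a = np.concatenate(rows_l)
    b = np.concatenate(cols_l)
    w = np.concatenate(w_l)
    graph = sparse.csr_matrix((w, (a, b)), shape=(n, n))

    si, sj = functional.cell_index(sources[:, 0], sources[:, 1])
    src = np.unique(idx[si, sj])
    dist = dijkstra(graph, directed=False, indices=src, min_only=True)
    out = dist.reshape(rows, cols)
    out[~np.isfinite(cost_grid)] = np.inf  # barrier cells are not destinations
    return out
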