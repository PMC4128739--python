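"""Synthetic landscapes, telemetry fixes and abundance series with known truth.

The generator states a small world matching the study system it emulates:
two plots with near-equal fractions of usable habitat (~0.61 clumped
"natural" vs ~0.74 interspersed "managed") but contrasting configuration,
birds that nest in open shrubland, roost by day in pinewood and forage by
night mainly on roads (31 % of foraging fixes), and radio fixes with
35 m (SD) biangulation error except on-road sightings, which are GPS-accurate.

Every stochastic operation takes a seed (or an ``numpy.random.Generator``)
and is deterministic under it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import FIX_COLUMNS, FUNCTIONAL_LEGEND, FixSet, GridLandscape, LandscapeError

__all__ = [
    "LandscapeSpec",
    "InfeasibleCompositionError",
    "EmptyClassError",
    "generate_functional_landscape",
    "attach_structural_layer",
    "simulate_individual_fixes",
    "simulate_plot_fixes",
    "generate_abundance_series",
    "natural_spec",
    "managed_spec",
    "STRUCTURAL_LEGEND",
    "NATURAL_TYPOLOGY_SPLIT",
    "MANAGED_TYPOLOGY_SPLIT",
]


class InfeasibleCompositionError(LandscapeError):
    """Requested composition/patch-scale combination cannot be realized."""


class EmptyClassError(LandscapeError):
    """A habitat class required by an operation is empty in the landscape."""


# Structural cover typologies (10, as in the structural map the world emulates).
STRUCTURAL_LEGEND: dict[int, str] = {
    10: "open shrubland",
    20: "natural mature pinewood",
    21: "newly planted pinewood",
    30: "road",
    31: "sandy path",
    32: "orange grove",
    40: "pasture",
    41: "marsh",
    42: "bare sand",
    43: "built-up",
}

#: typology weights within each functional class, clumped/natural plot
#: (reserve pinewood is mature; secondary foraging on sandy paths)
NATURAL_TYPOLOGY_SPLIT: dict[int, dict[int, float]] = {
    0: {40: 0.4, 41: 0.35, 42: 0.25},
    1: {10: 1.0},
    2: {20: 1.0},
    3: {30: 0.25, 31: 0.75},
}

#: typology weights within each functional class, interspersed/managed plot
#: (pinewood is plantation; secondary foraging in orange groves)
MANAGED_TYPOLOGY_SPLIT: dict[int, dict[int, float]] = {
    0: {40: 0.6, 43: 0.4},
    1: {10: 1.0},
    2: {21: 1.0},
    3: {30: 0.15, 32: 0.85},
}


@dataclass
class LandscapeSpec:
    """Recipe for one synthetic functional landscape.

    ``composition`` maps functional class code -> target areal fraction
    (must sum to 1). ``patch_scale_m`` is the characteristic patch diameter,
    either one value for all classes or a per-class mapping; the class with
    the largest target fraction becomes the background matrix and its patch
    scale is ignored.
    """

    dims: tuple[int, int]
    composition: dict[int, float]
    config: str  # "clumped" | "interspersed"
    cell_size_m: float = 10.0
    patch_scale_m: float | dict[int, float] = 600.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.dims) != 2 or min(self.dims) < 1:
            raise LandscapeError("dims must be (rows, cols) with positive entries")
        if self.config not in ("clumped", "interspersed"):
            raise LandscapeError(f"unknown config {self.config!r}")
        if not self.cell_size_m > 0:
            raise LandscapeError("cell_size_m must be > 0")
        fracs = np.array(list(self.composition.values()), dtype=float)
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise LandscapeError("composition fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise LandscapeError(f"composition must sum to 1 (got {fracs.sum():.6f})")
        if not set(self.composition) <= set(FUNCTIONAL_LEGEND):
            raise LandscapeError("composition keys must be functional codes 0-3")
        for c in self.composition:
            if self.scale_for(c) < self.cell_size_m:
                raise LandscapeError("patch_scale_m must be >= cell_size_m")

    def scale_for(self, code: int) -> float:
        if isinstance(self.patch_scale_m, Mapping):
            return float(self.patch_scale_m.get(code, max(self.patch_scale_m.values())))
        return float(self.patch_scale_m)

    @property
    def area_ha(self) -> float:
        return self.dims[0] * self.dims[1] * self.cell_size_m**2 / 1e4


def natural_spec(
    dims: tuple[int, int] = (700, 694), cell_size_m: float = 10.0, seed: int | None = None
) -> LandscapeSpec:
    """Clumped plot at the composition of the natural study area.

    Shrubland (breeding) matrix 47.5 %, usable total 60.9 %; default dims
    give ~4858 ha.
    """
    return LandscapeSpec(
        dims=dims,
        cell_size_m=cell_size_m,
        composition={0: 0.391, 1: 0.475, 2: 0.114, 3: 0.020},
        config="clumped",
        patch_scale_m=600.0,
        seed=seed,
    )


def managed_spec(
    dims: tuple[int, int] = (454, 454), cell_size_m: float = 10.0, seed: int | None = None
) -> LandscapeSpec:
    """Interspersed plot at the composition of the managed study area.

    Pinewood (roosting) matrix 54.3 %, shrubland remnants 14 %, usable total
    74.1 %; default dims give ~2061 ha. Shrubland remnants are ~450 m blocks
    (~20 ha, >= 20 per plot at full size); non-usable and foraging patches are
    ~100 m blocks.
    """
    return LandscapeSpec(
        dims=dims,
        cell_size_m=cell_size_m,
        composition={0: 0.259, 1: 0.140, 2: 0.543, 3: 0.058},
        config="interspersed",
        patch_scale_m={0: 100.0, 1: 450.0, 3: 100.0},
        seed=seed,
    )


def _largest_remainder(composition: dict[int, float], n_cells: int) -> dict[int, int]:
    codes = sorted(composition)
    raw = np.array([composition[c] * n_cells for c in codes])
    base = np.floor(raw).astype(int)
    short = n_cells - base.sum()
    order = np.argsort(-(raw - base))
    for k in range(short):
        base[order[k]] += 1
    return dict(zip(codes, base.tolist()))


def _grow_blobs(
    grid: np.ndarray, code: int, quota: int, n_blobs: int, rng: np.random.Generator
) -> None:
    """Accrete ``quota`` unassigned (-1) cells into <= ``n_blobs`` random blobs."""
    rows, cols = grid.shape
    remaining = quota
    blobs_done = 0
    extra_restarts = 0
    while remaining > 0:
        free = np.flatnonzero(grid.ravel() == -1)
        if free.size == 0:
            raise InfeasibleCompositionError(
                f"cannot fit class {code}: no unassigned cells left"
            )
        if blobs_done >= n_blobs:
            extra_restarts += 1
            if extra_restarts > 20:
                raise InfeasibleCompositionError(
                    f"cannot fit class {code}: blob growth repeatedly stranded"
                )
        target = remaining if blobs_done >= n_blobs - 1 else int(np.ceil(quota / n_blobs))
        target = min(target, remaining)
        seed_flat = int(free[rng.integers(free.size)])
        frontier = [seed_flat]
        grown = 0
        while frontier and grown < target:
            k = int(rng.integers(len(frontier)))
            frontier[k], frontier[-1] = frontier[-1], frontier[k]
            flat = frontier.pop()
            i, j = divmod(flat, cols)
            if grid[i, j] != -1:
                continue
            grid[i, j] = code
            grown += 1
            if i > 0 and grid[i - 1, j] == -1:
                frontier.append(flat - cols)
            if i < rows - 1 and grid[i + 1, j] == -1:
                frontier.append(flat + cols)
            if j > 0 and grid[i, j - 1] == -1:
                frontier.append(flat - 1)
            if j < cols - 1 and grid[i, j + 1] == -1:
                frontier.append(flat + 1)
        remaining -= grown
        blobs_done += 1


def _generate_clumped(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.dims
    grid = np.full((rows, cols), -1, dtype=np.int16)
    targets = _largest_remainder(spec.composition, rows * cols)
    background = max(targets, key=lambda c: (targets[c], c))
    # largest classes first so later small blobs fit in the gaps
    order = sorted(
        (c for c in targets if c != background and targets[c] > 0),
        key=lambda c: -targets[c],
    )
    for c in order:
        patch_cells = max(1.0, (spec.scale_for(c) / spec.cell_size_m) ** 2)
        n_blobs = int(min(5, max(1, round(targets[c] / patch_cells))))
        _grow_blobs(grid, c, targets[c], n_blobs, rng)
    grid[grid == -1] = background
    return grid


def _generate_interspersed(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Square blocks at uniform-random lattice positions over a background matrix.

    Blocks of each class are snapped to a lattice of the class's own patch
    size. The non-usable class (0) samples its slots uniformly from *all*
    lattice positions and overwrites earlier classes (later-wins), which makes
    the usable/non-usable indicator exchangeable across aggregation blocks;
    usable classes painted before it are over-provisioned to compensate, and
    usable classes painted after it avoid occupied cells by rejection.
    """
    rows, cols = spec.dims
    grid = np.full((rows, cols), -1, dtype=np.int16)
    targets = _largest_remainder(spec.composition, rows * cols)
    background = max(targets, key=lambda c: (targets[c], c))
    f_nonusable = spec.composition.get(0, 0.0) if background != 0 else 0.0

    placed = [c for c in targets if c != background and targets[c] > 0]
    # big patches first; class 0 keeps its place in the size ordering
    order = sorted(placed, key=lambda c: (-spec.scale_for(c), c))

    for c in order:
        s = max(1, int(round(spec.scale_for(c) / spec.cell_size_m)))
        lat_r, lat_c = rows // s, cols // s
        if lat_r < 1 or lat_c < 1:
            raise InfeasibleCompositionError(
                f"cannot fit class {FUNCTIONAL_LEGEND[c]}: patch larger than the grid"
            )
        quota = targets[c]
        before_class0 = c != 0 and spec.scale_for(c) > spec.scale_for(0) and 0 in placed
        if before_class0:
            # class 0 will later punch uniformly through these blocks
            quota = int(round(quota / max(1e-9, 1.0 - f_nonusable)))
        n_slots = quota // (s * s)
        remainder = quota - n_slots * s * s
        want = n_slots + (1 if remainder else 0)
        if want > lat_r * lat_c:
            raise InfeasibleCompositionError(
                f"cannot fit class {FUNCTIONAL_LEGEND[c]}: "
                f"{want} blocks of {s} cells exceed the lattice"
            )
        if c == 0:
            chosen = rng.choice(lat_r * lat_c, size=want, replace=False)
        else:
            # uniform positions avoiding already-painted cells
            chosen_list: list[int] = []
            occupied = set()
            budget = 200 * want + 200
            while len(chosen_list) < want and budget > 0:
                budget -= 1
                pos = int(rng.integers(lat_r * lat_c))
                if pos in occupied:
                    continue
                bi, bj = divmod(pos, lat_c)
                window = grid[bi * s : (bi + 1) * s, bj * s : (bj + 1) * s]
                if np.any(window != -1):
                    occupied.add(pos)
                    continue
                occupied.add(pos)
                chosen_list.append(pos)
            if len(chosen_list) < want:
                raise InfeasibleCompositionError(
                    f"cannot fit class {FUNCTIONAL_LEGEND[c]}: "
                    f"placed {len(chosen_list)} of {want} blocks"
                )
            chosen = np.array(chosen_list)
        for k, pos in enumerate(np.asarray(chosen, dtype=int)):
            bi, bj = divmod(int(pos), lat_c)
            window = grid[bi * s : (bi + 1) * s, bj * s : (bj + 1) * s]
            if remainder and k == want - 1:
                flat = window.ravel()
                flat[:remainder] = c
            else:
                window[...] = c
    grid[grid == -1] = background
    return grid


def generate_functional_landscape(spec: LandscapeSpec, seed: int | None = None) -> GridLandscape:
    """Generate a functional-level landscape realizing ``spec``.

    Realized class fractions land within +/-2 percentage points of the
    targets (exactly, for the clumped generator). Deterministic under
    ``spec.seed`` (or the ``seed`` override).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.config == "clumped":
        grid = _generate_clumped(spec, rng)
    else:
        grid = _generate_interspersed(spec, rng)
    return GridLandscape(
        class_grid=grid,
        cell_size_m=spec.cell_size_m,
        legend=dict(FUNCTIONAL_LEGEND),
        level="functional",
    )


def attach_structural_layer(
    functional: GridLandscape,
    typology_split: Mapping[int, Mapping[int, float]],
    seed: int | None = None,
    legend: Mapping[int, str] | None = None,
) -> tuple[GridLandscape, dict[int, int]]:
    """Refine a functional landscape into cover typologies.

    Each cell of functional class ``c`` is assigned one of the typology codes
    in ``typology_split[c]`` with the given weights (must sum to 1 per class).
    Returns the structural landscape and the truth mapping
    ``typology code -> functional class`` for recovery tests.
    """
    if functional.level != "functional":
        raise LandscapeError("attach_structural_layer expects a functional landscape")
    rng = np.random.default_rng(seed)
    present = set(np.unique(functional.class_grid).tolist())
    truth: dict[int, int] = {}
    for c in sorted(present):
        if c not in typology_split or len(typology_split[c]) == 0:
            raise LandscapeError(f"functional class {c} has no typologies")
    for c, split in typology_split.items():
        w = np.array(list(split.values()), dtype=float)
        if abs(w.sum() - 1.0) > 1e-6:
            raise LandscapeError(f"typology weights for class {c} must sum to 1")
        for t in split:
            if t in truth:
                raise LandscapeError(f"typology {t} appears under two functional classes")
            truth[int(t)] = int(c)
    out = np.empty_like(functional.class_grid)
    for c in sorted(present):
        mask = functional.class_grid == c
        codes = np.array(sorted(typology_split[c]), dtype=np.int16)
        weights = np.array([typology_split[c][int(t)] for t in codes], dtype=float)
        cum = np.cumsum(weights) / weights.sum()
        draws = np.searchsorted(cum, rng.random(int(mask.sum())), side="right")
        out[mask] = codes[np.minimum(draws, len(codes) - 1)]
    legend = dict(legend) if legend is not None else {
        t: STRUCTURAL_LEGEND.get(t, f"typology {t}") for t in truth
    }
    structural = GridLandscape(
        class_grid=out,
        cell_size_m=functional.cell_size_m,
        legend={t: legend[t] for t in truth},
        level="structural",
        origin_xy=functional.origin_xy,
    )
    return structural, truth


# -- telemetry --------------------------------------------------------------

def _cells_of_classes(structural: GridLandscape, truth: Mapping[int, int], func_class: int):
    lut = np.full(max(truth) + 1, -1, dtype=np.int16)
    for t, c in truth.items():
        lut[t] = c
    func_grid = lut[structural.class_grid]
    return np.argwhere(func_grid == func_class)


def _point_in_cell(ij: np.ndarray, landscape: GridLandscape, rng: np.random.Generator):
    i, j = ij
    x = landscape.origin_xy[0] + (j + rng.random()) * landscape.cell_size_m
    y = landscape.origin_xy[1] + (i + rng.random()) * landscape.cell_size_m
    return x, y


def _nearby(cells: np.ndarray, center_ij: np.ndarray, radius_cells: float, at_least: int):
    """Cells within radius of center; falls back to the nearest ``at_least``."""
    d2 = ((cells - center_ij) ** 2).sum(axis=1)
    inside = cells[d2 <= radius_cells**2]
    if len(inside) >= at_least:
        return inside
    order = np.argsort(d2, kind="stable")
    return cells[order[: max(at_least, min(len(cells), at_least))]]


def simulate_individual_fixes(
    structural: GridLandscape,
    truth_mapping: Mapping[int, int],
    individual_id: str = "bird01",
    n_fixes: int = 50,
    road_forage_share: float = 0.31,
    accuracy_sd_m: float = 35.0,
    sighted_accuracy_sd_m: float = 2.0,
    home_radius_m: float = 1500.0,
    behavior_mix: tuple[float, float, float] = (0.35, 0.30, 0.35),
    nest_ecotone_q: float = 0.25,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FixSet:
    """Simulate one bird's radio fixes with known behavioural rules.

    The bird gets one nest point in a breeding cell; each daylight fix sits at
    a roost point in a roosting cell within ``home_radius_m`` of the nest;
    night foraging fixes fall on foraging cells, a fraction
    ``road_forage_share`` of them on road-typology cells. Off-road foraging
    fixes get isotropic Gaussian error with per-axis sd ``accuracy_sd_m``
    (biangulation); nest, roost and on-road locations are physically sighted
    and get ``sighted_accuracy_sd_m`` (GPS). True coordinates are retained.

    Breeders commute daily between nest and roost, so the nest cell is drawn
    from the ``nest_ecotone_q`` quantile of breeding cells closest to roosting
    habitat (1.0 = uniform over all breeding cells).
    """
    if n_fixes < 10:
        raise ValueError("n_fixes must be >= 10")
    rng = rng if rng is not None else np.random.default_rng(seed)
    breeding = _cells_of_classes(structural, truth_mapping, 1)
    roosting = _cells_of_classes(structural, truth_mapping, 2)
    foraging = _cells_of_classes(structural, truth_mapping, 3)
    for cells, name in ((breeding, "breeding"), (roosting, "roosting"), (foraging, "foraging")):
        if len(cells) == 0:
            raise EmptyClassError(f"landscape has no {name} cells")
    road_codes = {
        t for t, name in structural.legend.items() if "road" in name.lower()
    }
    forage_codes = structural.class_grid[foraging[:, 0], foraging[:, 1]]
    is_road = np.isin(forage_codes, sorted(road_codes))
    road_cells = foraging[is_road]
    offroad_cells = foraging[~is_road]
    if road_forage_share > 0 and len(road_cells) == 0:
        raise EmptyClassError("landscape has no road cells but road_forage_share > 0")
    if road_forage_share < 1 and len(offroad_cells) == 0:
        offroad_cells = road_cells

    n_nest = max(1, int(round(behavior_mix[0] * n_fixes)))
    n_roost = max(1, int(round(behavior_mix[1] * n_fixes)))
    n_forage = n_fixes - n_nest - n_roost
    if n_forage < 1:
        raise ValueError("behavior_mix leaves no foraging fixes")

    radius_cells = home_radius_m / structural.cell_size_m
    if nest_ecotone_q < 1.0:
        from scipy import ndimage  # local import keeps module load light

        lut = np.full(max(truth_mapping) + 1, -1, dtype=np.int16)
        for t, c in truth_mapping.items():
            lut[t] = c
        roost_mask = lut[structural.class_grid] == 2
        d_roost = ndimage.distance_transform_edt(~roost_mask)
        d_at_breeding = d_roost[breeding[:, 0], breeding[:, 1]]
        cutoff = np.quantile(d_at_breeding, nest_ecotone_q)
        near = breeding[d_at_breeding <= cutoff]
        nest_ij = near[rng.integers(len(near))]
    else:
        nest_ij = breeding[rng.integers(len(breeding))]
    nest_xy = _point_in_cell(nest_ij, structural, rng)

    records = []  # last column: physically sighted (GPS accuracy)
    for _ in range(n_nest):
        records.append(("day", "nest", *nest_xy, True))
    roost_pool = _nearby(roosting, nest_ij, radius_cells, at_least=min(len(roosting), 50))
    for _ in range(n_roost):
        ij = roost_pool[rng.integers(len(roost_pool))]
        records.append(("day", "roost", *_point_in_cell(ij, structural, rng), True))
    road_pool = (
        _nearby(road_cells, nest_ij, radius_cells, at_least=min(len(road_cells), 30))
        if len(road_cells)
        else road_cells
    )
    offroad_pool = _nearby(
        offroad_cells, nest_ij, radius_cells, at_least=min(len(offroad_cells), 30)
    )
    for _ in range(n_forage):
        on_road = rng.random() < road_forage_share
        pool = road_pool if on_road else offroad_pool
        ij = pool[rng.integers(len(pool))]
        records.append(("night", "forage", *_point_in_cell(ij, structural, rng), on_road))

    df = pd.DataFrame(records, columns=["phase", "behavior", "true_x_m", "true_y_m", "_sighted"])
    sd = np.where(df["_sighted"], sighted_accuracy_sd_m, accuracy_sd_m)
    noise = rng.normal(size=(len(df), 2)) * sd[:, None]
    df["x_m"] = df["true_x_m"] + noise[:, 0]
    df["y_m"] = df["true_y_m"] + noise[:, 1]
    df["individual_id"] = individual_id
    return FixSet(df[FIX_COLUMNS])


def simulate_plot_fixes(
    structural: GridLandscape,
    truth_mapping: Mapping[int, int],
    n_individuals: int,
    fixes_per_individual: tuple[int, int] = (45, 64),
    prefix: str = "bird",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> FixSet:
    """Simulate a plot's tagged sample: per-bird fix counts drawn uniformly."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    parts = []
    lo, hi = fixes_per_individual
    for k in range(n_individuals):
        n = int(rng.integers(lo, hi + 1))
        parts.append(
            simulate_individual_fixes(
                structural,
                truth_mapping,
                individual_id=f"{prefix}{k + 1:02d}",
                n_fixes=n,
                rng=rng,
                **kwargs,
            )
        )
    return FixSet.concat(parts)


def generate_abundance_series(
    n_weeks: int,
    mean_rate_a: float,
    mean_rate_b: float,
    dispersion: float = 3.0,
    seed: int | None = None,
    transect_km: float = 10.0,
) -> pd.DataFrame:
    """Paired weekly road-transect counts, standardized to birds/km.

    Counts in the two plots share a multiplicative weekly environment effect
    (Gamma with shape ``dispersion``), giving overdispersed, positively
    correlated pairs, as repeated transects of the same nights would.
    """
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    if mean_rate_a < 0 or mean_rate_b < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    w = rng.gamma(shape=dispersion, scale=1.0 / dispersion, size=n_weeks)
    count_a = rng.poisson(mean_rate_a * transect_km * w)
    count_b = rng.poisson(mean_rate_b * transect_km * w)
    return pd.DataFrame(
        {
            "week": np.arange(1, n_weeks + 1),
            "birds_per_km_a": count_a / transect_km,
            "birds_per_km_b": count_b / transect_km,
        }
    )
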