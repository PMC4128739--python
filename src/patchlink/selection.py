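"""Used-vs-available habitat selection and the functional reclassification.

Per individual and behaviour (nesting, roosting, foraging), observed fix
counts per cover typology are compared against availability (areal fraction
within the individual's home range): a chi-square goodness-of-fit test
against random habitat choice, then per-typology Agresti-Coull confidence
intervals for the proportion of locations, Bonferroni-adjusted across the
typologies tested. A typology is *selected* when its availability falls below
the lower confidence limit of its use, *avoided* when above the upper limit.

Selection tables across individuals are then pooled into the functional map:
a typology is assigned to a behaviour's class when a strict majority of the
individuals tested for that behaviour selected it; everything else is
non-usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .grids import FUNCTIONAL_LEGEND, FixSet, GridLandscape, LandscapeError
from .home_range import HomeRange

__all__ = [
    "SelectionTable",
    "FunctionalAssignment",
    "BEHAVIOR_CLASS",
    "availability_within_range",
    "count_use",
    "selection_test",
    "build_functional_map",
    "usable_fraction",
]

#: behaviour label -> functional class code it defines
BEHAVIOR_CLASS = {"nesting": 1, "roosting": 2, "foraging": 3}

#: fix behaviour annotation -> selection behaviour context
_FIX_BEHAVIOR = {"nest": "nesting", "roost": "roosting", "forage": "foraging"}


@dataclass
class SelectionTable:
    """Per-cover-type use vs availability for one individual and behaviour."""

    table: pd.DataFrame  # cover, used_count, used_prop, avail_prop, ci_low, ci_high, call
    chi_square: float
    df: int
    p_value: float
    conf: float
    behavior: str | None = None
    individual: str | None = None

    @property
    def selected(self) -> list[int]:
        return self.table.loc[self.table["call"] == "selected", "cover"].tolist()

    @property
    def avoided(self) -> list[int]:
        return self.table.loc[self.table["call"] == "avoided", "cover"].tolist()


@dataclass
class FunctionalAssignment:
    """Typology -> functional class mapping plus the per-behaviour votes."""

    mapping: dict[int, int]
    votes: pd.DataFrame = field(repr=False)  # cover x behavior vote counts
    n_tested: dict[str, int] = field(default_factory=dict)


def availability_within_range(
    landscape: GridLandscape, hr: HomeRange
) -> dict[int, float]:
    """Areal fraction of each cover type among landscape cells inside ``hr``.

    Fractions cover every legend code (zeros included) and sum to 1.
    """
    X, Y = landscape.cell_centers()
    inside = hr.contains(X, Y)
    n = int(inside.sum())
    if n == 0:
        raise LandscapeError("home range does not overlap the landscape")
    codes_in = landscape.class_grid[inside]
    avail = {code: 0.0 for code in landscape.legend}
    codes, counts = np.unique(codes_in, return_counts=True)
    for c, k in zip(codes.tolist(), counts.tolist()):
        avail[int(c)] = k / n
    return avail


def count_use(
    landscape: GridLandscape, fixes: FixSet, behavior: str | None = None
) -> dict[int, int]:
    """Fix counts per cover type from reported coordinates.

    ``behavior`` filters on the fix annotation (``nest``/``roost``/``forage``).
    Fixes reported outside the landscape extent are dropped.
    """
    df = fixes.fixes if behavior is None else fixes.by_behavior(behavior)
    x = df["x_m"].to_numpy(float)
    y = df["y_m"].to_numpy(float)
    ok = landscape.contains_points(x, y)
    used = {code: 0 for code in landscape.legend}
    if ok.any():
        codes, counts = np.unique(landscape.class_at(x[ok], y[ok]), return_counts=True)
        for c, k in zip(codes.tolist(), counts.tolist()):
            used[int(c)] = k
    return used


def _agresti_coull(x: int, n: int, z: float) -> tuple[float, float]:
    p_tilde = (x + z**2 / 2) / (n + z**2)
    hw = z * np.sqrt(p_tilde * (1 - p_tilde) / (n + z**2))
    return max(0.0, p_tilde - hw), min(1.0, p_tilde + hw)


def selection_test(
    used_counts: Mapping[int, int],
    avail_prop: Mapping[int, float],
    conf: float = 0.95,
    behavior: str | None = None,
    individual: str | None = None,
) -> SelectionTable:
    """Chi-square test of use against availability plus per-type CIs and calls.

    Categories with zero availability and zero use are dropped; categories
    used despite zero availability are called selected and excluded from the
    chi-square. The confidence level of each Agresti-Coull interval is
    Bonferroni-adjusted to ``1 - (1 - conf)/k`` for the k types with non-zero
    availability.
    """
    extra = set(used_counts) - set(avail_prop)
    if extra:
        raise ValueError(f"used categories {sorted(extra)} absent from availability")
    avail_total = float(sum(avail_prop.values()))
    if abs(avail_total - 1.0) > 1e-6:
        raise ValueError(f"availability must sum to 1 (got {avail_total:.6f})")
    covers = sorted(avail_prop)
    used = {c: int(used_counts.get(c, 0)) for c in covers}
    n_total = sum(used.values())
    if n_total < 1:
        raise ValueError("need at least one used location")

    tested = [c for c in covers if avail_prop[c] > 0]
    flagged = [c for c in covers if avail_prop[c] == 0 and used[c] > 0]
    k = len(tested)
    alpha = (1.0 - conf) / k
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))

    n_chi = sum(used[c] for c in tested)
    if n_chi > 0 and k > 1:
        obs = np.array([used[c] for c in tested], dtype=float)
        exp = n_chi * np.array([avail_prop[c] for c in tested]) / sum(
            avail_prop[c] for c in tested
        )
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        dof = k - 1
        p = float(stats.chi2.sf(chi2, dof))
    else:
        chi2, dof, p = 0.0, max(k - 1, 0), 1.0

    rows = []
    for c in covers:
        if avail_prop[c] == 0 and used[c] == 0:
            continue  # dropped
        used_prop = used[c] / n_total
        lo, hi = _agresti_coull(used[c], n_total, z)
        if c in flagged:
            call = "selected"
        elif avail_prop[c] < lo:
            call = "selected"
        elif avail_prop[c] > hi:
            call = "avoided"
        else:
            call = "neutral"
        rows.append(
            {
                "cover": c,
                "used_count": used[c],
                "used_prop": used_prop,
                "avail_prop": float(avail_prop[c]),
                "ci_low": lo,
                "ci_high": hi,
                "call": call,
            }
        )
    return SelectionTable(
        table=pd.DataFrame(rows),
        chi_square=chi2,
        df=dof,
        p_value=p,
        conf=conf,
        behavior=behavior,
        individual=individual,
    )


def selection_tables_for_individual(
    structural: GridLandscape,
    fixes: FixSet,
    hr: HomeRange,
    conf: float = 0.95,
) -> list[SelectionTable]:
    """One selection table per behaviour observed for one bird."""
    avail = availability_within_range(structural, hr)
    tables = []
    individual = fixes.individuals[0]
    for fix_behavior, context in _FIX_BEHAVIOR.items():
        used = count_use(structural, fixes, behavior=fix_behavior)
        if sum(used.values()) == 0:
            continue
        tables.append(
            selection_test(used, avail, conf=conf, behavior=context, individual=individual)
        )
    return tables


def build_functional_map(
    tables: Iterable[SelectionTable], structural: GridLandscape
) -> tuple[FunctionalAssignment, GridLandscape]:
    """Pool selection tables into the four-class functional map.

    A typology joins a behaviour's class when selected by a strict majority of
    the individuals tested for that behaviour; a typology claimed by several
    behaviours goes to the one with the highest vote share (ties and
    everything unclaimed are non-usable).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no selection tables given")
    behaviors = sorted(BEHAVIOR_CLASS)
    present = {t.behavior for t in tables}
    missing = [b for b in behaviors if b not in present]
    if missing:
        raise ValueError(f"no selection tables for behaviour(s): {', '.join(missing)}")

    covers = sorted(structural.legend)
    votes = pd.DataFrame(0, index=covers, columns=behaviors, dtype=int)
    n_tested = {b: 0 for b in behaviors}
    for b in behaviors:
        individuals = {t.individual for t in tables if t.behavior == b}
        n_tested[b] = len(individuals)
    for t in tables:
        for c in t.selected:
            if c in votes.index:
                votes.loc[c, t.behavior] += 1

    mapping: dict[int, int] = {}
    for c in covers:
        best_class, best_share = 0, 0.0
        tie = False
        for b in behaviors:
            if n_tested[b] == 0:
                continue
            share = votes.loc[c, b] / n_tested[b]
            if share <= 0.5:  # strict majority required
                continue
            if share > best_share:
                best_class, best_share, tie = BEHAVIOR_CLASS[b], share, False
            elif share == best_share:
                tie = True
        mapping[c] = 0 if tie else best_class

    lut = np.zeros(max(covers) + 1, dtype=np.int16)
    for c, f in mapping.items():
        lut[c] = f
    functional = GridLandscape(
        class_grid=lut[structural.class_grid],
        cell_size_m=structural.cell_size_m,
        legend=dict(FUNCTIONAL_LEGEND),
        level="functional",
        origin_xy=structural.origin_xy,
    )
    return FunctionalAssignment(mapping=mapping, votes=votes, n_tested=n_tested), functional


def usable_fraction(functional: GridLandscape) -> float:
    """Fraction of cells in any usable (non-zero) functional class."""
    if functional.level != "functional":
        raise LandscapeError("usable_fraction expects a functional-level landscape")
    return float(np.mean(functional.class_grid != 0))
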