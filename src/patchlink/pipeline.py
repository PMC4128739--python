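"""End-to-end two-plot experiment: configuration, orchestration, report.

`run_experiment` composes the full analysis chain on synthetic data —
landscape generation -> telemetry -> kernel home ranges -> habitat selection
and functional reclassification -> Moran's I -> nest simulation and movement
needs -> cross-plot statistics — and returns a JSON-serializable report.
Everything is deterministic under the root seed (stage seeds are spawned from
it), so two runs of the same config produce byte-identical report JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import FixSet, GridLandscape, write_esri_ascii
from .home_range import estimate_ud, volume_contour
from .moran import aggregate_to_blocks, global_morans_i
from .movement import movement_needs, nearest_habitat_distance, simulate_nests
from .selection import (
    build_functional_map,
    selection_tables_for_individual,
    usable_fraction,
)
from .stats import (
    chisq_2x2,
    compare_correlations,
    poisson_rate_comparison,
    wilcoxon_signed_rank,
)
from .synthetic import (
    MANAGED_TYPOLOGY_SPLIT,
    NATURAL_TYPOLOGY_SPLIT,
    LandscapeSpec,
    attach_structural_layer,
    generate_abundance_series,
    generate_functional_landscape,
    managed_spec,
    natural_spec,
    simulate_plot_fixes,
)

__all__ = ["ExperimentConfig", "PipelineStageError", "default_config", "validate_config", "run_experiment"]

PLOTS = ("natural", "managed")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class ExperimentConfig:
    """Run configuration for the two-landscape experiment."""

    landscapes: dict[str, LandscapeSpec]
    n_individuals: dict[str, int] = field(default_factory=lambda: {"natural": 4, "managed": 6})
    fixes_per_individual: tuple[int, int] = (55, 64)
    road_forage_share: float = 0.31
    accuracy_sd_m: float = 35.0
    sighted_accuracy_sd_m: float = 2.0
    home_radius_m: float = 1500.0
    n_nests: int = 60
    min_dist_m: float = 50.0
    h_m: float = 200.0
    grid_resolution_m: float = 25.0
    isopleth: float = 0.95
    bootstrap_B: int = 10000
    block_size_m: float = 100.0
    abundance_n_weeks: int = 74
    abundance_rate: dict[str, float] = field(
        default_factory=lambda: {"natural": 1.1, "managed": 1.45}
    )
    abundance_dispersion: float = 3.0
    abundance_transect_km: float = 10.0
    seed: int = 2011

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        for k, v in self.__dict__.items():
            if k == "landscapes":
                d[k] = {
                    label: {
                        "dims": list(spec.dims),
                        "cell_size_m": spec.cell_size_m,
                        "composition": {str(c): f for c, f in spec.composition.items()},
                        "config": spec.config,
                        "patch_scale_m": (
                            {str(c): s for c, s in spec.patch_scale_m.items()}
                            if isinstance(spec.patch_scale_m, dict)
                            else spec.patch_scale_m
                        ),
                    }
                    for label, spec in v.items()
                }
            elif isinstance(v, tuple):
                d[k] = list(v)
            else:
                d[k] = v
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(seed: int = 2011, scale: float = 1.0) -> ExperimentConfig:
    """The experiment at its stated defaults.

    ``scale`` < 1 shrinks the plot edge lengths proportionally (for fast
    smoke runs); composition and patch scales are untouched.
    """
    nat_dims = (max(40, int(round(700 * scale))), max(40, int(round(694 * scale))))
    mng_dims = (max(40, int(round(454 * scale))), max(40, int(round(454 * scale))))
    return ExperimentConfig(
        landscapes={
            "natural": natural_spec(dims=nat_dims),
            "managed": managed_spec(dims=mng_dims),
        },
        seed=seed,
    )


def _spec_errors(label: str, raw: dict) -> tuple[LandscapeSpec | None, list[str]]:
    errors = []
    try:
        comp = {int(k): float(v) for k, v in raw.get("composition", {}).items()}
        patch = raw.get("patch_scale_m", 600.0)
        if isinstance(patch, dict):
            patch = {int(k): float(v) for k, v in patch.items()}
        spec = LandscapeSpec(
            dims=tuple(raw["dims"]),
            cell_size_m=float(raw.get("cell_size_m", 10.0)),
            composition=comp,
            config=raw["config"],
            patch_scale_m=patch,
        )
        return spec, errors
    except KeyError as e:
        errors.append(f"landscapes.{label}: missing field {e}")
    except Exception as e:
        errors.append(f"landscapes.{label}: {e}")
    return None, errors


def validate_config(path: str | Path) -> tuple[ExperimentConfig | None, list[str]]:
    """Parse and validate a YAML config; returns (config, []) or (None, errors)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as e:
        return None, [f"unreadable config: {e}"]
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]
    errors: list[str] = []
    landscapes: dict[str, LandscapeSpec] = {}
    for label in PLOTS:
        if label not in raw.get("landscapes", {}):
            errors.append(f"landscapes.{label}: missing")
            continue
        spec, errs = _spec_errors(label, raw["landscapes"][label])
        errors.extend(errs)
        if spec is not None:
            landscapes[label] = spec
    kwargs: dict[str, Any] = {}
    scalar_fields = {
        "road_forage_share": (0.0, 1.0),
        "accuracy_sd_m": (0.0, None),
        "sighted_accuracy_sd_m": (0.0, None),
        "home_radius_m": (1e-9, None),
        "n_nests": (1, None),
        "min_dist_m": (0.0, None),
        "h_m": (1e-9, None),
        "grid_resolution_m": (1e-9, None),
        "isopleth": (1e-9, 1.0 - 1e-9),
        "bootstrap_B": (1, None),
        "block_size_m": (1e-9, None),
        "abundance_n_weeks": (1, None),
        "abundance_dispersion": (1e-9, None),
        "abundance_transect_km": (1e-9, None),
        "seed": (None, None),
    }
    for name, (lo, hi) in scalar_fields.items():
        if name not in raw:
            continue
        v = raw[name]
        if lo is not None and v < lo:
            errors.append(f"{name}: must be >= {lo} (got {v})")
        elif hi is not None and v > hi:
            errors.append(f"{name}: must be <= {hi} (got {v})")
        else:
            kwargs[name] = type(ExperimentConfig.__dataclass_fields__[name].default)(v) \
                if name != "seed" else int(v)
    if "n_individuals" in raw:
        kwargs["n_individuals"] = {k: int(v) for k, v in raw["n_individuals"].items()}
    if "fixes_per_individual" in raw:
        lo, hi = raw["fixes_per_individual"]
        if not (10 <= lo <= hi):
            errors.append(f"fixes_per_individual: need 10 <= lo <= hi (got {lo}, {hi})")
        else:
            kwargs["fixes_per_individual"] = (int(lo), int(hi))
    if "abundance_rate" in raw:
        rates = {k: float(v) for k, v in raw["abundance_rate"].items()}
        if any(v < 0 for v in rates.values()):
            errors.append("abundance_rate: rates must be >= 0")
        else:
            kwargs["abundance_rate"] = rates
    if errors:
        return None, errors
    return ExperimentConfig(landscapes=landscapes, **kwargs), []


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


_TYPOLOGY_SPLITS = {"natural": NATURAL_TYPOLOGY_SPLIT, "managed": MANAGED_TYPOLOGY_SPLIT}


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> dict:
    """Run the full two-plot experiment; returns the report as a plain dict.

    With ``outdir``, also writes report.json plus .asc/CSV artifacts.
    """
    root = np.random.SeedSequence(config.seed)
    # fixed spawn order keeps every stage reproducible
    seeds = {name: s for name, s in zip(
        [f"{p}_{st}" for p in PLOTS for st in
         ("landscape", "structural", "fixes", "nests")] + ["abundance", "bootstrap"],
        root.spawn(len(PLOTS) * 4 + 2),
    )}

    report: dict[str, Any] = {
        "provenance": {
            "package": "patchlink",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
            "config": config.to_dict(),
        },
        "plots": {},
        "comparisons": {},
    }
    artifacts: dict[str, Any] = {}
    per_plot: dict[str, dict[str, Any]] = {}

    for label in PLOTS:
        plot: dict[str, Any] = {}
        state: dict[str, Any] = {}
        spec = config.landscapes[label]

        with _stage(f"{label}.synthetic_data"):
            rng_land = np.random.default_rng(seeds[f"{label}_landscape"])
            functional_true = generate_functional_landscape(
                spec, seed=rng_land.integers(2**31)
            )
            structural, truth = attach_structural_layer(
                functional_true,
                _TYPOLOGY_SPLITS[label],
                seed=int(np.random.default_rng(seeds[f"{label}_structural"]).integers(2**31)),
            )
            n_ind = config.n_individuals.get(label, 0)
            fixes = None
            if n_ind > 0:
                fixes = simulate_plot_fixes(
                    structural,
                    truth,
                    n_individuals=n_ind,
                    fixes_per_individual=config.fixes_per_individual,
                    prefix=f"{label[:3]}",
                    rng=np.random.default_rng(seeds[f"{label}_fixes"]),
                    road_forage_share=config.road_forage_share,
                    accuracy_sd_m=config.accuracy_sd_m,
                    sighted_accuracy_sd_m=config.sighted_accuracy_sd_m,
                    home_radius_m=config.home_radius_m,
                )
            plot["landscape"] = {
                "area_ha": functional_true.area_ha,
                "config": spec.config,
                "realized_composition": {
                    str(k): v for k, v in functional_true.fractions().items()
                },
            }
            plot["usable_fraction_true"] = usable_fraction(functional_true)

        with _stage(f"{label}.home_range"):
            home_ranges = {}
            hr_rows = []
            if fixes is not None:
                for ind in fixes.individuals:
                    f_ind = fixes.for_individual(ind)
                    ud = estimate_ud(
                        f_ind, h_m=config.h_m, grid_resolution_m=config.grid_resolution_m
                    )
                    hr = volume_contour(ud, isopleth_level=config.isopleth)
                    home_ranges[ind] = hr
                    hr_rows.append(
                        {"individual": ind, "n_fixes": len(f_ind), "area_ha": hr.area_ha}
                    )
            plot["home_ranges"] = hr_rows

        with _stage(f"{label}.habitat_selection"):
            tables = []
            for ind, hr in home_ranges.items():
                tables.extend(
                    selection_tables_for_individual(
                        structural, fixes.for_individual(ind), hr
                    )
                )
            assignment, functional_rec = build_functional_map(tables, structural)
            plot["functional_assignment"] = {
                str(k): v for k, v in sorted(assignment.mapping.items())
            }
            plot["assignment_matches_truth"] = assignment.mapping == {
                t: (c if c in (1, 2, 3) else 0) for t, c in truth.items()
            }
            plot["usable_fraction_recovered"] = usable_fraction(functional_rec)
            plot["n_selection_tables"] = len(tables)

        with _stage(f"{label}.spatial_config"):
            blocks = aggregate_to_blocks(functional_rec, block_size_m=config.block_size_m)
            mi = global_morans_i(blocks, weights="rook", null="randomization")
            plot["morans_i"] = mi.to_dict()
            state["blocks"] = blocks

        with _stage(f"{label}.movement_model"):
            nests = simulate_nests(
                functional_rec,
                n=config.n_nests,
                min_dist_m=config.min_dist_m,
                rng=np.random.default_rng(seeds[f"{label}_nests"]),
            )
            d_roost = nearest_habitat_distance(functional_rec, 2)
            d_forage = nearest_habitat_distance(functional_rec, 3)
            needs = movement_needs(nests, d_roost, d_forage, functional_rec, group=label)
            plot["movement"] = needs.summary()

        per_plot[label] = {
            "needs": needs,
            "functional_true": functional_true,
            "functional_rec": functional_rec,
            "structural": structural,
            "fixes": fixes,
            "tables": tables,
            "blocks": state["blocks"],
        }
        report["plots"][label] = plot
        artifacts[label] = per_plot[label]

    with _stage("inference_stats"):
        comp: dict[str, Any] = {}
        # composition contrast: usable vs non-usable 100-m blocks per plot
        usable_blocks = {
            label: (per_plot[label]["blocks"] >= 0.5).sum() for label in PLOTS
        }
        total_blocks = {label: per_plot[label]["blocks"].size for label in PLOTS}
        table = [
            [int(usable_blocks[l]), int(total_blocks[l] - usable_blocks[l])] for l in PLOTS
        ]
        stat, dof, p = chisq_2x2(table)
        comp["usable_fraction_chi2"] = {
            "table": table, "chi_square": stat, "df": dof, "p_value": p,
            "unit": "100-m blocks, usable-majority",
        }

        nat = per_plot["natural"]["needs"].table
        mng = per_plot["managed"]["needs"].table
        rc = poisson_rate_comparison(mng["d_total_m"], nat["d_total_m"])
        comp["d_total_rate_comparison"] = {
            "group_a": "managed", "group_b": "natural", **rc.to_dict()
        }

        cc = compare_correlations(
            mng["d_roost_m"], mng["d_forage_m"],
            nat["d_roost_m"], nat["d_forage_m"],
            n_boot=config.bootstrap_B,
            seed=int(np.random.default_rng(seeds["bootstrap"]).integers(2**31)),
        )
        comp["correlation_comparison"] = {
            "group1": "managed", "group2": "natural", **cc.to_dict()
        }

        ab = generate_abundance_series(
            n_weeks=config.abundance_n_weeks,
            mean_rate_a=config.abundance_rate["managed"],
            mean_rate_b=config.abundance_rate["natural"],
            dispersion=config.abundance_dispersion,
            seed=int(np.random.default_rng(seeds["abundance"]).integers(2**31)),
            transect_km=config.abundance_transect_km,
        )
        wr = wilcoxon_signed_rank(ab["birds_per_km_a"], ab["birds_per_km_b"])
        comp["abundance_wilcoxon"] = {
            "group_a": "managed", "group_b": "natural",
            "mean_a": float(ab["birds_per_km_a"].mean()),
            "mean_b": float(ab["birds_per_km_b"].mean()),
            **wr.to_dict(),
        }
        report["comparisons"] = comp
        artifacts["abundance"] = ab

    if outdir is not None:
        _write_artifacts(Path(outdir), report, artifacts)
    return report


def _selection_frame(tables) -> pd.DataFrame:
    rows = []
    for t in tables:
        df = t.table.copy()
        df.insert(0, "individual", t.individual)
        df.insert(1, "behavior", t.behavior)
        df["chi_square"] = t.chi_square
        df["model_p_value"] = t.p_value
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _write_artifacts(outdir: Path, report: dict, artifacts: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    for label in PLOTS:
        art = artifacts[label]
        write_esri_ascii(art["functional_true"], outdir / f"{label}_functional_true.asc")
        write_esri_ascii(art["functional_rec"], outdir / f"{label}_functional_recovered.asc")
        write_esri_ascii(art["structural"], outdir / f"{label}_structural.asc")
        if art["fixes"] is not None:
            art["fixes"].to_csv(outdir / f"{label}_fixes.csv")
        _selection_frame(art["tables"]).to_csv(outdir / f"{label}_selection.csv", index=False)
        art["needs"].to_csv(outdir / f"{label}_movement_needs.csv")
    artifacts["abundance"].to_csv(outdir / "abundance_series.csv", index=False)


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a run report."""
    return json.dumps(report, sort_keys=True, indent=2)
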