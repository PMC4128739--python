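"""Optional figures: movement-need histograms and the abundance series.

Requires matplotlib (not a package dependency); figures are written to
scratch/figures and are never load-bearing for any test.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from common import PLOTS, RESULTS, ROOT, require


def main():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = ROOT / "scratch" / "figures"
    outdir.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True, sharey=True)
    for ax, label in zip(axes, PLOTS):
        needs = pd.read_csv(
            require(RESULTS / "movement" / f"{label}_movement_needs.csv",
                    "analysis/05_movement_needs.py")
        )
        ax.hist(needs["d_total_m"], bins=20, color="#558b6e", edgecolor="black")
        ax.set_title(f"{label} (mean {needs['d_total_m'].mean():.0f} m)")
        ax.set_xlabel("summed nest-to-roost + nest-to-forage distance (m)")
    axes[0].set_ylabel("number of simulated nests")
    fig.tight_layout()
    fig.savefig(outdir / "movement_needs_hist.png", dpi=150)

    series = pd.read_csv(require(RESULTS / "abundance_series.csv",
                                 "analysis/06_abundance.py"))
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(series["week"], series["managed_birds_per_km"], label="managed")
    ax.plot(series["week"], series["natural_birds_per_km"], label="natural")
    ax.set_xlabel("week")
    ax.set_ylabel("birds/km")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "abundance_series.png", dpi=150)
    print(f"wrote figures to {outdir}")


if __name__ == "__main__":
    main()
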