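"""Optional figure artifacts: mass-scaling panels and Arrhenius panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .constants import BOLTZMANN_EV_PER_K
from .scaling import fit_mass_scaling
from .thermal import inverse_thermal_energy

__all__ = ["plot_mass_scaling", "plot_arrhenius_panels"]


def plot_mass_scaling(records: pd.DataFrame, path) -> None:
    """ln SMR vs ln M per site, one colour per temperature level."""
    sites = sorted(records["site"].unique())
    fig, axes = plt.subplots(1, len(sites), figsize=(4.2 * len(sites), 3.6), squeeze=False)
    for ax, site in zip(axes[0], sites):
        sub = records[records["site"] == site]
        for lev, g in sub.groupby("temp_level_c"):
            x = np.log(g["dry_mass_mg"])
            y = np.log(g["smr_j_per_day"])
            sc = ax.scatter(x, y, s=10, alpha=0.6, label=f"{lev:g} C")
            try:
                f = fit_mass_scaling(records, site=site, temp_level=lev)
                xs = np.linspace(x.min(), x.max(), 20)
                ax.plot(xs, f.intercept_ln + f.exponent_b * xs,
                        color=sc.get_facecolor()[0], lw=1,
                        label=f"b={f.exponent_b:.2f}")
            except ValueError:
                pass
        ax.set_title(site)
        ax.set_xlabel("ln M (mg)")
        ax.set_ylabel("ln SMR (J/day)")
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_arrhenius_panels(
    classed: pd.DataFrame, path, boltzmann_k: float = BOLTZMANN_EV_PER_K
) -> None:
    """ln mass-specific SMR vs 1/kT per mass class (inverted x-axis)."""
    classes = [c for c in ("small", "medium", "large") if c in set(classed["mass_class"])]
    fig, axes = plt.subplots(1, len(classes), figsize=(4.2 * len(classes), 3.6), squeeze=False)
    for ax, cls in zip(axes[0], classes):
        sub = classed[classed["mass_class"] == cls]
        for site, g in sub.groupby("site"):
            x = inverse_thermal_energy(g["temp_level_c"].to_numpy(), boltzmann_k)
            y = np.log(g["mass_specific_smr"])
            ax.scatter(x, y, s=10, alpha=0.6, label=site)
        ax.invert_xaxis()  # higher temperature to the right
        ax.set_title(cls)
        ax.set_xlabel("1/kT (1/eV)")
        ax.set_ylabel("ln SMR/M (J day$^{-1}$ mg$^{-1}$)")
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
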