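"""Figure regeneration: resistance landscape and capillary-diameter curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; figures are always written to files
import matplotlib.pyplot as plt
import numpy as np

from .geometry import terminal_capillary_diameter
from .literature import measured_capillary_band_um
from .optimize import OptimizationResult
from .parameters import SpeciesParameters

__all__ = ["diameter_figure", "resistance_figure"]

_FORMATS = ("svg", "png")


def _save(fig, out_base: str | Path) -> list[Path]:
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for fmt in _FORMATS:
        p = out_base.with_suffix(f".{fmt}")
        fig.savefig(p, format=fmt, dpi=150, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def resistance_figure(result: OptimizationResult, out_base: str | Path, title: str = "") -> list[Path]:
    """log10 total resistance versus bifurcation level, argmin marked.

    Writes SVG and PNG next to each other; returns the written paths.
    """
    table = result.landscape_table()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["N"], table["log10_R_total"], "o-", ms=3, lw=1, label=r"$\log_{10} R(N)$")
    r_star = table.loc[table["N"] == result.N_star, "log10_R_total"].iloc[0]
    ax.plot([result.N_star], [r_star], "r*", ms=14, label=f"minimum at N = {result.N_star}")
    ax.set_xlabel("bifurcation level N")
    ax.set_ylabel(r"$\log_{10}$ total resistance")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return _save(fig, out_base)


def diameter_figure(
    params: SpeciesParameters,
    out_base: str | Path,
    N_max: int = 30,
    tail: str = "exact",
) -> list[Path]:
    """Terminal-capillary diameter versus N with the measured band shaded."""
    n = np.arange(1, N_max + 1)
    d_um = np.array([terminal_capillary_diameter(params, int(k), tail=tail) for k in n]) * 1e6
    lo, hi = measured_capillary_band_um(params.species_label)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.semilogy(n, d_um, "o-", ms=3, lw=1, label=r"model $d_{ft}(N)$")
    ax.axhspan(lo, hi, color="tab:green", alpha=0.25, label=f"measured {lo:g}-{hi:g} um")
    ax.set_xlabel("bifurcation level N")
    ax.set_ylabel("terminal capillary diameter (um)")
    ax.set_title(params.species_label)
    ax.legend(frameon=False)
    return _save(fig, out_base)
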