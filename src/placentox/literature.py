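"""Published comparison constants for the audit report.

These are the values the source analysis *prints* — headline optima, totals,
morphometrics, Reynolds numbers — together with independently measured
capillary diameters.  They are transcribed once, versioned, and never
recomputed: the report module compares the package's own computations against
them and flags each as reproduced or not at the precision the value was
printed with (``atol`` is half a unit in the last printed digit).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Anchor", "LITERATURE_VERSION", "anchors_for", "measured_capillary_band_um"]

LITERATURE_VERSION = "2018.1"


@dataclass(frozen=True)
class Anchor:
    """One printed reference value with its printed-precision tolerance."""

    value: float
    atol: float
    units: str
    note: str = ""


#: Values common to both species' source analysis.
SHARED: dict[str, Anchor] = {
    "tail_coefficient": Anchor(4.85, 0.005, "", "rounded geometric tail coefficient"),
    "diffusive_prefactor": Anchor(0.00875, 0.000005, "", "rounded diffusive prefactor"),
    "C_bound_artery": Anchor(1.647, 0.0005, "mol/m^3", "reported bound O2, umbilical artery"),
    "C_bound_capillary": Anchor(4.244, 0.0005, "mol/m^3", "reported bound O2, fetal capillary"),
    "C_total_artery": Anchor(1.777, 0.0005, "mol/m^3", "reported total O2, umbilical artery"),
    "C_total_capillary": Anchor(4.374, 0.0005, "mol/m^3", "reported total O2, fetal capillary"),
    "C_diss": Anchor(0.13, 0.005, "mol/m^3", "dissolved O2 from 3 ml/l content"),
}

HUMAN: dict[str, Anchor] = {
    "N_optimum": Anchor(18, 0.5, "", "headline optimal bifurcation depth"),
    "R_total_at_optimum": Anchor(5.95e7, 0.005e7, "Pa s/m^3", "printed total resistance at N=18"),
    "log10_R_total": Anchor(7.77, 0.005, "", "printed log-resistance"),
    "L_tot": Anchor(2.34, 0.005, "m", "printed total tree length at N=18"),
    "d_ft": Anchor(300e-6, 0.5e-6, "m", "printed terminal-capillary diameter at N=18"),
    "oxygen_volume_flow": Anchor(25.13, 0.005, "ml/min", "printed optimal O2 volume flow"),
    "Re_umbilical": Anchor(0.663, 0.0005, "", "printed umbilical Reynolds number"),
    "bifurcation_prefactor": Anchor(1.82e-8, 0.005e-8, "kg/s", "printed junction-loss prefactor"),
}

MOUSE: dict[str, Anchor] = {
    "N_optimum": Anchor(22, 0.5, "", "headline optimal bifurcation depth (E17.5)"),
    "R_total_at_optimum": Anchor(3.56e10, 0.005e10, "Pa s/m^3", "printed total resistance at N=22"),
    "log10_R_total": Anchor(10.55, 0.005, "", "printed log-resistance"),
    "L_tot": Anchor(26.56e-3, 0.005e-3, "m", "printed total tree length at N=22"),
    "d_ft": Anchor(28e-6, 0.5e-6, "m", "printed terminal-capillary diameter at N=22"),
    "oxygen_volume_flow": Anchor(0.135, 0.0005, "ml/min", "printed optimal O2 volume flow (E17.5)"),
    "bifurcation_prefactor": Anchor(5.16e-7, 0.005e-7, "kg/s", "printed junction-loss prefactor"),
}

#: Printed Reynolds numbers per mouse stage.
MOUSE_REYNOLDS: dict[str, Anchor] = {
    "mouse-E13.5": Anchor(3.75, 0.005, "", "printed Reynolds number"),
    "mouse-E15.5": Anchor(3.75, 0.005, "", "printed Reynolds number"),
    "mouse-E17.5": Anchor(4.65, 0.005, "", "printed Reynolds number"),
}

#: Measured terminal-capillary diameters, micrometres.
HUMAN_CAPILLARY_BAND_UM = (30.0, 80.0)
MOUSE_CAPILLARY_BAND_UM = (10.5, 15.0)

#: Cast measurements of mouse fetal-capillary diameter (mean, s.d.), um.
MOUSE_CAST_DIAMETERS_UM: dict[str, tuple[float, float]] = {
    "E12.5": (14.07, 1.36),
    "E14.5": (14.57, 0.37),
    "E16.5": (11.77, 0.21),
    "E18.5": (10.47, 0.43),
}


def anchors_for(species_label: str) -> dict[str, Anchor]:
    """All applicable printed anchors for one preset label."""
    out = dict(SHARED)
    if species_label.startswith("mouse"):
        out.update(MOUSE)
        if species_label in MOUSE_REYNOLDS:
            out["Re_umbilical"] = MOUSE_REYNOLDS[species_label]
    else:
        out.update(HUMAN)
    return out


def measured_capillary_band_um(species_label: str) -> tuple[float, float]:
    """Measured terminal-capillary diameter band (um) for figure overlays."""
    if species_label.startswith("mouse"):
        return MOUSE_CAPILLARY_BAND_UM
    return HUMAN_CAPILLARY_BAND_UM
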