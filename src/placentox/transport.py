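"""Total oxygen-transport resistance of the feto-placental tree.

The oxygen path from umbilical artery to the placental barrier is modelled as
two resistances in series, both shared across ``alpha`` parallel cotyledons:

* a convective term that grows linearly with tree depth,

      R_conv(N) = (1/alpha) * 128 mu_b rho_b L0 (N+1) / (pi d0^4 * dC),

  where dC = |C_artery - C_capillary| is the arteriovenous oxygen-content
  difference driving uptake, and

* a diffusive term for the 2^N * beta terminal capillaries that decays
  geometrically with depth (deeper trees expose more, smaller capillaries):

      R_diff(N) = (1/alpha) * c * rho_b R'_ox T rho_ox * 2^((1-2N)/3)
                  / (beta D_ox C_capillary L0),

  with prefactor c = 0.2 / ((3 pi / 2) * tail) combining the barrier
  thickness (0.2 d_ft), the cylindrical exchange area ((3 pi/2) d_ft^2) and
  the geometric tail coefficient; c = 0.00875 with the rounded tail 4.85
  ("paper" coefficients, the default) or 0.0087556 exactly.

The sum R(N) = R_conv(N) + R_diff(N) is the quantity minimised over N by
:mod:`placentox.optimize`.  Junction (bifurcation) losses are computed but
excluded from the total by default, being orders of magnitude smaller.

The published expression mixes unit systems (a hydraulic resistance divided
by a molar concentration difference); this package evaluates it numerically
in SI with concentrations in mol/m^3 and labels results with the nominal
published unit Pa s/m^3 rather than repairing the dimensional looseness —
the audit report documents the consequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    AREA_COEFFICIENT,
    BARRIER_FRACTION,
    tail_coefficient,
    terminal_capillary_diameter,
)
from .hemodynamics import bifurcation_resistance
from .oxygen import compartment_concentrations
from .parameters import MMHG_TO_PA, SpeciesParameters

__all__ = [
    "DEFAULT_DP_TOTAL_MMHG",
    "ResistanceBreakdown",
    "TransportOptions",
    "blood_uptake",
    "diffusive_prefactor",
    "diffusive_resistance",
    "diffusive_resistance_unsubstituted",
    "oxygen_mass_current",
    "oxygen_volume_flow",
    "resistance_coefficients",
    "total_resistance",
]

#: Default whole-tree driving pressure, mmHg: the difference between the
#: largest reported output (37) and input (18) partial pressures.
DEFAULT_DP_TOTAL_MMHG = 19.0


@dataclass(frozen=True)
class TransportOptions:
    """Model conventions for evaluating the total resistance.

    concentration_source: "printed" uses the reported compartment contents
        (default, reproducing the published totals); "computed" evaluates the
        Hill curve.
    coefficients: "paper" uses the rounded diffusive prefactor 0.00875;
        "exact" evaluates 0.2 (1 - 2^(-1/3)) / (3 pi/2) in closed form.
    include_bifurcation: add junction losses to the total (off by default;
        they are negligible against the channel terms).
    kappa: multiplicative calibration factor applied to the diffusive term
        only (1.0 = uncalibrated model).
    """

    concentration_source: str = "printed"
    coefficients: str = "paper"
    include_bifurcation: bool = False
    kappa: float = 1.0

    def replace(self, **kw) -> "TransportOptions":
        return replace(self, **kw)


@dataclass(frozen=True)
class ResistanceBreakdown:
    """Resistance components at one bifurcation level (nominal Pa s/m^3)."""

    N: int
    R_conv_ox: float
    R_diff_ox: float
    R_bifur: float
    R_total: float
    log10_R_total: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "log10_R_total", math.log10(self.R_total))


def diffusive_prefactor(coefficients: str = "paper") -> float:
    """Numerical prefactor 0.2/((3 pi/2) * tail) of the diffusive term.

    "paper" evaluates it with the rounded tail coefficient 4.85 and rounds to
    the published 3-significant-figure value 0.00875; "exact" keeps the
    closed-form tail.
    """
    if coefficients == "paper":
        return 0.00875
    if coefficients == "exact":
        return BARRIER_FRACTION / (AREA_COEFFICIENT * tail_coefficient("exact"))
    raise ValueError(f"unknown coefficients mode {coefficients!r}; use 'paper' or 'exact'")


def _capillary_concentration(params: SpeciesParameters, source: str) -> float:
    return compartment_concentrations(params, source=source)[1]


def diffusive_resistance(
    params: SpeciesParameters,
    N: int,
    coefficients: str = "paper",
    concentration_source: str = "printed",
) -> float:
    """Diffusive resistance of the terminal capillaries at level N (per cotyledon set).

    c * rho_b R'_ox T rho_ox * 2^((1-2N)/3) / (beta D_ox C_capillary L0);
    strictly decreasing in N by a factor 2^(-2/3) per level.  The cotyledon
    factor 1/alpha is applied by :func:`total_resistance`, not here.
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    c_cap = _capillary_concentration(params, concentration_source)
    num = (
        diffusive_prefactor(coefficients)
        * params.rho_b
        * params.Rprime_ox
        * params.T
        * params.rho_ox
        * 2.0 ** ((1.0 - 2.0 * N) / 3.0)
    )
    den = params.beta_villi * params.D_ox * c_cap * params.L0
    if den == 0:
        raise ValueError("beta_villi, D_ox, capillary concentration and L0 must be nonzero")
    return num / den


def diffusive_resistance_unsubstituted(
    params: SpeciesParameters,
    N: int,
    tail: str = "exact",
    concentration_source: str = "printed",
) -> float:
    """Diffusive resistance in its pre-substitution form, as an oracle.

    0.2 rho_b R'_ox T rho_ox / (2^N beta D_ox C (3 pi/2) d_ft) with d_ft
    taken from the tree geometry at the same N.  With exact coefficients this
    equals :func:`diffusive_resistance` identically; with rounded ("paper")
    coefficients the two agree to ~0.1%.
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    c_cap = _capillary_concentration(params, concentration_source)
    d_ft = terminal_capillary_diameter(params, N, tail=tail)
    num = BARRIER_FRACTION * params.rho_b * params.Rprime_ox * params.T * params.rho_ox
    den = 2.0**N * params.beta_villi * params.D_ox * c_cap * AREA_COEFFICIENT * d_ft
    return num / den


def oxygen_mass_current(
    params: SpeciesParameters,
    N: int,
    dP: float,
    tail: str = "exact",
    concentration_source: str = "printed",
) -> float:
    """Oxygen current across all 2^N * beta barriers for a pressure drop dP (Pa).

    2^N beta D_ox C_capillary dP (3 pi/2) d_ft / (rho_b R'_ox T * 0.2);
    linear in dP.  Nominal published unit kg/s.
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    if dP < 0:
        raise ValueError(f"dP must be >= 0, got {dP}")
    c_cap = _capillary_concentration(params, concentration_source)
    d_ft = terminal_capillary_diameter(params, N, tail=tail)
    num = (
        2.0**N
        * params.beta_villi
        * params.D_ox
        * c_cap
        * dP
        * AREA_COEFFICIENT
        * d_ft
    )
    den = params.rho_b * params.Rprime_ox * params.T * BARRIER_FRACTION
    return num / den


def blood_uptake(Q_b: float, C_in: float, C_out: float) -> float:
    """Oxygen uptake Q_b * |C_in - C_out| carried by the blood stream, mol/s.

    The magnitude is used: the published form subtracts capillary from
    arterial content in an order that yields a negative number, which is a
    transcription-order slip (a negative uptake/resistance is unphysical).
    """
    if Q_b < 0:
        raise ValueError(f"Q_b must be >= 0, got {Q_b}")
    return Q_b * abs(C_in - C_out)


def resistance_coefficients(
    params: SpeciesParameters, options: TransportOptions | None = None
) -> tuple[float, float]:
    """Coefficients (A, C) of R(N) = A (N+1) + kappa C 2^((1-2N)/3).

    A is the convective slope per generation and C the diffusive scale, both
    already divided by the cotyledon count alpha.  kappa is *not* folded in.
    """
    opts = options or TransportOptions()
    c_art, c_cap = compartment_concentrations(params, source=opts.concentration_source)
    dC = abs(c_art - c_cap)
    if dC == 0:
        raise ValueError("arteriovenous oxygen-content difference is zero; R_conv undefined")
    alpha = params.alpha_cotyledons
    A = 128.0 * params.mu_b * params.rho_b * params.L0 / (np.pi * params.d0**4 * dC) / alpha
    C = (
        diffusive_prefactor(opts.coefficients)
        * params.rho_b
        * params.Rprime_ox
        * params.T
        * params.rho_ox
        / (params.beta_villi * params.D_ox * c_cap * params.L0)
        / alpha
    )
    return A, C


def total_resistance(
    params: SpeciesParameters, N: int, options: TransportOptions | None = None
) -> ResistanceBreakdown:
    """Total oxygen-transport resistance breakdown at bifurcation level N."""
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    opts = options or TransportOptions()
    A, C = resistance_coefficients(params, opts)
    r_conv = A * (N + 1)
    r_diff = opts.kappa * C * 2.0 ** ((1.0 - 2.0 * N) / 3.0)
    r_bifur = bifurcation_resistance(params, N)
    r_total = r_conv + r_diff + (r_bifur if opts.include_bifurcation else 0.0)
    return ResistanceBreakdown(
        N=N, R_conv_ox=r_conv, R_diff_ox=r_diff, R_bifur=r_bifur, R_total=r_total
    )


def breakdown_table(
    params: SpeciesParameters,
    N_values,
    options: TransportOptions | None = None,
) -> pd.DataFrame:
    """Resistance breakdown over a range of N as a tidy table."""
    rows = [total_resistance(params, int(n), options) for n in N_values]
    return pd.DataFrame(
        {
            "N": [b.N for b in rows],
            "R_conv_ox": [b.R_conv_ox for b in rows],
            "R_diff_ox": [b.R_diff_ox for b in rows],
            "R_bifur": [b.R_bifur for b in rows],
            "R_total": [b.R_total for b in rows],
            "log10_R_total": [b.log10_R_total for b in rows],
        }
    )


def oxygen_volume_flow(
    params: SpeciesParameters, N: int, dP_total: float | None = None
) -> float:
    """Optimal oxygen volume flow pi d0^4 dP_tot / (128 mu_b L0 (N+1)), m^3/s.

    ``dP_total`` is in Pa; when omitted, the default 19 mmHg driving pressure
    (largest reported output minus input partial pressure) is used.
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    if dP_total is None:
        dP_total = DEFAULT_DP_TOTAL_MMHG * MMHG_TO_PA
    if dP_total <= 0:
        raise ValueError(f"dP_total must be > 0, got {dP_total}")
    return np.pi * params.d0**4 * dP_total / (128.0 * params.mu_b * params.L0 * (N + 1))
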