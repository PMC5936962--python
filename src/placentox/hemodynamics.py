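"""Blood-flow quantities on the symmetric tree.

Laminar (Hagen-Poiseuille) flow in every channel: the single-channel
resistance is 128 mu L / (pi d^4).  Under Murray scaling L_k/d_k^4 grows by a
factor 2 per generation, so one channel at level k has resistance
2^k * R(0) while the 2^k parallel channels of that level combine back to
R(0) exactly — every generation contributes the same resistance, and the
series total over the tree is simply a multiple of R(0).

Two generation-count conventions coexist in the source model and both are
exposed: the tree-sum form counts N generations (``convention="eq13"``,
N * R(0)) while the total-resistance expression uses N+1
(``convention="eq19"``, the default here so downstream totals match the
optimised expression verbatim).

Bifurcation junction losses are computed from the published energy-dissipation
prefactor ``mdot0 / (758 rho_b L0 mu_b)``; they saturate quickly with N and
are small against the channel resistances, so they are reported but excluded
from totals by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import build_tree
from .parameters import SpeciesParameters

__all__ = [
    "FlowState",
    "bifurcation_prefactor",
    "bifurcation_resistance",
    "level_resistance",
    "poiseuille_resistance",
    "reynolds_number",
    "tree_convective_resistance",
    "tree_flow_table",
]

#: Dimensionless constant of the bifurcation energy-dissipation formula.
BIFURCATION_CONSTANT = 758.0


@dataclass(frozen=True)
class FlowState:
    """Flow in one channel: volumetric flow, mean velocity, Reynolds, drop."""

    Q: float  # m^3/s
    v_mean: float  # m/s
    Re: float
    dP: float  # Pa


def poiseuille_resistance(mu: float, L: float, d: float) -> float:
    """Hagen-Poiseuille resistance 128 mu L / (pi d^4) of one channel, Pa s/m^3."""
    if mu <= 0 or L <= 0 or d <= 0:
        raise ValueError("mu, L and d must all be strictly positive")
    return 128.0 * mu * L / (np.pi * d**4)


def level_resistance(params: SpeciesParameters, k: int) -> float:
    """Single-channel resistance at generation k: 2^k * R(0).

    Murray scaling gives L_k/d_k^4 = 2^k L0/d0^4, so each of the 2^k channels
    carries 2^k times the umbilical resistance; their parallel combination is
    R(0) again.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return 2.0**k * poiseuille_resistance(params.mu_b, params.L0, params.d0)


def tree_convective_resistance(
    params: SpeciesParameters, N: int, convention: str = "eq19"
) -> float:
    """Whole-tree convective blood-flow resistance, Pa s/m^3.

    Every generation contributes R(0) in series.  ``convention="eq19"``
    (default) counts N+1 generations — artery plus N bifurcation levels, the
    count used in the total oxygen-resistance expression; ``"eq13"`` counts N,
    the count of the tree-sum formula.  The two differ by exactly R(0).
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    r0 = poiseuille_resistance(params.mu_b, params.L0, params.d0)
    if convention == "eq19":
        return (N + 1) * r0
    if convention == "eq13":
        return N * r0
    raise ValueError(f"unknown convention {convention!r}; use 'eq19' or 'eq13'")


def bifurcation_prefactor(params: SpeciesParameters) -> float:
    """Saturation value mdot0 / (758 rho_b L0 mu_b) of the junction losses."""
    return params.mdot0 / (
        BIFURCATION_CONSTANT * params.rho_b * params.L0 * params.mu_b
    )


def bifurcation_resistance(params: SpeciesParameters, N: int) -> float:
    """Total junction-loss resistance of an N-level tree (published unit kg/s).

    prefactor * (1 - 2^(-2N/3)): zero for the bare artery, monotonically
    saturating toward the prefactor as N grows.
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    return bifurcation_prefactor(params) * (1.0 - 2.0 ** (-2.0 * N / 3.0))


def reynolds_number(params: SpeciesParameters, Q: float, d: float) -> float:
    """Reynolds number rho v d / mu = 4 rho Q / (pi mu d) of one channel."""
    if d <= 0:
        raise ValueError(f"d must be > 0, got {d}")
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q}")
    return 4.0 * params.rho_b * Q / (np.pi * params.mu_b * d)


def flow_state(params: SpeciesParameters, Q: float, d: float, L: float) -> FlowState:
    """Flow state of a single channel carrying volumetric flow Q."""
    v = 4.0 * Q / (np.pi * d**2)
    return FlowState(
        Q=Q,
        v_mean=v,
        Re=reynolds_number(params, Q, d),
        dP=Q * poiseuille_resistance(params.mu_b, L, d),
    )


def tree_flow_table(params: SpeciesParameters, N: int) -> pd.DataFrame:
    """Per-generation hemodynamics with total flow Q0 split equally.

    Extends the geometric edge table with per-branch flow, mean velocity,
    Reynolds number and pressure drop.  Flow is conserved: branch_count *
    Q_branch = Q0 at every generation, and under Murray scaling the pressure
    drop per generation is identical.
    """
    tree = build_tree(params, N)
    table = tree.edge_table()
    q_branch = params.Q0 / np.asarray(tree.branch_counts, dtype=float)
    d = table["diameter_m"].to_numpy()
    length = table["length_m"].to_numpy()
    table["Q_branch_m3_s"] = q_branch
    table["v_mean_m_s"] = 4.0 * q_branch / (np.pi * d**2)
    table["Re"] = 4.0 * params.rho_b * q_branch / (np.pi * params.mu_b * d)
    table["dP_Pa"] = q_branch * 128.0 * params.mu_b * length / (np.pi * d**4)
    return table
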