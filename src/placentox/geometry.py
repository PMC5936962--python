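"""Symmetric Murray-law tree geometry of the feto-placental vasculature.

The vasculature is idealised as a symmetric bifurcating tree: generation 0 is
the umbilical artery (length ``L0``, diameter ``d0``) and each channel splits
into two daughters whose diameter and length both shrink by the Murray factor
2^(-1/3), the optimum for laminar flow at a symmetric bifurcation.  After
``N`` bifurcation levels the tree ends in 2^N terminal villi, each holding a
single fetal capillary.

The terminal-capillary diameter ``d_ft`` is defined geometrically as the
length deficit between the infinite tree and the actual N-level tree,

    d_ft = sum_{k=N+1..inf} L_k = L0 * 2^(-(N+1)/3) / (1 - 2^(-1/3)),

so that ``d_ft + L_total(N)`` equals the infinite-tree length for every N.
The tail coefficient 1/(1 - 2^(-1/3)) = 4.8473... is often quoted rounded to
4.85; both conventions are available (``tail="exact"`` / ``"paper"``).

Derived exchange morphometrics: the capillary is a cylinder whose height
equals its diameter, giving an exchange area A = (3 pi / 2) d_ft^2 (lateral
surface plus both ends), and the placental barrier separating fetal from
maternal blood has thickness delta = 0.2 d_ft.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import SpeciesParameters

__all__ = [
    "MURRAY_RATIO",
    "TreeGeometry",
    "build_tree",
    "tail_coefficient",
    "terminal_capillary_diameter",
    "total_tree_length",
]

#: Daughter/parent diameter and length ratio at a symmetric bifurcation.
MURRAY_RATIO = 2.0 ** (-1.0 / 3.0)

#: Barrier thickness as a fraction of the terminal-capillary diameter.
BARRIER_FRACTION = 0.2

#: Exchange-area coefficient of a cylinder with height = diameter.
AREA_COEFFICIENT = 3.0 * np.pi / 2.0


def tail_coefficient(mode: str = "exact") -> float:
    """Geometric tail coefficient 1/(1 - 2^(-1/3)) of the length series.

    ``mode="exact"`` returns the closed-form value 4.847322...;
    ``mode="paper"`` returns the conventional 3-significant-figure rounding
    4.85 used in the published arithmetic.
    """
    if mode == "exact":
        return 1.0 / (1.0 - MURRAY_RATIO)
    if mode == "paper":
        return 4.85
    raise ValueError(f"unknown tail-coefficient mode {mode!r}; use 'exact' or 'paper'")


def total_tree_length(params: SpeciesParameters, N: int) -> float:
    """Total path length L0 + L1 + ... + LN (N+1 terms), in metres.

    Closed form of the partial geometric sum with ratio 2^(-1/3).
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    r = MURRAY_RATIO
    return params.L0 * (1.0 - r ** (N + 1)) / (1.0 - r)


def terminal_capillary_diameter(params: SpeciesParameters, N: int, tail: str = "exact") -> float:
    """Terminal fetal-capillary diameter d_ft = c * L0 * 2^(-(N+1)/3), metres.

    ``tail`` selects the exact tail coefficient c = 1/(1 - 2^(-1/3)) or the
    rounded 4.85 ("paper" mode).
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    return tail_coefficient(tail) * params.L0 * 2.0 ** (-(N + 1) / 3.0)


@dataclass(frozen=True)
class TreeGeometry:
    """Per-generation morphometrics of an N-level symmetric tree."""

    N: int
    diameters: np.ndarray  # d_k = d0 * 2^(-k/3), m, k = 0..N
    lengths: np.ndarray  # L_k = L0 * 2^(-k/3), m
    branch_counts: np.ndarray  # 2^k
    L_total: float  # sum of lengths, m
    d_ft: float  # terminal capillary diameter, m
    delta: float = field(init=False)  # placental-barrier thickness, m
    area_exchange: float = field(init=False)  # per-capillary exchange area, m^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", BARRIER_FRACTION * self.d_ft)
        object.__setattr__(self, "area_exchange", AREA_COEFFICIENT * self.d_ft**2)

    def edge_table(self) -> pd.DataFrame:
        """Per-generation edge table (generation, branch_count, diameter, length)."""
        return pd.DataFrame(
            {
                "generation": np.arange(self.N + 1),
                "branch_count": self.branch_counts,
                "diameter_m": self.diameters,
                "length_m": self.lengths,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, index=False)

    def summary(self) -> dict[str, float | int]:
        return {
            "N": self.N,
            "L_total_m": self.L_total,
            "d_ft_m": self.d_ft,
            "delta_m": self.delta,
            "area_exchange_m2": self.area_exchange,
            "terminal_branches": int(self.branch_counts[-1]),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True))


def build_tree(params: SpeciesParameters, N: int, tail: str = "exact") -> TreeGeometry:
    """Construct the N-level Murray tree for one parameter set.

    Generation 0 is the umbilical artery; generation k holds 2^k channels of
    diameter d0*2^(-k/3) and length L0*2^(-k/3).  ``tail`` controls the
    terminal-capillary diameter convention (see :func:`tail_coefficient`).
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    k = np.arange(N + 1, dtype=float)
    scale = 2.0 ** (-k / 3.0)
    # int64 holds 2^k exactly only up to k = 62; fall back to float64,
    # where powers of two remain exact, for deeper (hypothetical) trees.
    counts = 2 ** np.arange(N + 1, dtype=np.int64 if N <= 62 else np.float64)
    return TreeGeometry(
        N=N,
        diameters=params.d0 * scale,
        lengths=params.L0 * scale,
        branch_counts=counts,
        L_total=total_tree_length(params, N),
        d_ft=terminal_capillary_diameter(params, N, tail=tail),
    )
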