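"""Species/stage parameter records for the feto-placental transport model.

Every physical constant the model consumes lives in a :class:`SpeciesParameters`
record: umbilical-artery morphometry, blood rheology, oxygen diffusivity and
gas properties, the cotyledon and terminal-villus counts, and the
oxygen-chemistry constants (Hill coefficients, saturated and dissolved oxygen
content, compartment partial pressures).  Four presets ship with the package —
a third-trimester human placenta and three mouse gestational stages (E13.5,
E15.5, E17.5) — all transcribed from the published measurement compilation.

Units are SI throughout except pressures, which are stored in mmHg (the unit
the physiology literature reports) and converted explicitly at use sites via
:func:`convert_pressure`.

Two bound-oxygen concentrations (``C_bound_artery``, ``C_bound_capillary``)
are carried as literals rather than recomputed from the Hill curve: direct
Hill evaluation at the stated partial pressures does not reproduce them (see
:mod:`placentox.oxygen`), and downstream arithmetic in the source model uses
the literal values.  They remain overridable.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = [
    "MMHG_TO_PA",
    "ML_PER_MIN_TO_M3_PER_S",
    "PRESET_LABELS",
    "SpeciesParameters",
    "Violation",
    "convert_pressure",
    "load_preset",
    "validate",
]

#: 1 mmHg in pascal (conventional linear factor).
MMHG_TO_PA = 133.322

#: 1 ml/min in m^3/s.
ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0

PRESET_LABELS = ("human-T3", "mouse-E13.5", "mouse-E15.5", "mouse-E17.5")

_PRESSURE_IN_PA = {"mmHg": MMHG_TO_PA, "Pa": 1.0, "kPa": 1000.0}


class SpeciesParameters(BaseModel):
    """One species/gestational-stage parameter set, SI units (pressures mmHg).

    ``mdot0`` is the umbilical flow prefactor entering the bifurcation-
    resistance formula.  The source tables label it kg/s but its numeral
    equals the volumetric flow in m^3/s; it is stored as the printed numeral
    and used as such.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    species_label: str
    L0: float  # umbilical artery length, m
    d0: float  # umbilical artery diameter, m
    Q0: float  # umbilical blood volumetric flow, m^3/s
    mdot0: float  # printed umbilical flow prefactor (bifurcation formula)
    mu_b: float  # blood dynamic viscosity, Pa s
    rho_b: float  # blood density, kg/m^3
    D_ox: float  # oxygen diffusion coefficient, m^2/s
    T: float  # absolute temperature, K
    Rprime_ox: float  # specific gas constant of oxygen, J/(kg K)
    rho_ox: float  # oxygen density at the fetal capillary, kg/m^3
    alpha_cotyledons: int  # number of cotyledons
    beta_villi: int = 65  # terminal villi per cotyledon
    v_mean_mms: float | None = None  # measured mean umbilical velocity, mm/s
    P_input_range: tuple[float, float] | None = None  # mmHg
    P_output_range: tuple[float, float] | None = None  # mmHg
    K_Hill: float = 0.04  # Hill affinity, 1/mmHg
    n_Hill: float = 2.65  # Hill exponent
    C_max: float = 9.82  # O2 content at 100% saturation, mol/m^3
    C_diss: float = 0.13  # dissolved O2 in plasma, mol/m^3
    P_artery: float = 15.7  # umbilical-artery O2 partial pressure, mmHg
    P_capillary: float = 28.3  # fetal-capillary O2 partial pressure, mmHg
    C_bound_artery: float = 1.647  # printed bound O2, umbilical artery, mol/m^3
    C_bound_capillary: float = 4.244  # printed bound O2, fetal capillary, mol/m^3

    def with_overrides(self, **updates: Any) -> "SpeciesParameters":
        """Return a copy with the given fields replaced (revalidated)."""
        data = self.model_dump()
        data.update(updates)
        return SpeciesParameters(**data)


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate`."""

    field: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r}: {self.rule}"


_POSITIVE_FIELDS = (
    "L0",
    "d0",
    "Q0",
    "mdot0",
    "mu_b",
    "rho_b",
    "D_ox",
    "T",
    "Rprime_ox",
    "rho_ox",
    "K_Hill",
    "n_Hill",
    "C_max",
    "C_diss",
    "P_artery",
    "P_capillary",
    "C_bound_artery",
    "C_bound_capillary",
)


def validate(params: SpeciesParameters) -> list[Violation]:
    """Check all physical invariants; return violations instead of raising.

    An empty list means the record is consistent: every physical quantity is
    strictly positive and finite, the artery is longer than it is wide, the
    cotyledon/villus counts are in their admissible ranges, and pressure
    ranges (when present) are ordered.
    """
    out: list[Violation] = []
    for name in _POSITIVE_FIELDS:
        value = getattr(params, name)
        if not math.isfinite(value) or value <= 0:
            out.append(Violation(name, value, "must be strictly positive and finite"))
    if params.d0 >= params.L0:
        out.append(Violation("d0", params.d0, "umbilical diameter must be smaller than its length L0"))
    if not 1 <= params.alpha_cotyledons <= 200:
        out.append(Violation("alpha_cotyledons", params.alpha_cotyledons, "must lie in 1..200"))
    if not 1 <= params.beta_villi <= 1000:
        out.append(Violation("beta_villi", params.beta_villi, "must lie in 1..1000"))
    if params.v_mean_mms is not None and params.v_mean_mms <= 0:
        out.append(Violation("v_mean_mms", params.v_mean_mms, "must be strictly positive"))
    for name in ("P_input_range", "P_output_range"):
        rng = getattr(params, name)
        if rng is not None and not rng[0] < rng[1]:
            out.append(Violation(name, rng, "lower bound must be below upper bound"))
    return out


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between mmHg, Pa and kPa (exact linear factors)."""
    try:
        f_in = _PRESSURE_IN_PA[from_unit]
        f_out = _PRESSURE_IN_PA[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown pressure unit {exc.args[0]!r}; expected one of {sorted(_PRESSURE_IN_PA)}"
        ) from None
    return value * f_in / f_out


def _from_mapping(data: dict[str, Any], source: str) -> SpeciesParameters:
    try:
        params = SpeciesParameters(**data)
    except ValidationError as exc:
        missing = [
            ".".join(str(p) for p in err["loc"])
            for err in exc.errors()
            if err["type"] == "missing"
        ]
        if missing:
            raise ValueError(f"{source}: missing required field(s): {', '.join(missing)}") from exc
        raise ValueError(f"{source}: invalid parameter record: {exc}") from exc
    violations = validate(params)
    if violations:
        detail = "; ".join(str(v) for v in violations)
        raise ValueError(f"{source}: parameter invariants violated: {detail}")
    return params


def load_preset(label: str | Path) -> SpeciesParameters:
    """Load a shipped preset by label, or a user TOML/JSON config by path.

    Shipped labels: ``human-T3``, ``mouse-E13.5``, ``mouse-E15.5``,
    ``mouse-E17.5``.  A path must point to a TOML or JSON file whose keys
    match the :class:`SpeciesParameters` fields.  The returned record always
    passes :func:`validate` with zero violations.
    """
    if isinstance(label, str) and label in PRESET_LABELS:
        ref = resources.files("placentox.presets").joinpath(f"{label}.toml")
        data = tomllib.loads(ref.read_text())
        return _from_mapping(data, source=f"preset {label!r}")

    path = Path(label)
    if path.is_file():
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
        else:
            data = tomllib.loads(path.read_text())
        if "P_input_range" in data and data["P_input_range"] is not None:
            data["P_input_range"] = tuple(data["P_input_range"])
        if "P_output_range" in data and data["P_output_range"] is not None:
            data["P_output_range"] = tuple(data["P_output_range"])
        return _from_mapping(data, source=str(path))

    raise KeyError(
        f"unknown preset {str(label)!r}: not one of {PRESET_LABELS} and not an existing file"
    )
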