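"""Virtual-patient parameters: validation, presets and config I/O.

Every quantity in the package uses one internal unit system: pressures in
kPa, volumes in L, flows in L/s, time in s (rates such as cardiac output and
metabolic gas exchange are per minute, as labelled).  Conversion helpers for
clinical units live in :mod:`pleurasim.units`.

The default parameter set is a standard-physiology adult (FRC 2.4 L, VT
0.5 L, RR 12/min, room air); every value is overridable through
:func:`build_patient` or a YAML/JSON config file, so calibration against a
particular patient is data, not code.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "PatientParams",
    "PRESETS",
    "build_patient",
    "scale_param",
    "load_config",
    "save_config",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Unknown preset, unknown field, or invalid config file."""


class PatientParams(BaseModel):
    """All mechanical, gas-exchange and circulatory constants of the model.

    Immutable: simulation code reads, never mutates, these values.  Derive
    variants with :func:`scale_param` or ``with_updates``.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    # --- discretization / geometry -------------------------------------
    n_layers: int = 100          # horizontal layers per lung
    lung_height: float = 24.0    # apex-to-base height, cm
    hemithorax_capacity: float = 3.5   # prism volume of one hemithorax, L
    rho_f: float = 1.0           # pleural fluid density, kg/L

    # --- chest wall / mediastinum / diaphragm / abdomen ----------------
    C_med: float = 0.5           # mediastinal compliance, L/kPa
    C_rc: float = 2.0            # rib-cage compliance, L/kPa
    R_rc: float = 0.1            # rib-cage viscous resistance, kPa*s/L
    C_ab: float = 4.0            # abdominal compliance, L/kPa
    R_ab: float = 0.05           # abdominal viscous resistance, kPa*s/L
    C_di_ipsi: float = 1.5       # hemidiaphragm passive compliance, L/kPa
    C_di_contra: float = 1.5
    P_ab0: float = 0.5           # abdominal pressure at reference, kPa
    P_pl0: float = -0.5          # relaxed end-expiratory pleural pressure, kPa

    # --- airways --------------------------------------------------------
    R_tr: float = 0.05           # trachea, kPa*s/L
    R_mb_ipsi: float = 0.05      # each main bronchus, kPa*s/L
    R_mb_contra: float = 0.05
    R_small: float = 0.06        # total peripheral airway resistance per lung
    R_par: float = 0.05          # total viscous parenchyma resistance per lung
    collapse_beta: float = 2.0   # peripheral-resistance rise factor at low volume
    collapse_vfrac: float = 0.25 # volume fraction below which resistance rises

    # --- lung parenchyma ------------------------------------------------
    lung_Vmax: float = 1.8       # per-lung maximal gas volume, L
    lung_k: float = 2.1972       # exponential P-V constant, 1/kPa
    P_close: float = 0.0         # derecruitment threshold, kPa (transmural)
    P_open: float = 0.3          # recruitment threshold, kPa
    trap_frac: float = 0.02      # trapped volume fraction of a layer at init

    # --- respiratory muscles -------------------------------------------
    VT_target: float = 0.5       # target tidal volume, L
    RR: float = 12.0             # respiratory rate, 1/min
    Ti_frac: float = 0.4         # inspiratory fraction of the cycle
    mus_tau_frac: float = 0.1    # post-inspiratory release time constant, fraction of T
    rc_share: float = 0.22       # fraction of drive going to rib-cage muscles
    di_phi_span: float = 2.0     # displacement over which force-length factor falls, L
    di_phi_floor: float = 0.12   # force-length floor
    di_inversion_x: float = 0.3  # displacement beyond which contraction is paradoxical, L
    di_inversion_w: float = 0.1  # smoothing width of the inversion transition, L
    drive_max: float = 50.0      # muscle pressure amplitude bound, kPa

    # --- gases and circulation ------------------------------------------
    VD_anat: float = 0.15        # total anatomical dead space, L
    VO2: float = 0.25            # O2 uptake, L/min STPD
    VCO2: float = 0.20           # CO2 output, L/min STPD
    Hb: float = 14.0             # hemoglobin, g/dL
    P50: float = 3.55            # Hill P50, kPa
    hill_n: float = 2.7          # Hill exponent
    CO_total: float = 5.0        # cardiac output, L/min
    G_vasc: float = 1.0          # perfusion conductance scale (relative)
    P_half_vasc: float = 0.5     # pleural pressure of half vascular conductance, kPa
    w_vasc: float = 0.3          # width of the vascular suppression law, kPa
    FiO2: float = 0.21
    P_atm: float = 101.3         # barometric pressure, kPa
    P_H2O: float = 6.27          # saturated water vapour pressure at 37 C, kPa

    # --- solver ----------------------------------------------------------
    dt: float = 0.002            # fixed RK4 step, s
    washin_breaths: int = 3

    @model_validator(mode="after")
    def _check_invariants(self) -> "PatientParams":
        positive = [
            "lung_height", "hemithorax_capacity", "rho_f",
            "C_med", "C_rc", "R_rc", "C_ab", "R_ab", "C_di_ipsi", "C_di_contra",
            "R_tr", "R_mb_ipsi", "R_mb_contra", "R_small", "R_par",
            "lung_Vmax", "lung_k", "VT_target", "RR",
            "VD_anat", "VO2", "VCO2", "Hb", "P50", "hill_n", "CO_total",
            "G_vasc", "w_vasc", "P_atm", "dt", "drive_max",
            "di_phi_span", "di_inversion_w",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {self.n_layers}")
        if not self.P_open > self.P_close:
            raise ValueError(
                f"P_open ({self.P_open}) must exceed P_close ({self.P_close}): "
                "recruitment hysteresis must be a proper interval"
            )
        if not 0.0 < self.FiO2 <= 1.0:
            raise ValueError(f"FiO2 must be in (0, 1], got {self.FiO2}")
        if not 0.0 < self.Ti_frac < 1.0:
            raise ValueError(f"Ti_frac must be in (0, 1), got {self.Ti_frac}")
        if not 0.0 <= self.rc_share < 1.0:
            raise ValueError(f"rc_share must be in [0, 1), got {self.rc_share}")
        if not 0.0 <= self.trap_frac < 0.5:
            raise ValueError(f"trap_frac must be in [0, 0.5), got {self.trap_frac}")
        return self

    # ------------------------------------------------------------------
    def with_updates(self, **overrides: Any) -> "PatientParams":
        """Return a new, re-validated parameter set with fields replaced."""
        unknown = set(overrides) - set(type(self).model_fields)
        if unknown:
            raise ConfigurationError(f"unknown parameter field(s): {sorted(unknown)}")
        return type(self).model_validate({**self.model_dump(), **overrides})

    # convenience derived quantities -----------------------------------
    @property
    def T_breath(self) -> float:
        """Respiratory cycle duration, s."""
        return 60.0 / self.RR

    @property
    def Ti(self) -> float:
        """Inspiratory (active-effort) duration, s."""
        return self.Ti_frac * self.T_breath

    @property
    def layer_Vmax(self) -> float:
        """Maximal gas volume of one layer, L."""
        return self.lung_Vmax / self.n_layers

    @property
    def cross_section_area(self) -> float:
        """Hemithorax prism cross-section, L/cm."""
        return self.hemithorax_capacity / self.lung_height


#: Presets differ only in mediastinal compliance: the mediastinum is the
#: decisive structure for hemidiaphragm function under a large effusion.
PRESETS: dict[str, dict[str, float]] = {
    "default": {},
    "stiff_mediastinum": {"C_med": PatientParams().C_med / 5.0},
    "compliant_mediastinum": {"C_med": PatientParams().C_med * 5.0},
}


def build_patient(preset: str = "default",
                  overrides: Mapping[str, Any] | None = None) -> PatientParams:
    """Build a validated parameter set from a named preset plus overrides.

    Parameters
    ----------
    preset:
        One of ``default``, ``stiff_mediastinum`` (C_med / 5) or
        ``compliant_mediastinum`` (C_med x 5).
    overrides:
        Field-name -> value map applied after the preset.

    Raises
    ------
    ConfigurationError
        For an unknown preset name or unknown field.
    pydantic.ValidationError / ValueError
        When an invariant is violated (the message names the field).
    """
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    merged = dict(PRESETS[preset])
    if overrides:
        unknown = set(overrides) - set(PatientParams.model_fields)
        if unknown:
            raise ConfigurationError(f"unknown parameter field(s): {sorted(unknown)}")
        merged.update(overrides)
    return PatientParams.model_validate(merged)


_SCALABLE_EXCLUDED = {"n_layers", "washin_breaths"}


def scale_param(params: PatientParams, field: str, factor: float) -> PatientParams:
    """Return a copy of *params* with one scalar field multiplied by *factor*.

    This is the single-coefficient sweep primitive: a structure coefficient is
    first reduced below and then raised above its default to probe its effect.
    """
    if field not in PatientParams.model_fields or field in _SCALABLE_EXCLUDED:
        raise ConfigurationError(f"field {field!r} is not a scalable scalar parameter")
    if not factor > 0:
        raise ValueError(f"scale factor must be strictly positive, got {factor}")
    return params.with_updates(**{field: getattr(params, field) * factor})


# ---------------------------------------------------------------------------
# config file I/O


def load_config(path: str | Path) -> PatientParams:
    """Read a YAML or JSON patient config.  Unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} must be a mapping of field names")
    return build_patient("default", data)


def save_config(params: PatientParams, path: str | Path) -> None:
    """Write the full parameter set as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = params.model_dump()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
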