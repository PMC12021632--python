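"""Alveolar gas exchange, pulmonary perfusion and arterial blood gases.

Each lung is one well-mixed alveolar compartment (layers contribute through
their summed open-layer ventilation and end-expiratory volume).  Perfusion is
split between the lungs by a pleural-pressure-dependent vascular conductance;
flow reaching non-ventilated (collapsed) tissue is shunt.  Steady-state
alveolar and arterial gases are solved by fixed-point iteration of per-lung
O2/CO2 mass balances closed through the blood gas content curves and the Fick
principle for the venous return.

Conventions: partial pressures kPa, gas flows L/min (STPD corrections are
neglected), blood gas contents mL per dL of blood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .mechanics import CONTRA, IPSI, BreathRecording
from .patient_model import PatientParams

__all__ = [
    "GasState", "fresh_gas_ratio", "hill_saturation", "o2_content",
    "co2_content", "invert_o2_content", "invert_co2_content",
    "perfusion_split", "perfusion_split_layers", "alveolar_step",
    "steady_state_gases", "mix_arterial",
    "ventilation_from_recording", "gases_for_recording",
]

# linearized CO2 dissociation around the normal operating point
_CO2_REF_P = 5.33       # kPa (40 mmHg)
_CO2_REF_C = 48.0       # mL/dL at the reference point
_CO2_SLOPE = 3.5        # mL/dL per kPa


@dataclass
class GasState:
    """Alveolar and arterial gas state at (quasi) steady state."""

    P_AO2: np.ndarray        # (2,) alveolar O2 per lung, kPa
    P_ACO2: np.ndarray       # (2,) alveolar CO2 per lung, kPa
    FRC: np.ndarray          # (2,) end-expiratory open gas volume, L
    VD: np.ndarray           # (2,) dead space, L
    q: np.ndarray            # (2,) perfusion of ventilated tissue, L/min
    q_shunt: float           # perfusion of closed tissue, L/min
    PaO2: float              # mixed arterial O2, kPa
    PaCO2: float             # mixed arterial CO2, kPa
    PvO2: float = float("nan")
    PvCO2: float = float("nan")


def fresh_gas_ratio(VT: float, FRC: float, VD: float) -> float:
    """VT / (FRC + VD): the fresh-to-processed gas dilution ratio.

    This ratio sets how far inspired air shifts the alveolar mixture toward
    inspired composition each breath; with one lung collapsed (FRC and VD of
    the ventilated lung only) it can double, raising that lung's mean P_AO2.
    """
    for name, v in (("VT", VT), ("FRC", FRC), ("VD", VD)):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    return VT / (FRC + VD)


# ---------------------------------------------------------------------------
# blood gas transport


def hill_saturation(PO2, params: PatientParams):
    """Oxyhemoglobin saturation by the Hill curve: S = P^n / (P^n + P50^n)."""
    p = np.asarray(PO2, dtype=float)
    pn = p ** params.hill_n
    return pn / (pn + params.P50 ** params.hill_n)


def _check_pressure(P, params: PatientParams, name: str) -> None:
    if np.any(np.asarray(P) <= 0) or np.any(np.asarray(P) >= params.P_atm):
        raise ValueError(f"{name} must lie in (0, P_atm), got {P}")


def o2_content(PO2, params: PatientParams):
    """O2 content of blood, mL/dL: bound (1.34 Hb SO2) + dissolved."""
    _check_pressure(PO2, params, "PO2")
    po2_mmhg = np.asarray(PO2) / 0.133322
    return 1.34 * params.Hb * hill_saturation(PO2, params) + 0.003 * po2_mmhg


def co2_content(PCO2, params: PatientParams):
    """CO2 content of blood, mL/dL, linearized around 40 mmHg."""
    _check_pressure(PCO2, params, "PCO2")
    return _CO2_REF_C + _CO2_SLOPE * (np.asarray(PCO2) - _CO2_REF_P)


def invert_o2_content(C: float, params: PatientParams) -> float:
    """PO2 (kPa) at which blood carries content ``C`` mL/dL (bracketed root)."""
    lo, hi = 1e-6, params.P_atm - 1e-6
    c_lo, c_hi = o2_content(lo, params), o2_content(hi, params)
    if not c_lo <= C <= c_hi:
        raise ValueError(f"O2 content {C} mL/dL outside invertible range "
                         f"[{c_lo:.3f}, {c_hi:.3f}]")
    return brentq(lambda p: o2_content(p, params) - C, lo, hi, xtol=1e-9)


def invert_co2_content(C: float, params: PatientParams) -> float:
    """PCO2 (kPa) carrying content ``C`` mL/dL (linear curve, closed form)."""
    p = _CO2_REF_P + (C - _CO2_REF_C) / _CO2_SLOPE
    if not 0 < p < params.P_atm:
        raise ValueError(f"CO2 content {C} mL/dL maps outside (0, P_atm)")
    return p


# ---------------------------------------------------------------------------
# perfusion


def perfusion_split(P_pl_mean: np.ndarray, open_fraction: np.ndarray,
                    params: PatientParams):
    """Split cardiac output between lungs and shunt.

    Per-side vascular conductance falls smoothly with the local mean pleural
    pressure, g = g0 / (1 + exp((P_pl - P_half)/w)) (extramural compression
    of pulmonary vessels); the share of a side's flow feeding collapsed
    (non-ventilated) tissue counts as shunt.  The three flows sum exactly to
    cardiac output.
    """
    P_pl_mean = np.asarray(P_pl_mean, dtype=float)
    open_fraction = np.asarray(open_fraction, dtype=float)
    if np.any((open_fraction < 0) | (open_fraction > 1)):
        raise ValueError(f"open_fraction must lie in [0, 1], got {open_fraction}")
    g = params.G_vasc / (1.0 + np.exp((P_pl_mean - params.P_half_vasc) / params.w_vasc))
    if g.sum() <= 0:
        g = np.full(2, 0.5)
    q_side = params.CO_total * g / g.sum()
    q_vent = q_side * open_fraction
    q_shunt = float((q_side * (1.0 - open_fraction)).sum())
    return q_vent, q_shunt


def perfusion_split_layers(P_pl_local: np.ndarray, open_flags: np.ndarray,
                           params: PatientParams):
    """Layer-resolved perfusion split.

    Same vascular law as :func:`perfusion_split` applied per layer with its
    own local pleural pressure (submerged, compressed layers lose their flow
    to the rest of the vascular bed); the flow reaching closed layers is the
    shunt.  Flows sum exactly to cardiac output.
    """
    g = 1.0 / (1.0 + np.exp((np.asarray(P_pl_local) - params.P_half_vasc) / params.w_vasc))
    total = g.sum()
    if total <= 0:
        g = np.ones_like(g)
        total = g.sum()
    q_layer = params.CO_total * g / total
    q_vent = (q_layer * open_flags).sum(axis=1)
    q_shunt = float((q_layer * ~open_flags).sum())
    return q_vent, q_shunt


# ---------------------------------------------------------------------------
# alveolar balances


def _p_insp_o2(params: PatientParams) -> float:
    """Inspired (humidified, tracheal) O2 partial pressure, kPa."""
    return params.FiO2 * (params.P_atm - params.P_H2O)


def alveolar_step(P_AO2: np.ndarray, P_ACO2: np.ndarray, VA: np.ndarray,
                  q: np.ndarray, cv_o2: float, cv_co2: float,
                  FRC: np.ndarray, params: PatientParams, dt_min: float = 0.05):
    """Advance each lung's well-mixed alveolar compartment by ``dt_min`` minutes.

    Fresh-gas inflow at inspired partial pressures is balanced against
    perfusion-driven uptake/output: end-capillary blood leaves equilibrated
    with the alveolar gas, entering at mixed-venous content.
    """
    if np.any(np.asarray(VA) < 0) or np.any(np.asarray(q) < 0):
        raise ValueError("ventilation and perfusion must be non-negative")
    P_AO2 = np.asarray(P_AO2, dtype=float).copy()
    P_ACO2 = np.asarray(P_ACO2, dtype=float).copy()
    pio2 = _p_insp_o2(params)
    for s in (IPSI, CONTRA):
        if FRC[s] <= 0:
            continue
        vo2 = q[s] * 10.0 * (float(o2_content(max(P_AO2[s], 1e-3), params)) - cv_o2) / 1000.0
        vco2 = q[s] * 10.0 * (cv_co2 - float(co2_content(max(P_ACO2[s], 1e-3), params))) / 1000.0
        dpo2 = (VA[s] * (pio2 - P_AO2[s]) / params.P_atm - vo2) * params.P_atm / FRC[s]
        dpco2 = (vco2 - VA[s] * P_ACO2[s] / params.P_atm) * params.P_atm / FRC[s]
        P_AO2[s] += dpo2 * dt_min
        P_ACO2[s] += dpco2 * dt_min
    return np.clip(P_AO2, 1e-3, params.P_atm - 1e-3), np.clip(P_ACO2, 1e-3, params.P_atm - 1e-3)


def _per_lung_steady(VA: float, q: float, cv_o2: float, cv_co2: float,
                     params: PatientParams) -> tuple[float, float]:
    """Steady alveolar (P_AO2, P_ACO2) of one lung for given fresh-gas
    alveolar ventilation VA (L/min) and ventilated perfusion q (L/min)."""
    pio2 = _p_insp_o2(params)
    if VA <= 1e-9:                      # unventilated: equilibrates with venous blood
        return invert_o2_content(cv_o2, params), invert_co2_content(cv_co2, params)
    if q <= 1e-9:                       # unperfused: alveolar gas -> inspired gas
        return pio2, 1e-3

    def o2_balance(p):
        return (VA * (pio2 - p) / params.P_atm
                - q * 10.0 * (float(o2_content(p, params)) - cv_o2) / 1000.0)

    lo, hi = 1e-3, pio2
    p_o2 = brentq(o2_balance, lo, hi, xtol=1e-10) if o2_balance(lo) * o2_balance(hi) < 0 else (
        lo if o2_balance(lo) < 0 else hi)
    # CO2: linear content curve -> closed form
    # VA * p / P_atm = q*10*(cv_co2 - (C0 + s*(p - Pref)))/1000
    a = VA / params.P_atm + q * 10.0 * _CO2_SLOPE / 1000.0
    b = q * 10.0 * (cv_co2 - _CO2_REF_C + _CO2_SLOPE * _CO2_REF_P) / 1000.0
    p_co2 = min(max(b / a, 1e-3), params.P_atm - 1e-3)
    return p_o2, p_co2


def mix_arterial(end_cap_o2: np.ndarray, end_cap_co2: np.ndarray,
                 flows: np.ndarray, q_shunt: float,
                 venous: tuple[float, float], params: PatientParams,
                 rtol: float = 1e-6) -> tuple[float, float]:
    """Flow-weighted mixing of end-capillary and shunted venous blood.

    Mixing happens in CONTENT space; the mixed contents are inverted back to
    partial pressures through the dissociation curves (O2 numerically, CO2 in
    closed form).
    """
    flows = np.asarray(flows, dtype=float)
    total = flows.sum() + q_shunt
    if not np.isclose(total, params.CO_total, rtol=1e-6):
        raise ValueError(f"flows must sum to cardiac output {params.CO_total}, got {total}")
    pv_o2, pv_co2 = venous
    co2_srcs = np.array([float(o2_content(p, params)) for p in end_cap_o2])
    cco2_srcs = np.array([float(co2_content(p, params)) for p in end_cap_co2])
    ca_o2 = (np.dot(flows, co2_srcs) + q_shunt * float(o2_content(pv_o2, params))) / total
    ca_co2 = (np.dot(flows, cco2_srcs) + q_shunt * float(co2_content(pv_co2, params))) / total
    pa_o2 = invert_o2_content(ca_o2, params)
    pa_co2 = invert_co2_content(ca_co2, params)
    assert abs(float(o2_content(pa_o2, params)) - ca_o2) < rtol
    return pa_o2, pa_co2


def steady_state_gases(VA: np.ndarray, FRC: np.ndarray, VD: np.ndarray,
                       P_pl_mean: np.ndarray, open_fraction: np.ndarray,
                       params: PatientParams, max_iter: int = 200,
                       tol: float = 1e-8,
                       q_split: tuple[np.ndarray, float] | None = None) -> GasState:
    """Self-consistent steady state of the two-lung gas/circulation system.

    Outer fixed point on the mixed-venous contents: venous guess -> per-lung
    steady alveolar gases -> arterial mixing -> Fick closure
    (Cv = Ca - VO2 / (10 CO)) -> new venous.  Converges geometrically.
    """
    VA = np.asarray(VA, dtype=float)
    if q_split is None:
        q_vent, q_shunt = perfusion_split(P_pl_mean, open_fraction, params)
    else:
        q_vent, q_shunt = q_split
    cv_o2 = 15.0
    cv_co2 = 52.0
    pa = (13.0, 5.3)
    for _ in range(max_iter):
        gases = [
            _per_lung_steady(VA[s], q_vent[s], cv_o2, cv_co2, params)
            for s in (IPSI, CONTRA)
        ]
        p_ao2 = np.array([g[0] for g in gases])
        p_aco2 = np.array([g[1] for g in gases])
        pv = (invert_o2_content(cv_o2, params), invert_co2_content(cv_co2, params))
        pa = mix_arterial(p_ao2, p_aco2, q_vent, q_shunt, pv, params)
        ca_o2 = float(o2_content(pa[0], params))
        ca_co2 = float(co2_content(pa[1], params))
        new_cv_o2 = max(ca_o2 - params.VO2 * 100.0 / params.CO_total, 0.5)
        new_cv_co2 = ca_co2 + params.VCO2 * 100.0 / params.CO_total
        if abs(new_cv_o2 - cv_o2) < tol and abs(new_cv_co2 - cv_co2) < tol:
            cv_o2, cv_co2 = new_cv_o2, new_cv_co2
            break
        cv_o2, cv_co2 = new_cv_o2, new_cv_co2
    pv = (invert_o2_content(cv_o2, params), invert_co2_content(cv_co2, params))
    return GasState(P_AO2=p_ao2, P_ACO2=p_aco2, FRC=np.asarray(FRC, dtype=float),
                    VD=np.asarray(VD, dtype=float), q=q_vent, q_shunt=q_shunt,
                    PaO2=pa[0], PaCO2=pa[1], PvO2=pv[0], PvCO2=pv[1])


# ---------------------------------------------------------------------------
# bridging from mechanics recordings


def ventilation_from_recording(rec: BreathRecording, params: PatientParams):
    """Per-lung fresh-gas alveolar ventilation (L/min), end-expiratory open
    volume (L) and dead-space split from a steady-state recording.

    Dead space is split in proportion to each lung's inspired volume (the
    shared trachea washes toward the lung that draws the flow); per-lung
    alveolar ventilation is (inspired volume - dead space) * RR, floored at 0.
    """
    sl = rec.breath_slices()[-1]
    t = rec.t[sl]
    vin = np.array([
        np.trapezoid(np.maximum(rec.Q_mb_ipsi[sl], 0.0), t),
        np.trapezoid(np.maximum(rec.Q_mb_contra[sl], 0.0), t),
    ])
    share = vin / vin.sum() if vin.sum() > 0 else np.array([0.5, 0.5])
    VD = params.VD_anat * share
    VA = np.maximum(vin - VD, 0.0) * params.RR
    FRC = np.array([rec.V_open_ipsi[sl][-1], rec.V_open_contra[sl][-1]])
    return VA, FRC, VD


def gases_for_recording(rec: BreathRecording, params: PatientParams,
                        state=None) -> GasState:
    """Steady-state gases consistent with a recorded breathing pattern.

    When the final :class:`~pleurasim.mechanics.MechState` is supplied, the
    perfusion split uses the layer-resolved vascular law (local pleural
    pressures under the fluid); otherwise the two-compartment side-mean law.
    """
    from .mechanics import Engine

    VA, FRC, VD = ventilation_from_recording(rec, params)
    sl = rec.breath_slices()[-1]
    P_pl_mean = np.array([rec.P_pl_tis_ipsi[sl].mean(), rec.P_pl_tis_contra[sl].mean()])
    open_frac = np.array([rec.open_frac_ipsi[sl][-1], rec.open_frac_contra[sl][-1]])
    q_split = None
    if state is not None:
        hyd, _ = Engine(params).hydro_offsets(state.V_pf)
        P_local = state.P_pl_top[:, None] + np.vstack([hyd, np.zeros_like(hyd)])
        q_split = perfusion_split_layers(P_local, state.open, params)
    return steady_state_gases(VA, FRC, VD, P_pl_mean, open_frac, params,
                              q_split=q_split)
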