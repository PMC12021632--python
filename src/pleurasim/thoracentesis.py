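"""Stepwise therapeutic thoracentesis: aliquot schedule and session driver.

A session withdraws pleural fluid in the clinical protocol's portions
(200 mL until 1 L is out, then 100 mL), re-equilibrates the virtual patient
to a periodic breathing steady state after each aliquot (the clinical 1-min
pause idealized as "until periodic"), and records the observables a
manometry-guided procedure records: pleural pressure at FRC, the median
breath amplitude, the P-V loop and its morphology, arterial gases, shunt and
pendelluft.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import loop_analysis as la
from .gases_circulation import fresh_gas_ratio, gases_for_recording, ventilation_from_recording
from .mechanics import (CONTRA, IPSI, DriveState, Engine, SimulationError,
                        _record, hydrostatic_ppl, tidal_volume)
from .patient_model import PatientParams

__all__ = ["AliquotRecord", "TTSession", "make_schedule", "run_tt"]

#: clinical aliquot sizes, L
_ALIQUOT_EARLY = 0.2
_ALIQUOT_LATE = 0.1
_EARLY_TOTAL = 1.0


def make_schedule(total: float) -> list[float]:
    """Aliquot volumes for a planned total withdrawal.

    200 mL portions until 1 L is withdrawn, 100 mL portions afterwards; the
    final portion is truncated so the cumulative volume hits ``total`` exactly.
    """
    if total < 0:
        raise ValueError(f"total withdrawal volume cannot be negative: {total}")
    # work in integer millilitres to dodge float accumulation
    remaining = round(total * 1000)
    out, cum = [], 0
    while remaining > 0:
        step = 200 if cum < round(_EARLY_TOTAL * 1000) else 100
        step = min(step, remaining)
        out.append(step / 1000.0)
        cum += step
        remaining -= step
    return out


@dataclass
class AliquotRecord:
    """Observables recorded after one aliquot (or at baseline, index 0)."""

    V_withdrawn_cum: float      # L
    V_pf: float                 # remaining fluid, L
    P_pl_at_FRC: float          # end-expiratory pleural pressure at the catheter site, kPa
    amp_median: float           # median per-breath P_pl amplitude, kPa
    lean: str
    eight_shaped: bool
    PaO2: float                 # kPa
    PaCO2: float                # kPa
    PAO2_contra: float          # kPa
    q_shunt: float              # L/min
    fgr_contra: float           # VT/(FRC+VD) of the contralateral lung
    pendelluft_fraction: float
    open_fraction_ipsi: float
    VT: float                   # L
    drive_amp: float            # kPa
    loop_P: list = field(default_factory=list, repr=False)
    loop_V: list = field(default_factory=list, repr=False)


@dataclass
class TTSession:
    """A full stepwise-withdrawal session."""

    schedule: list[float]
    aliquots: list[AliquotRecord]
    params: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"schedule": self.schedule, "params": self.params,
                   "aliquots": [asdict(a) for a in self.aliquots]}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def V_withdrawn(self) -> np.ndarray:
        return np.array([a.V_withdrawn_cum for a in self.aliquots])

    def trace(self, fieldname: str) -> np.ndarray:
        return np.array([getattr(a, fieldname) for a in self.aliquots])

    def amplitude_slopes(self, split: float = la.STAGE_SPLIT_L) -> la.TrendSlopes:
        """Two-stage regression of the amplitude trace on withdrawn volume."""
        v = self.V_withdrawn
        return la.stage_slopes(v, self.trace("amp_median"), v, split=split)


def _analyze_aliquot(rec, state, params, v_cum, drive) -> AliquotRecord:
    from .mechanics import fluid_surface_level

    loop = la.loops_from_recording(rec)[-1]
    lean = la.classify_lean(loop)
    eight, _ = la.detect_eight(loop)
    sl = rec.breath_slices()[-1]
    pend, _ = la.pendelluft_fraction(rec.Q_mb_ipsi[sl], rec.Q_mb_contra[sl])
    amps = [rec.P_pl_ipsi[s].max() - rec.P_pl_ipsi[s].min()
            for s in rec.breath_slices()]
    gas = gases_for_recording(rec, params, state=state)
    vt = tidal_volume(rec)
    _, frc, vd = ventilation_from_recording(rec, params)
    fgr = fresh_gas_ratio(vt, frc[CONTRA], vd[CONTRA]) if frc[CONTRA] > 0 else float("nan")
    # manometry reads the pressure in the fluid at the catheter (lung base):
    # apex pressure plus the remaining hydrostatic column
    p_frc = hydrostatic_ppl(float(rec.P_pl_ipsi[-1]),
                            fluid_surface_level(state.V_pf, params),
                            params.rho_f)
    return AliquotRecord(
        V_withdrawn_cum=round(v_cum, 6), V_pf=state.V_pf,
        P_pl_at_FRC=p_frc,
        amp_median=float(np.median(amps)),
        lean=lean, eight_shaped=bool(eight),
        PaO2=gas.PaO2, PaCO2=gas.PaCO2, PAO2_contra=float(gas.P_AO2[CONTRA]),
        q_shunt=gas.q_shunt, fgr_contra=fgr, pendelluft_fraction=pend,
        open_fraction_ipsi=float(state.open_fraction[IPSI]),
        VT=vt, drive_amp=drive.amp,
        loop_P=np.round(loop.P, 6).tolist(), loop_V=np.round(loop.V, 6).tolist(),
    )


def run_tt(params: PatientParams, V_pf0: float = 3.0,
           stop: float | None = None, n_breaths: int = 2,
           dt_out: float = 0.02) -> TTSession:
    """Run a stepwise thoracentesis session.

    Parameters
    ----------
    params, V_pf0:
        Patient and initial effusion volume (L).
    stop:
        Total volume to withdraw (defaults to full drainage).  ``stop = 0``
        gives a session with the baseline record only.

    The drive controller re-targets tidal volume after every aliquot (the
    respiratory centre holds VT); the controller amplitude is warm-started
    from the previous aliquot, and the whole session is deterministic under
    the fixed-step solver.
    """
    stop = V_pf0 if stop is None else stop
    if stop > V_pf0 + 1e-12:
        raise ValueError(f"cannot withdraw {stop} L from {V_pf0} L of fluid")
    schedule = make_schedule(stop)
    engine = Engine(params)

    records: list[AliquotRecord] = []
    v_cum = 0.0
    amp_guess = 1.0
    v_pf = V_pf0
    for k, aliquot in enumerate([0.0] + schedule):
        v_pf = round(v_pf - aliquot, 9)
        v_cum = round(v_cum + aliquot, 9)
        try:
            state0 = engine.static_state(v_pf)
            drive = _adapt(engine, params, state0, amp_guess)
            rec, st = _record(engine, state0.copy(), drive, n_breaths, dt_out,
                              params.washin_breaths)
            records.append(_analyze_aliquot(rec, st, params, v_cum, drive))
            amp_guess = drive.amp
        except SimulationError as exc:
            raise SimulationError(f"aliquot {k} (V_pf={v_pf} L): {exc}") from exc
    return TTSession(schedule=schedule, aliquots=records,
                     params=params.model_dump())


def _adapt(engine: Engine, params: PatientParams, state0, amp0: float,
           rtol: float = 0.02, max_iter: int = 40) -> DriveState:
    """Drive-amplitude controller with warm start (see adapt_drive_to_vt)."""
    amp = amp0
    best = (np.inf, 0.0)
    for _ in range(max_iter):
        rec, _ = _record(engine, state0.copy(), DriveState(amp), 1, 0.02, washin=2)
        vt = tidal_volume(rec)
        err = abs(vt - params.VT_target) / params.VT_target
        best = min(best, (err, vt))
        if err <= rtol:
            return DriveState(amp, achieved_VT=vt)
        amp *= float(np.clip(params.VT_target / vt if vt > 1e-6 else 2.0, 0.5, 2.0))
        if amp > params.drive_max:
            raise SimulationError(
                f"VT target unreachable within drive bound; best VT = {best[1]:.3f} L")
    raise SimulationError(
        f"drive controller did not converge; best VT = {best[1]:.3f} L")
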