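"""The four in-silico experiment grids, as runnable report generators.

Each report is a plain dict (JSON-serializable) embedding the metrics and
full provenance: parameter hash, solver settings and package version, so a
report can be reproduced bit-for-bit from its own header under the
fixed-step solver.

The four questions the experiments probe:

1. Why need a large effusion not functionally invert the hemidiaphragm?
   (mediastinal-compliance sweep -> loop lean)
2. Why are some P-V loops 8-shaped?  (stiff-mediastinum run -> loop shape
   and phase-resolved main-bronchial flows / pendelluft)
3. Why is blood oxygenation so insensitive to withdrawal?  (gases, shunt and
   fresh-gas dilution along a full session)
4. Why can the pleural-pressure amplitude fall early in withdrawal?
   (amplitude trajectories under compliant vs. stiff mediastinum)
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd

from . import loop_analysis as la
from .mechanics import simulate_breaths
from .patient_model import PatientParams, build_patient, scale_param
from .thoracentesis import run_tt

__all__ = ["run_question", "analyze_session_frame", "CMED_SWEEP_FACTORS"]

#: sweep grid for the mediastinal-compliance experiment
CMED_SWEEP_FACTORS = (0.2, 0.5, 1.0, 2.0, 5.0)

PE_VOLUME = 3.0   # L, the study's effusion volume


def _provenance(params: PatientParams) -> dict:
    blob = json.dumps(params.model_dump(), sort_keys=True).encode()
    try:
        ver = _pkg_version("pleurasim")
    except Exception:
        ver = "unknown"
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "dt": params.dt,
        "n_layers": params.n_layers,
        "solver": "fixed-step RK4",
        "package_version": ver,
    }


def _loop_report(params: PatientParams, V_pf: float) -> dict:
    rec, st = simulate_breaths(params, V_pf, n_breaths=2)
    loop = la.loops_from_recording(rec)[-1]
    eight, crossings = la.detect_eight(loop)
    sl = rec.breath_slices()[-1]
    frac, mask = la.pendelluft_fraction(rec.Q_mb_ipsi[sl], rec.Q_mb_contra[sl])
    quads = la.pendelluft_phase_mask(mask, rec.phase[sl])
    insp_idx = np.where(loop.phase == "insp")[0]
    return {
        "lean": la.classify_lean(loop),
        "lean_delta_kpa": float(loop.P[insp_idx[-1]] - loop.P[-1]),
        "eight_shaped": bool(eight),
        "crossings": [list(map(float, c)) for c in crossings],
        "amplitude_kpa": float(loop.P.max() - loop.P.min()),
        "pendelluft_fraction": frac,
        "pendelluft_quadrants": quads,
        "open_fraction_ipsi": float(st.open_fraction[0]),
        "loop": {"P": np.round(loop.P, 5).tolist(),
                 "V": np.round(loop.V, 5).tolist()},
        "flows": {"t": np.round(rec.t[sl] - rec.t[sl][0], 4).tolist(),
                  "Q_mb_ipsi": np.round(rec.Q_mb_ipsi[sl], 5).tolist(),
                  "Q_mb_contra": np.round(rec.Q_mb_contra[sl], 5).tolist(),
                  "phase": rec.phase[sl].tolist()},
    }


def run_question(q: int, overrides: dict | None = None,
                 stop: float | None = None) -> dict:
    """Run one of the four experiment grids and return its report dict.

    ``overrides`` are applied on top of each grid's preset; ``stop`` truncates
    the thoracentesis sessions of questions 3 and 4 (default: full drainage).
    """
    if q not in (1, 2, 3, 4):
        raise ValueError(f"question must be 1..4, got {q}")
    overrides = dict(overrides or {})

    if q == 1:
        base = build_patient("default", overrides)
        runs = []
        for f in CMED_SWEEP_FACTORS:
            p = scale_param(base, "C_med", f)
            r = _loop_report(p, PE_VOLUME)
            r.pop("loop"), r.pop("flows"), r.pop("crossings")
            runs.append({"C_med_factor": f, "C_med": p.C_med, **r})
        report = {"question": 1, "pe_volume": PE_VOLUME, "sweep": runs,
                  "provenance": _provenance(base)}

    elif q == 2:
        p = build_patient("stiff_mediastinum", overrides)
        report = {"question": 2, "pe_volume": PE_VOLUME,
                  **_loop_report(p, PE_VOLUME), "provenance": _provenance(p)}

    elif q == 3:
        p = build_patient("default", overrides)
        session = run_tt(p, PE_VOLUME, stop=stop)
        report = {
            "question": 3, "pe_volume": PE_VOLUME,
            "V_withdrawn": session.V_withdrawn.tolist(),
            "PaO2": session.trace("PaO2").tolist(),
            "PaCO2": session.trace("PaCO2").tolist(),
            "PAO2_contra": session.trace("PAO2_contra").tolist(),
            "q_shunt": session.trace("q_shunt").tolist(),
            "fresh_gas_ratio_contra": session.trace("fgr_contra").tolist(),
            "open_fraction_ipsi": session.trace("open_fraction_ipsi").tolist(),
            "provenance": _provenance(p),
        }

    else:
        traces = {}
        prov = None
        for preset in ("compliant_mediastinum", "stiff_mediastinum"):
            p = build_patient(preset, overrides)
            session = run_tt(p, PE_VOLUME, stop=stop)
            slopes = session.amplitude_slopes()
            traces[preset] = {
                "V_withdrawn": session.V_withdrawn.tolist(),
                "amp_median": session.trace("amp_median").tolist(),
                "P_pl_at_FRC": session.trace("P_pl_at_FRC").tolist(),
                "lean": session.trace("lean").tolist(),
                "slope_stage1": slopes.slope_stage1,
                "slope_stage2": slopes.slope_stage2,
            }
            prov = _provenance(p)
        report = {"question": 4, "pe_volume": PE_VOLUME, **traces,
                  "provenance": prov}
    return report


# ---------------------------------------------------------------------------
# recorded/synthetic session analysis


def analyze_session_frame(frame: pd.DataFrame, fs: float = 25.0,
                          split: float = la.STAGE_SPLIT_L) -> dict:
    """Analyze a recorded or synthetic session table.

    Expects the recording CSV dialect (columns ``t, Ppl, flow`` plus
    optionally ``Q_ipsi, Q_contra, SBP, DBP, HR, V_withdrawn, interval``).
    Per interval: median amplitude, per-breath loop metrics (majority lean,
    any-eight), vitals indices; across intervals: two-stage amplitude trend
    slopes versus withdrawn volume.
    """
    # accept the simulator recording dialect as well
    alias = {"P_pl_ipsi": "Ppl", "Q_mouth": "flow",
             "Q_mb_ipsi": "Q_ipsi", "Q_mb_contra": "Q_contra"}
    renames = {k: v for k, v in alias.items()
               if k in frame.columns and v not in frame.columns}
    if renames:
        frame = frame.rename(columns=renames)
    if "interval" in frame.columns:
        groups = [g for _, g in frame.groupby("interval", sort=True)]
    else:
        groups = [frame]
    intervals = []
    for g in groups:
        P = g["Ppl"].to_numpy()
        flow = g["flow"].to_numpy()
        breaths = la.segment_breaths(flow, fs)
        amp = la.amplitude_stats(P, flow, fs)
        # fold the interval's breaths into a pointwise-median cycle: noise
        # shrinks ~ 1/sqrt(n_breaths) and loop morphology is read off the
        # ensemble breath, as on an averaged clinical loop display
        m = min(s.stop - s.start for s in breaths)
        P_med = np.median(np.vstack([P[s][:m] for s in breaths]), axis=0)
        q_med = np.median(np.vstack([flow[s][:m] for s in breaths]), axis=0)
        kern = np.ones(5) / 5.0   # light circular smoothing of the folded cycle
        P_med = np.convolve(np.concatenate([P_med[-2:], P_med, P_med[:2]]),
                            kern, mode="valid")
        loop = la.loop_from_breath(P_med, q_med, fs)
        row = {
            "amp_median": amp, "lean": la.classify_lean(loop),
            "eight_shaped": bool(la.detect_eight(loop)[0]),
            "n_breaths": len(breaths),
        }
        if "V_withdrawn" in g:
            row["V_withdrawn"] = float(g["V_withdrawn"].iloc[0])
        if {"SBP", "DBP", "HR"} <= set(g.columns):
            row["co_index"] = la.co_index(float(g["SBP"].iloc[0]),
                                          float(g["DBP"].iloc[0]),
                                          float(g["HR"].iloc[0]))
        if {"Q_ipsi", "Q_contra"} <= set(g.columns):
            row["pendelluft_fraction"] = la.pendelluft_fraction(
                g["Q_ipsi"].to_numpy(), g["Q_contra"].to_numpy())[0]
        intervals.append(row)
    out = {"fs": fs, "intervals": intervals}
    if len(intervals) > 1 and all("V_withdrawn" in r for r in intervals):
        v = np.array([r["V_withdrawn"] for r in intervals])
        a = np.array([r["amp_median"] for r in intervals])
        slopes = la.stage_slopes(v, a, v, split=split)
        out["amp_slopes"] = {"stage1": slopes.slope_stage1,
                             "stage2": slopes.slope_stage2,
                             "split_at": slopes.split_at}
    return out
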