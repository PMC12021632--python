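"""Synthetic 25 Hz manometry + spirometry sessions with controllable loop
morphology.

The generator emulates the clinical recording protocol — 1-minute intervals
of instantaneous ipsilateral pleural pressure and mouth flow sampled at
25 Hz between fluid aliquots, plus per-interval vitals — without any
simulator or patient data, so the analysis pipeline is testable end to end.

A two-harmonic pleural-pressure parameterization is the minimal family that
produces every observed loop class: with flow a pure sinusoid, the
fundamental's phase offset sets the loop lean (ellipse tilted left or
right), and a second harmonic above a threshold weight bends the ellipse
into a self-intersecting figure-eight.  This is a signal-level stand-in for
recorded breaths, not a physiological model.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .thoracentesis import make_schedule

__all__ = ["SynthSpec", "gen_breath", "gen_session", "session_to_csv"]


@dataclass(frozen=True)
class SynthSpec:
    """Declarative description of a synthetic session.

    Per-interval quantities follow linear trajectories in cumulative
    withdrawn volume ``Vw``: pressure mean ``P_mean0 + P_mean_slope * Vw``,
    peak-to-trough amplitude ``amp0 + amp_slope * Vw`` (floored at 10% of
    ``amp0``); the lean phase ``phi_lean`` (rad) and the second-harmonic
    weight ``eight_b`` (kPa) are constant.  ``seed`` is mandatory: one RNG
    stream per session, no global state.
    """

    seed: int
    RR: float = 12.0            # 1/min
    VT: float = 0.5             # L
    fs: float = 25.0            # Hz
    interval_s: float = 60.0
    total: float = 3.8          # planned withdrawal, L
    P_mean0: float = 1.0        # kPa
    P_mean_slope: float = -0.4  # kPa per L withdrawn
    amp0: float = 0.8           # kPa peak-to-trough at Vw = 0
    amp_slope: float = 0.1      # kPa per L withdrawn
    phi_lean: float = 0.0       # rad; < 0 leans the loop left
    eight_b: float = 0.0        # kPa second-harmonic weight
    phi2: float = 0.0           # rad second-harmonic phase
    noise_sd: float = 0.0       # kPa additive Gaussian noise on P_pl
    SBP: float = 120.0
    DBP: float = 80.0
    HR: float = 75.0

    def __post_init__(self):
        if self.fs <= 4.0 * self.RR / 60.0:
            raise ValueError(
                f"sampling rate {self.fs} Hz cannot resolve breaths at RR={self.RR}/min")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def T(self) -> float:
        return 60.0 / self.RR

    def amplitude_at(self, Vw: float) -> float:
        return max(self.amp0 + self.amp_slope * Vw, 0.1 * self.amp0)

    def mean_at(self, Vw: float) -> float:
        return self.P_mean0 + self.P_mean_slope * Vw


def _breath_arrays(spec: SynthSpec, Vw: float, n_samples: int,
                   rng: np.random.Generator | None):
    """Noise-free two-harmonic P_pl and sinusoid flow over ``n_samples``."""
    t = np.arange(n_samples) / spec.fs
    w = 2.0 * math.pi / spec.T
    q_amp = math.pi * spec.VT / spec.T          # so that the inhaled volume is VT
    flow = q_amp * np.sin(w * t)
    a = spec.amplitude_at(Vw) / 2.0
    P = (spec.mean_at(Vw)
         + a * np.sin(w * t + spec.phi_lean)
         + spec.eight_b * np.sin(2.0 * w * t + spec.phi2))
    if rng is not None and spec.noise_sd > 0:
        P = P + rng.normal(0.0, spec.noise_sd, n_samples)
    return P, flow


def gen_breath(spec: SynthSpec, breath_index: int = 0, Vw: float = 0.0):
    """One synthetic breath ``(P_pl(t), flow(t))`` on the 25 Hz grid.

    Noise is reproducible: the RNG is seeded from ``(seed, breath_index)``
    so any breath can be regenerated in isolation.
    """
    n = int(round(spec.T * spec.fs))
    rng = np.random.default_rng([spec.seed, breath_index])
    return _breath_arrays(spec, Vw, n, rng)


def _interval_truth(spec: SynthSpec, Vw: float) -> dict:
    """Ground-truth metrics of a noiseless interval (closed forms)."""
    n = int(round(spec.T * spec.fs))
    P, _ = _breath_arrays(spec, Vw, n, rng=None)
    a = spec.amplitude_at(Vw) / 2.0
    d_lean = -2.0 * a * math.sin(spec.phi_lean)   # P(end-insp) - P(end-exp)
    return {
        "V_withdrawn": Vw,
        "P_mean": spec.mean_at(Vw),
        "amplitude": float(P.max() - P.min()),
        "lean_delta": d_lean,
    }


def gen_session(spec: SynthSpec):
    """Generate a full synthetic session.

    Returns ``(frame, truth)``: a tidy DataFrame with columns
    ``t, Ppl, flow, SBP, DBP, HR, V_withdrawn, interval`` (one 1-minute
    interval at baseline and after each aliquot) and a ground-truth dict with
    per-interval noiseless metrics plus the declared trajectory slopes.
    Byte-identical output for equal specs (single seeded RNG stream).
    """
    rng = np.random.default_rng(spec.seed)
    schedule = make_schedule(spec.total)
    vw_points = np.concatenate([[0.0], np.cumsum(schedule)])
    n = int(round(spec.interval_s * spec.fs))

    frames = []
    truth_intervals = []
    t0 = 0.0
    for k, vw in enumerate(vw_points):
        P, flow = _breath_arrays(spec, vw, n, rng)
        frames.append(pd.DataFrame({
            "t": t0 + np.arange(n) / spec.fs,
            "Ppl": P, "flow": flow,
            "SBP": spec.SBP, "DBP": spec.DBP, "HR": spec.HR,
            "V_withdrawn": vw, "interval": k,
        }))
        truth_intervals.append(_interval_truth(spec, vw))
        t0 += spec.interval_s
    truth = {
        "spec": asdict(spec),
        "schedule": schedule,
        "amp_slope": spec.amp_slope,
        "P_mean_slope": spec.P_mean_slope,
        "intervals": truth_intervals,
    }
    return pd.concat(frames, ignore_index=True), truth


def session_to_csv(spec: SynthSpec, csv_path: str | Path,
                   truth_path: str | Path | None = None) -> None:
    """Write a session recording as CSV and its ground truth as JSON."""
    frame, truth = gen_session(spec)
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=2))
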