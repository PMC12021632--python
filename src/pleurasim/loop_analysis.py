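"""Analysis of manometry + spirometry recordings: breath segmentation, P-V
loop construction and morphology, pleural-pressure amplitude statistics,
pendelluft quantification and two-stage withdrawal trend slopes.

All operations work identically on simulator output and on recorded or
synthetic 25 Hz sessions.  The P-V loop pairs the ipsilateral pleural
pressure with the cumulative inhaled/exhaled volume of the whole respiratory
system (flow integral); its lean encodes hemidiaphragm function:

* leans LEFT  (P at end-inspiration above P at end-expiration): the
  ipsilateral hemidiaphragm is functionally inverted — pleural pressure rises
  paradoxically while air is drawn in;
* leans RIGHT: normal mechanics;
* a self-intersection (figure-eight) marks the within-breath reversal of the
  ipsilateral contribution (pendelluft).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PVLoop", "LoopMetrics", "VitalsSeries", "TrendSlopes",
    "segment_breaths", "integrate_flow", "loop_from_breath",
    "classify_lean", "detect_eight", "amplitude_stats",
    "pendelluft_fraction", "pendelluft_phase_mask",
    "co_index", "minute_ventilation", "stage_slopes",
    "loops_from_recording",
]

#: default half-width of the "vertical" lean band, kPa
LEAN_EPSILON = 0.05

#: dead-band for the pendelluft sign test, fraction of the larger peak flow
PENDELLUFT_DEADBAND = 0.01

#: empirical boundary between the two withdrawal stages, L
STAGE_SPLIT_L = 1.9


@dataclass
class PVLoop:
    """One breath's closed pleural-pressure / volume curve."""

    P: np.ndarray               # ipsilateral pleural pressure, kPa
    V: np.ndarray               # inhaled volume relative to breath start, L
    phase: np.ndarray           # "insp"/"exp" per sample

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.phase = np.asarray(self.phase)
        if len(self.P) < 8:
            raise ValueError(f"a P-V loop needs at least 8 samples, got {len(self.P)}")
        if not (len(self.P) == len(self.V) == len(self.phase)):
            raise ValueError("P, V and phase must have equal length")
        vt = max(self.V.max() - self.V.min(), 1e-12)
        if abs(self.V[-1] - self.V[0]) > 0.25 * vt:
            raise ValueError(
                f"loop is not closed: |V_end - V_start| = {abs(self.V[-1]-self.V[0]):.4f} L "
                f"vs tidal excursion {vt:.4f} L")


@dataclass
class LoopMetrics:
    lean: str                   # "left" | "vertical" | "right"
    eight_shaped: bool
    amplitude: float            # max(P) - min(P), kPa
    P_end_insp: float
    P_end_exp: float
    crossings: list = field(default_factory=list)


@dataclass
class VitalsSeries:
    """Per-interval vitals recorded between fluid aliquots."""

    t: np.ndarray               # min
    SBP: np.ndarray
    DBP: np.ndarray
    HR: np.ndarray
    VT: np.ndarray
    RR: np.ndarray
    V_withdrawn_cum: np.ndarray

    def __post_init__(self):
        if np.any(self.SBP <= self.DBP):
            raise ValueError("SBP must exceed DBP everywhere")
        if np.any(self.DBP <= 0) or np.any(self.HR <= 0) or np.any(self.RR <= 0):
            raise ValueError("DBP, HR and RR must be strictly positive")


@dataclass
class TrendSlopes:
    slope_stage1: float         # regression slope for V_withdrawn < split
    slope_stage2: float         # regression slope beyond the split
    split_at: float = STAGE_SPLIT_L

    def __post_init__(self):
        if not self.split_at > 0:
            raise ValueError("split_at must be positive")


# ---------------------------------------------------------------------------
# breath segmentation and volume reconstruction


def segment_breaths(flow: np.ndarray, fs: float,
                    hysteresis_frac: float = 0.02) -> list[slice]:
    """Delimit complete breaths at inspiratory-onset zero crossings of flow.

    A small hysteresis band (fraction of peak |flow|) suppresses noise
    chatter around zero: a new breath starts when flow rises above +band
    after having been below -band.  Partial first and last breaths are
    dropped.
    """
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    flow = np.asarray(flow, dtype=float)
    band = hysteresis_frac * np.max(np.abs(flow)) if len(flow) else 0.0
    if band == 0.0:
        raise ValueError("no breaths found: flow signal is identically zero")
    onsets = []
    # a recording that begins at rest (inside the band) and immediately rises
    # starts exactly at an inspiratory onset
    below = abs(flow[0]) <= band
    for i, q in enumerate(flow):
        if q < -band:
            below = True
        elif q > band and below:
            onsets.append(i)
            below = False
    if len(onsets) < 2:
        raise ValueError("no complete breath found in the signal")
    return [slice(a, b) for a, b in zip(onsets[:-1], onsets[1:])]


def integrate_flow(flow: np.ndarray, fs: float,
                   breaths: list[slice] | None = None) -> np.ndarray:
    """Cumulative trapezoidal volume from flow, re-zeroed at each breath onset.

    Re-zeroing removes integration drift (sensor offset, apparatus leak) per
    breath, which is how clinical spirometry volume traces are reconstructed.
    """
    flow = np.asarray(flow, dtype=float)
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow contains non-finite samples")
    V = np.concatenate([[0.0], cumulative_trapezoid(flow, dx=1.0 / fs)])
    if breaths:
        out = V.copy()
        for s in breaths:
            out[s.start:] = V[s.start:] - V[s.start]
        return out
    return V


def loop_from_breath(P_pl: np.ndarray, flow: np.ndarray, fs: float) -> PVLoop:
    """Build one breath's P-V loop from co-sampled pressure and flow."""
    P_pl = np.asarray(P_pl, dtype=float)
    flow = np.asarray(flow, dtype=float)
    V = np.concatenate([[0.0], cumulative_trapezoid(flow, dx=1.0 / fs)])
    phase = np.where(flow >= 0, "insp", "exp")
    return PVLoop(P=P_pl, V=V, phase=phase)


# ---------------------------------------------------------------------------
# morphology


def classify_lean(loop: PVLoop, epsilon: float = LEAN_EPSILON) -> str:
    """Lean of the loop: functional hemidiaphragm inversion test.

    ``left`` if pleural pressure at end-inspiration exceeds that at
    end-expiration by more than ``epsilon`` (functional inversion), ``right``
    if it is lower by more than ``epsilon``, ``vertical`` otherwise.
    End-inspiration is the last inspiratory sample (the volume peak);
    end-expiration is the loop's final sample.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    insp_idx = np.where(loop.phase == "insp")[0]
    if len(insp_idx) == 0 or len(insp_idx) == len(loop.P):
        raise ValueError("loop lacks phase labels for both inspiration and expiration")
    p_ei = float(loop.P[insp_idx[-1]])
    p_ee = float(loop.P[-1])
    d = p_ei - p_ee
    if d > epsilon:
        return "left"
    if d < -epsilon:
        return "right"
    return "vertical"


def _proper_crossings(x: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    """Proper (transversal) self-intersections of the closed polyline.

    Vectorized orientation test over all non-adjacent segment pairs of the
    closed curve (the closing edge included); shared endpoints of adjacent
    segments are not crossings.
    """
    pts = np.column_stack([x, y])
    seg_a = pts
    seg_b = np.roll(pts, -1, axis=0)
    n = len(pts)
    i, j = np.triu_indices(n, k=2)
    # adjacent through the wrap-around edge
    keep = ~((i == 0) & (j == n - 1))
    i, j = i[keep], j[keep]

    def cross2(a, b):
        return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

    p, r = seg_a[i], seg_b[i] - seg_a[i]
    q, s = seg_a[j], seg_b[j] - seg_a[j]
    denom = cross2(r, s)
    qp = q - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross2(qp, s) / denom
        u = cross2(qp, r) / denom
    hit = (np.abs(denom) > 1e-15) & (t > 1e-12) & (t < 1 - 1e-12) \
        & (u > 1e-12) & (u < 1 - 1e-12)
    out = [tuple(p[k] + t[k] * r[k]) for k in np.where(hit)[0]]
    # a revisited vertex (two non-adjacent samples coinciding) is also a
    # self-intersection, e.g. a figure-eight sampled exactly at its node
    scale = max(np.ptp(x), np.ptp(y), 1e-300)
    vi, vj = np.triu_indices(n, k=2)
    vkeep = ~((vi == 0) & (vj == n - 1))
    dup = np.linalg.norm(pts[vi[vkeep]] - pts[vj[vkeep]], axis=1) < 1e-12 * scale
    out.extend(tuple(pt) for pt in pts[vi[vkeep]][dup])
    return out


def detect_eight(loop: PVLoop) -> tuple[bool, list[tuple[float, float]]]:
    """Figure-eight test: does the closed P-V polyline properly self-intersect?

    Returns the flag and the crossing coordinates (P, V).  Degenerate
    (zero-area) loops are rejected.
    """
    P, V = loop.P, loop.V
    # degenerate = all samples (numerically) on one line; note a symmetric
    # figure-eight has zero SIGNED area, so the shoelace sum is no test here
    pts = np.column_stack([P, V])
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[0] <= 0 or sv[1] < 1e-9 * sv[0]:
        raise ValueError("degenerate (zero-area) loop")
    crossings = _proper_crossings(P, V)
    return len(crossings) > 0, crossings


def amplitude_stats(P_pl: np.ndarray, flow: np.ndarray, fs: float) -> float:
    """Median per-breath peak-to-trough pleural pressure over an interval."""
    breaths = segment_breaths(flow, fs)
    P_pl = np.asarray(P_pl, dtype=float)
    amps = [P_pl[s].max() - P_pl[s].min() for s in breaths]
    return float(np.median(amps))


# ---------------------------------------------------------------------------
# pendelluft


def pendelluft_fraction(Q_ipsi: np.ndarray, Q_contra: np.ndarray,
                        dead_band_frac: float = PENDELLUFT_DEADBAND):
    """Fraction of samples with opposite-signed main-bronchial flows.

    Both flows must exceed a dead-band (``dead_band_frac`` of the larger
    series' peak |flow|) so that numerical zero chatter is ignored.  Returns
    ``(fraction, event_mask)``.
    """
    Q_ipsi = np.asarray(Q_ipsi, dtype=float)
    Q_contra = np.asarray(Q_contra, dtype=float)
    if Q_ipsi.shape != Q_contra.shape:
        raise ValueError(f"flow series lengths differ: {Q_ipsi.shape} vs {Q_contra.shape}")
    band = dead_band_frac * max(np.max(np.abs(Q_ipsi)), np.max(np.abs(Q_contra)))
    mask = (np.sign(Q_ipsi) != np.sign(Q_contra)) \
        & (np.abs(Q_ipsi) > band) & (np.abs(Q_contra) > band)
    return float(mask.mean()), mask


def pendelluft_phase_mask(mask: np.ndarray, phase: np.ndarray) -> dict[str, int]:
    """Count pendelluft events per cycle quarter.

    Inspiration and expiration (by the phase labels) are each split into an
    early and a late half; returns event counts for ``early_insp``,
    ``late_insp``, ``early_exp`` and ``late_exp``.
    """
    mask = np.asarray(mask, dtype=bool)
    phase = np.asarray(phase)
    if mask.shape != phase.shape:
        raise ValueError("mask and phase must have equal length")
    counts = dict.fromkeys(("early_insp", "late_insp", "early_exp", "late_exp"), 0)
    for name, idx in (("insp", np.where(phase == "insp")[0]),
                      ("exp", np.where(phase != "insp")[0])):
        half = len(idx) // 2
        counts[f"early_{name}"] = int(mask[idx[:half]].sum())
        counts[f"late_{name}"] = int(mask[idx[half:]].sum())
    return counts


# ---------------------------------------------------------------------------
# vitals and trends


def co_index(SBP: float, DBP: float, HR: float) -> float:
    """Pulse-pressure x heart-rate proxy for cardiac output: (SBP - DBP) * HR."""
    if not SBP > DBP:
        raise ValueError(f"SBP ({SBP}) must exceed DBP ({DBP})")
    if HR <= 0:
        raise ValueError("HR must be positive")
    return (SBP - DBP) * HR


def minute_ventilation(VT: float, RR: float) -> float:
    """Minute ventilation V_E = VT * RR, L/min."""
    if VT <= 0 or RR <= 0:
        raise ValueError("VT and RR must be positive")
    return VT * RR


def stage_slopes(x: np.ndarray, y: np.ndarray, V_withdrawn: np.ndarray,
                 split: float = STAGE_SPLIT_L) -> TrendSlopes:
    """Ordinary-least-squares trend slope per withdrawal stage.

    Points with cumulative withdrawn volume below ``split`` belong to the
    first stage, the rest to the second.  A stage with fewer than two points
    gets slope NaN (undefined), not an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    V_withdrawn = np.asarray(V_withdrawn, dtype=float)
    if not (len(x) == len(y) == len(V_withdrawn)):
        raise ValueError("x, y and V_withdrawn must have equal length")

    def ols(m):
        if m.sum() < 2 or np.ptp(x[m]) == 0:
            return float("nan")
        return float(np.polyfit(x[m], y[m], 1)[0])

    stage1 = V_withdrawn < split
    return TrendSlopes(slope_stage1=ols(stage1), slope_stage2=ols(~stage1),
                       split_at=split)


# ---------------------------------------------------------------------------
# simulator bridge


def loops_from_recording(rec) -> list[PVLoop]:
    """P-V loops (one per recorded breath) from a simulator recording."""
    loops = []
    for s in rec.breath_slices():
        flow = rec.Q_mouth[s]
        V = np.concatenate([[0.0], cumulative_trapezoid(flow, rec.t[s])])
        loops.append(PVLoop(P=rec.P_pl_ipsi[s], V=V, phase=rec.phase[s]))
    return loops
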