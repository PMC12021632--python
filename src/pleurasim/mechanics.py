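"""Respiratory-mechanics core: layered lungs, pleural hydrostatics, recruitment,
hemidiaphragm drivers and breath simulation.

Model sketch
------------
Each lung is split into ``n_layers`` horizontal layers inside a vertical
prismatic hemithorax.  Pleural fluid (volume ``V_pf``, ipsilateral side only)
pools at the bottom; local pleural pressure rises hydrostatically below the
fluid surface.  Each open layer is an exponential-recoil gas compartment fed
through a collapsible peripheral airway; layers collapse and reopen across a
transmural-pressure hysteresis band.  The two hemithoraces are coupled by an
elastic mediastinum, share a viscoelastic rib cage, and are closed caudally by
two hemidiaphragms riding on a common viscoelastic abdomen.

Dynamic state: per-layer gas volumes plus the two hemidiaphragm displacement
volumes.  Rib-cage volume and mediastinal displacement follow algebraically
from the two hemithorax volume-compatibility constraints, and the two apex
pleural pressures are obtained at every right-hand-side evaluation from a
2x2 linear solve of (a) the rib-cage Kelvin-Voigt balance and (b) the
mediastinal elastic balance ``P_pl_ipsi - P_pl_contra = V_med / C_med``.
Flow continuity at the carina therefore holds exactly (algebraic elimination,
not penalty), as does the mediastinal contract.

Sign conventions (fixed package-wide): airflow positive into the patient;
``x_di`` positive caudal (inspiratory for a normal diaphragm); ``V_med``
positive toward the contralateral side; pleural pressures are reported at the
lung apex (``P_pl_top``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .patient_model import PatientParams
from .units import KPA_PER_CMH2O

__all__ = [
    "IPSI", "CONTRA",
    "MechState", "DriveState", "BreathRecording", "SimulationError",
    "hydrostatic_ppl", "fluid_surface_level",
    "force_length_factor", "drive_direction_factor", "muscle_driver",
    "hysteresis_step", "layer_recruitment_update",
    "Engine", "derivatives", "simulate_breaths", "adapt_drive_to_vt",
    "tidal_volume", "breath_amplitude",
]

IPSI, CONTRA = 0, 1


class SimulationError(RuntimeError):
    """Solver failure or non-convergence, with a diagnostic message."""


# ---------------------------------------------------------------------------
# elementary physics


def hydrostatic_ppl(P_pl_top: float, depth_cm: float, rho_f: float = 1.0) -> float:
    """Local pleural pressure at ``depth_cm`` below the fluid surface, kPa.

    Below the fluid surface the pleural pressure rises by the hydrostatic
    column rho_f * g * depth (1 cm of water ~ 0.0981 kPa); layers above the
    surface pass ``depth_cm = 0``.
    """
    if depth_cm < 0:
        raise ValueError(f"depth below fluid surface cannot be negative: {depth_cm}")
    return P_pl_top + rho_f * KPA_PER_CMH2O * depth_cm


def fluid_surface_level(V_pf: float, params: PatientParams) -> float:
    """Height of the pleural-fluid surface above the lung base, cm.

    The hemithorax is a vertical prism of uniform cross-section
    (capacity / height), so the level is linear in fluid volume.
    """
    if V_pf < 0:
        raise ValueError(f"pleural fluid volume cannot be negative: {V_pf}")
    if V_pf > params.hemithorax_capacity:
        raise ValueError(
            f"pleural fluid volume {V_pf} L exceeds hemithorax capacity "
            f"{params.hemithorax_capacity} L")
    return V_pf / params.cross_section_area


def force_length_factor(x_di: np.ndarray | float, params: PatientParams,
                        x_rest: np.ndarray | float = 0.0):
    """Force-length factor phi(x) of a hemidiaphragm, in [floor, 1].

    phi = 1 at (or beyond) the resting length ``x_rest`` (the relaxed
    baseline displacement) and falls linearly as the hemidiaphragm shortens
    (displaces caudally past it), clamped at ``di_phi_floor``.  Within a
    breath this makes a stretched contralateral hemidiaphragm strong early
    and progressively weaker as it shortens, while a deeply displaced
    (inverted) one sits at the floor.
    """
    x = np.asarray(x_di, dtype=float)
    phi = 1.0 - np.maximum(0.0, x - np.asarray(x_rest)) / params.di_phi_span
    return np.clip(phi, params.di_phi_floor, 1.0)


def drive_direction_factor(x_di: np.ndarray | float, params: PatientParams):
    """Smooth sign of the volume effect of contraction: +1 normal dome,
    -1 once the hemidiaphragm is inverted (contraction then lifts the dome
    cephalad, a paradoxical, expiratory action), 0 when flat."""
    x = np.asarray(x_di, dtype=float)
    return np.tanh((params.di_inversion_x - x) / params.di_inversion_w)


def effective_drive_factor(x_di, params: PatientParams, x_rest=0.0):
    """phi(x) * direction(x): signed mechanical advantage of contraction."""
    return (force_length_factor(x_di, params, x_rest)
            * drive_direction_factor(x_di, params))


def _waveform(t: float, params: PatientParams) -> float:
    """Normalized active muscle-pressure profile over one cycle.

    Parabolic rise peaking at end-inspiration, then exponential release
    (post-inspiratory braking) with time constant ``mus_tau_frac * T``.
    Pressure peaking at the volume peak is what places the paradoxical
    action of an inverted hemidiaphragm at end-inspiration.
    """
    tau = t % params.T_breath
    if tau < params.Ti:
        s = tau / params.Ti
        return s * (2.0 - s)
    return math.exp(-(tau - params.Ti) / (params.mus_tau_frac * params.T_breath))


def muscle_driver(t: float, params: PatientParams, drive: "DriveState",
                  x_di: tuple[float, float] = (0.0, 0.0),
                  x_rest: tuple[float, float] = (0.0, 0.0)):
    """Active muscle pressures at time ``t``.

    Returns ``(P_di_ipsi, P_di_contra, P_rc_mus, phase)`` where the
    hemidiaphragm pressures are the common neural drive scaled by each side's
    signed force-length factor, and ``phase`` is ``"insp"`` during the active
    effort window and ``"exp"`` otherwise.
    """
    if drive.amp < 0:
        raise ValueError("drive amplitude must be non-negative")
    w = _waveform(t, params)
    p_di_raw = drive.amp * (1.0 - params.rc_share) * w
    p_rc = drive.amp * params.rc_share * w
    psi = effective_drive_factor(np.asarray(x_di), params, np.asarray(x_rest))
    phase = "insp" if (t % params.T_breath) < params.Ti else "exp"
    return p_di_raw * float(psi[0]), p_di_raw * float(psi[1]), p_rc, phase


def hysteresis_step(open_flags: np.ndarray, p_gate: np.ndarray,
                    p_close: float, p_open: float) -> np.ndarray:
    """One step of the scalar recruitment hysteresis automaton.

    Open elements close when their gating pressure drops below ``p_close``;
    closed elements open when it exceeds ``p_open``; everything else keeps its
    flag (hysteresis).  Pure function of its arguments.
    """
    if not p_open > p_close:
        raise ValueError("hysteresis requires p_open > p_close")
    new = open_flags.copy()
    new[open_flags & (p_gate < p_close)] = False
    new[(~open_flags) & (p_gate > p_open)] = True
    return new


# ---------------------------------------------------------------------------
# state containers


@dataclass
class MechState:
    """Instantaneous mechanical state.  Index 0 = ipsilateral, 1 = contralateral."""

    V_alv: np.ndarray          # (2, N) layer gas volumes, L
    open: np.ndarray           # (2, N) recruitment flags
    x_di: np.ndarray           # (2,) hemidiaphragm displacement volumes, L
    V_pf: float                # ipsilateral pleural fluid volume, L
    P_pl_top: np.ndarray = field(default_factory=lambda: np.zeros(2))  # kPa
    V_med: float = 0.0         # mediastinal displacement volume, L
    V_rc: float = 0.0          # rib-cage volume above relaxation, L
    t: float = 0.0

    def copy(self) -> "MechState":
        return MechState(self.V_alv.copy(), self.open.copy(), self.x_di.copy(),
                         self.V_pf, self.P_pl_top.copy(), self.V_med, self.V_rc,
                         self.t)

    @property
    def V_lung(self) -> np.ndarray:
        """Total gas volume per lung (open + trapped), L."""
        return self.V_alv.sum(axis=1)

    @property
    def V_open(self) -> np.ndarray:
        """Open (ventilatable) gas volume per lung, L."""
        return (self.V_alv * self.open).sum(axis=1)

    @property
    def open_fraction(self) -> np.ndarray:
        return self.open.mean(axis=1)


@dataclass(frozen=True)
class DriveState:
    """Respiratory muscle drive: one amplitude feeding diaphragm and rib cage."""
    amp: float                  # kPa
    achieved_VT: float | None = None


_REC_COLUMNS = [
    "t", "P_pl_ipsi", "P_pl_contra", "Q_mouth", "Q_mb_ipsi", "Q_mb_contra",
    "V_lung_ipsi", "V_lung_contra", "V_open_ipsi", "V_open_contra",
    "V_med", "V_rc", "open_frac_ipsi", "open_frac_contra",
    "P_pl_tis_ipsi", "P_pl_tis_contra", "phase",
]


@dataclass
class BreathRecording:
    """Time series of one or more recorded steady-state breaths."""

    t: np.ndarray
    P_pl_ipsi: np.ndarray
    P_pl_contra: np.ndarray
    Q_mouth: np.ndarray
    Q_mb_ipsi: np.ndarray
    Q_mb_contra: np.ndarray
    V_lung_ipsi: np.ndarray
    V_lung_contra: np.ndarray
    V_open_ipsi: np.ndarray
    V_open_contra: np.ndarray
    V_med: np.ndarray
    V_rc: np.ndarray
    open_frac_ipsi: np.ndarray
    open_frac_contra: np.ndarray
    P_pl_tis_ipsi: np.ndarray   # tissue-mean (volume-site-averaged) pleural pressure
    P_pl_tis_contra: np.ndarray
    phase: np.ndarray           # "insp"/"exp" labels
    T_breath: float
    n_breaths: int

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def samples_per_breath(self) -> int:
        return int(round(self.T_breath / self.dt))

    def breath_slices(self) -> list[slice]:
        spb = self.samples_per_breath
        return [slice(i * spb, (i + 1) * spb) for i in range(self.n_breaths)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in _REC_COLUMNS})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, T_breath: float,
                       n_breaths: int) -> "BreathRecording":
        kw = {c: df[c].to_numpy() for c in _REC_COLUMNS}
        return cls(T_breath=T_breath, n_breaths=n_breaths, **kw)


# ---------------------------------------------------------------------------
# the engine


class Engine:
    """Precomputed constants and the right-hand side of the mechanics ODE."""

    def __init__(self, params: PatientParams):
        self.p = params
        p = params
        N = p.n_layers
        self.N = N
        self.h_layer = p.lung_height / N                      # cm
        self.z_center = (np.arange(N) + 0.5) * self.h_layer   # cm above base
        self.kpa_per_cm = KPA_PER_CMH2O * p.rho_f
        self.layer_Vmax = p.layer_Vmax
        # per-layer series resistances (N parallel branches per lung)
        self.R_aw0 = p.R_small * N
        self.R_par_layer = p.R_par * N
        self.V_half = p.collapse_vfrac * self.layer_Vmax
        self.V_trap = p.trap_frac * self.layer_Vmax

        # reference (relaxed, fluid-free) configuration ------------------
        ptp0 = -p.P_pl0
        self.V_layer0 = self.layer_Vmax * (1.0 - math.exp(-p.lung_k * ptp0))
        V_lung0 = self.V_layer0 * N
        # hemidiaphragm rest displacements: x_s = C_di_s*(P_pl0 - P_ab),
        # P_ab = P_ab0 + (x_i + x_c)/C_ab  -> 2x2 linear solve
        cdi = np.array([p.C_di_ipsi, p.C_di_contra])
        A = np.eye(2) + np.outer(cdi, np.ones(2)) / p.C_ab
        b = cdi * (p.P_pl0 - p.P_ab0)
        self.x0 = np.linalg.solve(A, b)
        self.V_rc0 = p.C_rc * p.P_pl0
        # volume-compatibility constants
        self.C0 = self.V_rc0 - 2.0 * V_lung0 + self.x0.sum()
        self.K_ipsi = self.V_rc0 / 2.0 + self.x0[IPSI] - V_lung0
        self._off_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    # -- algebraic closures ---------------------------------------------
    def rib_and_med_volumes(self, V_lung: np.ndarray, x_di: np.ndarray,
                            V_pf: float) -> tuple[float, float]:
        """Rib-cage and mediastinal displacement volumes from the two
        hemithorax volume-compatibility constraints."""
        V_rc = V_lung.sum() + V_pf - x_di.sum() + self.C0
        V_med = self.K_ipsi + V_lung[IPSI] + V_pf - V_rc / 2.0 - x_di[IPSI]
        return float(V_rc), float(V_med)

    def hydro_offsets(self, V_pf: float) -> tuple[np.ndarray, float]:
        """Per-layer ipsilateral hydrostatic pressure offsets (kPa) and the
        offset at the diaphragm (lung base)."""
        z_f = fluid_surface_level(V_pf, self.p)
        depth = np.maximum(0.0, z_f - self.z_center)
        return self.kpa_per_cm * depth, self.kpa_per_cm * z_f

    def _offsets2(self, V_pf: float):
        """(2, N) pleural offsets vs. apex and (2,) base offsets, cached:
        the fluid volume is constant within one integration run."""
        cached = self._off_cache.get(V_pf)
        if cached is None:
            hyd, hb = self.hydro_offsets(V_pf)
            cached = (np.vstack([hyd, np.zeros(self.N)]), np.array([hb, 0.0]))
            if len(self._off_cache) > 64:
                self._off_cache.clear()
            self._off_cache[V_pf] = cached
        return cached

    def recoil(self, V: np.ndarray) -> np.ndarray:
        """Elastic recoil of a layer: P_el = -(1/k) ln(1 - V/Vmax)."""
        frac = np.clip(V / self.layer_Vmax, 0.0, 1.0 - 1e-9)
        return -np.log1p(-frac) / self.p.lung_k

    def layer_conductance(self, V: np.ndarray, open_flags: np.ndarray) -> np.ndarray:
        """Conductance of each layer branch (collapsible airway + viscous
        parenchyma in series); zero for closed layers."""
        squeeze = np.maximum(0.0, (self.V_half - V) / self.V_half)
        R = self.R_aw0 * (1.0 + self.p.collapse_beta * squeeze) + self.R_par_layer
        g = open_flags / R
        return g

    # -- right-hand side --------------------------------------------------
    def rhs(self, t: float, V_alv: np.ndarray, x_di: np.ndarray,
            open_flags: np.ndarray, V_pf: float,
            drive_fn: Callable[[float], tuple[float, float]]) -> tuple:
        """Time derivatives of (V_alv, x_di) and a diagnostics dict.

        ``drive_fn(t)`` returns the raw (unscaled) diaphragm drive pressure
        and the rib-cage muscle pressure, both kPa.
        """
        p = self.p
        if not np.isfinite(V_alv.sum() + x_di.sum()):
            raise SimulationError(f"non-finite state at t={t:.4f}")

        V_lung = V_alv.sum(axis=1)
        V_rc, V_med = self.rib_and_med_volumes(V_lung, x_di, V_pf)
        offs, hb = self._offsets2(V_pf)              # pleural offsets vs apex

        p_di_raw, p_rc_mus = drive_fn(t)
        psi = effective_drive_factor(x_di, p, self.x0)
        D = p_di_raw * psi                      # signed active diaphragm pressures

        pel = self.recoil(V_alv)
        g = self.layer_conductance(V_alv, open_flags)
        G = g.sum(axis=1)                            # per-side total conductance
        src = g * (offs + pel)
        R_mb = np.array([p.R_mb_ipsi, p.R_mb_contra])

        # per-side Thevenin reduction: E_s = P_s + abar_s, r_s = 1/G_s + R_mb_s
        abar = np.where(G > 0, src.sum(axis=1) / np.where(G > 0, G, 1.0), 0.0)
        u = np.where(G > 0, 1.0 / (1.0 / np.where(G > 0, G, 1.0) + R_mb), 0.0)
        den = 1.0 / p.R_tr + u.sum()
        # Q_total = -P_car / R_tr, linear in apex pressures
        qa = -(u * abar).sum() / (p.R_tr * den)
        qb = -u / (p.R_tr * den)

        # hemidiaphragm velocities, linear in apex pressures
        P_ab = p.P_ab0 + x_di.sum() / p.C_ab
        cdi = np.array([p.C_di_ipsi, p.C_di_contra])
        xa = (hb + D - P_ab - x_di / cdi) / p.R_ab
        xb = np.full(2, 1.0 / p.R_ab)

        # rib-cage Kelvin-Voigt balance + mediastinal elastic balance
        ra = qa - xa.sum()
        rb = qb - xb
        a_coef = 0.5 - p.R_rc * rb          # coefficients of (P_i, P_c)
        b1 = V_rc / p.C_rc - p_rc_mus + p.R_rc * ra
        dpm = V_med / p.C_med
        P_c = (b1 - a_coef[IPSI] * dpm) / a_coef.sum()
        P_i = P_c + dpm
        P = np.array([P_i, P_c])

        # flows at the solved pressures
        E = P + abar
        P_car = (u * E).sum() / den
        Q_mb = (P_car - E) * u
        Q_mouth = -P_car / p.R_tr
        P_mb = P_car - R_mb * Q_mb
        dV = g * (P_mb[:, None] - (P[:, None] + offs + pel))
        dx = xa + xb * P

        diag = {
            "P_pl": P, "V_rc": V_rc, "V_med": V_med, "Q_mouth": Q_mouth,
            "Q_mb": Q_mb, "P_mb": P_mb, "pel": pel, "offs": offs,
            "dV": dV, "dx": dx, "P_ab": P_ab, "hyd_base": float(hb[IPSI]),
        }
        return dV, dx, diag

    # -- recruitment -------------------------------------------------------
    def recruitment_flags(self, V_alv, x_di, open_flags, V_pf, drive_fn, t):
        """Apply the hysteresis automaton to every layer.

        Open layers gate on alveolar-minus-local-pleural pressure (elastic
        recoil plus the viscous parenchymal drop); closed, sealed layers gate
        on the pressure available at the collapsed airway entrance (upstream
        main-bronchus pressure minus local pleural pressure).
        """
        _, _, diag = self.rhs(t, V_alv, x_di, open_flags, V_pf, drive_fn)
        gate_open = diag["pel"] + self.R_par_layer * diag["dV"]
        gate_closed = diag["P_mb"][:, None] - (diag["P_pl"][:, None] + diag["offs"])
        p_gate = np.where(open_flags, gate_open, gate_closed)
        new = hysteresis_step(open_flags, p_gate, self.p.P_close, self.p.P_open)
        # a layer squeezed to (near) zero gas is collapsed regardless of gates
        new[V_alv <= 0.5 * self.V_trap] = False
        return new, diag

    # -- static equilibrium ------------------------------------------------
    def static_state(self, V_pf: float) -> MechState:
        """Relaxed mechanical equilibrium at a given pleural fluid volume.

        Solves the two-pressure balance with the recruitment pattern iterated
        to a fixed point (at statics the airway tree is at mouth pressure, so
        every layer gates on minus its local pleural pressure).  Solved by
        continuation: fluid is added in <= 0.25 L increments, warm-starting
        pressures and the recruitment pattern from the previous level.
        """
        levels = np.arange(0.0, V_pf, 0.25).tolist() + [float(V_pf)]
        state = None
        P_guess = np.array([self.p.P_pl0, self.p.P_pl0], dtype=float)
        flags = np.ones((2, self.N), dtype=bool)
        for lvl in levels:
            state, P_guess, flags = self._static_at(lvl, P_guess, flags)
        return state

    def _static_at(self, V_pf: float, P_guess: np.ndarray,
                   flags0: np.ndarray):
        from scipy.optimize import root

        p = self.p
        hyd, hyd_base = self.hydro_offsets(V_pf)
        open_flags = flags0.copy()
        V_trap = np.full((2, self.N), self.V_trap)

        def volumes(P: np.ndarray, flags: np.ndarray) -> np.ndarray:
            offs = np.vstack([hyd, np.zeros(self.N)])
            ptp = np.maximum(0.0, -(P[:, None] + offs))
            V = self.layer_Vmax * (1.0 - np.exp(-p.lung_k * ptp))
            return np.where(flags, V, V_trap)

        def solve_x(P: np.ndarray) -> np.ndarray:
            cdi = np.array([p.C_di_ipsi, p.C_di_contra])
            A = np.eye(2) + np.outer(cdi, np.ones(2)) / p.C_ab
            b = cdi * (P + np.array([hyd_base, 0.0]) - p.P_ab0)
            return np.linalg.solve(A, b)

        def residual(P, flags):
            V = volumes(P, flags)
            x = solve_x(P)
            V_rc, V_med = self.rib_and_med_volumes(V.sum(axis=1), x, V_pf)
            return [P.mean() - V_rc / p.C_rc, (P[0] - P[1]) - V_med / p.C_med]

        P = P_guess.astype(float).copy()
        for _ in range(4 * self.N):
            sol = root(lambda q: residual(q, open_flags), P, tol=1e-12)
            if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
                # retry from jittered starts and with Levenberg-Marquardt;
                # the residual has recruitment kinks that can stall hybr
                for trial in ([P + d for d in ((0.2, 0.0), (-0.2, 0.0),
                                               (0.3, -0.1), (0.0, 0.2))]):
                    sol = root(lambda q: residual(q, open_flags), trial, tol=1e-12)
                    if sol.success and np.max(np.abs(sol.fun)) < 1e-8:
                        break
                else:
                    sol = root(lambda q: residual(q, open_flags), P,
                               method="lm", tol=1e-14)
                    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
                        raise SimulationError(
                            f"static equilibrium failed at V_pf={V_pf}: {sol.message}")
            P = sol.x
            offs = np.vstack([hyd, np.zeros(self.N)])
            p_gate = -(P[:, None] + offs)
            new = hysteresis_step(open_flags, p_gate, p.P_close, p.P_open)
            if np.array_equal(new, open_flags):
                break
            open_flags = new
        else:
            raise SimulationError(
                f"recruitment pattern did not reach a fixed point at V_pf={V_pf}")

        V = volumes(P, open_flags)
        x = solve_x(P)
        V_rc, V_med = self.rib_and_med_volumes(V.sum(axis=1), x, V_pf)
        state = MechState(V_alv=V, open=open_flags, x_di=x, V_pf=V_pf,
                          P_pl_top=P.copy(), V_med=V_med, V_rc=V_rc, t=0.0)
        return state, P, open_flags

    # -- integration --------------------------------------------------------
    def integrate(self, state: MechState, duration: float,
                  drive_fn: Callable[[float], tuple[float, float]],
                  record_from: float = np.inf, dt_out: float = 0.02,
                  phase_fn: Callable[[float], str] | None = None):
        """Fixed-step RK4 integration with per-step recruitment update.

        Returns ``(state, samples)`` where ``samples`` is a list of per-sample
        diagnostic rows recorded on the ``dt_out`` grid for t >= record_from.
        """
        p = self.p
        dt = p.dt
        n_steps = int(round(duration / dt))
        every = max(1, int(round(dt_out / dt)))
        V = state.V_alv.copy()
        x = state.x_di.copy()
        flags = state.open.copy()
        V_pf = state.V_pf
        t0 = state.t
        samples = []

        for i in range(n_steps):
            t = t0 + i * dt
            flags, diag = self.recruitment_flags(V, x, flags, V_pf, drive_fn, t)
            k1V, k1x, diag = self.rhs(t, V, x, flags, V_pf, drive_fn)
            if i % every == 0 and t >= record_from - 1e-12:
                samples.append(self._sample_row(t, V, x, flags, diag,
                                                phase_fn(t) if phase_fn else ""))
            k2V, k2x, _ = self.rhs(t + dt / 2, V + dt / 2 * k1V * flags,
                                   x + dt / 2 * k1x, flags, V_pf, drive_fn)
            k3V, k3x, _ = self.rhs(t + dt / 2, V + dt / 2 * k2V * flags,
                                   x + dt / 2 * k2x, flags, V_pf, drive_fn)
            k4V, k4x, _ = self.rhs(t + dt, V + dt * k3V * flags,
                                   x + dt * k3x, flags, V_pf, drive_fn)
            V = V + dt / 6 * (k1V + 2 * k2V + 2 * k3V + k4V) * flags
            x = x + dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
            np.clip(V, 1e-9, None, out=V)

        t_end = t0 + n_steps * dt
        _, _, diag = self.rhs(t_end, V, x, flags, V_pf, drive_fn)
        out = MechState(V_alv=V, open=flags, x_di=x, V_pf=V_pf,
                        P_pl_top=diag["P_pl"].copy(), V_med=diag["V_med"],
                        V_rc=diag["V_rc"], t=t_end)
        return out, samples

    def _sample_row(self, t, V, x, flags, diag, phase):
        V_lung = V.sum(axis=1)
        V_open = (V * flags).sum(axis=1)
        p_tis = diag["P_pl"] + diag["offs"].mean(axis=1)
        return (t, diag["P_pl"][IPSI], diag["P_pl"][CONTRA], diag["Q_mouth"],
                diag["Q_mb"][IPSI], diag["Q_mb"][CONTRA],
                V_lung[IPSI], V_lung[CONTRA], V_open[IPSI], V_open[CONTRA],
                diag["V_med"], diag["V_rc"],
                flags[IPSI].mean(), flags[CONTRA].mean(),
                p_tis[IPSI], p_tis[CONTRA], phase)

    def standard_drive(self, drive: DriveState):
        p = self.p

        def drive_fn(t: float):
            w = _waveform(t, p)
            return drive.amp * (1.0 - p.rc_share) * w, drive.amp * p.rc_share * w

        def phase_fn(t: float) -> str:
            return "insp" if (t % p.T_breath) < p.Ti else "exp"

        return drive_fn, phase_fn


# ---------------------------------------------------------------------------
# public operations


def derivatives(state: MechState, t: float, params: PatientParams,
                drive: DriveState) -> dict:
    """Named time-derivatives and pressures of the full pressure-balance
    network at one instant (thin wrapper over :meth:`Engine.rhs`)."""
    eng = Engine(params)
    drive_fn, _ = eng.standard_drive(drive)
    dV, dx, diag = eng.rhs(t, state.V_alv, state.x_di, state.open,
                           state.V_pf, drive_fn)
    return {
        "dV_alv": dV * state.open, "dx_di": dx,
        "P_pl_top": diag["P_pl"], "Q_mouth": diag["Q_mouth"],
        "Q_mb": diag["Q_mb"], "V_med": diag["V_med"], "V_rc": diag["V_rc"],
    }


def layer_recruitment_update(state: MechState, params: PatientParams,
                             drive: DriveState | None = None) -> MechState:
    """Apply one recruitment/derecruitment hysteresis pass to every layer."""
    eng = Engine(params)
    drive_fn, _ = eng.standard_drive(drive or DriveState(0.0))
    flags, _ = eng.recruitment_flags(state.V_alv, state.x_di, state.open,
                                     state.V_pf, drive_fn, state.t)
    out = state.copy()
    out.open = flags
    return out


def _record(engine: Engine, state: MechState, drive: DriveState,
            n_breaths: int, dt_out: float, washin: int):
    p = engine.p
    drive_fn, phase_fn = engine.standard_drive(drive)
    total = (washin + n_breaths) * p.T_breath
    record_from = state.t + washin * p.T_breath
    out, samples = engine.integrate(state, total, drive_fn,
                                    record_from=record_from, dt_out=dt_out,
                                    phase_fn=phase_fn)
    arr = list(zip(*samples))
    kw = {c: np.asarray(arr[i]) for i, c in enumerate(_REC_COLUMNS)}
    kw["t"] = kw["t"] - kw["t"][0]
    # phase labels follow the mouth-flow sign (inspiration = inflow), i.e. the
    # loop endpoints sit at the volume extremes as on a clinical P-V loop
    kw["phase"] = np.where(kw["Q_mouth"] >= 0.0, "insp", "exp")
    rec = BreathRecording(T_breath=p.T_breath, n_breaths=n_breaths, **kw)
    return rec, out


def tidal_volume(rec: BreathRecording) -> float:
    """Mean per-breath inhaled volume (time integral of inspiratory mouth flow)."""
    vts = [np.trapezoid(np.maximum(rec.Q_mouth[s], 0.0), rec.t[s])
           for s in rec.breath_slices()]
    return float(np.mean(vts))


def breath_amplitude(rec: BreathRecording) -> float:
    """Mean per-breath peak-to-trough ipsilateral pleural pressure, kPa."""
    amps = [rec.P_pl_ipsi[s].max() - rec.P_pl_ipsi[s].min()
            for s in rec.breath_slices()]
    return float(np.mean(amps))


def simulate_breaths(params: PatientParams, V_pf: float, n_breaths: int = 5,
                     dt_out: float = 0.02, drive: DriveState | None = None,
                     state: MechState | None = None,
                     check_periodic: bool = True):
    """Simulate breathing at a fixed pleural fluid volume.

    Wash-in breaths are integrated and discarded first, then ``n_breaths``
    steady-state cycles are recorded on the ``dt_out`` grid.  When ``drive``
    is omitted the drive controller (:func:`adapt_drive_to_vt`) is run first
    so that tidal volume lands within 2% of ``VT_target``.

    Returns ``(BreathRecording, MechState)``; the returned state allows
    chaining (e.g. across thoracentesis aliquots).
    """
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    eng = Engine(params)
    if state is None:
        state = eng.static_state(V_pf)
    if drive is None:
        drive = adapt_drive_to_vt(params, V_pf, state=state)
    rec, out = _record(eng, state.copy(), drive, n_breaths, dt_out,
                       params.washin_breaths)
    if check_periodic and n_breaths >= 2:
        sl = rec.breath_slices()
        vt = [np.trapezoid(np.maximum(rec.Q_mouth[s], 0.0), rec.t[s]) for s in sl]
        frc = [min(rec.V_lung_ipsi[s][-1] + rec.V_lung_contra[s][-1], 1e9) for s in sl]
        dvt = abs(vt[-1] - vt[-2]) / max(vt[-1], 1e-9)
        dfrc = abs(frc[-1] - frc[-2]) / max(frc[-1], 1e-9)
        if dvt > 0.005 or dfrc > 0.005:
            raise SimulationError(
                f"breathing not periodic after wash-in: relative change per "
                f"cycle VT={dvt:.2%}, FRC={dfrc:.2%} (limit 0.5%)")
    return rec, out


def adapt_drive_to_vt(params: PatientParams, V_pf: float,
                      state: MechState | None = None,
                      amp0: float = 1.0, rtol: float = 0.02,
                      max_iter: int = 40) -> DriveState:
    """Scale the muscle-drive amplitude until tidal volume is within ``rtol``
    of ``VT_target``.  Deterministic fixed-point iteration on the amplitude
    (VT is nearly proportional to drive); raises when the amplitude bound is
    hit first, reporting the best-achieved VT.
    """
    eng = Engine(params)
    if state is None:
        state = eng.static_state(V_pf)
    amp = amp0
    best = (np.inf, 0.0, amp)
    for _ in range(max_iter):
        rec, _ = _record(eng, state.copy(), DriveState(amp), 1, 0.02, washin=2)
        vt = tidal_volume(rec)
        err = abs(vt - params.VT_target) / params.VT_target
        if err < best[0]:
            best = (err, vt, amp)
        if err <= rtol:
            return DriveState(amp, achieved_VT=vt)
        factor = params.VT_target / vt if vt > 1e-6 else 2.0
        amp *= float(np.clip(factor, 0.5, 2.0))
        if amp > params.drive_max:
            raise SimulationError(
                f"VT target {params.VT_target} L unreachable within drive bound "
                f"{params.drive_max} kPa; best achieved VT = {best[1]:.3f} L")
    raise SimulationError(
        f"drive controller did not converge in {max_iter} iterations; "
        f"best achieved VT = {best[1]:.3f} L at amplitude {best[2]:.2f} kPa")
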