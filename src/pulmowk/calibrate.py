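"""Two-nested-loop inverse calibration of wall stiffness and distal totals.

The outer loop adjusts the linearized wall stiffness E against the measured
relative area change (RAC); the inner loop, at fixed E, adjusts the distal
totals (R_T, C_T) against diastolic and pulse pressure.  Updates are
multiplicative fixed-point steps with the correct sensitivity sign:

    inner:  R_T ← R_T · (m_target − P_ref)/(m_model − P_ref),
            C_T ← C_T · (ΔP_model / ΔP_target)  (multiplicative baseline),
                  accelerated by a secant on log ΔP vs log C_T,
    outer:  E   ← E · (RAC_model / RAC_target)^α,

with m = (P_sys + 2 P_dias)/3 evaluated identically on targets and model
output (so a self-consistent target set is a fixed point), ΔP the pulse
pressure and α an under-relaxation exponent.

The pulse pressure is not globally monotone in C_T: with inertance on, a
large terminal compliance moves an inertance-compliance resonance of the
0D ladder through the heart-rate band, dΔP/dC_T changes sign, and a second
(spurious) root appears in which a frozen outlet capacitor reproduces the
same scalar pressures with an unphysiologically slow diastolic decay.
The search is therefore confined to the physical (monotone, fast-decay)
branch by capping C_T below the network's fundamental resonance, with the
cap computed from the tree's effective path inertance; within the branch a
measured-slope secant accelerates the multiplicative baseline and steps
are clipped to a factor of 4 per iteration.  The characteristic impedance
R_p and all segment pulse-wave speeds are re-derived from the current E at
every inner iteration, keeping the boundary-condition chain
self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import units
from .forward import HemodynamicSolution, SolverConfig, solve, tawss
from .stats import SubjectRecord
from .tree import VesselTree
from .waveforms import PressureSummary, Waveform, compute_features, regurgitant_volume
from .windkessel import (
    BloodProperties,
    TotalsEstimate,
    WallModel,
    initial_totals,
    proximal_impedance_for_tree,
    split_outlets,
)

__all__ = [
    "CalibrationTargets",
    "CalibrationConfig",
    "CalibratedModel",
    "CalibrationError",
    "calibrate",
    "subject_metrics",
]


class CalibrationError(RuntimeError):
    """Non-convergence or infeasible targets; carries the iteration log."""

    def __init__(self, message: str, log: list | None = None):
        super().__init__(message)
        self.log = log or []


@dataclass(frozen=True)
class CalibrationTargets:
    """Measured RAC and systolic/diastolic pressure the model must match (SI)."""

    rac: float
    p_sys: float
    p_dias: float

    def __post_init__(self) -> None:
        if self.rac <= 0:
            raise ValueError("RAC target must be positive (an exactly rigid wall "
                             "with nonzero pulse pressure is infeasible)")
        if not (self.p_sys > self.p_dias > 0):
            raise ValueError("require p_sys > p_dias > 0")

    @property
    def pulse(self) -> float:
        return self.p_sys - self.p_dias


@dataclass(frozen=True)
class CalibrationConfig:
    rel_tol: float = 0.01  # relative tolerance per target
    max_outer: int = 30
    max_inner: int = 30
    relaxation: float = 0.7  # α for the stiffness update
    e_init: float = 100e3  # Pa
    e_bounds: tuple = (5e3, 5e6)  # Pa
    rt_bounds: tuple = (1e5, 1e10)  # Pa·s/m³
    ct_bounds: tuple = (1e-12, 1e-6)  # m³/Pa
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        for lo, hi in (self.e_bounds, self.rt_bounds, self.ct_bounds):
            if not (0 < lo < hi):
                raise ValueError("parameter bounds must be positive and ordered")
        if not (0 < self.relaxation <= 1):
            raise ValueError("relaxation must lie in (0, 1]")


@dataclass
class CalibratedModel:
    elastic_modulus: float  # Pa
    r_total: float  # Pa·s/m³
    c_total: float  # m³/Pa
    outlets: list
    solution: HemodynamicSolution
    log: list  # one dict per forward evaluation
    residuals: dict  # final relative residuals per target


def _clinical_mean(p_sys: float, p_dias: float) -> float:
    return (p_sys + 2.0 * p_dias) / 3.0


def _effective_path_inertance(t: VesselTree, blood: BloodProperties, sid=None) -> float:
    """Root-to-outlet blood-column inertance, parallel over branches (Pa·s²/m³)."""
    seg = t.root if sid is None else t.segment(sid)
    own = blood.density * seg.length / (np.pi * seg.radius**2)
    children = t.children(seg.id)
    if not children:
        return own
    inv = sum(1.0 / _effective_path_inertance(t, blood, c.id) for c in children)
    return own + 1.0 / inv


def _resonance_cap(t: VesselTree, blood: BloodProperties, period: float) -> float:
    """Upper bound on C_T keeping the fundamental L-C resonance of the
    network well above the heart rate (factor 2 in frequency)."""
    omega1 = 2.0 * np.pi / period
    l_eff = _effective_path_inertance(t, blood)
    return 0.25 / (omega1**2 * l_eff)


def calibrate(
    t: VesselTree,
    inflow: Waveform,
    targets: CalibrationTargets,
    blood: BloodProperties | None = None,
    cfg: CalibrationConfig | None = None,
    wall_template: WallModel | None = None,
    p_init: PressureSummary | None = None,
    initial: tuple[float, float, float] | None = None,
) -> CalibratedModel:
    """Calibrate (E, R_T, C_T) so the forward model reproduces the targets.

    ``initial`` overrides the default start (E from ``cfg.e_init``; totals
    from the flow features and target pressures); ``wall_template`` carries
    the fixed wall settings (ν, thickness rule, ζ) whose E field is ignored.
    Deterministic: identical inputs produce identical logs.
    """
    blood = blood or BloodProperties()
    cfg = cfg or CalibrationConfig()
    wall_template = wall_template or WallModel(elastic_modulus=cfg.e_init)

    feats = compute_features(inflow)
    if feats.mean_flow <= 0:
        raise CalibrationError("inflow has nonpositive mean flow")

    if initial is not None:
        e_mod, r_t, c_t = initial
    else:
        guess = p_init or PressureSummary(
            p_sys=targets.p_sys,
            p_dias=targets.p_dias,
            p_mean=_clinical_mean(targets.p_sys, targets.p_dias),
        )
        tot = initial_totals(feats, guess)
        e_mod, r_t, c_t = cfg.e_init, tot.resistance, tot.compliance

    p_ref = cfg.solver.distal_pressure
    m_t = _clinical_mean(targets.p_sys, targets.p_dias) - p_ref
    if m_t <= 0:
        raise CalibrationError("target mean pressure must exceed the distal reference")
    dp_t = targets.pulse

    log: list[dict] = []
    sol = None
    outlets = None
    r_dias = r_dp = r_rac = np.inf

    def run(e, rt, ct):
        wall = replace(wall_template, elastic_modulus=e)
        prox = proximal_impedance_for_tree(t, wall, blood)
        outs = split_outlets(t, TotalsEstimate(rt, ct), prox)
        return outs, solve(t, wall, outs, inflow, blood, cfg.solver)

    max_step = np.log(4.0)  # per-iteration bound on |Δlog C_T|
    prev_ct = None  # (log C_T, log ΔP) of the previous inner iterate
    ct_lo = cfg.ct_bounds[0]
    ct_hi = min(cfg.ct_bounds[1], _resonance_cap(t, blood, inflow.period))
    if ct_hi <= ct_lo:
        raise CalibrationError("compliance bounds exclude the sub-resonance branch")
    c_t = float(np.clip(c_t, ct_lo, ct_hi))

    for outer in range(1, cfg.max_outer + 1):
        prev_rmax = None
        slow_count = 0
        for inner in range(1, cfg.max_inner + 1):
            outlets, sol = run(e_mod, r_t, c_t)
            ps = sol.mpa_pressure
            m_m = _clinical_mean(ps.p_sys, ps.p_dias) - p_ref
            r_dias = abs(ps.p_dias - targets.p_dias) / targets.p_dias
            r_dp = abs(ps.pulse - dp_t) / dp_t
            r_rac = abs(sol.mpa_area.rac - targets.rac) / targets.rac
            log.append(
                {
                    "outer": outer,
                    "inner": inner,
                    "E": e_mod,
                    "R_T": r_t,
                    "C_T": c_t,
                    "resid_dias": r_dias,
                    "resid_pulse": r_dp,
                    "resid_rac": r_rac,
                }
            )
            # exit on the residual contract, but polish toward the exact root
            # while the iterates still improve (the fixed point is residual 0);
            # a stall is two consecutive iterations with < 5% improvement
            r_max = max(r_dias, r_dp)
            slow_count = slow_count + 1 if (
                prev_rmax is not None and r_max > 0.95 * prev_rmax
            ) else 0
            prev_rmax = r_max
            if r_max <= cfg.rel_tol and (r_max <= cfg.rel_tol / 3.0 or slow_count >= 2):
                prev_ct = (np.log(c_t), np.log(ps.pulse))
                break
            r_t = float(np.clip(r_t * (m_t / m_m), *cfg.rt_bounds))
            # C_T update: secant on log ΔP(log C_T) when a usable negative
            # local slope is available, else the multiplicative (slope −1) rule
            lct, ldp = np.log(c_t), np.log(ps.pulse)
            step = ldp - np.log(dp_t)  # multiplicative: Δlog C_T = log(ΔP_m/ΔP_t)
            if prev_ct is not None:
                dlc = lct - prev_ct[0]
                dlp = ldp - prev_ct[1]
                if abs(dlc) > 1e-12 and dlp / dlc < -0.02:
                    step = (np.log(dp_t) - ldp) * (dlc / dlp)
            prev_ct = (lct, ldp)
            step = float(np.clip(step, -max_step, max_step))
            c_t = float(np.clip(np.exp(lct + step), ct_lo, ct_hi))
        if r_dias <= cfg.rel_tol and r_dp <= cfg.rel_tol and r_rac <= cfg.rel_tol:
            return CalibratedModel(
                elastic_modulus=e_mod,
                r_total=r_t,
                c_total=c_t,
                outlets=outlets,
                solution=sol,
                log=log,
                residuals={"rac": r_rac, "dias": r_dias, "pulse": r_dp},
            )
        e_new = e_mod * (sol.mpa_area.rac / targets.rac) ** cfg.relaxation
        e_mod = float(np.clip(e_new, *cfg.e_bounds))
        prev_ct = None  # stiffness changed: local pulse sensitivity is stale
        if e_mod in cfg.e_bounds and e_new != e_mod:
            # keep iterating at the bound; report it if we fail to converge
            pass

    raise CalibrationError(
        f"calibration did not converge within {cfg.max_outer} outer iterations "
        f"(residuals: RAC {r_rac:.3g}, P_dias {r_dias:.3g}, pulse {r_dp:.3g})",
        log,
    )


def subject_metrics(
    m: CalibratedModel,
    inflow: Waveform,
    subject_id: str = "subject",
    group: str = "control",
) -> SubjectRecord:
    """Assemble the per-subject marker record, in clinical units."""
    sol = m.solution
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        e_kpa=m.elastic_modulus / 1e3,
        rac=sol.mpa_area.rac,
        d_mm=sol.mpa_area.diameter * 1e3,
        rt_mmhg_min_per_l=units.resistance_to_clinical(m.r_total),
        ct_ml_per_mmhg=units.compliance_to_clinical(m.c_total),
        tawss_mpa_pa=tawss(sol, sol.blood, "MPA"),
        tawss_all_pa=tawss(sol, sol.blood, "all"),
        regurgitant_ml=units.m3_to_ml(regurgitant_volume(inflow)),
    )
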