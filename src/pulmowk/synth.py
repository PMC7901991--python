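"""Seeded synthetic subjects: flow waveforms, trees and calibration targets.

Two archetypes are emulated.  A control-like subject has a single half-sine
systolic lobe, a low smooth diastolic plateau, no retrograde flow, an MPA
diameter near 25 mm and a compliant wall (E ≈ 75 kPa) with distal totals
near R_T ≈ 4 mmHg·min/l, C_T ≈ 0.85 ml/mmHg.  A PAH-like subject has a
post-systolic negative (regurgitant) lobe whose volume grows with wall
stiffness, an MPA diameter near 32 mm, a stiff wall (E ≈ 300 kPa) and
remodelled totals (R_T ≈ 7 mmHg·min/l, C_T ≈ 0.13 ml/mmHg).

Each subject's calibration targets are produced by a forward run at the
true parameters, so the inverse pipeline can be scored against known ground
truth.  Everything is reproducible from (archetype, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import units
from .calibrate import CalibrationTargets
from .forward import SolverConfig, solve
from .tree import DEFAULT_THICKNESS_COEFF, VesselSegment, VesselTree
from .waveforms import Waveform, _lobe_volumes
from .windkessel import (
    BloodProperties,
    TotalsEstimate,
    WallModel,
    proximal_impedance_for_tree,
    split_outlets,
)

__all__ = [
    "SubjectArchetype",
    "SyntheticSubject",
    "CONTROL_CENTER",
    "PAH_CENTER",
    "make_waveform",
    "make_tree",
    "make_archetype",
    "make_cohort",
    "regurgitant_fraction_for_stiffness",
]


@dataclass(frozen=True)
class SubjectArchetype:
    """Ground-truth description of one synthetic subject (SI units)."""

    group: str  # 'control' or 'PAH'
    period: float  # cardiac period T, s
    stroke_volume: float  # forward volume per beat, m³
    systolic_fraction: float  # systolic lobe duration / T
    f_reg: float  # regurgitant volume / stroke volume
    mpa_diameter: float  # end-diastolic MPA diameter, m
    tree_depth: int  # bifurcation generations beyond the MPA
    e_true: float  # wall stiffness, Pa
    rt_true: float  # total distal resistance, Pa·s/m³
    ct_true: float  # total distal compliance, m³/Pa
    noise: float = 0.0  # multiplicative waveform noise level

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_reg < 0.5):
            raise ValueError("f_reg must lie in [0, 0.5)")
        for name in ("period", "stroke_volume", "systolic_fraction",
                     "mpa_diameter", "e_true", "rt_true", "ct_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tree_depth < 1:
            raise ValueError("tree_depth must be >= 1")


@dataclass
class SyntheticSubject:
    subject_id: str
    archetype: SubjectArchetype
    inflow: Waveform
    tree: VesselTree
    targets: CalibrationTargets
    truth: dict  # ground-truth record in clinical units
    seed: int


# Archetype centres: group medians / cohort means reported for PAH vs control
# (stiffness, distal totals, MPA diameter) and stroke volume / heart rate.
CONTROL_CENTER = dict(
    e_kpa=75.0,
    rt_clin=3.99,
    ct_clin=0.85,
    d_mm=25.0,
    sv_ml=69.0,
    heart_rate=81.0,
    f_reg=0.0,
)
PAH_CENTER = dict(
    e_kpa=300.0,
    rt_clin=6.89,
    ct_clin=0.13,
    d_mm=32.0,
    sv_ml=71.0,
    heart_rate=71.0,
)

# archetype dispersion (lognormal coefficients of variation)
CV_PARAMS = 0.15  # E, R_T, C_T
CV_DIAMETER = 0.06
CV_STROKE = 0.15
CV_PERIOD = 0.10

DEFAULT_SYSTOLIC_FRACTION = 0.35
REGURGITANT_FRACTION_OF_T = 0.15  # duration of the negative lobe / T
PLATEAU_VOLUME_FRACTION = 0.08  # diastolic plateau volume / stroke volume


def regurgitant_fraction_for_stiffness(e_pa: float) -> float:
    """Regurgitant fraction coupled linearly to the true stiffness.

    f_reg = 0.02 + 0.0004·(E/kPa − 100), clipped to [0, 0.3], so the
    stiffness-regurgitation association is a recoverable pipeline output
    rather than an assumption made downstream.
    """
    return float(np.clip(0.02 + 0.0004 * (e_pa / 1e3 - 100.0), 0.0, 0.3))


def _lognormal(rng: np.random.Generator, center: float, cv: float) -> float:
    if cv <= 0:
        return center
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(center * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def make_archetype(group: str, rng: np.random.Generator) -> SubjectArchetype:
    """Draw one archetype around the group centre with lognormal jitter."""
    if group == "control":
        c = CONTROL_CENTER
    elif group == "PAH":
        c = PAH_CENTER
    else:
        raise ValueError(f"unknown group {group!r}")
    e_true = _lognormal(rng, c["e_kpa"] * 1e3, CV_PARAMS)
    rt_true = _lognormal(rng, units.resistance_to_si(c["rt_clin"]), CV_PARAMS)
    ct_true = _lognormal(rng, units.compliance_to_si(c["ct_clin"]), CV_PARAMS)
    d = _lognormal(rng, c["d_mm"] * 1e-3, CV_DIAMETER)
    sv = _lognormal(rng, c["sv_ml"] * 1e-6, CV_STROKE)
    period = _lognormal(rng, 60.0 / c["heart_rate"], CV_PERIOD)
    f_reg = 0.0 if group == "control" else regurgitant_fraction_for_stiffness(e_true)
    return SubjectArchetype(
        group=group,
        period=period,
        stroke_volume=sv,
        systolic_fraction=DEFAULT_SYSTOLIC_FRACTION,
        f_reg=f_reg,
        mpa_diameter=d,
        tree_depth=2,
        e_true=e_true,
        rt_true=rt_true,
        ct_true=ct_true,
    )


def make_waveform(a: SubjectArchetype, seed: int | None = None, n: int = 256) -> Waveform:
    """Parametric one-cycle MPA inflow with exact lobe volumes.

    Half-sine systolic lobe over the systolic fraction, an optional
    post-systolic negative half-sine lobe, and a smooth raised-cosine
    diastolic plateau.  After optional multiplicative noise the positive
    and negative parts are rescaled separately so that the forward volume
    equals the stroke volume and the retrograde volume equals
    f_reg · stroke volume exactly (to quadrature tolerance).
    """
    T = a.period
    dt = T / n
    # snap phase boundaries onto the sample grid so that lobes begin and end
    # exactly at zero-valued samples; the separate positive/negative rescale
    # below is then exact even with multiplicative noise
    ts = max(round(a.systolic_fraction * T / dt), 2) * dt
    tr = max(round(REGURGITANT_FRACTION_OF_T * T / dt), 2) * dt if a.f_reg > 0 else 0.0
    t0 = ts + tr
    if t0 >= T:
        raise ValueError("systolic plus regurgitant phases exceed the period")

    t = np.arange(n) * dt
    q = np.zeros(n)

    sv = a.stroke_volume
    plateau_volume = PLATEAU_VOLUME_FRACTION * sv
    # systolic half-sine carrying the remaining forward volume
    q_peak = np.pi * (sv - plateau_volume) / (2.0 * ts)
    sys_mask = t < ts
    q[sys_mask] = q_peak * np.sin(np.pi * t[sys_mask] / ts)

    if a.f_reg > 0:
        q_reg = np.pi * (a.f_reg * sv) / (2.0 * tr)
        reg_mask = (t >= ts) & (t < t0)
        q[reg_mask] = -q_reg * np.sin(np.pi * (t[reg_mask] - ts) / tr)

    # raised-cosine plateau, zero at both junctions
    dia_mask = t >= t0
    q_plateau = 2.0 * plateau_volume / (T - t0)
    q[dia_mask] = 0.5 * q_plateau * (1.0 - np.cos(2.0 * np.pi * (t[dia_mask] - t0) / (T - t0)))

    if a.noise > 0:
        rng = np.random.default_rng(seed)
        q = q * (1.0 + a.noise * rng.standard_normal(n))

    w = Waveform(times=t, values=q, period=T, kind="flow", location="MPA")
    # rescale lobes separately to the exact target volumes
    pos, neg = _lobe_volumes(w)
    values = np.where(q >= 0, q * (sv / pos), q)
    if neg > 0:
        values = np.where(values < 0, values * (a.f_reg * sv / neg), values)
    return replace(w, values=values)


def make_tree(
    a: SubjectArchetype,
    seed: int | None = None,
    taper: float = 0.72,
    child_taper: float = 0.78,
    jitter: float = 0.05,
    thickness_coeff: float = DEFAULT_THICKNESS_COEFF,
) -> VesselTree:
    """Bifurcating proximal tree with the archetype's MPA diameter.

    LPA/RPA taper from the MPA; each further generation tapers from its
    parent with a seeded multiplicative area-ratio jitter.  Thickness is
    filled from the diameter-thickness rule.
    """
    rng = np.random.default_rng(seed)
    r_mpa = a.mpa_diameter / 2.0
    segments = [
        VesselSegment(id="MPA", name="MPA", parent=None, length=0.045, radius=r_mpa)
    ]
    outlet_sides: dict[str, str] = {}

    def jittered(base: float) -> float:
        return base * float(np.exp(jitter * rng.standard_normal()))

    current = []
    for side, name in (("left", "LPA"), ("right", "RPA")):
        seg = VesselSegment(
            id=name, name=name, parent="MPA", length=0.035, radius=jittered(taper * r_mpa)
        )
        segments.append(seg)
        current.append((seg, side))

    for gen in range(2, a.tree_depth + 1):
        nxt = []
        for parent, side in current:
            for k in (1, 2):
                seg = VesselSegment(
                    id=f"{parent.id}-{k}",
                    name="branch",
                    parent=parent.id,
                    length=0.7 * parent.length,
                    radius=jittered(child_taper * parent.radius),
                )
                segments.append(seg)
                nxt.append((seg, side))
        current = nxt

    for seg, side in current:
        outlet_sides[seg.id] = side

    t = VesselTree(segments=segments, outlet_sides=outlet_sides)
    t.fill_thickness(thickness_coeff)
    return t


def forward_targets(
    subject_tree: VesselTree,
    inflow: Waveform,
    a: SubjectArchetype,
    blood: BloodProperties | None = None,
    solver: SolverConfig | None = None,
) -> CalibrationTargets:
    """Forward-run the model at the true parameters and read off the targets."""
    blood = blood or BloodProperties()
    solver = solver or SolverConfig()
    wall = WallModel(elastic_modulus=a.e_true)
    prox = proximal_impedance_for_tree(subject_tree, wall, blood)
    outlets = split_outlets(subject_tree, TotalsEstimate(a.rt_true, a.ct_true), prox)
    sol = solve(subject_tree, wall, outlets, inflow, blood, solver)
    return CalibrationTargets(
        rac=sol.mpa_area.rac,
        p_sys=sol.mpa_pressure.p_sys,
        p_dias=sol.mpa_pressure.p_dias,
    )


def make_subject(
    group: str,
    subject_id: str,
    seed: int,
    blood: BloodProperties | None = None,
    solver: SolverConfig | None = None,
) -> SyntheticSubject:
    """One fully specified subject: archetype, inputs, targets, ground truth."""
    rng = np.random.default_rng(seed)
    a = make_archetype(group, rng)
    wf_seed, tree_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    inflow = make_waveform(a, seed=wf_seed)
    t = make_tree(a, seed=tree_seed)
    targets = forward_targets(t, inflow, a, blood, solver)
    truth = {
        "e_kpa": a.e_true / 1e3,
        "rt_mmhg_min_per_l": units.resistance_to_clinical(a.rt_true),
        "ct_ml_per_mmhg": units.compliance_to_clinical(a.ct_true),
        "d_mm": a.mpa_diameter * 1e3,
        "f_reg": a.f_reg,
        "stroke_volume_ml": units.m3_to_ml(a.stroke_volume),
        "rac_target": targets.rac,
        "p_sys_mmhg": units.pa_to_mmhg(targets.p_sys),
        "p_dias_mmhg": units.pa_to_mmhg(targets.p_dias),
    }
    return SyntheticSubject(
        subject_id=subject_id,
        archetype=a,
        inflow=inflow,
        tree=t,
        targets=targets,
        truth=truth,
        seed=seed,
    )


def make_cohort(
    n_control: int,
    n_pah: int,
    seed: int = 0,
    blood: BloodProperties | None = None,
    solver: SolverConfig | None = None,
) -> list[SyntheticSubject]:
    """A seeded cohort of control and PAH synthetic subjects."""
    if n_control < 1 or n_pah < 1:
        raise ValueError("need at least one subject per group")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_control + n_pah)
    subjects = []
    for i in range(n_control):
        subjects.append(
            make_subject("control", f"CTL-{i + 1}", int(seeds[i]), blood, solver)
        )
    for j in range(n_pah):
        subjects.append(
            make_subject("PAH", f"PAH-{j + 1}", int(seeds[n_control + j]), blood, solver)
        )
    return subjects
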