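"""Reduced-order (0D) compliant-vessel network forward model.

Each tree segment is represented by a Poiseuille resistance, a blood-column
inertance and a wall compliance obtained from the linearized pressure-area
law dA/dP = A/(ρ c²) integrated over the segment length, with c the
segment's own end-diastolic pulse-wave speed.  Segment compliances are
lumped half onto each end node (a π-ladder), the prescribed inflow drives
the root node, and each leaf couples to a three-element Windkessel (RCR)
outlet with a distal reference pressure.

The wall is viscoelastic: a fraction of each node's wall compliance
responds instantaneously and the rest through a Voigt-type series
resistance with relaxation time τ_w, which damps the ringing of the
otherwise lossless inertance-compliance ladder (an artifact a purely
elastic 0D wall would exhibit near the inflow's harmonic band).  Setting
τ_w = 0 recovers the purely elastic wall.

The resulting system is linear,  M ẋ = K x + f(t),  with states
[node pressures; branch flows; outlet capacitor pressures; retarded wall
pressures] and is advanced with a fixed-step trapezoidal scheme
(stiff-safe, second order) cycle by cycle until the MPA pressure trace is
periodic to a relative tolerance.

Areas follow A(t) = A_ed (1 + (P − P_ref)/(ρ c²)) per segment, with P_ref
the diastolic (minimum ≈ end-diastolic) pressure of the converged cycle,
so the end-diastolic area equals the reconstruction geometry exactly.
Wall shear stress uses the Poiseuille surrogate τ(t) = 4 μ |Q(t)|/(π r³).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import VesselTree, validate_tree
from .waveforms import PressureSummary, Waveform
from .windkessel import BloodProperties, WallModel, WindkesselOutlet, wave_speed

__all__ = [
    "SolverConfig",
    "SegmentState",
    "AreaSummary",
    "WSSSummary",
    "HemodynamicSolution",
    "ConvergenceError",
    "segment_elements",
    "solve",
    "tawss",
    "wss_summary",
    "area_summary",
    "volume_balance",
]


class ConvergenceError(RuntimeError):
    """Raised when the cycle-to-cycle periodicity tolerance is not met."""


@dataclass(frozen=True)
class SolverConfig:
    steps_per_cycle: int = 512
    max_cycles: int = 20
    cycle_tol: float = 1e-3  # relative periodicity drift of the MPA pressure
    use_inertance: bool = True
    distal_pressure: float = 0.0  # venous reference, Pa
    wall_damping_tau: float = 0.008  # Voigt wall relaxation time, s (0 = elastic)
    wall_damping_fraction: float = 0.5  # retarded fraction of wall compliance

    def __post_init__(self) -> None:
        if self.steps_per_cycle < 32:
            raise ValueError("steps_per_cycle must be >= 32")
        if self.max_cycles < 1 or self.cycle_tol <= 0:
            raise ValueError("invalid cycle controls")
        if self.wall_damping_tau < 0:
            raise ValueError("wall_damping_tau must be >= 0")
        if not (0.0 <= self.wall_damping_fraction < 1.0):
            raise ValueError("wall_damping_fraction must lie in [0, 1)")

    @property
    def damped(self) -> bool:
        return self.wall_damping_tau > 0 and self.wall_damping_fraction > 0


@dataclass
class SegmentState:
    """Final-cycle histories of one segment on the shared uniform grid."""

    pressure: np.ndarray  # at the segment's inlet node, Pa
    inflow: np.ndarray  # branch flow entering the segment, m³/s
    outflow: np.ndarray  # flow leaving to children / the outlet, m³/s
    area: np.ndarray  # linearized lumen area, m²


@dataclass(frozen=True)
class AreaSummary:
    a_max: float
    a_min: float
    rac: float  # (A_max − A_min)/A_min
    diameter: float  # end-diastolic MPA diameter, m


@dataclass(frozen=True)
class WSSSummary:
    per_segment: dict
    mpa: float
    entire: float


@dataclass
class HemodynamicSolution:
    times: np.ndarray
    segments: dict  # id -> SegmentState
    outlet_flows: dict  # outlet id -> flow history into the RCR, m³/s
    inflow: np.ndarray  # prescribed inflow sampled on the grid
    mpa_pressure: PressureSummary
    mpa_area: AreaSummary
    wss: WSSSummary
    cycles: int
    drift: float
    tree: VesselTree = field(repr=False, default=None)
    blood: BloodProperties = field(repr=False, default=None)
    config: SolverConfig = field(repr=False, default=None)
    storage_change: float = 0.0  # net capacitor volume change over the cycle


def segment_elements(
    seg, wall: WallModel, blood: BloodProperties
) -> tuple[float, float, float]:
    """(resistance, inertance, compliance) of one segment, SI units.

    R = 8 μ L / (π r⁴),  I = ρ L / (π r²),  C = A_ed L / (ρ c_ed²).
    """
    r, length = seg.radius, seg.length
    if r <= 0 or length <= 0:
        raise ValueError(f"segment {seg.id!r} has invalid geometry")
    h = wall.thickness_for(r, seg.thickness)
    c_ed = wave_speed(wall.elastic_modulus, h, seg.area, blood.density, wall.zeta)
    resistance = 8.0 * blood.viscosity * length / (np.pi * r**4)
    inertance = blood.density * length / (np.pi * r**2)
    compliance = seg.area * length / (blood.density * c_ed**2)
    return resistance, inertance, compliance


def _segment_wave_speed(seg, wall: WallModel, blood: BloodProperties) -> float:
    h = wall.thickness_for(seg.radius, seg.thickness)
    return wave_speed(wall.elastic_modulus, h, seg.area, blood.density, wall.zeta)


def solve(
    t: VesselTree,
    wall: WallModel,
    outlets: list[WindkesselOutlet],
    inflow: Waveform,
    blood: BloodProperties | None = None,
    config: SolverConfig | None = None,
) -> HemodynamicSolution:
    """Run the network to a periodic state and return final-cycle histories."""
    blood = blood or BloodProperties()
    config = config or SolverConfig()
    report = validate_tree(t)
    if report:
        raise ValueError("invalid tree: " + "; ".join(report))
    if inflow.kind != "flow":
        raise ValueError("inflow waveform must have kind='flow'")

    # breadth-first segment ordering from the root
    ordered = [t.root]
    k = 0
    while k < len(ordered):
        ordered.extend(t.children(ordered[k].id))
        k += 1
    seg_index = {s.id: i for i, s in enumerate(ordered)}
    n_seg = len(ordered)
    out_index = {o.outlet_id: j for j, o in enumerate(outlets)}
    if set(out_index) != set(t.outlet_sides):
        raise ValueError("outlets do not match the tree's outlet set")

    elements = [segment_elements(s, wall, blood) for s in ordered]

    # state layout: [root node, seg distal nodes..., outlet capacitor nodes...,
    #               branch flows (inertance on), retarded wall pressures (τ_w > 0)]
    n_tn = 1 + n_seg  # tree (vessel-wall) nodes
    n_nodes = n_tn + len(outlets)
    n_branch = n_seg if config.use_inertance else 0
    n_wall = n_tn if config.damped else 0
    n_states = n_nodes + n_branch + n_wall
    node_of = lambda i: 1 + i  # distal node of segment i
    cap_of = lambda j: n_tn + j
    wall_of = lambda nn: n_nodes + n_branch + nn

    wall_cap = np.zeros(n_tn)  # total wall compliance lumped at each tree node
    K = np.zeros((n_states, n_states))
    f_const = np.zeros(n_states)

    up_of = np.empty(n_seg, dtype=int)
    for i, s in enumerate(ordered):
        up = 0 if s.parent is None else node_of(seg_index[s.parent])
        dn = node_of(i)
        up_of[i] = up
        r_i, l_i, c_i = elements[i]
        wall_cap[up] += 0.5 * c_i
        wall_cap[dn] += 0.5 * c_i
        if config.use_inertance:
            qi = n_nodes + i
            K[up, qi] -= 1.0
            K[dn, qi] += 1.0
            K[qi, up] += 1.0
            K[qi, dn] -= 1.0
            K[qi, qi] -= r_i
        else:
            g = 1.0 / r_i
            K[up, up] -= g
            K[up, dn] += g
            K[dn, up] += g
            K[dn, dn] -= g

    for j, o in enumerate(outlets):
        ln = node_of(seg_index[o.outlet_id])
        cn = cap_of(j)
        g = 1.0 / o.r_proximal
        K[ln, ln] -= g
        K[ln, cn] += g
        K[cn, ln] += g
        K[cn, cn] -= g
        K[cn, cn] -= 1.0 / o.r_distal
        f_const[cn] += config.distal_pressure / o.r_distal

    # split each tree node's wall compliance into an instantaneous part and a
    # retarded (Voigt) part behind the wall relaxation resistance
    fr = config.wall_damping_fraction if config.damped else 0.0
    cap = np.zeros(n_nodes)  # instantaneous capacitance of the pressure nodes
    cap[:n_tn] = (1.0 - fr) * wall_cap
    for j, o in enumerate(outlets):
        cap[cap_of(j)] = o.compliance
    if config.damped:
        for nn in range(n_tn):
            wn = wall_of(nn)
            g = fr * wall_cap[nn] / config.wall_damping_tau  # 1/R_w
            K[nn, nn] -= g
            K[nn, wn] += g
            K[wn, nn] += g
            K[wn, wn] -= g

    mass = np.zeros(n_states)
    mass[:n_nodes] = cap
    if config.use_inertance:
        mass[n_nodes : n_nodes + n_seg] = [e[1] for e in elements]
    if config.damped:
        mass[n_nodes + n_branch :] = fr * wall_cap

    # trapezoidal stepping: (M/dt − K/2) x⁺ = (M/dt + K/2) x + (f_k + f_{k+1})/2
    n = config.steps_per_cycle
    dt = inflow.period / n
    grid = np.arange(n + 1) * dt
    q_in = np.asarray(inflow.sample(grid), dtype=float)

    lhs = np.diag(mass / dt) - 0.5 * K
    rhs = np.diag(mass / dt) + 0.5 * K
    prop = np.linalg.solve(lhs, rhs)
    forcing = np.tile(f_const[:, None], (1, n))
    forcing[0, :] += 0.5 * (q_in[:-1] + q_in[1:])
    # f enters averaged over the step; the constant part is already averaged
    step_src = np.linalg.solve(lhs, forcing)

    # warm start: uniform mean pressure, area-share branch flows
    r_parallel = 1.0 / sum(1.0 / (o.r_proximal + o.r_distal) for o in outlets)
    q_mean = float(np.trapezoid(q_in, grid) / inflow.period)
    p0 = config.distal_pressure + q_mean * r_parallel
    x = np.full(n_states, config.distal_pressure, dtype=float)
    x[:n_nodes] = p0
    if config.use_inertance:
        x[n_nodes : n_nodes + n_seg] = q_mean * _subtree_area_shares(t, ordered, seg_index)
    if config.damped:
        x[n_nodes + n_branch :] = p0

    trace = np.empty((n + 1, n_states))
    prev_root = None
    drift = np.inf
    cycles = 0
    for cycle in range(config.max_cycles):
        trace[0] = x
        for step in range(n):
            x = prop @ x + step_src[:, step]
            trace[step + 1] = x
        cycles = cycle + 1
        root = trace[:, 0]
        if prev_root is not None:
            denom = max(float(np.abs(prev_root).max()), 1.0)
            drift = float(np.abs(root - prev_root).max()) / denom
            if drift < config.cycle_tol:
                break
        prev_root = root.copy()
    if not drift < config.cycle_tol:
        raise ConvergenceError(
            f"periodicity drift {drift:.3e} above tolerance {config.cycle_tol:.1e} "
            f"after {cycles} cycles"
        )

    # -- final-cycle histories ---------------------------------------------
    rho = blood.density
    seg_states: dict[str, SegmentState] = {}
    flows = np.empty((n_seg, n + 1))
    for i, s in enumerate(ordered):
        if config.use_inertance:
            flows[i] = trace[:, n_nodes + i]
        else:
            flows[i] = (trace[:, up_of[i]] - trace[:, node_of(i)]) / elements[i][0]

    outlet_flow = {}
    for j, o in enumerate(outlets):
        ln = node_of(seg_index[o.outlet_id])
        outlet_flow[o.outlet_id] = (trace[:, ln] - trace[:, cap_of(j)]) / o.r_proximal

    for i, s in enumerate(ordered):
        p_in = trace[:, up_of[i]]
        # area follows the stored wall charge: instantaneous + retarded parts
        if config.damped:
            p_wall = trace[:, wall_of(up_of[i])]
            p_eff = (1.0 - fr) * p_in + fr * p_wall
        else:
            p_eff = p_in
        c_ed = _segment_wave_speed(s, wall, blood)
        p_ref = float(p_eff.min())
        area = s.area * (1.0 + (p_eff - p_ref) / (rho * c_ed**2))
        if np.any(area <= 0):
            raise ConvergenceError(f"negative lumen area in segment {s.id!r}")
        children = [seg_index[c.id] for c in t.children(s.id)]
        outflow = flows[children].sum(axis=0) if children else np.zeros(n + 1)
        if s.id in outlet_flow:
            outflow = outflow + outlet_flow[s.id]
        seg_states[s.id] = SegmentState(
            pressure=p_in.copy(), inflow=flows[i].copy(), outflow=outflow, area=area
        )

    root_p = trace[:, 0]
    mpa = ordered[0]
    mpa_area_hist = seg_states[mpa.id].area
    a_max, a_min = float(mpa_area_hist.max()), float(mpa_area_hist.min())
    summary = AreaSummary(
        a_max=a_max, a_min=a_min, rac=(a_max - a_min) / a_min, diameter=mpa.diameter
    )
    storage = float(np.dot(cap, trace[-1, :n_nodes] - trace[0, :n_nodes]))
    if config.damped:
        dw = trace[-1, n_nodes + n_branch :] - trace[0, n_nodes + n_branch :]
        storage += float(np.dot(fr * wall_cap, dw))

    sol = HemodynamicSolution(
        times=grid,
        segments=seg_states,
        outlet_flows=outlet_flow,
        inflow=q_in,
        mpa_pressure=PressureSummary.from_trace(grid, root_p),
        mpa_area=summary,
        wss=None,
        cycles=cycles,
        drift=drift,
        tree=t,
        blood=blood,
        config=config,
        storage_change=storage,
    )
    sol.wss = wss_summary(sol, blood)
    return sol


def _subtree_area_shares(t: VesselTree, ordered, seg_index) -> np.ndarray:
    """Fraction of total outlet area drained through each segment (warm start)."""
    share = np.zeros(len(ordered))
    total = sum(t.outlet_area(o) for o in t.outlet_sides)
    for i in reversed(range(len(ordered))):
        s = ordered[i]
        if s.id in t.outlet_sides:
            share[i] += t.outlet_area(s.id) / total
        if s.parent is not None:
            share[seg_index[s.parent]] += share[i]
    return share


def tawss(sol: HemodynamicSolution, blood: BloodProperties, subset: str = "MPA") -> float:
    """Luminal-area-weighted time-averaged wall shear stress of a subset (Pa).

    Per segment τ(t) = 4 μ |Q(t)| / (π r³) averaged over the cycle; the
    aggregate weights segments by their luminal surface area 2π r L.
    """
    if subset == "MPA":
        ids = [sol.tree.root.id]
    elif subset == "all":
        ids = [s.id for s in sol.tree.segments]
    else:
        raise ValueError("subset must be 'MPA' or 'all'")
    if not ids:
        raise ValueError("empty segment subset")
    period = sol.times[-1] - sol.times[0]
    num = den = 0.0
    for sid in ids:
        seg = sol.tree.segment(sid)
        q = sol.segments[sid].inflow
        tau = 4.0 * blood.viscosity * np.abs(q) / (np.pi * seg.radius**3)
        tavg = float(np.trapezoid(tau, sol.times) / period)
        w = 2.0 * np.pi * seg.radius * seg.length
        num += w * tavg
        den += w
    return num / den


def wss_summary(sol: HemodynamicSolution, blood: BloodProperties) -> WSSSummary:
    period = sol.times[-1] - sol.times[0]
    per = {}
    for sid, st in sol.segments.items():
        seg = sol.tree.segment(sid)
        tau = 4.0 * blood.viscosity * np.abs(st.inflow) / (np.pi * seg.radius**3)
        per[sid] = float(np.trapezoid(tau, sol.times) / period)
    return WSSSummary(
        per_segment=per,
        mpa=tawss(sol, blood, "MPA"),
        entire=tawss(sol, blood, "all"),
    )


def area_summary(sol: HemodynamicSolution) -> AreaSummary:
    """MPA area extrema and relative area change RAC = (A_max − A_min)/A_min."""
    return sol.mpa_area


def volume_balance(sol: HemodynamicSolution) -> tuple[float, float]:
    """(residual volume, residual / stroke volume) over the final cycle.

    Residual = inflow volume − Σ outlet volumes − capacitor storage change;
    small at periodicity, bounded by the quadrature error otherwise.
    """
    v_in = float(np.trapezoid(sol.inflow, sol.times))
    v_out = sum(float(np.trapezoid(q, sol.times)) for q in sol.outlet_flows.values())
    residual = v_in - v_out - sol.storage_change
    sv = float(np.trapezoid(np.clip(sol.inflow, 0.0, None), sol.times))
    return residual, residual / sv if sv > 0 else np.nan
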