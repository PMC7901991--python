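"""Three-element Windkessel (RCR) outlet parameters from totals and geometry.

Every outlet shares the proximal resistance R_p, taken as the characteristic
impedance of the MPA,

    R_p = ρ c_ed / A_MPA,          c_ed² = 2 E h / (3 ρ r_ed),

where c_ed is the Moens-Korteweg pulse-wave speed of an incompressible
(ν = 1/2) thin-walled linear-elastic tube evaluated at the end-diastolic
geometry.  The distal totals R_T and C_T are split assuming an equal
left/right flow split and, within a side, proportionally to each outlet's
share of that side's total outlet area:

    R_T^side = 2 R_T,  C_T^side = C_T / 2,
    1/R_t^i = (A_i / A_T^side) / (2 R_T),  C^i = (C_T/2)(A_i / A_T^side),
    R_d^i = R_t^i − R_p.

The parallel combination of all R_t^i recovers R_T exactly and Σ C^i = C_T.
Initial totals come from flow features and pressures:

    R_T = P̄ / Q̄,    C_T = (Q̇max − Q̇min) Δt / (P_sys − P_dias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tree import DEFAULT_THICKNESS_COEFF, VesselTree, thickness_from_diameter
from .waveforms import PressureSummary, WaveformFeatures

__all__ = [
    "BloodProperties",
    "WallModel",
    "ProximalImpedance",
    "TotalsEstimate",
    "WindkesselOutlet",
    "wave_speed",
    "characteristic_impedance",
    "initial_totals",
    "proximal_impedance_for_tree",
    "split_outlets",
]

# prefactor ζ in c² = ζ E h / (ρ r); 2/3 is the incompressible-membrane value
DEFAULT_ZETA = 2.0 / 3.0


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood: density ρ (kg/m³) and dynamic viscosity μ (Pa·s)."""

    density: float = 1060.0
    viscosity: float = 0.004

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class WallModel:
    """Linear isotropic elastic membrane wall.

    ν defaults to 0.5 (incompressible); the thickness coefficient feeds the
    diameter-thickness rule for segments without an explicit thickness.
    """

    elastic_modulus: float
    poisson_ratio: float = 0.5
    thickness_coeff: float = DEFAULT_THICKNESS_COEFF
    zeta: float = DEFAULT_ZETA

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0:
            raise ValueError("elastic modulus must be positive")
        if not (0.0 <= self.poisson_ratio <= 0.5 + 1e-12):
            raise ValueError("Poisson ratio must lie in [0, 0.5]")

    def thickness_for(self, radius: float, explicit: float | None = None) -> float:
        if explicit is not None:
            return explicit
        return thickness_from_diameter(2.0 * radius, self.thickness_coeff)


@dataclass(frozen=True)
class ProximalImpedance:
    """MPA pulse-wave speed, characteristic impedance and end-diastolic area."""

    wave_speed: float  # c_ed, m/s
    impedance: float  # R_p, Pa·s/m³
    mpa_area: float  # A_MPA(t_ed), m²

    def __post_init__(self) -> None:
        if self.wave_speed <= 0 or self.impedance <= 0 or self.mpa_area <= 0:
            raise ValueError("all proximal-impedance fields must be positive")


@dataclass(frozen=True)
class TotalsEstimate:
    """Total distal arterial resistance R_T (Pa·s/m³) and compliance C_T (m³/Pa)."""

    resistance: float
    compliance: float

    def __post_init__(self) -> None:
        if self.resistance <= 0 or self.compliance <= 0:
            raise ValueError("totals must be positive")


@dataclass(frozen=True)
class WindkesselOutlet:
    """Per-outlet RCR triple (SI units)."""

    outlet_id: str
    side: str
    r_proximal: float
    r_distal: float
    compliance: float

    @property
    def r_total(self) -> float:
        return self.r_proximal + self.r_distal


def wave_speed(
    elastic_modulus: float,
    thickness: float,
    area: float,
    density: float,
    zeta: float = DEFAULT_ZETA,
) -> float:
    """End-diastolic pulse-wave speed c_ed = sqrt(ζ E h / (ρ r_ed)), m/s.

    ``area`` is the end-diastolic lumen area; r_ed = sqrt(area/π).
    ζ = 2/3 gives the Moens-Korteweg speed with the ν = 1/2
    incompressibility correction 1/(1−ν²) = 4/3.
    """
    if min(elastic_modulus, thickness, area, density) <= 0:
        raise ValueError("all wave-speed inputs must be positive")
    r_ed = math.sqrt(area / math.pi)
    return math.sqrt(zeta * elastic_modulus * thickness / (density * r_ed))


def characteristic_impedance(density: float, c_ed: float, area: float) -> float:
    """Characteristic impedance R_p = ρ c_ed / A (Pa·s/m³)."""
    if min(density, c_ed, area) <= 0:
        raise ValueError("all characteristic-impedance inputs must be positive")
    return density * c_ed / area


def initial_totals(f: WaveformFeatures, p: PressureSummary) -> TotalsEstimate:
    """Seed totals R_T = P̄/Q̄ and C_T = (Q̇max − Q̇min)·Δt/ΔP."""
    if f.mean_flow <= 0:
        raise ValueError("mean flow must be positive")
    if p.pulse <= 0:
        raise ValueError("pulse pressure must be positive")
    r_t = p.p_mean / f.mean_flow
    c_t = (f.max_flow - f.min_flow) * f.delta_t / p.pulse
    return TotalsEstimate(resistance=r_t, compliance=c_t)


def proximal_impedance_for_tree(
    t: VesselTree, wall: WallModel, blood: BloodProperties
) -> ProximalImpedance:
    """R_p and c_ed evaluated at the MPA's end-diastolic geometry."""
    mpa = t.root
    h = wall.thickness_for(mpa.radius, mpa.thickness)
    c_ed = wave_speed(wall.elastic_modulus, h, mpa.area, blood.density, wall.zeta)
    return ProximalImpedance(
        wave_speed=c_ed,
        impedance=characteristic_impedance(blood.density, c_ed, mpa.area),
        mpa_area=mpa.area,
    )


def split_outlets(
    t: VesselTree, totals: TotalsEstimate, prox: ProximalImpedance
) -> list[WindkesselOutlet]:
    """Distribute (R_T, C_T) over the tree's outlets.

    Equal flow split between sides, then area-proportional conductance and
    compliance within each side; each outlet's proximal resistance is the
    shared characteristic impedance R_p and R_d^i = R_t^i − R_p.
    """
    outlets: list[WindkesselOutlet] = []
    for side in ("left", "right"):
        side_ids = [o for o, s in t.outlet_sides.items() if s == side]
        if not side_ids:
            raise ValueError(f"tree has no outlets on side {side!r}")
        a_side = sum(t.outlet_area(o) for o in side_ids)
        for o in side_ids:
            share = t.outlet_area(o) / a_side
            r_total_i = 2.0 * totals.resistance / share
            c_i = 0.5 * totals.compliance * share
            r_d = r_total_i - prox.impedance
            if r_d <= 0:
                raise ValueError(
                    f"outlet {o!r}: total resistance {r_total_i:.3e} does not exceed "
                    f"the characteristic impedance {prox.impedance:.3e}"
                )
            outlets.append(
                WindkesselOutlet(
                    outlet_id=o,
                    side=side,
                    r_proximal=prox.impedance,
                    r_distal=r_d,
                    compliance=c_i,
                )
            )
    return outlets


def rcr_input_impedance(outlet: WindkesselOutlet, omega: float) -> complex:
    """Closed-form input impedance of one RCR element at angular frequency ω.

    Z(ω) = R_p + R_d / (1 + jω R_d C).  Zero frequency gives R_p + R_d,
    the infinite-frequency limit is R_p. Used as an analytic oracle.
    """
    return outlet.r_proximal + outlet.r_distal / (
        1.0 + 1j * omega * outlet.r_distal * outlet.compliance
    )
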