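"""Proximal pulmonary-tree data model.

Segments carry end-diastolic geometry (radius, length) and a wall thickness;
outlets are leaf segments labelled by lung side. The wall thickness may be
filled from a configurable linear diameter-thickness rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = [
    "VesselSegment",
    "VesselTree",
    "thickness_from_diameter",
    "validate_tree",
    "read_tree_json",
    "write_tree_json",
]

DEFAULT_THICKNESS_COEFF = 0.05  # h = 0.05 * d, i.e. thickness = 10% of radius


def thickness_from_diameter(d: float, coefficient: float = DEFAULT_THICKNESS_COEFF) -> float:
    """Linear diameter-thickness rule h = coefficient * d (m).

    The proportionality stands in for the published human-PA
    diameter-thickness relationship, whose coefficients are configurable
    rather than hard-coded; downstream the calibration adjusts E, so the
    product E*h acts as the effective stiffness.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    if not (0.0 < coefficient < 0.5):
        raise ValueError("coefficient must lie in (0, 0.5)")
    return coefficient * d


@dataclass
class VesselSegment:
    """One vessel segment with end-diastolic geometry (SI units)."""

    id: str
    name: str  # one of MPA, LPA, RPA, branch
    parent: str | None
    length: float
    radius: float  # end-diastolic inner radius
    thickness: float | None = None

    @property
    def area(self) -> float:
        """End-diastolic cross-sectional area π r² (m²)."""
        return math.pi * self.radius**2

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class VesselTree:
    """Bifurcating tree rooted at the MPA with side-labelled outlets.

    ``outlet_sides`` maps leaf segment ids to 'left' / 'right'.
    ``side_areas`` optionally stores per-side total outlet areas; when
    absent they are computed from the outlet geometry (and are then
    consistent by construction).
    """

    segments: list[VesselSegment]
    outlet_sides: dict[str, str]
    side_areas: dict[str, float] | None = None
    _by_id: dict[str, VesselSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {s.id: s for s in self.segments}
        if len(self._by_id) != len(self.segments):
            raise ValueError("duplicate segment ids")

    # -- topology ------------------------------------------------------------

    def segment(self, sid: str) -> VesselSegment:
        return self._by_id[sid]

    def children(self, sid: str) -> list[VesselSegment]:
        return [s for s in self.segments if s.parent == sid]

    @property
    def root(self) -> VesselSegment:
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    @property
    def leaves(self) -> list[VesselSegment]:
        has_child = {s.parent for s in self.segments if s.parent is not None}
        return [s for s in self.segments if s.id not in has_child]

    @property
    def outlets(self) -> list[str]:
        return list(self.outlet_sides)

    def outlet_area(self, sid: str) -> float:
        return self.segment(sid).area

    def side_outlet_area(self, side: str) -> float:
        """Total outlet area A_T of one side, Σ π r_i² over that side's outlets."""
        if self.side_areas is not None and side in self.side_areas:
            return self.side_areas[side]
        return sum(self.outlet_area(o) for o, s in self.outlet_sides.items() if s == side)

    def fill_thickness(self, coefficient: float = DEFAULT_THICKNESS_COEFF) -> None:
        """Fill missing wall thicknesses from the diameter-thickness rule."""
        for s in self.segments:
            if s.thickness is None:
                s.thickness = thickness_from_diameter(s.diameter, coefficient)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "segments": [
                {
                    "id": s.id,
                    "name": s.name,
                    "parent": s.parent,
                    "length_m": s.length,
                    "radius_m": s.radius,
                    "thickness_m": s.thickness,
                }
                for s in self.segments
            ],
            "outlets": [{"id": o, "side": side} for o, side in self.outlet_sides.items()],
        }
        if self.side_areas is not None:
            d["side_areas_m2"] = dict(self.side_areas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VesselTree":
        segments = [
            VesselSegment(
                id=str(s["id"]),
                name=s.get("name", "branch"),
                parent=(None if s.get("parent") in (None, "") else str(s["parent"])),
                length=float(s["length_m"]),
                radius=float(s["radius_m"]),
                thickness=(None if s.get("thickness_m") is None else float(s["thickness_m"])),
            )
            for s in d["segments"]
        ]
        outlet_sides = {str(o["id"]): str(o["side"]) for o in d["outlets"]}
        side_areas = d.get("side_areas_m2")
        if side_areas is not None:
            side_areas = {str(k): float(v) for k, v in side_areas.items()}
        return cls(segments=segments, outlet_sides=outlet_sides, side_areas=side_areas)


def validate_tree(t: VesselTree) -> list[str]:
    """Report violated structural invariants (empty list = valid tree)."""
    report: list[str] = []
    ids = {s.id for s in t.segments}

    roots = [s for s in t.segments if s.parent is None]
    if len(roots) != 1:
        report.append(f"expected exactly one root segment, found {len(roots)}")
    elif roots[0].name != "MPA":
        report.append(f"root segment {roots[0].id!r} is not named MPA")

    for s in t.segments:
        if s.parent is not None and s.parent not in ids:
            report.append(f"segment {s.id!r} has unknown parent {s.parent!r} (orphan)")
        if s.radius <= 0:
            report.append(f"segment {s.id!r} has nonpositive radius")
        if s.length <= 0:
            report.append(f"segment {s.id!r} has nonpositive length")
        if s.thickness is not None and not (0.0 < s.thickness < s.radius):
            report.append(f"segment {s.id!r} thickness must lie in (0, radius)")

    # LPA/RPA, when present, must be children of the MPA
    if len(roots) == 1:
        root_id = roots[0].id
        for s in t.segments:
            if s.name in ("LPA", "RPA") and s.parent != root_id:
                report.append(f"{s.name} segment {s.id!r} is not a child of the MPA")

    # reachability from the root
    if len(roots) == 1:
        reached = {roots[0].id}
        frontier = [roots[0].id]
        while frontier:
            nxt = [c.id for p in frontier for c in t.children(p)]
            frontier = [i for i in nxt if i not in reached]
            reached.update(frontier)
        unreachable = ids - reached
        for sid in sorted(unreachable):
            report.append(f"segment {sid!r} is not reachable from the root")

    leaf_ids = {s.id for s in t.leaves}
    for o, side in t.outlet_sides.items():
        if o not in ids:
            report.append(f"outlet {o!r} is not a segment")
        elif o not in leaf_ids:
            report.append(f"outlet {o!r} is not a leaf segment")
        if side not in ("left", "right"):
            report.append(f"outlet {o!r} has invalid side {side!r}")
    for side in ("left", "right"):
        if not any(s == side for s in t.outlet_sides.values()):
            report.append(f"side {side!r} has no outlets")

    if t.side_areas is not None:
        for side, stored in t.side_areas.items():
            computed = sum(
                t.outlet_area(o) for o, s in t.outlet_sides.items() if s == side and o in ids
            )
            if not math.isclose(stored, computed, rel_tol=1e-12, abs_tol=0.0):
                report.append(
                    f"stored total outlet area for side {side!r} ({stored:.6e} m²) "
                    f"differs from the sum of outlet areas ({computed:.6e} m²)"
                )
    return report


def write_tree_json(t: VesselTree, path) -> None:
    with open(path, "w") as fh:
        json.dump(t.to_dict(), fh, indent=2)


def read_tree_json(path) -> VesselTree:
    with open(path) as fh:
        return VesselTree.from_dict(json.load(fh))
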