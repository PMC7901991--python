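import dataclasses
import math

import numpy as np
import pytest

from pulmowk import units
from pulmowk.forward import (
    SolverConfig,
    segment_elements,
    solve,
    tawss,
    volume_balance,
)
from pulmowk.tree import VesselSegment, VesselTree
from pulmowk.waveforms import Waveform
from pulmowk.windkessel import (
    TotalsEstimate,
    WallModel,
    WindkesselOutlet,
    proximal_impedance_for_tree,
    rcr_input_impedance,
    split_outlets,
)


def constant_inflow(q, period=0.8, n=64):
    t = np.arange(n) * (period / n)
    return Waveform(times=t, values=np.full(n, q), period=period)


def outlets_for(tree, wall, blood, rt, ct):
    prox = proximal_impedance_for_tree(tree, wall, blood)
    return split_outlets(tree, TotalsEstimate(rt, ct), prox)


class TestSegmentElements:
    def test_control_mpa_compliance_value(self, blood):
        seg = VesselSegment(
            id="s", name="MPA", parent=None, length=0.05, radius=0.0125, thickness=1.5e-3
        )
        wall = WallModel(elastic_modulus=75e3)
        r, l, c = segment_elements(seg, wall, blood)
        c2 = 2 * 75e3 * 1.5e-3 / (3 * 1060 * 0.0125)
        assert c == pytest.approx(seg.area * 0.05 / (1060 * c2), rel=1e-12)
        assert c == pytest.approx(4.09e-9, rel=0.01)
        assert r == pytest.approx(8 * blood.viscosity * 0.05 / (math.pi * 0.0125**4))
        assert l == pytest.approx(1060 * 0.05 / (math.pi * 0.0125**2))

    def test_linear_in_length(self, blood):
        wall = WallModel(elastic_modulus=75e3)
        seg1 = VesselSegment("a", "branch", None, 0.02, 0.006, 0.6e-3)
        seg2 = dataclasses.replace(seg1, length=0.04)
        e1, e2 = segment_elements(seg1, wall, blood), segment_elements(seg2, wall, blood)
        for a, b in zip(e1, e2):
            assert b == pytest.approx(2 * a)

    def test_radius_power_laws(self, blood):
        wall = WallModel(elastic_modulus=75e3)
        seg1 = VesselSegment("a", "branch", None, 0.02, 0.006)
        seg2 = dataclasses.replace(seg1, radius=0.012)
        r1, l1, _ = segment_elements(seg1, wall, blood)
        r2, l2, _ = segment_elements(seg2, wall, blood)
        assert r2 == pytest.approx(r1 / 16)
        assert l2 == pytest.approx(l1 / 4)


class TestSteadyState:
    def test_mean_pressure_recovers_total_resistance(self, blood):
        # short, wide tree: viscous segment drop is negligible next to R_T
        segs = [
            VesselSegment("MPA", "MPA", None, 0.02, 0.0125),
            VesselSegment("LPA", "LPA", "MPA", 0.015, 0.009),
            VesselSegment("RPA", "RPA", "MPA", 0.015, 0.009),
        ]
        t = VesselTree(segs, {"LPA": "left", "RPA": "right"})
        t.fill_thickness()
        wall = WallModel(elastic_modulus=100e3)
        rt = units.resistance_to_si(6.0)
        q0 = 8e-5
        sol = solve(t, wall, outlets_for(t, wall, blood, rt, 5e-9),
                    constant_inflow(q0), blood)
        assert sol.mpa_pressure.p_mean == pytest.approx(q0 * rt, rel=1e-3)

    def test_zero_inflow_relaxes_to_reference(self, blood, tree3):
        wall = WallModel(elastic_modulus=100e3)
        pref = units.mmhg_to_pa(5.0)
        cfg = SolverConfig(distal_pressure=pref)
        sol = solve(tree3, wall, outlets_for(tree3, wall, blood, 3.2e7, 5e-9),
                    constant_inflow(0.0), blood, cfg)
        assert sol.mpa_pressure.p_mean == pytest.approx(pref, rel=1e-6)
        assert sol.mpa_area.rac == pytest.approx(0.0, abs=1e-9)


class TestClosedFormWindkessel:
    def test_sinusoidal_drive_matches_rcr_response(self, blood):
        # near-rigid short segments so the MPA pressure is the response of the
        # two identical RCR outlets in parallel
        segs = [
            VesselSegment("MPA", "MPA", None, 0.01, 0.0125),
            VesselSegment("LPA", "LPA", "MPA", 0.008, 0.009),
            VesselSegment("RPA", "RPA", "MPA", 0.008, 0.009),
        ]
        t = VesselTree(segs, {"LPA": "left", "RPA": "right"})
        t.fill_thickness()
        wall = WallModel(elastic_modulus=1e8)
        rt, ct = 3.2e7, 6e-9
        outs = [
            WindkesselOutlet(sid, side, r_proximal=5e6, r_distal=2 * rt - 5e6,
                             compliance=ct / 2)
            for sid, side in (("LPA", "left"), ("RPA", "right"))
        ]
        period = 0.8
        omega = 2 * math.pi / period
        q_mean, q_amp = 8e-5, 5e-5
        n = 256
        tt = np.arange(n) * (period / n)
        inflow = Waveform(times=tt, values=q_mean + q_amp * np.sin(omega * tt), period=period)
        cfg = SolverConfig(use_inertance=False, max_cycles=40)
        sol = solve(t, wall, outs, inflow, blood, cfg)

        z_par = 1.0 / sum(1.0 / rcr_input_impedance(o, omega) for o in outs)
        z_dc = 1.0 / sum(1.0 / (o.r_proximal + o.r_distal) for o in outs)
        p_exact = q_mean * z_dc + np.imag(q_amp * z_par * np.exp(1j * omega * sol.times))
        p_model = sol.segments["MPA"].pressure
        err = np.max(np.abs(p_model - p_exact)) / np.max(np.abs(p_exact))
        assert err < 0.01


class TestWallShearStress:
    def test_steady_poiseuille_value(self, blood):
        segs = [
            VesselSegment("MPA", "MPA", None, 0.02, 0.0125),
            VesselSegment("LPA", "LPA", "MPA", 0.015, 0.009),
            VesselSegment("RPA", "RPA", "MPA", 0.015, 0.009),
        ]
        t = VesselTree(segs, {"LPA": "left", "RPA": "right"})
        t.fill_thickness()
        wall = WallModel(elastic_modulus=100e3)
        q0 = 100e-6
        sol = solve(t, wall, outlets_for(t, wall, blood, 3.2e7, 5e-9),
                    constant_inflow(q0), blood)
        expected = 4 * blood.viscosity * q0 / (math.pi * 0.0125**3)
        assert expected == pytest.approx(0.26, rel=0.02)
        assert tawss(sol, blood, "MPA") == pytest.approx(expected, rel=1e-3)

    def test_single_segment_subset_equals_weighting_identity(self, blood, tree3):
        wall = WallModel(elastic_modulus=100e3)
        sol = solve(tree3, wall, outlets_for(tree3, wall, blood, 3.2e7, 5e-9),
                    constant_inflow(8e-5), blood)
        assert tawss(sol, blood, "MPA") == pytest.approx(sol.wss.per_segment["MPA"])

    def test_cubic_radius_law(self, blood):
        results = {}
        for scale in (1.0, 2.0):
            segs = [
                VesselSegment("MPA", "MPA", None, 0.02, 0.0125 * scale),
                VesselSegment("LPA", "LPA", "MPA", 0.015, 0.009 * scale),
                VesselSegment("RPA", "RPA", "MPA", 0.015, 0.009 * scale),
            ]
            t = VesselTree(segs, {"LPA": "left", "RPA": "right"})
            t.fill_thickness()
            wall = WallModel(elastic_modulus=100e3)
            sol = solve(t, wall, outlets_for(t, wall, blood, 3.2e7, 5e-9),
                        constant_inflow(8e-5), blood)
            results[scale] = tawss(sol, blood, "MPA")
        assert results[2.0] == pytest.approx(results[1.0] / 8, rel=1e-3)

    def test_invalid_subset_rejected(self, blood, tree3):
        wall = WallModel(elastic_modulus=100e3)
        sol = solve(tree3, wall, outlets_for(tree3, wall, blood, 3.2e7, 5e-9),
                    constant_inflow(8e-5), blood)
        with pytest.raises(ValueError):
            tawss(sol, blood, "distal-only")


class TestPhysicalInvariants:
    def test_cycle_volume_conservation(self, blood, tree5, control_inflow, control_archetype):
        wall = WallModel(elastic_modulus=control_archetype.e_true)
        sol = solve(tree5, wall,
                    outlets_for(tree5, wall, blood, control_archetype.rt_true,
                                control_archetype.ct_true),
                    control_inflow, blood)
        _, rel = volume_balance(sol)
        assert abs(rel) < 0.005

    def test_rac_non_increasing_in_stiffness(self, blood, tree5, control_inflow,
                                             control_archetype):
        racs = []
        for e in (75e3, 150e3, 300e3):
            wall = WallModel(elastic_modulus=e)
            sol = solve(tree5, wall,
                        outlets_for(tree5, wall, blood, control_archetype.rt_true,
                                    control_archetype.ct_true),
                        control_inflow, blood)
            racs.append(sol.mpa_area.rac)
        assert racs[0] >= racs[1] >= racs[2]
        assert racs[2] < 0.6 * racs[0]  # strongly stiffness-controlled

    def test_pulse_non_increasing_in_total_compliance(self, blood, tree5, control_inflow):
        wall = WallModel(elastic_modulus=150e3)
        pulses = []
        for ct in (2e-9, 4e-9, 8e-9):
            sol = solve(tree5, wall, outlets_for(tree5, wall, blood, 3.2e7, ct),
                        control_inflow, blood)
            pulses.append(sol.mpa_pressure.pulse)
        assert pulses[0] >= pulses[1] >= pulses[2]

    def test_rigid_limit_has_vanishing_rac(self, blood, tree5, control_inflow):
        # outlets fixed directly: at this stiffness the characteristic
        # impedance would exceed the per-outlet totals
        wall = WallModel(elastic_modulus=1e8)
        outs = [
            WindkesselOutlet(sid, side, r_proximal=5e6, r_distal=2 * 3.2e7 - 5e6,
                             compliance=2.5e-9)
            for sid, side in (("L1", "left"), ("R1", "right"))
        ]
        sol = solve(tree5, wall, outs, control_inflow, blood)
        assert sol.mpa_area.rac < 1e-3

    def test_grid_convergence(self, blood, tree5, control_inflow, control_archetype):
        wall = WallModel(elastic_modulus=control_archetype.e_true)
        outs = outlets_for(tree5, wall, blood, control_archetype.rt_true,
                           control_archetype.ct_true)
        vals = {}
        for n in (512, 1024):
            cfg = SolverConfig(steps_per_cycle=n)
            sol = solve(tree5, wall, outs, control_inflow, blood, cfg)
            vals[n] = (sol.mpa_pressure.p_sys, sol.mpa_pressure.p_dias, sol.mpa_area.rac)
        for a, b in zip(vals[512], vals[1024]):
            assert abs(a / b - 1) < 0.005
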