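"""Unit conversions between SI internals and clinical reporting units.

All model code works in strict SI (Pa, m³/s, Pa·s/m³, m³/Pa, s). Clinical
layers report pressure in mmHg, flow in l/min, resistance in mmHg·min/l,
compliance in ml/mmHg and wall shear stress in Pa (dyn/cm² = 10 × Pa).
"""

MMHG = 133.322  # Pa per mmHg

# 1 mmHg·min/l in Pa·s/m³
RESISTANCE_CLINICAL = MMHG * 60.0 / 1e-3
# 1 ml/mmHg in m³/Pa
COMPLIANCE_CLINICAL = 1e-6 / MMHG
# 1 l/min in m³/s
FLOW_CLINICAL = 1e-3 / 60.0


def mmhg_to_pa(p: float) -> float:
    return p * MMHG


def pa_to_mmhg(p: float) -> float:
    return p / MMHG


def resistance_to_si(r_clin: float) -> float:
    """mmHg·min/l -> Pa·s/m³."""
    return r_clin * RESISTANCE_CLINICAL


def resistance_to_clinical(r_si: float) -> float:
    """Pa·s/m³ -> mmHg·min/l."""
    return r_si / RESISTANCE_CLINICAL


def compliance_to_si(c_clin: float) -> float:
    """ml/mmHg -> m³/Pa."""
    return c_clin * COMPLIANCE_CLINICAL


def compliance_to_clinical(c_si: float) -> float:
    """m³/Pa -> ml/mmHg."""
    return c_si / COMPLIANCE_CLINICAL


def flow_to_si(q_lmin: float) -> float:
    """l/min -> m³/s."""
    return q_lmin * FLOW_CLINICAL


def flow_to_clinical(q_si: float) -> float:
    """m³/s -> l/min."""
    return q_si / FLOW_CLINICAL


def ml_to_m3(v: float) -> float:
    return v * 1e-6


def m3_to_ml(v: float) -> float:
    return v * 1e6


def pa_to_dyncm2(tau: float) -> float:
    return tau * 10.0
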