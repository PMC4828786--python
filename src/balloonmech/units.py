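"""Unit conversions.

The mechanics core works in a consistent mm / N / MPa system (so volumes
are mm^3 and pressures MPa).  Interfaces exchange the units customary in
the catheterisation lab: mmHg for pressure, ml for volume, mm for length.
"""

MMHG_PER_ATM = 760.0
PA_PER_MMHG = 133.322
MPA_PER_MMHG = PA_PER_MMHG * 1e-6
MM3_PER_ML = 1000.0


def mmhg_to_mpa(p_mmhg):
    return p_mmhg * MPA_PER_MMHG


def mpa_to_mmhg(p_mpa):
    return p_mpa / MPA_PER_MMHG


def atm_to_mmhg(p_atm):
    return p_atm * MMHG_PER_ATM


def ml_to_mm3(v_ml):
    return v_ml * MM3_PER_ML


def mm3_to_ml(v_mm3):
    return v_mm3 / MM3_PER_ML


def per_mpa_to_per_mmhg(d_per_mpa):
    """Convert a distensibility-like quantity from MPa^-1 to mmHg^-1."""
    return d_per_mpa * MPA_PER_MMHG
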