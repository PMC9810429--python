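"""Unit system and physical constants.

Internal unit system is mm-g-s:

* length  mm
* mass    g
* time    s
* force   g mm s^-2  = microNewton (uN)
* stress  g mm^-1 s^-2 = Pascal (Pa)
* density g mm^-3

The pleasant coincidence that the mm-g-s stress unit *is* the Pascal means
material moduli and strengths can be carried in Pa without conversion.
Public interfaces report forces in N and speeds in m/s; helpers below
convert at the boundary.
"""

#: gravitational acceleration, mm s^-2
GRAVITY = 9810.0

#: air density, g mm^-3 (1.225 kg m^-3)
RHO_AIR = 1.225e-6

#: default stem tissue density, g mm^-3
RHO_STEM = 3.0e-4

#: kinematic viscosity of air at ~20 C, mm^2 s^-1 (1.51e-5 m^2 s^-1)
NU_AIR = 15.1

UN_PER_N = 1.0e6
MM_S_PER_M_S = 1.0e3


def n_from_un(force_un: float) -> float:
    """Convert a force from uN (internal) to N (interface)."""
    return force_un / UN_PER_N


def un_from_n(force_n: float) -> float:
    """Convert a force from N (interface) to uN (internal)."""
    return force_n * UN_PER_N


def mm_s_from_m_s(speed_m_s: float) -> float:
    """Convert a speed from m/s (interface) to mm/s (internal)."""
    return speed_m_s * MM_S_PER_M_S


def m_s_from_mm_s(speed_mm_s: float) -> float:
    """Convert a speed from mm/s (internal) to m/s (interface)."""
    return speed_mm_s / MM_S_PER_M_S
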