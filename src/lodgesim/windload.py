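"""External forcing: upper-plant weight, panicle drag, wind protocol, Reynolds.

Only the panicle carries drag by default; the stem's own frontal area is
neglected (it is small and sits inside the floor boundary layer).  A config
flag on :func:`panicle_drag` callers can add distributed stem drag for
sensitivity studies via :func:`stem_drag_per_length`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .morphotypes import Panicle, PlantMorphology

__all__ = [
    "WindCase",
    "LoadSet",
    "upper_plant_weight",
    "panicle_drag",
    "wind_protocol",
    "protocol_segments",
    "reynolds",
    "build_loadset",
]


#: (t_start, t_end, speed at start, speed at end) in seconds / m s^-1.
#: 50 s plateaus at 4, 8, 12 m/s, 5 s linear ramps, deceleration to 4 m/s,
#: stop at 2 min 50 s; camera runs to 3 min 5 s.
_PROTOCOL = (
    (0.0, 50.0, 4.0, 4.0),
    (50.0, 55.0, 4.0, 8.0),
    (55.0, 105.0, 8.0, 8.0),
    (105.0, 110.0, 8.0, 12.0),
    (110.0, 160.0, 12.0, 12.0),
    (160.0, 165.0, 12.0, 4.0),
    (165.0, 170.0, 4.0, 4.0),
)

VIDEO_SPAN_S = 185.0


@dataclass(frozen=True)
class WindCase:
    """A wind condition: steady speed (internal mm/s) plus the tunnel protocol."""

    v_w: float  # mm s^-1
    rho_a: float = units.RHO_AIR  # g mm^-3
    protocol: tuple = _PROTOCOL

    def __post_init__(self) -> None:
        if self.v_w < 0:
            raise ValueError("wind speed must be >= 0")
        last_end = -np.inf
        for t0, t1, *_ in self.protocol:
            if t1 <= t0 or t0 < last_end:
                raise ValueError("protocol segments must be time-ordered, non-overlapping")
            last_end = t1

    @classmethod
    def from_m_s(cls, v_m_s: float, **kwargs) -> "WindCase":
        return cls(v_w=units.mm_s_from_m_s(v_m_s), **kwargs)


@dataclass(frozen=True)
class LoadSet:
    """External loads on the modelled (two lowermost internodes) stem part.

    Forces in uN, moment in uN mm, body force density in uN mm^-3.
    """

    W_u: float
    F_w0: float
    M_w0: float
    G: float = units.RHO_STEM * units.GRAVITY
    g: float = units.GRAVITY

    def __post_init__(self) -> None:
        for name in ("W_u", "F_w0", "M_w0", "G", "g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def upper_plant_weight(morphology: PlantMorphology) -> float:
    """Weight of the unmodelled upper plant (panicle + internodes 3, 4), uN.

    W_u = g (m_p + rho pi sum_{i=3,4} L_i t_i (2 r_i - t_i)).
    """
    g = units.GRAVITY
    rho = morphology.stem_density
    tube = sum(
        inode.length * inode.wall_thickness
        * (2.0 * inode.outer_radius - inode.wall_thickness)
        for inode in morphology.internodes[2:4]
    )
    return g * (morphology.panicle.mass + rho * np.pi * tube)


def panicle_drag(
    case: WindCase, panicle: Panicle, L3: float, L4: float
) -> tuple[float, float]:
    """Panicle drag force and its moment about the top of internode 2.

    F_w0 = 1/2 rho_a A_p C_dp v_w^2 (uN); M_w0 = F_w0 (L3 + L4 + h_p / 2)
    (uN mm) — the parenthesis is the lever arm from the modelled part's top
    node to the panicle mid-height.
    """
    if panicle.frontal_area < 0:
        raise ValueError("panicle frontal area must be >= 0")
    F_w0 = 0.5 * case.rho_a * panicle.frontal_area * panicle.drag_coefficient * case.v_w ** 2
    M_w0 = F_w0 * (L3 + L4 + 0.5 * panicle.height)
    return F_w0, M_w0


def stem_drag_per_length(case: WindCase, diameter_mm: float, c_d: float = 1.0) -> float:
    """Optional distributed stem drag, uN per mm of stem (default off upstream)."""
    return 0.5 * case.rho_a * diameter_mm * c_d * case.v_w ** 2


def wind_protocol(t: float, protocol: tuple = _PROTOCOL) -> float:
    """Tunnel wind speed (m/s) at time ``t`` (s): plateaus, linear ramps, stop."""
    if t < 0:
        raise ValueError("t must be >= 0")
    for t0, t1, v0, v1 in protocol:
        if t0 <= t < t1:
            if v0 == v1:
                return v0
            return v0 + (v1 - v0) * (t - t0) / (t1 - t0)
    return 0.0


def protocol_segments(protocol: tuple = _PROTOCOL) -> np.ndarray:
    """Protocol as an array of (t_start, t_end, v_start, v_end) rows."""
    return np.array(protocol)


def reynolds(v_w: float, D: float, nu: float = units.NU_AIR) -> float:
    """Reynolds number Re = v_w D / nu (internal units mm, mm^2/s)."""
    if D <= 0 or nu <= 0:
        raise ValueError("D and nu must be positive")
    return v_w * D / nu


def build_loadset(morphology: PlantMorphology, case: WindCase) -> LoadSet:
    """All external loads for a plant under a wind case."""
    L3 = morphology.internodes[2].length
    L4 = morphology.internodes[3].length
    F_w0, M_w0 = panicle_drag(case, morphology.panicle, L3, L4)
    return LoadSet(
        W_u=upper_plant_weight(morphology),
        F_w0=F_w0,
        M_w0=M_w0,
        G=morphology.stem_density * units.GRAVITY,
    )
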