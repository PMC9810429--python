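"""Composition -> cell wall -> tissue -> macroscale stiffness/strength cards.

A two-step homogenization chain for cereal stem materials:

1. **Cell wall** from constituent mass fractions (lignin, cellulose,
   hemicellulose, other) by a Voigt (uniform-strain) stiffness average —
   appropriate for the stiff, tightly bonded wall laminate.
2. **Tissue** from the cell wall and its porosity by a Mori-Tanaka estimate
   with aligned spheroidal voids (cell lumina), using an isotropized-matrix
   Eshelby tensor; the matrix stiffness itself stays transversely isotropic.
   Tissue types (ground tissue, vascular bundles) combine by volume-weighted
   stiffness averaging.

Limit strengths scale with the same per-direction stiffness concentration
factors, anchored to cell-wall yield strains; this is the simplest rule
consistent with the homogenization weights and is deliberately pluggable.

Axis 3 is the stem axis; transverse isotropy (E1 = E2) is enforced
throughout.  All moduli in Pa (= mm-g-s stress unit).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ElasticConstants",
    "StrengthCard",
    "MaterialCard",
    "isotropic_constants",
    "stiffness_matrix",
    "compliance_matrix",
    "constants_from_stiffness",
    "eshelby_spheroid_mandel",
    "voigt_average",
    "reuss_average",
    "cell_wall_constants",
    "tissue_constants",
    "mix_tissues",
    "material_cards",
    "CONSTITUENT_MODULI",
    "COMPOSITIONS",
    "TISSUE_STRUCTURES",
    "WALL_YIELD_STRAINS",
    "build_crop_cards",
]

_D_MANDEL = np.diag([1.0, 1.0, 1.0, np.sqrt(2.0), np.sqrt(2.0), np.sqrt(2.0)])


# ---------------------------------------------------------------------------
# Elastic constants and tensor plumbing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElasticConstants:
    """Transversely isotropic engineering constants (axis 3 = stem axis).

    ``nu12`` etc. follow the load-direction convention
    ``nu_ij = -eps_j / eps_i`` for a uniaxial load along i, so the
    compliance entry is ``S_ij = -nu_ij / E_i``.
    """

    E1: float
    E2: float
    E3: float
    G12: float
    G13: float
    G23: float
    nu12: float
    nu13: float
    nu23: float

    def __post_init__(self) -> None:
        for name in ("E1", "E2", "E3", "G12", "G13", "G23"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if abs(self.E1 - self.E2) > 1e-6 * self.E1:
            raise ValueError("transverse isotropy requires E1 == E2")
        if abs(self.G13 - self.G23) > 1e-6 * self.G13:
            raise ValueError("transverse isotropy requires G13 == G23")
        if abs(self.nu13 - self.nu23) > 1e-6 * max(abs(self.nu13), 1e-3):
            raise ValueError("transverse isotropy requires nu13 == nu23")
        eig = np.linalg.eigvalsh(stiffness_matrix(self))
        if eig.min() <= 0:
            raise ValueError(
                f"implied stiffness tensor is not positive definite (min eig {eig.min():.3e})"
            )

    def scale(self, k: float) -> "ElasticConstants":
        """All moduli scaled by ``k`` (Poisson ratios unchanged)."""
        return dataclasses.replace(
            self, E1=self.E1 * k, E2=self.E2 * k, E3=self.E3 * k,
            G12=self.G12 * k, G13=self.G13 * k, G23=self.G23 * k,
        )

    def moduli(self) -> np.ndarray:
        return np.array([self.E1, self.E2, self.E3, self.G12, self.G13, self.G23])


def isotropic_constants(E: float, nu: float) -> ElasticConstants:
    G = E / (2.0 * (1.0 + nu))
    return ElasticConstants(E, E, E, G, G, G, nu, nu, nu)


def compliance_matrix(c: ElasticConstants) -> np.ndarray:
    """6x6 engineering compliance (shear strains are gammas)."""
    S = np.zeros((6, 6))
    S[0, 0], S[1, 1], S[2, 2] = 1.0 / c.E1, 1.0 / c.E2, 1.0 / c.E3
    S[0, 1] = S[1, 0] = -c.nu12 / c.E1
    S[0, 2] = S[2, 0] = -c.nu13 / c.E1
    S[1, 2] = S[2, 1] = -c.nu23 / c.E2
    S[3, 3], S[4, 4], S[5, 5] = 1.0 / c.G23, 1.0 / c.G13, 1.0 / c.G12
    return S


def stiffness_matrix(c: ElasticConstants) -> np.ndarray:
    """6x6 engineering stiffness."""
    return np.linalg.inv(compliance_matrix(c))


def _to_mandel(C_eng: np.ndarray) -> np.ndarray:
    return _D_MANDEL @ C_eng @ _D_MANDEL


def _from_mandel(C_m: np.ndarray) -> np.ndarray:
    Dinv = np.linalg.inv(_D_MANDEL)
    return Dinv @ C_m @ Dinv


def constants_from_stiffness(C_eng: np.ndarray, symmetrize_ti: bool = True) -> ElasticConstants:
    """Engineering constants from a 6x6 engineering stiffness matrix.

    Small departures from exact transverse isotropy (numerical round-off)
    are symmetrized away by averaging the 1/2 in-plane directions.
    """
    S = np.linalg.inv(0.5 * (C_eng + C_eng.T))
    E1, E2, E3 = 1.0 / S[0, 0], 1.0 / S[1, 1], 1.0 / S[2, 2]
    nu12, nu13 = -S[0, 1] * E1, -S[0, 2] * E1
    nu23 = -S[1, 2] * E2
    G23, G13, G12 = 1.0 / S[3, 3], 1.0 / S[4, 4], 1.0 / S[5, 5]
    if symmetrize_ti:
        E1 = E2 = 0.5 * (E1 + E2)
        G13 = G23 = 0.5 * (G13 + G23)
        nu13 = nu23 = 0.5 * (nu13 + nu23)
    return ElasticConstants(E1, E2, E3, G12, G13, G23, nu12, nu13, nu23)


def _isotropize(C_m: np.ndarray) -> tuple[float, float]:
    """Closest isotropic (bulk, shear) moduli of a Mandel stiffness (Hill average)."""
    J = np.zeros((6, 6))
    J[:3, :3] = 1.0 / 3.0
    k = np.trace(C_m @ J) / 3.0
    G = (np.trace(C_m) - 3.0 * k) / 10.0
    return k, G


# ---------------------------------------------------------------------------
# Eshelby tensor for an aligned spheroid in an isotropic matrix
# ---------------------------------------------------------------------------

def eshelby_spheroid_mandel(nu: float, aspect: float) -> np.ndarray:
    """Eshelby tensor of a spheroid (symmetry axis 3) in Mandel 6x6 form.

    ``aspect`` = a3/a1: > 1 prolate (pore elongated along the stem axis),
    = 1 sphere, < 1 oblate.  Closed forms from the classical elliptic-
    integral solution.
    """
    if aspect <= 0:
        raise ValueError("aspect ratio must be positive")
    S = np.zeros((6, 6))
    # the general formulas lose all precision as aspect -> 1 (difference of
    # near-equal elliptic terms), so route near-spheres to the sphere branch
    if abs(aspect - 1.0) < 1e-4:
        # sphere
        a = (7.0 - 5.0 * nu) / (15.0 * (1.0 - nu))
        b = (5.0 * nu - 1.0) / (15.0 * (1.0 - nu))
        s_shear = (4.0 - 5.0 * nu) / (15.0 * (1.0 - nu))
        S[:3, :3] = b
        np.fill_diagonal(S[:3, :3], a)
        S[3, 3] = S[4, 4] = S[5, 5] = 2.0 * s_shear
        return S

    a2 = aspect * aspect
    q = a2 - 1.0
    if aspect > 1.0:
        g = aspect / q ** 1.5 * (aspect * np.sqrt(q) - np.arccosh(aspect))
    else:
        g = aspect / (-q) ** 1.5 * (np.arccos(aspect) - aspect * np.sqrt(-q))
    c = 1.0 / (1.0 - nu)

    S1111 = 0.375 * c * a2 / q + 0.25 * c * (1.0 - 2.0 * nu - 2.25 / q) * g
    S3333 = 0.5 * c * (
        1.0 - 2.0 * nu + (3.0 * a2 - 1.0) / q
        - (1.0 - 2.0 * nu + 3.0 * a2 / q) * g
    )
    S1122 = 0.25 * c * (a2 / (2.0 * q) - (1.0 - 2.0 * nu + 0.75 / q) * g)
    S1133 = -0.5 * c * a2 / q + 0.25 * c * (3.0 * a2 / q - (1.0 - 2.0 * nu)) * g
    S3311 = -0.5 * c * (1.0 - 2.0 * nu + 1.0 / q) + 0.5 * c * (
        1.0 - 2.0 * nu + 1.5 / q
    ) * g
    S1212 = 0.25 * c * (a2 / (2.0 * q) + (1.0 - 2.0 * nu - 0.75 / q) * g)
    S1313 = 0.25 * c * (
        1.0 - 2.0 * nu - (a2 + 1.0) / q
        - 0.5 * (1.0 - 2.0 * nu - 3.0 * (a2 + 1.0) / q) * g
    )

    S[0, 0] = S[1, 1] = S1111
    S[2, 2] = S3333
    S[0, 1] = S[1, 0] = S1122
    S[0, 2] = S[1, 2] = S1133
    S[2, 0] = S[2, 1] = S3311
    S[3, 3] = S[4, 4] = 2.0 * S1313
    S[5, 5] = 2.0 * S1212
    return S


# ---------------------------------------------------------------------------
# Mixture rules
# ---------------------------------------------------------------------------

def _check_fractions(fractions: Sequence[float]) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("phase fractions must be non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"phase fractions must sum to 1, got {f.sum()!r}")
    return f


def voigt_average(
    fractions: Sequence[float], phases: Sequence[ElasticConstants]
) -> ElasticConstants:
    """Uniform-strain (arithmetic stiffness) mixture — the upper bound."""
    f = _check_fractions(fractions)
    C = sum(fi * stiffness_matrix(p) for fi, p in zip(f, phases))
    return constants_from_stiffness(C)


def reuss_average(
    fractions: Sequence[float], phases: Sequence[ElasticConstants]
) -> ElasticConstants:
    """Uniform-stress (arithmetic compliance) mixture — the lower bound."""
    f = _check_fractions(fractions)
    S = sum(fi * compliance_matrix(p) for fi, p in zip(f, phases))
    return constants_from_stiffness(np.linalg.inv(S))


def cell_wall_constants(
    composition, constituent_moduli: Mapping[str, ElasticConstants]
) -> ElasticConstants:
    """Effective cell-wall stiffness from constituent fractions (Voigt).

    ``composition`` is a :class:`~lodgesim.morphotypes.Composition`;
    ``constituent_moduli`` maps 'lignin'/'cellulose'/'hemicellulose'/'other'
    to their elastic constants (cellulose transversely isotropic along the
    microfibril direction, matrix polymers isotropic).
    """
    names = ("lignin", "cellulose", "hemicellulose", "other")
    missing = [n for n in names if n not in constituent_moduli]
    if missing:
        raise ValueError(f"missing constituent moduli for {missing}")
    fractions = composition.as_array()
    phases = [constituent_moduli[n] for n in names]
    return voigt_average(fractions, phases)


def tissue_constants(
    cell_wall: ElasticConstants, vf_wall: float, pore_aspect: float = 1.0
) -> ElasticConstants:
    """Porous-tissue stiffness by Mori-Tanaka with aligned spheroidal voids.

    ``vf_wall`` is the cell-wall volume fraction (1 - porosity); pores are
    spheroids with symmetry axis along the stem, aspect = axial/transverse.
    ``vf_wall = 1`` returns the cell wall unchanged; moduli are monotone
    non-decreasing in ``vf_wall``.
    """
    if not 0.0 < vf_wall <= 1.0:
        raise ValueError(f"vf_wall must lie in (0, 1], got {vf_wall}")
    if vf_wall == 1.0:
        return cell_wall
    phi = 1.0 - vf_wall
    C_m = _to_mandel(stiffness_matrix(cell_wall))
    k, G = _isotropize(C_m)
    nu = (3.0 * k - 2.0 * G) / (2.0 * (3.0 * k + 2.0 * G))
    S_esh = eshelby_spheroid_mandel(nu, pore_aspect)
    I6 = np.eye(6)
    A_dil = np.linalg.inv(I6 - S_esh)
    A_mt = A_dil @ np.linalg.inv((1.0 - phi) * I6 + phi * A_dil)
    C_eff = C_m @ (I6 - phi * A_mt)
    C_eff = 0.5 * (C_eff + C_eff.T)
    return constants_from_stiffness(_from_mandel(C_eff))


def mix_tissues(
    fractions: Sequence[float], tissues: Sequence[ElasticConstants]
) -> ElasticConstants:
    """Volume-weighted (Voigt) mixture over tissue types within a region."""
    return voigt_average(fractions, tissues)


# ---------------------------------------------------------------------------
# Material cards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrengthCard:
    """Limit strengths, Pa; transversely isotropic (sigma11 = sigma22)."""

    sigma11: float
    sigma22: float
    sigma33: float

    def __post_init__(self) -> None:
        for name in ("sigma11", "sigma22", "sigma33"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.sigma11 - self.sigma22) > 1e-6 * self.sigma11:
            raise ValueError("transverse isotropy requires sigma11 == sigma22")


@dataclass(frozen=True)
class MaterialCard:
    region: str  # 'pith' | 'shell'
    elastic: ElasticConstants
    strength: StrengthCard

    def __post_init__(self) -> None:
        if self.region not in ("pith", "shell"):
            raise ValueError(f"region must be 'pith' or 'shell', got {self.region!r}")


def material_cards(
    pith_tissue: ElasticConstants,
    shell_tissue: ElasticConstants,
    strength_rule: Mapping,
) -> tuple[MaterialCard, MaterialCard]:
    """Assemble pith and shell cards; strengths follow the stiffness weights.

    ``strength_rule`` carries the reference (cell-wall) state:
    ``{"reference": ElasticConstants, "reference_strength": StrengthCard}``.
    Each region's limit strength in direction d is the wall strength scaled
    by the region's stiffness concentration ``E_d(region) / E_d(wall)`` —
    the same per-direction weights the homogenization applied to stiffness.
    """
    ref: ElasticConstants = strength_rule["reference"]
    ref_s: StrengthCard = strength_rule["reference_strength"]

    def card(region: str, tissue: ElasticConstants) -> MaterialCard:
        s11 = ref_s.sigma11 * tissue.E1 / ref.E1
        s33 = ref_s.sigma33 * tissue.E3 / ref.E3
        return MaterialCard(region, tissue, StrengthCard(s11, s11, s33))

    return card("pith", pith_tissue), card("shell", shell_tissue)


def card_to_dict(card: MaterialCard) -> dict:
    return {
        "region": card.region,
        "elastic": dataclasses.asdict(card.elastic),
        "strength": dataclasses.asdict(card.strength),
    }


def card_from_dict(d: dict) -> MaterialCard:
    return MaterialCard(
        region=d["region"],
        elastic=ElasticConstants(**d["elastic"]),
        strength=StrengthCard(**d["strength"]),
    )


def save_cards(cards: Mapping[str, MaterialCard], directory, crop: str) -> list[str]:
    """Write cards as ``material_card_{crop}_{region}.json``; return paths."""
    import os

    paths = []
    for region, card in cards.items():
        path = os.path.join(directory, f"material_card_{crop}_{region}.json")
        with open(path, "w") as fh:
            json.dump(card_to_dict(card), fh, indent=1)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Crop fixtures (synthetic: literature-typical values, not measured data)
# ---------------------------------------------------------------------------

#: Base constituent elastic constants (Pa).  Synthetic fixture values in
#: literature-typical ranges for plant cell-wall polymers; the cellulose
#: entry is an effective in-wall fibril (microfibril-angle-softened), hence
#: well below the crystal modulus.
CONSTITUENT_MODULI: dict[str, ElasticConstants] = {
    "cellulose": ElasticConstants(
        E1=15.0e9, E2=15.0e9, E3=40.0e9, G12=5.0e9, G13=4.0e9, G23=4.0e9,
        nu12=0.30, nu13=0.10, nu23=0.10,
    ),
    "lignin": isotropic_constants(4.0e9, 0.30),
    "hemicellulose": isotropic_constants(7.0e9, 0.30),
    "other": isotropic_constants(2.0e9, 0.35),
}

#: Cell-wall compositions per crop (mass fractions).  Wheat carries the
#: higher lignin fraction.  Synthetic fixture values.
COMPOSITIONS: dict[str, "object"] = {}


def _init_compositions() -> None:
    from .morphotypes import Composition

    COMPOSITIONS.update({
        "oat": Composition(lignin_frac=0.16, cellulose_frac=0.42,
                           hemicellulose_frac=0.33, other_frac=0.09),
        "wheat": Composition(lignin_frac=0.23, cellulose_frac=0.44,
                             hemicellulose_frac=0.27, other_frac=0.06),
    })


_init_compositions()

#: Tissue structures per crop and region.  Wheat parenchyma carries the
#: higher cell-wall volume fraction.  Synthetic fixture values.
TISSUE_STRUCTURES: dict[tuple[str, str], "object"] = {}


def _init_tissues() -> None:
    from .morphotypes import TissueStructure

    TISSUE_STRUCTURES.update({
        ("oat", "pith"): TissueStructure(
            cell_wall_volume_fraction_parenchyma=0.10,
            bundle_volume_fraction=0.0, pore_aspect_ratio=2.0),
        ("wheat", "pith"): TissueStructure(
            cell_wall_volume_fraction_parenchyma=0.28,
            bundle_volume_fraction=0.0, pore_aspect_ratio=2.0),
        ("oat", "shell"): TissueStructure(
            cell_wall_volume_fraction_parenchyma=0.80,
            bundle_volume_fraction=0.25, pore_aspect_ratio=6.0),
        ("wheat", "shell"): TissueStructure(
            cell_wall_volume_fraction_parenchyma=0.85,
            bundle_volume_fraction=0.25, pore_aspect_ratio=6.0),
    })


_init_tissues()

#: Cell-wall yield strains anchoring the strength cascade (axial, transverse).
#: Synthetic fixture values near the proportional limit of green stem tissue;
#: transverse walls yield earlier than axial.
WALL_YIELD_STRAINS = {"axial": 0.0018, "transverse": 0.00144}

#: Dense wall fraction of vascular-bundle tissue (near-solid fibre caps).
_BUNDLE_VF_WALL = 0.95


def build_crop_cards(crop: str) -> tuple[MaterialCard, MaterialCard]:
    """Run the full cascade for a crop fixture -> (pith card, shell card).

    Pith = parenchyma tissue with a small admixture of vascular bundles;
    shell = dense sclerenchyma-like tissue with its bundle fraction.
    """
    if crop not in ("oat", "wheat"):
        raise ValueError(f"unknown crop {crop!r}")
    wall = cell_wall_constants(COMPOSITIONS[crop], CONSTITUENT_MODULI)
    wall_strength = StrengthCard(
        sigma11=WALL_YIELD_STRAINS["transverse"] * wall.E1,
        sigma22=WALL_YIELD_STRAINS["transverse"] * wall.E1,
        sigma33=WALL_YIELD_STRAINS["axial"] * wall.E3,
    )
    rule = {"reference": wall, "reference_strength": wall_strength}

    bundle = tissue_constants(wall, _BUNDLE_VF_WALL, pore_aspect=6.0)

    ts_p = TISSUE_STRUCTURES[(crop, "pith")]
    parenchyma = tissue_constants(
        wall, ts_p.cell_wall_volume_fraction_parenchyma, ts_p.pore_aspect_ratio
    )
    bv = ts_p.bundle_volume_fraction
    pith = mix_tissues([1.0 - bv, bv], [parenchyma, bundle])

    ts_s = TISSUE_STRUCTURES[(crop, "shell")]
    dense = tissue_constants(
        wall, ts_s.cell_wall_volume_fraction_parenchyma, ts_s.pore_aspect_ratio
    )
    bv = ts_s.bundle_volume_fraction
    shell = mix_tissues([1.0 - bv, bv], [dense, bundle])

    return material_cards(pith, shell, rule)
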