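"""Domain types for cereal plants and trials, plus the synthetic-data generator.

This module makes the whole downstream pipeline testable without any field or
wind-tunnel data: it draws plant morphologies around crop template means,
lays out randomized-complete-block trials, and renders side-view silhouettes
of bent stems that stand in for wind-tunnel video frames.

Conventions
-----------
* Internal units are mm-g-s (see :mod:`lodgesim.units`).
* The image frame has its origin at the stem base; x increases downstream
  (wind direction) and y increases upward.  Arrays are indexed ``[row, col]``
  with row 0 at the top of the image.
* Internodes are numbered 1..4 from the ground up.  A wall thickness equal
  to the outer radius encodes a solid cross-section.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from .phenotypes import PhenotypeRecord

__all__ = [
    "Composition",
    "TissueStructure",
    "Internode",
    "Panicle",
    "PlantMorphology",
    "TrialRecord",
    "CropTemplate",
    "OAT_TEMPLATE",
    "WHEAT_TEMPLATE",
    "CULTIVARS",
    "TRAIT_MEANS",
    "SilhouetteFrame",
    "generate_morphology",
    "generate_trial",
    "render_silhouette",
    "morphology_to_dict",
    "morphology_from_dict",
    "trials_to_dataframe",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """Cell-wall constituent mass fractions (must sum to 1)."""

    lignin_frac: float
    cellulose_frac: float
    hemicellulose_frac: float
    other_frac: float

    def __post_init__(self) -> None:
        fracs = self.as_array()
        if np.any(fracs < 0):
            raise ValueError(f"composition fractions must be non-negative, got {fracs}")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"composition fractions must sum to 1, got {fracs.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.lignin_frac, self.cellulose_frac, self.hemicellulose_frac, self.other_frac]
        )


@dataclass(frozen=True)
class TissueStructure:
    """Cellular-scale descriptors of a stem tissue.

    ``pore_aspect_ratio`` is the ratio of the pore (lumen) axis along the stem
    to its transverse axis; parenchyma cells are mildly prolate, fibre lumina
    strongly so.
    """

    cell_wall_volume_fraction_parenchyma: float
    bundle_volume_fraction: float
    pore_aspect_ratio: float

    def __post_init__(self) -> None:
        for name in ("cell_wall_volume_fraction_parenchyma", "bundle_volume_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pore_aspect_ratio <= 0:
            raise ValueError("pore_aspect_ratio must be positive")


@dataclass(frozen=True)
class Internode:
    """One stem internode with a hollow circular cross-section.

    ``wall_thickness == outer_radius`` encodes a solid section (as in the
    first internode of wheat).
    """

    index: int
    length: float  # mm
    outer_radius: float  # mm
    wall_thickness: float  # mm

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 4:
            raise ValueError(f"internode index must be 1..4, got {self.index}")
        if self.length <= 0:
            raise ValueError("internode length must be positive")
        if not 0 < self.wall_thickness <= self.outer_radius + 1e-12:
            raise ValueError(
                f"wall thickness must satisfy 0 < t <= r, got t={self.wall_thickness}, "
                f"r={self.outer_radius}"
            )

    @property
    def is_solid(self) -> bool:
        return self.wall_thickness >= self.outer_radius - 1e-12

    @property
    def area(self) -> float:
        """Cross-section area of the tube wall, mm^2."""
        r, t = self.outer_radius, self.wall_thickness
        return np.pi * t * (2.0 * r - t)


@dataclass(frozen=True)
class Panicle:
    """Grain head (panicle for oat, spike for wheat): the dominant drag collector."""

    mass: float  # g
    height: float  # mm
    frontal_area: float  # mm^2
    drag_coefficient: float = 0.5  # close to a vertical cylinder in cross flow

    def __post_init__(self) -> None:
        for name in ("mass", "height", "frontal_area", "drag_coefficient"):
            if getattr(self, name) < 0:
                raise ValueError(f"panicle {name} must be >= 0")


@dataclass(frozen=True)
class PlantMorphology:
    """Macroscale geometry of a single plant stem."""

    crop: str
    internodes: tuple[Internode, ...]
    panicle: Panicle
    total_height: float  # mm, base to panicle tip
    stem_density: float = 3.0e-4  # g mm^-3

    def __post_init__(self) -> None:
        if self.crop not in ("oat", "wheat"):
            raise ValueError(f"unknown crop {self.crop!r}; expected 'oat' or 'wheat'")
        if len(self.internodes) != 4:
            raise ValueError(f"expected exactly 4 internodes, got {len(self.internodes)}")
        if tuple(i.index for i in self.internodes) != (1, 2, 3, 4):
            raise ValueError("internodes must be ordered 1..4 from the ground up")
        if self.stem_density <= 0:
            raise ValueError("stem density must be positive")
        total_l = sum(i.length for i in self.internodes)
        if self.total_height < total_l - 1e-9:
            raise ValueError(
                f"total height {self.total_height} is below the summed internode "
                f"length {total_l}"
            )

    @property
    def internode_lengths(self) -> np.ndarray:
        return np.array([i.length for i in self.internodes])


@dataclass
class TrialRecord:
    """One cultivar x block observation in a randomized complete block design."""

    crop: str
    cultivar: str
    block: int
    heading_days: float
    plant_strength_n: float
    height_cm: float
    biomass_g: float
    run_order: int = 0
    phenotypes: "PhenotypeRecord | None" = None

    def __post_init__(self) -> None:
        if self.cultivar not in CULTIVARS.get(self.crop, ()):  # pragma: no branch
            raise ValueError(
                f"cultivar {self.cultivar!r} does not belong to crop {self.crop!r}"
            )
        if self.block < 1:
            raise ValueError("block must be >= 1")


# ---------------------------------------------------------------------------
# Crop templates
# ---------------------------------------------------------------------------

#: Germplasm panel the generator emulates: four cultivars per crop, three blocks.
CULTIVARS: dict[str, tuple[str, ...]] = {
    "oat": ("Gopher", "IL078721", "ND021052", "Reins"),
    "wheat": ("Linkert", "MN113946", "Rollag", "Shelly"),
}

#: Crop-level trait means used by :func:`generate_trial`.
TRAIT_MEANS: dict[str, dict[str, float]] = {
    "oat": {"heading_days": 47.4, "plant_strength_n": 0.78, "height_cm": 98.44,
            "biomass_g": 13.11},
    "wheat": {"heading_days": 47.7, "plant_strength_n": 1.23, "height_cm": 72.09,
              "biomass_g": 9.87},
}


@dataclass(frozen=True)
class CropTemplate:
    """Named parameter set for morphology generation.

    ``means`` holds per-trait means; SDs default to ``cv * mean`` unless
    overridden in ``sds``.  ``solid_first_internode`` pins t1 = r1 (wheat).
    Internode-length means plus the panicle height sum to the crop mean
    total height, so generated heights match the crop aggregate by
    construction.
    """

    crop: str
    means: dict[str, float]
    cv: float = 0.10
    sds: dict[str, float] = field(default_factory=dict)
    solid_first_internode: bool = False

    _TRAITS = (
        "L1", "L2", "L3", "L4",
        "r1", "r2", "r3", "r4",
        "t1", "t2", "t3", "t4",
        "panicle_mass", "panicle_height", "panicle_area",
    )

    def __post_init__(self) -> None:
        missing = [k for k in self._TRAITS if k not in self.means]
        if missing:
            raise ValueError(f"template for {self.crop!r} is missing traits {missing}")
        for k, v in self.means.items():
            if v <= 0:
                raise ValueError(f"template mean {k} must be positive, got {v}")
        for k, v in self.sds.items():
            if v < 0:
                raise ValueError(f"template SD {k} must be >= 0, got {v}")

    def sd(self, trait: str) -> float:
        return self.sds.get(trait, self.cv * self.means[trait])

    def replace(self, **kwargs) -> "CropTemplate":
        return dataclasses.replace(self, **kwargs)


# Template means are synthetic fixtures: crop-level aggregates (total height,
# near-solid wheat first internode) plus literature-typical internode and
# panicle dimensions.
# The lowermost internode is the narrowest (cereal culms widen acropetally
# toward mid-stem); wheat's first internode is near-solid.
OAT_TEMPLATE = CropTemplate(
    crop="oat",
    means={
        "L1": 110.0, "L2": 150.0, "L3": 200.0, "L4": 274.4,
        "r1": 1.22, "r2": 1.35, "r3": 1.10, "r4": 0.98,
        "t1": 0.427, "t2": 0.446, "t3": 0.363, "t4": 0.323,
        "panicle_mass": 1.8, "panicle_height": 250.0, "panicle_area": 3200.0,
    },
)

WHEAT_TEMPLATE = CropTemplate(
    crop="wheat",
    means={
        "L1": 80.0, "L2": 120.0, "L3": 180.0, "L4": 250.9,
        "r1": 1.00, "r2": 1.10, "r3": 0.94, "r4": 0.86,
        # t1 is pinned to r1 at sampling time (near-solid first internode)
        "t1": 1.00, "t2": 0.495, "t3": 0.423, "t4": 0.37,
        "panicle_mass": 1.5, "panicle_height": 90.0, "panicle_area": 2500.0,
    },
    solid_first_internode=True,
)

_TEMPLATES = {"oat": OAT_TEMPLATE, "wheat": WHEAT_TEMPLATE}


def crop_template(crop: str) -> CropTemplate:
    """Return the shipped template for ``crop`` ('oat' or 'wheat')."""
    try:
        return _TEMPLATES[crop]
    except KeyError:
        raise ValueError(
            f"unknown crop label {crop!r}; available templates: {sorted(_TEMPLATES)}"
        ) from None


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    """Draw from N(mean, sd) truncated to (low, high) by rejection.

    With the shipped 10% CVs the bounds sit many SDs from the mean, so
    rejection is essentially free; it keeps sampling exact (no clipping
    atoms at the bounds).
    """
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out <= low) | (out >= high)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= low) | (out >= high)
    return out


def generate_morphology(
    template: CropTemplate | str, n: int, seed: int
) -> list[PlantMorphology]:
    """Draw ``n`` plant morphologies around a crop template.

    Traits are independent truncated normals (truncated at physical bounds).
    Wall thicknesses are drawn conditionally on the radius so that
    0 < t <= r always holds; a solid-first-internode template pins t1 = r1.
    Total height is the sum of internode lengths plus the panicle height,
    so generated heights inherit the template's aggregate mean.
    """
    if isinstance(template, str):
        template = crop_template(template)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    draws: dict[str, np.ndarray] = {}
    for trait in ("L1", "L2", "L3", "L4", "panicle_mass", "panicle_height",
                  "panicle_area"):
        draws[trait] = _truncated_normal(
            rng, template.means[trait], template.sd(trait), 0.0, np.inf, n
        )
    for i in (1, 2, 3, 4):
        r = _truncated_normal(
            rng, template.means[f"r{i}"], template.sd(f"r{i}"), 0.0, np.inf, n
        )
        draws[f"r{i}"] = r
        if i == 1 and template.solid_first_internode:
            draws["t1"] = r.copy()
        else:
            t = np.empty(n)
            for k in range(n):
                t[k] = _truncated_normal(
                    rng, template.means[f"t{i}"], template.sd(f"t{i}"),
                    0.0, r[k], 1
                )[0]
            draws[f"t{i}"] = np.minimum(t, r)

    plants = []
    for k in range(n):
        internodes = tuple(
            Internode(
                index=i,
                length=float(draws[f"L{i}"][k]),
                outer_radius=float(draws[f"r{i}"][k]),
                wall_thickness=float(draws[f"t{i}"][k]),
            )
            for i in (1, 2, 3, 4)
        )
        panicle = Panicle(
            mass=float(draws["panicle_mass"][k]),
            height=float(draws["panicle_height"][k]),
            frontal_area=float(draws["panicle_area"][k]),
        )
        total_height = float(sum(i.length for i in internodes) + panicle.height)
        plants.append(
            PlantMorphology(
                crop=template.crop,
                internodes=internodes,
                panicle=panicle,
                total_height=total_height,
            )
        )
    return plants


def generate_trial(
    cultivar_sets: dict[str, Sequence[str]] | None = None,
    blocks: int = 3,
    seed: int = 0,
    trait_means: dict[str, dict[str, float]] | None = None,
    cultivar_cv: float = 0.05,
    block_cv: float = 0.03,
    noise_cv: float = 0.08,
) -> list[TrialRecord]:
    """Lay out a randomized complete block trial: one record per cultivar x block.

    Trait values are crop mean x (1 + cultivar effect + block effect + noise),
    with multiplicative effects drawn once per cultivar / block from the
    stated CVs.  Within each block the testing order is a seeded permutation.
    """
    if cultivar_sets is None:
        cultivar_sets = {c: list(v) for c, v in CULTIVARS.items()}
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    for crop, cvs in cultivar_sets.items():
        if not cvs:
            raise ValueError(f"cultivar set for crop {crop!r} is empty")
        unknown = set(cvs) - set(CULTIVARS.get(crop, ()))
        if unknown:
            raise ValueError(f"cultivars {sorted(unknown)} not registered for {crop!r}")
    means = trait_means or TRAIT_MEANS
    traits = ("heading_days", "plant_strength_n", "height_cm", "biomass_g")

    rng = np.random.default_rng(seed)
    all_cultivars = [(crop, cv) for crop in sorted(cultivar_sets) for cv in cultivar_sets[crop]]
    cult_eff = {
        (crop, cv): {t: rng.normal(0.0, cultivar_cv) for t in traits}
        for crop, cv in all_cultivars
    }
    block_eff = {b: {t: rng.normal(0.0, block_cv) for t in traits} for b in range(1, blocks + 1)}

    records: list[TrialRecord] = []
    for b in range(1, blocks + 1):
        order = rng.permutation(len(all_cultivars))
        for pos, idx in enumerate(order):
            crop, cv = all_cultivars[idx]
            vals = {}
            for t in traits:
                base = means[crop][t]
                mult = 1.0 + cult_eff[(crop, cv)][t] + block_eff[b][t] + rng.normal(0.0, noise_cv)
                vals[t] = max(base * mult, 1e-6)
            records.append(
                TrialRecord(
                    crop=crop, cultivar=cv, block=b, run_order=pos + 1,
                    heading_days=vals["heading_days"],
                    plant_strength_n=vals["plant_strength_n"],
                    height_cm=vals["height_cm"],
                    biomass_g=vals["biomass_g"],
                )
            )
    return records


# ---------------------------------------------------------------------------
# Silhouette renderer
# ---------------------------------------------------------------------------

@dataclass
class SilhouetteFrame:
    """A rendered side-view silhouette with its geometric sidecar.

    ``image`` is a float array in [0, 1] with a one-pixel antialiased
    boundary (foreground ~1); ``anchor_rc`` is the (row, col) pixel of the
    stem base.
    """

    image: np.ndarray
    mm_per_pixel: float
    anchor_rc: tuple[int, int]
    stem_width_mm: float
    timestamp: float | None = None

    def sidecar(self) -> dict:
        return {
            "mm_per_pixel": self.mm_per_pixel,
            "anchor_rc": list(self.anchor_rc),
            "stem_width_mm": self.stem_width_mm,
            "timestamp": self.timestamp,
        }


def render_silhouette(
    centerline: np.ndarray,
    image_size: tuple[int, int] = (360, 440),
    mm_per_pixel: float = 3.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    stem_width_mm: float = 12.0,
    anchor_rc: tuple[int, int] | None = None,
    timestamp: float | None = None,
) -> SilhouetteFrame:
    """Render a bent-stem centerline as a side-view silhouette frame.

    The centerline is an (N, 2) array of (x, y) points in mm starting at the
    base (origin); x points downstream, y up.  The foreground is a band of
    width ``stem_width_mm`` centred on the centerline, drawn with a one-pixel
    antialiasing ramp so the boundary can be located to sub-pixel accuracy.
    ``noise_sd`` (pixels) jitters each image row's boundary horizontally,
    emulating segmentation noise in masked video frames.
    """
    centerline = np.asarray(centerline, dtype=float)
    if centerline.ndim != 2 or centerline.shape[1] != 2 or len(centerline) < 2:
        raise ValueError("centerline must be an (N, 2) array with N >= 2")
    if np.linalg.norm(centerline[0]) > 1e-6:
        raise ValueError("centerline must start at the base (origin)")
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    h, w = image_size
    if anchor_rc is None:
        anchor_rc = (h - 1 - max(2, h // 20), max(2, w // 8))
    a_row, a_col = anchor_rc

    # field-of-view check (in mm relative to the anchor)
    x_min_mm, x_max_mm = -a_col * mm_per_pixel, (w - 1 - a_col) * mm_per_pixel
    y_min_mm, y_max_mm = -(h - 1 - a_row) * mm_per_pixel, a_row * mm_per_pixel
    cx, cy = centerline[:, 0], centerline[:, 1]
    if (cx.min() < x_min_mm or cx.max() > x_max_mm
            or cy.min() < y_min_mm or cy.max() > y_max_mm):
        raise ValueError(
            "centerline leaves the field of view: extent "
            f"x [{cx.min():.1f}, {cx.max():.1f}] mm, y [{cy.min():.1f}, {cy.max():.1f}] mm "
            f"vs view x [{x_min_mm:.1f}, {x_max_mm:.1f}], y [{y_min_mm:.1f}, {y_max_mm:.1f}]"
        )

    # densify the centerline to ~1/3 pixel spacing for the distance field
    seg = np.diff(centerline, axis=0)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    n_dense = max(int(arclen[-1] / (mm_per_pixel / 3.0)), 2)
    s_dense = np.linspace(0.0, arclen[-1], n_dense)
    dense = np.column_stack(
        [np.interp(s_dense, arclen, cx), np.interp(s_dense, arclen, cy)]
    )
    tree = cKDTree(dense)

    rows = np.arange(h)
    cols = np.arange(w)
    x_mm = (cols - a_col) * mm_per_pixel  # (w,)
    y_mm = (a_row - rows) * mm_per_pixel  # (h,)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        row_shift = rng.normal(0.0, noise_sd * mm_per_pixel, size=h)
    else:
        row_shift = np.zeros(h)
    px = x_mm[None, :] - row_shift[:, None]  # jitter shifts the row's boundary
    py = np.broadcast_to(y_mm[:, None], (h, w))
    pts = np.column_stack([px.ravel(), py.ravel()])
    dist, _ = tree.query(pts, workers=-1)
    dist = dist.reshape(h, w)

    image = np.clip(0.5 + (stem_width_mm / 2.0 - dist) / mm_per_pixel, 0.0, 1.0)
    return SilhouetteFrame(
        image=image,
        mm_per_pixel=mm_per_pixel,
        anchor_rc=(a_row, a_col),
        stem_width_mm=stem_width_mm,
        timestamp=timestamp,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def morphology_to_dict(plant: PlantMorphology) -> dict:
    return {
        "crop": plant.crop,
        "internodes": [dataclasses.asdict(i) for i in plant.internodes],
        "panicle": dataclasses.asdict(plant.panicle),
        "total_height": plant.total_height,
        "stem_density": plant.stem_density,
    }


def morphology_from_dict(d: dict) -> PlantMorphology:
    return PlantMorphology(
        crop=d["crop"],
        internodes=tuple(Internode(**i) for i in d["internodes"]),
        panicle=Panicle(**d["panicle"]),
        total_height=d["total_height"],
        stem_density=d.get("stem_density", 3.0e-4),
    )


def save_morphologies(plants: Iterable[PlantMorphology], path) -> None:
    with open(path, "w") as fh:
        json.dump([morphology_to_dict(p) for p in plants], fh, indent=1)


def load_morphologies(path) -> list[PlantMorphology]:
    with open(path) as fh:
        return [morphology_from_dict(d) for d in json.load(fh)]


def trials_to_dataframe(records: Sequence[TrialRecord]):
    """Flatten trial records (and any attached phenotypes) to a DataFrame."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "crop": r.crop, "cultivar": r.cultivar, "block": r.block,
            "run_order": r.run_order, "heading_days": r.heading_days,
            "plant_strength_n": r.plant_strength_n, "height_cm": r.height_cm,
            "biomass_g": r.biomass_g,
        }
        if r.phenotypes is not None:
            row.update(r.phenotypes.as_row())
        rows.append(row)
    return pd.DataFrame(rows)
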