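"""Silhouette-derived stem bending phenotypes.

From masked side-view frames of a bending stem, this module extracts the
windward edge, fits a power-law bending profile f(x) = c x^d, and derives
the phenotypes used to compare crops: the bending angle theta against the
floor, the frontal-area upper bound A_ub, the equivalent horizontal drag
force F_w from a load-cell follower force F_s, the drag-coefficient lower
bound C_d, and the coefficient of lodging resistance CL_r.

All coordinates are mm in the base-anchored frame (x downstream, y up);
forces uN, speeds mm/s internally.

theta is the secant angle from the base to the half-arc-length point of the
fitted curve: the point x0 where the arc length along f equals H/2 defines
theta = atan(f(x0)/x0).  The reference stem deformation is theta = 50 deg;
C_d and CL_r are evaluated there, or — flagged — at the smallest angle the
stem reaches if 50 deg is never attained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, odr, optimize
from skimage import measure

from . import units
from .morphotypes import SilhouetteFrame

__all__ = [
    "EdgeProfile",
    "PowerLawFit",
    "PhenotypeRecord",
    "extract_edge",
    "fit_power_law",
    "arc_length",
    "bending_angle",
    "frontal_area_ub",
    "force_from_loadcell",
    "drag_coefficient",
    "lodging_resistance",
    "phenotype_timeseries",
]

REFERENCE_THETA_DEG = 50.0


@dataclass
class EdgeProfile:
    """Windward-edge points of a masked frame, mm, base at origin."""

    points: np.ndarray  # (N, 2): x (downstream), f(x) (height)
    timestamp: float | None = None
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("edge profile needs an (N, 2) point array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("edge profile contains non-finite values")

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def vertical_extent(self) -> float:
        return float(self.y.max() - self.y.min())


@dataclass(frozen=True)
class PowerLawFit:
    """f(x) = c x^d fitted to a windward edge."""

    c: float  # mm^(1-d)
    d: float  # dimensionless
    rms_residual: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"power-law coefficient c must be positive, got {self.c}")
        if not 0.0 < self.d < 2.0:
            raise ValueError(f"power-law exponent d must lie in (0, 2), got {self.d}")

    def __call__(self, x):
        return self.c * np.asarray(x, dtype=float) ** self.d

    def slope(self, x):
        return self.c * self.d * np.asarray(x, dtype=float) ** (self.d - 1.0)


@dataclass
class PhenotypeRecord:
    """Video-derived phenotypes of one plant over a tunnel test."""

    theta_max: float  # deg, bending angle at the maximum-speed plateau
    recovery_theta: float  # deg, recovered after wind stops
    c: float
    d: float
    a_ub_mm2: float
    f_w_un: float
    f_s_un: float
    c_d: float
    cl_r: float
    cl_r_definition: str = "lever-arm-deficit"
    reference_reached: bool = True
    theta_series: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_max <= 90.0 + 1e-9:
            raise ValueError(f"theta_max must lie in (0, 90] deg, got {self.theta_max}")
        if self.c_d < 0:
            raise ValueError("C_d must be >= 0")
        if not -1e-9 <= self.cl_r <= 1.0 + 1e-9:
            raise ValueError(f"CL_r must lie in [0, 1], got {self.cl_r}")

    def as_row(self) -> dict:
        return {
            "theta_max_deg": self.theta_max,
            "recovery_theta_deg": self.recovery_theta,
            "c": self.c,
            "d": self.d,
            "a_ub_mm2": self.a_ub_mm2,
            "f_w_n": units.n_from_un(self.f_w_un),
            "f_s_n": units.n_from_un(self.f_s_un),
            "c_d": self.c_d,
            "cl_r": self.cl_r,
            "cl_r_definition": self.cl_r_definition,
            "reference_reached": self.reference_reached,
        }


# ---------------------------------------------------------------------------
# Edge extraction and power-law fitting
# ---------------------------------------------------------------------------

def extract_edge(
    frame: SilhouetteFrame,
    threshold: float = 0.5,
    correct_stem_width: bool = True,
) -> EdgeProfile:
    """Windward (smallest-x) boundary of the masked plant, in mm.

    For each image row intersecting the plant the left threshold crossing is
    located to sub-pixel accuracy on the antialiased boundary.  When the
    frame's sidecar carries the stem width and ``correct_stem_width`` is on,
    edge points are shifted half a stem width along the local inward normal
    so the profile tracks the stem centerline rather than its windward face.
    """
    img = frame.image
    binary = img >= threshold
    if not binary.any():
        raise ValueError("empty mask: no foreground above threshold")
    labels = measure.label(binary, connectivity=2)
    n_comp = labels.max()
    if n_comp > 1:
        # noise specks (< 2% of the main blob) are cleaned away, as any
        # masking pipeline would; a genuinely split silhouette is an error
        sizes = np.bincount(labels.ravel())[1:]
        main = int(np.argmax(sizes)) + 1
        substantial = np.sum(sizes >= 0.02 * sizes.max())
        if substantial > 1:
            raise ValueError(
                f"foreground is disconnected: {int(substantial)} components "
                f"(pixel counts {sorted(sizes.tolist(), reverse=True)})"
            )
        binary = labels == main

    a_row, a_col = frame.anchor_rc
    s = frame.mm_per_pixel
    rows_with = np.where(binary.any(axis=1))[0]
    xs, ys = [], []
    for row in rows_with:
        cols = np.where(binary[row])[0]
        c0 = cols[0]
        if c0 > 0:
            v0, v1 = img[row, c0 - 1], img[row, c0]
            frac = (threshold - v0) / (v1 - v0) if v1 > v0 else 1.0
            x_px = (c0 - 1) + frac
        else:
            x_px = float(c0)
        xs.append((x_px - a_col) * s)
        ys.append((a_row - row) * s)
    x = np.array(xs)
    y = np.array(ys)
    order = np.argsort(y)
    x, y = x[order], y[order]
    keep = y >= 0.0  # drop the band cap below the base anchor
    x, y = x[keep], y[keep]

    w = frame.stem_width_mm if correct_stem_width else 0.0
    if w > 0 and len(y) > 8:
        # rows within ~w of the profile ends see the rounded band caps, not
        # the stem flank; drop them before any slope estimate
        trim = (y >= y.min() + 0.75 * w) & (y <= y.max() - 0.75 * w)
        if trim.sum() >= 5:
            x, y = x[trim], y[trim]
    if w > 0 and len(y) >= 3:
        # slope for the inward-normal shift comes from a smoothed profile:
        # raw per-row noise would inflate sqrt(1 + x'^2) and bias the
        # correction toward zero
        if len(y) >= 11:
            from scipy.signal import savgol_filter

            win = int(round(1.5 * w / frame.mm_per_pixel)) | 1
            win = min(max(win, 5), (len(y) - 1) | 1)
            x_s = savgol_filter(x, win, 2)
        else:
            x_s = x
        dxdy = np.gradient(x_s, y)
        norm = np.sqrt(1.0 + dxdy**2)
        x = x + 0.5 * w / norm
        y = y - 0.5 * w * dxdy / norm
    return EdgeProfile(points=np.column_stack([x, y]), timestamp=frame.timestamp)


def fit_power_law(profile: EdgeProfile, min_points: int = 5) -> PowerLawFit:
    """Fit f(x) = c x^d to the windward edge.

    Three-stage fit: a log-log linear seed, a vertical least-squares refine,
    then an orthogonal-distance polish.  The orthogonal stage matters where
    the curve runs near-vertical (small x near the base): there a sub-pixel
    x error produces an enormous *vertical* residual that would otherwise
    dominate the objective and bias the exponent.  Recovery is exact on
    noiseless power-law data.  A perfectly upright profile (no downstream
    excursion) has no defined exponent and is rejected.
    """
    x, y = profile.x, profile.y
    good = (x > 0) & (y > 0)
    if good.sum() < min_points:
        if np.all(np.abs(x) < 1e-6) or good.sum() == 0:
            raise ValueError(
                "no measurable downstream excursion: stem is upright, d undefined"
            )
        raise ValueError(
            f"need at least {min_points} points with x > 0, have {int(good.sum())}"
        )
    xg, yg = x[good], y[good]
    # log-log seed
    coef = np.polyfit(np.log(xg), np.log(yg), 1)
    d0, c0 = float(coef[0]), float(np.exp(coef[1]))
    d0 = min(max(d0, 0.05), 1.95)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, c, d: c * t**d, xg, yg, p0=[max(c0, 1e-6), d0], maxfev=10000
        )
    except RuntimeError:  # pragma: no cover - pathological profiles
        popt = [max(c0, 1e-6), d0]
    out = odr.ODR(
        odr.Data(xg, yg),
        odr.Model(lambda B, t: B[0] * np.abs(t) ** B[1]),
        beta0=list(popt),
    ).run()
    c_fit, d_fit = float(out.beta[0]), float(out.beta[1])
    if not (c_fit > 0 and 0.0 < d_fit < 2.0):  # pragma: no cover - safety net
        c_fit, d_fit = float(popt[0]), float(popt[1])
    resid = yg - c_fit * xg**d_fit
    return PowerLawFit(c=c_fit, d=d_fit, rms_residual=float(np.sqrt(np.mean(resid**2))))


# ---------------------------------------------------------------------------
# Bending angle
# ---------------------------------------------------------------------------

def arc_length(fit: PowerLawFit, x0: float) -> float:
    """Arc length of f(x) = c x^d from the origin to x0.

    Integrates over whichever coordinate keeps the integrand bounded
    (x for d >= 1, height y otherwise), so the curve's vertical tangent at
    the base never hits the quadrature.
    """
    if x0 <= 0:
        return 0.0
    c, d = fit.c, fit.d
    if d >= 1.0:
        val, _ = integrate.quad(
            lambda t: np.sqrt(1.0 + (c * d * t ** (d - 1.0)) ** 2), 0.0, x0,
            limit=200,
        )
    else:
        y0 = c * x0**d
        # x(y) = (y/c)^(1/d); dx/dy bounded at 0 for d <= 1
        val, _ = integrate.quad(
            lambda u: np.sqrt(
                1.0 + ((u / c) ** (1.0 / d - 1.0) / (c * d)) ** 2
            ),
            0.0, y0, limit=200,
        )
    return float(val)


def bending_angle(
    fit: PowerLawFit, height_mm: float, x_max: float | None = None
) -> float:
    """Bending angle theta (deg) at the half-length point of the stem.

    Finds x0 with arc length H/2 along the fitted curve, then
    theta = atan(f(x0) / x0).  If ``x_max`` (the observed profile extent) is
    given, the curve must reach H/2 within it.
    """
    if height_mm <= 0:
        raise ValueError("plant height must be positive")
    target = 0.5 * height_mm
    if x_max is not None:
        attained = arc_length(fit, x_max)
        if attained < target:
            raise ValueError(
                f"fitted curve is shorter than H/2 within the profile: arc length "
                f"{attained:.1f} mm < {target:.1f} mm"
            )
    x0, y0 = half_length_point(fit, height_mm)
    return float(np.degrees(np.arctan2(y0, x0)))


def half_length_point(fit: PowerLawFit, height_mm: float) -> tuple[float, float]:
    """(x0, f(x0)) where the arc length along the fit equals H/2."""
    target = 0.5 * height_mm
    hi = max(target, 1e-3)
    while arc_length(fit, hi) < target:
        hi *= 2.0
    x0 = optimize.brentq(lambda t: arc_length(fit, t) - target, 0.0, hi, xtol=1e-10)
    return float(x0), float(fit(x0))


# ---------------------------------------------------------------------------
# Forces, areas and coefficients
# ---------------------------------------------------------------------------

def frontal_area_ub(profiles: list[EdgeProfile], plant_width_mm: float) -> float:
    """Upper bound on the frontal area over a time window, mm^2.

    The projected vertical extent of the windward edge times the plant
    width bounds any physically smeared frontal area with the same extent.
    """
    if not profiles:
        raise ValueError("frontal-area window is empty")
    if plant_width_mm <= 0:
        raise ValueError("plant width must be positive")
    extent = max(p.vertical_extent() for p in profiles)
    return extent * plant_width_mm


def force_from_loadcell(
    f_s_un: float,
    theta_ref_deg: float,
    height_mm: float,
    fit: PowerLawFit | None = None,
) -> float:
    """Equivalent horizontal force F_w from the load-cell follower force F_s.

    The load cell applies F_s perpendicular to the stem at the half-height
    point.  Equating virtual work on a rigid virtual rotation of the
    deformed configuration about the base gives, for a straight-line stem at
    angle theta, ``F_w = F_s / sin(theta)``; with a fitted bending profile
    the same construction is evaluated on the curve at its half-arc-length
    point.  Linear in F_s.
    """
    if f_s_un < 0:
        raise ValueError("F_s must be >= 0")
    if not 0.0 < theta_ref_deg <= 90.0:
        raise ValueError(f"theta_ref must lie in (0, 90] deg, got {theta_ref_deg}")
    if fit is None:
        return f_s_un / np.sin(np.radians(theta_ref_deg))
    x0, y0 = half_length_point(fit, height_mm)
    fp = fit.slope(x0)
    # follower direction normal to the stem; virtual rotation about the base
    return f_s_un * (fp * y0 + x0) / (y0 * np.sqrt(1.0 + fp**2))


def drag_coefficient(
    f_w_un: float, area_mm2: float, v_w_mm_s: float, rho_air: float = units.RHO_AIR
) -> float:
    """C_d = 2 F_w / (rho_air A v_w^2); a lower bound when A is A_ub."""
    if area_mm2 <= 0:
        raise ValueError("frontal area must be positive")
    if v_w_mm_s <= 0:
        raise ValueError("drag coefficient undefined at zero wind speed")
    return 2.0 * f_w_un / (rho_air * area_mm2 * v_w_mm_s**2)


def lodging_resistance(
    fit: PowerLawFit,
    height_mm: float,
    f_w_un: float | None = None,
    definition: str = "lever-arm-deficit",
) -> tuple[float, str]:
    """Coefficient of lodging resistance CL_r in [0, 1], with its definition tag.

    Default 'lever-arm-deficit': CL_r = 1 - f(x0)/(H/2), the relative drop of
    the half-length point below its rigid-upright elevation — the fraction of
    the applied torque's lever arm the stem has surrendered by bending.
    Strategies are pluggable; the record always stores which definition
    produced the value.
    """
    if definition != "lever-arm-deficit":
        raise ValueError(f"unknown CL_r definition {definition!r}")
    if height_mm <= 0:
        raise ValueError("rigid lever arm is zero: H must be positive")
    _, y0 = half_length_point(fit, height_mm)
    val = 1.0 - y0 / (0.5 * height_mm)
    return float(min(max(val, 0.0), 1.0)), definition


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def phenotype_timeseries(
    frames: list[SilhouetteFrame],
    wind_log: np.ndarray,
    height_mm: float,
    plant_width_mm: float,
    f_s_un: float = 0.0,
    frame_rate: int = 24,
    theta_ref_deg: float = REFERENCE_THETA_DEG,
) -> PhenotypeRecord:
    """Per-second phenotypes from a frame stack and the pitot wind log.

    Frames are averaged in one-second bins of ``frame_rate`` frames to align
    with the 1 s pitot cadence.  ``theta_max`` is the mean bending angle over
    the maximum-speed plateau; the recovery angle is the final angle minus
    the minimum during that plateau.  C_d and CL_r are evaluated at the
    reference deformation (50 deg) or, flagged, at the minimum angle reached.
    ``wind_log`` rows are (t seconds, v m/s).
    """
    wind_log = np.asarray(wind_log, dtype=float)
    if wind_log.ndim != 2 or wind_log.shape[1] != 2:
        raise ValueError("wind log must be (n, 2): time s, speed m/s")
    n_sec = len(frames) // frame_rate
    if n_sec < 1:
        raise ValueError(f"need at least {frame_rate} frames (one second)")
    t_frames = np.array([f.timestamp if f.timestamp is not None else np.nan
                         for f in frames])
    if np.all(np.isfinite(t_frames)):
        t0_f, t0_w = t_frames[0], wind_log[0, 0]
        if abs(t0_f - t0_w) > 0.5:
            raise ValueError(
                f"frame and pitot logs are misaligned: first frame at {t0_f:.2f} s, "
                f"first pitot sample at {t0_w:.2f} s (offset {t0_f - t0_w:+.2f} s)"
            )

    theta_sec = np.full(n_sec, np.nan)
    fits_sec: list[PowerLawFit | None] = [None] * n_sec
    profiles_sec: list[list[EdgeProfile]] = [[] for _ in range(n_sec)]
    for k in range(n_sec):
        thetas = []
        for f in frames[k * frame_rate:(k + 1) * frame_rate]:
            profile = extract_edge(f)
            profiles_sec[k].append(profile)
            try:
                fit = fit_power_law(profile)
            except ValueError:
                thetas.append(90.0)  # upright: no excursion
                continue
            fits_sec[k] = fit
            thetas.append(bending_angle(fit, height_mm))
        theta_sec[k] = float(np.mean(thetas))

    t_sec = np.arange(n_sec, dtype=float) + wind_log[0, 0]
    v_sec = np.interp(t_sec, wind_log[:, 0], wind_log[:, 1])
    v_peak = v_sec.max()
    plateau = v_sec >= 0.98 * v_peak
    theta_max = float(np.mean(theta_sec[plateau]))
    theta_plateau_min = float(np.min(theta_sec[plateau]))
    recovery = float(theta_sec[-1] - theta_plateau_min)

    # reference deformation: the second at (or nearest above) theta_ref
    reached = bool(np.nanmin(theta_sec) <= theta_ref_deg)
    k_ref = int(np.nanargmin(np.abs(theta_sec - theta_ref_deg))) if reached else int(
        np.nanargmin(theta_sec)
    )
    fit_ref = fits_sec[k_ref]
    if fit_ref is None:
        raise ValueError("no power-law fit available at the reference second")
    a_ub = frontal_area_ub(profiles_sec[k_ref], plant_width_mm)
    theta_at_ref = theta_sec[k_ref]
    f_w = force_from_loadcell(f_s_un, theta_at_ref, height_mm, fit=fit_ref)
    v_ref = max(v_sec[k_ref], 1e-9) * units.MM_S_PER_M_S
    c_d = drag_coefficient(f_w, a_ub, v_ref) if f_w > 0 else 0.0
    cl_r, cl_def = lodging_resistance(fit_ref, height_mm, f_w)

    return PhenotypeRecord(
        theta_max=theta_max,
        recovery_theta=recovery,
        c=fit_ref.c,
        d=fit_ref.d,
        a_ub_mm2=a_ub,
        f_w_un=f_w,
        f_s_un=f_s_un,
        c_d=c_d,
        cl_r=cl_r,
        cl_r_definition=cl_def,
        reference_reached=reached,
        theta_series=theta_sec,
    )
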