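"""Geometrically nonlinear elastoplastic bending of the two lowermost internodes.

The stem is a vertical cantilever (fixed base) discretized with corotational
planar beam elements.  Geometric nonlinearity enters through the corotational
kinematics (exact rigid-body rotation split); material nonlinearity through
elastoplastic fibers tiling each cross-section, with the pith and shell
annuli carrying their own material cards and the axial limit strength
sigma33 acting as fiber yield stress.  Fibers carry a modest linear
kinematic hardening (default H = 0.3 E): under load control a perfectly
plastic section loses equilibrium immediately after first yield, whereas the
observable of interest — residual displacement growing gradually with wind
speed — requires a stable post-yield branch, which the redistributing 3D
continuum possesses and a fiber beam must recover through hardening.

Cross-sections taper linearly within each internode around its mean
radius, and a short stiffened solid segment represents the node (joint)
between the two internodes.  An optional Brazier-style ovalization rule
knocks down the fiber yield strength as curvature grows, scaled by the ratio
of axial shell stiffness to transverse pith stiffness — the mechanism by
which a soft-pith hollow stem localizes damage while a solid-pith stem
spreads it.

Loading follows the tunnel protocol abstraction: gravity (body force and
upper-plant weight) is applied first and held; the wind drag force and
moment ramp up (loading step) and back down (unloading step).  ``u_max`` and
``u_res`` are the top-node displacement magnitudes at the ends of the two
steps, and the residual ratio ``u_res/u_max`` is the failure metric; the
limiting wind speed is the smallest speed whose residual ratio reaches the
threshold (0.3 by default).

Internal units mm-g-s; speeds at the interface in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .micromech import MaterialCard
from .morphotypes import PlantMorphology
from .windload import LoadSet, WindCase, build_loadset

__all__ = [
    "FiberSection",
    "BeamModel",
    "SimResult",
    "OvalizationRule",
    "build_stem_model",
    "make_prismatic_model",
    "solve_quasistatic",
    "simulate_load_unload",
    "residual_ratio",
    "extend_profile",
    "limiting_wind_speed",
    "localization_index",
    "LimitingSpeedResult",
    "NonConvergence",
]

_GAUSS_XI = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
_GAUSS_W = np.array([0.5, 0.5])


class NonConvergence(RuntimeError):
    """Raised when the Newton solver cannot equilibrate a load step."""


@dataclass(frozen=True)
class OvalizationRule:
    """Brazier-style strength knock-down for bent tubular sections.

    Bending a tube flattens (ovalizes) its cross-section: wall fibers under
    axial stress ``sigma_a ~ E3 kappa r`` are curved radially inward, pressing
    on the core with a crushing stress ``p ~ sigma_a t kappa = E3 kappa^2 r t``.
    Damage initiates when that demand approaches the transverse strength of
    the pith that braces the section, so fiber yield stresses are scaled by
    ``1 / (1 + coeff * eta)`` with ``eta = (1 - t/r) p / sigma11_pith``; the
    lumen-openness factor reflects that a filled (solid) section has no void
    to flatten into.  A soft-pith hollow stem (low sigma11) is penalized
    strongly; a solid-pith stem not at all.
    """

    enabled: bool = True
    coeff: float = 1.5


@dataclass
class FiberSection:
    """A circular (hollow or solid) cross-section tiled with fibers.

    Fibers occupy polar cells; ``y`` is the fiber centroid coordinate along
    the bending (wind) direction.  Areas are exact polar-cell areas, so they
    tile the section area exactly.
    """

    y: np.ndarray
    area_fib: np.ndarray
    E_fib: np.ndarray
    sy_fib: np.ndarray
    is_shell: np.ndarray
    outer_radius: float
    wall_thickness: float
    oval_factor: float  # coeff * E3_shell r t / sigma11_pith; 0 if off
    hardening_ratio: float = 0.0  # H / E per fiber

    @property
    def area(self) -> float:
        return float(self.area_fib.sum())

    @property
    def second_moment(self) -> float:
        return float((self.area_fib * self.y**2).sum())


def _build_section(
    r: float,
    t: float,
    shell_card: MaterialCard,
    pith_card: MaterialCard | None,
    n_theta: int = 24,
    n_rad: int = 6,
    ovalization: OvalizationRule = OvalizationRule(),
    hardening_ratio: float = 0.0,
) -> FiberSection:
    """Tile a hollow/solid circular section with polar fiber cells."""
    if not 0 < t <= r + 1e-12:
        raise ValueError(f"wall thickness must satisfy 0 < t <= r (t={t}, r={r})")
    solid = t >= r - 1e-12
    theta_edges = np.linspace(0.0, 2.0 * np.pi, n_theta + 1)
    th0, th1 = theta_edges[:-1], theta_edges[1:]
    th_c, dth = 0.5 * (th0 + th1), th1 - th0

    def ring_fibers(rho_in: float, rho_out: float, n: int):
        edges = np.linspace(rho_in, rho_out, n + 1)
        ys, areas = [], []
        for ri, ro in zip(edges[:-1], edges[1:]):
            a = 0.5 * (ro**2 - ri**2) * dth
            if ro > ri:
                rho_c = (2.0 / 3.0) * (ro**3 - ri**3) / (ro**2 - ri**2)
            else:  # pragma: no cover - degenerate ring
                rho_c = ri
            # centroid of an annular sector along the bending axis
            y = rho_c * np.sin(0.5 * dth) / (0.5 * dth) * np.cos(th_c)
            ys.append(y)
            areas.append(a)
        return np.concatenate(ys), np.concatenate(areas)

    y_parts, a_parts, e_parts, s_parts, shell_parts = [], [], [], [], []
    # shell annulus
    y_s, a_s = ring_fibers(r - t, r, n_rad)
    y_parts.append(y_s)
    a_parts.append(a_s)
    e_parts.append(np.full_like(y_s, shell_card.elastic.E3))
    s_parts.append(np.full_like(y_s, shell_card.strength.sigma33))
    shell_parts.append(np.ones_like(y_s, dtype=bool))
    if not solid:
        if pith_card is None:
            raise ValueError("hollow section with an interior requires a pith card")
        y_p, a_p = ring_fibers(0.0, r - t, n_rad)
        y_parts.append(y_p)
        a_parts.append(a_p)
        e_parts.append(np.full_like(y_p, pith_card.elastic.E3))
        s_parts.append(np.full_like(y_p, pith_card.strength.sigma33))
        shell_parts.append(np.zeros_like(y_p, dtype=bool))

    if ovalization.enabled and not solid:
        s11_pith = (pith_card or shell_card).strength.sigma11
        # lumen openness (1 - t/r): a filled section has no void to flatten
        # into, so its ovalization demand vanishes
        oval = (
            ovalization.coeff * (1.0 - t / r)
            * shell_card.elastic.E3 * r * t / s11_pith
        )
    else:
        oval = 0.0
    return FiberSection(
        y=np.concatenate(y_parts),
        area_fib=np.concatenate(a_parts),
        E_fib=np.concatenate(e_parts),
        sy_fib=np.concatenate(s_parts),
        is_shell=np.concatenate(shell_parts),
        outer_radius=r,
        wall_thickness=t,
        oval_factor=oval,
        hardening_ratio=hardening_ratio,
    )


@dataclass
class BeamModel:
    """Two-internode cantilever with fiber sections and attached loads."""

    node_y: np.ndarray  # undeformed heights of nodes, mm (base at 0)
    sections: list[FiberSection]  # one per element (midpoint geometry)
    loadset: LoadSet
    joint_height: float  # height of the internode joint, mm
    crop: str = ""

    def __post_init__(self) -> None:
        if len(self.sections) != len(self.node_y) - 1:
            raise ValueError("need one section per element")
        if np.any(np.diff(self.node_y) <= 0):
            raise ValueError("element lengths must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.node_y)

    @property
    def n_elems(self) -> int:
        return len(self.sections)

    @property
    def length(self) -> float:
        return float(self.node_y[-1] - self.node_y[0])

    def element_lengths(self) -> np.ndarray:
        return np.diff(self.node_y)

    def element_midheights(self) -> np.ndarray:
        return 0.5 * (self.node_y[:-1] + self.node_y[1:])


def build_stem_model(
    morphology: PlantMorphology,
    pith_card: MaterialCard,
    shell_card: MaterialCard,
    mesh_density: int = 8,
    loadset: LoadSet | None = None,
    taper: float = 0.2,
    node_segment_frac: float = 0.05,
    ovalization: OvalizationRule = OvalizationRule(),
    hardening: float = 0.3,
    n_theta: int = 24,
    n_rad: int = 6,
) -> BeamModel:
    """Mesh the two lowermost internodes as a fiber-section cantilever.

    ``taper`` is the total relative radius change across an internode (the
    mean is preserved); ``node_segment_frac`` sets the stiffened solid joint
    segment length as a fraction of L1, straddling the joint.
    """
    if mesh_density < 1:
        raise ValueError("mesh_density must be >= 1")
    i1, i2 = morphology.internodes[0], morphology.internodes[1]
    L1, L2 = i1.length, i2.length
    l_node = node_segment_frac * L1
    if loadset is None:
        loadset = LoadSet(W_u=0.0, F_w0=0.0, M_w0=0.0)

    def radius_at(inode, s_frac: float) -> float:
        # linear taper, wide at the bottom, mean preserved
        return inode.outer_radius * (1.0 + taper * (0.5 - s_frac))

    def thickness_at(inode, s_frac: float) -> float:
        if inode.is_solid:
            return radius_at(inode, s_frac)
        return inode.wall_thickness * (1.0 + taper * (0.5 - s_frac))

    node_y: list[float] = [0.0]
    sections: list[FiberSection] = []

    def add_span(y0: float, y1: float, n: int, sec_fn) -> None:
        ys = np.linspace(y0, y1, n + 1)[1:]
        for ya, yb in zip([y0, *ys[:-1]], ys):
            node_y.append(yb)
            sections.append(sec_fn(0.5 * (ya + yb)))

    # internode 1 below the joint segment
    top1 = L1 - 0.5 * l_node if l_node > 0 else L1
    add_span(
        0.0, top1, mesh_density,
        lambda ym: _build_section(
            radius_at(i1, ym / L1), thickness_at(i1, ym / L1),
            shell_card, pith_card, n_theta, n_rad, ovalization, hardening,
        ),
    )
    # stiffened solid node segment straddling the joint
    if l_node > 0:
        r_node = max(radius_at(i1, top1 / L1), radius_at(i2, 0.0))
        add_span(
            top1, L1 + 0.5 * l_node, 1,
            lambda ym: _build_section(
                r_node, r_node, shell_card, None, n_theta, n_rad,
                OvalizationRule(enabled=False), hardening,
            ),
        )
        bot2 = L1 + 0.5 * l_node
    else:
        bot2 = L1
    # internode 2
    add_span(
        bot2, L1 + L2, mesh_density,
        lambda ym: _build_section(
            radius_at(i2, (ym - L1) / L2), thickness_at(i2, (ym - L1) / L2),
            shell_card, pith_card, n_theta, n_rad, ovalization, hardening,
        ),
    )

    return BeamModel(
        node_y=np.array(node_y),
        sections=sections,
        loadset=loadset,
        joint_height=L1,
        crop=morphology.crop,
    )


def make_prismatic_model(
    length: float,
    r: float,
    t: float,
    shell_card: MaterialCard,
    pith_card: MaterialCard | None = None,
    n_elem: int = 10,
    loadset: LoadSet | None = None,
    ovalization: OvalizationRule = OvalizationRule(enabled=False),
    hardening: float = 0.0,
    n_theta: int = 24,
    n_rad: int = 6,
) -> BeamModel:
    """A uniform cantilever (oracle/benchmark geometry)."""
    sec = _build_section(r, t, shell_card, pith_card, n_theta, n_rad, ovalization,
                         hardening)
    node_y = np.linspace(0.0, length, n_elem + 1)
    if loadset is None:
        loadset = LoadSet(W_u=0.0, F_w0=0.0, M_w0=0.0)
    return BeamModel(
        node_y=node_y, sections=[sec] * n_elem, loadset=loadset,
        joint_height=length,
    )


# ---------------------------------------------------------------------------
# Section and element response
# ---------------------------------------------------------------------------

_TANGENT_FLOOR = 1e-8  # fraction of E kept on the plastic branch for stability


def _model_arrays(model: BeamModel) -> dict:
    """Padded per-element fiber arrays, cached on the model.

    Sections have differing fiber counts (solid vs hollow); padding fibers
    carry zero area so they never contribute.
    """
    cache = getattr(model, "_fiber_cache", None)
    if cache is not None:
        return cache
    nel = model.n_elems
    nf = max(len(s.y) for s in model.sections)
    Y = np.zeros((nel, nf))
    A = np.zeros((nel, nf))
    E = np.ones((nel, nf))
    SY = np.full((nel, nf), 1e30)  # padding fibers never yield
    for e, s in enumerate(model.sections):
        k = len(s.y)
        Y[e, :k], A[e, :k], E[e, :k], SY[e, :k] = s.y, s.area_fib, s.E_fib, s.sy_fib
    cache = {
        "Y": Y, "A": A, "E": E, "SY": SY,
        "H": np.array([s.hardening_ratio for s in model.sections])[:, None] * E,
        "OV": np.array([s.oval_factor for s in model.sections]),
        "L0": np.diff(model.node_y),
    }
    object.__setattr__(model, "_fiber_cache", cache)
    return cache


class _State:
    """Committed fiber state plus energy bookkeeping."""

    def __init__(self, model: BeamModel):
        arr = _model_arrays(model)
        nel, nf = arr["Y"].shape
        self.eps_p = np.zeros((nel, 2, nf))
        self.sig = np.zeros((nel, 2, nf))
        self.diss_elem = np.zeros(nel)
        self.work_ext = 0.0

    def copy(self) -> "_State":
        new = object.__new__(_State)
        new.eps_p = self.eps_p.copy()
        new.sig = self.sig.copy()
        new.diss_elem = self.diss_elem.copy()
        new.work_ext = self.work_ext
        return new


def _assemble(model, d, state, commit_to=None):
    """Internal force vector and tangent matrix, vectorized over elements."""
    arr = _model_arrays(model)
    Y, A, E, SY, H, OV, L0 = (
        arr["Y"], arr["A"], arr["E"], arr["SY"], arr["H"], arr["OV"], arr["L0"]
    )
    nel = model.n_elems
    D = d.reshape(-1, 3)
    dx = D[1:, 0] - D[:-1, 0]
    ey = D[1:, 1] - D[:-1, 1]  # elongation along the undeformed axis
    dy = L0 + ey
    # Ln^2 - L0^2 without cancellation (ey is exact nodal data); the naive
    # difference would inject eps*EA-scale noise into the axial force
    lsq_excess = dx * dx + ey * (ey + 2.0 * L0)
    Ln = np.sqrt(L0 * L0 + lsq_excess)
    cos, sin = dx / Ln, dy / Ln
    alpha = np.arctan2(dy, dx) - np.pi / 2.0
    eps0 = lsq_excess / (Ln + L0) / L0
    th1 = D[:-1, 2] - alpha
    th2 = D[1:, 2] - alpha

    f_loc = np.zeros((nel, 3))
    k_loc = np.zeros((nel, 3, 3))
    for g, (xi, wg) in enumerate(zip(_GAUSS_XI, _GAUSS_W)):
        b1 = (6.0 * xi - 4.0) / L0
        b2 = (6.0 * xi - 2.0) / L0
        kappa = b1 * th1 + b2 * th2
        # fiber state with kinematic hardening and ovalization knock-down
        eps = eps0[:, None] - Y * kappa[:, None]
        eta = OV * kappa**2
        sy = SY / (1.0 + eta[:, None])
        sig_tr = E * (eps - state.eps_p[:, g, :])
        xi_tr = sig_tr - H * state.eps_p[:, g, :]
        over = np.abs(xi_tr) - sy
        plastic = over > 0.0
        d_eps_p = np.where(plastic, np.sign(xi_tr) * over / (E + H), 0.0)
        sig = sig_tr - E * d_eps_p
        Et = np.where(plastic, np.maximum(E * H / (E + H), _TANGENT_FLOOR * E), E)

        N = (sig * A).sum(axis=1)
        M = -(sig * Y * A).sum(axis=1)
        d11 = (Et * A).sum(axis=1)
        d12 = -(Et * Y * A).sum(axis=1)
        d22 = (Et * Y**2 * A).sum(axis=1)

        f_loc[:, 0] += wg * N
        f_loc[:, 1] += wg * M * (6.0 * xi - 4.0)
        f_loc[:, 2] += wg * M * (6.0 * xi - 2.0)
        w = wg * L0
        k_loc[:, 0, 0] += w * d11 / L0**2
        k_loc[:, 0, 1] += w * d12 * b1 / L0
        k_loc[:, 0, 2] += w * d12 * b2 / L0
        k_loc[:, 1, 0] += w * d12 * b1 / L0
        k_loc[:, 2, 0] += w * d12 * b2 / L0
        k_loc[:, 1, 1] += w * d22 * b1 * b1
        k_loc[:, 1, 2] += w * d22 * b1 * b2
        k_loc[:, 2, 1] += w * d22 * b1 * b2
        k_loc[:, 2, 2] += w * d22 * b2 * b2

        if commit_to is not None:
            commit_to.diss_elem += w * (
                0.5 * (sig + state.sig[:, g, :]) * d_eps_p * A
            ).sum(axis=1)
            commit_to.eps_p[:, g, :] = state.eps_p[:, g, :] + d_eps_p
            commit_to.sig[:, g, :] = sig

    zeros = np.zeros(nel)
    r_vec = np.stack([-cos, -sin, zeros, cos, sin, zeros], axis=1)
    z_vec = np.stack([sin, -cos, zeros, -sin, cos, zeros], axis=1)
    T = np.zeros((nel, 3, 6))
    T[:, 0, :] = r_vec
    T[:, 1, :] = -z_vec / Ln[:, None]
    T[:, 1, 2] += 1.0
    T[:, 2, :] = -z_vec / Ln[:, None]
    T[:, 2, 5] += 1.0

    f_glob = np.einsum("eai,ea->ei", T, f_loc)
    k_glob = np.einsum("eai,eab,ebj->eij", T, k_loc, T)
    k_glob += (f_loc[:, 0] / Ln)[:, None, None] * np.einsum(
        "ei,ej->eij", z_vec, z_vec
    )
    m_sum = (f_loc[:, 1] + f_loc[:, 2]) / Ln**2
    rz = np.einsum("ei,ej->eij", r_vec, z_vec)
    k_glob += m_sum[:, None, None] * (rz + rz.transpose(0, 2, 1))

    n = 3 * model.n_nodes
    F = np.zeros(n)
    K = np.zeros((n, n))
    for e in range(nel):
        sl = slice(3 * e, 3 * e + 6)
        F[sl] += f_glob[e]
        K[sl, sl] += k_glob[e]
    return F, K


def _external_load(model: BeamModel, lam_gravity: float, lam_wind: float) -> np.ndarray:
    """Dead (fixed-direction) nodal loads for given gravity/wind factors."""
    n = 3 * model.n_nodes
    P = np.zeros(n)
    ls = model.loadset
    # body force: lumped element weights over the full (pith + shell) section
    for e, sec in enumerate(model.sections):
        L0 = model.node_y[e + 1] - model.node_y[e]
        w = ls.G * np.pi * sec.outer_radius**2 * L0
        P[3 * e + 1] -= lam_gravity * 0.5 * w
        P[3 * (e + 1) + 1] -= lam_gravity * 0.5 * w
    top = 3 * (model.n_nodes - 1)
    P[top + 1] -= lam_gravity * ls.W_u
    P[top] += lam_wind * ls.F_w0
    P[top + 2] -= lam_wind * ls.M_w0
    return P


# ---------------------------------------------------------------------------
# Quasi-static solver
# ---------------------------------------------------------------------------

_REL_TOL = 1e-8
_MAX_ITER = 25


def _newton(model, d, state, lam_g, lam_w):
    """Equilibrate one load level; returns (d, trial_state) or raises."""
    P = _external_load(model, lam_g, lam_w)
    free = np.arange(3, 3 * model.n_nodes)  # base node fully fixed
    # relative residual tolerance with an absolute floor of 3e-5 uN (3e-11 N):
    # the round-off floor of assembled internal forces sits near 5e-6 uN, so
    # near-zero load levels cannot be held to 1e-8 of their own tiny norm
    ref = max(np.linalg.norm(P[free]), 3.0e3)
    d = d.copy()
    best = np.inf
    worse = 0
    for _ in range(_MAX_ITER):
        F, K = _assemble(model, d, state)
        R = P - F
        rnorm = np.linalg.norm(R[free])
        if rnorm <= _REL_TOL * ref:
            commit = state.copy()
            _assemble(model, d, state, commit_to=commit)
            return d, commit, P
        # bail out early on clear divergence: load stepping will halve
        if rnorm < best:
            best, worse = rnorm, 0
        else:
            worse += 1
            if worse >= 4 or rnorm > 1e6 * ref:
                break
        try:
            dd = np.linalg.solve(K[np.ix_(free, free)], R[free])
        except np.linalg.LinAlgError:
            break  # singular tangent: let load stepping halve the increment
        if not np.all(np.isfinite(dd)):
            break
        d[free] += dd
    raise NonConvergence(
        f"no equilibrium at load factors gravity={lam_g:.3f}, wind={lam_w:.4f}"
    )


@dataclass
class SimResult:
    """Outcome of a loading/unloading simulation."""

    u_max: float
    u_res: float
    tip_path: np.ndarray  # (n_steps, 2) tip displacement per committed step
    deformed_profiles: dict  # phase name -> (n_nodes, 2) current coordinates
    pemag: np.ndarray  # (n_elems, 2) plastic strain magnitude per Gauss point
    dissipation_per_element: np.ndarray
    converged: bool
    energy: dict = field(default_factory=dict)
    element_midheights: np.ndarray | None = None
    joint_height: float = 0.0
    model_length: float = 0.0

    def __post_init__(self) -> None:
        if self.u_max < 0 or self.u_res < -1e-12:
            raise ValueError("displacements must be non-negative")
        if np.any(self.pemag < -1e-15):
            raise ValueError("plastic strain magnitude must be non-negative")


def solve_quasistatic(
    model: BeamModel,
    schedule: list[tuple[float, float]],
    max_halvings: int = 8,
    record_profiles: bool = False,
):
    """March through (lambda_gravity, lambda_wind) load levels with Newton.

    The schedule must start at zero load.  Steps that fail to converge are
    automatically bisected (up to ``max_halvings`` times); a persistent
    failure raises :class:`NonConvergence` carrying the last converged state
    rather than returning silently wrong results.

    Returns ``(d, state, history)`` where ``history`` is a list of
    ``(lam_g, lam_w, d, P_ext)`` at committed levels.
    """
    if schedule[0] != (0.0, 0.0):
        raise ValueError("load schedule must start at zero load")
    d = np.zeros(3 * model.n_nodes)
    state = _State(model)
    P_prev = np.zeros_like(d)
    history = [(0.0, 0.0, d.copy(), P_prev.copy())]
    lam = (0.0, 0.0)
    for target in schedule[1:]:
        pending = [target]
        guard = 0
        while pending:
            guard += 1
            if guard > 500:  # pragma: no cover - pathological schedules
                raise NonConvergence(
                    f"load stepping stalled before reaching {target}"
                )
            tg = pending[-1]
            try:
                d_new, state_new, P = _newton(model, d, state, tg[0], tg[1])
            except NonConvergence:
                if len(pending) > max_halvings:
                    raise
                pending.append((0.5 * (lam[0] + tg[0]), 0.5 * (lam[1] + tg[1])))
                continue
            # external work by trapezoid over the increment
            state_new.work_ext = state.work_ext + float(
                0.5 * (P + P_prev) @ (d_new - d)
            )
            d, state, P_prev, lam = d_new, state_new, P, tg
            history.append((lam[0], lam[1], d.copy(), P.copy()))
            pending.pop()
    return d, state, history


def _elastic_energy(model: BeamModel, state: _State) -> float:
    arr = _model_arrays(model)
    per_gauss = (0.5 * state.sig**2 / arr["E"][:, None, :] * arr["A"][:, None, :]).sum(
        axis=2
    )
    return float((per_gauss * _GAUSS_W[None, :] * arr["L0"][:, None]).sum())


def simulate_load_unload(
    model: BeamModel,
    case: WindCase | None = None,
    n_load: int = 8,
    n_unload: int = 6,
    record_profiles: bool = True,
) -> SimResult:
    """Gravity on, wind drag ramped 0 -> 1 -> 0; W_u and body force held.

    ``u_max`` is the top-node displacement magnitude (relative to the
    gravity-only state) at the end of loading; ``u_res`` the same at the end
    of unloading.
    """
    lam_w_up = np.linspace(0.0, 1.0, n_load + 1)[1:]
    lam_w_down = np.linspace(1.0, 0.0, n_unload + 1)[1:]
    schedule = [(0.0, 0.0), (0.5, 0.0), (1.0, 0.0)]
    schedule += [(1.0, lw) for lw in lam_w_up]
    schedule += [(1.0, lw) for lw in lam_w_down]
    d, state, history = solve_quasistatic(model, schedule)
    converged = True

    top = 3 * (model.n_nodes - 1)
    # reference: gravity fully applied, wind not yet started (sub-stepping may
    # insert extra history entries, so locate it by its load factors)
    i_ref = next(
        i for i, h in enumerate(history)
        if h[0] >= 1.0 - 1e-12 and h[1] <= 1e-12
    )
    tip_ref = history[i_ref][2][top:top + 2]
    tip_path = np.array([h[2][top:top + 2] - tip_ref for h in history[i_ref:]])
    # end of loading = last point with lam_w == 1
    i_load_end = max(i for i, h in enumerate(history) if h[1] >= 1.0 - 1e-12)
    u_max = float(np.linalg.norm(history[i_load_end][2][top:top + 2] - tip_ref))
    u_res = float(np.linalg.norm(history[-1][2][top:top + 2] - tip_ref))

    pemag = np.max(np.abs(state.eps_p), axis=2)  # (n_elems, 2 Gauss points)

    profiles = {}
    if record_profiles:
        X = np.column_stack([np.zeros(model.n_nodes), model.node_y])
        for name, i in (("loaded", i_load_end), ("unloaded", len(history) - 1)):
            di = history[i][2]
            profiles[name] = X + di.reshape(-1, 3)[:, :2]

    u_elastic_res = _elastic_energy(model, state)
    energy = {
        "external_work": state.work_ext,
        "plastic_dissipation": float(state.diss_elem.sum()),
        "residual_elastic_energy": u_elastic_res,
    }
    return SimResult(
        u_max=u_max,
        u_res=u_res,
        tip_path=tip_path,
        deformed_profiles=profiles,
        pemag=pemag,
        dissipation_per_element=state.diss_elem.copy(),
        converged=converged,
        energy=energy,
        element_midheights=model.element_midheights(),
        joint_height=model.joint_height,
        model_length=model.length,
    )


def residual_ratio(result: SimResult) -> float:
    """u_res / u_max: 0 = fully elastic recovery, 0.3 = assumed failure."""
    if result.u_max <= 0:
        raise ValueError("residual ratio undefined: u_max is zero")
    ratio = result.u_res / result.u_max
    if ratio > 1.0 + 1e-6:
        raise ValueError(f"residual ratio {ratio} exceeds 1")
    return ratio


@dataclass
class LimitingSpeedResult:
    v_limit_m_s: float | None
    reached: bool
    curve: np.ndarray  # (n, 2): speed m/s, residual ratio
    threshold: float


def limiting_wind_speed(
    morphology: PlantMorphology,
    pith_card: MaterialCard,
    shell_card: MaterialCard,
    threshold: float = 0.3,
    grid: float = 0.5,
    v_max: float = 20.0,
    mesh_density: int = 8,
    refine: int = 3,
    **model_kwargs,
) -> LimitingSpeedResult:
    """Smallest wind speed whose load/unload residual ratio reaches threshold.

    Scans the speed grid upward, then bisects the bracketing interval
    ``refine`` times.  The returned curve holds the full (speed, ratio)
    sweep for the elastic/elastoplastic regimes plot.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if grid <= 0:
        raise ValueError("grid must be positive")

    def ratio_at(v_m_s: float) -> float:
        case = WindCase.from_m_s(v_m_s)
        loads = build_loadset(morphology, case)
        model = build_stem_model(
            morphology, pith_card, shell_card, mesh_density=mesh_density,
            loadset=loads, **model_kwargs,
        )
        try:
            res = simulate_load_unload(model, case, record_profiles=False)
        except NonConvergence:
            # loss of equilibrium under load control = structural collapse,
            # which certainly exceeds the residual-ratio failure threshold
            return 1.0
        return residual_ratio(res)

    curve = []
    v_lo, v_hi = None, None
    v = grid
    while v <= v_max + 1e-9:
        rr = ratio_at(v)
        curve.append((v, rr))
        if rr >= threshold:
            v_hi = v
            v_lo = v - grid if v - grid > 0 else 0.0
            break
        v = round(v + grid, 10)
    if v_hi is None:
        return LimitingSpeedResult(None, False, np.array(curve), threshold)

    lo, hi = v_lo, v_hi
    for _ in range(refine):
        mid = 0.5 * (lo + hi)
        if mid <= 0:
            break
        rr = ratio_at(mid)
        curve.append((mid, rr))
        if rr >= threshold:
            hi = mid
        else:
            lo = mid
    curve = np.array(sorted(curve))
    return LimitingSpeedResult(float(hi), True, curve, threshold)


def extend_profile(
    profile: np.ndarray, extra_length: float, n_points: int = 40
) -> np.ndarray:
    """Append a straight segment along the final tangent of a deformed profile.

    Stands in for the rigid upper plant (internodes 3-4 and panicle) above
    the modeled part when a full-plant centerline is needed, e.g. for
    silhouette rendering.
    """
    p = np.asarray(profile, dtype=float)
    if extra_length <= 0:
        return p
    tang = p[-1] - p[-2]
    tang = tang / np.linalg.norm(tang)
    s = np.linspace(0.0, extra_length, n_points + 1)[1:, None]
    return np.vstack([p, p[-1] + s * tang])


def localization_index(result: SimResult, window: float = 0.10) -> float:
    """Fraction of plastic dissipation within ``window``*L below the joint.

    0 when no plasticity occurred anywhere.
    """
    if not 0.0 < window <= 1.0:
        raise ValueError("window must lie in (0, 1]")
    total = result.dissipation_per_element.sum()
    if total <= 0.0:
        return 0.0
    lo = result.joint_height - window * result.model_length
    hi = result.joint_height
    mid = result.element_midheights
    mask = (mid >= lo) & (mid < hi)
    return float(result.dissipation_per_element[mask].sum() / total)
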