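# Methods

This note documents the models behind `lodgesim`, the assumptions they
make, the shipped parameter values and where they come from, and the
numerical choices that matter for reproducing its outputs.

## Scope and units

The package analyses single cereal stems (oat and wheat) under steady wind
in a controlled-flow setting: no canopy interaction, no turbulence or
gusts, no structural dynamics, and no root–soil anchorage — wind drag and
gravity are the only loads, applied quasi-statically. Internally
everything is mm–g–s: the force unit is then the microNewton and the
stress unit is exactly the Pascal, so material moduli carry no conversion
factors. Interfaces report Newtons and m s⁻¹.

## Synthetic plants (`morphotypes`)

A crop template holds per-trait means and SDs for four internode lengths,
outer radii and wall thicknesses, plus panicle mass, height and frontal
area. Traits are drawn as independent truncated normals (truncated at the
physical bounds; the 10% default CV keeps the bounds many SDs away, so
rejection sampling is essentially exact). Wall thickness is drawn
conditionally on the radius so 0 < t ≤ r always holds; the wheat template
pins t1 = r1 (near-solid first internode). Total height is the sum of
internode lengths plus panicle height, so the generated height inherits
the template aggregate (oat 984.4 mm, wheat 720.9 mm — the crop means of
the population the generator emulates, as are the trial-trait means:
heading 47.4/47.7 days, plant strength 0.78/1.23 N, biomass 13.11/9.87 g).

Radii order follows culm allometry — the lowermost internode is the
narrowest and the culm widens toward mid-stem (oat 1.22/1.35/1.10/0.98 mm,
wheat 1.00/1.10/0.94/0.86 mm). This matters mechanically: with the
panicle-drag moment nearly uniform over the modelled part, the weakest
cross-section sets the failure location, and the taper puts it just below
the first node, where stem failure is observed.

The silhouette renderer draws the deformed centerline as a band of the
stated stem width with a one-pixel antialiased boundary (so the edge can
be located to sub-pixel accuracy), anchored at the stem base; x points
downstream, y up. Per-row Gaussian jitter emulates segmentation noise.
What the renderer does *not* emulate: leaves and their smearing in wind,
occlusion, lighting, or background clutter — passing the imaging tests
therefore shows the geometry pipeline is correct, not that masking of real
footage is solved.

Trial layout: one record per cultivar × block (4 oat + 4 wheat cultivars,
3 blocks), with multiplicative cultivar (5% CV), block (3%) and residual
(8%) effects on each trait, and a seeded permutation as the within-block
run order.

## Material cards (`micromech`)

Two-step homogenization, axis 3 = stem axis, transverse isotropy enforced
throughout:

1. **Cell wall** — Voigt (uniform-strain) stiffness average over
   constituent mass fractions treated as volume fractions. Appropriate
   for a stiff, tightly bonded laminate; it is the upper mixture bound,
   and the test suite brackets every output between the Voigt and Reuss
   tensor bounds.
2. **Tissue** — Mori–Tanaka estimate with aligned spheroidal voids (cell
   lumina; aspect ratio = axial/transverse, prolate for parenchyma ~2 and
   fibre lumina ~6). The Eshelby tensor uses the isotropized (Hill
   average) matrix — the standard engineering approximation; the matrix
   stiffness itself stays transversely isotropic. Aspect ratios within
   1e-4 of a sphere are routed to the closed-form sphere branch because
   the general elliptic expressions lose all precision there.
   Regions then mix by volume-weighted stiffness averaging
   (pith = parenchyma; shell = dense sclerenchyma-like tissue + 25%
   vascular bundles at 95% wall fraction).

Limit strengths scale with the same per-direction stiffness concentration
factors, anchored to cell-wall yield strains (axial 0.0018, transverse
0.00144). This is the simplest rule consistent with the homogenization
weights; it is isolated behind `material_cards` so a measured strength
table can replace it.

Fixture provenance: none of the constituent moduli, compositions or
tissue fractions are measured values — they are
synthetic fixtures chosen once within literature-typical ranges
(cellulose as an effective in-wall fibril at 40 GPa axial, i.e.
microfibril-angle-softened; lignin 4 GPa; hemicellulose 7 GPa), with the
two crop differences that drive the analysis: wheat has the higher lignin
fraction (0.23 vs 0.16) and the higher parenchyma wall fraction (0.28 vs
0.10). Those two differences alone produce a wheat/oat transverse pith
stiffness and strength ratio of 3.18 — the ~3× contrast at the heart of
the crop comparison. The yield strains and the morphology fixtures were
calibrated once so the limiting-speed sweep lands in the regime the
method is designed to resolve (oat near 8, wheat near 10 m s⁻¹) and then
frozen; they are inputs of the shipped demo conditions, not fitted
parameters of the model.

## Wind loading (`windload`)

Only the panicle carries drag (the stem's frontal area is small and sits
in the floor boundary layer); `stem_drag_per_length` exists for
sensitivity studies but nothing uses it by default. The panicle drag
coefficient is 0.5 (a vertical cylinder in cross flow). The drag force is
exactly quadratic in wind speed and acts at the top of the modelled part
together with its moment through the rigid upper-plant lever arm
(L3 + L4 + h_p/2). The upper plant's weight W_u and the modelled part's
body force (stem density 3×10⁻⁴ g mm⁻³) are dead loads, constant through
loading and unloading. The tunnel protocol is three 50 s plateaus at 4, 8
and 12 m s⁻¹ joined by 5 s linear ramps (the ramp shape is our choice; only
its duration is prescribed), deceleration to 4 m s⁻¹, and a stop at 170 s.

## Bending simulation (`stemfe`)

**Discretization.** Planar corotational beam elements (3 DOF/node) along
the two lowermost internodes, 8 elements per internode plus one stiffened
solid element of length 0.05·L1 straddling the node; the base node is
fully fixed. Each element carries a fiber section: polar cells (24
angular × 6 radial per region) tiling the shell annulus and pith core
exactly in area (cell centroids preserve the first moment; the second
moment matches the closed form within 0.7%). Sections taper linearly
within each internode (total relative radius change 0.2, mean preserved).

**Kinematics.** The corotational split handles arbitrary rigid rotations;
local behaviour is Euler–Bernoulli with a linear curvature field and two
Gauss points per element. The element elongation is computed from the
exact nodal elongation difference rather than coordinate-norm differences
— the naive form injects eps·EA-scale noise (~10⁻⁵ µN) into the axial
residual and stalls Newton at small loads.

**Material.** Fibers are elastoplastic in the axial direction with yield
stress sigma33 of their region and linear kinematic hardening H = 0.3 E.
The hardening is a deliberate departure from a perfectly plastic idealization:
under load control a perfectly plastic fiber beam has no equilibrium past
its limit moment and jumps from fully elastic to collapse within one
sweep step, whereas the observable this model exists for — residual
displacement growing gradually with wind speed — requires a stable
post-yield branch, which a redistributing 3D continuum possesses and a
fiber beam must recover through hardening.

**Ovalization.** Bending flattens a hollow section. Wall fibers at axial
stress ~E3·kappa·r curved radially press on the core with crushing
pressure p ≈ E3·kappa²·r·t; fiber yield stresses are scaled by
1/(1 + 1.5·(1 − t/r)·p/sigma11_pith). The lumen-openness factor (1 − t/r)
encodes that a filled section has no void to flatten into. The knock-down
acts on strength only (not stiffness): it models damage initiation, and a
state-dependent stiffness would make unloading path-inconsistent. This
single rule produces the crop-differentiating mechanism: oat's hollow,
soft-pith first internode softens locally just below the node and
concentrates plastic dissipation there (localization index 0.66 at its
limiting speed), while wheat's solid, 3× transversely stronger pith takes
no knock-down and spreads plasticity along the first internode (0.40).

**Solution.** Full Newton per load level with the consistent tangent;
convergence at residual ≤ 1e-8 × applied-load norm with an absolute floor
of 3×10⁻⁵ µN (the assembly round-off floor is ~5×10⁻⁶ µN). Load levels
that fail (divergence, singular tangent) are bisected toward the last
converged level up to 8 times; persistent failure raises, never returns
silently — and in the speed sweep a collapse under load control is scored
as residual ratio 1 (failure certainly exceeds the threshold). The
load/unload schedule is gravity in 2 steps, wind 0→1 in 8, wind 1→0 in 6.

**Outputs.** u_max and u_res are top-node displacement magnitudes relative
to the gravity-only state at the ends of loading and unloading; the
residual ratio u_res/u_max is 0 for elastic response and reaches the 0.3
failure threshold at the limiting wind speed, located by an upward grid
scan (0.5 m s⁻¹) plus 3 bisection refinements. Energy bookkeeping (external
work, plastic work, residual stored energy) closes to ~10⁻⁴ relative and
is asserted at 2% in the tests. PEMAG is the per-Gauss-point maximum
fiber plastic strain; the localization index is the fraction of plastic
dissipation within the 10% of modelled length just below the node.

With the shipped fixtures the sweeps give oat 7.94 m s⁻¹ and wheat
9.88 m s⁻¹ (threshold 0.3, grid 0.5), the oat residual ratio at 8 m s⁻¹ is
0.32, and wheat both recovers more at any common speed and fails later —
the stiffness/recovery contrast between the crops.

## Phenotyping (`phenotypes`)

The windward edge is the left threshold crossing per image row, refined to
sub-pixel on the antialiased boundary; specks under 2% of the main blob
are cleaned, genuinely split silhouettes rejected. Edge points shift half
a stem width along the local inward normal (slope from a Savitzky–Golay
smoothed profile — a raw-noise slope inflates √(1+x'²) and biases the
correction) so profiles track the centerline; rows within ~¾ width of the
profile ends are dropped (band caps).

The bending profile is fit with f(x) = c·x^d in three stages: log–log
seed, vertical least squares, then orthogonal-distance refinement. The
orthogonal stage is essential near the base, where the curve runs
near-vertical and a sub-pixel x error produces an enormous vertical
residual that would dominate a naive objective; with it, noiseless
round trips recover (c, d) to better than 0.1%.

θ is the secant angle from the base to the half-arc-length point: solve
arc-length(x0) = H/2 along the fitted curve (integrating over x for d ≥ 1
and over height otherwise, keeping the integrand bounded at the vertical
tangent), then θ = atan(f(x0)/x0). The reference deformation is θ = 50°;
when a stem never reaches it, C_d and CL_r are evaluated at the smallest
angle attained and flagged.

F_w converts the load-cell follower force F_s (applied ⊥ to the stem at
the half-height point) to the equivalent horizontal force by equating
virtual work over a rigid virtual rotation of the deformed shape about
the base: F_s/sin θ for a straight-line shape, the analogous curve
expression when a fit is supplied. The frontal-area upper bound is the
windward edge's projected vertical extent times the plant width, making
C_d = 2F_w/(rho_air·A·v²) a lower bound — enlarging A can only lower it.

CL_r uses the pluggable "lever-arm-deficit" definition:
CL_r = 1 − f(x0)/(H/2), the fraction of the rigid-upright lever arm the
stem has surrendered at the half-length point; every record stores the
definition tag that produced its value. Note the sign consequence: under
this definition *more bending gives a higher CL_r*, so the crop ordering
is inverted relative to a torque-resisted/torque-applied ratio, for which
uprightness scores high. The strategy hook exists precisely so an
alternative definition can be dropped in without touching records.

Per-second time series average the frames in one-second bins (24 fps
against the 1 s pitot cadence; misaligned logs are rejected with the
offset). θ_max is the mean θ over the maximum-speed plateau and the
recovery angle is the final θ minus the plateau minimum.

## Trial statistics (`stats`)

The additive fixed-effects model crop + cultivar-within-crop + block is
fitted by OLS (statsmodels); the Type-I table, however, is assembled from
explicit orthonormal projections onto the nested design spaces. The
reason is structural: cultivar indicators sum exactly to their crop
indicator, so the dummy design is rank-deficient and generic sequential
ANOVA assigns the nested term 7 df instead of 8 − 2 = 6, breaking the SS
partition. The projection construction gives the exact partition (asserted
at 1e-8) and the correct df; block is treated as fixed. Fisher's LSD at
α = 0.05 separates crop means with a strict inequality at the boundary,
computed (and flagged) whether or not the F-test is significant. The
Pearson matrix runs over cultivar-averaged values with t-distribution
stars at 0.05/0.01/0.001. A permutation oracle (free permutation for
crop, within-crop permutation for the nested term; F recomputed from the
same projections) cross-checks the parametric p-values.

## Problem sizes

The shipped defaults are sized for desk-scale runs: 17 beam elements and
~290 fibers per section; speed sweeps of ~20 load/unload simulations per
crop; imaging round trips of 4–6 simulated seconds at 24 frames each;
10⁴-draw permutation oracles on 24-record trials. The full demo pipeline
runs in about a minute on one CPU.

## Known limitations

* The fiber beam reproduces the reported observables (u_max, u_res, the
  PEMAG distribution along the stem, limiting speeds) but not element-wise
  3D fields; cross-section distortion is parameterized, not resolved.
* The strength-from-stiffness rule and the ovalization coefficient are
  plausible closures, not measured laws; both are isolated and
  replaceable.
* Material cards, compositions and morphology fixtures are synthetic;
  conclusions about *real* cultivars require replacing them with measured
  tables (the JSON card format and crop templates are the insertion
  points).
* The renderer's silhouettes are leafless and high-contrast; the imaging
  chain is validated only for such scenes.
* Quasi-static loading cannot capture resonance or gust transients, which
  matter in canopies; the model is representative for direct steady wind
  exposure.
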