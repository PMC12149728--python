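# Methods

## Problem setting

A cylindrical intracavitary applicator (20 mm outer diameter) holds a
rotatable tungsten shield (15 mm diameter) with a central 2 mm source
channel and an azimuthal emission window of 180° or 90°, 8 cm long.
Dwell positions are spaced 5 mm along the window (17 positions,
inclusive of both ends and centred on the window) and shield angles are
discretized in 15° increments (24 angles), giving |J| = 408
dwell/angle combinations. The optimization variables are the dwell
times t_j ≥ 0.

Positional uncertainty is systematic: one signed rotational offset of
the shield angle, or one signed translational offset of the source
along the applicator axis, applied identically to every combination.
Planning scenario sets default to {nominal, +δ, −δ} with δ = 5° for
rotations and δ = 2 mm for translations; evaluation sweeps ±3°, ±5°,
±10° and ±1, ±2, ±3 mm. Including the nominal scenario in the planning
set is configurable (default on): the minimax term weighs the worst
scenario against the scenario average, and the nominal scenario is the
natural anchor of that average.

## Synthetic phantoms

Each phantom is a water-equivalent voxel grid (default extent
52 × 52 × 130 mm) with the applicator on the +z axis. Structures:

- **CTV** — an azimuthal sector of the rectal-wall annulus
  (applicator surface to +5 mm wall thickness) abutting the applicator,
  centred at azimuth 0° by convention. Sector width, axial length and
  axial offset are drawn per phantom from uniform ranges (90–150°,
  30–50 mm, ±8 mm) under a splittable (master_seed, index) seed, so
  cohorts are bit-reproducible and each phantom is independent of
  cohort ordering.
- **contra** — the contralateral wall sector centred at 180°, default
  width 180° (every voxel ≥ 90° from the CTV centre), sharing the CTV's
  axial extent. With the 180° emission window its edges sit exactly at
  the window edges, which is what makes its hot-spot index (D0.1cc)
  sensitive to rotational errors.
- **sup / inf** — dose-spill boxes (30 mm square cross-section minus
  the applicator bore, 10 mm long) whose proximal faces sit exactly
  10 mm beyond the CTV's superior/inferior extent.

Membership is by voxel centre on a grid centred on the axis, which
keeps a CTV centred at azimuth 0 exactly mirror-symmetric under
y → −y — the symmetry the ±δ rotation tests rely on. Structure
geometry is continuous and resolution-independent; the same anatomy is
rasterized at 3 mm for planning and 1 mm for evaluation (the
two-resolution workflow of HDR planning systems). Dose points are the
centres of all voxels inside each mask at the working resolution.
The sup/inf boxes' lateral extent is not a clinical convention; it is
an explicit parameter (default 15 mm half-width) chosen to give the
boxes a few cm³ so that D2cc is well defined.

Voxel-centre rasterization with closed intervals counts boundary-
aligned voxel centres as inside; with round-number geometry at 1 mm
this inflates structure volumes by a few percent. Volume-accuracy
checks therefore rasterize at 0.5 mm, where centres fall off the exact
boundaries.

## Dose engine

The per-combination kernel is a point-source approximation:

    d(p) = R10 · (10/r)² · exp(−μ_w (r − 10)) · T(φ)

with r the source-to-point distance in mm, R10 = 7.5 cGy/s the
unshielded reference dose rate at 10 mm (a ~10 Ci HDR source),
μ_w = 0.003 mm⁻¹ an effective attenuation coefficient (scatter build-up
nearly cancels primary attenuation for high-energy HDR sources over the
first few cm), and T(φ) the azimuthal shield transmission. Because the
source sits on the axis, rays are radial in cross-section and the
tungsten path outside the window is the full annulus chord
(7.5 − 1 = 6.5 mm) independent of azimuth; T = exp(−μ_s · 6.5) with
μ_s = 1.0 mm⁻¹ (transmission ~1.5 × 10⁻³, effectively opaque) and a 5°
linear penumbra ramp inside the window edge. A hard edge is available
(penumbra 0) but creates non-differentiable kernels that exaggerate
rotational-error discontinuities. Points closer than 2 mm to a dwell
position are evaluated at the clamped distance and counted in the
build log, never at infinity. Line-source anisotropy, scatter
modelling, heterogeneity corrections and the oblique lengthening of
shield chords for out-of-plane rays are omitted: the optimization and
evaluation contracts only require a smooth, monotone, azimuthally
shaped kernel, and every parameter is configurable.

Scenario kernels are recomputed exactly at the perturbed angles and
positions (the engine treats the shield angle as continuous); nothing
is interpolated from the 15° planning library.

## Optimization

With the penalty variables eliminated as positive parts, each scenario
penalty g_r(t) is convex piecewise-quadratic and the robust program
reduces to min_{t≥0} λ·max_r g_r + (m/|R|)·Σ_r g_r, exactly equivalent
to the explicit QP with shortfall/excess/epigraph variables. Smooth
weighted sums (singleton scenario set, or λ = 0) are minimized by
L-BFGS-B with exact gradients followed by a projected-Newton polish on
the locally active quadratic piece (KKT residuals driven to ~1e-10; the
active set stabilizes after a few steps). The minimax term is handled
by the epigraph formulation in scipy's trust-constr with analytic
gradients and active-set Hessians, warm-started from the mean-scenario
solution; afterwards the epigraph multipliers (which sum to λ) define a
weighted-sum whose projected-Newton polish sharpens the returned point,
and the best of {epigraph point, warm start, polished point} by true
objective is returned. Weighted-sum weights are normalized to sum to
one before solving, so the iterate sequence — and therefore the
resolution of ties among non-unique optima — is invariant to objective
scaling; this is what makes the robust model with a singleton nominal
scenario bit-identical to the plain quadratic model.

Degenerate cases behave as expected: all-zero weights give t = 0 with
objective 0; a single dose point with a quadratic shortfall penalty
drives the shortfall to zero at t* = L/d. When the Hessian is singular
in t the optimum is a set; the solver's deterministic iterate sequence
picks one member and no post-processing is applied. Minimum deliverable
dwell times are deliberately not enforced — dwell times are reported at
full floating precision, with deliverability summarized separately
(active positions above 0.5 s, longest dwell, total time).

Default penalty template (package defaults for the synthetic phantoms,
not published clinical weights): CTV L = 10 Gy, U = 15 Gy, q^l = 1,
q^u = 0.1; contra U = 5 Gy, q^u = 1; sup/inf U = 5 Gy, q^u = 0.5; all
linear weights 0 (pure quadratic penalties are smooth and scale-free
under the rescaling step). λ and the mean weight both default to 1 and
are exposed — the trade-off between worst-case and average performance
is a user priority, not a constant of the model.

An automated analogue of manual penalty-weight fine-tuning is provided
(optional, off by default since the rescaling step already normalizes
coverage): target shortfall weights are scaled up and overdose weights
down while the un-rescaled CTV D90 is below the prescription, and vice
versa, with a secant step in log space on the monotone weight-ratio →
D90 response; non-convergence returns the best iterate with a warning
flag rather than raising.

## Evaluation protocol

DVH indices use the step-DVH convention: DX (or DXcc) is the dose of
the ⌈fraction·n⌉-th hottest voxel, no interpolation — exact, testable,
and indistinguishable from interpolated readings at 1 mm resolution.
Dwell times are rescaled once, on the nominal 1 mm matrix, to CTV
D90 = 10 Gy; error scenarios are then scored with the plan (and the
rescale factor) frozen. The worst case is taken per index over the two
signed scenarios of a magnitude — minimum for CTV indices, maximum for
OAR indices — excluding the nominal scenario, so OAR ratios below 1 are
possible and meaningful. Every reported worst-case value is attained by
a listed scenario; magnitude 0 reproduces the nominal scenario and
gives ratios of exactly 1.

The paired signed-rank test drops zero differences and assigns average
ranks to ties; the two-sided p-value is exact (full enumeration of the
2ⁿ sign assignments) for n ≤ 15 and a tie-corrected normal
approximation without continuity correction beyond. Identical samples
return a flagged no-difference result. Significance is declared at
p ≤ 0.05.

## Problem sizes

Defaults were chosen so a full cohort study runs on a desktop: 10
phantoms, 3 mm planning grid (~1000–1500 dose points), 1 mm evaluation
grid (~20k dose points), 408 combinations. A non-robust solve takes
~1 s, a three-scenario robust solve a few seconds, and a full
evaluation sweep (13 scenarios at 1 mm) a few seconds per phantom. The
acceptance script uses a five-phantom cohort with the 180° shield.

## What the synthetic study does and does not show

The phantoms emulate the geometry of noncircumferential rectal tumors
around an intracavitary applicator, and the analytic kernel preserves
the structure that drives the robustness question: steep lateral
falloff, a sharp azimuthal window edge, and smooth response to small
rotations and translations. Passing tests therefore demonstrate the
correctness of the optimization and evaluation machinery and reproduce
the qualitative degradation trends (hot-spot indices of the shielded
wall grow steeply with rotational error; spill-region indices grow with
translational error; CTV D90 is comparatively robust). They do not
validate absolute dosimetry — no Monte Carlo transport, no consensus
source data, no patient anatomy — so the numeric ratios are not
comparable to values measured on patient CTs with Monte Carlo kernels,
and clinical conclusions about specific error tolerances cannot be
drawn from them.

## Known limitations

- Point-source kernel: no line-source anisotropy or scatter build-up;
  shield chords are computed for in-plane rays only.
- Tilted applicator axes are not modelled (the axis is +z).
- The voxel-wise worst-case variant shares the planning scenario sets;
  mixed rotation+translation scenario products are not generated.
- The weight-tuning loop assumes a monotone weight-ratio → D90
  response; strongly non-monotone configurations fall back to the best
  iterate.
- Structure masks are voxel-centre rasterizations; volumes carry
  O(voxel) boundary error on the coarse planning grid.
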