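# Methods

This note documents the models, numerical choices and study conditions
implemented in `brainshift`, and what the synthetic tests do and do not
demonstrate about real data.

## The measurement procedure

High-speed video (2,500 fps, 320×480 px, ≈0.41 mm/px) of a transected
head shows dark ink dots on the cut brain surface (24–48 dots, 2–3 mm)
and on the rigid skull/potting annulus (6–16 dots). Per frame, dots are
isolated by a global Otsu threshold on the contrast-normalised image and
8-connected components within area bounds are reduced to
darkness-weighted centroids; a 1-px halo around each component is
included in the weighting so the anti-aliased dot edge contributes
(without it, the centroid bias drifts with the dot's sub-pixel phase and
can approach 0.1 px). Tracks are formed by greedy mutual-nearest linking
with a hard 10-px radius: both endpoints must prefer each other,
equidistant ties resolve to the lowest index, unmatched detections start
new tracks, and a gap terminates a track (no re-identification). Tracks
shorter than 90 % of the frames are dropped.

Each brain track is paired with the rigid track nearest at the first
analysis frame (many-to-one allowed). The pair distance is averaged over
the 50 frames before motion to give a baseline; relative displacement is
the per-frame distance minus baseline, converted once from px to mm. Two
scalars summarise a pair: the maximum during motion, and the maximum over
the pre-motion window (the error measure). Motion start is detected from
the angular-rate trace (first sample above 1 % of peak); the
end-of-motion helper declares rest when the displacement rate stays below
0.01 mm/frame for 25 consecutive frames (both configurable). Cohort rows
pool pairs with count weights (Σnᵢmᵢ/Σnᵢ), never as means of means; when
only rounded per-experiment rows are available the pooled SD is not
recoverable and only the pooled mean is reported. Paired comparisons use
the two-sided Wilcoxon signed-rank test, exact for n ≤ 25 without zero
differences, normal approximation otherwise.

## The synthetic-experiment generator

The generator emulates the study conditions so the pipeline can be tested
against known truth: a C¹ velocity pulse (half-cosine ramps whose slopes
hit the requested peak acceleration/deceleration, optional plateau,
integral rescaled to the exact total angle — 65°, ≈52 rad/s,
≈8.6 krad/s² by default, 10 kHz sampling); marker rings at even arclength
with seeded jitter bounded so no two dots come within one dot diameter;
rigid-body rotation for all markers about a configurable centre; and, for
brain markers, a relative-displacement waveform added in the corotating
frame. The waveform is a sum of two smooth bumps tied to the acceleration
and deceleration phases plus a saturating residual (20 % of peak by
default), normalised so its global maximum equals the requested amplitude
exactly at the end of deceleration — reproducing the qualitative
two-peak/decel-max structure of measured traces without inventing
dynamics. The lag direction defaults to tangential (rotational inertia
acts tangentially); an inward-radial option aims the lag along the
brain-to-rigid chord so that quantitative recovery tests can compare the
measured maximum against the full truth amplitude — with a tangential
lag, the pair distance only sees the chord projection. Frames are
rendered as anti-aliased dark disks (area-weighted edge coverage, so
rendering adds ≪ 1 px of centroid error) with optional illumination
flicker; Gaussian centroid jitter at the measured ≈0.31 mm scale models
digitisation error.

The rotation centre sits in the cervical spine just below the section
(default (0, −35) mm in the section frame), close enough that the full
65° sweep keeps every marker inside the camera view, as in the physical
rig. What the generator does *not* model: motion blur, specular
reflections, dot deformation and partial occlusion, non-Gaussian
segmentation failures, out-of-plane motion. Passing tests therefore show
the pipeline's correctness and its noise response, not its robustness to
every real-video artifact.

## The reduced-order simulator

The full 3-D hexahedral head model is replaced by a plane-strain triangle
mesh of one cross-section (sagittal profile with brainstem notch,
cerebellar lobe and olfactory prominence; smooth axial ovoid; or a
circle for benchmarks), with unit-free thickness chosen so the section
carries half the intact 44.6 g brain mass at ρ = 1.04 g/cm³. The cut
plane is the modelled plane, so the cover-plate constraint (in-plane
translation only) is automatic. The skull is the brain outline offset
outward by a small subarachnoid gap (0.3 mm default) and rotates rigidly
with the (CFC-200 filtered, forward–backward second-order Butterworth,
−3 dB at 330 Hz) input pulse; the falx is treated as part of this rigid
boundary because its 15 MPa modulus is ~4 orders above brain tissue (its
constants are carried in `material.FALX_PROPERTIES` but not assigned to
deformable elements).

Brain elements use the first-order Ogden energy in isochoric principal
stretches with a penalty bulk term `K = 2μ₀(1+ν)/(3(1−2ν))`; the
published ν = 0.49999 is softened to 0.495 by default for explicit
stability (configurable). Viscoelasticity follows the two-term Prony
relaxation applied to the deviatoric stress through the standard
internal-variable exponential recurrence, which reproduces μ(t)/μ₀
exactly for a held deformation. Time integration is semi-implicit
(symplectic) Euler at 0.5× the stability bound derived from the
dilatational wave speed and the stiffest spring present (connector,
contact penalty, or vein tangent); mass-proportional damping defaults to
5 % of critical for the rigid-translation mode on the connectors — light
enough to leave the displacement waveform intact, needed to keep the
most compliant boundary stiffnesses numerically tame. Contact is a
penalty on penetration past the skull polyline with Coulomb-capped
viscous tangential friction (μ = 0.2); energy diagnostics (kinetic +
element strain + connector potential) are available and conserve to
< 2 % during free ringing with damping, contact and relaxation off.

**Connector convention.** The boundary springs are linear with a single
stiffness k shared by all connectors. By default each spring resists the
full relative displacement vector of its endpoints away from the
corotated rest chord ("cartesian"); an axial-only variant (force along
the current chord, proportional to length change) is available. The
cartesian form is the one under which the boundary rigidifies as
k → ∞ — a pure axial spring with a finite rest length leaves tangential
sliding unresisted to first order, and no stiffness would reproduce the
near-rigid behaviour the stiff end of the calibration sweep exhibits.
With the near-zero default gap the two conventions coincide in the small-
displacement limit.

**Bridging veins.** Eleven tension-only axial elements anchor along the
falx arc, divided anterior-to-posterior into 20/20/30/30 % segments with
5 veins in the first and 6 in the third, evenly spaced inside their
segment at fractions i/(c+1) (endpoints excluded). Their stress–stretch
curves are *synthetic* piecewise-linear families shaped like the measured
behaviours — `post_cyclic` (long compliant toe, then stiff rise; the
weakest tethering case and the default) and `high_rate` (short toe,
stiffest rise) — because the tabulated vein test data are not shipped
here; all knots, the shared 0.6 mm² cross-section and the 1.8 ultimate-
stretch flag threshold are configuration values, clearly marked as
package defaults rather than measurements. Compression carries no load;
stretches beyond the last knot clamp with a warning and are flagged
against the ultimate-stretch threshold.

**Scale caveat.** With tens of boundary nodes instead of ~1,400, a given
per-connector stiffness yields a much softer total boundary than in the
full model, so stiffness values calibrate to *model-internal* synthetic
experiments; the calibration *procedure* (sweep → regression → CI rule),
not any particular stiffness value, is what transfers. Hourglass and
distortion control are unnecessary for constant-strain triangles.

## Calibration

For each stiffness on the sweep grid (default: the 14 distinct published
values from 34.6 to 4,000 N/m), all experiments are simulated, virtual
markers (node subsets averaged like ink-dot registrations, skipping
vein-reserved nodes, which at coarse resolution would place a marker on
an unconnected node) run through the identical measurement pipeline, and
pooled pairs are fitted with `d_FEM = a·d_EXP`:
`a = Σxy/Σx²`, `CI = a ± t(0.975, n−1)·sqrt(Σr²/((n−1)Σx²))`. The n−1
degrees of freedom follow the single-parameter no-intercept model (the
convention is stated explicitly because no-intercept CIs vary between
texts; it matches the no-constant OLS fit in statsmodels). A stiffness
qualifies when both the all-pairs and superior-only CIs contain 1; the
winner minimises max(|a_all−1|, |a_sup−1|), ties breaking toward the
stiffer k. On the published sweep the sum-of-deviations metric selects
the same stiffness, so the metric choice is not outcome-determining
there. The "superior" subset defaults to brain markers in the top
tercile of the marker bounding box at frame 0 (configurable predicate).
No continuous optimisation over k is attempted — grid search only, by
design.

The end-to-end recovery harness generates synthetic "measured" maxima by
simulating at a known true stiffness and adding measurement noise, then
sweeps and selects. Noiseless recovery is exact by construction (the
true-k regression has unit slope and zero residual); with 0.1 mm noise
the selected stiffness stays within one grid step of truth in ≥ 80 % of
seeded replicates. Sweep simulations are cached per stiffness, so the
Monte Carlo costs one sweep regardless of replicate count.

## Problem sizes and defaults

Test and acceptance runs use target edge lengths of 5–6 mm (≈100–200
elements, ≈30–40 boundary nodes), 3 animals × 2 rotations, and 7-point
recovery grids; a single pulse simulation takes well under a second, a
full sweep a few seconds. Finer meshes change the absolute displacement
scale (see the scale caveat) but not the qualitative behaviour the tests
assert: stiffness monotonicity, decel-end peak timing, geometry
dominance of the smooth axial/circular section over the irregular
sagittal one, rigid-limit convergence, and exact/near recovery of a
known stiffness.

## Known limitations

* 2-D plane strain: no out-of-plane drainage, no 3-D vein geometry, no
  gyri/sulci, no grey/white differentiation, no CSF fluid elements.
* Connector stiffness values are mesh-resolution specific (see above).
* Vein material curves and cross-section are representative synthetic
  defaults, not measured data.
* Contact uses each surface node's opposite skull point and reference
  normal — accurate for the sub-mm penetrations seen in practice, not
  for gross sliding of a very soft boundary.
* The Wilcoxon exact path requires no zero differences; ties in
  magnitude are handled by the underlying permutation distribution.
* The generator's lag waveform is phenomenological; it constrains the
  measurement pipeline, not the physics of brain lag.
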