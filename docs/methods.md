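# Methods

## The measurement model

A graded quadrant is a 2-D cross section of the anterior chamber angle,
represented by ordered polylines in micrometres: the inner corneoscleral
boundary running anteriorly from the iris recess, and the anterior and
posterior iris surfaces running from the iris root toward the pupil margin,
with two landmarks (scleral spur, iris recess). All arc lengths are polyline
arc lengths with linear interpolation inside segments; this is the standard
convention for spur-referenced AS-OCT metrics and is stable on curved
boundaries, unlike chord (Euclidean) offsets.

**TIA750.** The trabecular–iris angle has its apex V at the iris recess.
One arm passes through the trabecular-meshwork point P located 750 μm of
arc anterior to the scleral spur along the corneal boundary. The second arm
passes through the iris point Q where the line through P perpendicular to
the ray V→P meets the anterior iris surface; when that perpendicular misses
the surface inside the evaluation window, Q falls back to the iris point
nearest P. Clinical graders judge this arm visually; the
perpendicular-foot construction is the deterministic operationalization,
and on straight-armed geometry it reproduces the wedge angle exactly.

**AOD750.** The angle opening distance is the length of that perpendicular
segment P→Q; it is 0 when the iris is apposed at P, and reported undefined
(error code `aod-undefined`) when the perpendicular exits the evaluation
window — the quadrant is still classifiable by the preset rule.

**Preset-angle classification.** A wedge of `tia_threshold` = 12° is hinged
at V along V→P, opening toward the iris. The quadrant is *closed* when iris
and cornea are apposed (below), *narrow* when any evaluated iris point lies
strictly inside the wedge, and *open* otherwise. Ties sit on the open side:
the rule is strictly "angle < 12°", so a wedge built at exactly 12°
classifies open (a 10⁻⁹-degree guard absorbs trig rounding in synthetic
constructions). On straight-iris geometry this point test is exactly
equivalent to `TIA750 < 12°`.

**Apposition and the apex guard.** Apposition is a minimum distance at or
below `apposition_tol` = 10 μm between the two boundaries, with both
restricted to arc length in `[apex_guard, eval_window]` = [250, 1000] μm
from the recess. The guard is load-bearing: the two traces meet anatomically
at the recess, so an unguarded minimum distance tends to zero for every
angle width and would label all quadrants closed. 250 μm keeps a 5°-wide
angle (separation ≈ 22 μm at the guard) clear of the 10 μm tolerance while
a truly apposed contour is flagged at any width. A consequence: straight
wedges narrower than ≈ 2.3° are genuinely within tolerance of contact in
the guarded window and classify closed rather than narrow — both count
toward HRAC.

### Geometry parameters

| parameter | default | meaning |
| --- | --- | --- |
| `tm_offset` | 750 μm | spur → TM-point arc length (the "750" in TIA750/AOD750) |
| `tia_threshold` | 12° | preset wedge; calibrated from gonioscopy-anchored TIA (below) |
| `apposition_tol` | 10 μm | contact tolerance, below typical trace noise |
| `eval_window` | 1000 μm | peripheral-iris region evaluated; covers the TM region with margin |
| `apex_guard` | 250 μm | apex exclusion for contact/wedge point tests (see above) |

All lengths scale together: `GeometryConfig.scaled(s)` keeps TIA invariant
and AOD equivariant under uniform magnification, which the tests verify
along with rigid-motion invariance.

## Eye-level grading

An eye is at high risk of angle closure (HRAC) when ≥ 3 of 4 quadrants are
narrow and/or closed. The count is absolute: an eye with only three
gradable quadrants needs all three. With fewer than three gradable
quadrants and fewer than three qualifying, the eye is *ungradable for
HRAC*, a distinct state from HRAC-negative. The right eye is analyzed
unless ≥ 2 of its quadrants are unidentifiable, in which case the left eye
is used; if both fail, the participant maps to the bilateral-poor-quality
exclusion. Two independent grades are adjudicated by agreement, else by a
third grade's majority; a three-way split is flagged `unresolved`.

**Threshold calibration.** `calibrate_threshold` takes TIA measurements
from quadrants anchored at a reference gonioscopic narrowness (Scheie N3,
anterior third of the trabecular meshwork visible) and returns the sample
mean rounded half-up to a whole degree, alongside mean ± SD. A sample with
mean 12.1 ± 5.8 yields the 12° preset.

**Iris configuration.** The visual taxonomy (flat, bowing, bombé, thick
peripheral, mixed) is operationalized with two measurements: signed
sagittal curvature — the extremal perpendicular deviation of the anterior
surface from its end-to-end chord, positive toward the cornea — and iris
thickness, measured perpendicular to the anterior surface 750 μm from the
root (the local tangent is estimated over a ±150 μm window so vertex-level
trace noise does not swing the normal direction). Cuts: |curvature| > 80 μm
→ bombé (positive) or bowing (negative); thickness > 600 μm → thick
peripheral. Two or more base flags give *mixed* (the single-contour
realization of "two configurations in the same quadrant"); at eye level,
two or more distinct quadrant labels — or any mixed quadrant — give mixed.
The cuts are this package's choices, not published constants; the shape
presets of the generator sit at ≥ 2× the curvature cut and well clear of
the thickness cut, so a green recovery test establishes separability of
clearly expressed morphologies, not the taxonomy's behavior near its
boundaries.

## Screening cascade and statistics

Exclusions are applied first-match in the order: bilateral poor image
quality; presenting visual acuity < 6/12 (strict, Snellen fractions) in the
better eye; IOP ≥ 24 mmHg in the worse eye; suspected glaucomatous
neuropathy; other retinal abnormality; prior ocular surgery. The source
protocol reports disjoint counts without stating precedence or laterality;
first-match in listed order and worse-eye IOP are the choices here, and the
accounting is conserved by construction (included + Σ excluded = enrolled).

Percentages render half-up to one decimal; p-values to three decimals with
a "< 0.001" floor. The chi-square is uncorrected Pearson — with Yates
continuity correction the reference stratified significance levels
(gender p = 0.001, youngest band p = 0.011) are not reproduced, without it
they are. Continuous comparisons gate Student's t (pooled variance) on
Shapiro–Wilk normality of both samples at α = 0.05, falling back to the
two-sided Mann–Whitney U; constant samples fail the gate. The reference
age-by-gender table carries its published internal inconsistencies (male
age-stratum denominators sum to 561 against a male total of 579; the ≥ 70
row's printed percentage and p-value); `StratifiedCounts` therefore accepts
explicit margins so a transcribed table is reproduced verbatim, while
margins of computed tables are always cell sums.

## Synthetic data: what it emulates, and what it does not

**Scans.** The recess sits at the origin, coincident with the scleral spur
and both trace roots. The corneal arm is straight at half the corneal wedge
angle (default 35°/2); the anterior iris leaves the recess along a chord at
`cornea_wedge/2 − target_tia`, so the trabecular-iris angle equals
`target_tia` exactly before noise. Shape presets deform the chord with a
signed sagittal bump (+400 μm bombé, −300 μm bowing, thickness 450 or
700 μm for the posterior offset). The bump is supported on the
mid-peripheral/pupillary 60 % of the contour, *beyond* the evaluation
window: the shape classifier sees the full sagitta while the angle region
keeps the exact target TIA. (A naive circular arc through the recess at
+400 μm sagitta rotates the root tangent by ≈ 30°, crosses the corneal
boundary inside the window, and destroys any relation between the target
angle and the graded class — the windowed-bump family is the deliberate
replacement.) Gaussian perpendicular vertex noise (seeded) models trace
jitter; the first vertex stays anchored at the recess. Appositional
(closed) quadrants come from a separate generator that tracks the cornea at
a 3 μm gap before falling away.

Consequently a green test establishes: exact recovery of target angles and
preset labels on clean geometry, ≥ 95 % shape-label recovery at 15 μm
noise, and unbiased cohort statistics. It does **not** establish behavior
on real segmentations: curved corneas, curvature inside the angle region,
spur-localization error, or non-Gaussian artifacts (eyelid shadow, motion)
are outside the generator's vocabulary.

**Cohorts.** The default cohort spec reproduces the reference campaign:
1282 enrolled; fixed exclusion counts 80/93/17/30/38/33; included strata
579 men / 412 women across decade bands with per-stratum HRAC prevalence
(overall 78/991 ≈ 7.9 %). The 18 men unaccounted between the published
male age-stratum denominators (561) and the male total (579) are placed in
the 60–69 stratum; `TABLE_DENOMINATOR_GAP` records this. HRAC eyes receive
3 or 4 narrow quadrants (50/50 — the 3-vs-4 split is unreported) with TIA ~
U(5°, 11°), others at U(15°, 30°); non-HRAC eyes at most 2. Ages are
uniform within bands, capped at 84. Cohort scan recipes are noise-free by
default, so grading reproduces the sampled labels exactly and the
stochastic content of a simulation is the Bernoulli label draw itself;
`CohortSpec.noise_sd` enables jitter. The deterministic
`exact_paper_cohort()` uses no randomness at all.

## Numerical choices and degenerate inputs

* Landmarks must lie within 50 μm of their reference trace; the TM-point
  construction projects the spur onto the boundary before walking 750 μm.
* Apex/arm points closer than 1 μm are a degenerate angle (`degenerate-angle`).
* Any geometry error downgrades the quadrant to ungradable (with the reason
  in `notes`) instead of raising — mirroring how poor acquisitions are
  discarded clinically — and ungradable quadrants propagate into the
  ≥ 3-quadrant and eye-selection rules as described above.
* Ingest normalizes units (`pixel_scale`) and reflects mirror-imaged frames
  so the cornea lies on the positive-y side of the iris; all side
  conventions (wedge opening direction, curvature sign) rest on that frame.
* The narrow-wedge point test evaluates polyline vertices plus a 25 μm
  resampling of the windowed iris, so penetration between sparse vertices
  is not missed.

## Statistical design of the end-to-end check

The end-to-end simulation check pools each stratum's HRAC count over a
fixed 600-seed sweep and tests it against its exact binomial null with a
Holm correction at a 5 % family level. Eight simultaneous uncorrected 95 %
intervals would reject a correct generator for roughly one seed stream in
three; the family-corrected form is the calibrated version of "consistent
with the binomial stratum model at 95 %". Three full-geometry cohorts
(n = 991 each) additionally require zero disagreement between graded HRAC
and sampled labels, pinning the deterministic part of the pipeline
separately from the sampling noise.

## Known limitations

* No image segmentation: the package starts from boundary traces and
  landmark annotations; spur detection quality is upstream.
* Two B-scans / four quadrants per eye, not 360° swept-source maps.
* The shape taxonomy thresholds are package conventions; agreement with
  human visual typing on real images is not established here.
* The screening statistics apply no multiplicity adjustment across the
  stratified tests, matching common reporting practice for such tables.
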