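# Methods

This note documents the models implemented in `ergocab`, the parameter
defaults and why they were chosen, the numerical decisions, what the
synthetic generator does and does not emulate, and the known limitations.

## Frames and units

All public angles are degrees; lengths metres; forces newtons; masses
kilograms. The literature behind the individual scorers uses mutually
incompatible local conventions (the vision model wants z along the line of
sight, the arm chain wants y vertical with sagittal flexion in the x–y
plane, the leg model is 2-D sagittal). `ergocab` therefore defines one
right-handed **cab frame** (origin at the seat H-point, x forward, y left,
z up) and three configured rigid transforms — `eye_from_cab`,
`shoulder_from_cab`, `hip_from_cab` — so each scorer can work in its native
frame exactly as its equations are written. `standard_frames()` supplies a
nominal seated operator (eye 0.68 m and shoulder 0.52 m above the H-point);
per-participant stature/seat differences are modelled as a cab-frame offset
applied to all three landmark origins.

## Vision (P1–P3)

The visible volume is an asymmetric frustum: near plane `n` = 0.3 m, far
plane `f` = 2 m (a cab is small), horizontal aperture 120°, vertical 60°
upward and 70° downward. Head rotation widens the effective half-angles to
`(θ + rotation)/2`. Two numerical decisions:

* **Clamping.** At yaw ≥ 60° the effective horizontal half-angle reaches
  90° and its tangent diverges; effective half-angles are clamped at 89°
  (configurable). The clamped view is "almost a half-space", which is the
  intended semantics of an extreme head turn.
* **Sweep.** P1 uses the union of views over the comfortable head-rotation
  range (yaw ±60°, pitch ±30°). Because containment is monotone in the
  half-angle, that union equals the view at the positive extremes, so a
  single containment test suffices. The maximum physiological range
  (yaw ±90°, pitch −70..50°) and a recorded single head pose are available
  as alternative sweep modes.

Occlusion uses bounded planar rectangles (centre, unit normal, two
half-extents; in-plane axes default to the plane's natural horizontal/
vertical directions). A target is occluded iff the sight-line/plane
intersection parameter satisfies 0 < t₀ < 1, the intersection lies within
the rectangle, and the intersection is itself inside the field of view. A
sight line parallel to the plane never divides by zero — it simply does not
intersect.

Colour recognition has no published angular thresholds for this use case;
the defaults are a central cone per colour (red/green 30°, yellow/blue 40°,
other 60° half-angle), reflecting the narrowing of chromatic discrimination
away from the visual axis. They are configuration, flagged as package
defaults, not literature values.

## Reach (P4–P7)

The upper-limb model is a two-segment shoulder–elbow chain with signed
joint ranges (comfort: shoulder flexion −20..120°, abduction −10..90°,
elbow 30..130°, forearm ±60°; physiological limits are wider). Maximum
reach adds trunk flexion 0..30° and lateral bend 0..15°, displacing the
shoulder origin and contributing the trunk length to the chain's printed
z-expression. The printed chain mixes a lateral arm z-term with a vertical
trunk z-term; the package implements the expression as printed and, for
membership queries, compares the maximum-reach endpoint after subtracting
the neutral trunk rise (0, 0, Lt). This makes the comfortable set a strict
subset of the maximum set (the physiologically required property) while
preserving the printed forward model, whose raw output `arm_max_endpoint`
still returns.

**Membership** ("can any admissible joint combination put the hand here?")
is decided by a coarse grid over the joint box (10° for the 4-D comfort
search, 20° for the 6-D maximum search) followed by bounded L-BFGS-B
refinement of the squared endpoint distance from the best four starts,
tolerance ε = 5 mm. The squared distance is smooth where the plain norm is
not, which is what makes the quasi-Newton refinement reliable; a dense-grid
forward sweep is used as the oracle in the test suite. A full dense grid at
few-degree resolution is used only in tests — over six joints it would be
computationally absurd as a default.

The lower limb is a sagittal thigh–shank chain (hip frame: x forward,
y down). The chain parameter `tk` equals 180° for a straight leg; knee
*flexion* from full extension is `180° − tk`, and samples store flexion.
Knee-only ("comfortable") reach is an arc of the circle centred at the knee
with radius `Lshank`, evaluated with a 3 cm thickness — a pedal is a contact
patch, not a point. Knee–hip ("maximum") reach is the region enclosed by
four boundary curves: the straight-leg outer arc, the maximum-flexion inner
curve (default 135°), and the two fixed-hip sweeps (hip 0..90° seated
default; the hip limits are not published and are configuration). The
boundary closes exactly because all four curves are generated by the same
forward model at shared corner parameters; point membership uses a buffered
polygon test (Shapely).

Controls operated ≥ 4 times per minute are *intensive* and must lie in the
single-joint comfortable envelope; the rest are *secondary* and must lie in
the two-joint maximum envelope. Each of P4–P7 is the "bad fraction" of its
class; an empty class yields a not-applicable marker, never a division by
zero.

## Posture load (P8–P11)

**Additive RULA variant.** Part points from the printed bands (upper arm
1–4, forearm 1–2, wrist 1–2, neck 1–2, trunk 1–2) are *summed*:
PA = upper arm + forearm + wrist, PB = neck + trunk, PT = PA + PB + Δw
(wrist twist), final P = PT + Δe where Δe depends on the PT band, external
load (0 / ≤2 kg / >2 kg) and muscle use (static ≥ 1 min or > 4 repeats/min).
This deliberately differs from canonical RULA's lookup tables; consequently
the attainable range differs too, and `rula_range()` computes it by
exhaustive enumeration — (6, 16) whole-body, (5, 14) upper, (2, 6) trunk —
for use as the normalisation interval. The adjustment table omits the
(low-PT, no-load, muscle-use) cell; any non-zero load *or* muscle use takes
the adjusted row. Band edges belong to the band whose printed inequality is
non-strict.

**OWAS.** Four-digit coding (back 1–4, arms 1–3, legs 1–4, load 1–3)
derived from the sample's angles and flags (slight flexion threshold 10°;
the load bands ≤10 / 10–20 / >20 kg). The published classification table
lists only a handful of the 144 combinations; listed rows (including "Any"
wildcards) are returned verbatim, and unlisted codes are resolved by the
default *severity* policy — the worst single dimension, clamped to level 4 —
which reproduces every listed row. A *strict* policy raises instead, for
table-only fidelity.

**Lower-back analysis.** The L5/S1 moment is
`M = F_load·d_load + a·F_body·d_body` (the body term uses the upper-body
weight fraction `a`, default 0.5 of the 0.40–0.60 typical range, because
`d_body` is the upper-body centre-of-mass lever); compression is
`M/d_muscle + F_load + a·F_body` with the extensor lever `d_muscle`
defaulting to 0.06 m (midpoint of the typical 5–7 cm); shear is
`(F_load + F_body)·sin θ₃` with the full body weight, as printed. When not
supplied, `d_body` defaults to `0.5·Lt·sin θ₃` (mid-trunk centre of mass)
and `d_load` to 0.4 m for a held load. Compression is normalised on
0–6000 N.

**Comfort assessment.** Per-joint deviation `D = |θ − θ_neutral|` and grade
`Dᵢ ∈ {0, 1, 2}`: 0 inside the comfort range (shoulder abduction 0–20°,
elbow 80–120°, lumbar 0–20°, knee 90–110°), 2 beyond the high-risk
threshold (>30°, <60°/>140°, >30°, <70°/>130° respectively), 1 between.
Deviation is two-sided because the thresholds are. The per-joint weights
are not published; the default is equal weights scaled so the worst posture
scores exactly 80, the ceiling of the published 0–80 comfort scale, and the
same scaling is applied per region so regional scores share the 0–80
normalisation. The published deviation-rating table's risk column appears
inverted (near-neutral labelled "high"); the implementation follows the
deviation-description column.

**Region mapping.** The scorers are evaluated on body-region subsets:
upper = arm + wrist + neck RULA, shoulder/elbow comfort, OWAS arms;
trunk = neck + trunk RULA, lumbar comfort, OWAS back; lower = lumbar
compression (whole-body by definition) and OWAS legs; whole = everything.
The exact subsets are documented assumptions — the source material shows
them only graphically.

## Fusion and comparison

Ratio scores P1–P7 are already in [0, 1]; P8–P11 are min–max normalised on
the ranges above (values outside are clipped with a warning). Domains are
fixed means: MA1 = (P1+P2)/2, MA2 = P3, MB1 = (P4+P5)/2, MB2 = (P6+P7)/2,
MC1/MC3/MC4 = (P8+P10+P11)/3 on the upper/trunk/whole regions,
MC2 = (P9+P11)/2 on the lower region. A not-applicable leaf is excluded and
the mean renormalised (logged in the result's ledger); a domain with no
applicable leaf anywhere in the cohort is dropped from the weight matrix
and from M.

CRITIC uses the population (1/n) standard deviation as contrast and
`Rⱼ = Σₖ(1 − rⱼₖ)` as conflict. Pearson correlation with a zero-variance
column is undefined; it is defined here as 0 (maximal conflict
contribution), and the self term contributes 0. A zero-variance column
therefore gets zero weight — a domain identical for every operator carries
no discriminating information. If *every* domain is constant the weights
fall back to uniform with a warning, which makes the all-neutral cohort
well-defined. Weights are computed per layout cohort by default (pooling
before weighting is an open modelling choice; per-layout was chosen as the
more conservative reading).

M = Σ x̄ⱼωⱼ. Per-sample M values use the cohort weights, and participant
values average a participant's tasks, giving the n = cohort-size pairing
unit for comparison. `compare_layouts` runs, per indicator (8 domains + M),
a Shapiro–Wilk normality check on the paired differences, a paired t-test
with df = n − 1, and a Bonferroni-corrected significance flag at
α′ = α / 9 ≈ 0.0056. Identical pairs are reported as "no difference"
(t = 0, p = 1); a constant non-zero shift has no finite t and is reported
as unbounded evidence (p = 0).

## Synthetic data

`generate_cohort` emulates a 30-operator, three-task study: named task
templates (driving, parking, emergency braking) jittered with independent
truncated Gaussian noise (SD 3° per joint, truncated at the physiological
limits), an anthropometry mix P5/P50/P95 = 0.2/0.6/0.2 with 1 % relative
segment-length scatter, and 5 mm landmark-placement scatter. Everything is
reproducible from a single seed.

`generate_layout` places controls by rejection sampling against the
package's own predicates and records each control's intended memberships,
so leaf scores are checkable by exact counting. Defect placements (out of
reach, hidden, occluded, off-colour-zone) are planted the same way.
`paperlike_fixture` builds a defective/clean pair and additionally plants
*marginal* controls — one on the P50 comfort-envelope boundary, one on the
lower field-of-view edge — whose membership flips across the cohort's
anthropometric scatter. Without such boundary cases a synthetic cohort
produces zero variance in the geometric domains and CRITIC (correctly)
assigns them zero weight; real cabs have borderline controls, and the
fixture reflects that.

What the generator does **not** emulate: real capture noise structure
(marker dropout, soft-tissue artefacts), correlated joint angles within a
posture, asymmetric left/right usage, time-series fatigue, or the actual
geometry of any real vehicle. Passing tests demonstrate that the pipeline's
arithmetic, geometry, and statistics are correct and internally consistent
on controlled inputs — not that any particular real cab scores any
particular value.

## Problem sizes

The shipped defaults keep every computation interactive: cohorts of 30
participants × 3 tasks evaluate in a few seconds per layout; membership
queries cost a few milliseconds each (coarse grid + refinement); the test
suite's dense oracles use 3–6° grids and a few hundred probes, chosen as
the smallest sizes that still exercise the boundary behaviour.

## Known limitations

* Reach membership is kinematic only — no collision avoidance, no
  obstacle-aware paths, single configured operating hand (left-hand
  evaluation mirrors the lateral angle signs by negating lateral
  coordinates in the configured frames).
* Occluders are bounded planes; curved or volumetric geometry must be
  approximated by several plates.
* The additive RULA variant is intentionally not canonical RULA; its
  scores are comparable within this framework only.
* The knee-drive "envelope" is a one-dimensional arc thickened by a pedal
  contact patch; its 3 cm default is a physical design choice, and very
  unusual pedal geometries may warrant a different value.
* No glare, lighting, vibration, binocularity, or acuity falloff in the
  vision model; no dynamic (time-series) load accumulation anywhere.
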