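# Methods

## The problem

After an acquired brain injury, many patients show visuospatial attention
problems — most prominently unilateral spatial neglect, a bias toward
ipsilesional space that makes contralesional stimuli hard to orient
toward, perceive and act upon.  Immersive-VR visual search motivates wide,
naturalistic spatial behaviour and records far richer telemetry than
pen-and-paper cancellation tests: per-trial response accuracy and reaction
time, and per-frame headset and hand-controller orientation.  This package
turns that telemetry into a normative model of gameplay: it computes a
battery of attention metrics per player and flags *visuospatial
atypicality* — metric values falling outside the typical range of **both**
a control and a patient reference group — without ever assigning a
clinical label.

## Telemetry model

Directions live in a right-handed calibrated frame (forward = +z, up = +y,
right = +x) and are summarised by two signed angles in degrees: the
**lateral** angle (azimuth, positive right, `atan2(x, z)`) and the
**vertical** angle (elevation, positive up, `asin(y)`).  Raycast telemetry
for this class of task is often labelled latitude/longitude; the mapping
(lateral ↔ latitude, vertical ↔ longitude) is a single documented constant
in `geometry.RAYCAST_AXIS_LABELS` so it can be flipped if a data source uses
the opposite convention.  Search arrays sit on a sphere of 2 m radius in
concentric rings whose eccentricities are multiples of 12.5°, with
within-ring polar spacing dividing 360° (15° for dense rings).

The short six-level game preset is: tutorial 0.5 min (excluded from
analysis), axes 3.0, stimuli 4.5, depth 6.0 (elements on 2 m and 4 m
surfaces), full field 4.5 (four rings at 12.5°–50°), free viewing 1.0
(frames only, no trials) — 19.5 min of minimum level time in total.  Two
published statements about the eight-element levels conflict (a single
ring "15° from central vision" vs the 12.5°-spaced ring system); the
default here places the eight-element ring at 12.5° so those levels
participate in the 12.5°/25.0° eccentricity contrast, and the ring is
configurable per level.

## Attention metrics (14 per player)

Six *primary* metrics are computed per game level:

* **accuracy** (%): `100 · n_correct / n_trials`;
* **rt** (s): mean reaction time of correct trials after a single-pass
  Tukey trim against the player's own RTs — a trial is dropped iff its RT
  lies strictly outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` of the RTs entering
  the computation (per level for level RT, pooled across levels for the
  spatial-preference scores); fences are never re-estimated on the kept
  set;
* **head_lat / head_vert / ctrl_lat / ctrl_vert** (°): arithmetic means of
  the headset/controller angles over search-array frames (cue-phase frames
  excluded).  Free viewing contributes these four only.

Eight *spatial-preference* difference scores pool trials across levels.
Targets are assigned to quadrants by the dominant-axis rule (|lateral| >
|vertical| → left/right by sign; the reverse → up/down; exact ties →
"axis", excluded) and to eccentricity rings within ±1°.  Sign conventions:
quadrant scores are positive for a right/up advantage (accuracy
right−left and up−down; RT left−right and down−up); eccentricity scores
are positive for a central advantage (accuracy central−peripheral, RT
peripheral−central) — the direction of the eccentricity convention is not
fully determined by the source analyses, so it is a flippable argument.
A metric cell requires at least one qualifying observation; otherwise it
is missing (never zero-imputed).

## The atypicality statistic

For each metric (per level for the six primary metrics, pooled for the
eight preference scores), quartiles Q1/Q3 are estimated within each
reference group by linear interpolation between order statistics (numpy's
`linear`, R type 7 — the convention under which the demographic table's
published IQRs are reproduced exactly), and Tukey fences are
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`.  A value is **atypical** iff it lies
strictly outside the fences of *both* the control and the patient group.
Strict inequalities mean zero-IQR (constant) reference data can flag
nothing.  The conjunction makes the rule conservative by construction:
every flag is a single-group Tukey outlier for each group separately, so
the false-positive rate is bounded by the single-group rate (verified
empirically on simulated null cohorts), and when the two reference groups
coincide the rule reduces exactly to the ordinary Tukey rule.

Per-level Booleans are averaged over a player's non-missing levels into a
cell value in [0, 1]; pooled metrics contribute a single Boolean.  The
player × 14-metric **summary matrix** of these proportions, with an
explicit missingness mask, is the unit of all group-level statistics.
**Mean atypicality** per player is the mean of their non-missing cells.

Choices where the original analysis is not fully specified, each exposed
as an option: the evaluated player is *included* in their own group's
quartiles (no leave-one-out; `leave_one_out=True` available); fences are
per metric × level rather than level-pooled (required for the cell value
to be a mean of per-level Booleans); a group needs ≥ 2 non-missing values
for fences, otherwise the affected cells are missing with a warning;
typicality counts for the 2×2 group table are tallied at the finest
Boolean grain (player × metric × level), with a `cell` grain option.

## Group-level statistics

All tests are distribution-free.  The 2×2 typicality table is tested with
the Pearson chi-square, closed form `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`,
1 df, no Yates correction by default (flag available).  Group midpoints of
mean atypicality use the Wilcoxon rank-sum test (midrank ties,
tie-corrected variance, 0.5 continuity correction, two-sided normal p);
variances use Levene's test with median centring (the Brown–Forsythe
variant, robust to the skewed [0, 1] atypicality scale).  Paired subscale
comparisons use the Wilcoxon signed-rank test (zeros dropped, midranks, W
= smaller signed-rank sum, continuity-corrected normal p).  The rank-test
p values were validated against permutation oracles (within 0.02 on
continuous samples of 8–15 per group); the continuity corrections exist
precisely to keep the normal approximation inside that band at these
sample sizes.

## Questionnaires and demographics

Simulator sickness is the single 7-category rating (1 = no symptoms … 7 =
vomiting); eligibility requires a rating strictly below moderate nausea
(< 4) and an MMSE orientation score ≥ 6/10.  GEQ-R factors
(positive affect, competence, negativity, flow) are means of their 1–5
items; the item→factor mapping ships as editable package-data JSON whose
default assignment is a synthetic placeholder (the published instrument's
mapping is not reproduced here).  SUS uses standard scoring (odd items
score−1, even items 5−score, sum × 2.5) with lower-inclusive bands:
acceptable ≥ 70, marginal ≥ 50, unacceptable < 50.  FIM subscale sums are
normalised by item counts (13 motor, 5 cognition, 18 total), so total =
(13·motor + 5·cognition)/18; the bundled 13-patient demographic table is
reproduced verbatim from its published source, including one row whose
printed FIM total is internally inconsistent beyond rounding (documented
in the consistency test).

## The synthetic cohort

The simulator exists so that every pipeline stage is testable without the
clinical recordings.  It emulates the statistical structure the analysis
assumes — cue/array trial flow, spherical arrays, orientation traces at a
configurable frame rate (default 90 Hz), lateralised orienting bias,
hemifield detection deficits, slowed responses, and give-up distractor
selections — and nothing more: there is no saccade-level eye model, no
biomechanics, and no claim of behavioural realism.  Passing tests
demonstrate that the *pipeline* behaves correctly under this structure,
not that the generator reproduces real patients.

Behaviour model (per trial): the next inspected element is drawn with
softmax weight `exp(−(d(el, gaze) + λ·d(el, rest))/τ)` where `rest` is
straight-ahead shifted by the agent's (lateral, vertical) bias, λ = 1 and
τ = 10°; inspecting the target detects it with probability
`1 − slope·max(0, angle into the neglected hemifield)` (the neglected side
is contralateral to the bias); after `give_up_after` (default 20)
inspections the agent selects the inspected distractor nearest its gaze.
Each inspection costs a noisy dwell (default 0.6 ± 0.15 s, floored at
0.05 s) split between a re-centring at `rest` and the excursion; selection
adds a 0.4 s motor constant.  RT is the array-phase interval, and frames
sample the piecewise-linear gaze path at the frame rate.

The head carries the postural bias and follows gaze excursions with a
small gain: `head = rest + 0.1·(gaze − rest) + ε`, ε white with 3° SD
(controller gain 0.2).  This construction makes the headset lateral mean a
consistent estimator of the injected bias — recovery is within ±2° across
a 5–30° bias grid with 100 trials — because the gaze path's deviation from
`rest` enters the mean only through the small gain.  A larger gain would
couple the head mean to the array geometry (targets must be visited
wherever they are), biasing the estimator toward the array centroid.

Cohorts draw per-player agent parameters from group-level samplers:
controls are unbiased with mild individual variation; the default patient
mixture is *sparse and heterogeneous* (≈40% typical, 25% lateral bias of
10–30° mostly rightward with a contralesional detection deficit, 10%
vertical bias, 15% marked slowing, 10% detection deficit without bias).
Sparsity matters: the double-reference rule flags only values atypical for
the patient group *too*, so a deficit shared by half the group would be
typical-for-patients and invisible — mirroring how the statistic behaves
on real heterogeneous cohorts.  All randomness flows from one master seed
through SeedSequence spawning; identical specs give bit-identical
cohorts.

## Problem sizes and numerical choices

Bulk simulation studies (null calibration over 200 unbiased 9+13 cohorts,
detection monotonicity over a {0, 5, 10, 20, 30}° bias grid with 50
cohorts per point) run on a duration-scaled game (×0.04, a few trials per
level) at 10 Hz frames — the level structure, grids and behaviour model
are unchanged, only the amount of data per session is reduced; these sizes
keep the full validation suite to a few minutes.  The analysis scripts use
×0.1 scaling at 10 Hz.  Quartiles are type 7 everywhere unless overridden;
fences use strict inequalities; trimming is single-pass; angle round-trips
are exact to 1e−9 away from the poles (at the poles the lateral angle is
degenerate and reported as 0).  Histograms for case reports span −50° to
+50° with 1° half-open bins; out-of-window frames are excluded from counts
but reported.

## Limitations

The atypicality statistic is sample-referential: the same player may be
typical or atypical depending on the reference cohorts, and small groups
(9 and 13) make fences noisy.  No multiple-testing correction is applied
across the 14 metrics, matching the descriptive intent; output is an
atypicality profile, never a diagnosis.  The simulator's agent model is a
minimal statistical stand-in; effect sizes measured on it (e.g. detection
rates by bias) characterise the pipeline, not clinical sensitivity.
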