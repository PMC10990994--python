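# Methods

This note documents the statistical procedures `gazekit` implements, the
generative models behind its synthetic sessions, the defaults and why they
were chosen, and what the package's tests do and do not establish about
real recordings.

## 1. Coordinate conventions

All gaze time series are converted at load time to one canonical sign
convention: rightward looks increase x, upward looks increase y. Raw
model-based estimator output uses the opposite sign on both axes and is
flipped by the reader. Because the origin of a calibration-free estimator's
coordinate frame is unknown (and the two estimator families use different
units — degrees vs. normalized screen coordinates), the convention fixes
*signs only*; no statistic in the package depends on the absolute origin,
and the two unit systems are made comparable by using unit-free ratios
throughout.

A sample is *invalid* when its validity flag is 0 or a gaze field is
empty/non-numeric. Invalid samples are never dropped on read — they count
toward data loss and are excluded from every other statistic.

## 2. Grid-session quality statistics

A grid session is one short recording per point of an `n_cols × n_rows`
stimulus grid (default 3 × 3; 18.6 cm horizontal and 11.6 cm vertical
spacing viewed from 95 cm, i.e. ~11.08° and ~6.96° between adjacent
points). Block membership is known by design — each point is a separate
recording — so no fixation classification is needed.

- **Per-fixation medians** over valid samples; the median makes the
  statistic robust to blink transients and stray saccades.
- **Scale ratio** (per axis): the median of the six axis-adjacent
  fixation-median separations (within-row pairs for x, within-column pairs
  for y) divided by the grid's angular separation on that axis. Additive
  offsets cancel; a pure multiplicative gain is recovered exactly in the
  noise-free limit.
- **Precision ratio** (per axis): the median within-block sample standard
  deviation divided by the median axis-adjacent separation of the fixation
  medians. The quotient is invariant under any affine rescaling applied
  jointly to all samples, which is what makes degree-valued and
  normalized-coordinate estimates comparable. The sample SD (not the
  sample-to-sample RMS) is the spread estimator.
- **Data loss**: `100 × invalid / total` samples.
- **Blink flagging**: intervals where the vertical velocity between
  consecutive valid samples exceeds a threshold (default 150 signal
  units/s), merged when closer than 0.1 s. This is a feasibility heuristic,
  not a validated blink detector: the default threshold is chosen to
  separate the generator's default blink transient (25° in 0.1 s ≈ 250°/s)
  from its default fixation noise at 60 Hz (0.5° · √2 · 60 ≈ 42°/s), and
  both knobs are exposed.

One deliberate simplification: the angle per grid step is the single
arctangent `atan(spacing/distance)` measured from screen centre, one value
per axis. Eccentricity-dependent per-pair angles are not modelled — the
outermost pair subtends slightly less than the central pair — because the
evaluation statistics themselves use one separation per axis; modelling the
nonlinearity would break the exact gain-recovery property without changing
any conclusion at these eccentricities (< 2 % effect at ±11°).

## 3. The grid-session generator

Per stimulus point with true angles (θx, θy) (row-major from top-left,
each grid step contributing exactly one `atan(spacing/distance)`):

    x = gain_x · θx + offset_x + N(0, noise_sd_x²)     (same for y)

- `gain` (default 0.5 horizontal / 0.4 vertical) models the scale
  compression regime that motivates the scale-ratio statistic; a second
  condition with gains (0.9, 0.8) models fixation with head movement,
  where estimated scale is closer to faithful. The head-and-eyes condition
  is *only* a different (gain, offset) configuration; no head-pose model is
  simulated.
- `offset` (2.0 / −1.0°) is the unknown-origin shift; it must cancel in
  every reported statistic.
- `noise_sd` (0.5°) is within-fixation estimator noise at 60 Hz.
- Blinks arrive as a Poisson process (12/min) and add a −25° transient to
  the vertical channel for 0.1 s **while leaving samples valid** —
  estimators report gaze even with the eyes fully shut, so blink artefacts
  and missing samples are independent mechanisms (`p_missing`, default 0,
  controls the latter; no lost data is the empirically typical case for
  these toolkits).

Defaults are testability choices representative of a 60-Hz webcam
estimator, not empirical claims; no quantitative noise or gain
distributions are available to fit them to.

Blink transients deliberately inflate the within-fixation SD, so precision
ratios computed on blink-containing sessions are worse (sometimes far
worse) than `noise_sd / separation`; that is the realistic behaviour of
uncleaned gaze signals, and the precision-limit tests therefore use
blink-free configurations.

## 4. The infant-session generator

A 90-s session at a nominal 30 Hz (per-frame timestamp jitter SD 2 ms,
emulating webcam frame-interval variability). Gaze alternates among four
states — `left_lamp`, `parent`, `right_lamp`, `none` — via a semi-Markov
chain with no self-transitions, next state drawn by relative weights
(3 : 2 : 3 : 1.5; the rotating lamps are designed to be the most engaging
stimuli, the parent is a person and socially salient, off-AOI looking is
residual). Dwell durations are log-normal (log-mean 0.7, log-SD 0.6 →
median ≈ 2 s) truncated below at 0.4 s.

Schedules are resampled (up to 200 draws) until every AOI holds ≥ 8 % of
the session. This emulates the elicitation protocol — the lamps light up
and rotate on a fixed alternating schedule precisely to guarantee looks to
each of them, and the parent is continuously present — rather than an
unconstrained wander in which an AOI can happen to attract almost no
looking time. Without the constraint, a session can lack a discernible
histogram peak for a rarely-visited AOI, and no histogram-based rule can
then segment it correctly (on real data such sessions are the ones a human
analyst flags or excludes).

Horizontal gaze during a dwell on AOI *a* is `N(mean_a, noise_sd²)` with
means (−20, 0, +20)° and noise SD 2°. Off-AOI looking is **not** a
structureless wash: infants fixate idiosyncratic distractors (table edge,
door, own hands), so each session draws 6 distractor directions beyond the
lamps (stratified per side, offsets uniform in 25–40° beyond the outer AOI
means) and none-state samples scatter around them with SD 3°, kept ≥ 5°
from every AOI mean (gaze a human coder calls off-AOI is, by definition,
not directed at an AOI centre). Two properties motivated this model over a
single broad none-distribution: (i) real session histograms show deep
valleys between AOI peaks and sections that do not tile the axis, which a
broad uniform background destroys; (ii) it keeps off-AOI structure clear
of the AOI structure, so segmentation failures in the noisy regime reflect
the method, not an artificial overlap the scene never had.

The ground-truth dwell file is *frame-accurate*: boundaries sit on the
timestamps of the frames where each dwell starts (manual coding is itself
frame-by-frame video coding), the file is contiguous and covers the whole
session. `degrade_manual_coding` perturbs internal boundaries by
`N(0, jitter²)` (default 0.05 s in the pipelines) to emulate human-coder
boundary uncertainty while preserving labels, order and contiguity.

## 5. AOI segmentation

The histogram of all valid horizontal gaze angles (bin width 1°, well
below the AOI separations) is smoothed with a Gaussian kernel (bandwidth
1.5°). *Discernible peaks* are local maxima with prominence ≥ 10 % of the
smoothed maximum — an explicit, reproducible surrogate for the visual
judgment the procedure is based on, with every knob exposed.

- **< 2 peaks** → the session is excluded (a result, not an error).
- **≥ 3 peaks** → the three AOI peaks are the position-ordered triple with
  the greatest total peak height (the AOIs carry most of the looking time,
  so smaller stray distractor peaks never make the triple); left-to-right
  they are `left_lamp`, `parent`, `right_lamp`. Sections span
  valley-to-valley between neighbouring peaks, trimmed where the smoothed
  density falls below 2 % of its maximum, so sparse tails fall to `none`
  and sections need not tile the axis.
- **Exactly 2 peaks** → the peaks are the two lamps and the space between
  their (floor-trimmed) sections is assigned to `parent`.

Consequences of the floor trim worth knowing: with strongly separated,
tight clusters the section boundary is the floor crossing, not the empty
valley midpoint; boundaries converge to the analytic mixture valleys only
when the components overlap enough that the valley density exceeds the
floor. Both regimes are covered by tests.

## 6. Dwell detection

Per-sample labels (section membership; `none` for anything outside all
sections and for invalid samples) are turned into dwells by a hysteresis
rule: a dwell on *a* ends only when ≥ `switch_frames` (default 3)
consecutive frames carry one different label *b*; the dwell on *b* starts
at the first frame of that run; shorter excursions are absorbed into the
enclosing dwell and their frames count toward it. `none` is an AOI for
this rule — it can break a dwell and forms its own dwells — so the four
relative total dwell times partition the session. The rule counts frames,
not seconds, matching its native formulation at ~30 Hz even under
timestamp jitter. With `switch_frames = 1` the rule reduces exactly to
run-length encoding (a tested oracle). Manually coded dwells are taken
verbatim — the coder had the surrounding video context and needed no
hysteresis.

Dwell times come from sample timestamps; the final dwell ends at the
session end (last timestamp plus one nominal frame).

## 7. Dwell measures and agreement

Per AOI: relative total dwell time (summed dwell duration / session
duration), mean dwell duration (arithmetic mean; **absent**, never 0, for
an AOI with no dwells — a zero would fabricate agreement), and dwell
count. Subjects with an undefined value for an AOI are dropped pairwise
from that AOI's ICC with a logged count.

ICC(A,1) is computed from the two-way ANOVA mean squares (subjects ×
raters, k = 2). The significance test of ICC > 0 uses `F = MS_R / MS_E`
with (n−1, (n−1)(k−1)) degrees of freedom, one-sided, starred at
.05/.01/.001. The 95 % CI follows the McGraw–Wong absolute-agreement
formulation with Satterthwaite denominator degrees of freedom. Koo–Li
labels (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent)
are attached to both CI bounds, read as a "label-to-label reliability"
pair. The implementation is cross-checked in the tests against a
from-definition brute-force ANOVA and against an independent established
implementation.

## 8. Pipelines and reproducibility

`run_experiment1` scores a cohort of grid sessions (default 9 participants
× 2 repetitions × 2 conditions = 18 recordings per condition) and reports
per-recording statistics plus per-condition medians. `run_experiment2`
runs the infant cohort (default 44 participants, of which 14 are marked
uncodable — the video-unusable failure mode has no synthetic counterpart,
so it is cohort configuration — and 5 are generated with a degraded,
unimodal estimate distribution that the segmentation itself then excludes;
default inclusion is therefore 44 − 14 − 5 = 25), compares
estimator-derived and degraded-manual dwell measures, and emits the
agreement table plus an exclusion log that always sums to the cohort size.

All randomness flows from one pipeline seed through `SeedSequence.spawn`;
fixed (config, seed) reproduces every output byte for byte. Problem sizes
in the test suite and acceptance script (12–20-participant cohorts, 100
Monte-Carlo seeds for recovery checks, 10⁴ samples/fixation for the
precision limit) are chosen so the whole suite runs in seconds while
keeping Monte-Carlo error well inside the asserted tolerances.

## 9. What the synthetic results do and do not show

Passing tests establish that the *statistics and rules are implemented
correctly* (oracle equality, exact noise-free recovery, convergence to
closed forms) and that the *pipeline behaves as designed* under the
generator's assumptions. They do not certify any real estimator: the
generator has no head pose, no saccade dynamics within dwells, no
slow drift, no face-detection dropouts correlated with pose, and its
off-AOI model keeps distractors clear of the AOIs. On real infant data
the same pipeline yields materially lower agreement — especially for mean
dwell duration, which is boundary-sensitive: estimates near a section
border break dwells that a human coder, who sees the video context, keeps
intact. The synthetic noisy regime reproduces that contrast qualitatively
(relative totals remain highly reliable while mean dwell duration
degrades), at agreement levels higher than real recordings show.

Known limitations:

- At zero noise the smoothed point-mass peaks keep density above the trim
  floor out to roughly ±5°, the same distance as the generator's none
  margin; an off-AOI sample sitting exactly at the margin can then attach
  to a section edge and shift one dwell boundary by a frame or two. With
  default seeds this does not occur; across arbitrary seeds it can move a
  noise-free relative-total ICC from 1.0 to ≈ 0.999998.
- The ">3 discernible peaks" disambiguation (greatest-total-height triple)
  is a design choice beyond the stated two/three-peak rules; it is robust
  under the generator's conditions but, like any automated surrogate for
  visual judgment, can misread pathological histograms (e.g. a distractor
  lump taller than a genuinely rarely-visited AOI peak).
- The blink detector is a feasibility heuristic; its default threshold is
  tied to the generator's blink model and will need retuning for signals
  with different units or rates.
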