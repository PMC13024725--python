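# Methods notes

## Scope and data model

The package analyzes the retrieval phase of a 3AFC object-memory design
with three object conditions (NR / RR / UR), two age groups, and gaze
recorded while participants choose among the three condition-variants of
one stimulus triad. Inputs are plain-text tables: a behavioral trial CSV
(one row per retrieval trial), a fixation-event TSV with `TRIALID n` /
`TRIAL_RESULT n` demarcation messages (the format of an exported
fixation report), and per-trial AOI rectangles in stimulus-pixel space
(JSON). Every stage is a pure function of (inputs, configuration, seed).

## Ingest conventions

Several rules the input format leaves open are fixed as package
defaults, each switchable where noted:

- **Trial membership by onset.** A fixation belongs to the trial whose
  marker window contains its onset time; a fixation straddling
  `TRIAL_RESULT` is kept with the trial it began in. Rationale: the
  onset marks where processing began, and the rule is deterministic.
- **60 ms rule.** Fixations strictly shorter than 60 ms are removed;
  exactly 60 ms is kept.
- **Eye selection.** One eye per participant by a fixed priority (right
  then left), applied at the participant level; trials recorded only
  with the non-selected eye are dropped.
- **Coordinate mapping.** Stimulus presentation is centered and
  unscaled: `x_stim = x_screen − (screen_w − stim_w)/2`, likewise for y.
- **AOI containment** is half-open, `[xmin, xmax) × [ymin, ymax)`, so
  the three rectangles partition the plane with no double counting.
  Overlapping rectangles are a configuration error, never tie-broken.
- **Quality control.** A trial is retained iff both the proportion of
  fixations and the proportion of fixation time on the stimulus are
  ≥ 0.50 (inclusive). QC runs after the 60 ms filter by default
  (`qc_before_filter` switches the order; the orderings differ only
  when sub-60 ms fixations are off-stimulus-heavy). Participants
  retaining < 30% of any condition's trials are flagged for exclusion.

## Gaze metrics

Six trial × AOI metrics: viewing proportion (AOI fixation time over
total AOI fixation time, so the three proportions form a composition),
early viewing (indicator of which AOI received the first AOI-landing
fixation — its target column is the early-target-viewing proportion),
first-fixation latency from trial onset, first-fixation duration, mean
fixation duration, and revisits (entries − 1, where an entry is a
maximal run of consecutive same-AOI fixations in the full sequence).
The viewing-proportion denominator uses AOI time rather than total
on-stimulus time, treating the three objects as a competitive
composition; unvisited AOIs yield missing time-based values — never
zeros, which would inject spurious rank structure into the
representational matrices. Condition-level values are means over
QC-passing trials; empty cells stay missing.

## Memory scoring

d′ uses the log-linear correction by default (add 0.5 to each cell, 1
to each denominator), keeping perfect rates finite; `none` and the
1/(2N) replacement rule are selectable. Hit rates are per condition;
the false-alarm rate pools all new cues (new cues have no condition of
their own — the generator assigns them a nominal label that only feeds
this pool). Old cues judged "new" are cue misses and leave the
object-selection denominator. The false-memory decomposition is defined
only for restructured (RR/UR) targets; errors on NR targets appear in
the choice-proportion matrix's off-diagonal cells but belong to neither
false-memory category.

## Representational similarity

Both 3×3 matrices are vectorized column-wise (top-to-bottom within
columns, left-to-right across columns, the same fixed rule for both
spaces) and rank-correlated: Spearman with average ranks on ties
(primary), Kendall τ-b (robustness). Perfect 9-pair correlations are
common, so |ρ| is clamped at 1 − 10⁻⁶ before the Fisher transform.
Zero-variance vectors make the correlation undefined; the
participant-metric pair is excluded and logged, never imputed.
Inference families are corrected separately: one BH-FDR family of six
metrics for the primary Welch tests, one for the permutation scheme,
one for the bootstrap scheme. The permutation p is two-sided on the
absolute mean difference with add-one smoothing; an exact-enumeration
mode exists for small samples.

The trial-level bootstrap pairs choice trials with gaze trials by triad
identity within participant and condition, drops pairs missing the
metric, and resamples a fixed number of pairs with replacement within
each condition (default: the median paired-trial count across
participants × conditions × metrics). The fixed size is used even when
a participant has fewer pairs; the deficit is reported. Bootstrap RNG
uses independent child streams per (participant, metric); the
permutation test uses a single stream. A caveat discovered during
validation: when the pooled matrices contain *nearly* tied cells, the
resampled rank order flips at random at every resample size, so the
bootstrap mean converges to a tie-averaged value rather than the
plug-in similarity; convergence to the plug-in holds when cells are
well separated (or exactly, structurally tied).

## Group statistics

The mixed 2 × k ANOVA is computed in two strata: a one-way ANOVA on
subject means (between), and orthonormal-contrast scores for the within
effects, with the condition main effect tested as the unweighted
average of group profiles (Type III / unweighted-means convention for
unbalanced groups, matching conventional RM-ANOVA software).
Greenhouse–Geisser ε comes from the pooled within-group covariance and
scales both degrees of freedom of the within tests; partial η² CIs
(90%) invert the noncentral-F CDF with the lower bound clipped at 0.
Bonferroni follow-ups contrast condition means using difference scores
with variance pooled across groups (error df = N − G), reducing to the
ordinary paired t when only one group is present; Cohen's d uses the
difference-score SD by default ("cell" average-SD selectable), with
noncentral-t CIs. The a-priori power routine for the within-between
interaction uses λ = N·m·f²·ε/(1 − ρ), df₁ = (g−1)(m−1)ε,
df₂ = (N−g)(m−1)ε — the conventional G*Power parameterization — and
returns the smallest total N with equal allocation meeting the target
(44 at f = 0.25, α = 0.05, power = 0.95, ρ = 0.5, ε = 1).

## Synthetic-data generator

The generator emulates the study conditions: 26 young and 29 older
participants by default, 60 triads, 20 trials per condition, and 30 new
cues at retrieval (the new-cue count is not constrained by the design
and is parameterized; 30 = half the old-cue count). Choice-probability
presets follow the published group × condition proportions (e.g. older
adults in RR: 0.84 target / 0.14 schema-consistent / 0.02
schema-inconsistent). Cue hit/false-alarm rates are free parameters set
to 0.95/0.10 (young) and 0.88/0.25 (older), i.e. d′ ≈ 2.9 and 1.9 —
plausible for a short-delay recognition test with distinctive cues.
Latency and fixation-duration parameters, and the early-orienting bias,
follow the published group × condition descriptives.

Per selection trial: first-fixation latency is lognormal; the fixation
count is 1 + Poisson; the AOI allocation w is Dirichlet(1 + κ on the
to-be-chosen AOI); fixation labels are i.i.d. draws from w with the
first AOI landing overridden by the early-orienting bias; durations are
truncated-normal (floor = the 60 ms threshold) with per-AOI means
scaled by 3·w, so both dwell-count and duration share concentrate on
the chosen object. κ therefore couples *fixation-time allocation* to
the upcoming choice: κ = 0 decouples gaze from choice (null similarity)
and the default contrast κ = 3.0 (young) vs. 0.5 (older) encodes the
finding the RSA is designed to detect. One RNG child stream per
participant (with a fixed cohort offset) means growing either cohort
never changes existing participants. AOI layouts use three fixed
horizontal slots with a seeded per-trial permutation of labels, shared
across participants (counterbalancing across trials); Latin-square triad
assignment is not modeled — conditions are assigned uniformly at random
per triad, since no downstream stage uses triad identity beyond
choice–gaze pairing.

What the generator does **not** emulate: encoding-phase gaze, saccade
kinematics, blinks/drift (inputs are assumed to be clean fixation
events — blink handling is upstream of this format), pupil size,
rating-scale psychometrics (RT and rating columns are plumbing), or
image-level stimulus effects. Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, and the recoverability
of coupling differences under the modeled mechanism — not claims about
any real recording.

## Verification scale choices

The test suite runs everything at sizes chosen to keep the full run in
a few minutes: oracle comparisons use 500 random 9-vector/p-set
instances; permutation calibration uses 2000 null datasets of 12 + 12
with 400 permutations; the ANOVA type-I check uses 2000 AR(1) null
datasets; the end-to-end coupling recovery uses 200 replications of the
full 26/29 design; bootstrap consistency uses three (resample size,
n_boot) points up to (384, 8000) on a constructed 36-pair pool.

## Known limitations

- The six gaze metrics' exact field definitions vary across labs; each
  deviation-prone choice (early orienting from the first AOI landing,
  revisits as entries − 1, AOI-time denominator) is a documented default
  behind a switch, not a claim of uniqueness.
- The bootstrap's non-convergence under near-tied pooled cells (above)
  is inherent to rank correlations under resampling, not a defect of
  the implementation.
- The mixed ANOVA supports one between factor and one within factor
  (the design analyzed here), not general factorial layouts.
- Effect-size CIs assume the standard noncentral-distribution
  inversions; they are not bootstrap CIs.
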