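# Methods

## The task model

A MILO (Multi-Item Localization) trial presents N symbols on a touchscreen;
the participant touches them in a prescribed order as fast as possible.
`milotask.engine` models the trial as a deterministic state machine driven
by timed touch events:

* **Display geometry.** Items occupy distinct cells of an invisible
  `rows x cols` grid (default 4 x 4 on a 1024 x 768 screen). Cell centres
  span `[offset_x, screen_w - offset_x]` horizontally and the analogous
  vertical range; with the default 200/150-px offsets this puts a 208-px
  horizontal and 156-px vertical pitch between neighbouring centres. The
  original app's description ("offset from top left") is ambiguous about
  whether the offsets are margins or a grid origin; we chose the
  margin/even-span reading. Each item is jittered uniformly by up to
  +/-80 px horizontally and +/-30 px vertically. Because that jitter can
  bring neighbouring 98-px items into contact, jitter is rejection-resampled
  (cells kept, at most 1000 attempts) until all pairwise centre distances
  are at least one item diameter and every item is fully on screen.
* **Selection.** A touch selects the nearest item whose centre lies within
  the touch radius (49 px, one item radius); background touches are logged
  and otherwise ignored. Touching the current target records a selection;
  in the *Vanish* condition the item disappears, in *Remain* it stays
  visible. Touching any other still-required item ends the trial in error —
  the only error the task defines. Re-touching an already-selected Remain
  item is treated as a background touch, since that item is no longer "out
  of sequence" in any meaningful way.
* **Manipulations.** *Shuffle* permutes the identities of all
  not-yet-selected targets over their fixed positions after every correct
  selection (including the first); the position multiset never changes.
  *Identical* mode makes order irrelevant (a pure cancellation task) and is
  incompatible with Shuffle. A *preview* period shows the display with
  responses locked; response timing is measured from response-enable, so a
  trial's `total_ms` is the last selection time minus the preview duration
  and the serial reaction times (SRTs) always sum exactly to `total_ms`.
  *Dual-sequence* trials concatenate two sequences (sequential mode) or
  alternate them item by item starting with the first list (interleaved
  mode, as in Trail-Making-Test part B).
* **Sessions.** A session design lists blocks of per-condition trial
  counts; scheduling interleaves them by random permutation (or keeps a
  fixed order where a design demands it), draws a fresh layout per trial,
  and gives every trial its own shuffle seed so logged sessions replay
  bit-exactly. An error trial is immediately followed by a replacement
  from the same condition with a new layout.

## The virtual participant

`milotask.simulate` generates touch streams with the canonical SRT
structure of sequential search. The generative model is a deterministic
mean latency per position and context, multiplied by lognormal noise whose
*median* equals that mean (medians are the analysis's point estimate, and
empirical SRT distributions are right-skewed). Defaults, all in ms:

| parameter | default | role |
|---|---|---|
| `t1_base_ms` | 600 | display-registration + motor-initiation cost of T1 |
| `t1_slope_ms_per_item` | 60 | planning cost per additional sequence item (0 for identical targets) |
| `cancel_tap_ms` | 200 | T2..TN taps with identical targets |
| `srt_profile` | (540, 525, 490, 435, 380, 330, 282) | T2..T8 medians for an 8-item sequence; mean 426; plateau then decline |
| `remain_offset_ms` | 19 | constant Remain slowing from T2 onward |
| `shuffle_floor_ms`, `shuffle_slope_ms_per_item` | 180, 105 | Shuffle latency = floor + slope x remaining items |
| `switch_cost_ms` | 360 | added at the first item of the second sequence |
| `sigma_log` | 0.15 | lognormal trial dispersion |
| `p_error` | 0.001 | per-touch out-of-sequence probability |
| `between_sd_log` | 0.08 | lognormal sd of a per-participant speed factor |

Sequence-mode T1 follows the linear law `600 + 60 x (N - 1)`, so an
8-item trial has a ~1020-ms first response. For sequence lengths other
than 8 the stored T2..T8 profile is linearly interpolated over relative
position, preserving its shape; for 12-item dual trials this leaves the
neighbourhood of positions 6–8 locally linear, so the switch-cost
estimator (SRT at position 7 minus the mean of 6 and 8) is unbiased for
`switch_cost_ms` up to the lognormal mean/median factor `exp(sigma^2/2)`
(~1.1% at the default sigma). The Shuffle defaults make an 8-item shuffle
trial start at the sequence T1 level (180 + 8x105 = 1020) and end near the
vanish final response (285 vs 282), matching the qualitative picture that
shuffled latencies track the physically remaining set size.

With `p_error = 0.001` per touch and 7 error opportunities in an 8-item
trial (the last touch cannot be out of sequence), the expected trial error
rate is `1 - 0.999^7 ≈ 0.70%`. A 40-trial session sample is therefore
noisy (+/-0.27 percentage points per 960 trials); rate checks in the test
suite use at least 2,000 attempted trials.

What the simulator does **not** model: eye movements, motor kinematics,
learning or fatigue across blocks, preview-duration effects on T1, and any
saw-tooth pair structure in interleaved trials beyond an optional constant
(`sawtooth_ms`, default 0). Passing tests therefore show that the
*pipeline* recovers the latency structure it was given, not that human data
will follow it.

## Statistics

* **SRT.** T1 is measured from response onset; Ti (i >= 2) from the
  previous selection. Error and ignored touches contribute no SRT rows;
  analyses use completed trials.
* **Median curves.** Cell-wise medians per participant x condition x
  target position (even counts average the central pair), summarised as
  between-participant mean +/- SEM.
* **Mixed ANOVA.** Balanced-design sums of squares for one between-subject
  factor crossed with one or two within-subject factors, the standard
  univariate repeated-measures decomposition (each within effect tested
  against its interaction with subjects-within-groups). Unbalanced input
  is rejected outright rather than approximated. Latencies are rescaled to
  seconds before squaring so error mean squares land on the conventional
  scale. Greenhouse–Geisser epsilon is computed per within error term from
  the pooled within-group covariance of orthonormal contrast scores
  (Helmert contrasts for main effects, their Kronecker product for the
  interaction), clipped to `[1/df, 1]`, and applied to both degrees of
  freedom. No installed package covers this 1-between x 2-within design,
  so the decomposition is implemented here; the test suite cross-checks it
  against `pingouin.mixed_anova` (1 x 1 subcase) and
  `statsmodels` `AnovaRM` (within-only subcase).
* **Polynomial trends.** Orthonormal polynomial contrasts over ordered
  levels, each tested as a one-sample F on per-participant contrast scores.
* **Bayes factors.** BIC approximation from the ANOVA F:
  `SSE1/SSE0 = df_err / (df_err + F * df_eff)`,
  `dBIC = n ln(SSE1/SSE0) + df_eff ln(n)`, `BF01 = exp(dBIC/2)`; posterior
  probability `BF/(1+BF)` under equal priors. `n` is the number of
  participants (recorded in the result and overridable — the literature is
  not unanimous on the observation unit). Evidence is labelled *weak* iff
  BF < 3.0 and posterior < .75, both strict.
* **Power.** Noncentral-F power for the repeated-measures within factor
  with `lambda = f^2 N m epsilon / (1 - rho)`, `df1 = (m-1) epsilon`,
  `df2 = (N - groups)(m-1) epsilon` (the G*Power "within factors"
  convention; an "as in SPSS" flag omits the correlation adjustment, since
  published analyses rarely state which convention they used). `min_n`
  scans group sizes from 2. With eta_p^2 = 0.3, alpha = .05, power = .95,
  m = 8, rho = .1 this lands in the single digits; the exact value depends
  on the convention chosen.

## Numerical and design choices

* Coordinates are integer pixels (origin top-left), times integer ms; the
  `.milo` log format stores integers only, which is what makes
  write -> read -> write byte-identical and sessions fully replayable
  (every trial carries its own shuffle seed).
* Hit-test ties go to the nearest centre; a touch exactly at the radius
  counts as a hit.
* The trend tests use a scale-aware zero threshold so constant contrast
  scores (which carry only floating-point dust) report F = 0 rather than
  an enormous spurious F.
* Simulated touches scatter uniformly within 45 px of the target centre,
  keeping every touch strictly inside the 49-px radius after integer
  rounding.
* Test and script problem sizes: end-to-end recovery runs 2,000 trials per
  set size/condition; the ANOVA type-I calibration uses 500 replicate null
  cohorts of 12 participants simulated at the median-table level (the
  event-level engine path is exercised separately); the power oracle uses
  20,000 Monte-Carlo replicates.

## Known limitations

* The generative model is a calibration target, not a cognitive theory:
  the true shape of the SRT decline, the mechanism of the Remain offset,
  and preview effects on T1 are not modelled.
* The mixed ANOVA requires complete balanced data, as the median-curve
  design guarantees; it is not a general linear-mixed-model replacement.
* The `.milo` dialect is this toolkit's own; no importer exists for the
  original app's files.
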