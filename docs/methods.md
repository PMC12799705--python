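# Methods

## The estimation method

Dental age estimation here follows the classical three-step staging
method restricted to the seven left mandibular teeth (FDI 31–37), each
assigned one of eight ordered mineralization stages A–H.  Step one —
reading stages off a panoramic radiograph — is a human task and sits
outside the package; stages arrive as data.  Step two assigns each
(sex, tooth, stage) a maturity score from a reference table and sums the
seven contributions into the maturity score `S`.  Step three converts `S`
to a dental age through a sex-specific grid of expected scores at ages
6.0–16.0 in 0.1-year steps (101 rows, strictly increasing).

The bundled tables are normative values for Kosovar children and
adolescents.  Unlike the original French-Canadian system, whose scores are
abstract 0–100 maturity units, these scores are *median chronological
ages* (years) of the children observed in each stage, so `S` is on a
years-equivalents scale; the seven all-H scores sum to 95.9 (girls) and
98.0 (boys).  The table is stored verbatim, including its non-monotone
within-tooth runs (e.g. the boys' second molar starts 8.7 then 7.7); no
smoothing is ever applied to a published reference.

Teeth assessed in a 6–16-year window lack early-stage observations, so a
tooth's scored stages form a contiguous run ending at H.  Rows with fewer
than eight printed values are right-aligned to stage H: the last value must
be H because completed mineralization is explicitly tallied, and the
missing stages are the early ones a 6+ cohort cannot observe.  A stage
earlier than a tooth's first scored stage raises `StageBelowCoverage`
rather than scoring zero — a zero would corrupt a years-scaled sum, and
silently so.

## Conversion

* **Grid route (default).**  Linear interpolation between grid rows; exact
  on grid nodes.  Linear is indistinguishable from higher-order schemes at
  0.1-year resolution and is auditable by hand.  Dental age is reported at
  2 dp.  Scores outside the grid clamp to 6.0/16.0 with a `clamped` flag:
  extrapolating a sigmoid beyond its calibration window fabricates
  precision.
* **Curve route.**  A four-parameter logistic
  `S(a) = A + (K−A)/(1+exp(−r(a−m)))` with lower/upper asymptotes `A < K`
  (score units), rate `r > 0` (per year) and midpoint `m` (years).  With
  those constraints the curve is strictly increasing and has a closed-form
  inverse on (A, K).  Fitting is scipy least squares with deterministic
  multi-starts and asymptote bounds that bracket the anchor range;
  non-convergence after all starts raises `FitDiverged`.  Discretizing a
  fitted curve onto the grid rounds to 2 dp; rounding ties on a near-flat
  curve are broken by a minimal upward nudge at the third decimal and
  flagged.

Both bundled grids are reproduced to within a few hundredths of a score
unit by a 4PL fitted through their own eleven integer-age rows (the
fitted asymptotes land near 0 and 100, the natural bounds of the original
maturity scale); the package's acceptance tests quantify this, which
supports reading the printed grids as logistic evaluations.  Whether they
were generated that way or via ordinal-regression class probabilities is
not decidable from the published material; the printed grid is
authoritative either way and the curve route is used only for newly
calibrated populations.

## Calibration model

`DentalMaturityModel.fit()` composes four steps, each also exposed as a
module function:

1. **Stage cells** (`stage_median_ages`): per (sex, tooth, stage), the
   median (default) or mean chronological age of subjects observed in that
   stage, with n, quartiles and an occupancy flag per cell.  The median is
   the default because it is robust and translation-equivariant; the mean
   is offered as both conventions appear in practice.
2. **Score table** (`derive_score_table`): cell centers become scores at
   0.1-year precision.  Cells need `min_n` subjects (default 10 — the
   accepted floor for age/sex groups in dental maturity references, also
   limiting age-mimicry).  The threshold trims *leading* low-coverage
   stages (the table simply starts later), but an interior hole is never
   dropped: doing so would make every subject observed in that stage
   unscoreable and can cascade into losing whole age bins.  Interior holes
   are filled from their low-n observed center, or by the midpoint of the
   adjacent scores when unobserved, and flagged in `filled_cells` — these
   are imputations, not estimates, and the saved diagnostics say so.
3. **Anchors** (`summed_score_anchors`): subjects are re-scored under the
   new table and binned by completed years (bin k = [k, k+1), the oldest
   bin truncated at 16.99).  Each bin anchors the curve at (median CA in
   bin, median `S` in bin); the bin median score belongs at the bin median
   age, not at the integer label, which would shift the curve by half a
   year.  Small-sample medians can invert; non-monotone anchor sequences
   are repaired by pool-adjacent-violators (weighted by bin size) and
   flagged.  Any bin under `min_n` raises `SparseBin`.  Subjects the new
   table cannot score are excluded here and listed in `unscoreable_ids`.
4. **Curve and grid**: PAV can leave ties, so tied anchors are spread by a
   minimal 0.01-score nudge before the 4PL fit (flagged); the fitted curve
   is discretized to the standard grid.

A cohort must span at least five integer-age bins per sex (four curve
parameters plus one), and all ages must lie in the declared window
(default [6, 17)).  Calibration itself is deterministic: shuffling the
cohort changes nothing, and shifting all ages by +c shifts all stage
scores by +c.

`percentile_curves` reports per-bin empirical score quantiles using the
type-7 (linear interpolation) definition — numpy's default and the one
most statistics packages print.

## Synthetic cohorts

The generator is a latent-tempo threshold model — the simplest mechanism
consistent with "stages are entered at population-typical ages with
individual variation":

* **Entry thresholds.**  If a stage's score is the median age of children
  in that stage, the boundary between consecutive stages sits midway
  between their scores; the first scored stage enters half a gap below its
  own score.  Midpoints of non-monotone published runs are repaired by PAV
  and spread to a 0.05-year minimal spacing, flagged.
* **Subjects.**  Each child draws one maturation tempo
  ~ Normal(1, `tempo_sd`), truncated below at 0.5 and shared by all seven
  teeth — this induces the within-mouth correlation real dentitions show —
  plus independent per-tooth jitter ~ Normal(0, `stage_noise_sd`) years on
  the effective age.  A tooth gets the highest stage whose threshold its
  effective age has reached, floored at the first scored stage.
* **Structure.**  Balanced `n_per_bin` subjects per sex per integer bin
  6–16, ages uniform within the bin (2 dp).  Defaults: `n_per_bin=50`
  (≈ the per-cell average of the reference study's 1106-subject frame),
  `tempo_sd=0.05`, `stage_noise_sd=0.4` yr, chosen so simulated DA−CA
  spread lands near the ~1.1–1.2-year SD such cohorts exhibit — a
  plausibility heuristic, not a fitted claim.  All randomness flows from
  one seed through per-(sex, bin, slot) substreams, so a cohort is
  reproducible even when regenerated at a different size.

What the simulator does **not** emulate: radiographic error modes
(blur, distortion, unreadable teeth), missing or malformed dentition,
secular trends, or any validated between-tooth correlation structure (the
tempo term induces one of unverified magnitude).  Passing recovery tests
therefore demonstrates internal consistency of the calibration machinery,
not field accuracy on real radiographs.

The parameter-recovery experiment (acceptance suite and
`scripts/acceptance.py`) uses `n_per_bin=150` and a low-noise setting
(`tempo_sd=0.02`, `stage_noise_sd=0.1`) so the measured recovery error
reflects the estimator's structural behaviour rather than sampling noise.
Even noiselessly, recovery is not exact: within a 6–17 observation window
the median age of a stage's occupants is the midpoint of the stage's age
interval clipped to the window, which differs from the generating score by
a quarter of the score sequence's second difference in the interior and by
substantially more at the window-truncated first and H stages — the same
age-window truncation (age mimicry) that real reference studies face.
Recovery error is summarized over the cells the calibration *estimated*
(n ≥ `min_n`); flagged filled cells are imputations and are excluded.
Held-out bias is evaluated on subjects the recovered table can score with
CA ≤ 16.0, the conversion grid's validity window.

## Evaluation

* `bias_report`: mean DA−CA with SD, t-based 95% CI, one-sample and paired
  t tests (two-sided throughout, no multiplicity correction), a seeded
  percentile bootstrap of the mean difference (2000 resamples; the seed is
  a required argument), median absolute deviation, half-year histogram of
  |DA−CA| (last bin closed so counts always sum to n), and the
  conventional accuracy bands (|DA−CA| < 1 year accurate, > 2 years
  inaccurate).  All differences equal → `degenerate_variance` flag with
  NaN p-values rather than an exception.
* `correlation_report`: Pearson's r and Spearman's rho (midrank ties) via
  scipy; constant input raises `ConstantInput`.
* `cohen_kappa`: unweighted by default (weighted linear/quadratic behind a
  flag, since stages are ordinal), via scikit-learn; a single shared
  category makes chance agreement 1 and raises
  `PerfectExpectedAgreement`, except inside `rater_comparison` where an
  identical single-stage column is, by construction, perfect agreement and
  reported as 1.0.  `agreement_label` maps kappa to the Altman bands
  (0.6–0.8 "good", etc.).
* `method_comparison`: paired dental ages for one cohort under two table
  sets, with the bias battery on DA(a)−DA(b) and the correlation between
  them.  No non-local table set is bundled; comparisons against other
  populations' scores require a user-supplied reference JSON.

## Known limitations

* The bundled tables cover ages 6–16 and the left mandible only; no third
  molars, so discrimination fades in late adolescence as everything
  saturates at stage H.
* Published evaluation statistics of the source study (its cohort-level
  biases, kappas and deviation ranges) are not reproducible here because
  the underlying 1106-subject cohort is not public; the evaluation module
  is validated against closed-form oracles and synthetic data instead.
* Calibration provides a simple seeded train/test split helper but no
  cross-validation machinery.
* The right-alignment of short score rows and the stage membership of the
  boys' second-molar row (seven printed values) are the most defensible
  reading of the published table, not a certainty; both are validated
  indirectly by the all-H column sums matching the conversion grids'
  upper region.
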