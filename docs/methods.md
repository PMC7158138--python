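# Methods notes

## The oximetry index

Autoregulation is probed statically: within one dose window the infusion
rate is constant, MAP fluctuates (and ramps after a dose change), and the
question is whether TOI co-moves with it. The index is the Spearman rank
correlation of the 60 paired (MAP, TOI) samples — Pearson correlation of
mid-ranks, with average ranks for ties (10-s device readouts are discretized,
so ties occur). Rank correlation is preferred to Pearson here because the
MAP–TOI coupling need not be linear within a window and because it is
invariant to monotone drifts in either channel's calibration.

Classification at ±0.36: strictly above is pressure-passive, strictly below
−0.36 is paradoxical, the closed interval in between (including both
boundary values) is intact. The boundary assignment is measure-zero in
practice but fixed for determinism. The threshold is a field convention
(published choices range 0.25–0.5), not an estimated quantity; it is
exposed as a parameter everywhere.

Degenerate windows: zero variance in MAP or TOI (or fewer than three
complete pairs) makes rank correlation incomputable. Such windows are
classified *undefined* and tallied separately — a constant TOI is
physiologically meaningful (perfect regulation), and folding it into
*intact* would silently bias pattern counts. Missing TOI samples inside an
otherwise present site are dropped pairwise by the index (with `n` recording
the complete pairs) and flagged by validation; they are never interpolated.

Tallies: a *stepwise infusion* is one condition × drug arm of one animal
(five per animal under the full protocol). An infusion counts as paradoxical
when any of its dose windows is paradoxical; animal-level counts are animals
with at least one such window. With 10 animals this yields the natural
denominators 50 (all sites) and 45 (lumbar, after one animal's loss).

## Windows and the data model

Recordings are tidy long-format CSV, one row per timestamp, with MAP shared
across the site columns (MAP is one arterial measurement; site-per-row would
duplicate it). Time is relative to the dose-step start; the analysis never
uses absolute experiment time. A conformant window has
`step_duration / sampling_interval` = 60 samples; windows with any other
length are kept but flagged non-conformant, never truncated or padded. Site
presence is an animal-level property (a lost probe loses the whole site),
while isolated gaps inside a present site are validation findings. Doses are
protocol labels matched exactly, not measurements.

Window extraction is a partition: every record contributes to exactly one
window per present site, so per-site paired-sample totals are conserved —
this is tested, and it makes the full-protocol census exact:
10 animals × 5 arms × 5 doses × 3 sites − 25 lost lumbar windows = 725.

## The simulator

The generator emulates the stepwise-infusion protocol, not the physiology
that produced it. Its pieces:

- **MAP**: per-dose target level (defaults are the packaged envelope means)
  plus a per-animal offset (between-animal SD 3 mmHg, the envelope's
  pre-infusion spread), a linear ramp from the previous step's level over
  the first 30% of the window (a ~3-min stabilization after an infusion-rate
  change), and stationary AR(1) fluctuation (SD 3 mmHg, coefficient 0.5).
  Samples are floored at 20 mmHg with a logged warning — a guard against
  degenerate configurations, not a modelled event.
- **TOI**: a static piecewise-linear (Lassen-type) autoregulation curve —
  plateau between lower and upper MAP limits, pressure-passive slopes
  outside — evaluated at the *window-mean* MAP, plus an additive condition
  offset, plus the window's regime slope times the within-window MAP
  deviation, plus AR(1) observation noise (SD 1%, coefficient 0.5), clipped
  into (0, 100) with logging. A dynamic flow model is deliberately not
  attempted: the analysis is a per-window static correlation, and dynamics
  beyond serial correlation are unidentifiable from its outputs.
- **Regimes** are drawn per window (the same animal switches patterns
  across doses, as real animals do), with default probabilities shaped like
  the qualitative findings: paradoxical responses concentrated in the
  cerebrum under phenylephrine, vasodilator windows mostly pressure-passive,
  the spinal cord more pressure-passive than the brain. Default slopes are
  ±0.2 %/mmHg (passive/paradoxical) and 0 (intact). Every window's regime
  and slope are returned as ground truth.

Site profiles put the cerebral plateau at 65% with spinal plateaus 48%
(thoracic) and 53% (lumbar) — the ~15%/10% relative offsets of the
envelope — with the cerebral curve flatter and wider (lower limit 45 vs
65 mmHg, below-limit slope 0.3 vs 0.2 %/mmHg), so simulated site means
order cerebral > lumbar > thoracic at every dose. Condition offsets
(hypovolemia −2.5, post-resuscitation −2.0 TOI points) encode that a 600-ml
bleed lowers the curves by under 5% of plateau and that fluid resuscitation
does not restore them.

Within-window variability (MAP SD 3 mmHg, TOI SD 1%, AR 0.5) is our choice:
published tables report only across-animal SDs, so these defaults are set to
values a 10-s hemodynamic series plausibly shows and are exposed in
`SimConfig`. The AR coefficient matters: serial correlation widens the null
distribution of the windowed Spearman statistic (effective sample size
~36 of 60 at coefficient 0.5), which is exactly the regime a threshold of
0.36 was calibrated against in practice.

What passing the recovery test shows — and what it does not: with
ground-truth slopes ±0.2 %/mmHg against 1% noise, the classifier recovers
~90–93% of labels, dominated by dose-0 windows where no ramp adds MAP range.
Real recordings have no ground truth, non-stationary noise, and regime
mixtures within windows; the test validates the pipeline's wiring and the
classifier's calibration, not its field accuracy.

Per-dose *level* summaries of simulated data should be computed on the
steady-state portion of each window (`window_means(discard_fraction=0.3)`).
Published per-dose hemodynamic values are steady-state readings taken after
each dose stabilized; a full-window mean that includes the transition ramp
under-reports high-dose steps by several mmHg by construction.

## Dose-response aggregation

Summaries are across animals: each animal contributes its window mean, cells
report mean ± sample SD (n−1; single-animal cells get SD = NaN, flagged
rather than zero). Regressions are OLS of TOI on MAP over the five per-dose
mean points of one arm — fitting the printed means reproduces the published
cerebral and thoracic coefficients at printed precision, which confirms this
reading over pooled-raw-sample fits. Known limitation, documented rather
than patched: a few published lumbar coefficients and two R² values differ
by 0.01–0.03 when recomputed from rounded means (the original fits used
unrounded data, and lumbar means cover nine animals); these are not asserted
anywhere.

Percent changes use the dose-0 value of the same condition × drug arm as
reference; cross-condition (bleed/resuscitation) changes compare dose-0
phenylephrine rows. Sign convention: positive = decrease from reference.
Rounding is half away from zero to integer percent (12.5 → 13, −10.5 → −11),
the rule under which every reproducible printed integer is recovered.
Condition shifts evaluate two arms' fitted lines at a common MAP inside both
fitted ranges; extrapolation requires an explicit override.

## Group tests

- **Repeated-measures one-way ANOVA**: two-way additive decomposition
  (subjects × treatments), F = MS_treatment/MS_error on (k−1, (k−1)(n−1))
  df. No sphericity correction is applied — a deliberate fidelity choice to
  the analysis style this package mirrors; under compound-symmetry
  violations the test is anti-conservative.
- **Scheffé post hoc** on the same error term: pair contrast
  F = n(m_i−m_j)²/(2 MS_error) against (k−1)F_{α;k−1,df_e}; the reported
  p-value is the Scheffé bound, so post-hoc significance is impossible when
  the omnibus F is sub-critical (tested).
- **Friedman**: tie-robust statistic from within-block mid-ranks, chi-square
  reference on k−1 df. An exact permutation p-value (all (k!)^n within-block
  orderings, capped at 10^6 assignments) is computed automatically for small
  designs; the chi-square approximation is known to be conservative at small
  n (measured size ~0.04–0.05 at n=10, k=5).
- **Steel–Dwass**: each unordered pair jointly mid-ranked; the standardized
  rank-sum z (tie-corrected variance, no continuity correction) is referred
  as √2·|z| to the studentized-range distribution with k groups and infinite
  df — the standard large-sample form. Exact small-sample tables are out of
  scope. Measured familywise error ≈ 0.03 at α = 0.05 with k = 5 groups of
  10 (rank tests are discrete, hence conservative).
- **Wilcoxon signed-rank**: zeros dropped (logged) per the original
  procedure; exact two-sided p by sign-assignment convolution over mid-ranks
  of |d| for n ≤ 25, normal approximation with tie-corrected variance and
  continuity correction above. Two-sided p is twice the smaller tail,
  capped at 1.

Whether original analyses used one- or two-sided tests or which tie/zero
conventions is generally unstated in this literature; the defaults above are
documented choices, not claims about any particular study.

## Problem sizes and determinism

Validation experiments use: one full default protocol (10 animals, 725
windows) for recovery; 10,000 windows for the classifier null; 5,000
replicates for test size; 500 replicates for Steel–Dwass familywise error.
All simulations take a single integer seed through
`numpy.random.default_rng`; identical configurations are bit-reproducible.
Hypothesis-based property tests run derandomized.

## Known limitations

- TOI is taken as given; no NIRS physics, no device formats.
- The MAP→TOI coupling is phenomenological; no hemoglobin/oxygen-content
  physiology, no HR/CVP/cardiac-output co-modelling.
- Single fixed window per dose step; no moving-window (PRx-style)
  continuous monitoring, no autoregulation-limit (breakpoint) estimation.
- Linear dose-response fits only; no sigmoid/piecewise curve fitting to
  data, no confidence intervals on the fitted coefficients.
- Animal-level medians, pattern counts and infusion tallies from the
  original experiments require per-animal raw recordings that are not
  public; the package exercises that machinery on synthetic data only.
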