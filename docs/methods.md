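# Methods

## Rank inference

**Contest model of the data.** The primitive observation is a dyadic
tube-test outcome: one winner per contest, no ties (a trial in which both
animals retreat is re-run and logged once as its final outcome). Sessions
are round robins — every cage pair contests exactly once per session day.
The code accepts any ascending set of 1-based study days; the
alternating-day calendar (9 sessions over 18 days) used throughout the
fixtures and the synthetic generator is a study convention, not a code
constraint.

**David's Score.** Win proportions `P_ij = wins_ij / n_ij` feed the four
sums `w, w2, l, l2` and `DS = w + w2 − l − l2`. Raw proportions are used
rather than the dyadic chance-corrected index: only the raw-P variant
attains the full [−6, 6] range in a tetrad, which is the range the
quartile class cutoffs (±3) presuppose. A pair with no contests in the
window is an error, never an imputation — the opponent-weighted terms
would silently bias otherwise. `Σ DS = 0` holds for every complete
matrix and is property-tested.

**Normalized DS and steepness.** `NormDS = DS/N + (N−1)/2` maps scores
into `[0, N−1]`. Steepness is the magnitude of the OLS slope of the
descending-ordered NormDS against positions 1..N — 1 for a unanimous
linear hierarchy, 0 for a flat one. The analytic bound |slope| ≤ 1 is
enforced by clamping the few-ulp excess floating-point regression can
produce at the despotic extreme. Windows: 4 sessions for rank (spanning
8 days at the alternating cadence), 7 for steepness, anchored to a named
event day (stress start) or the ledger's end.

**Linearity, stability, mobility.** A day is linear exactly when its win
counts are a permutation of {0..N−1}; for a complete single-day round
robin this is equivalent to the absence of a directed 3-cycle (the score
sequence characterization), and the tests verify the equivalence against
exhaustive cycle search on all 64 tetrad tournaments and random 5- and
6-animal tournaments. On non-linear days rank positions are left
undefined — not tie-broken. Stability compares the final 4 consecutive
sessions; the default criterion requires identical full pairwise outcome
sets (well defined even on non-linear days), with an identical-rank-order
criterion available as a config option. Mobility counts rank-position
changes between consecutive *linear* days, skipping non-linear days
entirely: one change or fewer is LOW, two or more HIGH, and fewer than
two linear days yields an explicit UNDEFINED rather than a silent LOW.

## Behavioral scores

* **SI ratio** = interaction-zone time with the social target present /
  time with it absent; susceptible strictly below 1 (a ratio of exactly 1
  classifies resilient). A zero target-absent time raises rather than
  capping.
* **Coping score** = (escapes + fighting back − passive events) /
  attack bouts. The full active-minus-passive numerator is divided by
  attacks, consistent with reading the score as net active responding per
  aggressive bout.
* **Wound score** sums 0–3 points over four body regions: lower back by
  wound area (0.01–1 cm² = 1, 1–2 cm² = 2, ≥2 cm² = 3; below 0.01 cm²
  scores 0), the other regions by discrete wound count with bins [1,5),
  [5,10), [10,∞). Shared bin boundaries are lower-inclusive /
  upper-exclusive so the partition has no gaps; "10+" includes 10. Only
  the area contributes for the lower back even when discrete wounds are
  countable there.
* **Vigilance** sums interval durations in which the animal is oriented
  to the aggressor while outside the interaction zone; intervals must be
  non-overlapping and inside the trial.

## Statistics

Outlier removal follows the two-SD rule within each rank x stress cell:
one pass (not iterated), strict inequality at the boundary, mean and
sample SD computed including the candidate value, groups smaller than 3
passed through with a warning record. Note that with an inclusive sample
SD no point can exceed 2 SD in groups of five or fewer (the inclusive
z-score is bounded by `(n−1)/√n`), so the rule only bites in reasonably
sized cells — the filter log records exactly what was removed.

Pearson correlations report r, df = n−2, the t-transform two-sided p and
a Fisher-z 95% CI. Two-sample t-tests are Student's with pooled variance
(paired variant on differences); a zero-variance arm with a nonzero
difference is an error rather than an infinite statistic. The 2x2
chi-square is Pearson's without continuity correction.

The two-way factorial (stress x rank, or mobility x rank) is fit by least
squares with sum-to-zero coding and reports Type-III partial F tests,
the decomposition that stays interpretable for the unbalanced cell sizes
real cohorts produce; with a single level of the second factor the
design collapses to the pooled t-test (F = t²). Within-rank contrasts use
the model's pooled residual mean square with Sidak adjustment
`p_adj = 1 − (1 − p)^m` over the m rank classes, and Sidak-adjusted CIs.
One-way comparisons report the classical F plus Tukey–Kramer all-pairs
contrasts from scipy's studentized-range distribution; if that
computation fails to produce finite values the contrast falls back to a
Sidak-adjusted t flagged `tukey_approx`. Null calibration of every test
(rejection rate at α = 0.05 over 1000 replicates) is asserted in the
test suite.

Published r/CI/p triplets in this literature are not always internally
consistent; the implementation computes self-consistent statistics and
does not attempt to reproduce any specific printed triplet.

## Synthetic cohorts

Contests follow a logistic latent-ability model:
`P(i beats j) = logistic((θ_i − θ_j)/τ)` with `θ ~ N(0, σ_θ²)` per
animal. Defaults `σ_θ = 1, τ = 0.3`, winner effect `δ = 0.05` (added to
the winner's and subtracted from the loser's ability after every
contest, persisting thereafter) and per-session ability jitter
`σ_s = 0.15` were chosen once to produce what hierarchy studies actually
report: a mixture of stable and unstable cages (roughly 40% stable under
the 4-identical-sessions criterion) with a large majority of linear days
and steepness well below the despotic ceiling. Higher `σ_θ/τ` with zero
jitter and winner effect recovers latent ability almost perfectly
(within-cage Spearman(θ, DS) ≥ 0.9 — asserted at ratio 5 across seeds),
which is the generator's parameter-recovery check.

**Defeat outcomes (CSDS).** Controls draw SI ratios from
`N(1.3, 0.4²)` truncated at 0 (unstressed mice prefer the social
target); stressed animals lose a per-rank-class deficit — defaults 0.45
(SUB), 0.35 (INT), 0 (DOM), the male defeat pattern — plus an optional
`ds_si_slope · DS` term. Effect sizes in SI units are not published
quantities; these defaults are config-exposed choices that reproduce the
qualitative pattern at realistic cohort sizes, not estimates. Coping
event counts are constructed so the realized coping score tracks the
realized SI ratio (one response per attack bout, active fraction
`(1+s)/2`); vigilance is elevated for stressed subordinates only under
the inter-female flag.

**Chronic variable stress (CVS).** A latent stress-reactivity trait is
carried by a fraction (default 0.3) of animals with severity ≈ 1. The
trait is constitutive for social interaction — carriers' SI is lower by
`cvs_si_coupling · severity` in both arms — while its hierarchy
consequence expresses only under stress: stressed carriers take an
ability penalty during the stress epoch and sink. This makes every
pre-stress rank x stress cell identical in trait composition (the
pre-window contrasts are null by construction, matching the absence of a
stress main effect in this design) while the emergent subordinate cell
concentrates carriers, producing the emergent-rank deficit and the
emergent DS–SI correlation. An alternative in which the SI deficit also
expresses only under stress was considered and rejected: it induces an
overall stress main effect that contaminates the pre-window contrasts,
which is not the structure this design exhibits.

**Recombination.** After the tetrad phase, top-DS and bottom-DS animals
are re-paired DOM-with-DOM and SUB-with-SUB; dyad contests over 7
sessions decide who keeps the position. SI is drawn with a configurable
DOM-DOM minus DOM-SUB gap (default 0.5) and no gap between the SUB arms.

All randomness flows from one seed through named `SeedSequence` streams
(stream key = CRC32 of the stream name), so adding a generator never
perturbs existing streams and every artifact is byte-reproducible.

## What the generator does and does not emulate

It reproduces the statistical structure the pipeline consumes: round
robin ledgers with realistic stability/linearity mixtures, rank-linked
outcome distributions, and the four study designs. It does not model
aggressor behavior, wounding physics, habituation, body-mass effects, or
cage-level correlation of outcomes beyond the cage-randomized stress
assignment — so green tests demonstrate that the pipeline recovers known
structure from data of this shape, not that real cohorts satisfy the
generative assumptions.

## Problem sizes and numerical choices

End-to-end checks run at study-realistic sizes chosen as the package's
own test conditions: 80 cages (320 animals, ~40/cell) for the defeat
design, 100 cages for the CVS design, 20 seeds per design; calibration
uses 1000 null replicates per test. Degenerate inputs are errors, not
silent values: empty windows, missing pairs, zero denominators,
zero-variance arms, empty factorial cells. Daily rank ties never occur
on linear days by construction; DS ties in ordinal ranking (possible in
principle) are broken by the `min` rank convention in the rank-change
fraction. Window DS is computed from all contests in the window,
including non-linear days — round robins are complete regardless of
linearity, and excluding them would bias win proportions.
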