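# Methods

## The seasonal model

Each stratum (test + specimen, unit, lab ID, sex, 10-year age group) is
assumed to vary over the year as a single-harmonic cosine in normalized
units:

    y(week) = β₀ + β₁ · cos(2π · (week − θ) / 52)

with offset β₀ and amplitude β₁ bounded to [−1, 1] and phase θ to [0, 52]
weeks. One harmonic captures one peak and one trough per year, which is the
dominant pattern for temperature-, light- and diet-driven analytes; multiple
peaks, secular trends and year effects are deliberately out of scope.

Time is ISO week-of-year 1–52, with week 53 folded into 52; the model is
periodic with period 52 by construction. Fits are reported in a canonical
form with β₁ ≥ 0 (an amplitude-negated fit is the same curve with θ shifted
half a period), and phase errors are always measured as angular distance
min(|Δθ|, 52 − |Δθ|).

### Normalization

Values are z-scored within the stratum (mean 0, sd 1, sample sd with
ddof = 1) over the *fitting subset*: records from patients who survived more
than 28 days after the draw, so that acutely dying patients do not distort
the seasonal signal. Z-scoring (rather than mean-centering alone) is what
makes the [−1, 1] amplitude bound meaningful across analytes with very
different scales. The stratum mean/sd are retained: the fitted deviation is
mapped back to measurement units by multiplying by the stratum sd, which
also exactly undoes the amplitude shrinkage that z-scoring introduces
(the normalized amplitude is β₁·σ_noise-free/σ_total, and the adjustment
multiplies by σ_total again). Zero-variance or <2-point strata are marked
unfittable and excluded with a logged reason.

### Fitting

The default fit target is the 52 count-weighted weekly means pooled across
years, not the raw records: the model is week-indexed, the weighted
least-squares problem is then well-conditioned at any cohort size, and
residual degrees of freedom are well-defined. Per-record fitting is
available via `aggregate=False` and agrees with the aggregate fit to well
within sampling error (covered by a test). At least 26 non-missing weeks are
required — half the year, enough to pin down three parameters including a
phase.

Optimization is bounded trust-region least squares
(`scipy.optimize.least_squares`, the same bounded-NLS family as the classic
"port" routines), multi-started over θ ∈ {0, 13, 26, 39} because the SSE
surface is periodic in θ with local minima half a period apart; the lowest
SSE wins. Standard errors come from the asymptotic covariance
s²·(JᵀJ)⁻¹ with s² the weighted residual mean square on n − 3 degrees of
freedom, and p-values are two-sided Wald t-tests of each parameter against
0 — what an NLS summary prints. s² is floored at (10⁻⁹·scale)² so that a
noiseless, exactly-interpolating fit does not yield zero SEs and a
"significant" 10⁻¹¹ amplitude.

### Significance

p-values are Benjamini–Hochberg corrected *per parameter family* across
strata (all β₀ p-values together, all β₁, all θ). The default significance
rule requires q < 0.05 for **amplitude and phase** (`beta1_theta`). The
all-three-parameters rule is implemented (`rule="all"`) but is not the
default: after normalization to mean 0 the fitted β₀ is ≈0 by construction,
so a Wald test of β₀ = 0 is approximately uniform no matter how strong the
seasonality, and requiring it would veto essentially every stratum. A
`beta1`-only rule is also available; testing θ against 0 with a Wald
statistic is itself scientifically odd (θ = 0 is a legitimate phase, not an
absence of effect), so strata with true phase near 0/52 can be missed under
the default rule — a documented trade-off, not an accident.

### Adjusted reference intervals

For a significant stratum the standard interval (lower, upper) is translated
week-by-week by the de-normalized deviation σ·y(week): both bounds move
together, interval width is week-invariant, and the mean shift over a full
year is σ·β₀ (the cosine integrates to zero). Non-significant strata keep
the standard interval, so with no seasonality the whole adjustment is the
identity. Translation is the minimal adjustment consistent with "shift the
interval to where the population sits this week"; rescaling the width would
require a seasonal variance model the data does not support.

## Cohort rules

* Encounters of one patient whose gap (next start − running maximum end) is
  **strictly less than 24 h** are merged into one admission; a gap of
  exactly 24 h does not merge. Overlapping encounters merge. The operation
  is idempotent.
* A lab record attaches to an admission iff it falls in the **closed,
  one-sided** window [start, start + 24 h]; if two windows could qualify the
  earliest admission wins, and a record attaches at most once.
* Repeated measurements of one test within the window reduce to the **most
  abnormal** record: any out-of-interval record beats in-interval ones, and
  between out-of-interval records (including a −1 vs a +1) the larger
  deviation normalized by interval width wins — a scale-free rule that makes
  a deep low beat a shallow high. All-normal repeats return the last record
  by timestamp (flag 0 regardless).
* Filters, in order: age ≥ 20 at draw; ICD codes truncated to level 3
  (I21.2 → I21); tests kept iff measured in ≥ 20% of admissions (boundary
  inclusive); outcomes kept iff ≥ `min_patients` unique patients (1,000 by
  default, configurable for desk scale); and a separate fitting mask
  excluding records whose patient died ≤ 28 days after the draw. The
  survivor rule is applied to the draw timestamp itself, which is defined
  for every record whether or not it attaches to an admission. Filter order
  matters only in that coverage/prevalence are computed on the age-eligible
  cohort; an emptied cohort raises instead of silently succeeding.
* A record's stratum uses age **at draw**; a patient crossing a decade
  boundary legitimately contributes to two strata over time.

## Feature encoding and models

Flags are +1 above / −1 below / 0 within, with values exactly on a bound
counted normal (the standard interval is a closed central band). Version 1
flags against the standard RI, version 2 against the adjusted RI at the
record's week; most-abnormal selection is re-run per version because the
flag that defines "most abnormal" depends on the bounds. Missing tests are
imputed 0 (= within interval), sex is encoded 0/1 (F/M), and columns are
standardized with mean/scale fitted on the development split only —
split-wise scaling is the leakage-free reading of a global standardization
step. Zero-variance columns pass through unscaled with a warning.

The split is at patient level (70/30 by unique patient ID). Tuning is random
search (≤ 40 configurations by default) scored by mean F1 at the fixed 0.5
threshold over patient-grouped K-fold CV (grouping prevents the outer
split's leakage guarantee from being undone inside CV); balanced
case/control resampling (minority oversampled with replacement to the
majority count) is applied to training folds and the final refit only,
never to validation or test data. Ties go to the earliest sampled
configuration. The four families are ordinary scikit-learn classifiers
behind one interface — the contribution here is the comparison harness, not
the learners.

## Paired bootstrap and BCa

Point AUROC/AUPRC are computed on the full test set. Each of `n_boots`
(default 1,000) resamples draws test admissions with replacement using an
index derived from (seed, boot index) — identical for both versions, so each
difference isolates the encoding change; resamples with a single class are
redrawn, keeping the count fixed. The BCa interval (default 10,000 outer
boots) is taken on the **mean** of the paired-difference distribution — the
mean is the smooth functional for which the jackknife acceleration is
defined — while the **median** difference is reported as the effect size.
z₀ comes from the fraction of outer-boot means below the observed mean
(mid-p at ties, clipped away from 0/1), a from the jackknife skewness, and
degenerate all-equal input returns a point interval. The implementation is
cross-checked in the test suite against `scipy.stats.bootstrap(method="BCa")`
on skewed samples. A verdict of `v2_better`/`v1_better` requires the BCa
interval to exclude 0; per-family net gain sums the significant median AUROC
differences across outcomes, zeroing non-significant ones.

## Permutation-Shapley attributions

Attributions are computed on the model's probability output (ANOVA needs a
continuous response). For each explained row, a sampled (feature-ordering,
background-row) pair walks the ordering, switching each feature from the
background value to the row's value and crediting the output change to that
feature; averaging over all d!·|background| pairs gives exact Shapley values
(verified against subset-formula enumeration to 1e−9 in tests), and the
Monte-Carlo estimator is unbiased with error shrinking in the number of
sampled pairs. Local accuracy (attributions sum to output − base value)
holds exactly under exhaustive enumeration. The background is a seeded draw
of up to 100 development rows — the baseline the "feature absent" value is
drawn from; small backgrounds keep runtime proportional to
rows × permutations × (d + 1) model calls. Mean-|SHAP| summaries optionally
scale by the per-outcome maximum (ranking features within an outcome on
[0, 1]); the level ANOVA groups attributions by the feature's
pre-standardization level (−1/0/+1) and Bonferroni-corrects across the
features actually tested, reporting features with fewer than two populated
levels as untested rather than dropping them.

## Synthetic generator: what it emulates, and what it does not

Lab values are `baseline_mean + σ·(s(week) + ε)`, ε ~ N(0, 1), with s the
generating cosine — exactly the model the fitter assumes, with Gaussian
noise matching the least-squares/normalization assumptions. Admission
counts are Poisson (0.6/patient-year over 4 years, matching the ~1.4 M
encounters / 561 k patients / 4 y regime the method targets), sex is 54%
female, timestamps are uniform within the study period (the within-week
timestamp distribution of real draws is unknown; uniform is assumed), a
configurable fraction of admissions is split into transfer encounters < 24 h
apart, tests are missing/repeated with configurable probabilities, 2% of
patients die within 28 days of a random admission (exercising the survivor
mask), and admission outcomes are Bernoulli draws from a logistic model over
per-test abnormality flags (signed), sex, and an intercept. When
`uses_seasonal_truth` is set the flags driving the outcome are computed
against the *seasonally shifted* true RI, giving the version-2 encoding a
real signal advantage; with it unset (or β₁ = 0) the two versions are
exchangeable and the correct verdict is "no difference". Distinct admissions
of one patient are spaced ≥ 48 h end-to-start so generated admissions never
merge accidentally.

Default experiment conditions (frozen, used by the CLI demo and the
acceptance script): 2,000 patients, 4 years, four seasonal tests with
β₁ = 0.6 and phases spread over the year, standard RI = mean ± 1.645 σ (a
central-90% band), ages 20–39 (so strata stay well-populated at desk
scale), one outcome with weight 1.5 per abnormal flag. In this regime the
seasonal shift moves well over 15% of the abnormality flags across a bound,
which is the regime where adjustment can matter.

What the generator does **not** emulate: real demography, multiple labs and
unit systems, analyte-specific distributions (log-normal skew, detection
limits), correlated test panels, diagnosis-code hierarchies beyond level-3
strings, or admission-length/outcome dependence. Passing tests therefore
demonstrate that the machinery is correct and sensitive under its own
assumptions — not that any particular real analyte will yield a gain.

## Numerical choices and problem sizes

* Multi-start NLS over four phases; SSE ties broken by first-found; s²
  floored as above; pseudo-inverse for near-singular JᵀJ (β₁ → 0 makes the
  θ column vanish).
* BH correction via `statsmodels.stats.multitest.multipletests`.
* Bootstrap resamples are indexed by (seed, b), so execution order and
  parallelism cannot change the distribution.
* Desk-scale defaults in tests and the acceptance script: the sensitivity
  experiment uses a compact random-forest search (3 configurations × 3
  patient-grouped folds, 60 trees) with 200 paired boots / 2,000 BCa boots;
  parameter recovery uses 50 strata × 100 draws/week; FDR specificity uses
  200 null strata × 20 replicates at 20 draws/week. These sizes were chosen
  as the package's own desk-scale study conditions; all are plain arguments
  and scale up unchanged.

## Known limitations

* One harmonic; analytes with two seasonal peaks are mis-modelled.
* The Wald test on θ makes near-zero-phase strata harder to declare
  significant under the default rule (see above).
* Translation-only adjustment cannot represent seasonal variance changes.
* The logistic outcome model uses signed flags; a disease driven by |flag|
  would weaken linear learners (trees are unaffected).
* `uses_seasonal_truth` gives version 2 an advantage by construction; the
  harness measures whether the pipeline *recovers* it, not whether it exists
  in any real dataset.
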