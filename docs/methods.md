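# Methods

## Data model

The unit of analysis is a complete N x R matrix of ordinal categorical
scores: N cases, R observers, C ordered categories with integer codes
(HER2 IHC: `0,1+,2+,3+` coded 0–3). Completeness is a hard requirement —
missing cells are rejected, not imputed — because every statistic below
assumes balanced data with exactly R ratings per case. Partial panels are
out of scope. Both label cells (`"1+"`) and integer-code cells are accepted
on input; labels are always written. Case and observer order is preserved
as read, since per-case export plots depend on input order.

The sufficient statistic for OPA and Fleiss' kappa is the N x C table of
per-case category counts `n_ij`.

## Agreement statistics

**OPA.** The point estimate is the number of fully unanimous cases divided
by N. The 95% CI is a Wilson score interval on the unanimous-case count.
Rationale for Wilson over a case-resampling bootstrap: with zero unanimous
cases a bootstrap can never produce a nonzero upper bound, whereas
published tables for such subsets report intervals like 0.00 (0.00–0.02);
Wilson (and Clopper–Pearson, offered as an option) reproduce that bound.
The Wilson lower limit is clamped to exactly 0 at zero successes.

**Fleiss' kappa.** Computed from the count table by the standard formula
(`P_i = (Σ_j n_ij² − R)/(R(R−1))`, chance agreement `Σ_j p_j²` from pooled
proportions). The 95% CI uses the Fleiss–Nee–Landis fixed-marginal
large-sample standard error, `κ ± 1.96·SE`, truncated to [−1, 1]. Published
concordance tables sometimes print zero-width kappa intervals; we treat
that as a rounding/reporting artifact and make no attempt to reproduce it.
Kappa is undefined (a typed error, not 0 or 1) when all ratings fall in a
single category.

**ICC(A,1).** Categories enter a two-way random-effects ANOVA as their
numeric codes (0–3; 0/1 after dichotomization). With mean squares MSR
(cases), MSC (observers), MSE (residual),

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

the absolute-agreement single-rater form; the 95% CI follows McGraw &
Wong's F-distribution method with Satterthwaite denominator degrees of
freedom. When observers are numerically identical (MSE = MSC = 0) the ICC
is reported as exactly 1 with a degenerate interval; when total variance is
zero the statistic is undefined. Treating an ordinal score as equally
spaced numeric values is an assumption, not a theorem; it matches the
common SPSS workflow for such tables, and the dichotomized rows are
insensitive to it.

**Report assembly.** The full agreement table computes all three metrics
for: the 4-category matrix; the 3-category merge (1+,2+ → "low"); the five
"X only" subsets (cases given X by at least one observer; "low only" is the
union rule, ≥1 observer assigning 1+ or 2+); and the six dichotomizations.
Subset rows keep the original 4-category codes — all four categories remain
present inside each subset, so reducing the schema there would change the
statistics. Undefined metrics and empty subsets become row-level notes, not
run failures. Display rounding is half-up to 2 decimals; full precision is
retained internally and in the JSON outputs.

**Stratified OPA.** For observer strata (experience), OPA is computed among
each stratum's observers over all cases (each stratum needs ≥ 2 observers,
since one observer is trivially unanimous); for case strata (specimen
type), over each stratum's cases with the full panel. The reported
difference is highest minus lowest stratum OPA.

## ONEST

For a random ordering p of the R observers and k = 2..R, `O_p(k)` is the
OPA restricted to the first k observers of p. Orderings are sampled
uniformly with replacement (collisions are immaterial at R = 15, where
R! ≈ 1.3·10¹²); an exhaustive mode enumerates all R! orderings when R! is
below a cap, and is used as the oracle in tests. Defaults: 1000
permutations, mandatory seed. Each curve is non-increasing in k and the
mean curve at k = R equals the full-panel OPA exactly — both are asserted
properties.

The plateau is defined on the mean curve: the smallest k such that
|mean(k′) − mean(R)| ≤ ε for all k′ ≥ k, with ε = 0.01 OPA by default.
"Plateau" has no universal definition; ε is an exposed parameter and
plateau claims should be read as approximate.

## Synthetic panels

The generator draws a true category per case from a prevalence vector and
then, independently per observer given the truth, a score from that
observer's row-stochastic confusion matrix. Observer heterogeneity is a
shared confusion template whose off-diagonal mass is scaled per rater
(capped so diagonals stay positive); experience strata are groups sharing a
multiplier; an optional specimen effect scales the off-diagonal mass again
for a randomly flagged case subset. The hidden truth vector is returned
out-of-band and never written to the score CSV.

Conditional independence given truth makes the expected OPA available in
closed form — `Σ_t π_t Σ_j Π_r C_r[t, j]`, mixed over flagged/unflagged
case strata — which the simulation must match within Monte-Carlo error;
recovery tests use this as the oracle.

**Shipped study-like configuration** (460 cases, 15 raters): prevalence
(0.25, 0.30, 0.33, 0.12) over 0/1+/2+/3+; confusion template with 0↔1+ as
the dominant error (true 0: 17% scored 1+), a smaller 1+↔2+ exchange, and
reliable 3+ calls (92% retained); 8 "senior" raters at noise multiplier
0.7 and 7 "junior" at 1.3; 54/460 of cases biopsy-flagged with 1.6x extra
confusion. These values were fixed from the closed-form unanimity
probability to land the 4-category OPA near 0.12 (the calibration band is
[0.08, 0.22]) and every rater's 3+ fraction near 12% (the study-reported
per-rater range is 7.39%–19.57%), before any simulation was scored.

**What the generator does not emulate.** Real panels contain case-difficulty
heterogeneity: a large block of easy cases on which essentially all raters
agree deterministically, plus hard borderline cases. A homogeneous
latent-class model reproduces the overall OPA and the marginals but not
that mixture, with two visible consequences: (i) chance-corrected
statistics (kappa ≈ 0.63, ICC ≈ 0.82 on simulated panels) run higher than
a real panel with the same OPA, and the 3-category merge recovers less
agreement than it does on real data; (ii) ONEST curves keep decaying by
more than ε = 0.01 per added rater all the way to R = 15, so the plateau
estimate sits at the full panel rather than at ~7–12 observers. Passing
calibration tests therefore demonstrates correct machinery and calibrated
first-order behaviour, not that the simulator is a substitute for the
deposited data; the full-study reproduction tests run only when that
dataset is placed under `data/`.

## Numerical choices and sizes

- All randomness flows from a single seed, fanned out to named substreams
  (SHA-256 of `seed:name`, reduced below 2³¹) so each stochastic analysis
  is independently reproducible.
- Ties in the plateau definition resolve to the smallest qualifying k; if
  no earlier k qualifies the full panel size is returned.
- Off-diagonal confusion mass is capped at 0.98 per row under noise
  scaling, keeping every row a valid distribution with positive diagonal.
- Default problem sizes in tests and the acceptance script — 460 x 15
  panels, 500-permutation ONEST runs, 20–30 replicate recovery suites,
  exhaustive ONEST enumeration at R = 5 — were chosen so the whole suite
  exercises study-scale data while completing in seconds.

## Known limitations

- Balanced complete panels only; no missing-data support.
- No weighted kappa, pairwise Cohen's kappa, or Krippendorff's alpha; no
  significance tests between groupings.
- The ICC's equal-spacing assumption for ordinal codes (above).
- Simulated observers are conditionally independent given truth; real
  pathologists share training and guidelines, which induces correlated
  errors the model cannot represent.
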