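# Methods

## Scope and model

`lymphoref` implements the guideline workflow for establishing and
verifying age-partitioned clinical reference intervals (RIs), specialized
to a 16-analyte pediatric lymphocyte-subset panel: 7 subset percentages of
total lymphocytes (T, CD4 T, CD8 T, DNT, B, NK, NKT-like), the CD4/CD8
ratio, and 8 absolute counts in cells/µl (the same subsets plus total
lymphocytes). The RI of an analyte in a reference group is the central 95%
of its distribution, reported as median (2.5th–97.5th percentile) on the
original measurement scale.

Ages are handled in **completed months**: days → ⌊days/30.44⌋, months →
⌊months⌋, years → ⌊12·years⌋. The default scheme has five contiguous bins
covering 0–227 completed months: 0–1 (neonatal), 2–12 (infancy), 13–47
(early childhood), 48–83 (preschool), 84–227 (school age). The printed bin
labels ("2–12 months", "1–3 years") are ambiguous at the boundaries; the
completed-month reading above is contiguous and exhaustive and is fixed
throughout.

## Stages and numerical choices

**Normality screen.** Bias-adjusted sample skewness G₁ and excess kurtosis
G₂ with exact small-sample standard errors
SE_skew = √(6n(n−1)/((n−2)(n+1)(n+3))) and
SE_kurt = 2·SE_skew·√((n²−1)/((n−3)(n+5))); the sample is normal iff both
|z| ratios are < 1.96. Kurtosis is *excess* (criterion centered at 0).
Minimum n = 8; zero-variance samples are refused.

**Box-Cox.** y = ((x+c)^λ − 1)/λ, natural log at λ = 0, computed as
expm1(λ·ln(x+c))/λ so the λ→0 limit is exact to machine precision. λ is
fitted by profile maximum likelihood on a grid over [−3, 3] in steps of
0.05 (ties broken toward 0, favouring the interpretable log) and refined by
golden section within the winning grid cell. The shift c is 0 unless the
minimum is ≤ 0, then |min| plus half the smallest positive value (counts of
rare subsets can be 0 in small children). The transform supplies only the
*analysis scale* for fences, ANOVA and the z-test; percentiles are always
taken on the raw scale, which is safe because the transform is strictly
monotone.

**Tukey elimination.** Fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR with
quartiles by the repo-wide rank rule (below); values *strictly* outside are
outliers (fence-exact values are kept). One elimination pass by default
(iteration available). Fences are computed on the analysis scale of each
analyte, **pooled across the whole cohort by default** — elimination
precedes subgrouping in the workflow — with a per-(age × sex)-cell mode
available (`outlier_grouping="per-cell"`). Removal is per-analyte by
default (a subject flagged for NK counts still contributes T-cell values);
whole-subject removal is selectable. Every removal is written to a ledger
(analyte, group, subject, raw value, fence, limit).

*Caveat measured on synthetic data:* for genuinely heavy-tailed analytes
(log-scale spread near 1, e.g. NK counts in neonates) the distribution's
own ~99th percentile lies beyond its Tukey fence, so even a clean sample
loses ~1% of genuine upper-tail mass and the post-filter 97.5th percentile
is biased low by ~10–13%. This is a property of the prescribed method on
such data, not of the implementation; per-cell fencing makes it
substantially worse (up to ~40% on the 2.5th percentile), which is why
pooled is the default.

**Partitioning.** Sex first, on the full filtered cohort, then adjacent age
bins per analyte. A pair splits iff the omnibus test rejects at α = 0.05
(one-way ANOVA on the analysis scale by default; Kruskal–Wallis on request
— being rank-based it is indifferent to the transform) *and* the
Harris–Boyd deviate z = |m₁−m₂|/√(s₁²/n₁+s₂²/n₂) exceeds
z\* = 3·√((n₁+n₂)/240). z\* is always computed from the group sizes
actually under test. Age merging is greedy and deterministic: each round
evaluates every adjacent pair of current groups and merges the mergeable
pair with the largest omnibus p, repeating until every adjacent pair says
split; non-adjacent bins never pool and order is preserved. No
multiple-testing correction is applied across analytes (mirroring field
practice; the run report exposes every p). If the sex test says split, the
pipeline still reports age-pooled intervals (the output table is age-only)
and flags the analyte in the run report — users needing sex-stratified
intervals should run the pipeline per sex.

**Interval estimation.** All percentiles use one rule: rank r = p(n+1),
linear interpolation between order statistics, clamped to [1, n] (numpy's
"weibull" method; an independent brute-force implementation backs it in the
tests). Nonparametric minimum n = 39 (the smallest n putting the 2.5th rank
at the first order statistic); n < 120 triggers a small-sample warning.
Display rounding: two decimals for percentages and ratios, integers for
counts. No confidence intervals on endpoints are reported.

**Verification.** Per analyte × age group, values strictly outside the
interval count against it (endpoint-exact values are inside, consistent
with the fence convention); pass iff the outside fraction is ≤ 5%
(pct_within ≥ 95), with a strict `< 5%` variant selectable. Protocol size
is 40 per group; other sizes run with a protocol-deviation note. Note that
with n = 40 a *perfectly calibrated* interval passes a single cell with
probability P[Binom(40, 0.05) ≤ 2] ≈ 0.68 — scattered red cells are
expected in any honest verification table, and an all-green table of 80
cells would itself be remarkable.

## The synthetic cohort generator

Each analyte × age-group cell is a **two-piece (split) lognormal**: with
probability ½, x = exp(μ − σ_low·|Z|), else x = exp(μ + σ_high·|Z|),
Z ~ N(0,1). Fitting μ = ln(median), σ_low = (ln median − ln p₂.₅)/1.95996,
σ_high = (ln p₉₇.₅ − ln median)/1.95996 reproduces the three published
quantiles of every cell *exactly* and guarantees 95% central coverage by
construction. This is the minimal family honouring strictly positive,
right-skewed data with asymmetric printed percentiles; it makes no claim
about unprinted moments or tail shape beyond the 2.5th/97.5th points.

Defaults are the published study conditions: group sizes (187, 154, 197,
155, 120), sex ratio 476:337 with no sex effect, ages uniform over the
completed months of each bin (no within-bin age distribution is published),
and analytes drawn independently per subject. Compositional coherence
(percentages summing toward the T-cell total; counts = percentage ×
lymphocytes) is *not* enforced — the reference table specifies marginals
only. Optional contamination multiplies a random fraction of values by a
fixed scale (default 10×) and logs every injection. Randomness uses one
root seed with per-(analyte, bin) substreams, so adding an analyte never
perturbs another's draws.

What passing tests on this generator do **not** show about real data:
between-analyte correlation structure, measurement error, within-bin age
trends, and any tail behaviour beyond the matched quantiles are all absent.
Age groups that the source table pooled carry identical triplets, so
synthetic data cannot probe splits the source itself merged. Contaminated
percentage values above 100 are caught by cohort validation (range
invariant) before the outlier stage sees them.

## Simulation sizes

The test suite and the reproduction script use: 200 replicates × 100,000
evaluation draws for interval coverage; 50 full pipeline runs on 813-child
cohorts for parameter recovery; 100 seeds for null merging behaviour; 1000
replicates for the omnibus type-I rate; 500 seeds for endpoint calibration.
These sizes put Monte-Carlo error well below every asserted tolerance.

## Known limitations

- The Tukey truncation bias on extremely dispersed cells (above): one
  endpoint of one generator cell (neonatal NK counts, 97.5th) recovers to
  ~10.5% rather than within 10% under the default conditions.
- Adjacent age groups whose true quantile differences are small relative to
  their spread (e.g. B-cell counts at 2–12 vs 13–47 months) merge under the
  Harris–Boyd rule at these sample sizes; the rule is deliberately
  conservative, and the synthetic marginals may understate real
  between-group separation.
- Discrete age bins only; no continuous centile modelling (GAMLSS-style).
- No parametric (Gaussian-on-transformed-scale) interval option; the
  nonparametric estimator is the only one exposed.
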