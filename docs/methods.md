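# Methods

This note records the statistical procedures the package implements,
the modelling choices behind the synthetic-data generators, and the
numerical conventions and known limitations a user should be aware of
before trusting the outputs.

## Delphi item screening

Each round is an m × n grid of integer Likert ratings (experts × items,
1–5). Per item we report the mean, the standard deviation, the
coefficient of variation CV = s/x̄ (stored as a fraction, displayed as
a percent), and the full-score frequency — the proportion of the m
experts awarding a 5 (stored in [0, 1] even though survey reports often
print it as a percentage, so it is directly comparable with its
threshold).

Screening thresholds are derived from the distribution of each
statistic **across the items of the current round only** (successive
rounds rate different item sets, so pooling would contaminate the
thresholds): mean − SD for full-score frequency and mean score, mean +
SD for CV. An item is excluded when *any* of the three rules fires.
Comparisons are strict (`<`, `>`): an item exactly on a threshold is
retained, the conservative reading of "below"/"above". All standard
deviations default to the sample (n−1) convention — panels are small,
and this is the convention in Delphi reporting — with a population
(`n`) toggle (`sd_mode="population"`) for cross-checking against
software that defaults the other way.

Panel concordance is Kendall's W with the standard tie correction:
ranks within each expert use average ranks for ties, S is the sum of
squared deviations of the item rank sums about their mean, Tᵢ = Σ(t³−t)
over tie groups of expert i, and

    W = 12 S / (m²(n³ − n) − m ΣᵢTᵢ).

Significance uses the chi-square approximation χ² = m(n−1)W on n−1
degrees of freedom, which is what consensus studies print; this
statistic is algebraically identical to Friedman's tie-corrected test,
and the test suite verifies that identity against an independent
implementation. When every expert ties every item the denominator
vanishes and the coefficient is undefined; the package raises a
degenerate-input error rather than returning 0 or 1.

Expert authority is Cr = (Ca + Cs)/2 with both components on [0, 1];
Ca may be supplied as the pre-summed judgment-basis score or as its
four components (theoretical analysis, practical experience, peer
understanding, intuition) summed by the loader. Cr ≥ 0.7 is flagged as
high authority.

## AHP weighting

Pairwise comparison matrices are positive and reciprocal with unit
diagonal; strict-scale validation additionally restricts single-expert
entries to the Saaty set {1..9} ∪ {1/2..1/9} (it is disabled for
aggregates, whose geometric means fall between scale points). Expert
panels are combined by element-wise geometric mean — the standard
aggregation-of-individual-judgments choice, and the only simple one
that preserves reciprocity exactly; the test suite checks that
preservation property on random panels.

Weights are the normalized principal right eigenvector, computed by
power iteration (tolerance 1e−10 on the weight vector, cap 10,000
iterations; Perron–Frobenius guarantees a unique positive dominant
eigenpair for a positive matrix, and the eigenvector is cross-checked
against a dense eigensolver in the tests). Row-geometric-mean weights
are offered as an alternative mode (`method="geomean"`); the two
coincide exactly on consistent matrices. Consistency uses
CI = (λmax − n)/(n − 1) and CR = CI/RI(n) with Saaty's classic
random-index table {3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, …}; the table
is configurable because published RI variants differ in the third
decimal. n ≤ 2 short-circuits to CR = 0 (a 2×2 reciprocal matrix is
always consistent, λmax = 2 identically). CR < 0.10 is acceptable, with
equality failing; CR is stored at full precision and displayed at three
decimals, half-up.

The packaged hierarchy fixture transcribes the published 5-domain /
18-characteristic / 84-item weight table. Its combination weights are
printed at two decimals of a percent and sum to 99.95%, so the loader
applies a 0.1% slack on the sum-to-one invariants for this fixture
(strictly 1e−6 otherwise); local weights are recovered from the printed
global weights (domain weight = sum of its children's combination
weights, characteristic local weight = its share within the domain), so
the product identity *combination = local × domain* holds exactly by
construction. The published per-node λmax/CR diagnostics are carried as
metadata; note that two of the printed CR values appear truncated
rather than rounded (0.045 where the eigenvalue arithmetic gives
0.0456, 0.022 vs 0.0228), a display-convention quirk of the source
table that the fixture preserves as printed. The characteristic
numbering also skips one ordinal (3.3) exactly as printed.

## Likert scoring

Levels map A/B → 0, C → 2, D → 3, E → 4 points (A: no activity; B:
discussed but not implemented; C: partial in part of the organization;
D: full in part; E: full throughout). Every aggregate is a mean percent
score, mean points ÷ 4 × 100. The headline overall is the **unweighted**
mean over all answered items — the instrument's own worked example
divides the average item score by the maximum with no weights — and the
AHP-weighted overall (combination-weight-weighted mean of
characteristic percents, renormalised over characteristics with at
least one answered item) is reported separately and clearly labeled.
Domain percents average over the domain's items by default; averaging
over its characteristic percents instead is a flag
(`domain_aggregation="characteristics"`), since the two differ whenever
characteristics have unequal item counts. Missing responses are never
imputed: they are excluded from every mean and surfaced as a
completeness fraction per facility. Points are integers; percents are
stored at full precision and displayed at one decimal.

## ADE validation

Facility incidence is 100 × count / prescriptions per indicator, and a
facility's overall incidence is the **sum** of its three indicator
incidences (so the cohort overall mean equals the sum of the three
indicator means — the construction used in the application study —
rather than a pooled-count rate; pooled counts would weight facilities
by volume, which is a different estimand). Cohort CIs are mean ±
1.96·SE across facilities by default, with a Student-t critical value
by flag. The facility, not the prescription, is the unit of analysis
throughout.

The validity check is the Spearman rank correlation between the overall
unweighted percent score and the overall incidence, paired by facility
(any score column can be substituted). Ties get average ranks; the
two-sided p-value uses t = ρ√((n−2)/(1−ρ²)) on n−2 df, matching
standard statistical-package behaviour at cohort sizes in the tens,
with exact full-enumeration p-values available for n ≤ 10 (used as the
oracle in the tests).

**Known limitation — CI coverage under heavy dispersion.** A Wald-type
interval with a fixed 1.96 critical value cannot exceed the coverage of
the corresponding t-interval (≈ 94.3% at n = 43 even for perfectly
normal data), and right-skew pushes it lower. Under this package's
default cohort generator — whose facility-level dispersion is
deliberately as heavy as real medication-error data (facility SD of the
same order as the mean) — simulated coverage of the overall-incidence
CI is ≈ 88% rather than the nominal 95%, and the t-variant recovers
only about half a point because the deficit is skewness, not the
critical value. Simulations confirm the implementation itself is exact:
with the skew turned down, coverage matches the theoretical
t-vs-1.96 ceiling to Monte-Carlo error. Users wanting calibrated
intervals on real cohorts of this size and dispersion should prefer a
bootstrap or a log-scale interval; the normal-approximation form is
kept as the default because it is what assessment studies of this kind
report.

## Synthetic-data generators

No raw panel or facility data are deposited for instruments of this
kind, so the generators provide every input with controllable ground
truth. A single integer seed drives all modules through derived
child streams (`SeedSequence([seed, stream])`), so panels, matrices and
cohorts can be regenerated independently and byte-identically.

**Panels.** Item j has a latent quality θⱼ on the 1–5 scale; expert i
rates clip(round(θⱼ + εᵢⱼ), 1, 5) with ε ~ N(0, σ),
σ = 2·(1 − consensus). Defaults: 15 experts, 91 items of which 7 are
planted weak items (θ ~ U(2.0, 2.6) against U(4.75, 5.0) for the rest),
consensus 0.8. These defaults were calibrated once so that the
screening rules recover exactly the planted outlier set in the median
replicate (and never miss an outlier); that choice favours clean
separation over matching any particular published round's aggregate
statistics, which sit in a noisier regime — with only 15 experts, the
binomial noise in full-score frequency makes "exactly k exclusions" and
"realistically low concordance" mutually exclusive at the same noise
level. Lower `consensus` (≈ 0.55) reproduces the weaker-agreement
regime (W ≈ 0.25–0.3) at the cost of a few borderline false exclusions
per round. Deterministic fixtures, not the generator, are used where a
test needs an exact published aggregate.

**Comparison matrices.** Above-diagonal entries are (wᵢ/wⱼ)·exp(ε),
ε ~ N(0, noise), reciprocally filled, optionally snapped to the nearest
Saaty value on the log scale. Zero noise reproduces the consistent
matrix and CR = 0 exactly; at noise 0.1 a 15-expert aggregate recovers
the generating weights within L1 0.05.

**Cohorts.** Facility quality q ~ Beta(36, 10) (mean 0.783, SD 0.059).
Responses follow an ordered-threshold model: item latent value
u = q + N(0, 0.07) cut at (0.49, 0.59, 0.67, 0.80) into A–E, so the
expected score is strictly increasing in q. Error probabilities are
log-linear and decreasing in q with a shared facility frailty,
pₖ = baseₖ · exp(−9.0·(q − E[q]) + η), η ~ N(0, 1), clipped at 0.2;
counts are Binomial(Nᵢ, pₖ) with monthly prescription volumes
Nᵢ ~ U(4,000, 42,000) (a monthly-volume scale consistent with annual
patient volumes in the tens to hundreds of thousands). Baselines
(0.073%, 1.22%, 0.30%) and the slope/frailty pair were calibrated once
against the published application regime: across 50 seeds the default
43-facility cohort gives an overall score of 81.9 ± 12.0%, indicator
incidence means (0.145, 2.28, 0.60)% and a score–error Spearman ρ
averaging −0.44 (negative in 100% of replicates). The frailty SD of 1
is not a free styling choice: it is what the printed CI widths of the
application study imply (facility SD ≈ mean per indicator).
`expected_score_pct` and `expected_incidence` expose the generator's
population-level expectations in closed form (up to quadrature over the
Beta and Gaussian laws), which is what the coverage simulations use as
ground truth.

What the generators deliberately do **not** model: item-level content
(all items within a characteristic are exchangeable), expert-specific
severity or style effects, temporal error dynamics, volume–quality
correlation, and reporting/ascertainment bias in error counts. Passing
tests therefore demonstrate that the *pipeline arithmetic and its
statistical behaviour* are correct under a plausible data-generating
process — not that any particular real cohort satisfies that process.

## Numerical conventions and degenerate inputs

- Ratings must be integers in [1, 5]; m ≥ 2 and n ≥ 2 for any consensus
  statistic; thresholds need ≥ 2 items (SD undefined otherwise).
- Kendall's W is clipped into [0, 1] against floating-point drift; an
  all-ties panel raises rather than returning a value.
- Power iteration failure past the cap raises a numerical-failure
  error; λmax is floored at n (values microscopically below n are
  rounding artefacts of a consistent matrix).
- Matrix orders above 10 have no tabulated random index and are
  rejected for CR purposes.
- A facility with no answered items, a constant score or incidence
  vector, and a zero prescription volume all raise typed errors
  (`UndefinedScoreError`, `DegenerateInputError`, `InvalidInputError`)
  rather than propagating NaNs.
- CSV loaders reject duplicate keys and incomplete grids loudly;
  response levels are case-insensitive on input and canonical uppercase
  on output.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on synthetic or
constructed inputs: Delphi rounds up to 15 × 91, AHP nodes up to order
7 (order 5–6 for the published-table checks), cohorts of 43 facilities
(400–2,000 for the monotone-link and expectation checks), 500
replicates for the correlation-sign power check, 1,000 replicates for
the CI-coverage simulation, and full 8!-permutation enumeration for the
exact Spearman oracle.
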