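# Methods

## Problem setting

The package models work-related stress (WRS) and anxiety in healthcare staff
as a function of four impact factors: psychological (PCG), financial (FIN),
socio-demographic (SCF) and technological (TECH).  Each factor is a score on
[0, 1] derived from a Likert survey; the outcome is also a [0, 1] score
carrying a five-term linguistic reading (*very low* … *extremely high*).
Because these constructs are graded and overlapping, the analysis uses fuzzy
sets end to end: factor scores are fuzzified over linguistic term sets,
associations between factor terms and stress terms are mined as fuzzy rules,
and a Mamdani inference engine turns a rule base back into per-respondent
scores.

## Factor scoring

Likert answers (0 = "Not at All" … 4 = "Extremely") normalise to a/4.  A
factor score is the loading-weighted mean over its retained items,
`Σ wᵢ(aᵢ/4) / Σ wᵢ`, using each item's standardised loading on its own
factor as the weight.  Seven items with extremely low loadings (the
workload/management/support/relationship WRS items, two psychological items
and one financial item) are excluded by default; they stay in the survey
schema so files containing them still validate.  A factor is scored when at
least half of its retained items are answered, otherwise it is reported
unscorable — a conservative rule chosen because the instrument's own
missing-data handling is unknown.

SCF is not a Likert block.  It is scored as the equally-weighted share of
six risk-aligned demographic indicators (age 18–29, single, opposes
lockdown, internet/social-media news source, fewer than five cohabitants,
under two pre-lockdown outdoor hours per day).  The directions follow the
cluster profile of high-stress respondents (younger, single, lockdown-
resistant, media-reliant, few cohabitants, little outdoor time); the equal
weights are the package's choice and are configurable.

TECH items are placeholders (TECH-1..3) weighted 0.697/0.745/0.721 — the two
published technology/teamwork loadings plus their mean — because the
technological block's item list was never published.

## Fuzzy partitions

Every variable carries an ordered term set of triangular membership
functions.  The default layout is the uniform partition: k terms have peaks
at i/(k−1), each foot at the adjacent peak, and the first/last terms are
shoulders clamped at 0 and 1.  This layout is a partition of unity
(memberships sum to 1 everywhere), which keeps fuzzy supports on the same
scale as classical supports and makes at most two terms active at any point.
A degenerate triangle (left = peak = right) acts as a crisp singleton so
binary data can flow through the same machinery, which the crisp-reduction
tests rely on.  Explicit (left, peak, right) triples can be supplied per
term through the YAML variable config.

## Fuzzy association rule mining

A respondent's fuzzy transaction holds their membership in every
(variable, term) item.  Itemset support is the mean over transactions of the
minimum membership across the itemset; rule confidence is the support ratio
of (antecedent ∪ consequent) to antecedent.  The t-norm is minimum,
matching the `and` connective used for rule firing (a product t-norm is a
one-line change but is not exposed as a default).  Because min never
exceeds its arguments, support is anti-monotone in the itemset and the
classical levelwise Apriori search applies unchanged; itemsets are
restricted to at most one term per variable (terms of one variable are
mutually exclusive readings of the same score) and rules conclude on a
single WRS term with at most four antecedent items.

Rules are annotated with lift (confidence over consequent support) and a
chi-square p-value from the 2×2 antecedent-present × consequent-present
table built at the 0.5 α-cut, with Yates continuity correction; the default
significance level is 0.05.  The α-cut level and alpha are package choices —
the discretisation behind the study's own chi-square test is unspecified.
A rule with a zero margin is untestable and is dropped with p recorded as 1.
Redundancy pruning removes any rule dominated by a retained rule with the
same consequent, a strict-subset antecedent and at least equal confidence.

Mining thresholds are data-dependent.  Under uniform partitions a four-item
antecedent's fuzzy support is the mean of a minimum of four membership
values and is routinely below 0.01 even for real associations, so recovery
runs use a low support floor (10⁻⁴) and filter by confidence and lift
instead; the CLI default floor is 0.05, appropriate for one- and two-item
antecedents.

## Rule-count selection and rule seeding

K-means (Lloyd, 10 restarts, tolerance 1e−6, seeded) clusters the
five-dimensional factor profiles.  The cluster count is selected by mean
Euclidean silhouette over a k range, with near-ties (within 0.01) resolved
to the smaller k so that structureless data floors at the minimum k rather
than chasing silhouette noise.  Each center becomes a candidate rule: per
variable, the term with maximal membership at the center coordinate (ties
resolve to the more moderate term after rounding memberships to 9 decimals,
so the 0.5/0.5 crossing point is handled deterministically); duplicates
merge.

## Mamdani inference

Canonical Mamdani composition: activation is the min of antecedent
memberships, implication clips the consequent membership function at the
activation, aggregation is the pointwise max over rules on a 1001-point grid
of [0, 1], and defuzzification is the centroid of the aggregate.  Scores map
to levels through fixed bands: very low [0, 0.25), low [0.25, 0.45),
moderate [0.45, 0.65], high (0.65, 0.90], extremely high (0.90, 1] — the
upper edges of the moderate and high bands are closed.  Refining the grid
from 1001 to 10001 points moves scores by less than 10⁻³ (tested).  When no
rule fires the engine raises by default; callers may configure a fallback
score (the pipeline uses mid-scale 0.5).

## Reference rule base and breakpoint calibration

The packaged nine-rule reference base carries the published per-rule support
and confidence values.  Only four antecedents were published; the other five
are synthetic reconstructions (marked as such in the fixture) chosen to
cover the term space consistently with the published factor polarities —
low FIN means *deteriorating*, low TECH means *negative impact*, and high
stress is concluded only from high-PCG/high-SCF patterns.  One published
consequent reads "moderate high (0.767)", which is not a term of the
outcome's term set; 0.767 lies in the *high* band, so the fixture encodes
*high*.

The study's membership-function breakpoints were published only as a figure,
so exact per-respondent scores are not reproducible; the contract is
agreement of the linguistic level on the published 11-respondent reference
table.  `calibrate_breakpoints` searches interior term-peak placements
(first/last peaks stay clamped, feet follow the adjacent peaks, so every
candidate remains a partition of unity): deterministic coordinate descent
with single-peak moves to a local optimum, then pairwise joint moves, which
escape interactions a single move cannot (an input peak and an output peak
that must shift together).  Candidate positions come from a 0.05-spaced
grid with a minimum 0.05 gap.  The search reaches 9/11 concordance; the two
stable misses are one respondent whose printed *high* level contradicts the
factor polarities his own inputs imply (all inputs mid-to-low), and one
adjacent-band miss (*high* vs *extremely high*) at the top of the scale,
where centroid defuzzification compresses scores below 0.92.

## Synthetic cohort generator

The original survey data are private, so the pipeline is exercised on
synthetic cohorts engineered to match the published summary structure.

**Copula.**  Factor scores and the two numeric covariates (cohabitants,
pre-lockdown outdoor hours) are drawn from a Gaussian copula.  Marginals are
Beta distributions solved from a (mean, skewness) pair by a 1-D root-find on
the concentration (with the mean fixed, |skewness| is monotone in a+b); an
infeasible pair raises a config error naming the factor.  The published
skewness values (WRS 0.0167, FIN −0.2898, PCG 0.9295) are targets; the means
are the package's calibration choices (PCG 0.25, FIN 0.60, WRS 0.494,
SCF 0.35, TECH 0.60), set once from the published response narrative (68%
report no psychiatric complaints, hence a low PCG mass; technology is viewed
mostly positively) and from feasibility (a 0.93 skewness forces the PCG mean
below ≈0.28; the FIN/WRS means must sit on the correct side of 0.5 for
their skewness signs).

**Correlation matching.**  Skewed marginal transforms attenuate Pearson
correlation, so each latent correlation is solved per pair so that the
*post-transform* correlation hits its target: the quantile transform is
expanded in probabilists' Hermite polynomials (15 terms, 96-node
Gauss–Hermite quadrature), giving the transformed correlation as a
polynomial in the latent ρ, solved by bisection.  Pairwise-printed tables
need not be jointly feasible, so both the target and the solved latent
matrix are repaired to the nearest positive semi-definite correlation
matrix by eigenvalue clipping with diagonal renormalisation.  The SCF and
TECH rows were never published; the defaults (SCF–WRS 0.30, SCF–PCG 0.25,
TECH–WRS 0.10, others 0) are modest values consistent with the narrative
that socio-demographic risk raises stress and technology is near neutral.

**Item answers.**  Each item thresholds its factor score plus independent
Gaussian noise (default sd 0.3) through the population CDF of that latent
(computed by 96-node Gauss–Legendre quadrature of the Beta density against
the normal CDF), then cuts at the cumulative target probabilities.  Since
the population CDF of the latent is uniform on [0, 1], the expected category
shares equal the targets exactly; at n = 10,000 the sampling error of a 68%
share is about 0.5 points.  Items with published response shares use those
shares as pinned entries of their 5-vector (the rest of each vector is a
unimodal completion); unpublished items get a neutral unimodal profile.

**Demographics.**  Occupation strata are exact (41 nurses, 21 medical
doctors, 19 health technicians, 16 medical secretaries, 44 dentists, 12
physiotherapists, 18 pharmacists, 11 engineers, 22 other = 204); other
cohort sizes rescale by largest remainder, keeping counts exact rather than
expected.  The four SCF-aligned binary indicators are Bernoulli draws with
probability equal to the respondent's SCF score, so the demographic-derived
SCF recomputed by the scorer tracks the generated factor; cohabitants and
outdoor time come from the copula (kept continuous internally because
rounding would perturb the calibrated correlations; the survey column is
rounded for display).

**Rule-base mechanism.**  For end-to-end recovery tests the WRS column is
replaced by the Mamdani prediction of a rule base plus truncated
N(0, 0.05²) noise; profiles where no rule fires are resampled in bounded
rounds.  Mining such a cohort recovers the planted extreme-stress
association (confidence ≈ 0.96, lift ≈ 130 at n = 5,000) — its fuzzy support
is small (≈ 7·10⁻⁴) because the four-way archetype is rare under the
realistic marginals, which is why recovery mining uses the low support
floor.

**What the generator does not emulate.**  Respondent-level answer styles
(straight-lining, central tendency), item non-response, measurement error
correlated across items beyond the single factor+noise channel, and any
joint structure of the demographics beyond the SCF channel.  Passing tests
therefore demonstrate that the pipeline recovers structure it was pointed
at, not that the instrument itself is valid.

## Problem sizes and determinism

Default analysis cohorts use n = 204 (the study size); calibration-recovery
checks use n = 10,000 and recovery mining n = 5,000, sizes at which the
±0.05/±2-point/±0.1 tolerances hold with wide margin across seeds.  All
randomness flows from a single integer seed per run (child streams are
spawned for item answers and noise), and identical seeds give byte-identical
output files.

## Known limitations

* The nine-rule reference base covers the term space sparsely; profiles in
  uncovered corners raise a no-rule-fired error unless a fallback score is
  configured.
* Centroid defuzzification cannot reach scores below ≈0.08 or above ≈0.92,
  so the extreme bands are reachable only on narrow input sets; mean-of-
  maximum defuzzification is not implemented.
* The chi-square filter discretises memberships at a fixed 0.5 α-cut; very
  diffuse rules can be significant in the fuzzy sense yet untestable after
  discretisation.
* Correlation targets involving SCF/TECH are assumptions, not published
  values, and the cohabitants/outdoor covariates are continuous proxies for
  counts/hours.
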