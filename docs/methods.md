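# Methods

`longmicro` reimplements, as a tested library, the downstream statistical
analyses used for dense longitudinal infant-gut metagenome cohorts: profiles
arrive as species-level relative abundances (MetaPhlAn2 merged-table
dialect, percent scale) and species-stratified gene-family / EC / pathway
abundances in copies per million (HUMAnN2 dialect), joined to per-sample
metadata in which all timing is integer age in days. Because the cohorts
these methods were designed for are controlled access, the package ships a
synthetic-cohort generator that reproduces the statistical structure the
analyses rely on, together with a truth table of every planted parameter so
each analysis can be validated by parameter recovery.

## Community stability and variance partitioning

**Bray-Curtis dissimilarity** between two abundance vectors is
`1 - 2 * sum(min(x_i, y_i)) / (sum x + sum y)`; all-pair matrices are built
with scipy's pairwise machinery and validated for symmetry, range and zero
diagonal.

**Stability windows.** Pairs of samples whose collection ages both fall in a
90-day window (advanced in 60-day steps, grid anchored at age 0 regardless
of when sampling starts) are stratified into within-subject, within-centre
and between-centre pairs — each pair belongs to exactly one stratum — and
summarised by the median dissimilarity with a seeded percentile-bootstrap
99% confidence interval (1,000 resamples; the interval type is a package
choice, as only the confidence level is standard for this analysis). A pair
whose two ages fall in two overlapping windows is counted in both windows;
strata with fewer than 5 pairs report a median without an interval.

**PERMANOVA.** The single-term partition of squared dissimilarities:
`SS_total = sum_{i<j} d_ij^2 / n`, `SS_within` the same quantity pooled
within groups, `R^2 = (SS_total - SS_within) / SS_total`, pseudo-F on
(k-1, n-k) degrees of freedom, and `p = (1 + #{F_perm >= F_obs}) / (1 +
n_perm)` under seeded label permutations (optionally restricted within
strata). Marginal terms are run one at a time; sequential multi-term
decompositions are out of scope. The implementation is checked against
vegan's `adonis2` and scikit-bio's `permanova` in the test suite.

**Dominance.** A sample is assigned to a dominance state when one of the
four target taxa (*B. longum*, *B. breve*, *B. bifidum*, or the phylum
Proteobacteria, summed over its member species) exceeds relative abundance
0.5 — strictly greater, so exactly 0.5 is "mixed".

## Antibiotic perturbation

Consecutive same-subject sample pairs less than 50 days apart (strict
inequality) within the first three years are labelled by whether an
antibiotic course *starts* strictly between the two collection ages; a
course already running at the first collection does not count. Pair
dissimilarities are smoothed against age at first collection with LOESS per
stratum, with pointwise 95% bands from permuting stratum labels (999
permutations by default), plus Mann-Whitney comparisons in the early and
late halves of the age axis.

Per-species depletion uses pairs with an intervening course and the species
present (> 0) in the first sample. The statistic is
`log2((a_after + delta) / (a_before + delta))` with `delta` half the
species' smallest nonzero abundance in the data set (its detection floor);
the pseudo-abundance keeps zero-after pairs finite and is reported
alongside the estimate. The
reported mean and s.d. are taken over 1,000 bootstrap resamples of the
eligible pairs. Relative (not count) abundances are used throughout, since
the input profiles are compositional.

## Alpha-diversity trajectory

Shannon diversity (natural log, renormalised nonzero fractions) accrues
along a four-parameter logistic
`D(t) = d_min + (d_max - d_min) / (1 + exp(-k (t - t_mid)))` fitted by
bounded least squares from a 3x3 grid of starts (t_mid at the 0.25/0.5/0.75
age quantiles; slow, moderate and steep rates), keeping the best residual
sum of squares; if no start converges, a straight-line fallback supplies
residuals. The source analysis names only "a sigmoid"; the 4PL form and the
multi-start initialisation are package choices. Residuals then enter a
linear mixed model with a subject random intercept (REML, via statsmodels)
and the requested covariates as fixed effects, reporting Wald p-values.
Covariates with a single observed level are dropped with a warning; samples
with unknown breastfeeding are excluded whenever that covariate is
requested.

## Enzyme consistency

For two target ages (default 90 and 365 days, tolerance +-45 days — half
the sampling interval plus jitter — ties to the earlier sample), each
subject contributes one community-total CPM per EC feature. "Most
consistent change" is operationalised as the sign-consistency score
`(n_up - n_down) / n_subjects` with strict inequalities (exact zeros count
in neither direction); this is the module's core interpretive decision, as
the source analysis names no formula. Rankings break ties by |median
difference| then feature id. Contribution matrices average species-
stratified CPM over a timepoint's samples, keep the top 15 contributing
species, pool the remainder (including unclassified mass) as "other" so
rows stay additive, and order rows/columns by average-linkage clustering of
rank-correlation (Spearman) distance at the first timepoint, with that
order reusable at later timepoints.

## HMO gene carriage

Homology hits (tabular alignment format plus query/subject lengths) are
kept at >= 50% identity and >= 80% *mutual* coverage — alignment length
over each sequence's full length, both sides required, capped at 1 —
deduplicated per (gene family, carrier species) by best identity. A gene is
present in a sample when its species-stratified abundance satisfies
log10(CPM) > 0.1 (strict), and eligible for testing when present in at
least 50 breastfeeding samples (the floor is a parameter so small fixtures
can exercise the logic). Prevalence during breastfeeding versus after
weaning — restricted to samples where the carrier species exceeds 1%
relative abundance and the feeding state is known; "after weaning" means
collection age at or past the recorded weaning age — is compared with the
two-sample proportion test (Yates continuity correction on by default,
mirroring the classical R routine; toggleable), BH-adjusted across genes,
significant at adjusted p < 0.001. Display matrices divide gene CPM by the
carrier species' relative-abundance fraction in samples where the species
exceeds 10%, and order rows and columns by complete-linkage clustering
(Euclidean distance on log10(1+x); the transform and metric are package
choices, only the linkage is standard for this display).

## Case-control association

Taxa are arcsin-square-root transformed on the fraction scale; pathways are
log2(CPM + 2^6) transformed. Each feature is fitted with a subject
random-intercept linear model whose fixed effects are age, delivery mode,
clinical centre (cohort-wide runs only; per-centre runs drop the term),
breastfeeding status, solid-food status, log10 sequencing reads — the
source is ambiguous on the reads scale; log is the package's choice — and
case-control outcome. Features nonzero in fewer than 10% of samples are
skipped (the conventional prevalence default, configurable), as are
zero-variance features. Outcome p-values are BH-adjusted within a run and
features with q < 0.25 are flagged reportable. The upstream covariate
*selection* step of boosted multivariate frameworks is deliberately not
reproduced: all listed fixed effects always enter, which is deterministic
and conservative. Pairs whose control member is missing or later converted,
and subjects with unknown breastfeeding status together with their matched
pairs, are excluded before modelling.

BH adjustment is the step-up `q_(i) = min_{j>=i} min(1, p_(j) m / j)`; the
Yates statistic is `n (|ad-bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d))` with the
correction capped at zero. Both are authored here (they gate the carriage
pipeline) and verified against statsmodels/scipy in the tests.

## The synthetic cohort

Defaults define the study conditions: monthly sampling from day 90 with
+-7-day jitter to three years, six clinical centres, subjects paired
case-control within centre (IA or T1D end points), caesarean probability
0.25, and a lognormal breastfeeding duration (ln-mean 5.2, ln-sd 1.2)
chosen so that ~73% of subjects are still breastfed at 3 months and ~28% at
1 year, matching the cohort percentages these analyses were built around.
Antibiotic courses arrive as a Poisson process at 1 course/year, making
~8% of consecutive pairs antibiotic pairs, close to the observed share.

Each subject draws one of four dominance states (probabilities 0.35 /
0.25 / 0.20 / 0.20 over *B. longum*, *B. breve*, *B. bifidum*,
Proteobacteria). A sample's composition is a mixture of the dominant taxon
at fraction `p` (phylum states split over three member species) and a
Dirichlet tail around a subject-specific base over the remaining panel of
30 named species, tilted by centre-level factors. The tail concentration
ramps with age (early communities are sparse and turbulent, mature ones
richer and stabler), which also gives the upper diversity asymptote
entropic headroom. `p` is solved per sample by vectorised bisection so
realised Shannon diversity equals the planted sigmoid (d_min 0.8, d_max
2.6 nats, k 0.012/day, t_mid 400 days) plus a subject intercept (sd 0.15)
and noise (sd 0.2), using the mixture identity
`H = H_binary(p) + p H_dom + (1-p) H_tail`; before day 365 `p` is floored
just above 0.5 so the dominance definition holds. Abundances below a 0.01%
detection floor report as zero, like real marker-based profiles. An
antibiotic course multiplies the susceptible species' *relative* abundance
in the next sample by `2^(planted + N(0, 0.3))` (capped inside the
available headroom, remainder rescaled — so the planted fold change is
exact on the scale the estimator measures), knocks the dominant fraction
down by 0.65x, and redraws the tail at 0.3x concentration.

HMO carriage: 10 synthetic gene families stand in for the milk-utilisation
cluster, carried by *B. longum*. Five planted genes draw per-subject
carriage flags at probability 0.8 during breastfeeding and 0.2 after
weaning (a strain shift at weaning); the remaining five are core genes
carried by all strains in both states — the appropriate null for a
sample-level prevalence test, see limitations. Carrier samples' gene CPM
scales with the *B. longum* fraction well above the presence threshold;
non-carriers stay below it. EC features plant a declining milk-fermentation
enzyme (lactate dehydrogenase, decaying around each subject's weaning age
and weighted onto Bifidobacteria and lactic-acid bacteria) and a rising
fibre enzyme (transketolase, rising after solid-food introduction), with
ten flat null enzymes; stratified rows attribute 85% of each total to
species by suitability-weighted abundance, the remainder to unclassified,
so additivity is exact. Pathways are community-level lognormal features
with subject intercepts; one fermentation superpathway carries a planted
+1 log2 shift in controls.

### What the generator does and does not emulate

It reproduces compositionality, longitudinal autocorrelation, subject and
centre structure, dominance, perturbation, carriage and planted effects —
enough for every analysis here to be validated by parameter recovery. It
does not model ecological interactions, strain phylogenetics, read-level
noise, viral/fungal fractions, or realistic correlations between
covariates (e.g. antibiotics and feeding are independent here). Passing
recovery tests therefore demonstrates the *procedures* are implemented
correctly under the assumed structure, not that the procedures are robust
to violations of that structure in real data.

## Numerical choices and degenerate inputs

Writers use fixed 10-significant-digit formatting, which round-trips
bit-identically and keeps the percent-sum and additivity invariants intact
after a write/read cycle. All-zero abundance vectors yield NaN diversity
and dissimilarity with warnings rather than errors. A zero total sum of
squares makes PERMANOVA's R^2 undefined (returned as NaN). Permutation
p-values use the add-one convention, so they are never zero. Bootstrap,
permutation and simulation seeds are explicit arguments everywhere; the
pipeline derives per-stage seeds from one global seed via a stable hash so
stages are independently reproducible.

## Problem sizes

Recovery analyses run at deliberately modest scale — 40-200 subjects with
one- to three-year follow-up depending on the statistic, chosen so each
planted quantity is estimated with comfortable margin (>= 50 eligible
antibiotic pairs; ~300 eligible samples per feeding group; 200 subjects
for trajectory fits) — and the acceptance script regenerates them from
scratch at the same sizes.

## Known limitations

- The sample-level proportion test of the carriage analysis treats samples
  as independent; per-subject carriage heterogeneity that is *unrelated* to
  feeding status would inflate its type-I error through within-subject
  clustering (a design effect of roughly the square root of samples per
  subject per state). The default generator therefore makes non-contrasted
  genes core genes; set `hmo_null_carriage_prob` below 1 to reproduce the
  clustered behaviour. A subject-level or mixed-model prevalence test would
  be the robust alternative, but is not the procedure being reimplemented.
- BH at q < 0.25 controls the false-discovery *rate*, not the per-run
  family-wise error: with one strong true positive among otherwise null
  features, some null feature exceeds the reporting threshold in roughly a
  third of runs. This is inherent to the reporting rule, not an
  implementation artifact.
- The single-term PERMANOVA reports marginal R^2 one covariate at a time;
  covarying terms are not adjusted for one another.
- LOESS bands near the sparse antibiotic stratum's age boundaries are
  extrapolation and should not be read quantitatively.
- The sigmoid fit assumes a monotone trajectory; strongly non-monotone
  diversity (e.g. heavy repeated perturbation) degrades it to the linear
  fallback.
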