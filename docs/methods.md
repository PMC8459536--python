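# Methods

## Data model

The analysis unit is one *cross combination*: all replicate female–male
pairs of the same type (same maternal and paternal population, or the
same hybrid-dam backcross type) summed into a single count record. The
residual degrees of freedom of the barrier models (42 interpopulation +
7 control combinations minus model parameters) only arise at this
aggregation level, so per-replicate input rows are summed on read.
Every record must satisfy the accounting identity
`eggs = sons + daughters + unhatched + dead_juv`; `dead_juv` covers all
post-hatch pre-adult deaths of either sex, even though male mortality is
treated as negligible downstream. Records violating the identity are
rejected, never repaired.

Genetic distance enters a record as: 0 for intra-population controls;
the K2P distance between the two parental populations for
interpopulation crosses; and, for backcrosses, the distance between the
*hybrid dam's* two parental populations — the dam's degree of hybridity
is what drives her sterility, not the relatedness to the backcross sire.

## Barrier indices

Four count-pair (k, n) responses per combination, as listed in the
README. Design points worth noting:

* **Undefined inviability.** An all-male brood (eggs = sons) makes the
  inviability denominator zero. Such records are excluded from the
  inviability model with a logged warning. Exclusion is the only option
  that never fabricates a denominator; imputation has no principled
  basis here.
* **Sterility is uncorrected.** The backcross dead-offspring fraction
  includes background mortality (a few percent in controls), so it
  slightly overestimates sterility. The standard analysis keeps the
  overestimate; `correct_background()` offers an explicitly
  non-standard corrected variant for sensitivity checks only.
* **Control set for the sterility model.** Intra-population crosses are
  included as distance-zero controls alongside the 16 backcross types by
  default (`include_controls_in_sterility=False` disables this).

## K2P distances

Transitions are A↔G and C↔T; everything else among {A,C,G,T} mismatches
is a transversion. Sites with a gap or any non-ACGT symbol in either
sequence of a pair are excluded for that pair only (pairwise deletion,
the default convention of standard distance software); IUPAC ambiguity
codes are treated as missing rather than fractionally matched — the
simplest defensible convention. If `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` the
correction is undefined and a saturation error names the pair. No
among-site rate (gamma) correction is applied: that belongs to ML tree
inference, which is out of scope here. Outputs print 3 decimals; full
precision is kept internally. When P and Q stand in the 1:2 ratio of
equal per-pathway rates, the K2P formula reduces exactly to the JC69
distance, which the tests exploit as a consistency check.

## Quasibinomial GLM

Responses are modelled as k successes of n trials (not unweighted
proportions): the data are counts, and the weighting is what produces
the published df structure. Fitting is plain binomial IRLS on the logit
scale:

* start from empirical logits with Haldane correction (k+½)/(n+1);
* convergence when the relative deviance change is < 1e-10, cap 50
  iterations (typically 4–6 suffice);
* dispersion φ = Pearson X²/df_residual — the Pearson estimator, which
  is what the conventional quasibinomial F statistics imply;
  coefficient covariance φ(XᵀWX)⁻¹, t = β/se with p from a t
  distribution on df_residual.

Degenerate inputs: a rank-deficient design raises an error naming the
aliased column (found by pivoted QR) — e.g. `gd` when all distances are
zero; a saturated model (0 residual df) is allowed with φ fixed at 1
and a warning, so exact two-point examples remain expressible;
|linear predictor| > 30 flags likely separation without aborting.

**Sequential tests.** Term significance uses type-I analysis of
deviance: models grow in the stated order (gd, female population,
interaction), and each addition is tested with
F = (Δdeviance/Δdf)/φ_full against F(Δdf, df_resid of the fullest model
in the sequence). Sequential rather than marginal testing is forced by
the df structure of the published analysis (1,47 then 6,41 on 49
observations is a sequential pattern). With φ forced to 1 the
coefficient estimates are unchanged — dispersion affects only inference
— and aggregated vs disaggregated encodings of the same counts give
identical β (dispersion may differ; both properties are asserted in
tests).

**Simplification rule** (α = 0.05): interaction significant → re-fit
gd-only within each female population (subsets with < 3 observations are
skipped with a warning); not significant → drop it and re-test the main
effects. Single-population input degrades to a gd-only fit.

## Threshold inversion

`gd* = (logit(p) − β₀)/β₁`, computed analytically rather than by root
finding — the logit model makes the inverse exact and trivially
testable (predict(gd*) = p to 1e-12). Requires β₁ > 0; otherwise the
barrier does not complete at any finite distance and an error says so.
Levels default to 0.99 and 0.999. No confidence intervals are attached
by default (the standard report carries point estimates only); a
delta-method CI is available behind an explicit flag. Thresholds beyond
the observed distance range are flagged `extrapolated` but still
reported — the prezygotic thresholds (≈0.47–0.66) lie far above the
data's maximum distance of 0.075, and that extrapolation is itself part
of the result.

## Synthetic-data generator

The generator emulates the study conditions, not an abstract ideal:

| parameter | default | meaning |
|---|---|---|
| distance matrix | packaged 7-population COI matrix | study populations |
| prezygotic (a, b) | (−1.453, 12.728) | logit-linear fertilization-failure curve |
| inviability (a, b) | (−1.337, 39.450) | diploid death curve |
| sterility (a, b) | (−1.308, 54.552) | backcross offspring death curve |
| rho | 0.1 | within-brood beta-binomial correlation |
| fecundity_mean | 40 eggs/female | 5-day oviposition window, ≈8 eggs/day |
| n_pairs | uniform 12–30 (backcross 10–32) | replicate pairs per combination |
| hatch_fraction | 0.7 | share of dying diploids that hatch first |
| hybrid_male_viability | 0 | sons of hybrid dams with distinct parents |

Mechanism per replicate female: eggs ~ Poisson(fecundity); the
unfertilized fraction is beta-binomial around m(gd) = expit(a + b·gd)
and develops into sons; fertilized eggs die with beta-binomial
probability v(gd), split into unhatched vs dead-juvenile by the hatch
fraction (an arbitrary convention — only the sum enters any index);
survivors are daughters. Backcrosses apply the sterility curve as
per-egg death, control-level fertilization failure, and a hybrid-male
viability factor (0 unless the dam's parents are genetically
identical, reflecting the near-absence of viable hybrid males).
The accounting identity holds by construction, and identical seed +
config gives byte-identical datasets.

Defaults were fixed once from the study's stated ranges and the
published model coefficients. rho = 0.1 gives a combination-level
dispersion φ ≈ 5 at brood size ≈ 40 — clearly overdispersed, which the
study's choice of a quasibinomial family indicates, though no φ value is
published to calibrate against. The generator draws one record per
combination with one haplotype per population; it does **not** emulate
within-population sequence variation, asymmetric (direction-specific)
incompatibilities, endosymbiont effects, or day-by-day oviposition
dynamics. Passing tests therefore demonstrate correctness of the
estimators under the stated logistic/beta-binomial mechanism, not that
real rearing data satisfy that mechanism.

## Problem sizes in the test suite

Calibration tests use the full 49-combination study layout: 400
replicates for the type-I error of the sequential gd test, 120 for
coefficient recovery, and 500 for recovery of the 99%-completeness
threshold of the inviability barrier (mean over replicates compared to
the generating value within Monte-Carlo error of the mean). The K2P
estimator is checked on 100 pairs of 100 kb sequences at the study's
maximum divergence (0.075). These sizes keep the full suite under half
a minute while leaving Monte-Carlo error well below the effect sizes
being checked.

## Known limitations

* The ratio form gd* = c/β₁ is a nonlinear function of the estimates,
  so the threshold estimator carries O(1/n) bias at small sample sizes;
  at the study layout and default noise the bias is below the
  Monte-Carlo error of the mean over 500 replicates.
* Distances are used as fixed covariates; no phylogenetic
  non-independence correction is applied (the reciprocal-cross
  asymmetries the design cares about would be erased by one).
* The sterility model treats each backcross type as one observation and
  fits a single curve; no dam-level random effects.
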