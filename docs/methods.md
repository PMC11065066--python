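# Methods

`worktraj` implements a two-stage analysis of lifetime employment
trajectories and a binary health outcome, of the kind used in life-course
epidemiology on retrospective life-calendar surveys.

## Sequence model

Each subject's working life is a categorical state sequence: one employment
state per year of age, drawn from an 8-category alphabet (1 employed
full-time, 2 employed part-time, 3 self-employed, 4 unemployed, 5
home/family, 6 retired, 7 full-time education, 8 other — the last bundling
illness or disability, voluntary work, military service and travelling).
Sequences are aligned to the half-open age span [16, 65), i.e. **49 states**
per subject. The inclusive reading of "age 16 to 65" would give 50 states;
we pin the span to the explicit 49-state count and expose `end_age=66` for
anyone who wants the inclusive variant.

Missing years are kept as an explicit marker during I/O and alignment, and
`filter_complete` then drops any subject with at least one missing year
inside the span (complete-case inclusion; no imputation). This mirrors the
exclusion flow of retrospective cohort analyses, where partial employment
histories are removed before clustering.

## Dissimilarity

Pairwise dissimilarity is the plain positionwise **Hamming distance**: the
number of ages at which two sequences hold different states. Because no
shifting or indels are allowed, the measure is sensitive to *timing* — being
unemployed at 25 and being unemployed at 55 are different exposures — which
is the rationale for preferring it over optimal-matching/edit distances for
employment trajectories. Distances are integers in [0, 49]; an optional
normalization divides by the length. Optimal matching and substitution-cost
matrices are deliberately out of scope.

## Clustering and typology size

Clustering is classical **PAM (partitioning around medoids)** run directly
on the distance matrix:

- BUILD: the first medoid minimizes total distance to all points; each
  subsequent medoid is the point whose addition maximally reduces total
  cost.
- SWAP: repeatedly apply the single best (medoid, non-medoid) exchange while
  it *strictly* reduces total cost. Equal-gain swaps are not taken, nearest-
  medoid ties go to the lowest medoid index, so the procedure is
  deterministic and needs no seed; the cost strictly decreases at each swap,
  guaranteeing termination.

Swap deltas for all (medoid, candidate) pairs are computed per iteration in
O(n²) via the nearest/second-nearest-medoid decomposition, so a full k-range
search on panels of a few thousand sequences runs in seconds. BUILD+SWAP is
a greedy local search: on small instances it is usually exactly optimal
(verified against exhaustive medoid enumeration in the tests, within 5% on
random instances with n ≤ 12).

The number of trajectory types is chosen by maximizing the **Average
Silhouette Width**: s(i) = (b−a)/max(a,b), with a the mean distance to the
subject's own cluster (excluding itself) and b the smallest mean distance to
another cluster; singletons score 0 by convention. The default search range
is k = 2…10, ties go to the smaller k, and the ASW is computed on the same
unnormalized distances used for clustering.

Chronograms (per-cluster state-by-age proportion matrices) and composition
summaries (n, percentage, modal state path, medoid) describe the resulting
typology. Cluster *naming* is a qualitative judgement and is left to the
user; the modal path is provided to assist it. Percentages are rounded
half-up to one decimal, matching printed-table conventions.

## Association model

The outcome stage fits a maximum-likelihood logistic regression of a binary
ever-diagnosed outcome on trajectory-type indicators (a user-chosen
reference type omitted; default the largest cluster) plus the baseline
adjustment set: age at baseline, birth cohort, BMI, smoking, ≥ 2 chronic
conditions, low physical activity, and attrition (no dropout / dropout /
deceased). Birth cohort uses the historical-crisis windows — war period
1914–1918 or 1939–1945, Great Depression 1929–1938, otherwise no crisis.
Low activity means neither the vigorous nor the moderate item was answered
"more than once a week" on the 4-point scale.

Odds ratios are exponentiated coefficients with **95% Wald confidence
intervals**, exp(β ± 1.96·SE); the CI method is a conventional choice made
here, as is entering both baseline age and birth cohort despite their
partial collinearity (a condition-number warning is emitted above 1e6).
Quasi-complete separation is detected by a diverging trajectory coefficient
(|β| > 15 on the log-odds scale) and flagged as non-converged rather than
silently penalized — transparency over automatic bias correction. Firth-type
corrections are a possible extension. A site filter restricts the outcome to
one reported cancer site; site analyses default to the female panel in the
intended use.

## Synthetic cohort generator

Because harmonized life-history survey data are access-restricted, the
package ships a generator that emulates their *structure*: gendered panels
of aligned sequences drawn from trajectory templates, baseline covariates,
and outcomes from a known logistic model.

- **Templates**: 8 women's shapes (mainly full-time; mainly home/family;
  full-time→home/family; mainly self-employment; full-time or home/family→
  part-time; home/family→full-time; mainly unemployment; other) and 2 men's
  shapes (mainly full-time; mainly self-employment), each opening with a
  short full-time-education segment. Transition ages are fixed design
  constants. The full-time→home/family transition is placed at age 33 so the
  shape has a substantial full-time first half; an earlier transition leaves
  that template nearly indistinguishable (11 of 49 positions) from the
  mainly-home/family shape, collapsing two types the typology is meant to
  separate.
- **Noise**: each age is independently corrupted with probability
  `noise_rate` (default 0.05), replacing the state with a uniformly random
  *different* state. This is the simplest corruption consistent with a
  clustered panel; it does not emulate serially correlated recall errors,
  country heterogeneity, or state-dependent misreport, so recovery results
  on synthetic panels demonstrate algorithmic correctness, not field
  performance on real life calendars. The default noise level is set for
  testability: real within-type heterogeneity is not quantified anywhere we
  could calibrate to.
- **Covariates**: birth years uniform on 1914–1945 (populating all three
  crisis cohorts; baseline age = 2006 − birth year), BMI ~ N(26.5, 4²)
  clipped to [15, 55], smoking ~ Bernoulli(0.13), chronic count ~
  Poisson(1.5) (≈ 44% with ≥ 2), low activity ~ Bernoulli(0.30), attrition ~
  multinomial(0.44, 0.30, 0.26). These echo the baseline composition of the
  kind of ageing cohort the pipeline targets.
- **Outcomes**: P(outcome) = logistic(intercept + log-OR[cluster] +
  covariate terms); default intercept −2.04 (≈ 11.5% reference prevalence),
  all log-ORs 0 unless configured. Exactly one cluster must have log-OR 0
  (the reference).
- **Seeding**: one global integer seed; stream j is
  `default_rng(SeedSequence(seed, spawn_key=(j,)))` with j = 0 sequences,
  1 covariates, 2 outcomes, so each layer is reproducible independently and
  runs are bit-identical.

## Numerical choices and problem sizes

- Swap improvements require a gain below −1e−12 (guards against float
  round-off cycling).
- Logistic fits use statsmodels' Newton MLE, 200 iterations max.
- The recovery experiments in the tests and the acceptance script use 100
  sequences per cluster at noise 0.05 (800 women-like, 200 men-like
  sequences) with a k = 2…10 search; parameter-recovery uses 200 replicate
  cohorts of n = 5,000 and CI-coverage 2,000 null replicates of n = 400 —
  sizes chosen so the whole battery completes in well under a minute while
  keeping Monte-Carlo error small relative to the tolerances checked
  (coverage SE ≈ 0.5%, OR-recovery SE ≈ 0.005).

## Known limitations

- Hamming distance requires equal-length complete sequences; panels with
  systematic late entry need a different design.
- BUILD+SWAP PAM is a local search without restarts; the determinism is a
  feature for reproducibility but global optimality is only guaranteed
  empirically on small instances.
- ASW can prefer merging genuinely close types when between-type separation
  approaches within-type noise; the k-profile is always reported so users
  can inspect the margin.
- The association stage is a cross-sectional logistic model of lifetime
  outcome status — not a time-to-event analysis — and inherits the usual
  caveats (reporting bias in self-reported diagnoses, exposure-outcome
  overlap in time).
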