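# Methods

`garep` implements the computational chain from bulk T-cell receptor
beta (TRB) repertoires to an HLA-restricted treatment-response
biomarker: discovery of treatment-associated public clonotypes,
one-wildcard motif generalization, multi-cohort replication, HLA
carrier imputation and assignment, clonal breadth/depth scoring,
exposure prediction, and treatment-by-HLA clinical interaction
modelling. Because the motivating datasets are patient-level and not
freely redistributable, the package ships a synthetic cohort generator
that reproduces the statistical structure those analyses assume; every
stage is exercised end to end on generated data.

## Repertoire model and statistics

A repertoire is a table of unique nucleotide-level V(D)J rearrangements
with absolute template counts. Clonotype identity for all association
analyses is the amino-acid triple (CDR3 junction, V gene, J gene) at
gene resolution; gene calls are canonicalized (`TRBV5-6*01` →
`TRBV05-06`) so that dialects agree. Non-productive rearrangements are
stored but excluded from every denominator: `R_unique` is the number of
unique productive nucleotide rearrangements and `T_total` the sum of
their templates, both always recomputed from rows. Deduplication is at
the nucleotide level — several nucleotide rearrangements encoding the
same clonotype each count toward breadth.

- **Productive clonality** = 1 − H/ln(R_unique), with H the Shannon
  entropy (natural log; the base cancels) of productive template
  frequencies. Defined as 1 for a single-rearrangement repertoire.
- **Expansion**: a nucleotide rearrangement absent at baseline and
  ranked in the treated sample's top k = 100 by templates. The paper
  trail for ranking ties is silent, so ranking is made deterministic:
  descending templates, ties broken lexicographically by nucleotide
  sequence, exactly k rows eligible. Non-productive rearrangements are
  eligible (the rule is nucleotide-level); this is configurable.
- **Breadth / depth** of a sample against a pattern (a set of
  clonotypes and/or one-wildcard motifs): fraction of unique productive
  rearrangements matching, and fraction of productive templates carried
  by the matches.

## Enhanced-Sequence discovery

Per cohort, each public clonotype's presence (≥1 productive
rearrangement) is tabulated for exposed cases vs controls and tested by
one-sided Fisher's exact test (hypergeometric tail, enrichment in
cases). Clonotypes below p < 10⁻³ are Enhanced Sequences (ES). For each
ES and each interior junction position (the conserved C/F flanks are
never freed) a one-wildcard motif is formed; its members are every
observed same-length clonotype with the same V/J matching the pattern,
its presence is presence of any member, and it is retained in a cohort
when its FET p is below 10⁻⁴ *and* strictly below every member's
individual p ("combined p" is implemented as the FET on union presence,
the reading consistent with the strict-improvement condition). Finally,
replication: an ES (clonotype or motif) must meet its rule in at least
two cohorts. No multiplicity correction is applied by default — the
stringent threshold plus replication is the filter — with
Benjamini–Hochberg available as an option.

The discovery surface is a scikit-learn-style estimator
(`EnhancedSequenceDiscovery.fit(X, y, cohort)`), with `transform`
producing per-sample breadth/depth against the discovered pattern.

## HLA imputation and assignment

Carrier status of an allele is imputed by logistic regression on two
covariates: the count of allele-associated marker clonotypes present
and ln R_unique (deeper repertoires contain more of everything). Marker
clonotypes are selected by one-sided FET carrier enrichment (default
p < 10⁻⁴, configurable — the upstream classifier literature does not
pin the selection rule); the reported AUROC is from stratified 5-fold
cross-validation with selection inside each fold, and the final model
is refit on all training data (`HLACarrierClassifier`). Typed genotypes
always override imputed labels.

Each discovered ES is then tested against every allele label with a
one-sided FET and assigned the minimal-p allele; for a motif, the most
significant (member, allele) pair decides. Categories: assigned
(p < 10⁻⁴), uncertain (10⁻⁴ ≤ p < 10⁻³), unassigned. Ties in minimal p
are reported, not silently broken, and downgrade to uncertain.

## Exposure prediction

Within the pattern's own HLA stratum, breadth (or depth) scores are
summarized by the AUC, computed as the midrank Mann–Whitney statistic
(exactly the pair-counting probability with ties counted half). The
95% CI uses the DeLong placement-value variance estimator —
deterministic, hence the default; a stratified bootstrap is available
by flag. The tests verify CI coverage (~95% at n = 200 over 200
replicates) and exact agreement with a pair-counting oracle.

## Clinical models

- **Carrier-level D′**: with carrier fractions fA, fB, fAB,
  D = fAB − fA·fB normalized by its maximum attainable magnitude given
  the margins. This deliberately treats *carrier phenotype* (not
  haplotype) frequencies, because the published cohort tables report
  carrier counts and their printed D′ values are reproduced exactly
  from those counts (all six, at two decimals). The absolute value is
  reported.
- **Matching**: exact strata on categorical variables with
  quantile-binned age; strata lacking either group are dropped and
  reported. The source description mixes an exact method with a
  model-based distance; exact matching is what is implemented, and
  balance is guaranteed within strata (marginal balance requires
  per-stratum weights, which the matched table supports).
- **Linear interaction models**: OLS (statsmodels) with age and disease
  duration min-max scaled within the analysis dataset (scaling affects
  only those coefficients' scale, not other effects).
- **Cox / Andersen-Gill**: maximum partial likelihood via lifelines
  (`CoxPHFitter`), Efron tie handling. The recurrent-event model uses
  counting-process (start, stop] intervals (left truncation) with
  robust sandwich standard errors clustered by subject — required for
  valid recurrent-event inference. Monotone likelihoods (separation:
  a covariate cell with no events) are detected by a |log HR| > 5 flag
  and reported on the fit (`separated_terms`); such coefficients are
  not identified. Schoenfeld residuals and Kaplan–Meier curves
  (Greenwood variance) come from the same layer. Dual-route checks:
  the 6-subject partial likelihood equals a brute-force risk-set
  enumeration oracle; single-interval Andersen-Gill reduces exactly to
  the plain Cox fit; the two-group no-censoring limit matches the
  closed-form exponential rate ratio.

## Synthetic cohort generator

The generator is the package's study-conditions definition, a pure
function of (config, seed):

- **Genotypes**: per-subject carrier pairs for HLA-A\*03:01 and
  HLA-DRB1\*15:01 drawn from the 2×2 carrier distribution implied by
  marginal carrier frequencies and a carrier-level D′ target. Defaults
  per cohort follow the published carrier tables (e.g. 0.31/0.48 at
  D′ 0.31 for the NationMS-like cohort, 0.49/0.47 at D′ 0.10 for the
  FinBB-like cohort).
- **Repertoires**: unique productive counts ~ negative binomial
  (default mean 3000, dispersion 10); clone sizes ~ discrete power law
  (Zipf, exponent 2.0 — the shape is conventional for repertoires; no
  clone-size law is prescribed by the source); public clonotypes drawn
  from a shared pool with presence 0.02; planted treatment-associated
  clonotypes (65 class-I-restricted, 35 class-II, 5 unrestricted) rise
  to presence 0.30 in exposed carriers of their allele, times a synergy
  factor 1.5 when the other allele is co-carried (the synergy is shown
  only graphically in the source; 1.5 is a documented free choice);
  allele-marker clonotypes (100 per allele) rise from 0.015 to 0.30 in
  carriers regardless of exposure. About 10% extra non-productive rows
  are appended.
- **Longitudinal pairs**: the treated sample keeps every baseline
  rearrangement with log-normally jittered templates, adds newly
  arriving public clonotypes strictly below the top-100 template
  boundary, and plants a configured number of expansions strictly
  above it, tie-safely (expansion templates exceed the (k−m)th largest
  persisted template; arrivals stay below the kth largest, and are
  omitted when the repertoire is too small or too flat to have a
  sub-top-k stratum). Expansion clonotypes preferentially realize the
  planted treatment-associated keys of the subject's carried allele.
- **Clinical outcomes**: recurrent relapses from a Poisson process with
  multiplicative covariate effects on a constant baseline intensity
  (default 0.3 events/year over 3 years), including
  treatment-by-carrier interaction hazard ratios (defaults 0.66 GA arm,
  0.67 combination arm); optional log-normal subject frailty induces
  within-subject correlation for robust-variance checks; first-event
  data are the first of those times under administrative censoring;
  continuous outcomes follow a linear model with Gaussian noise
  (default interaction effect −0.34 on ΔEDSS/year).

What the generator does *not* emulate: V(D)J recombination statistics,
sequencing error, batch effects, shared-ancestry structure between
cohorts, or any correlation between repertoire features and clinical
outcomes beyond the planted effects. Passing tests therefore
demonstrate that the pipeline's estimators recover the effects they
target at the stated sizes and noise levels — not that the biological
signal exists in real repertoires.

## Reproduction experiments and problem sizes

`garep.experiments` defines the study-scale experiments used by the
acceptance tests and `scripts/acceptance.py`:

- **HLA imputation**: 600 repertoires (~3000 clonotypes each from a
  60000-clonotype pool), 40% carriers, 100 marker clonotypes at
  0.30 vs 0.015; train on 480 with 5-fold CV, report holdout AUROC on
  120, averaged over 10 generations (2 in the test suite, for runtime).
- **Recurrent-event interaction**: 693 subjects in three arms with the
  published arm-by-carrier allocation, 3 years at 0.3 events/year,
  interaction HRs planted at 0.66/0.67; geometric mean of the
  combination-arm interaction estimate over 50 replicates (12 in the
  test suite). Test tolerances are derived a priori from the design's
  information content: the published interaction CI implies a per-fit
  log-HR SE of ~0.18, so the mean of k replicates is allowed 3·SE/√k.
- **First-relapse interaction**: 335 subjects in the published
  two-group-by-carrier allocation, censored at one year, interaction HR
  planted at 0.37. The baseline first-relapse intensity (0.7/year) is
  calibrated so the fitted interaction's SE (~0.40) matches the
  precision implied by the published CI for that estimate; at lower
  intensities the smallest cell (32 carriers on treatment) produces
  occasional monotone likelihoods. Separated replicates are excluded
  from the geometric mean and counted.
- **Discovery operating characteristics**: three cohorts at the
  discovery case/control splits (58/211, 75/234, 71/978) with 105
  planted clonotypes at presence 0.30 in exposed cases vs 0.02
  background — the stated effect size at the level the per-clonotype
  test sees. (Under the carrier-conditioned default the per-case
  contrast is diluted by carrier frequency to ~0.15, and the pooled
  sensitivity of the replication filter sits near 0.82 with large
  seed-to-seed spread; that regime is exercised by the estimator and
  assignment tests rather than by the sensitivity bound.) Repertoire
  size is scaled to 300 clonotypes/sample from a 2000-clonotype pool —
  discovery power depends only on presence probabilities, not
  repertoire depth.

## Numerical choices and degenerate inputs

FET p-values come from the exact hypergeometric survival function
(vectorized over clonotypes); the test suite checks them against an
exhaustive tail-sum oracle over all small tables. Logistic fits are
unpenalized maximum likelihood; under complete separation (easy at the
planted effect sizes) coefficients are large but rankings — hence
AUROC — are stable. Empty repertoires: breadth/depth are 0 by
convention when a pattern is scored against an empty productive set,
clonality and imputation raise. Empty discovery (no ES) short-circuits
the scoring and classification pipeline stages. D′ raises on
degenerate margins. Matching with no overlapping strata returns an
empty table with a warning.

## Known limitations

- The production 145-allele HLA classifiers, trained on thousands of
  genotyped subjects, are out of scope; the two-covariate form is
  implemented and validated on synthetic labels only.
- Linear mixed models (lesion-count outcomes) and frailty models are
  not implemented.
- The wildcard expansion considers single wildcards only, seeded from
  ES clonotypes, as specified; multi-wildcard or all-key seeding is not
  provided.
- Exposure-prediction AUCs on synthetic validation cohorts reflect the
  planted presence model; no attempt is made to reproduce the published
  real-data AUC values, which depend on unavailable repertoires.
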