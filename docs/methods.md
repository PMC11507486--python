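# Methods

This note documents the statistical procedure tgspipe implements, the
assumptions baked into each stage, the synthetic-data generator's scope, and
the numerical/design choices that were genuinely open.

## Study design

The pipeline mirrors a two-stage case/control polygenic profiling study.
Candidate variants (an rsID-keyed, biallelic panel exported from population
GWAS of sport-related traits) are intersected with a genotyped cohort of
athletes (cases) and non-athletes (controls). The cohort is split 80/20,
stratified by phenotype, with per-stratum training counts rounded half-up —
211 cases and 522 controls therefore split 169/42 and 418/104, and the two
training arms merge to 587 samples. Everything estimated from data — QC
decisions, per-variant odds ratios, tag selection, score weights, the final
logistic model — uses the training set only; validation labels are consumed
exactly once, by the final AUC. Because the TGS model has no hyperparameters,
five-fold cross-validation is an assessment device, not a selection device.

## Quality control

Variant filters, in fixed attribution order with strict inequalities
(a variant exactly on a printed threshold is retained):

| filter | excluded when | default |
|---|---|---|
| imputation info score | info < `min_info` | 0.6 |
| variant missing rate | miss > `max_variant_missing` | 0.02 |
| Hardy–Weinberg | exact p < `hwe_alpha` | 0.05 |
| minor allele frequency | MAF < `min_maf` | 0.05 |

Variants lacking an info score pass the info filter (the filter targets
imputed data that carries one). Exclusions are charged to the first failing
filter; retained counts are order-independent, attribution is not. HWE is
computed over all training samples by default, with a `hwe_scope="controls"`
switch for the common controls-only convention.

The HWE test is the standard exact conditional test (not mid-p, matching
common GWAS tooling defaults): conditional on allele counts, heterozygote
counts of matching parity are enumerated via the numerically stable
recurrence, and the p-value sums all tables no more probable than the one
observed. Monomorphic input returns p = 1. A relative guard of 1e-12
decides probability ties so exactly tied tables are included regardless of
floating-point noise.

Sample filters run in order missing rate → relatedness → heterozygosity →
sex check, each on the survivors of the previous stage. Sample QC runs
*before* variant QC in the pipeline because the sex check needs the
X-chromosome variants that variant QC would remove (hemizygous male coding
deliberately fails the autosomal HWE test).

**Relatedness.** Method-of-moments IBD estimation: per pair, observed
IBS 0/1/2 counts over mutually non-missing autosomal variants are equated to
their expectations given allele frequencies, yielding P(IBD=0/1/2) and
PI_HAT = P(IBD=2) + P(IBD=1)/2, clipped to [0,1]. Two numerical choices
matter at candidate-panel scale (~2,000 markers rather than genome-wide):

* the component estimators are kept *linear* (unclipped) and only the final
  PI_HAT is clipped — clipping P(IBD=1/2) at zero first adds a positive bias
  of about 0.4·SD to every unrelated pair;
* expectations use falling-factorial (unbiased) moments of the allele
  counts, and estimation runs on an LD-pruned marker subset (greedy r² > 0.2
  within 250 kb), since correlated markers inflate variance without adding
  information.

Even so, PI_HAT on ~1,600 pruned markers has a sampling SD around 0.02, so a
0.125 cutoff occasionally flags truly unrelated pairs (measured ≈ 0.02% of
pairs at n = 735; a few dozen samples per study-scale run). This is a
property of the estimator at panel scale, not of the implementation, and it
is why the `relatedness` docstring recommends as many polymorphic variants
as possible. For each flagged pair the member with the higher missing rate
is excluded (ties: the later sample in cohort order); the comparison is
strictly greater than the threshold.

**Heterozygosity.** Per-sample autosomal het rate; exclusion outside
mean ± k·SD (k = 3, sample SD). Degenerate SD = 0, or fewer than three
samples, excludes nobody. At 3 SD about 0.3% of clean samples fall by
chance; that is the intended behaviour of the filter, not a bug.

**Sex check.** Per-sample X inbreeding F = 1 − observed het / expected het
(expected from cohort allele frequencies); F > 0.8 infers male, F < 0.2
female, in between undetermined and never excluded. Only determined
inferences contradicting a reported male/female label exclude a sample.

## Association

Per variant, complete-case univariate logistic regression of case status on
alt-allele dosage, fitted by IRLS (Newton scoring) with at most 50
iterations and a log-likelihood change below 1e-10 as convergence; Wald
p-values, matching the reporting convention of standard GWAS software. No
covariates are fitted by default — the mirrored analysis is strictly
univariate despite sex imbalance between groups; this is a documented
limitation, and the engine accepts arbitrary predictors should adjustment be
needed. A slope escaping |β| > 15 marks quasi-separation: the slope is
capped, the fit flagged, the p reported missing, and the variant barred from
tag selection (its lnOR weight would be unstable). Constant dosage is
flagged untestable. A constant predictor in the TGS model fit falls back to
the intercept-only closed form (slope 0, intercept = logit of the case
fraction). Under case/control ascertainment the logistic slope remains a
consistent estimator of the population lnOR (only the intercept absorbs the
sampling fractions), which is what the parameter-recovery check verifies.

## Clumping and thresholding

Greedy, single-assignment: among converged association rows with
p ≤ tier (tiers 0.05 and 0.01), the smallest p becomes an index variant;
ties break to smaller chromosome, then position, then rsID, for determinism.
Candidates on the same chromosome within 250 kb (inclusive at exactly
250,000 bp) with r² > 0.2 to the index are recorded as clump members and
removed; members are never re-evaluated for later tags. LD is composite:
squared Pearson correlation of unphased dosages over pairwise-complete
samples — the natural estimator post-imputation, numerically close to but
not identical with haplotype-based r². Undefined r² (constant vector,
fewer than two complete pairs) is treated as 0 with a warning. An empty
candidate set is a valid, empty result.

## Total Genotype Score

TGS_j = Σ S_i·G_ij / (2·M_j), with S_i = lnOR from the training association
(signed; every tag must have a converged fit), and M_j the count of tags
with non-missing dosage — a zero-weight tag still increments M_j. Samples
with M_j = 0 carry an undefined score and are dropped from model fitting
with a warning. Standardization (for distribution plots) uses the sample
(n−1) SD.

## Evaluation

AUC is the Mann–Whitney rank form — the probability a random case outscores
a random control with half-credit ties — identical to trapezoidal ROC
integration. Three AUCs are reported per tier: resubstitution on the
training set, stratified five-fold cross-validated, and held-out
validation. Resubstitution is reported because "training AUC" in this study
design is conventionally the resubstitution value; the CV mean is reported
alongside as the honest in-sample estimate. ROC point lists come from
scikit-learn's `roc_curve` on the model probabilities.

All randomness in a pipeline run (simulation, split, CV folds) derives from
one master seed through `numpy.random.SeedSequence`, so identical
configuration yields byte-identical reports and artifacts; SVG plots fix
matplotlib's hash salt and omit timestamps for the same reason.

## Synthetic cohort generator

The generator produces the statistical structure the analysis consumes and
nothing more:

* **Genotypes.** Gaussian copula: each haplotype's latent normal is
  thresholded at Φ⁻¹(MAF), so marginal allele frequencies are exact. A
  fraction `ld_block_fraction` (default 0.35) of variants forms tight
  equicorrelated blocks (`block_size` 5, latent correlation
  `within_block_rho` 0.8 → dosage r² ≈ 0.26, above the 0.2 clumping
  threshold); the rest are independent singleton loci. This mirrors
  multi-trait candidate panels, where most hits are isolated loci and a
  minority cluster within a region — consistent with published clump sizes
  in this design averaging ~1.4 members — and it keeps the effective marker
  count high enough for PI_HAT to be usable. Blocks sit 2 Mb apart so
  clumping windows never bridge groups.
* **Phenotypes.** Logistic liability: P(case) = expit(logit(base_rate) +
  Σ lnOR·(g − 2·MAF)), centred so the population case rate stays near
  `base_rate` (0.3) and rejection stays efficient; samples are drawn until
  the fixed case/control counts are reached (case/control ascertainment, as
  in a study that recruits fixed group sizes). Defaults: 211/522, 2,075
  variants, 20 causal loci at lnOR 0.5 (one per block).
* **QC foils.** Independent per-cell missingness (1.5%); near-duplicate
  relative pairs (per-locus resampling with probability 1 − copy_fidelity,
  default fidelity 0.95); X variants coded {0,2} in males and {0,1,2} in
  females; sex mismatches planted by swapping reported sex.

What the generator does **not** emulate: decaying LD within blocks,
recombination maps, population structure/admixture, imputation error
correlated with info score, genotyping batch effects. Passing tests
therefore demonstrate the pipeline's correctness and its behaviour under
the assumed sampling model, not robustness to confounding — a real cohort
with population stratification would need the PCA adjustment this design
(deliberately, matching its target analysis) omits.

With true causal weights the validation AUC ceiling of the default design
is ≈ 0.80; C+T weights estimated at n_train ≈ 587 reach ≈ 0.55–0.65. The
power of this design is genuinely modest — which is the scientific point
the cross-tier overfitting comparison makes.

## Problem sizes in tests and the acceptance script

Oracle suites run exhaustively at small n (all HWE triples with n ≤ 25;
AUC instances n ≤ 30; clumping instances m ≤ 50). Calibration uses null
cohorts of m = 1,000 variants and 600 samples (10 seeds end-to-end);
parameter recovery uses 20 seeds at n = 4,000; the overfitting signature
uses 10 study-scale seeds (735 samples, 2,075 variants). These sizes give
each check comfortable statistical resolution while keeping a full run in
the minutes range on one CPU.

## File formats

* **VCF 4.x** — GT hard calls (or a configurable dosage FORMAT field such
  as DS); imputation quality read from INFO key `INFO`, falling back to
  `R2`. Multi-allelic records are rejected with instructions to normalize
  upstream (splitting silently would change allele semantics; the panel is
  biallelic by construction). Positions 1-based; BED intervals 0-based
  half-open; internal coordinates 1-based. The "mutant" allele of the
  dosage coding is the VCF alt allele — the only orientation available
  post-imputation.
* **Phenotype TSV** — `sample_id, phenotype, sex[, subgroup]`; phenotype
  tokens athlete/case/1 and control/0, case-insensitive.
* **Panel TSV** — `rsid, trait[, effect_allele, p_source]`; duplicate rsids
  merge into one entry with the union of traits.
* **Truth JSON** (simulated bundles) — object with keys `causal` (list of
  `{rsid, ln_or}`), `related_pairs` (list of `[donor_id, copy_id]`),
  `sex_mismatches` (list of sample ids), `seed`.
* **Outputs** — QC reports (TSV + JSON), association table
  (`rsid, chrom, pos, effect_allele, OR, lnOR, SE, P, N, converged`), tag
  sets (with `rsid:r2` member lists), weights (`rsid, effect_allele, lnOR`,
  column-compatible with common score-file conventions), score TSVs
  (`sample_id, TGS, M, z`), ROC TSVs, an `eval_report.json`, and SVG plots.

## Known limitations

* No covariate adjustment or population-structure correction (by design,
  matching the mirrored analysis; both are the first extensions a real
  deployment should add).
* PI_HAT at candidate-panel marker counts is noisy; the 0.125 threshold
  will occasionally discard unrelated samples (quantified above).
* Composite-LD r² differs slightly from haplotype-frequency r²; clump
  memberships near the 0.2 boundary can differ from phased-data tools.
* The array-vs-sequencing reconciliation of a two-platform cohort is
  modelled only as intersection on chrom/pos/alleles at merge; platform-
  specific error modes are out of scope.
* Genome-build liftover is out of scope; merging enforces coordinate
  agreement but cannot detect two cohorts on different builds.
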