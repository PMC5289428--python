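# Methods

`tissueqtl` implements the statistical machinery of a germline-variant /
expression association study in paired tumor and adjacent-normal tissue:
per-SNP gene-level eQTL scans with empirical-Bayes moderated statistics,
a paired tumor/normal interaction model, a gene-set ("functional") QTL
statistic with genotype-permutation FDR, a cross-platform adequacy check,
and the supporting expression QC operators. Everything is exercisable on
synthetic studies with planted truth; this note records the models, the
defaults, and the choices made where the design was open.

## Gene-wise linear models and variance moderation

For SNP s, gene g, and samples i within a tissue stratum, the eQTL model is

    y_ig = b0 + X_i' b1 + b2 * D_is + e_ig,    e_ig ~ (0, sigma_g^2)

with X_i the adjustment covariates — age at diagnosis (years), year of
diagnosis, assay-plate indicator dummies, optionally sample-space principal
component scores retained by the QC step — and D_is the allelic dosage in
[0, 2] (counts of the minor allele; continuous when imputed). Fits are
ordinary least squares, vectorized over genes against the one design shared
by a SNP's scan; genes with missing values fall back to per-gene
complete-case fits with their n recorded.

Residual variances are shrunk by the classical empirical-Bayes treatment:
s_g^2 on d_g df are modelled as exchangeable draws under a scaled
inverse-chi-square prior (d0, s0^2), giving the posterior variance
s~_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g) and a moderated t for the dosage
coefficient with d0 + d_g df. The hyperparameters are estimated by
moment-matching the log sample variances against the scaled-F marginal:
with e_g = log s_g^2 − digamma(d_g/2) + log(d_g/2), the excess of var(e)
over its trigamma sampling floor identifies d0 through a trigamma
inversion (Newton iteration on the 1/y scale), and the mean of e then
identifies s0^2. When the observed spread does not exceed the floor the
variances are treated as constant: d0 = +inf, s~^2 = s0^2 = mean(s^2), and
tail probabilities are normal. d0 = 0 is accepted as the no-shrinkage limit
and reproduces classical t and F exactly. One prior is estimated per
(SNP, stratum) fit set, mirroring a per-SNP model family; neither a
mean-variance trend nor robust down-weighting of outlier variances is
applied. All tests are two-sided.

The moderated F for a joint test of k coefficients is
beta_J' V_J^{-1} beta_J / (k s~^2) with V_J the unscaled coefficient
covariance submatrix, on (k, d0 + d) df; for k = 1 it equals the moderated
t squared. The joint test requires the shared-design (complete-case) path.

Benjamini-Hochberg adjustment is applied within each SNP's gene list, so
the 10% default reporting level controls FDR per SNP, per tissue stratum.
Strata are ER+ tumors, ER− tumors, all tumors, and normals; samples with
unknown ER status are excluded from the ER strata only.

## Paired tumor/normal interaction scan

Subjects contributing both tissues enter a fixed-effects design: subject
dummies, a tissue indicator (tumor = 1), and the tissue × dosage product,
whose coefficient is the effect of interest. Dosage, age, and year are
constant within subject and therefore aliased with the subject dummies;
aliased columns are detected by a left-to-right rank scan and dropped with
a log record (protected columns — intercept, tissue, interaction — are
scanned first so they survive whenever a full-rank design containing them
exists). Subjects with only one tissue are excluded.

## Gene-set QTL statistic

Each gene is standardized to mean 0 and sample SD 1 (n−1 denominator)
across the stratum's samples; constant genes are dropped with a warning.
For gene set i with m resolvable member genes (minimum 5; unresolvable ids
dropped with a count logged), member z-profiles are stacked into one
response of length m·n and regressed on the tiled small design
(intercept, year of diagnosis, age at diagnosis, dosage):

    z_ijk = b0 + b1 YrDx_k + b2 AgeDx_k + b3 Dosage_k + e_ijk.

b3 is the change in mean set-level z-score per minor allele. Member genes
are treated as repeated measures on one process and assumed to share a
residual variance; the t statistic for b3 carries m·n − 4 df. Because the
stacked design is the small design tiled m times, the stacked OLS collapses
exactly: coefficients equal the OLS of the per-set mean z-profile, and the
pooled RSS follows from per-set sufficient statistics (column sums and the
total sum of squares). The scan and the permutation loop use this collapsed
form; the direct stacked fit is retained and the two are asserted equal to
machine precision in the tests. Plate and PC covariates are not included
by default (an option adds them); the df is deliberately optimistic when
member genes are correlated, which is one reason significance is referred
to a permutation null rather than the t reference alone.

FDR for the set scan is estimated by permuting the sample-to-genotype
assignment: per round, one shared permutation is applied to the whole
dosage matrix (preserving the correlation structure within expression and
among SNPs; an independent-per-SNP mode exists behind a flag), and all
(SNP, set) |t| statistics are recomputed. With observed statistics pooled
across SNPs and sets within a stratum, the estimate at threshold t* is

    FDR(t*) = mean_b #{perm stats >= t*} / #{observed >= t*},

capped at 1 and monotonized by the q-value convention (each record takes
the minimum raw value over itself and all less significant records). The
default is B = 1000 rounds (500 in the replicated validation studies);
below B = 100 a coarse-resolution warning is logged. This plug-in
estimator is approximately unbiased for FDR when nearly all hypotheses are
null; realized false-discovery proportions of small call sets are
correspondingly noisy around the nominal level, which is why the
validation criteria compare replicate means against nominal plus a
5-percentage-point Monte-Carlo margin.

## Cross-platform adequacy

Per platform, each gene's sensitivity to tumor biology is a 3-d.f.
moderated F for equal means over the four ER/PR receptor groups (dummies
for +/−, −/+, +/+ against reference −/−; samples missing either status are
excluded; an empty group degrades to a reduced-df test with a warning, or
an error in strict mode). Platforms may differ freely in sample size and
hence denominator df. Agreement is the Spearman correlation of the two F
vectors over exactly-matching gene identifiers.

## Quality control

* Control-probe AUC: per sample, the Mann-Whitney AUC separating positive
  from negative control-probe signals (ties at half credit). Samples with
  AUC strictly below 0.55 are removed from every bundle component, order
  preserved.
* Replicate concordance: minimum pairwise Pearson correlation of
  expression columns within each technical-replicate group (reference
  benchmark r ≥ 0.93 on well-behaved arrays).
* PC batch screen: the genes × samples matrix is row-centered and
  decomposed by SVD; sample scores of the first 50 PCs (or fewer if rank
  limits) are each tested against batch by one-way ANOVA. Every associated
  PC (p < 0.05) is handled, not only the first, since the associated
  component need not be unique: in "clip" mode its rank-one term is
  subtracted from the matrix, in "covariate" mode the matrix is left
  intact and the scores are returned for use as regression covariates.
  Both modes are offered because removing the component and adjusting for
  it are both defensible; the mode is recorded in the QC report.

## Synthetic studies and what they do (not) show

The generator emulates the statistical structure the analyses assume:
Hardy-Weinberg hard-call dosages at configurable MAFs (defaults drawn from
0.015–0.50, the span of risk-variant frequencies in this setting; optional
Gaussian jitter emulates imputation), subject-level baselines shared by a
tumor/normal pair (the subject random intercept realized as a fixed draw,
so the paired fixed-effect model is the correct analysis), per-gene age and
year slopes, plate shifts detectable on leading PCs, ER/PR group shifts on
a subset of genes, gene sets with set-level dosage effects, control-probe
signals whose expected AUC is Phi(delta/sqrt 2), and i.i.d. Gaussian noise
with a common SD (matching the set model's equal-variance assumption).
Defaults mirror a postmenopausal breast-cancer FFPE cohort: 300 subjects,
70% with a paired normal, 70% ER+, mean age 57, diagnoses 1990–2004, nine
assay plates. Every planted effect is recorded in a TruthTable.

Deliberately absent: linkage disequilibrium between SNPs, probe-level
microarray artifacts, RNA degradation gradients, heavy-tailed or
heteroskedastic noise, and correlated co-expression beyond what planted
effects induce. Passing the validation studies therefore certifies the
statistical machinery under its own assumptions, not robustness to the
full messiness of archival tissue data.

Because gene sets are sampled with replacement across (not within) sets,
sets overlap; a set sharing members with a planted set carries the planted
shift on those genes and is genuinely associated with the SNP. The
validation studies score such induced associations as true discoveries.

## Replicated validation studies

`tissueqtl.studies` runs the scoring studies end to end; the acceptance
script reports the two headline numbers. Problem sizes: the eQTL screen
study uses 20 bundles (seeds 1–20) of 40 SNPs (MAF 0.1–0.5) × 2000 genes
at n = 300 with 5% of SNP-gene pairs planted at 0.3 SD per allele; the set
screen study uses 20 bundles of 20 SNPs, 50 sets of 10–50 genes over 1500
genes, 3 planted SNP × set effects of 0.3 z-units per allele, B = 500.
Parameter-recovery studies use n = 120–300 over 20 seeds; the concordance
study plants shared receptor-group effects on 17 genes across two
platforms at a 4:1 signal-to-noise ratio.

## Numerical notes

* Aliased-column detection scans left to right with incremental rank
  checks, so earlier columns win and the reported aliased column is the
  later duplicate.
* Saturated fits (residual df 0) are flagged with undefined s^2 rather
  than erroring; monomorphic SNPs within a stratum are skipped with a log
  count rather than erroring.
* The trigamma inversion runs Newton iterations to 1e-10 relative with
  closed-form guards for extreme arguments.
* The cis window defaults to 1 Mb from the SNP to the nearest gene
  boundary (0 inside the gene body), boundary-inclusive, same chromosome
  required; coordinates are 1-based inclusive and strand is ignored.
* BH and the permutation-FDR monotonization both use stable sorts, making
  results invariant to input order up to matching permutation.
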