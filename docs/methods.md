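# Methods

`protx` re-implements, as a tested and reusable pipeline, an integrative
differential-abundance analysis of multiplexed (TMT 6-plex) proteomics and
bulk RNA-Seq from a post-mortem brain case/control study, together with the
downstream gene-set enrichment, cross-platform concordance analysis and
GWAS locus-to-gene mapping. Because the original cohort is not required to
exercise the code, a synthetic cohort generator with planted ground truth
drives all tests and the acceptance script. This note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Study design emulated by the generator

The generator (`protx.simulate`) draws a cohort of 29 case and 44 control
RNA-Seq samples; a nested proteomics subset of 12 + 12 samples (the
lowest-PMI samples per group) is arranged as four 6-plex runs, each with 3
cases and 3 controls. Covariates are drawn uniformly over the ranges the
study reports: age at death 46–97 (control) / 64–95 (case) years,
post-mortem interval 2–32 / 1–31 h, RNA integrity number (RIN) 6.0–9.1 /
5.8–8.5, with RIN binned at 7 (ties to the low bin) wherever a binned
covariate is used.

**Counts.** Gene *g* in sample *j* is negative-binomial with mean
`s_j · μ_g · 2^(x_j' β_g)`: library-size factors `s_j` (lognormal, log2 SD
0.25, geometric mean 1), base means `μ_g = 2^N(5, 2²)`, a planted group
log2 fold change, and small per-gene coefficients on standardized age/PMI
and the RIN bin (SDs 0.02/0.02/0.05 — nuisance-scale effects that exercise
the covariate machinery without dominating the group contrast). Gene
dispersions are lognormal (`meanlog −2.5`, `sdlog 0.6`), typical of bulk
brain RNA-Seq; the Poisson limit is reached as dispersion → 0. A fraction
0.135 of genes is forced near zero (mean count 0.02) to exercise the
low-count filter — matching the share of protein-coding genes the study's
filter removed (2751/20331). Defaults: 20 000 genes, 6 % of genes with a
nonzero RNA effect and 8 % with a nonzero protein effect (the study's
1095/17580 and 283/3558 significant fractions), effects drawn bivariate
normal with SD 1 and correlation 0.6 between platforms.

**Reporter intensities.** For each detected protein,
`log2 intensity = base + plex batch + group·effect + loadings·scores + ε`,
with per-plex batch shifts `N(0, 0.5²)` (log2), three latent factors
(loadings `N(0, 0.3²)`, standard-normal sample scores — three factors
because the original analysis found three significant surrogate variables),
and channel noise `N(0, 0.25²)`. The reporter-ion noise distribution is not
documented for this instrument class; lognormal is assumed. Whole proteins
are present or absent per plex (MS identification is per run), never
individual channels.

**Detection bias.** Whether a gene's protein is detected follows a
logistic function of its standardized log mean mRNA abundance, slope 1,
intercept logit(0.2) (≈20 % of genes detected, the study's 3558/17580).
This plants, as a mechanism, the bias the study reports as an observed
contrast: genes captured by proteomics have higher mRNA abundance.

**ID space, loci, gene sets.** Protein IDs map to gene symbols through a
map with 4 unmapped proteins and 35 duplicate-symbol proteins (the study's
counts). Gene models are laid on 22 toy chromosomes with inter-gene gaps of
250 kb–1 Mb so that decoy SNPs placed at gap centers are unambiguously
outside every 100 kb window. Twenty genes are SNP-linked, each receiving
1–4 genome-wide-significant SNPs (p < 5×10⁻⁸) inside
[start − 100 kb, end + 100 kb]; decoys are sub-threshold SNPs near genes
and significant SNPs far from all genes. Gene-set collections (GMT) include
a few sets enriched for planted differential genes.

Everything is a deterministic function of the seed, via fixed
sub-stream keys per component, so cohorts are byte-reproducible.

## Proteomics preprocessing

Order of operations: common-protein filter (present in every plex) →
within-plex normalization (each protein's channel value divided by the
protein's total ion intensity in that plex; rows sum to 1) → ID-to-symbol
mapping (unmapped dropped, duplicate-symbol proteins averaged per sample) →
across-plex normalization (each value divided by the protein's mean over
all samples; rows have mean 1). Averaging after the within-plex step keeps
both normalization invariants exact, and the across-plex step removes any
per-plex multiplicative batch scale by construction (tested as exact
invariance to scaling a plex). "Total ion intensity within the plex" is
read as the sum over the six channels of that protein in that plex — the
only reading that yields a per-sample fraction. Modeling is done on log2
of the final matrix so group effects are symmetric fold changes; the
original analysis does not state its transform, and this is recorded as a
deviation surface.

## Surrogate variables

The number of latent components is chosen by permutation parallel analysis
on the design-residual matrix: each observed singular-value *variance
fraction* is compared against the 95th percentile of the matching fraction
across B = 100 copies in which each feature's residuals are independently
permuted and re-residualized; k is the count of leading components
exceeding their null percentile. Variance fractions, not raw singular
values, are compared: the second residualization shrinks the permuted
copies' total variance, and raw-value comparison is biased toward k > 0 on
pure noise.

Scores are estimated by the canonical two-step: (1) SVD of the residual
matrix gives candidate eigengenes; (2) for each candidate, features
associated with it at raw p < 0.1 in a per-feature simple regression are
collected, and the surrogate is the eigengene of the *raw* (row-centered)
sub-matrix most correlated with the candidate. Using the raw sub-matrix
matters: eigengenes of the residual sub-matrix are exactly orthogonal to
the design, so adding them to the model can only soak up residual variance
and inflates the null type-I error of the downstream moderated test
severely; with the raw-matrix refit the type-I error stays at nominal
(verified on simulations with planted batch). Scores are re-orthonormalized
by QR and are invariant to per-feature recentering of the input.

## Differential engines

**Moderated linear model (proteins).** Per-feature OLS on log2 abundance
against intercept + group (+ surrogate variables). Residual variances are
shrunk by an empirical-Bayes scaled-F prior fitted by matching the first
two moments of log s² (closed-form digamma/trigamma moment equations; the
trigamma inverse is solved by Newton iteration). The group coefficient is
tested with a moderated t on d₀ + d residual degrees of freedom; d₀ = 0
recovers ordinary t-tests, d₀ = ∞ fully pools variances (both exposed for
testing). All-constant features are flagged and report p = 1, effect 0.
Agreement with the reference R implementation (limma) is verified in the
test suite to ≤ 1e-4 relative on p-values. Adjustment: Storey q-values,
significance q < 0.05.

**Negative-binomial GLM (counts).** A deliberately compact re-derivation
of the standard count-based DE recipe: (1) median-of-ratios size factors
normalized to geometric mean 1; (2) per-gene dispersion by maximum
likelihood given fitted means, via a 60-point grid on log-dispersion in
[1e-8, 30] with 3-point parabolic refinement (deterministic, vectorized
across genes); (3) a dispersion trend α(μ) = a₁/μ + a₀ fitted by iterated
trimmed non-negative least squares; (4) shrinkage of gene-wise dispersions
toward the trend through a lognormal prior whose width is the MAD-based
spread of log residuals minus the expected sampling variance
(trigamma((n−p)/2)), floored at 0.25; dispersion outliers more than 2
residual SD above the trend keep their gene-wise estimate; (5) final
log-link IRLS (vectorized across genes, ridge 1e-8 for conditioning,
convergence 1e-6) and a two-sided Wald test on the group coefficient,
reported in log2 units. Non-converged genes are flagged and keep p = 1, so
the BH denominator always equals the filtered gene count (the analysis is
run without independent filtering). Not reproduced from the original tool:
fold-change shrinkage, the Cox-Reid degrees-of-freedom adjustment, and
count-outlier replacement — equivalence is claimed only at the level of
simulation calibration (null type-I 0.05 ± 0.015; planted log2FC = 1
recovered within ±0.1 mean bias), not bit-for-bit.

**Filters and adjustment.** The low-count filter keeps a gene iff zeros do
not exceed 50 % of cases *and* 50 % of controls (strictly more than half
removes). BH is the step-up procedure (delegated to scipy behind the
package surface and cross-checked against a brute-force double loop).
q-values use the Storey estimator with π₀ from a cubic smoother through
π₀(λ), λ ∈ {0.05, …, 0.95}, evaluated at λ = 0.95, falling back to the
λ = 0.5 plug-in if the smoother misbehaves; π₀ is clipped to (0, 1], and
π₀ = 1 reduces q-values to BH exactly.

## Enrichment

One-sided Fisher exact tests (hypergeometric upper tail) of gene sets
against nested top-k prefixes of the ranked significant list (default
tiers 25/50/100/350/600/850 plus the full list), with sets restricted to
the analysis background and sets smaller than 10 background members
excluded. BH is applied within each tier; the per-set summary is the
minimum p over tiers (a descriptive ranking, ties broken by larger overlap
then name). The flat-set Fisher approach replaces graph-weighted GO
decorrelation deliberately: it reproduces the pathway-collection analysis
exactly in form and the GO analysis approximately.

## Integration and GWAS mapping

Direction of effect is the sign of the log2 fold change; exact zeros have
no direction class and are excluded from direction strata (logged). The
detection-bias test is a Pearson χ² without continuity correction on the
2×2 of direction × detected — the no-correction choice reproduces the
published 33.68 from the published margins, whereas the corrected statistic
does not (≈32.5). Fold-change concordance uses Spearman rank correlation
with midranks. Per-gene protein/mRNA correlations are Pearson, between
log2 inter-normalized protein abundance and log2(size-factor-normalized
count + 1) over the proteomics-profiled samples; the +1 transform is a
package choice, as the original transform is unstated. Evidence classes:
AND = corrected-significant in at least one platform and nominally
significant in the other; OR = corrected-significant in either. The
absolute-correlation contrast (all genes vs AND-evidence genes) is a Welch
t-test. A second expression platform (e.g. microarray) is compared by
feeding its moderated-lm result table through the same overlap and
correlation operations — there is no separate code path.

Locus mapping: a SNP qualifies for a gene iff p < 5×10⁻⁸ (strict) and its
position lies in [start − 100 kb, end + 100 kb], 1-based inclusive
coordinates with inclusive endpoints (both the threshold strictness and
endpoint convention are configurable; inclusive endpoints are the chosen
default). Per gene, the best SNP minimizes p with ties to the smaller
position. The positional classifier is simplified: inside the gene body →
intronic (exon/UTR sub-annotation degrades to this default when no exon
structure is supplied), otherwise upstream/downstream by strand.

## Problem sizes and what the benchmarks show

Defaults run the generator at the study's scale (20 000 genes, 73 RNA /
24 proteomics samples; ≈10 s end to end on one core). Calibration suites
use 2 000 features; the latent-factor null uses 50 seeded 500 × 24
matrices. Passing benchmarks demonstrate that the estimators are
calibrated and recover *their own generative model*: negative-binomial
counts with smooth covariate effects, multiplicative lognormal intensity
structure, logistic detection. Real data depart from this in ways the
generator does not emulate — correlated genes, count outliers, peptide-
level quantification artifacts, isoform mixtures, non-logistic detection,
LD structure among SNPs — so recovery correlations near 0.98 on synthetic
cohorts bound optimism, not real-data performance.

## Known limitations

- The NB engine's Wald test relies on a normal approximation; at very
  small sample sizes (< ~10 per group) it is slightly anticonservative.
- π₀ smoothing uses a generic cubic smoother, not the exact reference
  smoothing-spline defaults; q-values can differ in the third decimal.
- The surrogate-variable variant is the deterministic two-step, not the
  iteratively re-weighted variant; equivalence with any particular
  reference run is not claimed.
- UTR3/UTR5/exonic position classes require exon annotations the toy gene
  models do not carry; synthetic runs therefore only exercise
  intronic/upstream/downstream.
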