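# Methods

This note documents the statistical models, the defaults and the design
choices behind `areqtl`, and what the synthetic-data tests do and do not
establish about real cohort data.

## Differential expression (`areqtl.expression`)

Per probe, the target smoking group is compared with the never-smoker
baseline by a two-sample t-test on log2 intensities. The default is the
Welch (unequal-variance) form with Welch–Satterthwaite degrees of freedom;
the pooled-variance form is available via `equal_var=True`. Welch is the
default because airway cohorts have unequal group sizes and visibly unequal
spread (the pack-years comparison 52±53, n = 24 vs 58±28, n = 20 gives
p = 0.63 only under the unequal-variance form). Identically constant groups
return t = 0, p = 1 so flat probes can never rank as significant.

Benjamini–Hochberg q-values are the step-up map
q_(i) = min_{j ≥ i} p_(j)·m/j computed within each comparison separately
(SC-vs-NS and SNC-vs-NS have their own probe universes after filtering).
Fold change is 2^(mean_target − mean_baseline) — the ratio of geometric
means of the linear intensities. Whether the original microarray fold
changes were computed on linear MAS5 intensities or anti-logged log2 means
is not recoverable from summary descriptions; the geometric form is used
because the package operates on log2 values throughout. Classes
(over > 1.2, under < 0.8) are assigned only when q ≤ the FDR level
(default 0.1).

Filtering order: detection first (probe detected in ≥ 20% of samples of at
least one of NS/SNC/SC), then exclusion of probes whose expression regresses
on age at BH q ≤ 0.1. Age exclusion guards the group-age confound (cancer
patients are older); it is probe removal, not covariate adjustment, so the
downstream regressions stay univariate.

## GSEA (`areqtl.enrichment`)

Weighted (2005-form) gene-set enrichment. Genes are ranked by signal-to-noise
(μ_A − μ_B)/(σ_A + σ_B) with each σ floored at 0.2·|μ| of its group and |μ|
itself floored at 0.2 — the standard guard against near-zero denominators on
log-scale data. The running sum increments by |s|^w / Σ_hits |s|^w at set
members and decrements by 1/(N − N_hits) otherwise; ES is the extremum of
largest magnitude. The weight exponent defaults to 1; 0 gives the classic
Kolmogorov–Smirnov walk.

Significance uses phenotype-label permutation (group sizes here, ≥ 7 per
group, make phenotype permutation the appropriate null; a gene-set
permutation fallback is not provided). Nominal p is the sign-matched tail
with a (1+k)/(1+n) estimator; NES divides ES by the mean |permuted ES| of
matching sign; FDR q follows the pooled positive/negative-permuted-NES
procedure with a step-up monotonicity pass (a more extreme NES may inherit
the smallest raw q among less extreme cutoffs, exactly as BH allows).
`nperm` defaults to 1000 and must be ≥ 100; tails are unstable below that.

Probe-sets mapping many-to-one to genes are collapsed by keeping the probe
with the highest mean expression.

## ARE motif scanning (`areqtl.motif`)

The PWM is column counts + pseudocount → frequencies → log2(freq/background).
Defaults: pseudocount 0.25 per base, uniform background; both configurable.
A pseudocount of zero is rejected because absent bases would give infinite
log-odds. The repository ships a **synthetic** training-site collection
(`data/are_sites.synthetic.fasta`, 11-nt sites around the TGAC…GC ARE core)
as a documented stand-in; analyses of real sequence should supply the
user's own curated sites.

Scanning scores every window on both strands (minus-strand windows score
their reverse complement; positions are reported in plus-strand 0-based
half-open coordinates). Windows containing non-ACGT bases are skipped and
logged. Site calls keep windows scoring ≥ threshold_fraction × the maximum
attainable score — default 0.8, a package choice since no published cutoff
exists for this motif — with overlapping same-strand calls resolved by
higher score (ties: leftmost). SNP allele deltas substitute each allele and
take the best window overlapping the variant offset; when no above-threshold
site of either allele covers the SNP, the delta is still reported over raw
windows but flagged `inside_site=False`. Candidate ranking sorts by
(inside_site, |delta|) descending, stable. Conservation scoring is out of
scope; a user-supplied boolean column can carry it.

## Genotype QC and cis-eQTL mapping (`areqtl.assoc`)

QC thresholds default to call rate ≥ 0.90, MAF ≥ 0.01 and Hardy–Weinberg
exact p ≥ 0.001, with an analysis set restricted to MAF ≥ 0.05. MAF and HWE
use non-missing calls. The HWE test is the exact conditional test: all
heterozygote counts compatible with the allele counts are enumerated and
probabilities ≤ the observed configuration's are summed (plain two-sided
probability-mass definition, no mid-p). It is computed in exact integer
arithmetic, so probability ties are handled without floating error.

LD r² comes from EM haplotype-frequency estimation over unphased two-locus
genotypes (double heterozygotes split iteratively between the two phase
resolutions), r² = D²/(p_A p_a p_B p_b).

cis pairing links a SNP to a probe when its position lies within 10 kb of
the gene region, inclusive on both bounds; coordinates are 1-based inclusive
(VCF convention).

The association model is OLS of log2 expression on additive dosage with no
covariates (age is handled by probe exclusion). Family-wise correction
permutes the expression vector across samples, records the minimum nominal p
over the probe's cis-SNP family per permutation, and reports both
corrected p = (1+k)/(1+N) — never exactly zero — and a significance flag
(observed nominal p below the empirical 5% quantile of the min-p
distribution). The permutation family is all cis SNPs of one probe-set
(regional min-p), not a genome-wide minimum. Missing dosages use
pairwise-complete samples per SNP; permutations shuffle the full expression
vector and then apply each SNP's missingness mask, so one permutation stream
serves the whole family and nested families are exactly comparable.
`nperm` defaults to 10,000 (the conventional choice for a 0.05 tail) and
must be ≥ 100.

## Phenotype tests and integration (`areqtl.integrate`)

Fisher's exact test uses the probability-mass two-sided definition: the sum
of probabilities of all tables with the observed margins that are no more
probable than the observed table — hypergeometric closed form for 2×2,
full enumeration (exact integer weights n!/Π n_ij!) for r×c. Zero-margin
rows/columns are dropped with a log message. Genotype–status tests default
to the 2×3 genotypic table; dominant and recessive 2×2 collapses are
available by flag. Of note, the 2×2 cohort sex table (2:22 vs 4:16) gives
p ≈ 0.387 under this standard definition; some published tables report other
values for the same margins, which cannot be reproduced without knowing the
exact table and sidedness used.

Logistic regression of cancer status on per-probe expression is fitted by an
in-package vectorised Newton/IRLS solver (a univariate logistic fit must be
re-run probe × permutation times for the min-p correction, which rules out
generic fitters; statsmodels verifies the solver in the test suite).
The p-value is the likelihood-ratio test against the intercept-only model.
Complete separation (unbounded slope) is detected via non-convergence or
|standardised slope| > 30 and handled by an L2-penalised refit (ridge 0.5 on
the slope), with the record flagged `separation`. The min-p correction over
the probe family mirrors the eQTL estimator exactly.

The integration report joins the three axes on (snp, probe). Direction
consistency: with b_e the eQTL slope, b_l the logistic slope and df the
minor-allele frequency difference (cases − controls), the configuration is
consistent when sign(df) = sign(b_e·b_l); zero signs are inconsistent.
Tier 1 = all three tests ≤ α (default 0.05, on corrected p where available)
and consistent; tier 2 = eQTL plus at least one phenotype test (including
the all-significant-but-inconsistent case); tier 3 = eQTL only; eQTL
failures are unranked. Tiers partition the joined records.

Cohort summaries compare SC vs SNC continuous variables by the Welch t-test
from summary statistics (identical to the raw-data Welch test, verified in
the suite) and categorical variables by Fisher's exact test.

## Synthetic data (`areqtl.simulate`)

The generator's defaults are the study conditions: 8/24/20 samples in
NS/SNC/SC; ages Normal(32,9²)/(53,18²)/(68,15²) truncated at 18 years;
pack-years 0 for NS and truncated-at-zero Normal(52,53²)/(58,28²) for
SNC/SC; sex and race drawn from the per-group cohort proportions.
Truncation shifts the realised moments slightly above the nominal ones;
cohort-level checks therefore compare distributions, not exact moments.

Genotypes: SNPs come in LD blocks (default 3 SNPs) within each gene's cis
region; each block draws a pool of 20 haplotypes whose per-SNP carrier
counts match a target frequency drawn from maf_range (clamped to keep the
pool polymorphic), and every individual is the sum of two independent pool
draws. This guarantees per-SNP Hardy–Weinberg exactly while producing
within-block LD through shared haplotypes — chosen over multivariate-normal
thresholding because the HWE and LD properties are then provable rather
than approximate. Dosage is re-oriented to the globally minor allele after
generation (frequency ties broken by allele lexicographic order). Missing
calls are injected at a configurable rate (default 0).

Expression: y = μ_gene + a_snc·1[SNC] + b_sc·1[SC] (ARE-flagged genes) +
β·dosage (causal pairs) + Normal(0, noise_sd). Defaults a_snc = +0.58 and
b_sc = −0.74 log2 units reproduce the ~1.5-fold SNC elevation and ~0.6-fold
SC reduction characteristic of the MAFG-like ARE pattern; β defaults to
1.0 log2 units/allele with 20% of genes causal; noise_sd defaults to
0.5 log2 units, a typical within-group microarray SD. Detection flags mark
a 5% slice of genes as essentially undetected to exercise the filter.

Sequences: uniform-background FASTA with motif-consensus sites planted at
recorded positions/strands and SNPs planted inside and outside sites.
Planted sites score the PWM maximum by construction, so recall at the 0.8
threshold is a correctness check of the scanner, not a power statement.

The planted-signal integration cohort (`simulate_integration_dataset`)
models 44 smokers, 150 genes of which 25 are ARE genes sharing a latent
regulator f (loading 0.9), one ARE gene carrying a cis effect of
2.0 log2 units/allele at MAF 0.35 (loading 0.5 on f; residual SD 0.35), and
status sampled from logit P(SC) = −(0.9 f + 2.6 z) with z the standardised
causal-gene expression. These effect sizes were fixed by a design-time power
analysis: at n = 44 the genotype–status Fisher test is by far the weakest
link of the three axes (as such cohort sizes inherently make it) and needs
a marginal per-allele odds ratio near 10 before attenuation by the latent
factor to be detected reliably. The planted-signal test therefore
demonstrates that the pipeline recovers a strong, internally consistent
signal — it says nothing about power for the modest effects expected in
real cohorts, where tier-1 calls at n ≈ 44 will be rare.

What the generator does not emulate: population structure, relatedness,
imputation uncertainty, sex chromosomes, probe-level measurement artefacts,
and realistic LD decay beyond block boundaries. Passing tests validate the
statistical machinery under its stated assumptions, not robustness to these
features of real data.

## Numerical choices and problem sizes

- Exact tests (HWE, Fisher) use integer/rational arithmetic internally and
  convert to float only on return; oracle tests assert equality to 1e-12.
- Permutation p estimators are (1+k)/(1+N), bounded away from zero; all
  permutation machinery is bit-reproducible given a seed (numpy
  `default_rng`, one stream per operation salted from the configured seed).
- Monte-Carlo checks in the suite and acceptance script use moderate sizes
  chosen for stable statistics at interactive runtimes: 500 null families ×
  1000 permutations for family-wise error calibration, 500 replicates for
  slope recovery, 20 seeds for the planted-signal pipeline, ~10⁴ SNPs for
  Hardy–Weinberg calibration. These sizes give Monte-Carlo standard errors
  comfortably inside the asserted bands.
- Degenerate inputs fail loudly (`InputError`/`ConfigError`) rather than
  returning NaN: empty families, monomorphic SNPs, constant covariates,
  ragged motif alignments, zero pseudocounts.

## Known limitations

- The GSEA FDR q of the original desktop implementations depends on version-
  specific tie handling; values here agree in procedure, not to the digit,
  with any particular release, and reproducing a specific cohort's NES
  requires the original data.
- The r×c Fisher enumeration is exponential in table size; it is intended
  for the 2×3 / 2×5 tables of cohort work, not large sparse tables.
- The penalised-separation fallback in the logistic scan yields an
  approximate, flagged p; Firth regression would be a principled upgrade.
- `fold_change` reproduction from deposited MAS5 data may differ where the
  original pipeline averaged on the linear scale (see above).
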