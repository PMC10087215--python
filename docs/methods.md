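# Methods

`xlinker` analyses X-chromosome evolution in male-heterogametic (XX/X0 or
XY) genomes from three kinds of evidence: sequencing depth (males carry one
X copy, females two), population-genetic variation (the X has at most 3/4 of
the autosomal effective population size), and RNA-seq expression (dosage
compensation and sex-biased expression). This note records the models,
defaults and numerical choices, what the synthetic-data generators do and do
not emulate, and the design decisions taken where the procedure was
genuinely open.

## Coverage-based X classification

**Model.** For a scaffold of length L, a library of nominal depth d
contributes Poisson read counts with rate `d·(L/r)·(copy/2)·G·B`, where r is
the read length, copy is 1 for the X in males and 2 otherwise, G is a
scaffold-specific log-normal factor shared across libraries (GC-like
mappability bias; it cancels in male:female ratios but gives each sex's
depth distribution realistic width, σ = 0.1 by default), and B is a
gamma-distributed block-level bias. B's coefficient of variation is
`dispersion·sqrt(block/L)` with block = 1 kb and dispersion = 0.07: depth
bias acts at a kilobase correlation scale and averages out on long
scaffolds, which is what makes kilobase-scale scaffolds scatter between the
classification bands while multi-kilobase scaffolds classify cleanly. A
length-independent depth CV would contradict that routinely observed
pattern. The per-scaffold depth variance of real libraries is not a
published quantity; the dispersion default is a free parameter documented as
such.

**Procedure.**
1. *QC*: for each library, a length-weighted Gaussian KDE (Silverman
   bandwidth) of per-scaffold mean depth is searched for modes with
   prominence ≥ 10% of the peak density. Female libraries must show one
   dominant mode; male libraries one or two, and a secondary male mode must
   look like an X mode (position 0.3–0.7 of the autosomal mode, density
   ≤ 0.6 of it). This is an automated stand-in for visual inspection of
   coverage histograms; all thresholds are arguments.
2. *Normalization*: each passing library is divided by its own modal depth
   (for males, the higher-coverage = autosomal mode), the normalized values
   are summed per sex, and the sums are re-normalized by their mode. The
   per-library step makes the result exactly invariant to rescaling any
   single library; whether the original analyses normalized before or after
   summing is not derivable from their description, so this is our choice.
   Mean depth per scaffold is used throughout (not per-base histograms);
   scaffolds shorter than 1 kb are dropped.
3. *Ratio model*: the log2 male:female ratio density (length-weighted KDE)
   is searched for the autosomal peak (qualifying mode nearest 0) and the X
   peak (densest mode in [autosomal − 1.5, autosomal − 0.5]). If no X mode
   exists — e.g. a genome with no X-linked sequence — the X peak falls back
   to autosomal − 1 and the model is flagged.
4. *Calls*: liberal scheme, X iff ratio < autosomal peak − 0.5; stringent
   scheme, X iff within 0.1 of the X peak. The stringent scheme as published
   defines only the X band; we add the mirrored autosomal band (within 0.1
   of the autosomal peak) so that "unclassified" exists — this symmetric
   extension is ours. Zero-coverage scaffolds get no pseudocounts: their
   ratio is undefined and they stay unclassified, because pseudocounts
   distort the X band for short scaffolds.
5. *Corroboration*: males are hemizygous for the X, so the covered-site-
   weighted median heterozygous proportion of X-called scaffolds in males
   should be near the genotyping error rate; the call set is flagged if it
   exceeds 20% of the autosomal median.
6. *Anchoring*: calls can be transferred to a second assembly through
   alignment coordinate tables: query scaffolds with < 10 kb anchored are
   dropped; a reference scaffold is X-linked iff X-called queries cover more
   than twice the bases of A-called queries (mirrored for autosomal).

## Heterozygosity, diversity, Ne

Per-scaffold heterozygous/covered site counts (or per-scaffold π) are
consumed from upstream genotype-likelihood estimation (ANGSD-style; the
expected provenance includes a minimum depth of 5 and a maximum of twice the
median genome coverage — recorded here as metadata, not recomputed). Class
summaries are covered-site-weighted medians (short scaffolds are
repeat-enriched and unreliable, so they get little weight), with midpoint
interpolation at an exact half-weight split. Diversity uses female samples
only — male hemizygosity biases X heterozygosity directly and π indirectly —
and the module warns if the sex filter is disabled. Ne = π/(4μ), with the
fruit-fly (2.8e-9) and butterfly (2.9e-9) spontaneous mutation rates as the
conventional bracketing choices. Both per-sample and pooled summaries are
reported, since the published ratios could have been computed either way.

The neutral X:A expectation is checked with a pairwise coalescent oracle:
π is a pairwise quantity, so E[π] is exactly proportional to chromosomal
copy number and per-locus coalescence times T ~ Exp(mean ∝ copies) suffice —
no ancestral-recombination-graph machinery is needed. With copies 3:4,
E[π_X]/E[π_A] = 0.75 and μ cancels.

## Selection contrasts

dN/dS (computed upstream from sites under purifying selection or
neutrality), dN, dS and total divergence dN+dS are compared between X and
autosomal genes per species with two-sided Wilcoxon rank-sum tests, BH-
adjusted across species. The permutation ANOVA controls the dN/dS contrast
for GC content and log mean expression: an OLS fit of
`dnds ~ linkage + gc + log(expr)` gives the observed partial F for linkage,
whose null distribution comes from permuting the linkage labels
(Frisch–Waugh–Lovell residualization makes each permutation a vector
operation; algebraically identical to refitting). We permute raw labels
rather than residuals (Freedman–Lane): the simple scheme is what the name
"permutation ANOVA" most plainly denotes, and its exchangeability caveat —
covariates strongly associated with linkage weaken the null — is accepted
and documented. `p = (1+#{F ≥ F_obs})/(n_perm+1)` with n_perm ≥ 999.
Positive-selection enrichment is a two-sided Fisher exact test of the
upstream gene flags against linkage.

## Expression: normalization, dosage, sex bias

**Units.** TMM normalization factors follow the standard trimmed-mean-of-
M-values recipe (reference = library whose 75th count percentile is closest
to the panel mean; 30% two-sided trim on M, 5% on A; inverse-asymptotic-
variance weights; geometric mean rescaled to 1). The implementation was
checked against the canonical one and agrees to four decimals.
FPKM = count·1e9/(length·effective size); TPM rescales per-kilobase rates to
a million per library. Gene length is the merged-exon union, matching
exon-level read counting.

**Autosome-referenced normalization for dosage summaries.** When ~12% of
genes (the X) shift two-fold in one sex, whole-transcriptome TMM absorbs
part of that shift: the rank-based trim becomes asymmetric for the majority
class and the factors soak up ≈ +0.08 log2 of the signal (the canonical
implementation behaves identically — this is a property of the estimator,
not of this implementation). Because the X:A contrast is the quantity under
study, `dosage_panel` therefore computes TMM factors and library sizes from
autosome-called genes only by default (`normalize_on="autosomes"`), the
usual practice in the dosage-compensation literature; with it the
uncompensated X median recovers −1.00 ± 0.02 instead of −0.92.
`normalize_on="all"` restores plain whole-transcriptome TMM.

**Filter.** Genes with expression < 2 (FPKM or TPM) in ≥ 2 libraries of
either sex are excluded. The per-sex direction of the published rule is
ambiguous; the default either-sex reading also removes sex-limited genes,
consistent with the filter's stated purpose. `include_sex_limited=True`
switches to the both-sexes-fail variant, which retains genes expressed in
one sex only (the sensitivity analysis); their ratios are then ±∞ and are
capped at ±10 for summaries.

**Dosage.** Per gene, log2 of the arithmetic mean of male replicate
expression over the female mean (whether the original ratios used plain or
library-size-weighted means is unstated; arithmetic is our choice). Class
medians and an X-vs-A rank-sum test are computed per species × tissue cell,
BH-adjusted across the panel (gene-level tests form one family per
species × tissue; class-level tests one family across the panel). For
autosomes or a compensated X the median is ≈ 0; an uncompensated X gives
≈ −1 with the ratio histogram peaking at a two-fold male reduction.
`dc_type` separates compensation mechanisms via X:A expression per sex: male
X:A ≈ 1, female X:A ≈ 1 and X male:female ≈ 1 (all within 0.15 log2) is
type-I male hyper-transcription; male X:A ≈ 0.5 with female X:A ≈ 1 is
absence of compensation; X < A in both sexes is neither.

**NB-GLM tests.** Gene-wise sex effects (and species-by-sex interactions)
are tested with log-link NB2 GLMs (offset = log effective library size)
fitted by vectorized Fisher-scoring IRLS — the design matrix is shared
across genes, so each iteration is a batched small linear solve, which keeps
thousand-gene calibration runs cheap. Dispersions are estimated once per
gene (pooled method-of-moments across design cells), shrunk 70:30 toward a
binned-mean trend, and held fixed; the trend averages the raw,
sign-preserving moment estimates because their right-skewed sampling
distribution makes a median- or truncation-based trend biased low, which in
turn makes likelihood-ratio tests anticonservative. Nested models are
compared by LRT against chi-square. This is a documented approximation of
the standard count-model approach, validated by calibration and power on
synthetic data rather than numeric parity with any package: with the true
dispersion the null rejection rate at 0.05 is 0.050; with estimated
dispersions the null p-value KS statistic stays below 0.05 and false calls
at FDR 0.05 stay far below 7% of genes. Sex-biased genes: FDR < 0.05
(optionally also a two-fold change); interaction genes: FDR < 0.1.
Enrichment of sex-biased genes on the X, and underrepresentation of
species-by-sex interactions among sex-biased X genes, use Fisher exact
tests with BH across the panel.

## Multi-set ortholog overlap

The m-way intersection test is computed exactly: drawing m independent
uniform subsets of sizes s₁…s_m from a universe of n, the intersection after
adding set k is hypergeometric(n, x, s_k) given a current intersection of x,
so the full distribution is an iterated convolution. It is evaluated in log
space (log-sum-exp), so p-values far below the smallest positive float
survive; `log10_p` is reported alongside `p`, and the expected overlap is
n·∏(sᵢ/n) with fold enrichment observed/expected. With m = 2 the tail
reduces exactly to the hypergeometric survival function, which is one of the
test-suite oracles (the others: full enumeration for tiny universes and
Monte Carlo).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis relies on:
half-copy male X depth with realistic ratio-peak widths; reduced X
heterozygosity (default θ_A = 0.004, X:A ratio 0.3, within the
heterozygosity ratios observed in this system) and error-level male X
heterozygosity (2e-4); negative-binomial counts (dispersion 0.05, i.e.
biological CV ≈ 0.22 — the low end of what triplicate insect tissue samples
show) under per-tissue compensation regimes, with somatic tissues
compensated and the reproductive tract not, multiplicative sex-biased genes
(default 5% per direction, four-fold), species-specific sex effects for
interaction genes, and optional sex-limited genes (off by default); and
per-species X-ortholog sets sharing a 90% core. Defaults for panel geometry
follow the study design they emulate: 5000 scaffolds, 12% X by length,
nominal depth 20, four male and five female genomic libraries, five
species × three tissues × three RNA-seq replicates per sex, 8000 genes.

Not emulated: read-level artifacts (mapping ambiguity, reference bias,
duplicate reads), positional structure along chromosomes (no dosage
variation along the X), isoform structure, and correlated gene-gene
expression. Passing recovery tests therefore demonstrates that the
estimators are correct and calibrated under the assumed generative model,
not that real libraries are free of mapping pathologies — the QC stage and
the male-heterozygosity corroboration exist precisely because real data can
violate those assumptions. Every generated dataset ships a truth sidecar;
recovery tests compare against it, never against hard-coded numbers.

## Numerical conventions and degenerate inputs

- Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
  BED are converted at the I/O boundary.
- Weighted median: midpoint interpolation at an exact half split
  (deterministic and symmetric).
- Two-sided Fisher p: sum of table probabilities ≤ the observed table's
  (classical convention).
- Wilcoxon: exact enumeration only for untied pooled samples of ≤ 20;
  otherwise the tie- and continuity-corrected normal approximation (the
  tests run over thousands of genes; whether the original analyses used
  exact or approximate p-values is unknowable, so no numeric parity with a
  specific implementation is attempted).
- KDE degenerate inputs (near-constant values) collapse to a single mode at
  the weighted mean rather than failing.
- NB GLM: means clipped to [1e-10, 1e12], dispersions to [1e-6, 10],
  coefficients to ±50; a 1e-8 ridge stabilizes the batched solves; negative
  LRT statistics from converged-but-ties fits are clipped at zero.
- All generators take integer seeds (or a Generator) and are byte-
  deterministic given them; the pipeline writes a manifest with input
  checksums, config, seed and version for every run.

## Problem sizes

The test suite and the acceptance script run the study-condition defaults
where the quantity demands it (5000-scaffold coverage panel, 50,000
coalescent loci, 8000-gene expression panels) and smaller instances
(hundreds of scaffolds/genes) where the check is structural rather than
statistical; calibration loops use 20–200 replicate seeds at reduced gene
counts, sizes chosen so Monte-Carlo error stays well under the tolerances
being asserted.

## Known limitations

- The stringent scheme's autosomal band is our symmetric extension (see
  above); unclassified fractions under "stringent" are not comparable to
  implementations without an A band.
- TPM-based dosage summaries keep whole-transcriptome scaling and therefore
  retain the composition shift that autosome-referenced FPKM removes.
- The permutation ANOVA's simple label permutation assumes exchangeability;
  with covariates structurally tied to linkage, prefer residual-permutation
  schemes (not implemented).
- The NB-GLM dispersion estimator is moment-based; with < 3 replicates per
  cell it leans almost entirely on the trend.
- Upstream steps (mapping, genotype likelihoods, codon-model fits,
  whole-genome alignment) are consumed as tables, never recomputed.
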