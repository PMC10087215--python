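# xlinker

Identify the X chromosome in a fragmented genome assembly from sequencing
depth, and characterize its evolution: population-genetic variation,
protein-coding sequence evolution, dosage compensation, and sex-biased gene
expression.

The package is aimed at analyses of male-heterogametic systems (XX/X0 or
XY) where no chromosome-level assembly exists — e.g. non-model insects —
and the X must be recovered scaffold by scaffold from resequencing data of
both sexes.

## What it computes

**X-scaffold classification from depth.** Males carry one X copy, females
two, so for an X-linked scaffold the log2 ratio of modal-normalized
male:female coverage is ≈ −1 and for autosomes ≈ 0. After per-library QC
(coverage-distribution mode counting), depth is summed per sex, normalized
by the modal coverage, and the ratio density is fit by length-weighted KDE.
Scaffolds are called under a *liberal* rule (ratio < autosomal peak − 0.5)
and a *stringent* rule (within 0.1 of the X peak); calls propagate to genes
and can be anchored onto a second assembly through alignment coordinates
(≥ 10 kb anchored, X iff X-assigned queries cover > 2× the autosome-assigned
bases).

**Population genetics.** Covered-site-weighted medians of per-scaffold
heterozygosity or nucleotide diversity π by linkage class (females only for
diversity — males are hemizygous for the X), the X:A ratio, and effective
population sizes via π = 4·Ne·μ. Under neutrality with a balanced sex ratio
E[π_X]/E[π_A] = 3/4, a reference point the package verifies with a built-in
pairwise-coalescent simulation.

**Selection.** Per-species X-vs-autosome Wilcoxon contrasts of dN/dS, dN,
dS and dN+dS (BH across species), a permutation ANOVA for the linkage
effect on dN/dS controlling for GC and expression level, and Fisher tests
for positive-selection enrichment.

**Expression and dosage compensation.** TMM normalization, FPKM/TPM, the
low-expression filter (< 2 FPKM in ≥ 2 libraries per sex), per-gene log2
male:female ratios by linkage class (compensated X ≈ 0, uncompensated
X ≈ −1), gene-wise negative-binomial GLM likelihood-ratio tests for sex
bias (FDR < 0.05) and species-by-sex interactions (FDR < 0.1), Fisher
enrichment of sex-biased genes on the X, and inference of the compensation
type (e.g. male X hyper-transcription) from X:A expression per sex.

**Ortholog overlap.** An exact m-way set-intersection test (iterated
hypergeometric convolution in log space) for whether X-linked ortholog sets
are more conserved across species than chance allows.

Every input the pipeline consumes can also be *simulated* with known ground
truth (`xlinker.simulate`), which is how the test suite validates recovery,
calibration and power.

## Worked example

```python
from xlinker import simulate, coverage as cov, popgen

# a 5000-scaffold assembly, 12% X by length, 4 male + 5 female libraries
g = simulate.simulate_genome(n_scaffolds=5000, x_fraction=0.12, seed=1)
cm = cov.qc_all_samples(simulate.simulate_coverage(g, mean_depth=20.0, seed=2))
norm = cov.sex_summed_normalized_coverage(cm)
ratios = cov.log2_mf_ratio(norm)
model = cov.find_ratio_peaks(ratios, norm["length"])
calls = cov.classify_scaffolds(ratios, model)
is_x = calls["call_liberal"] == "X"
x_frac = norm.loc[is_x, "length"].sum() / norm["length"].sum()
print(f"autosomal peak {model.autosomal_peak:+.3f}, X peak {model.x_peak:+.3f}")
print(f"{is_x.sum()} scaffolds called X-linked ({100*x_frac:.1f}% of assembly length)")

het = simulate.simulate_het_sites(g, theta_A=0.004, x_ratio=0.3, seed=3)
summary = popgen.summarize_diversity(het, calls, mu=2.8e-9, sex="F")
pooled = summary[summary["sample"] == "pooled"].iloc[0]
print(f"X:A heterozygosity ratio {pooled['ratio']:.2f}; "
      f"Ne_A {pooled['ne_A']:,.0f}, Ne_X {pooled['ne_X']:,.0f}")
```

Output:

```
autosomal peak +0.012, X peak -0.990
660 scaffolds called X-linked (12.0% of assembly length)
X:A heterozygosity ratio 0.29; Ne_A 355,720, Ne_X 103,270
```

The ratio peaks sit at 0 and −1 as copy number predicts; the called X
fraction matches the simulated 12%; the recovered X:A heterozygosity ratio
matches the generating value 0.3 and lies below the neutral 0.75, as
expected when diversity on the X is further reduced; and Ne follows from
π/(4μ) at the fruit-fly mutation rate.

The same stages are exposed as a CLI for file-based runs:

```sh
xlinker simulate --out sim/ --seed 1
xlinker classify-x --coverage sim/coverage.tsv --samples sim/samples.tsv --out calls/
xlinker popgen --het sim/het.tsv --calls calls/calls.tsv --mu 2.8e-9 --out pg/
xlinker run --config config.yaml --out run/      # multi-stage, with manifest
```

See `docs/methods.md` for the models, defaults and design decisions.

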