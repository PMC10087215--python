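"""Dosage-compensation and sex-biased-expression analysis from RNA-seq counts.

The chain mirrors standard count-based differential-expression practice:
TMM normalization factors, FPKM/TPM expression units, a low-expression filter
(< 2 FPKM in 2 or more libraries per sex) whose default direction also
removes sex-limited genes, per-gene log2 male:female mean-expression ratios
contrasted between X and autosomes, gene-wise NB-GLM likelihood-ratio tests
for sex effects (FDR < 0.05) and species-by-sex interactions (FDR < 0.1),
Fisher enrichment of sex-biased genes by linkage, and inference of the
dosage-compensation type from X:A expression levels in each sex.

Interpretation anchors: for autosomal genes, or X genes in a tissue with
complete dosage compensation, log2(M/F) ~ 0; an uncompensated X gives ~ -1
(two-fold male reduction, one X copy transcribed at the baseline rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nbglm
from .stats import bh_adjust, fisher_exact_2x2, wilcoxon_rank_sum

__all__ = [
    "tmm_factors",
    "effective_sizes",
    "autosomal_effective_sizes",
    "normalize",
    "filter_expressed",
    "log2_mf_expression",
    "DosageSummary",
    "dosage_summary",
    "dosage_panel",
    "sex_bias_test",
    "interaction_test",
    "bias_enrichment",
    "interaction_underrepresentation",
    "dc_type",
    "ratio_histogram",
]

RATIO_CAP = 10.0


def _counts_only(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.drop(columns=["length"], errors="ignore")


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference library is the one whose 75th count percentile (scaled by
    library size) is closest to the panel mean. For each library, genes with
    zero counts in either library are dropped, the most extreme ``trim_m`` of
    log-ratios (each tail) and ``trim_a`` of average log-intensities are
    trimmed, and the factor is two to the inverse-variance-weighted mean of
    the remaining log-ratios. Factors are rescaled to geometric mean 1, so
    ``library size x factor`` is the effective library size.
    """
    y = _counts_only(counts)
    lib = y.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("library with zero total counts")
    if y.shape[1] < 2:
        raise ValueError("need at least two libraries")
    f75 = np.quantile(y.to_numpy(float) / lib.to_numpy(), 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = y.columns[ref_idx]
    yr = y[ref].to_numpy(float)
    nr = float(lib[ref])
    factors = {}
    for col in y.columns:
        yk = y[col].to_numpy(float)
        nk = float(lib[col])
        ok = (yk > 0) & (yr > 0)
        if col == ref or ok.sum() == 0:
            factors[col] = 1.0
            continue
        pk, pr = yk[ok] / nk, yr[ok] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = 1.0 / ((nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok]))
        nn = m.size
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = ((rm > nn * trim_m) & (rm < nn * (1 - trim_m) + 1)
                & (ra > nn * trim_a) & (ra < nn * (1 - trim_a) + 1))
        if keep.sum() == 0:
            keep = np.ones(nn, dtype=bool)
        f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        factors[col] = 1.0 if abs(f) < 1e-10 else float(2.0 ** f)
    fac = pd.Series(factors)[y.columns]
    fac = fac / np.exp(np.mean(np.log(fac)))
    return fac


def effective_sizes(counts: pd.DataFrame,
                    factors: pd.Series | None = None) -> pd.Series:
    y = _counts_only(counts)
    if factors is None:
        factors = tmm_factors(counts)
    return y.sum(axis=0).astype(float) * factors


def autosomal_effective_sizes(counts: pd.DataFrame,
                              linkage: pd.Series) -> pd.Series:
    """TMM effective library sizes computed from autosome-called genes only.

    Normalizing against the autosomes is the appropriate reference when the
    quantity of interest is X:autosome (or male:female X) relative
    expression: if a sizeable gene class (the X, ~12% of genes) shifts in one
    direction in one sex, whole-transcriptome TMM absorbs part of that shift
    into the factors — the rank-based trim becomes asymmetric for the
    majority class — compressing the very signal being measured. Factors and
    library sizes are both computed on the autosomal subset, so the result is
    an unbiased scale for relative comparisons.
    """
    is_a = (linkage.reindex(_counts_only(counts).index) == "A").to_numpy()
    if is_a.sum() < 100:
        raise ValueError("need at least 100 autosome-called genes to normalize")
    sub = counts.loc[is_a]
    return effective_sizes(sub, tmm_factors(sub))


def normalize(counts: pd.DataFrame, lengths: pd.Series | None = None,
              factors: pd.Series | None = None,
              eff_sizes: pd.Series | None = None,
              unit: str = "FPKM") -> pd.DataFrame:
    """FPKM or TPM matrix from raw counts.

    FPKM = count * 1e9 / (length * effective library size), with the
    TMM-adjusted effective size (or ``eff_sizes`` supplied directly, e.g.
    from :func:`autosomal_effective_sizes`). TPM rescales per-kilobase rates
    so each column sums to one million (computed from raw counts; the
    within-library proportions are unaffected by a global size factor).
    """
    if lengths is None:
        if "length" not in counts.columns:
            raise ValueError("gene lengths required (column 'length' or argument)")
        lengths = counts["length"]
    y = _counts_only(counts)
    L = lengths.reindex(y.index).to_numpy(float)
    if np.any(L <= 0):
        raise ValueError("gene lengths must be positive")
    if unit.upper() == "FPKM":
        if eff_sizes is None:
            eff_sizes = effective_sizes(counts, factors)
        eff = eff_sizes.reindex(y.columns).to_numpy(float)
        if np.any(eff <= 0):
            raise ValueError("zero effective library size")
        return y * 1e9 / (L[:, None] * eff[None, :])
    if unit.upper() == "TPM":
        rate = y.to_numpy(float) / L[:, None]
        return pd.DataFrame(rate / rate.sum(axis=0, keepdims=True) * 1e6,
                            index=y.index, columns=y.columns)
    raise ValueError(f"unknown unit {unit!r}")


def filter_expressed(expr: pd.DataFrame, design: pd.DataFrame,
                     threshold: float = 2.0, min_low_libs: int = 2,
                     include_sex_limited: bool = False) -> pd.Series:
    """Boolean mask of genes passing the low-expression filter.

    Default: a gene is excluded when, in either sex, at least ``min_low_libs``
    libraries fall below ``threshold`` — this removes lowly expressed genes
    and, deliberately, sex-limited ones. With ``include_sex_limited=True`` a
    gene is excluded only when both sexes fail, which retains genes expressed
    in one sex only (the sensitivity-analysis variant).
    """
    sexes = design.loc[expr.columns, "sex"]
    for sex in ("M", "F"):
        if (sexes == sex).sum() < min_low_libs:
            raise ValueError(f"need >= {min_low_libs} libraries of sex {sex}")
    low = expr < threshold
    n_low_m = low.loc[:, (sexes == "M").to_numpy()].sum(axis=1)
    n_low_f = low.loc[:, (sexes == "F").to_numpy()].sum(axis=1)
    fail_m = n_low_m >= min_low_libs
    fail_f = n_low_f >= min_low_libs
    if include_sex_limited:
        return ~(fail_m & fail_f)
    return ~(fail_m | fail_f)


def log2_mf_expression(expr: pd.DataFrame, design: pd.DataFrame,
                       cap: float = RATIO_CAP) -> pd.Series:
    """Per-gene log2 of mean male over mean female expression.

    Means are arithmetic over replicate libraries. A zero mean in one sex
    (possible only when sex-limited genes are retained) gives ±``cap``; zero
    in both gives NaN.
    """
    sexes = design.loc[expr.columns, "sex"]
    mean_m = expr.loc[:, (sexes == "M").to_numpy()].mean(axis=1)
    mean_f = expr.loc[:, (sexes == "F").to_numpy()].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(mean_m / mean_f)
    r = np.where((mean_m > 0) & (mean_f == 0), cap, r)
    r = np.where((mean_m == 0) & (mean_f > 0), -cap, r)
    r = np.where((mean_m == 0) & (mean_f == 0), np.nan, r)
    return pd.Series(r, index=expr.index, name="log2_mf")


@dataclass
class DosageSummary:
    species: str | None
    tissue: str | None
    median_A: float
    median_X: float
    p: float
    n_A: int
    n_X: int
    per_gene: pd.DataFrame = field(repr=False)


def dosage_summary(expr: pd.DataFrame, linkage: pd.Series, design: pd.DataFrame,
                   tissue: str | None = None, species: str | None = None,
                   ) -> DosageSummary:
    """X-vs-A contrast of per-gene log2 male:female expression ratios.

    ``expr`` should already be normalized and filtered; ``linkage`` maps genes
    to 'A'/'X'. Subsets libraries to the requested tissue/species, computes
    per-gene ratios, class medians, and the two-sided rank-sum p for the X-A
    difference.
    """
    libs = design.index.intersection(expr.columns)
    sub = design.loc[libs]
    if tissue is not None:
        if tissue not in set(sub["tissue"]):
            raise ValueError(f"tissue {tissue!r} absent from design")
        sub = sub[sub["tissue"] == tissue]
    if species is not None:
        sub = sub[sub["species"] == species]
    ratios = log2_mf_expression(expr[sub.index], sub)
    per_gene = pd.DataFrame({"log2_mf": ratios,
                             "linkage": linkage.reindex(ratios.index)})
    per_gene = per_gene[per_gene["linkage"].isin(["A", "X"])
                        & np.isfinite(per_gene["log2_mf"])]
    a = per_gene.loc[per_gene["linkage"] == "A", "log2_mf"].to_numpy()
    x = per_gene.loc[per_gene["linkage"] == "X", "log2_mf"].to_numpy()
    if a.size == 0 or x.size == 0:
        raise ValueError("empty linkage class after filtering")
    _, p = wilcoxon_rank_sum(x, a)
    return DosageSummary(species=species, tissue=tissue,
                         median_A=float(np.median(a)),
                         median_X=float(np.median(x)), p=p,
                         n_A=a.size, n_X=x.size, per_gene=per_gene)


def dosage_panel(counts: pd.DataFrame, linkage: pd.Series, design: pd.DataFrame,
                 unit: str = "FPKM", threshold: float = 2.0,
                 min_low_libs: int = 2, include_sex_limited: bool = False,
                 normalize_on: str = "autosomes") -> pd.DataFrame:
    """Dosage summaries for every species x tissue cell, BH across the panel.

    Normalization, filtering and the ratio contrast are run independently per
    cell (each cell is its own expression experiment); the rank-sum p-values
    are then adjusted across the whole panel. With the default
    ``normalize_on='autosomes'`` FPKM effective sizes come from
    :func:`autosomal_effective_sizes`, which keeps a sex-specific shift of the
    whole X class (the signal under study) out of the normalization factors;
    ``normalize_on='all'`` uses whole-transcriptome TMM.
    """
    if normalize_on not in {"autosomes", "all"}:
        raise ValueError(f"unknown normalize_on {normalize_on!r}")
    rows = []
    for (sp, tis), sub in design.groupby(["species", "tissue"], sort=True):
        cell = counts[["length", *sub.index]] if "length" in counts.columns \
            else counts[sub.index]
        eff = None
        if normalize_on == "autosomes" and unit.upper() == "FPKM":
            eff = autosomal_effective_sizes(cell, linkage)
        expr = normalize(cell, eff_sizes=eff, unit=unit)
        mask = filter_expressed(expr, sub, threshold=threshold,
                                min_low_libs=min_low_libs,
                                include_sex_limited=include_sex_limited)
        ds = dosage_summary(expr[mask], linkage, sub, tissue=tis, species=sp)
        rows.append({"species": sp, "tissue": tis, "median_A": ds.median_A,
                     "median_X": ds.median_X, "p": ds.p,
                     "n_A": ds.n_A, "n_X": ds.n_X})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def _sex_design(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sex = (design["sex"] == "M").to_numpy(float)
    X_full = np.column_stack([np.ones(len(design)), sex])
    X_red = np.ones((len(design), 1))
    return X_full, X_red


def sex_bias_test(counts: pd.DataFrame, design: pd.DataFrame,
                  fdr: float = 0.05, fold_rule: bool = False,
                  dispersion: np.ndarray | None = None) -> pd.DataFrame:
    """Gene-wise NB-GLM likelihood-ratio test for a sex effect on expression.

    One species x tissue panel. Offsets are log TMM-effective library sizes;
    dispersions are estimated from the data unless supplied. Genes with
    q < ``fdr`` are classed male-/female-biased by the sign of the log2 fold
    change (male over female); with ``fold_rule`` a two-fold change is also
    required. All other genes are unbiased.
    """
    sub = design.loc[design.index.intersection(counts.columns)]
    for sex in ("M", "F"):
        if (sub["sex"] == sex).sum() < 2:
            raise ValueError("need at least two replicates per sex")
    y = _counts_only(counts)[sub.index].to_numpy(float)
    eff = effective_sizes(counts[sub.index] if "length" not in counts.columns
                          else counts[["length", *sub.index]])
    offset = np.log(eff.to_numpy())
    X_full, X_red = _sex_design(sub)
    if dispersion is None:
        dispersion = nbglm.estimate_dispersion(
            y, sub["sex"].to_numpy(), eff.to_numpy())
    beta, stat, p = nbglm.nb_lrt(y, X_full, X_red, offset, dispersion)
    log2fc = beta[:, 1] / np.log(2.0)
    q = bh_adjust(p)
    called = q < fdr
    if fold_rule:
        called = called & (np.abs(log2fc) > 1.0)
    cls = np.where(called & (log2fc > 0), "male_biased",
                   np.where(called & (log2fc < 0), "female_biased", "unbiased"))
    return pd.DataFrame({"log2fc": log2fc, "lrt": stat, "p": p, "q": q,
                         "class": cls}, index=counts.index)


def interaction_test(counts: pd.DataFrame, design: pd.DataFrame,
                     fdr: float = 0.1,
                     dispersion: np.ndarray | None = None) -> pd.DataFrame:
    """NB-GLM test of the species-by-sex interaction for matched orthologs.

    One tissue across several species: full model sex + species + sex:species
    versus the additive reduced model; genes with interaction q < ``fdr``
    (0.1 by default) are flagged as having species-specific sex effects.
    """
    sub = design.loc[design.index.intersection(counts.columns)]
    species = sorted(sub["species"].unique())
    if len(species) < 2:
        raise ValueError("interaction test needs at least two species")
    sex = (sub["sex"] == "M").to_numpy(float)
    sp_dummies = np.column_stack([(sub["species"] == s).to_numpy(float)
                                  for s in species[1:]])
    X_red = np.column_stack([np.ones(len(sub)), sex, sp_dummies])
    X_full = np.column_stack([X_red, sp_dummies * sex[:, None]])
    y = _counts_only(counts)[sub.index].to_numpy(float)
    eff = effective_sizes(counts[["length", *sub.index]]
                          if "length" in counts.columns else counts[sub.index])
    offset = np.log(eff.to_numpy())
    if dispersion is None:
        cells = (sub["species"].astype(str) + ":" + sub["sex"].astype(str))
        dispersion = nbglm.estimate_dispersion(y, cells.to_numpy(),
                                               eff.to_numpy())
    _, stat, p = nbglm.nb_lrt(y, X_full, X_red, offset, dispersion)
    q = bh_adjust(p)
    return pd.DataFrame({"lrt": stat, "p": p, "q": q,
                         "interaction": q < fdr}, index=counts.index)


def bias_enrichment(calls: pd.DataFrame, linkage: pd.Series) -> pd.DataFrame:
    """Fisher enrichment of sex-biased genes on the X, per panel and direction.

    ``calls`` is a long frame with columns species, tissue, gene, class
    (male_biased / female_biased / unbiased). For each species x tissue x
    direction a 2x2 table (direction membership x X-linkage) is tested;
    BH adjustment spans all rows.
    """
    rows = []
    for (sp, tis), sub in calls.groupby(["species", "tissue"], sort=True):
        link = sub["gene"].map(linkage)
        keep = link.isin(["A", "X"]).to_numpy()
        sub, link = sub[keep], link[keep]
        is_x = (link == "X").to_numpy()
        for direction in ("male_biased", "female_biased"):
            d = (sub["class"] == direction).to_numpy()
            table = [[int((d & is_x).sum()), int((d & ~is_x).sum())],
                     [int((~d & is_x).sum()), int((~d & ~is_x).sum())]]
            odds, p = fisher_exact_2x2(table)
            n_x, n_a = int(is_x.sum()), int((~is_x).sum())
            rows.append({
                "species": sp, "tissue": tis, "direction": direction,
                "prop_X": table[0][0] / n_x if n_x else 0.0,
                "prop_A": table[0][1] / n_a if n_a else 0.0,
                "odds_ratio": odds, "p": p,
            })
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def interaction_underrepresentation(bias: pd.DataFrame,
                                    interaction: pd.Series,
                                    linkage: pd.Series) -> dict:
    """Fisher test: are sex-biased X genes depleted of species-by-sex interactions?

    ``bias`` is one tissue's call table (gene, class); genes classed as
    sex-biased are cross-tabulated by linkage and interaction flag. Consistent
    male:female differences across species (as expected from a shared
    uncompensated X) show up as underrepresentation (odds ratio < 1).
    """
    biased = bias[bias["class"].isin(["male_biased", "female_biased"])]
    link = biased["gene"].map(linkage) if "gene" in biased.columns \
        else biased.index.map(linkage)
    inter = (biased["gene"].map(interaction) if "gene" in biased.columns
             else biased.index.map(interaction)).astype(bool)
    is_x = (pd.Series(link).reset_index(drop=True) == "X").to_numpy()
    inter = pd.Series(inter).reset_index(drop=True).to_numpy()
    table = [[int((inter & is_x).sum()), int((inter & ~is_x).sum())],
             [int((~inter & is_x).sum()), int((~inter & ~is_x).sum())]]
    odds, p = fisher_exact_2x2(table)
    return {"table": table, "odds_ratio": odds, "p": p}


def dc_type(expr: pd.DataFrame, linkage: pd.Series, design: pd.DataFrame,
            tissue: str | None = None, tol: float = 0.15) -> dict:
    """Infer the dosage-compensation mechanism from X:A expression levels.

    Computes, per sex, the median X-gene expression over the median autosomal
    expression (gene means across that sex's libraries), plus the median
    male:female ratio on the X. Complete compensation by male X
    hyper-transcription ("type I") leaves all three near 1 (within ``tol`` on
    the log2 scale): the single male X is up-regulated rather than both
    sexes' X being shifted.
    """
    sub = design.loc[design.index.intersection(expr.columns)]
    if tissue is not None:
        sub = sub[sub["tissue"] == tissue]
    link = linkage.reindex(expr.index)
    res = {}
    for sex in ("M", "F"):
        libs = sub.index[sub["sex"] == sex]
        means = expr[libs].mean(axis=1)
        med_x = float(means[link == "X"].median())
        med_a = float(means[link == "A"].median())
        res[f"xa_{sex}"] = med_x / med_a if med_a > 0 else np.inf
    ratios = log2_mf_expression(expr[sub.index], sub)
    res["x_log2_mf"] = float(ratios[link == "X"].median())
    lx_m = np.log2(res["xa_M"])
    lx_f = np.log2(res["xa_F"])
    if abs(lx_m) <= tol and abs(lx_f) <= tol and abs(res["x_log2_mf"]) <= tol:
        label = "type_I_male_hypertranscription"
    elif lx_m < -tol and abs(lx_f) <= tol:
        label = "no_compensation_male_X_reduced"
    elif lx_m < -tol and lx_f < -tol:
        label = "X_reduced_in_both_sexes"
    else:
        label = "other"
    res["label"] = label
    return res


def ratio_histogram(ratios: pd.Series, bins: int = 60,
                    lo: float = -4.0, hi: float = 4.0) -> pd.DataFrame:
    """Histogram of log2 M:F ratios as a table (for export/plotting)."""
    r = ratios.to_numpy(dtype=float)
    r = r[np.isfinite(r)]
    counts, edges = np.histogram(r, bins=bins, range=(lo, hi))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
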