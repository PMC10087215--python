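"""Molecular-evolution contrasts between X-linked and autosomal genes.

Consumes a per-gene table of branch statistics (dN/dS computed from sites
under purifying selection or neutrality, dN, dS, a positive-selection flag
from upstream codon-model comparisons, GC content and mean expression) and
asks whether the X differs from the autosomes: rank-sum contrasts of dN/dS,
dN, dS and total divergence (dN + dS) per species with BH adjustment across
species; a permutation ANOVA testing whether the linkage effect on dN/dS
survives controlling for GC and expression level; and a Fisher test for
enrichment of positively selected genes on the X.

The permutation ANOVA permutes the linkage labels directly (the simple
scheme): the observed partial F for linkage in an OLS fit of
``dnds ~ linkage + covariates`` is compared with its distribution over label
permutations. Exchangeability of labels is assumed; covariates strongly
correlated with linkage weaken that assumption.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact_2x2, wilcoxon_rank_sum

__all__ = [
    "gc_content",
    "compare_branch_stats",
    "permutation_anova",
    "pos_sel_enrichment",
]

_STATS = {"dnds", "dn", "ds", "dn_plus_ds"}


def gc_content(sequence: str) -> float:
    """GC proportion of a nucleotide sequence, ignoring ambiguity codes.

    (G+C) / (A+C+G+T), case-insensitive; characters outside ACGT (N, IUPAC
    ambiguity codes, gaps) are excluded from the denominator.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous nucleotides in sequence")
    return gc / (gc + at)


def compare_branch_stats(table: pd.DataFrame, stat: str = "dnds",
                         min_genes: int = 20) -> pd.DataFrame:
    """Per-species X-vs-A rank-sum contrast of a branch statistic.

    ``table`` columns: species, linkage ('A'/'X') and the statistic columns
    (``dn_plus_ds`` is derived from dn + ds). Returns one row per species with
    class medians, the Wilcoxon p, BH q across species, and the direction of
    the difference ('X>A', 'X<A' or 'none').
    """
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {sorted(_STATS)}")
    df = table.copy()
    if stat == "dn_plus_ds":
        df[stat] = df["dn"] + df["ds"]
    rows = []
    for sp, sub in df.groupby("species", sort=True):
        x = sub.loc[sub["linkage"] == "X", stat].dropna().to_numpy()
        a = sub.loc[sub["linkage"] == "A", stat].dropna().to_numpy()
        if len(x) < min_genes or len(a) < min_genes:
            raise ValueError(f"species {sp!r}: fewer than {min_genes} genes in a class")
        _, p = wilcoxon_rank_sum(x, a)
        med_x, med_a = float(np.median(x)), float(np.median(a))
        direction = "X>A" if med_x > med_a else ("X<A" if med_x < med_a else "none")
        rows.append({"species": sp, "stat": stat, "median_A": med_a,
                     "median_X": med_x, "p": p, "direction": direction,
                     "n_A": len(a), "n_X": len(x)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def permutation_anova(y, linkage, covariates: pd.DataFrame | np.ndarray,
                      n_perm: int = 999, seed=None) -> dict:
    """Permutation test of the linkage effect on a response, given covariates.

    Fits ``y ~ linkage + covariates`` by OLS and computes the partial F for
    linkage; the null distribution comes from ``n_perm`` random permutations
    of the linkage labels (covariates fixed), using the Frisch–Waugh–Lovell
    residualization so each permutation is a vector operation.
    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")
    y = np.asarray(y, dtype=float)
    link = np.asarray(linkage)
    if np.unique(link).size < 2:
        raise ValueError("linkage labels are constant")
    l = (link == link[0]).astype(float) if link.dtype.kind in "OUS" \
        else link.astype(float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(C)):
        raise ValueError("response/covariates contain missing values")
    n = y.size
    C1 = np.column_stack([np.ones(n), C])
    pinv = np.linalg.pinv(C1)
    e_y = y - C1 @ (pinv @ y)
    p_full = C1.shape[1] + 1

    def partial_f(lvec_resid: np.ndarray) -> float:
        sll = float(lvec_resid @ lvec_resid)
        if sll <= 0:
            return 0.0
        beta = float(lvec_resid @ e_y) / sll
        rss_full = float(e_y @ e_y) - beta**2 * sll
        rss_red = float(e_y @ e_y)
        return (rss_red - rss_full) / (rss_full / (n - p_full))

    e_l = l - C1 @ (pinv @ l)
    f_obs = partial_f(e_l)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.array([rng.permutation(l) for _ in range(n_perm)])
    E = perms - (perms @ pinv.T) @ C1.T
    sll = np.einsum("ij,ij->i", E, E)
    sly = E @ e_y
    syy = float(e_y @ e_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_full = syy - np.where(sll > 0, sly**2 / sll, 0.0)
        f_perm = (syy - rss_full) / (rss_full / (n - p_full))
    f_perm = np.nan_to_num(f_perm, nan=0.0)
    p = (1.0 + np.sum(f_perm >= f_obs)) / (n_perm + 1.0)
    return {"f_obs": f_obs, "p": float(p), "n_perm": n_perm}


def pos_sel_enrichment(table: pd.DataFrame) -> dict:
    """Fisher test of positively selected gene enrichment on the X.

    ``table`` columns: linkage ('A'/'X'), pos_sel (bool). Returns per-class
    proportions and the two-sided Fisher p.
    """
    sub = table[table["linkage"].isin(["A", "X"])]
    pos = sub["pos_sel"].astype(bool)
    is_x = sub["linkage"] == "X"
    a = int((pos & is_x).sum())
    b = int((pos & ~is_x).sum())
    c = int((~pos & is_x).sum())
    d = int((~pos & ~is_x).sum())
    n_x, n_a = a + c, b + d
    odds, p = fisher_exact_2x2([[a, b], [c, d]])
    return {
        "prop_X": a / n_x if n_x else 0.0,
        "prop_A": b / n_a if n_a else 0.0,
        "odds_ratio": odds,
        "p": p,
        "table": [[a, b], [c, d]],
    }
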