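"""X-versus-autosome contrasts of heterozygosity and nucleotide diversity.

Summaries use covered-site-weighted medians across scaffolds, because short
scaffolds are typically repeat-enriched and give unreliable estimates.
Diversity-based quantities (pi and the derived effective population size
Ne = pi / (4 mu)) should be computed from female samples only: males are
hemizygous for the X, which biases X heterozygosity directly and pi
indirectly.

The module consumes per-scaffold heterozygous/covered site counts (or pi and
site counts) produced upstream by genotype-likelihood machinery (ANGSD-style,
typically with a minimum depth of 5 and a maximum of twice the median genome
coverage); that estimation itself is out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import weighted_median

__all__ = [
    "ClassSummary",
    "het_proportion",
    "class_summary",
    "estimate_ne",
    "neutral_xa_expectation_check",
    "summarize_diversity",
]

#: spontaneous per-site mutation rates used for Ne: fruit fly and butterfly
MU_DMEL = 2.8e-9
MU_HMEL = 2.9e-9


@dataclass(frozen=True)
class ClassSummary:
    median_A: float
    median_X: float

    @property
    def ratio(self) -> float:
        return self.median_X / self.median_A if self.median_A > 0 else np.inf


def het_proportion(het_sites, covered_sites) -> np.ndarray:
    """Proportion of heterozygous sites per scaffold (NaN when uncovered)."""
    h = np.asarray(het_sites, dtype=float)
    c = np.asarray(covered_sites, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(c > 0, h / c, np.nan)


def class_summary(values, weights, linkage, min_scaffolds: int = 10,
                  ) -> ClassSummary:
    """Weighted-median summary of a per-scaffold statistic by linkage class."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    link = np.asarray(linkage)
    ok = np.isfinite(v) & (w > 0)
    med = {}
    for cls in ("A", "X"):
        sel = ok & (link == cls)
        if sel.sum() < min_scaffolds:
            raise ValueError(f"class {cls} has fewer than {min_scaffolds} scaffolds")
        med[cls] = weighted_median(v[sel], w[sel])
    return ClassSummary(median_A=med["A"], median_X=med["X"])


def estimate_ne(pi: float, mu: float) -> float:
    """Effective population size from nucleotide diversity: Ne = pi / (4 mu)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if pi < 0:
        raise ValueError("pi must be nonnegative")
    return pi / (4.0 * mu)


def neutral_xa_expectation_check(pi_A, pi_X) -> float:
    """mean(pi_X) / mean(pi_A) for coalescent-simulated per-locus diversities."""
    return float(np.mean(pi_X) / np.mean(pi_A))


def summarize_diversity(table: pd.DataFrame, calls: pd.DataFrame,
                        samples: pd.DataFrame | None = None,
                        call_col: str = "call_liberal", sex: str | None = "F",
                        mode: str = "per_sample", mu: float = MU_DMEL,
                        min_scaffolds: int = 10) -> pd.DataFrame:
    """Per-sample (or pooled) X:A weighted-median diversity summary.

    ``table`` is a long frame with columns ``scaffold``, ``sample`` and either
    ``het_sites``/``covered_sites`` or ``pi``/``sites``. ``calls`` maps
    scaffolds to linkage. With ``mode='per_sample'`` one row per sample is
    returned plus a ``pooled`` row over all retained observations; with
    ``mode='pooled'`` only the pooled row. Each row carries medians, the X:A
    ratio, and Ne estimates (median / (4 mu)).

    ``sex`` filters samples (default females only, the appropriate choice for
    pi); passing ``sex=None`` disables the filter with a warning.
    """
    if mode not in {"per_sample", "pooled"}:
        raise ValueError(f"unknown mode {mode!r}")
    if {"het_sites", "covered_sites"}.issubset(table.columns):
        value_col, weight_col = "het_sites", "covered_sites"
        values = het_proportion(table["het_sites"], table["covered_sites"])
    elif {"pi", "sites"}.issubset(table.columns):
        value_col, weight_col = "pi", "sites"
        values = table["pi"].to_numpy(dtype=float)
    else:
        raise ValueError("table needs het_sites/covered_sites or pi/sites columns")
    df = table.copy()
    df["_value"] = values
    df["_weight"] = df[weight_col].astype(float)
    if sex is None:
        warnings.warn("no sex filter applied; X diversity from male samples "
                      "is biased by hemizygosity", stacklevel=2)
    else:
        if "sex" in df.columns:
            df = df[df["sex"] == sex]
        elif samples is not None and "sex" in samples.columns:
            df = df[df["sample"].map(samples["sex"]) == sex]
        else:
            raise ValueError("cannot filter by sex: no sex column or sample sheet")
        if df.empty:
            raise ValueError(f"no samples of sex {sex!r}")
    df["_linkage"] = df["scaffold"].map(
        calls[call_col] if call_col in calls.columns else calls)
    df = df[df["_linkage"].isin(["A", "X"]) & (df["_weight"] > 0)
            & np.isfinite(df["_value"])]

    def _row(sub: pd.DataFrame, label: str) -> dict:
        cs = class_summary(sub["_value"], sub["_weight"], sub["_linkage"],
                           min_scaffolds=min_scaffolds)
        return {"sample": label, "median_A": cs.median_A,
                "median_X": cs.median_X, "ratio": cs.ratio,
                "ne_A": estimate_ne(cs.median_A, mu),
                "ne_X": estimate_ne(cs.median_X, mu), "mu": mu}

    rows = []
    if mode == "per_sample":
        for smp, sub in df.groupby("sample", sort=True):
            rows.append(_row(sub, str(smp)))
    rows.append(_row(df, "pooled"))
    return pd.DataFrame(rows)
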