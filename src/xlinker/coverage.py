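"""Identify X-linked scaffolds from sex-labeled sequencing depth.

In an XX/X0 (or XY) system males carry a single X while females carry two, so
X-linked scaffolds show half the male read depth of autosomes. The workflow:

1. per-library QC on the per-scaffold depth distribution (females should show
   one dominant coverage mode, males one autosomal mode plus an X mode at half
   depth);
2. sum depth across passing libraries per sex and normalize each sex by its
   modal (autosomal) coverage;
3. take the per-scaffold log2 male:female ratio, locate the autosomal (~0) and
   X (~-1) peaks of its length-weighted density;
4. call scaffolds under a liberal rule (ratio < autosomal peak - 0.5) and a
   stringent rule (within 0.1 of the X peak), propagate calls to genes, and
   optionally anchor calls onto a second assembly through alignment
   coordinates.

Modes are found on a length-weighted Gaussian KDE (Silverman bandwidth);
peaks below 10% of the maximum density are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .stats import weighted_median

__all__ = [
    "CoverageMatrix",
    "RatioModel",
    "qc_sample_coverage",
    "qc_all_samples",
    "sex_summed_normalized_coverage",
    "log2_mf_ratio",
    "find_ratio_peaks",
    "classify_scaffolds",
    "male_x_heterozygosity_check",
    "assign_genes",
    "anchor_scaffolds",
]

PROMINENCE_FRAC = 0.10


@dataclass
class CoverageMatrix:
    """Per-scaffold mean depth for a panel of sex-labeled libraries.

    ``depths`` is indexed by scaffold id with one column per library;
    ``lengths`` gives scaffold lengths (bp); ``samples`` is indexed by library
    id with at least a ``sex`` column ('M'/'F') and, once QC has run, a
    boolean ``qc_pass`` column.
    """

    depths: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.depths.index)
        missing = set(self.depths.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet is missing libraries: {sorted(missing)}")

    def filter_length(self, min_length: int = 1000) -> "CoverageMatrix":
        keep = self.lengths >= min_length
        return CoverageMatrix(self.depths.loc[keep], self.lengths.loc[keep],
                              self.samples)


@dataclass
class RatioModel:
    """Fitted peaks of the log2 male:female coverage-ratio density."""

    autosomal_peak: float
    x_peak: float
    bandwidth: float
    x_peak_fallback: bool = False
    grid: np.ndarray | None = field(default=None, repr=False)
    density: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "autosomal_peak": self.autosomal_peak,
            "x_peak": self.x_peak,
            "bandwidth": self.bandwidth,
            "x_peak_fallback": self.x_peak_fallback,
        }


def _weighted_kde(values: np.ndarray, weights: np.ndarray,
                  grid: np.ndarray) -> tuple[np.ndarray, float]:
    kde = gaussian_kde(values, weights=weights, bw_method="silverman")
    return kde(grid), float(kde.factor * values.std(ddof=1))


def _kde_modes(values: np.ndarray, weights: np.ndarray, grid_size: int = 512,
               prominence_frac: float = PROMINENCE_FRAC,
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """Positions and densities of KDE modes above the prominence floor.

    Degenerate (near-constant) input collapses to a single mode at the
    weighted mean.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    mu = float(np.average(values, weights=weights))
    if values.std() < 1e-12 * max(1.0, abs(mu)):
        return np.array([mu]), np.array([np.inf]), 0.0
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo) + 1e-9
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens, bw = _weighted_kde(values, weights, grid)
    floor = prominence_frac * dens.max()
    peaks, _ = find_peaks(dens, prominence=floor)
    if peaks.size == 0:  # monotone density; take the global maximum
        peaks = np.array([int(np.argmax(dens))])
    keep = dens[peaks] >= floor
    peaks = peaks[keep]
    return grid[peaks], dens[peaks], bw


def qc_sample_coverage(depths: pd.Series, lengths: pd.Series, sex: str,
                       min_scaffolds: int = 100,
                       prominence_frac: float = PROMINENCE_FRAC,
                       ) -> tuple[bool, int]:
    """Automated check of one library's per-scaffold depth distribution.

    A stand-in for visual inspection of coverage histograms: the
    length-weighted depth density should show one dominant mode in females and
    one or two modes in males (autosomal plus the half-depth X mode, which
    carries only ~the X fraction of the genome's mass). Libraries with
    contaminated or mixed coverage (e.g. a 50:50 depth mixture) fail.

    Returns ``(passed, n_modes)``.
    """
    if depths.size < min_scaffolds:
        raise ValueError(f"need at least {min_scaffolds} scaffolds for QC")
    d = depths.to_numpy(dtype=float)
    w = lengths.reindex(depths.index).to_numpy(dtype=float)
    pos = d > 0
    if pos.sum() < min_scaffolds:
        return False, 0
    modes, dens, _ = _kde_modes(d[pos], w[pos], prominence_frac=prominence_frac)
    n_modes = len(modes)
    if sex.upper().startswith("F"):
        return n_modes == 1, n_modes
    if n_modes == 1:
        return True, n_modes
    if n_modes == 2:
        order = np.argsort(modes)
        low, high = modes[order]
        low_dens, high_dens = dens[order]
        # a genuine X mode sits near half the autosomal depth with minor mass
        pos_ok = 0.3 <= low / high <= 0.7
        mass_ok = low_dens <= 0.6 * high_dens
        return bool(pos_ok and mass_ok), n_modes
    return False, n_modes


def qc_all_samples(cov: CoverageMatrix, min_scaffolds: int = 100) -> CoverageMatrix:
    """Run per-library QC and record ``qc_pass`` / ``n_modes`` in the sheet."""
    samples = cov.samples.copy()
    flags, nmodes = {}, {}
    for lib in cov.depths.columns:
        ok, k = qc_sample_coverage(cov.depths[lib], cov.lengths,
                                   samples.loc[lib, "sex"],
                                   min_scaffolds=min_scaffolds)
        flags[lib], nmodes[lib] = ok, k
    samples["qc_pass"] = pd.Series(flags)
    samples["n_modes"] = pd.Series(nmodes)
    return CoverageMatrix(cov.depths, cov.lengths, samples)


def _modal_value(values: np.ndarray, weights: np.ndarray, male: bool) -> float:
    modes, dens, _ = _kde_modes(values, weights)
    if male and len(modes) > 1:
        # the autosomal mode is the higher-coverage one
        return float(modes.max())
    return float(modes[int(np.argmax(dens))])


def sex_summed_normalized_coverage(cov: CoverageMatrix,
                                   normalize_libraries: bool = True,
                                   ) -> pd.DataFrame:
    """Sum depth across QC-passing libraries per sex, normalize by the mode.

    Per sex, depth is summed over passing libraries per scaffold and divided
    by the modal value of the length-weighted per-scaffold distribution; for
    males the higher-coverage (autosomal) mode is the normalizer, so autosomal
    scaffolds center at 1 in both sexes. With ``normalize_libraries`` (the
    default) each library is first divided by its own modal depth, which
    equalizes library contributions and makes the result exactly invariant to
    rescaling any single library's depths.

    Returns a frame indexed by scaffold with columns ``length``, ``male_norm``
    and ``female_norm``.
    """
    samples = cov.samples
    if "qc_pass" not in samples.columns:
        samples = samples.assign(qc_pass=True)
    out = {"length": cov.lengths}
    w = cov.lengths.to_numpy(dtype=float)
    for sex, col in (("M", "male_norm"), ("F", "female_norm")):
        libs = samples.index[(samples["sex"] == sex) & samples["qc_pass"]]
        libs = [l for l in libs if l in cov.depths.columns]
        if not libs:
            raise ValueError(f"no QC-passing libraries of sex {sex!r}")
        male = sex == "M"
        parts = []
        for lib in libs:
            vals = cov.depths[lib].to_numpy(dtype=float)
            if normalize_libraries:
                pos = vals > 0
                vals = vals / _modal_value(vals[pos], w[pos], male=male)
            parts.append(vals)
        summed = np.sum(parts, axis=0)
        pos = summed > 0
        mode = _modal_value(summed[pos], w[pos], male=male)
        out[col] = pd.Series(summed / mode, index=cov.depths.index)
    return pd.DataFrame(out, index=cov.depths.index)


def log2_mf_ratio(norm: pd.DataFrame) -> pd.Series:
    """Per-scaffold log2(male/female) of modal-normalized coverage.

    Scaffolds with zero coverage on either side get NaN (flagged missing;
    no pseudocounts) and end up unclassified downstream.
    """
    m = norm["male_norm"].to_numpy(dtype=float)
    f = norm["female_norm"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((m > 0) & (f > 0), np.log2(m / f), np.nan)
    return pd.Series(r, index=norm.index, name="log2_mf")


def find_ratio_peaks(ratios: pd.Series, lengths: pd.Series,
                     prominence_frac: float = PROMINENCE_FRAC) -> RatioModel:
    """Locate the autosomal and X peaks of the log2 ratio density.

    The autosomal peak is the qualifying mode nearest 0; the X peak is the
    densest mode in [autosomal - 1.5, autosomal - 0.5]. When no X mode exists
    (e.g. no X-linked sequence in the input) the X peak falls back to
    autosomal - 1 and the model is flagged.
    """
    r = ratios.to_numpy(dtype=float)
    w = lengths.reindex(ratios.index).to_numpy(dtype=float)
    ok = np.isfinite(r)
    if ok.sum() < 100:
        raise ValueError("need at least 100 finite ratios to fit peaks")
    r, w = r[ok], w[ok]
    lo, hi = r.min(), r.max()
    pad = 0.1 * (hi - lo) + 1e-9
    grid = np.linspace(lo - pad, hi + pad, 1024)
    dens, bw = _weighted_kde(r, w, grid)
    floor = prominence_frac * dens.max()
    pk, _ = find_peaks(dens, prominence=floor)
    if pk.size == 0:
        pk = np.array([int(np.argmax(dens))])
    pk = pk[dens[pk] >= floor]
    modes, mdens = grid[pk], dens[pk]
    a_peak = float(modes[int(np.argmin(np.abs(modes)))])
    in_band = (modes >= a_peak - 1.5) & (modes <= a_peak - 0.5)
    if in_band.any():
        band_modes, band_dens = modes[in_band], mdens[in_band]
        x_peak = float(band_modes[int(np.argmax(band_dens))])
        fallback = False
    else:
        x_peak = a_peak - 1.0
        fallback = True
    return RatioModel(autosomal_peak=a_peak, x_peak=x_peak, bandwidth=bw,
                      x_peak_fallback=fallback, grid=grid, density=dens)


def classify_scaffolds(ratios: pd.Series, model: RatioModel,
                       scheme: str = "both", stringent_band: float = 0.1,
                       liberal_offset: float = 0.5) -> pd.DataFrame:
    """Call scaffolds A/X/unclassified under the liberal and stringent rules.

    Liberal: X iff ratio < autosomal_peak - 0.5, else A. Stringent: X iff the
    ratio is within 0.1 of the X peak, A iff within 0.1 of the autosomal peak,
    otherwise unclassified. Missing ratios are unclassified under both.
    """
    if scheme not in {"liberal", "stringent", "both"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    r = ratios.to_numpy(dtype=float)
    out = pd.DataFrame({"log2_mf": ratios}, index=ratios.index)
    if scheme in {"liberal", "both"}:
        lib = np.where(np.isnan(r), "unclassified",
                       np.where(r < model.autosomal_peak - liberal_offset, "X", "A"))
        out["call_liberal"] = lib
    if scheme in {"stringent", "both"}:
        strg = np.full(r.shape, "unclassified", dtype=object)
        strg[np.abs(r - model.x_peak) <= stringent_band] = "X"
        strg[np.abs(r - model.autosomal_peak) <= stringent_band] = "A"
        strg[np.isnan(r)] = "unclassified"
        out["call_stringent"] = strg
    return out


def male_x_heterozygosity_check(het: pd.DataFrame, calls: pd.DataFrame,
                                call_col: str = "call_liberal",
                                flag_ratio: float = 0.2) -> dict:
    """Corroborate X calls with male heterozygosity.

    Males are hemizygous for the X, so apparent heterozygosity on true X
    scaffolds should be near zero (sequencing-error level). Computes the
    covered-site-weighted median heterozygous proportion on X- and A-called
    scaffolds over male samples and flags the call set when the X median
    exceeds ``flag_ratio`` times the autosomal median.

    ``het`` columns: scaffold, het_sites, covered_sites (male samples only).
    """
    merged = het.merge(calls[[call_col]], left_on="scaffold", right_index=True,
                       how="inner")
    merged = merged[merged["covered_sites"] > 0]
    res = {}
    for cls in ("A", "X"):
        sub = merged[merged[call_col] == cls]
        if sub.empty:
            raise ValueError(f"no scaffolds called {cls}")
        prop = sub["het_sites"] / sub["covered_sites"]
        res[f"median_{cls}"] = weighted_median(prop.to_numpy(),
                                               sub["covered_sites"].to_numpy())
    res["ratio"] = (res["median_X"] / res["median_A"]
                    if res["median_A"] > 0 else np.inf)
    res["flagged"] = bool(res["median_X"] > flag_ratio * res["median_A"])
    return res


def assign_genes(gene_map: pd.DataFrame, calls: pd.DataFrame,
                 call_col: str = "call_liberal") -> pd.DataFrame:
    """Propagate scaffold calls to genes (gene inherits its scaffold's call).

    ``gene_map`` columns: gene, scaffold (and optionally length). Genes on
    scaffolds absent from ``calls`` raise; genes on unclassified scaffolds are
    kept with linkage 'unclassified'.
    """
    unknown = set(gene_map["scaffold"]) - set(calls.index)
    if unknown:
        raise ValueError(f"genes map to unknown scaffolds: {sorted(unknown)[:5]}")
    if gene_map["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in gene map")
    out = gene_map.merge(calls[[call_col]], left_on="scaffold", right_index=True)
    return out.rename(columns={call_col: "linkage"})


def anchor_scaffolds(coords: pd.DataFrame, calls: pd.DataFrame,
                     call_col: str = "call_liberal",
                     min_anchored_bases: int = 10_000) -> pd.DataFrame:
    """Transfer calls onto a reference assembly through alignment coordinates.

    ``coords`` columns: query, reference, aligned_bases. Query scaffolds with
    fewer than ``min_anchored_bases`` total anchored bases are dropped. Each
    reference scaffold is called X when bases contributed by X-called queries
    exceed twice those from A-called queries, A in the mirrored case, and
    unclassified otherwise.
    """
    required = {"query", "reference", "aligned_bases"}
    if not required.issubset(coords.columns):
        raise ValueError(f"coords table must have columns {sorted(required)}")
    anchored = coords.groupby("query")["aligned_bases"].sum()
    keep = anchored.index[anchored >= min_anchored_bases]
    sub = coords[coords["query"].isin(keep)].copy()
    call_of = calls[call_col] if call_col in calls.columns else calls
    sub["call"] = sub["query"].map(call_of)
    sub = sub[sub["call"].isin(["A", "X"])]
    pivot = (sub.pivot_table(index="reference", columns="call",
                             values="aligned_bases", aggfunc="sum",
                             fill_value=0)
             .reindex(columns=["A", "X"], fill_value=0))
    x, a = pivot["X"].to_numpy(float), pivot["A"].to_numpy(float)
    call = np.where(x > 2 * a, "X", np.where(a > 2 * x, "A", "unclassified"))
    return pd.DataFrame({"x_bases": x, "a_bases": a, "call": call},
                        index=pivot.index)
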