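"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes in an
XX/X0 genome: scaffold-level sequencing depth with the X at half copy number
in males, heterozygous-site counts with a reduced X rate, pairwise coalescent
draws giving the neutral X:autosome diversity expectation, negative-binomial
RNA-seq counts under compensated/uncompensated dosage regimes with sex-biased
and species-by-sex interaction genes, and high-overlap per-species X-ortholog
sets. Each dataset carries a truth sidecar so recovery tests compare pipeline
output against the generating parameters rather than hard-coded numbers.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix

__all__ = [
    "SimGenome",
    "SimTruth",
    "simulate_genome",
    "default_coverage_samples",
    "simulate_coverage",
    "simulate_het_sites",
    "simulate_pairwise_diversity",
    "make_design",
    "simulate_counts",
    "simulate_ortholog_sets",
]

TISSUES = ("head", "leg", "reproductive_tract")
#: default dosage regimes: somatic tissues compensated, gonadal tissue not
DEFAULT_DC_REGIMES = {
    "head": "compensated",
    "leg": "compensated",
    "reproductive_tract": "uncompensated",
}


@dataclass
class SimGenome:
    """Simulated assembly: scaffolds with true linkage, plus gene placements."""

    scaffolds: pd.DataFrame  # scaffold, length, truth_linkage
    genes: pd.DataFrame      # gene, scaffold, length, truth_linkage
    x_fraction: float
    seed: int | None = None

    @property
    def lengths(self) -> pd.Series:
        return self.scaffolds.set_index("scaffold")["length"]

    @property
    def truth(self) -> pd.Series:
        return self.scaffolds.set_index("scaffold")["truth_linkage"]

    def realized_x_fraction(self) -> float:
        s = self.scaffolds
        return float(s.loc[s["truth_linkage"] == "X", "length"].sum()
                     / s["length"].sum())


@dataclass
class SimTruth:
    """Ground-truth sidecar serialized with every simulated dataset."""

    seed: int | None
    params: dict = field(default_factory=dict)
    scaffold_linkage: dict | None = None
    gene_truth: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "params": self.params}
        if self.scaffold_linkage is not None:
            payload["scaffold_linkage"] = self.scaffold_linkage
        if self.gene_truth is not None:
            payload["gene_truth"] = self.gene_truth.to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genome(n_scaffolds: int = 5000, x_fraction: float = 0.12,
                    n_genes: int = 14000, mean_log_length: float = 8.5,
                    sd_log_length: float = 1.0, min_length: int = 1000,
                    mean_log_gene_length: float = 7.3,
                    sd_log_gene_length: float = 0.5, seed=None) -> SimGenome:
    """Draw a fragmented assembly with a target X length fraction.

    Scaffold lengths are log-normal (clipped at ``min_length``); scaffolds are
    assigned to the X in random order until the cumulative length reaches
    ``x_fraction`` of the genome (~12% by default, the size of the X relative
    to these genomes). Genes are placed on scaffolds with probability
    proportional to scaffold length.
    """
    if n_scaffolds < 2:
        raise ValueError("need at least 2 scaffolds")
    if not 0.0 <= x_fraction < 1.0:
        raise ValueError("x_fraction must be in [0, 1)")
    rng = _rng(seed)
    lengths = np.maximum(
        rng.lognormal(mean_log_length, sd_log_length, n_scaffolds), min_length
    ).astype(np.int64)
    linkage = np.full(n_scaffolds, "A", dtype=object)
    if x_fraction > 0:
        order = rng.permutation(n_scaffolds)
        target = x_fraction * lengths.sum()
        cum = np.cumsum(lengths[order])
        n_x = int(np.searchsorted(cum, target)) + 1
        linkage[order[:n_x]] = "X"
    ids = np.array([f"scf{i:06d}" for i in range(n_scaffolds)])
    scaffolds = pd.DataFrame({"scaffold": ids, "length": lengths,
                              "truth_linkage": linkage})
    gene_scf = rng.choice(n_scaffolds, size=n_genes,
                          p=lengths / lengths.sum())
    gene_len = np.maximum(
        rng.lognormal(mean_log_gene_length, sd_log_gene_length, n_genes), 200
    ).astype(np.int64)
    genes = pd.DataFrame({
        "gene": [f"g{i:06d}" for i in range(n_genes)],
        "scaffold": ids[gene_scf],
        "length": gene_len,
        "truth_linkage": linkage[gene_scf],
    })
    return SimGenome(scaffolds=scaffolds, genes=genes, x_fraction=x_fraction,
                     seed=seed if isinstance(seed, int) else None)


def default_coverage_samples(n_males: int = 4, n_females: int = 5,
                             species: str = "sp1") -> pd.DataFrame:
    """Sample sheet for the default genomic panel (4 males, 5 females)."""
    rows = [(f"{species}_M{i+1}", "M", species) for i in range(n_males)]
    rows += [(f"{species}_F{i+1}", "F", species) for i in range(n_females)]
    return (pd.DataFrame(rows, columns=["sample", "sex", "species"])
            .set_index("sample"))


def simulate_coverage(genome: SimGenome, samples: pd.DataFrame | None = None,
                      mean_depth: float = 20.0, dispersion: float = 0.07,
                      block_bp: int = 1000, read_length: int = 100,
                      scaffold_sigma: float = 0.1,
                      sample_depth_sigma: float = 0.05,
                      bad_library_rate: float = 0.0, seed=None,
                      ) -> CoverageMatrix:
    """Simulate per-scaffold mean depth for each library.

    Read counts per scaffold are Poisson with a gamma-distributed rate
    multiplier (i.e. negative binomial), scaled by copy number (autosomes: 2
    in both sexes; X: 2 in females, 1 in males) and by a per-scaffold
    log-normal factor shared across libraries (GC-like bias; it cancels in
    the male:female ratio but widens each sex's depth distribution
    realistically). Depth bias acts at the scale of ``block_bp`` blocks, so
    the gamma multiplier's coefficient of variation is ``dispersion`` for a
    1-block scaffold and shrinks as 1/sqrt(length/block_bp): long scaffolds
    give tight ratio estimates while kilobase-scale scaffolds scatter, as in
    real fragmented assemblies. "Bad" libraries — drawn with probability
    ``bad_library_rate`` and recorded in the sample sheet's ``truth_bad``
    column — get a 50:50 mixture of 0.3x and 1.7x depth to exercise QC.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = _rng(seed)
    if samples is None:
        samples = default_coverage_samples()
    lengths = genome.lengths.to_numpy(dtype=float)
    is_x = (genome.truth == "X").to_numpy()
    n_scf, n_lib = lengths.size, len(samples)
    scf_factor = rng.lognormal(0.0, scaffold_sigma, n_scf)
    depth_cols = {}
    bad_flags = {}
    for lib, row in samples.iterrows():
        sample_depth = mean_depth * rng.lognormal(0.0, sample_depth_sigma)
        copy_factor = np.where(is_x & (row["sex"] == "M"), 0.5, 1.0)
        lam = sample_depth * (lengths / read_length) * copy_factor * scf_factor
        bad = bool(rng.random() < bad_library_rate)
        bad_flags[lib] = bad
        if bad:
            mix = rng.random(n_scf) < 0.5
            lam = lam * np.where(mix, 0.3, 1.7)
        if dispersion > 0:
            shape = (lengths / block_bp) / dispersion**2
            lam = lam * rng.gamma(shape, 1.0 / shape)
        reads = rng.poisson(lam)
        depth_cols[lib] = reads * read_length / lengths
    depths = pd.DataFrame(depth_cols, index=genome.scaffolds["scaffold"])
    sheet = samples.copy()
    sheet["truth_bad"] = pd.Series(bad_flags)
    return CoverageMatrix(depths=depths, lengths=genome.lengths, samples=sheet)


def simulate_het_sites(genome: SimGenome, samples: pd.DataFrame | None = None,
                       theta_A: float = 0.004, x_ratio: float = 0.3,
                       covered_fraction: float = 0.8,
                       error_rate: float = 2e-4, seed=None) -> pd.DataFrame:
    """Simulate per-scaffold heterozygous/covered site counts per sample.

    Heterozygosity per covered site is ``theta_A`` on autosomes and
    ``theta_A * x_ratio`` on the X in females. Males are hemizygous for the X,
    so their apparent X heterozygosity is just the genotyping error rate.
    Returns a long table (scaffold, sample, sex, het_sites, covered_sites).
    """
    if theta_A <= 0:
        raise ValueError("theta_A must be positive")
    if not 0 < x_ratio <= 1:
        raise ValueError("x_ratio must be in (0, 1]")
    rng = _rng(seed)
    if samples is None:
        samples = default_coverage_samples()
    lengths = genome.lengths.to_numpy(dtype=np.int64)
    is_x = (genome.truth == "X").to_numpy()
    rows = []
    for lib, row in samples.iterrows():
        covered = rng.binomial(lengths, covered_fraction)
        theta = np.where(is_x,
                         error_rate if row["sex"] == "M" else theta_A * x_ratio,
                         theta_A)
        het = rng.binomial(covered, theta)
        rows.append(pd.DataFrame({
            "scaffold": genome.scaffolds["scaffold"],
            "sample": lib, "sex": row["sex"],
            "het_sites": het, "covered_sites": covered,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_pairwise_diversity(copies_A: float = 4.0, copies_X: float = 3.0,
                                mu: float = 2.8e-9, n_loci: int = 50_000,
                                n_per_copy: float = 125_000.0, seed=None,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-coalescent oracle for the neutral X:A diversity ratio.

    For each locus a pairwise coalescence time is drawn exponentially with
    mean proportional to the class's chromosomal copy number (X carries 3
    copies per breeding pair versus 4 autosomal copies under a balanced sex
    ratio), and per-locus diversity is 2*mu*T. Expected mean(pi_X)/mean(pi_A)
    is exactly ``copies_X / copies_A`` (0.75 by default); mu cancels.

    Returns ``(pi_A, pi_X)`` per-locus vectors.
    """
    rng = _rng(seed)
    t_a = rng.exponential(copies_A * n_per_copy, n_loci)
    t_x = rng.exponential(copies_X * n_per_copy, n_loci)
    return 2.0 * mu * t_a, 2.0 * mu * t_x


def make_design(species=("sp1", "sp2", "sp3", "sp4", "sp5"),
                tissues=TISSUES, replicates: int = 3) -> pd.DataFrame:
    """RNA-seq design sheet: ``replicates`` libraries per sex/tissue/species."""
    rows = []
    for sp in species:
        for tis in tissues:
            for sex in ("M", "F"):
                for r in range(1, replicates + 1):
                    rows.append((f"{sp}_{tis}_{sex}{r}", sp, tis, sex, r))
    return (pd.DataFrame(rows, columns=["library", "species", "tissue", "sex",
                                        "replicate"])
            .set_index("library"))


def simulate_counts(genome: SimGenome, design: pd.DataFrame | None = None,
                    baseline_log_mean: float = 3.4, baseline_log_sd: float = 1.3,
                    dc_regime_by_tissue: dict | None = None,
                    sexbias_fractions: tuple[float, float] = (0.05, 0.05),
                    sexbias_fold: float = 4.0,
                    interaction_fraction: float = 0.0,
                    interaction_fold: float = 2.0,
                    sex_limited_fraction: float = 0.0,
                    dispersion: float = 0.05,
                    library_sigma: float = 0.1,
                    species_sigma: float = 0.05,
                    seed=None) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate an RNA-seq count matrix under known dosage/sex-bias truth.

    Gene baselines are log-normal; expected counts are
    ``baseline * (length/1kb) * library_factor * sex_effect * dosage_factor``
    and counts are negative binomial with dispersion ``dispersion``. The
    dosage factor is 0.5 for X-linked genes in males in uncompensated tissues
    and 1 otherwise (in compensated tissues the single male X is
    hyper-transcribed two-fold, restoring parity). Male-/female-biased genes
    get a ``sexbias_fold`` multiplicative effect in every tissue; interaction
    genes get an independent per-species sex effect (fold or its reciprocal);
    sex-limited genes (off by default) are silenced in one sex.

    Returns ``(counts, design, truth)`` where ``counts`` has genes as rows
    (with a ``length`` column) and one column per library.
    """
    rng = _rng(seed)
    if design is None:
        design = make_design()
    regimes = dict(DEFAULT_DC_REGIMES if dc_regime_by_tissue is None
                   else dc_regime_by_tissue)
    for tis in design["tissue"].unique():
        if regimes.get(tis) not in {"compensated", "uncompensated"}:
            raise ValueError(f"no dosage regime for tissue {tis!r}")
    genes = genome.genes
    n_genes = len(genes)
    species = list(design["species"].unique())
    is_x = (genes["truth_linkage"] == "X").to_numpy()

    baseline = rng.lognormal(baseline_log_mean, baseline_log_sd, n_genes)
    length_factor = genes["length"].to_numpy(dtype=float) / 1000.0

    # gene classes
    u = rng.random(n_genes)
    f_m, f_f = sexbias_fractions
    bias_class = np.where(u < f_m, "male_biased",
                          np.where(u < f_m + f_f, "female_biased", "unbiased"))
    interaction = rng.random(n_genes) < interaction_fraction
    sex_limited = np.full(n_genes, "none", dtype=object)
    if sex_limited_fraction > 0:
        v = rng.random(n_genes)
        sex_limited = np.where(v < sex_limited_fraction / 2, "male_only",
                               np.where(v < sex_limited_fraction, "female_only",
                                        "none"))

    male_mult = np.where(bias_class == "male_biased", sexbias_fold, 1.0)
    male_mult = male_mult * np.where(bias_class == "female_biased",
                                     1.0 / sexbias_fold, 1.0)
    # per-species sex multiplier for interaction genes
    inter_mult = np.ones((n_genes, len(species)))
    if interaction.any():
        flips = rng.random((int(interaction.sum()), len(species))) < 0.5
        inter_mult[interaction] = np.where(flips, interaction_fold,
                                           1.0 / interaction_fold)
    species_factor = rng.lognormal(0.0, species_sigma, (n_genes, len(species)))

    shape = 1.0 / dispersion if dispersion > 0 else np.inf
    counts = {}
    for lib, row in design.iterrows():
        sp_i = species.index(row["species"])
        lib_factor = rng.lognormal(0.0, library_sigma)
        mu = baseline * length_factor * lib_factor * species_factor[:, sp_i]
        sexmul = male_mult if row["sex"] == "M" else 1.0 / male_mult
        mu = mu * np.where(sexmul != 1.0, sexmul, 1.0)
        mu = mu * np.where(inter_mult[:, sp_i] != 1.0,
                           inter_mult[:, sp_i] if row["sex"] == "M"
                           else 1.0 / inter_mult[:, sp_i], 1.0)
        if regimes[row["tissue"]] == "uncompensated" and row["sex"] == "M":
            mu = mu * np.where(is_x, 0.5, 1.0)
        off = ((sex_limited == "male_only") & (row["sex"] == "F")) | \
              ((sex_limited == "female_only") & (row["sex"] == "M"))
        mu = np.where(off, 1e-3, mu)
        if dispersion > 0:
            counts[lib] = rng.negative_binomial(shape, shape / (shape + mu))
        else:
            counts[lib] = rng.poisson(mu)
    out = pd.DataFrame(counts, index=genes["gene"])
    out.insert(0, "length", genes["length"].to_numpy())

    gene_truth = pd.DataFrame({
        "gene": genes["gene"].to_numpy(),
        "linkage": genes["truth_linkage"].to_numpy(),
        "bias_class": bias_class,
        "interaction": interaction,
        "sex_limited": sex_limited,
    })
    truth = SimTruth(
        seed=seed if isinstance(seed, int) else None,
        params={"dc_regime_by_tissue": regimes, "sexbias_fold": sexbias_fold,
                "interaction_fraction": interaction_fraction,
                "dispersion": dispersion},
        gene_truth=gene_truth,
    )
    return out, design, truth


def simulate_ortholog_sets(n_species: int = 5, universe_size: int = 10_000,
                           x_set_size: int = 1000, shared_fraction: float = 0.9,
                           seed=None) -> dict[str, set]:
    """Per-species X-linked ortholog sets with a shared core.

    A core of ``shared_fraction * x_set_size`` orthologs is common to all
    species; each species tops up to ``x_set_size`` with its own random draw
    from the remaining universe. Emulates high conservation of X gene content
    across species.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = _rng(seed)
    universe = np.array([f"og{i:06d}" for i in range(universe_size)])
    perm = rng.permutation(universe_size)
    n_core = int(round(shared_fraction * x_set_size))
    core = universe[perm[:n_core]]
    rest = universe[perm[n_core:]]
    sets = {}
    for s in range(n_species):
        fill = rng.choice(rest, size=x_set_size - n_core, replace=False)
        sets[f"sp{s+1}"] = set(core) | set(fill)
    return sets
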