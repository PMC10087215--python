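"""File-format readers/writers and the run manifest.

All tabular interchange is TSV; gene models come from GFF3 (or an equivalent
3-column TSV), intervals from BED/BED-graph, sequences from FASTA. GFF3
coordinates (1-based inclusive) are converted to the internal 0-based
half-open convention at the boundary. Gene length for FPKM is the length of
the union of the gene's exons with overlaps merged, matching exon-level read
counting.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from .coverage import CoverageMatrix

__all__ = [
    "read_depth_table",
    "aggregate_bedgraph",
    "read_sample_sheet",
    "read_coverage",
    "read_gene_map",
    "read_counts",
    "read_design",
    "read_het_table",
    "read_coords",
    "read_ortholog_sets",
    "read_calls",
    "fasta_gc",
    "RunManifest",
]


class FormatError(ValueError):
    """Malformed input file."""


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) "
                          f"{', '.join(sorted(missing))}")


def read_depth_table(path, min_length: int = 1000) -> pd.DataFrame:
    """Per-scaffold depth TSV: columns scaffold, length, one per library.

    Scaffolds shorter than ``min_length`` are dropped (the count is recorded
    in ``df.attrs['n_dropped_short']``). Non-numeric depths raise with the
    offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise FormatError(f"{path}: empty depth table")
    _require_columns(df, {"scaffold", "length"}, path)
    sample_cols = [c for c in df.columns if c not in ("scaffold", "length")]
    for col in sample_cols + ["length"]:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based
            raise FormatError(f"{path}: non-numeric value in column "
                              f"{col!r} at line {line}")
        df[col] = num
    n_before = len(df)
    df = df[df["length"] >= min_length].reset_index(drop=True)
    df.attrs["n_dropped_short"] = n_before - len(df)
    return df


def aggregate_bedgraph(path, lengths: pd.Series) -> pd.Series:
    """Per-scaffold mean depth from a per-base BED-graph.

    BED-graph rows are (chrom, start, end, depth) with 0-based half-open
    intervals; the mean is sum(depth * span) / scaffold length.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "depth"])
    if df.empty:
        raise FormatError(f"{path}: empty BED-graph")
    df["mass"] = (df["end"] - df["start"]) * df["depth"]
    total = df.groupby("chrom")["mass"].sum()
    mean = total / lengths.reindex(total.index)
    return mean.reindex(lengths.index).fillna(0.0)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: columns sample, sex (and optionally species, include)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"sample", "sex"}, path)
    df = df.set_index("sample")
    if "include" in df.columns:
        df["include"] = df["include"].astype(bool)
    return df


def read_coverage(depth_path, samples_path, min_length: int = 1000,
                  ) -> CoverageMatrix:
    depth = read_depth_table(depth_path, min_length=min_length)
    samples = read_sample_sheet(samples_path)
    if "include" in samples.columns:
        samples = samples[samples["include"]]
    libs = [c for c in depth.columns if c in samples.index]
    if not libs:
        raise FormatError("no depth columns match the sample sheet")
    depths = depth.set_index("scaffold")[libs]
    lengths = depth.set_index("scaffold")["length"]
    return CoverageMatrix(depths=depths, lengths=lengths,
                          samples=samples.loc[libs])


def _gene_map_from_gff3(path) -> pd.DataFrame:
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:  # gffutils wraps the parse position in the message
        raise FormatError(f"{path}: malformed GFF3 ({exc})") from exc
    rows = []
    for gene in db.features_of_type("gene"):
        exons = [(e.start - 1, e.end) for e in db.children(gene, featuretype="exon")]
        if exons:
            # merge overlapping exon spans; length = union of spans
            exons.sort()
            merged = [list(exons[0])]
            for s, e in exons[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            length = sum(e - s for s, e in merged)
        else:
            length = gene.end - (gene.start - 1)
        rows.append({"gene": gene.id, "scaffold": gene.seqid, "length": length})
    return pd.DataFrame(rows)


def read_gene_map(path) -> pd.DataFrame:
    """Gene-to-scaffold map from GFF3 or a (gene, scaffold, length) TSV."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        df = _gene_map_from_gff3(path)
    else:
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, {"gene", "scaffold"}, path)
    if df.empty:
        raise FormatError(f"{path}: no gene records")
    dup = df["gene"].duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicate gene id {df.loc[dup.idxmax(), 'gene']!r}")
    return df.reset_index(drop=True)


def read_counts(path) -> pd.DataFrame:
    """Count matrix TSV: columns gene, length, one per library."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"gene", "length"}, path)
    return df.set_index("gene")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"library", "sex", "species", "tissue"}, path)
    return df.set_index("library")


def read_het_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"scaffold", "sample", "het_sites", "covered_sites"},
                     path)
    return df


def read_coords(path) -> pd.DataFrame:
    """Alignment coordinate TSV: query, reference, aligned_bases."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"query", "reference", "aligned_bases"}, path)
    num = pd.to_numeric(df["aligned_bases"], errors="coerce")
    bad = num.isna()
    if bad.any():
        raise FormatError(f"{path}: non-numeric aligned_bases at row "
                          f"{int(bad.idxmax()) + 2}")
    df["aligned_bases"] = num.astype(int)
    return df


def read_ortholog_sets(path) -> dict[str, set]:
    """Per-species ortholog sets from a (species, gene) long TSV."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"species", "gene"}, path)
    return {sp: set(sub["gene"]) for sp, sub in df.groupby("species")}


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"scaffold"}, path)
    return df.set_index("scaffold")


def fasta_gc(path) -> pd.Series:
    """GC proportion per FASTA record (ambiguity codes excluded)."""
    from .selection import gc_content
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = gc_content(str(rec.seq))
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return pd.Series(out, name="gc")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every run's outputs."""

    subcommand: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    seed: int | None = None
    version: str | None = None
    started: float = field(default_factory=time.time)

    def add_input(self, path) -> None:
        p = Path(path)
        if p.exists():
            self.inputs[str(p)] = _checksum(p)

    def write(self, path) -> None:
        from . import __version__
        payload = {
            "subcommand": self.subcommand,
            "config": self.config,
            "inputs": self.inputs,
            "seed": self.seed,
            "version": self.version or __version__,
            "started": self.started,
            "finished": time.time(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
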