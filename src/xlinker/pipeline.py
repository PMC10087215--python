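"""Stage orchestration: run the analysis end to end from a config mapping.

Stages (``simulate``, ``classify_x``, ``popgen``, ``dosage``, ``overlap``,
``anchor``) are executed in dependency order; each stage reads either the
outputs of earlier stages in the same run directory or explicit input paths
from the config, writes TSV/JSON outputs, and the run finishes with a
manifest recording config, input checksums, seed and version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import expression as expr
from . import io as xio
from . import popgen, simulate
from .stats import multiset_intersection_test

__all__ = ["PipelineError", "run_pipeline"]

_STAGE_ORDER = ["simulate", "classify_x", "popgen", "dosage", "overlap",
                "anchor"]


class PipelineError(RuntimeError):
    pass


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _stage_simulate(cfg: dict, out: Path, seed: int) -> dict:
    params = cfg.get("simulate", {})
    genome = simulate.simulate_genome(
        n_scaffolds=params.get("n_scaffolds", 5000),
        x_fraction=params.get("x_fraction", 0.12),
        n_genes=params.get("n_genes", 14000), seed=seed)
    samples = simulate.default_coverage_samples()
    covm = simulate.simulate_coverage(
        genome, samples, mean_depth=params.get("mean_depth", 20.0),
        seed=seed + 1)
    het = simulate.simulate_het_sites(genome, samples, seed=seed + 2)
    counts, design, truth = simulate.simulate_counts(
        genome, simulate.make_design(species=params.get(
            "species", ("sp1", "sp2", "sp3", "sp4", "sp5"))),
        seed=seed + 3)
    _write_tsv(genome.scaffolds, out / "scaffolds.tsv")
    depth = covm.depths.copy()
    depth.insert(0, "length", covm.lengths)
    _write_tsv(depth.reset_index(names="scaffold"), out / "coverage.tsv")
    _write_tsv(covm.samples.reset_index(names="sample"), out / "samples.tsv")
    _write_tsv(het, out / "het.tsv")
    _write_tsv(counts.reset_index(), out / "counts.tsv")
    _write_tsv(design.reset_index(), out / "design.tsv")
    _write_tsv(genome.genes, out / "genes.tsv")
    truth.scaffold_linkage = genome.truth.to_dict()
    truth.to_json(out / "truth.json")
    return {"coverage": covm, "het": het, "counts": counts,
            "design": design, "genome": genome}


def _stage_classify(cfg: dict, out: Path, state: dict) -> dict:
    params = cfg.get("classify_x", {})
    if "coverage" in state:
        covm = state["coverage"]
    else:
        try:
            covm = xio.read_coverage(params["coverage"], params["samples"],
                                     min_length=params.get("min_length", 1000))
        except KeyError as exc:
            raise PipelineError(
                "classify_x needs the simulate stage or explicit "
                "'coverage' and 'samples' paths") from exc
    covm = covm.filter_length(params.get("min_length", 1000))
    covm = cov.qc_all_samples(covm)
    norm = cov.sex_summed_normalized_coverage(covm)
    ratios = cov.log2_mf_ratio(norm)
    model = cov.find_ratio_peaks(ratios, norm["length"])
    calls = cov.classify_scaffolds(ratios, model)
    calls.insert(0, "length", norm["length"])
    _write_tsv(calls.reset_index(names="scaffold"), out / "calls.tsv")
    (out / "ratio_model.json").write_text(json.dumps(model.to_dict(), indent=1))
    x_bed = calls[calls["call_liberal"] == "X"]
    bed = pd.DataFrame({"chrom": x_bed.index, "start": 0,
                        "end": x_bed["length"].astype(int)})
    bed.to_csv(out / "x_scaffolds.bed", sep="\t", index=False, header=False)
    state["calls"] = calls
    return state


def _stage_popgen(cfg: dict, out: Path, state: dict) -> dict:
    params = cfg.get("popgen", {})
    if "calls" not in state:
        raise PipelineError("popgen requires the classify_x stage")
    het = state.get("het")
    if het is None:
        if "het" not in params:
            raise PipelineError("popgen needs the simulate stage or a 'het' path")
        het = xio.read_het_table(params["het"])
    summary = popgen.summarize_diversity(het, state["calls"],
                                         mu=params.get("mu", popgen.MU_DMEL))
    _write_tsv(summary, out / "popgen_summary.tsv")
    state["popgen"] = summary
    return state


def _stage_dosage(cfg: dict, out: Path, state: dict) -> dict:
    params = cfg.get("dosage", {})
    if "calls" not in state:
        raise PipelineError("dosage requires the classify_x stage")
    counts, design = state.get("counts"), state.get("design")
    if counts is None:
        try:
            counts = xio.read_counts(params["counts"])
            design = xio.read_design(params["design"])
        except KeyError as exc:
            raise PipelineError("dosage needs the simulate stage or "
                                "'counts' and 'design' paths") from exc
    genome = state.get("genome")
    if genome is not None:
        gene_link = genome.genes.set_index("gene")["scaffold"].map(
            state["calls"]["call_liberal"])
    else:
        gene_map = xio.read_gene_map(params["genes"])
        gene_link = gene_map.set_index("gene")["scaffold"].map(
            state["calls"]["call_liberal"])
    panel = expr.dosage_panel(counts, gene_link, design,
                              unit=params.get("unit", "FPKM"))
    _write_tsv(panel, out / "dosage_summary.tsv")
    state["dosage"] = panel
    return state


def _stage_overlap(cfg: dict, out: Path, state: dict, seed: int) -> dict:
    params = cfg.get("overlap", {})
    if "sets" in params:
        sets = xio.read_ortholog_sets(params["sets"])
        universe = int(params["universe_size"])
    else:
        sets = simulate.simulate_ortholog_sets(seed=seed + 4)
        universe = 10_000
    observed = len(set.intersection(*sets.values()))
    res = multiset_intersection_test(universe, [len(s) for s in sets.values()],
                                     observed)
    (out / "overlap.json").write_text(json.dumps({
        "observed": res.observed, "expected": res.expected,
        "p_value": res.p_value, "log10_p": res.log10_p,
        "fold_enrichment": res.fold_enrichment}, indent=1))
    state["overlap"] = res
    return state


def _stage_anchor(cfg: dict, out: Path, state: dict) -> dict:
    params = cfg.get("anchor", {})
    if "calls" not in state:
        raise PipelineError("anchor requires the classify_x stage")
    if "coords" not in params:
        raise PipelineError("anchor needs a 'coords' path")
    coords = xio.read_coords(params["coords"])
    anchored = cov.anchor_scaffolds(
        coords, state["calls"],
        min_anchored_bases=params.get("min_anchored_bases", 10_000))
    _write_tsv(anchored.reset_index(), out / "anchored_calls.tsv")
    state["anchor"] = anchored
    return state


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the requested stages in dependency order.

    ``config`` maps stage names to their parameter dicts, plus optional
    top-level ``stages`` (list, default all runnable), and ``seed``.
    Returns the in-memory state dict of stage outputs; files and a manifest
    land in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["simulate", "classify_x", "popgen",
                                   "dosage", "overlap"])
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in _STAGE_ORDER if s in stages]
    manifest = xio.RunManifest(subcommand="run", config=config, seed=seed)
    for stage_cfg in config.values():
        if isinstance(stage_cfg, dict):
            for v in stage_cfg.values():
                if isinstance(v, str) and Path(v).exists():
                    manifest.add_input(v)
    state: dict = {}
    for stage in stages:
        if stage == "simulate":
            state = _stage_simulate(config, out, seed)
        elif stage == "classify_x":
            state = _stage_classify(config, out, state)
        elif stage == "popgen":
            state = _stage_popgen(config, out, state)
        elif stage == "dosage":
            state = _stage_dosage(config, out, state)
        elif stage == "overlap":
            state = _stage_overlap(config, out, state, seed)
        elif stage == "anchor":
            state = _stage_anchor(config, out, state)
    manifest.write(out / "manifest.json")
    return state
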