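import pandas as pd
import pytest

from xlinker import coverage as cov
from xlinker import simulate


@pytest.fixture(scope="session")
def genome():
    """Mid-sized simulated assembly shared by recovery tests."""
    return simulate.simulate_genome(n_scaffolds=3000, x_fraction=0.12,
                                    n_genes=4000, seed=11)


@pytest.fixture(scope="session")
def coverage_matrix(genome):
    return simulate.simulate_coverage(genome, seed=12)


@pytest.fixture(scope="session")
def classified(genome, coverage_matrix):
    cm = cov.qc_all_samples(coverage_matrix)
    norm = cov.sex_summed_normalized_coverage(cm)
    ratios = cov.log2_mf_ratio(norm)
    model = cov.find_ratio_peaks(ratios, norm["length"])
    calls = cov.classify_scaffolds(ratios, model)
    return {"norm": norm, "ratios": ratios, "model": model, "calls": calls}


@pytest.fixture(scope="session")
def truth_calls(genome):
    """Oracle linkage calls straight from the generator's truth labels."""
    return pd.DataFrame({"call_liberal": genome.truth})


@pytest.fixture(scope="session")
def expression_sim():
    """One-species expression panel with default dosage regimes, no sex bias.

    8000 genes with 12% X-linked — the default study conditions for the
    expression analyses.
    """
    g = simulate.simulate_genome(n_scaffolds=2000, x_fraction=0.12,
                                 n_genes=8000, seed=15)
    design = simulate.make_design(species=("sp1",))
    counts, des, truth = simulate.simulate_counts(
        g, design, sexbias_fractions=(0.0, 0.0), seed=13)
    return {"counts": counts, "design": des, "truth": truth,
            "linkage": truth.gene_truth.set_index("gene")["linkage"]}
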