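"""Tests of coverage QC, modal normalization, ratio peaks and classification."""

import numpy as np
import pandas as pd
import pytest

from xlinker import coverage as cov
from xlinker import simulate


class TestQC:
    def test_clean_libraries_pass(self, coverage_matrix):
        cm = cov.qc_all_samples(coverage_matrix)
        assert cm.samples["qc_pass"].all()
        # males show the half-depth X mode, females a single mode
        assert (cm.samples.loc[cm.samples["sex"] == "M", "n_modes"] == 2).all()
        assert (cm.samples.loc[cm.samples["sex"] == "F", "n_modes"] == 1).all()

    def test_mixture_library_fails(self, genome):
        cm = simulate.simulate_coverage(genome, bad_library_rate=1.0, seed=9)
        cm = cov.qc_all_samples(cm)
        assert not cm.samples["qc_pass"].any()

    def test_too_few_scaffolds_rejected(self):
        depths = pd.Series(np.ones(50), index=[f"s{i}" for i in range(50)])
        with pytest.raises(ValueError):
            cov.qc_sample_coverage(depths, depths * 1000, "F")


def _constant_matrix(depth=8.0, n=300):
    idx = pd.Index([f"s{i}" for i in range(n)], name="scaffold")
    depths = pd.DataFrame({lib: np.full(n, depth)
                           for lib in ("m1", "m2", "f1", "f2")}, index=idx)
    lengths = pd.Series(np.full(n, 2000), index=idx)
    samples = pd.DataFrame({"sex": ["M", "M", "F", "F"]},
                           index=["m1", "m2", "f1", "f2"])
    return cov.CoverageMatrix(depths, lengths, samples)


class TestNormalization:
    def test_constant_depth_normalizes_to_one(self):
        norm = cov.sex_summed_normalized_coverage(_constant_matrix())
        assert np.allclose(norm["male_norm"], 1.0)
        assert np.allclose(norm["female_norm"], 1.0)

    def test_autosomal_scaffolds_center_at_one(self, classified, genome):
        norm = classified["norm"]
        auto = genome.truth == "A"
        assert norm.loc[auto, "male_norm"].median() == pytest.approx(1.0,
                                                                     abs=0.05)
        assert norm.loc[auto, "female_norm"].median() == pytest.approx(1.0,
                                                                       abs=0.05)

    def test_scaling_one_library_leaves_calls_unchanged(self, coverage_matrix):
        cm = cov.qc_all_samples(coverage_matrix)
        male_lib = cm.samples.index[cm.samples["sex"] == "M"][0]
        scaled = cov.CoverageMatrix(
            cm.depths.assign(**{male_lib: cm.depths[male_lib] * 7.0}),
            cm.lengths, cm.samples)
        for m in (cm, scaled):
            m.norm = cov.sex_summed_normalized_coverage(m)
        assert np.allclose(cm.norm["male_norm"], scaled.norm["male_norm"])

    def test_missing_sex_rejected(self):
        m = _constant_matrix()
        m.samples.loc[["f1", "f2"], "sex"] = "M"
        with pytest.raises(ValueError):
            cov.sex_summed_normalized_coverage(m)


class TestLog2Ratio:
    def test_values_and_zero_flagging(self):
        norm = pd.DataFrame({"male_norm": [0.5, 1.0, 0.7, 0.0],
                             "female_norm": [1.0, 1.0, 0.0, 0.0]},
                            index=list("abcd"))
        r = cov.log2_mf_ratio(norm)
        assert r["a"] == pytest.approx(-1.0)
        assert r["b"] == pytest.approx(0.0)
        assert np.isnan(r["c"]) and np.isnan(r["d"])


class TestRatioPeaks:
    def test_peaks_near_expected_positions(self, classified):
        model = classified["model"]
        assert model.autosomal_peak == pytest.approx(0.0, abs=0.05)
        assert model.x_peak == pytest.approx(-1.0, abs=0.08)
        assert not model.x_peak_fallback

    def test_all_autosome_simulation_triggers_fallback(self):
        g = simulate.simulate_genome(1500, 0.0, seed=51)
        cm = simulate.simulate_coverage(g, seed=52)
        norm = cov.sex_summed_normalized_coverage(cm)
        model = cov.find_ratio_peaks(cov.log2_mf_ratio(norm), norm["length"])
        assert model.x_peak_fallback
        assert model.x_peak == pytest.approx(model.autosomal_peak - 1.0)

    def test_too_few_ratios_rejected(self):
        r = pd.Series(np.zeros(50))
        with pytest.raises(ValueError):
            cov.find_ratio_peaks(r, pd.Series(np.ones(50)))


class TestClassify:
    def test_liberal_rule_boundaries(self):
        model = cov.RatioModel(autosomal_peak=0.01, x_peak=-1.0, bandwidth=0.1)
        ratios = pd.Series([-1.02, -0.45, np.nan], index=list("abc"))
        calls = cov.classify_scaffolds(ratios, model)
        assert calls.loc["a", "call_liberal"] == "X"
        assert calls.loc["b", "call_liberal"] == "A"
        assert calls.loc["c", "call_liberal"] == "unclassified"

    def test_stringent_bands(self):
        model = cov.RatioModel(autosomal_peak=0.0, x_peak=-1.0, bandwidth=0.1)
        ratios = pd.Series([-1.05, -0.5, 0.08], index=list("abc"))
        calls = cov.classify_scaffolds(ratios, model, scheme="stringent")
        assert list(calls["call_stringent"]) == ["X", "unclassified", "A"]

    def test_recovery_on_long_scaffolds(self, classified, genome):
        calls, truth = classified["calls"], genome.truth
        long = genome.lengths >= 5000
        lib = calls["call_liberal"]
        sens = (((lib == "X") & (truth == "X") & long).sum()
                / ((truth == "X") & long).sum())
        spec = (((lib == "A") & (truth == "A") & long).sum()
                / ((truth == "A") & long).sum())
        assert sens >= 0.99 and spec >= 0.99
        agree_long = (calls.loc[long, "call_liberal"]
                      == calls.loc[long, "call_stringent"]).mean()
        assert agree_long >= 0.98

    def test_short_scaffolds_disagree_more(self, classified, genome):
        calls = classified["calls"]
        long = genome.lengths >= 5000
        agree = (calls["call_liberal"] == calls["call_stringent"])
        assert agree[~long].mean() < agree[long].mean()

    def test_stringent_x_subset_of_liberal_x(self, classified):
        calls = classified["calls"]
        strict_x = calls["call_stringent"] == "X"
        assert (calls.loc[strict_x, "call_liberal"] == "X").all()


class TestHetCorroboration:
    def test_hemizygous_males_corroborate_calls(self, genome, truth_calls):
        het = simulate.simulate_het_sites(genome, seed=61)
        males = het[het["sex"] == "M"]
        res = cov.male_x_heterozygosity_check(males, truth_calls)
        assert res["ratio"] <= 0.1
        assert not res["flagged"]

    def test_equal_rates_raise_flag(self, genome, truth_calls):
        het = simulate.simulate_het_sites(genome, x_ratio=1.0,
                                          error_rate=0.004, seed=62)
        males = het[het["sex"] == "M"]
        res = cov.male_x_heterozygosity_check(males, truth_calls)
        assert res["flagged"]

    def test_empty_class_rejected(self, genome):
        het = simulate.simulate_het_sites(genome, seed=63)
        all_a = pd.DataFrame({"call_liberal": ["A"] * len(genome.truth)},
                             index=genome.truth.index)
        with pytest.raises(ValueError):
            cov.male_x_heterozygosity_check(het[het["sex"] == "M"], all_a)


class TestAssignGenes:
    def test_genes_inherit_scaffold_calls(self, genome, truth_calls):
        out = cov.assign_genes(genome.genes, truth_calls)
        assert (out["linkage"] == out["truth_linkage"]).all()

    def test_unknown_scaffold_rejected(self, truth_calls):
        gm = pd.DataFrame({"gene": ["g1"], "scaffold": ["nope"]})
        with pytest.raises(ValueError):
            cov.assign_genes(gm, truth_calls)

    def test_stringent_leaves_more_genes_unclassified(self, classified, genome):
        calls = classified["calls"]
        lib = cov.assign_genes(genome.genes, calls, call_col="call_liberal")
        strg = cov.assign_genes(genome.genes, calls, call_col="call_stringent")
        assert ((strg["linkage"] == "unclassified").sum()
                >= (lib["linkage"] == "unclassified").sum())


class TestAnchorScaffolds:
    @pytest.fixture()
    def calls(self):
        return pd.DataFrame({"call_liberal": ["X", "A", "X", "A"]},
                            index=["q1", "q2", "q3", "q4"])

    def test_two_to_one_rule(self, calls):
        coords = pd.DataFrame({
            "query": ["q1", "q2", "q3", "q4"],
            "reference": ["r1", "r1", "r2", "r2"],
            "aligned_bases": [30_000, 10_000, 15_000, 10_000],
        })
        out = cov.anchor_scaffolds(coords, calls)
        assert out.loc["r1", "call"] == "X"        # 30k > 2 x 10k
        assert out.loc["r2", "call"] == "unclassified"  # 15k < 2 x 10k

    def test_min_anchored_bases(self, calls):
        coords = pd.DataFrame({
            "query": ["q1", "q2"],
            "reference": ["r1", "r1"],
            "aligned_bases": [9_999, 25_000],
        })
        out = cov.anchor_scaffolds(coords, calls)
        # q1 dropped: only the A-called q2 remains
        assert out.loc["r1", "x_bases"] == 0
        assert out.loc["r1", "call"] == "A"

    def test_malformed_coords_rejected(self, calls):
        with pytest.raises(ValueError):
            cov.anchor_scaffolds(pd.DataFrame({"query": ["q1"]}), calls)
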