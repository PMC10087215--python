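"""Tests of normalization, filtering, dosage summaries and NB-GLM bias tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from xlinker import expression as expr
from xlinker import simulate


def _design2(n=3):
    rows = [(f"M{i}", "sp1", "head", "M", i) for i in range(1, n + 1)]
    rows += [(f"F{i}", "sp1", "head", "F", i) for i in range(1, n + 1)]
    return (pd.DataFrame(rows, columns=["library", "species", "tissue",
                                        "sex", "replicate"])
            .set_index("library"))


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, 500).astype(float) + 1
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(expr.tmm_factors(counts), 1.0)

    def test_scaled_library_equalizes_cpm(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(4, 1, 2000)
        counts = pd.DataFrame({"a": rng.poisson(base),
                               "b": rng.poisson(2 * base)})
        eff = expr.effective_sizes(counts)
        cpm = counts / eff * 1e6
        med_ratio = np.median((cpm["b"] + 0.5) / (cpm["a"] + 0.5))
        assert med_ratio == pytest.approx(1.0, abs=0.02)

    def test_robust_to_a_few_extreme_de_genes(self):
        # 5% of genes 8-fold up in one library: the trim drops them, so the
        # factors barely move, while an untrimmed mean of M-values shifts
        rng = np.random.default_rng(3)
        base = rng.lognormal(4, 1, 2000)
        clean = pd.DataFrame({"a": rng.poisson(base), "b": rng.poisson(base)})
        order = np.argsort(base)
        de = order[:100]  # spike low-expression genes: totals barely change
        spiked = clean.copy()
        spiked.loc[de, "b"] = spiked.loc[de, "b"] * 8
        f_clean = expr.tmm_factors(clean)
        f_spiked = expr.tmm_factors(spiked)
        assert np.allclose(f_spiked, f_clean, rtol=0.02)
        lib = spiked.sum()
        m = np.log2((spiked["b"] / lib["b"] + 1e-12)
                    / (spiked["a"] / lib["a"] + 1e-12))
        untrimmed = 2.0 ** np.mean(m[np.isfinite(m)])
        ratio = f_spiked["b"] / f_spiked["a"]
        clean_ratio = f_clean["b"] / f_clean["a"]
        assert abs(ratio - clean_ratio) < abs(untrimmed - clean_ratio)

    def test_all_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            expr.tmm_factors(counts)


class TestNormalize:
    def test_fpkm_arithmetic(self):
        # two identical libraries of 1e7 counts -> factors 1, eff size 1e7
        counts = pd.DataFrame({
            "length": [1000, 1000],
            "a": [100, 10_000_000 - 100], "b": [100, 10_000_000 - 100],
        }, index=["g1", "g2"])
        fpkm = expr.normalize(counts, unit="FPKM")
        assert fpkm.loc["g1", "a"] == pytest.approx(10.0, rel=1e-6)

    def test_tpm_columns_sum_to_a_million(self, expression_sim):
        counts = expression_sim["counts"]
        libs = list(counts.columns[1:7])
        tpm = expr.normalize(counts[["length"] + libs], unit="TPM")
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_single_gene_library_tpm(self):
        counts = pd.DataFrame({"length": [500], "a": [42], "b": [7]},
                              index=["g1"])
        tpm = expr.normalize(counts, unit="TPM")
        assert np.allclose(tpm, 1e6)

    def test_fpkm_tpm_proportional_within_library(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame({"length": rng.integers(300, 5000, 200),
                               "a": rng.poisson(60, 200),
                               "b": rng.poisson(80, 200)})
        fpkm = expr.normalize(counts, unit="FPKM")
        tpm = expr.normalize(counts, unit="TPM")
        ratio = tpm["a"] / fpkm["a"].replace(0, np.nan)
        ratio = ratio.dropna()
        assert np.allclose(ratio, ratio.iloc[0])


class TestFilterExpressed:
    @pytest.fixture()
    def design(self):
        return _design2()

    def _expr(self, female, male):
        return pd.DataFrame([list(male) + list(female)], index=["g"],
                            columns=["M1", "M2", "M3", "F1", "F2", "F3"])

    def test_sex_limited_gene_excluded_by_default(self, design):
        e = self._expr(female=(10, 12, 11), male=(0, 0, 1))
        assert not expr.filter_expressed(e, design).loc["g"]

    def test_sex_limited_gene_kept_with_flag(self, design):
        e = self._expr(female=(10, 12, 11), male=(0, 0, 1))
        assert expr.filter_expressed(e, design,
                                     include_sex_limited=True).loc["g"]

    def test_expressed_gene_retained(self, design):
        e = self._expr(female=(10, 12, 11), male=(3, 2.5, 9))
        assert expr.filter_expressed(e, design).loc["g"]

    def test_single_low_library_tolerated(self, design):
        e = self._expr(female=(10, 12, 11), male=(3, 1, 9))
        assert expr.filter_expressed(e, design).loc["g"]


class TestLog2MF:
    def test_capping_of_sex_limited_ratios(self):
        design = _design2(2)
        e = pd.DataFrame({"M1": [4.0, 0.0, 0.0], "M2": [4.0, 0.0, 0.0],
                          "F1": [1.0, 5.0, 0.0], "F2": [1.0, 5.0, 0.0]},
                         index=["g1", "g2", "g3"])
        r = expr.log2_mf_expression(e, design.loc[["M1", "M2", "F1", "F2"]])
        assert r["g1"] == pytest.approx(2.0)
        assert r["g2"] == -expr.RATIO_CAP
        assert np.isnan(r["g3"])


class TestDosage:
    def test_regime_recovery_per_tissue(self, expression_sim):
        panel = expr.dosage_panel(expression_sim["counts"],
                                  expression_sim["linkage"],
                                  expression_sim["design"])
        for _, row in panel.iterrows():
            assert row["median_A"] == pytest.approx(0.0, abs=0.15)
            target = -1.0 if row["tissue"] == "reproductive_tract" else 0.0
            assert row["median_X"] == pytest.approx(target, abs=0.1)
        rt = panel[panel["tissue"] == "reproductive_tract"]
        assert (rt["q"] < 0.001).all()

    def test_missing_tissue_rejected(self, expression_sim):
        counts, des = expression_sim["counts"], expression_sim["design"]
        e = expr.normalize(counts)
        with pytest.raises(ValueError):
            expr.dosage_summary(e, expression_sim["linkage"], des,
                                tissue="antenna")

    def test_histogram_peak_at_twofold_reduction(self, expression_sim):
        counts, des = expression_sim["counts"], expression_sim["design"]
        sub = des[des["tissue"] == "reproductive_tract"]
        cell = counts[["length", *sub.index]]
        e = expr.normalize(cell)
        mask = expr.filter_expressed(e, sub)
        ds = expr.dosage_summary(e[mask], expression_sim["linkage"], sub,
                                 tissue="reproductive_tract")
        x_ratios = ds.per_gene.loc[ds.per_gene["linkage"] == "X", "log2_mf"]
        hist = expr.ratio_histogram(x_ratios, bins=40, lo=-4, hi=4)
        peak = hist.loc[hist["count"].idxmax()]
        assert peak["bin_left"] <= -1.0 <= peak["bin_right"] + 1e-9


class TestSexBiasTest:
    def test_identical_columns_give_no_calls(self):
        rng = np.random.default_rng(5)
        col = rng.poisson(100, 400)
        counts = pd.DataFrame({"length": 1000, "M1": col, "M2": col, "M3": col,
                               "F1": col, "F2": col, "F3": col},
                              index=[f"g{i}" for i in range(400)])
        res = expr.sex_bias_test(counts, _design2())
        assert (res["class"] == "unbiased").all()

    def test_fourfold_bias_power(self, genome):
        design = simulate.make_design(species=("sp1",), tissues=("head",))
        counts, des, truth = simulate.simulate_counts(
            genome, design, sexbias_fractions=(0.15, 0.0), sexbias_fold=4.0,
            seed=81)
        res = expr.sex_bias_test(counts, des)
        mb = (truth.gene_truth.set_index("gene")["bias_class"]
              == "male_biased").reindex(res.index)
        assert (res.loc[mb.to_numpy(), "class"] == "male_biased").mean() >= 0.8

    def test_null_calibration_across_seeds(self, genome):
        design = simulate.make_design(species=("sp1",), tissues=("head",))
        calls = total = 0
        for seed in range(10):
            counts, des, _ = simulate.simulate_counts(
                genome, design, sexbias_fractions=(0.0, 0.0), seed=900 + seed)
            res = expr.sex_bias_test(counts, des)
            calls += int((res["class"] != "unbiased").sum())
            total += len(res)
        assert calls / total <= 0.07

    def test_fold_rule_is_stricter(self, genome):
        design = simulate.make_design(species=("sp1",), tissues=("head",))
        counts, des, _ = simulate.simulate_counts(
            genome, design, sexbias_fractions=(0.1, 0.1), sexbias_fold=1.8,
            seed=82)
        loose = expr.sex_bias_test(counts, des)
        strict = expr.sex_bias_test(counts, des, fold_rule=True)
        n_loose = (loose["class"] != "unbiased").sum()
        n_strict = (strict["class"] != "unbiased").sum()
        assert n_strict <= n_loose
        assert (strict.loc[strict["class"] != "unbiased", "log2fc"]
                .abs() > 1.0).all()

    def test_no_replication_rejected(self):
        counts = pd.DataFrame({"length": [1000], "M1": [5], "F1": [7]},
                              index=["g1"])
        design = _design2(1)
        with pytest.raises(ValueError):
            expr.sex_bias_test(counts, design)


class TestInteractionTest:
    def test_power_and_calibration(self, genome):
        design = simulate.make_design(species=("sp1", "sp2", "sp3"),
                                      tissues=("head",))
        counts, des, truth = simulate.simulate_counts(
            genome, design, sexbias_fractions=(0.0, 0.0),
            interaction_fraction=0.1, seed=83)
        res = expr.interaction_test(counts, des)
        it = truth.gene_truth.set_index("gene")["interaction"].reindex(res.index)
        assert res.loc[it.to_numpy(), "interaction"].mean() >= 0.7
        assert res.loc[~it.to_numpy(), "interaction"].mean() <= 0.12

    def test_single_species_rejected(self, expression_sim):
        with pytest.raises(ValueError):
            expr.interaction_test(expression_sim["counts"],
                                  expression_sim["design"])


class TestBiasEnrichment:
    def _calls_frame(self, rng, link, enrich_female_on_x=1.0):
        n = len(link)
        p_f = np.where(link == "X", 0.05 * enrich_female_on_x, 0.05)
        u = rng.random(n)
        cls = np.where(u < p_f, "female_biased",
                       np.where(u < p_f + 0.05, "male_biased", "unbiased"))
        return pd.DataFrame({"species": "sp1", "tissue": "head",
                             "gene": [f"g{i}" for i in range(n)],
                             "class": cls})

    def test_unbiased_placement_not_significant(self):
        rng = np.random.default_rng(6)
        link = pd.Series(np.where(rng.random(6000) < 0.12, "X", "A"),
                         index=[f"g{i}" for i in range(6000)])
        calls = self._calls_frame(rng, link.to_numpy())
        out = expr.bias_enrichment(calls, link)
        assert (out["q"] >= 0.05).all()

    def test_doubled_female_bias_on_x_detected(self):
        rng = np.random.default_rng(7)
        link = pd.Series(np.where(rng.random(12_000) < 0.2, "X", "A"),
                         index=[f"g{i}" for i in range(12_000)])
        calls = self._calls_frame(rng, link.to_numpy(),
                                  enrich_female_on_x=2.5)
        out = expr.bias_enrichment(calls, link)
        female = out[out["direction"] == "female_biased"].iloc[0]
        assert female["q"] < 0.05 and female["odds_ratio"] > 1

    def test_uncompensated_tissue_mimics_female_bias_enrichment(
            self, expression_sim):
        # absent compensation, X genes look "female-biased": the confound
        counts, des = expression_sim["counts"], expression_sim["design"]
        sub = des[des["tissue"] == "reproductive_tract"]
        res = expr.sex_bias_test(counts[["length", *sub.index]], sub)
        calls = pd.DataFrame({"species": "sp1", "tissue": "reproductive_tract",
                              "gene": res.index, "class": res["class"]})
        out = expr.bias_enrichment(calls, expression_sim["linkage"])
        female = out[out["direction"] == "female_biased"].iloc[0]
        assert female["odds_ratio"] > 1 and female["q"] < 0.05


class TestInteractionUnderrepresentation:
    def test_depletion_detected(self):
        rng = np.random.default_rng(8)
        n = 4000
        genes = [f"g{i}" for i in range(n)]
        link = pd.Series(np.where(rng.random(n) < 0.3, "X", "A"), index=genes)
        inter_rate = np.where(link == "X", 0.02, 0.15)
        inter = pd.Series(rng.random(n) < inter_rate, index=genes)
        bias = pd.DataFrame({"gene": genes, "class": "female_biased"})
        res = expr.interaction_underrepresentation(bias, inter, link)
        assert res["odds_ratio"] < 1 and res["p"] < 0.01


class TestDCType:
    def _prepared(self, expression_sim, tissue):
        counts, des = expression_sim["counts"], expression_sim["design"]
        sub = des[des["tissue"] == tissue]
        e = expr.normalize(counts[["length", *sub.index]])
        mask = expr.filter_expressed(e, sub)
        return e[mask], sub

    def test_compensated_tissue_is_type_one(self, expression_sim):
        e, sub = self._prepared(expression_sim, "head")
        res = expr.dc_type(e, expression_sim["linkage"], sub, tissue="head")
        assert res["label"] == "type_I_male_hypertranscription"

    def test_uncompensated_tissue(self, expression_sim):
        e, sub = self._prepared(expression_sim, "reproductive_tract")
        res = expr.dc_type(e, expression_sim["linkage"], sub,
                           tissue="reproductive_tract")
        assert res["label"] == "no_compensation_male_X_reduced"

    def test_global_x_downregulation_is_not_type_one(self, expression_sim):
        e, sub = self._prepared(expression_sim, "head")
        link = expression_sim["linkage"].reindex(e.index)
        e = e.copy()
        e.loc[(link == "X").to_numpy()] *= 0.5  # X halved in both sexes
        res = expr.dc_type(e, expression_sim["linkage"], sub, tissue="head")
        assert res["label"] == "X_reduced_in_both_sexes"


class TestNullPValueUniformity:
    def test_nb_glm_null_ks(self, genome):
        design = simulate.make_design(species=("sp1",), tissues=("head",))
        counts, des, _ = simulate.simulate_counts(
            genome, design, sexbias_fractions=(0.0, 0.0), seed=85)
        res = expr.sex_bias_test(counts, des)
        assert kstest(res["p"], "uniform").statistic < 0.05
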