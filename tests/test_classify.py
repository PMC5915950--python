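import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from homeokit.classify import (
    ClassifyOptions,
    bh_adjust,
    classify_additivity,
    classify_bias,
    classify_transcriptome,
    nb_wald_test,
    relation_of,
    size_factors,
)
from homeokit.models import AdditivityCategory, BiasCategory, PatternClass, Relation
from homeokit.quant import CountSet

from oracles import bh_reference

EQ, GT, LT = Relation.EQ, Relation.GT, Relation.LT


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
    def test_matches_reference_implementation(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_reference(p), atol=1e-12)

    def test_order_preserving(self):
        p = [0.9, 0.001, 0.5, 0.02]
        adj = bh_adjust(p)
        assert list(np.argsort(adj, kind="stable")) == list(np.argsort(p, kind="stable"))


class TestRelationOf:
    def test_nonsignificant_is_eq(self):
        assert relation_of(0.05, 2.0) is EQ

    def test_boundary_inclusive(self):
        assert relation_of(0.001, 2.0) is not EQ

    def test_orientation(self):
        # log2fc is second-over-first: positive means the second group higher
        assert relation_of(0.0005, +2.0) is LT
        assert relation_of(0.0005, -2.0) is GT


class TestCategoryMaps:
    @pytest.mark.parametrize(
        "rels,expected",
        [
            ((EQ, GT, LT), AdditivityCategory.ADDITIVE),
            ((EQ, EQ, EQ), AdditivityCategory.ADDITIVE),
            ((GT, EQ, LT), AdditivityCategory.ELD_BD),
            ((LT, EQ, GT), AdditivityCategory.ELD_BD),
            ((GT, GT, EQ), AdditivityCategory.ELD_BS),
            ((GT, GT, GT), AdditivityCategory.TRANSGRESSIVE_UP),
            ((LT, LT, LT), AdditivityCategory.TRANSGRESSIVE_DOWN),
            ((GT, GT, LT), AdditivityCategory.OTHER_NONADDITIVE),
            ((GT, EQ, EQ), AdditivityCategory.OTHER_NONADDITIVE),
        ],
    )
    def test_additivity(self, rels, expected):
        assert classify_additivity(*rels) is expected

    def test_additivity_partition_exhaustive(self):
        for rels in itertools.product([EQ, GT, LT], repeat=3):
            category = classify_additivity(*rels)
            assert isinstance(category, AdditivityCategory)
            if rels[0] is EQ:
                assert category is AdditivityCategory.ADDITIVE

    @pytest.mark.parametrize(
        "anc,hyb,category,pattern",
        [
            (EQ, EQ, BiasCategory.NO_BIAS, PatternClass.ANCESTRAL),
            (GT, GT, BiasCategory.BIAS_RETAINED, PatternClass.ANCESTRAL),
            (LT, LT, BiasCategory.BIAS_RETAINED, PatternClass.ANCESTRAL),
            (GT, EQ, BiasCategory.BIAS_LOST, PatternClass.NONANCESTRAL),
            (LT, EQ, BiasCategory.BIAS_LOST, PatternClass.NONANCESTRAL),
            (EQ, GT, BiasCategory.BIAS_GAINED, PatternClass.NONANCESTRAL),
            (EQ, LT, BiasCategory.BIAS_GAINED, PatternClass.NONANCESTRAL),
            (GT, LT, BiasCategory.BIAS_REVERSED, PatternClass.NONANCESTRAL),
            (LT, GT, BiasCategory.BIAS_REVERSED, PatternClass.NONANCESTRAL),
        ],
    )
    def test_bias_all_nine_pairs(self, anc, hyb, category, pattern):
        got_cat, got_pattern = classify_bias(anc, hyb)
        assert got_cat is category and got_pattern is pattern


class TestSizeFactors:
    def test_scaling_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(500, 1)).astype(float)
        counts = pd.DataFrame(
            np.hstack([base, base * 2, base * 4]), columns=["a", "b", "c"]
        )
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-6)
        assert sf["c"] / sf["a"] == pytest.approx(4.0, rel=1e-6)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))


def _nb_frame(mean, phi, n, rng, prefix):
    lam = rng.gamma(1.0 / phi, np.outer(mean, np.ones(n)) * phi)
    return pd.DataFrame(rng.poisson(lam), columns=[f"{prefix}{i}" for i in range(n)])


class TestNbWaldTest:
    def test_identical_columns_give_eq(self):
        counts = pd.DataFrame({"a1": [10, 50], "a2": [12, 48], "a3": [9, 52]})
        res = nb_wald_test(counts, counts.rename(columns=lambda c: c.replace("a", "b")))
        assert (res["log2fc"] == 0).all()
        assert (res["relation"] == "EQ").all()

    def test_all_zero_genes_skipped(self):
        a = pd.DataFrame({"a1": [0, 5], "a2": [0, 6], "a3": [0, 4]}, index=["dead", "ok"])
        b = pd.DataFrame({"b1": [0, 9], "b2": [0, 8], "b3": [0, 10]}, index=["dead", "ok"])
        res = nb_wald_test(a, b)
        assert "dead" not in res.index and "ok" in res.index

    def test_too_few_replicates_raise(self):
        a = pd.DataFrame({"a1": [1]})
        b = pd.DataFrame({"b1": [1], "b2": [2]})
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_test(a, b)

    def test_null_calibration(self):
        rng = np.random.default_rng(21)
        mean = np.exp(rng.normal(np.log(150), 0.7, size=2_000))
        a = _nb_frame(mean, 0.05, 3, rng, "a")
        b = _nb_frame(mean, 0.05, 3, rng, "b")
        res = nb_wald_test(a, b)
        frac = (res["p"] < 0.05).mean()
        assert 0.02 < frac < 0.09

    def test_power_on_planted_fold_change(self):
        rng = np.random.default_rng(22)
        null_mean = np.exp(rng.normal(np.log(150), 0.7, size=2_000))
        planted_mean = np.maximum(np.exp(rng.normal(np.log(150), 0.5, size=400)), 50)
        a = pd.concat(
            [_nb_frame(null_mean, 0.05, 3, rng, "a"), _nb_frame(planted_mean, 0.05, 3, rng, "a")],
            ignore_index=True,
        )
        b = pd.concat(
            [_nb_frame(null_mean, 0.05, 3, rng, "b"), _nb_frame(planted_mean * 8, 0.05, 3, rng, "b")],
            ignore_index=True,
        )
        res = nb_wald_test(a, b)
        planted = res.loc[res.index >= 2_000]
        assert (planted["fdr"] <= 0.001).mean() >= 0.9
        assert (planted["log2fc"] > 0).all()  # B is higher

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(23)
        mean = np.exp(rng.normal(np.log(100), 0.5, size=300))
        a = _nb_frame(mean, 0.05, 3, rng, "a")
        b = _nb_frame(mean * 2, 0.05, 3, rng, "b")
        fwd = nb_wald_test(a, b)
        rev = nb_wald_test(b, a)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-10)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)


class TestClassifyTranscriptome:
    def test_planted_category_recovery(self, planted_counts):
        cs, truth, _ = planted_counts
        table = classify_transcriptome(cs, ClassifyOptions())
        assert len(table) > 0.9 * len(truth)
        add_acc = np.mean([table.loc[g, "additivity"] == truth[g]["additivity"] for g in table.index])
        bias_acc = np.mean([table.loc[g, "bias"] == truth[g]["bias"] for g in table.index])
        assert add_acc >= 0.9
        assert bias_acc >= 0.9

    def test_null_study_is_mostly_additive(self):
        from homeokit.simulate import SimConfig, simulate_ancestral_genomes, simulate_counts

        cfg = SimConfig(
            seed=31, genome_length=700_000, n_genes=300, dispersion=0.02,
            mu_log=math.log(3e-4), sigma_log=0.4, baseline_floor=1.2e-4,
            category_proportions={"ADDITIVE": 1.0},
            bias_proportions={"NO_BIAS": 1.0},
        )
        _, _, genes, _ = simulate_ancestral_genomes(cfg)
        cs, _, _ = simulate_counts(genes, cfg)
        table = classify_transcriptome(cs, ClassifyOptions())
        nonadditive = (table["additivity"] != "ADDITIVE").mean()
        assert nonadditive <= 0.05

    def test_unexpressed_genes_absent(self, planted_config):
        from homeokit.simulate import SimConfig, simulate_ancestral_genomes, simulate_counts

        cfg = SimConfig(
            seed=32, genome_length=120_000, n_genes=60, dispersion=0.02,
            mu_log=math.log(1e-7), sigma_log=0.2,  # far below the RPM≥1 line
        )
        _, _, genes, _ = simulate_ancestral_genomes(cfg)
        cs, _, _ = simulate_counts(genes, cfg)
        table = classify_transcriptome(cs, ClassifyOptions())
        assert len(table) == 0

    def test_ancestor_swap_symmetry(self, planted_counts):
        cs, _, _ = planted_counts
        table = classify_transcriptome(cs, ClassifyOptions())

        swap_group = {"BD": "BS", "BS": "BD", "BH_BD": "BH_BS", "BH_BS": "BH_BD"}
        swapped_meta = cs.samples.copy()
        swapped_meta["group"] = swapped_meta["group"].map(swap_group)
        swapped = CountSet(cs.counts, swapped_meta, cs.library_sizes)
        table_swapped = classify_transcriptome(swapped, ClassifyOptions())

        assert set(table.index) == set(table_swapped.index)
        swap_add = {
            "ELD_BD": "ELD_BS", "ELD_BS": "ELD_BD",
            "ADDITIVE": "ADDITIVE",
            "TRANSGRESSIVE_UP": "TRANSGRESSIVE_UP",
            "TRANSGRESSIVE_DOWN": "TRANSGRESSIVE_DOWN",
            "OTHER_NONADDITIVE": "OTHER_NONADDITIVE",
        }
        for g in table.index:
            assert table_swapped.loc[g, "additivity"] == swap_add[table.loc[g, "additivity"]]
            assert table_swapped.loc[g, "bias"] == table.loc[g, "bias"]

    def test_missing_group_raises(self, planted_counts):
        cs, _, _ = planted_counts
        keep = cs.samples.index[cs.samples["group"] != "BS"]
        partial = CountSet(cs.counts[keep], cs.samples.loc[keep], cs.library_sizes[keep])
        with pytest.raises(ValueError, match="missing group"):
            classify_transcriptome(partial, ClassifyOptions())
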