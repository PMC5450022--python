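"""Replicate averaging, control normalization, symbol merge and
strong-EMT stratification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from emtconv import meta
from emtconv.meta import (
    MergedCompendium,
    RawDataset,
    merge_by_symbol,
    normalize_dataset,
    score_columns,
    stratify_by_emt,
    upregulation_fraction,
)
from emtconv.scoring import SignatureSet
from emtconv.synthetic.compendium import CompendiumConfig, generate_compendium


def make_raw(expr_cols, meta_rows, genes, scale="linear", ds="D1"):
    expr = pd.DataFrame(expr_cols, index=genes)
    md = pd.DataFrame(meta_rows, columns=["sample", "treatment", "replicate",
                                          "is_control"])
    return RawDataset(ds, expr, md, scale=scale)


class TestNormalize:
    def test_replicate_mean_over_control_mean(self):
        raw = make_raw(
            {"t1": [4.0], "t2": [4.0], "c1": [2.0], "c2": [2.0]},
            [("t1", "T", 0, False), ("t2", "T", 1, False),
             ("c1", "ctrl", 0, True), ("c2", "ctrl", 1, True)],
            genes=["G"],
        )
        out = normalize_dataset(raw)
        assert out.loc["G", "T"] == pytest.approx(1.0)

    def test_treatment_equal_to_control_gives_zero(self):
        raw = make_raw(
            {"t1": [5.0, 7.0], "c1": [5.0, 7.0]},
            [("t1", "T", 0, False), ("c1", "ctrl", 0, True)],
            genes=["G1", "G2"],
        )
        out = normalize_dataset(raw)
        assert np.allclose(out["T"], 0.0)

    def test_multiple_treatments_share_one_control(self):
        raw = make_raw(
            {"a": [8.0], "b": [2.0], "c1": [4.0]},
            [("a", "TA", 0, False), ("b", "TB", 0, False),
             ("c1", "ctrl", 0, True)],
            genes=["G"],
        )
        out = normalize_dataset(raw)
        assert out.loc["G", "TA"] == pytest.approx(1.0)
        assert out.loc["G", "TB"] == pytest.approx(-1.0)

    def test_nonpositive_control_mean_fails_naming_gene(self):
        raw = make_raw(
            {"t1": [4.0], "c1": [0.0]},
            [("t1", "T", 0, False), ("c1", "ctrl", 0, True)],
            genes=["BadGene"],
        )
        with pytest.raises(ValueError, match="BadGene"):
            normalize_dataset(raw)

    def test_log2_vs_control_passthrough_is_idempotent(self):
        expr = pd.DataFrame({"T": [1.0, -0.5]}, index=["G1", "G2"])
        md = pd.DataFrame([("T", "T", 0, False)],
                          columns=["sample", "treatment", "replicate", "is_control"])
        raw = RawDataset("D", expr, md, scale="log2-vs-control")
        out = normalize_dataset(raw)
        assert np.allclose(out["T"], expr["T"])

    def test_log2_intensity_scale_handled(self):
        # log2 intensities: treatment 3, control 2 → ratio 2 → log2FC 1
        raw = make_raw(
            {"t1": [3.0], "c1": [2.0]},
            [("t1", "T", 0, False), ("c1", "ctrl", 0, True)],
            genes=["G"], scale="log2",
        )
        assert normalize_dataset(raw).loc["G", "T"] == pytest.approx(1.0)

    def test_undeclared_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            make_raw(
                {"t1": [1.0], "c1": [1.0]},
                [("t1", "T", 0, False), ("c1", "ctrl", 0, True)],
                genes=["G"], scale="mystery",
            )


class TestMerge:
    def test_shared_genes_no_missing_cells(self):
        n1 = pd.DataFrame({"T": [1.0, 2.0]}, index=["A", "B"])
        n2 = pd.DataFrame({"T": [0.5, 0.1]}, index=["A", "B"])
        comp = merge_by_symbol({"D1": n1, "D2": n2})
        assert comp.matrix.shape == (2, 2)
        assert not comp.matrix.isna().any().any()

    def test_private_gene_stays_missing(self):
        n1 = pd.DataFrame({"T": [1.0, 2.0]}, index=["A", "B"])
        n2 = pd.DataFrame({"T": [0.5]}, index=["A"])
        n3 = pd.DataFrame({"T": [0.2]}, index=["A"])
        comp = merge_by_symbol({"D1": n1, "D2": n2, "D3": n3})
        row_b = comp.matrix.loc["B"]
        assert row_b.isna().sum() == 2

    def test_alias_applied_before_merge_collapses_rows(self):
        n1 = pd.DataFrame({"T": [1.0]}, index=["SNAI2"])
        n2 = pd.DataFrame({"T": [2.0]}, index=["SLUG"])
        aliases = pd.DataFrame({"alias": ["SNAI2"], "official": ["SLUG"]})
        comp = merge_by_symbol({"D1": n1, "D2": n2}, alias_table=aliases)
        assert list(comp.matrix.index) == ["SLUG"]
        assert comp.matrix.shape == (1, 2)

    def test_duplicate_symbols_collapse_by_mean(self, caplog):
        n1 = pd.DataFrame({"T": [1.0, 3.0]}, index=["A", "A"])
        with caplog.at_level("WARNING"):
            comp = merge_by_symbol({"D1": n1})
        assert comp.matrix.loc["A", ("D1", "T")] == pytest.approx(2.0)
        assert any("collapsing duplicate" in r.message for r in caplog.records)

    def test_merge_conservation_of_nonmissing_cells(self):
        rng = np.random.default_rng(0)
        frames = {}
        total = 0
        for d in range(3):
            genes = [f"G{i}" for i in rng.choice(20, size=rng.integers(5, 15),
                                                 replace=False)]
            frames[f"D{d}"] = pd.DataFrame(
                {"T": rng.normal(size=len(genes))}, index=genes
            )
            total += len(genes)
        comp = merge_by_symbol(frames)
        assert int(comp.matrix.notna().sum().sum()) == total

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            merge_by_symbol({})


def small_compendium(values_by_col, genes):
    cols = pd.MultiIndex.from_tuples(
        [(f"D{i}", "T") for i in range(len(values_by_col))],
        names=["dataset", "treatment"],
    )
    mat = pd.DataFrame(np.array(values_by_col).T, index=genes, columns=cols)
    return MergedCompendium(matrix=mat, species="human")


class TestUpregulationFraction:
    def test_eight_of_ten(self):
        vals = [[1.0]] * 8 + [[0.0]] * 2
        comp = small_compendium(vals, ["STAT3"])
        r = upregulation_fraction(comp, "STAT3", fold_threshold=1.5)
        assert r.percent == 80.0 and r.basis == 10

    def test_threshold_one_counts_any_increase(self):
        vals = [[0.1]] * 5
        comp = small_compendium(vals, ["STAT3"])
        r = upregulation_fraction(comp, "STAT3", fold_threshold=1.0)
        assert r.percent == 100.0

    def test_missing_columns_shrink_basis(self):
        vals = [[1.0]] * 5 + [[np.nan]] * 5
        comp = small_compendium(vals, ["STAT3"])
        r = upregulation_fraction(comp, "STAT3", fold_threshold=1.5)
        assert r.percent == 100.0 and r.basis == 5

    def test_absent_gene_fails(self):
        comp = small_compendium([[1.0]], ["STAT3"])
        with pytest.raises(KeyError):
            upregulation_fraction(comp, "NOPE")


SIG = SignatureSet("EMT", up=("UPG",), down=("DNG",))


class TestStratify:
    def test_threshold_responder_enriched_in_strong_group(self):
        cfg = CompendiumConfig(seed=1)
        datasets, truth = generate_compendium(cfg)
        comp = merge_by_symbol(
            {d.dataset_id: normalize_dataset(d) for d in datasets},
            species="mouse",
        )
        sig = SignatureSet("EMT", up=tuple(cfg.up_genes), down=tuple(cfg.down_genes))
        strat = stratify_by_emt(comp, sig).set_index("gene")
        assert strat.loc["Sox2", "strong_pct"] > strat.loc["Sox2", "weak_pct"]

    def test_universal_gene_similar_across_groups(self):
        cfg = CompendiumConfig(seed=1)
        datasets, truth = generate_compendium(cfg)
        comp = merge_by_symbol(
            {d.dataset_id: normalize_dataset(d) for d in datasets},
            species="mouse",
        )
        sig = SignatureSet("EMT", up=tuple(cfg.up_genes), down=tuple(cfg.down_genes))
        strat = stratify_by_emt(comp, sig).set_index("gene")
        # Stat3's effect is independent of EMT strength: the two group
        # fractions differ by no more than binomial noise allows
        n_strong = strat.loc["Stat3", "strong_basis"]
        se = 100 * math.sqrt(0.25 / n_strong + 0.25 / strat.loc["Stat3", "weak_basis"])
        assert abs(strat.loc["Stat3", "diff"]) <= 3 * se

    def test_too_few_columns_rejected(self):
        comp = small_compendium([[1.0, 1.0]] * 3, ["UPG", "DNG"])
        with pytest.raises(ValueError):
            stratify_by_emt(comp, SIG)


class TestRecovery:
    def test_stat3_fraction_matches_normal_tail_within_3se(self):
        """On a 30-dataset synthetic compendium the Stat3 up-regulation
        fraction at 1.5× must match the closed-form Normal tail
        P(log2FC > log2 1.5) within 3 binomial standard errors."""
        cfg = CompendiumConfig(n_datasets=30, seed=2)
        datasets, truth = generate_compendium(cfg)
        comp = merge_by_symbol(
            {d.dataset_id: normalize_dataset(d) for d in datasets},
            species="mouse",
        )
        r = upregulation_fraction(comp, "Stat3", fold_threshold=1.5)
        p = 1.0 - norm.cdf((math.log2(1.5) - cfg.stat3_b) / cfg.stat3_sigma)
        se = math.sqrt(p * (1 - p) / r.basis)
        assert abs(r.percent / 100 - p) <= 3 * se


class TestCompendiumGenerator:
    def test_noise_free_limit_exact_fold_changes(self):
        cfg = CompendiumConfig(
            n_datasets=2, sigma=1e-12, replicate_log2_sd=1e-12,
            s_range=(1.0, 1.0), a=1.0, seed=0,
        )
        datasets, truth = generate_compendium(cfg)
        out = normalize_dataset(datasets[0])
        for g in cfg.up_genes:
            assert out.loc[g, "EMT"] == pytest.approx(1.0, abs=1e-6)
        for g in cfg.down_genes:
            assert out.loc[g, "EMT"] == pytest.approx(-1.0, abs=1e-6)

    def test_null_strength_keeps_sox2_centered_at_zero(self):
        cfg = CompendiumConfig(n_datasets=40, s_range=(0.0, 0.0), seed=4)
        datasets, truth = generate_compendium(cfg)
        assert abs(truth.sox2_log2fc.mean()) < 3 * cfg.sox2_sigma / math.sqrt(40)

    def test_determinism_and_truth_alignment(self):
        a_sets, a_truth = generate_compendium(CompendiumConfig(seed=9))
        b_sets, b_truth = generate_compendium(CompendiumConfig(seed=9))
        assert a_truth.equals(b_truth)
        assert all(x.expression.equals(y.expression)
                   for x, y in zip(a_sets, b_sets))

    def test_zero_datasets_rejected(self):
        with pytest.raises(ValueError):
            CompendiumConfig(n_datasets=0).validate()

    def test_special_genes_must_be_unique(self):
        cfg = CompendiumConfig()
        cfg.genes = cfg.genes + ["Stat3"]
        with pytest.raises(ValueError, match="Stat3"):
            cfg.validate()
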