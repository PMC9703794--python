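"""Differential expression, integration statistics and batch scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conet.datasets import GeneSetCollection
from conet.integration import (
    differential_expression,
    gene_set_frequency,
    moderated_ttest,
    occurrence_ranking,
    scale_compendium,
    significance_score,
)
from conet.synthetic import CompendiumConfig, generate_compendium

from conftest import make_dataset


def _limma_fixture():
    """Deterministic 10-gene, 5v5 matrix with a few planted effects."""
    rng = np.random.default_rng(42)
    x = rng.normal(7, 1, size=(10, 10))
    effect = np.array([2, 0, 1, 0, 0, -1.5, 0, 0, 0.5, 0], dtype=float)
    x[:, :5] += effect[:, None]
    return x


# p values of the fixture computed with the reference empirical-Bayes
# moderated t implementation (limma 3.58.1 eBayes/lmFit), frozen
LIMMA_P = np.array([
    2.7963100559e-05, 0.0988232474463, 0.152010414888, 0.689012178929,
    0.636330496486, 0.000302827927498, 0.621080930003, 0.15277537048,
    0.795127245436, 0.277647859958,
])
LIMMA_LOGFC = np.array([
    2.27302809564, 0.7877742093, 0.67694376248, 0.20484332394, -0.21809193832,
    -1.90203210336, -0.2412989504, -0.68537111926, -0.12062483678, 0.52986248174,
])


class TestModeratedT:
    def test_matches_reference_implementation(self):
        x = _limma_fixture()
        logfc, _, p = moderated_ttest(x[:, :5], x[:, 5:])
        np.testing.assert_allclose(logfc, LIMMA_LOGFC, atol=1e-9)
        np.testing.assert_allclose(p, LIMMA_P, rtol=1e-8)

    def test_zero_noise_exact_shift_flagged(self):
        x = np.full((3, 8), 4.0)
        x[0, :4] = 6.0  # +2 shift on the log2 scale in the case arm
        ds = make_dataset(x, 4)
        tab = differential_expression(ds)
        assert tab.loc["g0", "logFC"] == pytest.approx(2.0)
        assert tab.loc["g0", "direction"] == "up"

    def test_identical_arms_are_ns(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (3, 2)).reshape(3, 8)
        ds = make_dataset(x, 4)
        tab = differential_expression(ds)
        assert (tab["logFC"] == 0).all()
        assert (tab["direction"] == "ns").all()
        assert (tab["pval"] == 1.0).all()

    def test_single_condition_rejected(self):
        x = np.random.default_rng(0).normal(size=(4, 6))
        ds = make_dataset(x, 6)  # all case, no control arm
        with pytest.raises(ValueError):
            differential_expression(ds)

    def test_welch_fallback_agrees_on_strong_effects(self):
        rng = np.random.default_rng(1)
        x = rng.normal(7, 0.3, size=(20, 20))
        x[:5, :10] += 3.0
        ds = make_dataset(x, 10)
        mod = differential_expression(ds, method="moderated")
        wel = differential_expression(ds, method="welch")
        assert list(mod[mod.direction != "ns"].index[:5]) == list(
            wel[wel.direction != "ns"].index[:5]
        )


class TestSignificanceScore:
    def test_neutral_adjusted_p_gives_zero(self):
        assert significance_score(3.2, 1.0) == 0.0

    def test_zero_fold_change_gives_zero(self):
        assert significance_score(0.0, 0.001) == 0.0

    def test_direct_evaluation(self):
        assert significance_score(2.0, 0.01) == pytest.approx(4.0)
        assert significance_score(-2.0, 0.01) == pytest.approx(4.0)  # magnitude

    def test_out_of_range_adjusted_p_rejected(self):
        with pytest.raises(ValueError):
            significance_score(1.0, 0.0)
        with pytest.raises(ValueError):
            significance_score(1.0, 1.5)


def _fake_de_table(genes, up=(), down=(), ss=None):
    direction = ["up" if g in up else "down" if g in down else "ns" for g in genes]
    return pd.DataFrame(
        {
            "logFC": [1.0 if g in up else -1.0 if g in down else 0.0 for g in genes],
            "pval": 0.5,
            "adj_pval": 0.5,
            "direction": direction,
            "ss": ss if ss is not None else [0.0] * len(genes),
        },
        index=pd.Index(genes, name="gene"),
    )


class TestOccurrence:
    genes = ["a", "b", "c", "d"]

    def test_counts_and_consistency(self):
        tables = [
            _fake_de_table(self.genes, up=("a",), down=("b",)),
            _fake_de_table(self.genes, up=("a", "b")),
            _fake_de_table(self.genes, up=("a",)),
        ]
        occ = occurrence_ranking(tables)
        assert occ.loc["a", "occurrence"] == 3
        assert occ.loc["a", "Cg"] == 3
        assert bool(occ.loc["a", "consistent"])
        # b: up once, down once -> occurrence 2, Cg 0, inconsistent
        assert occ.loc["b", "occurrence"] == 2
        assert occ.loc["b", "Cg"] == 0
        assert not bool(occ.loc["b", "consistent"])

    def test_balanced_calls_cancel(self):
        tables = [_fake_de_table(self.genes, up=("c",)) for _ in range(3)] + [
            _fake_de_table(self.genes, down=("c",)) for _ in range(3)
        ]
        occ = occurrence_ranking(tables)
        assert occ.loc["c", "occurrence"] == 6
        assert occ.loc["c", "Cg"] == 0

    def test_ordering_by_occurrence_then_ss(self):
        t1 = _fake_de_table(self.genes, up=("a", "b"), ss=[1.0, 5.0, 0, 0])
        t2 = _fake_de_table(self.genes, up=("a",), ss=[1.0, 5.0, 0, 0])
        occ = occurrence_ranking([t1, t2])
        assert list(occ.index[:2]) == ["a", "b"]  # a: occ 2 beats b: occ 1
        # tie on occurrence broken by larger median ss
        t3 = _fake_de_table(self.genes, up=("a", "b"), ss=[1.0, 5.0, 0, 0])
        occ = occurrence_ranking([t3])
        assert list(occ.index[:2]) == ["b", "a"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            occurrence_ranking([])

    def test_occurrence_identity(self):
        tables = [
            _fake_de_table(self.genes, up=("a",), down=("b",)),
            _fake_de_table(self.genes, down=("a", "b")),
        ]
        occ = occurrence_ranking(tables)
        assert (occ["occurrence"] == occ["up_datasets"] + occ["down_datasets"]).all()
        assert (occ["Cg"] <= occ["occurrence"]).all()


class TestGeneSetFrequency:
    universe = [f"g{i}" for i in range(100)]

    def test_set_equal_to_all_deg_lists(self):
        degs = tuple(self.universe[:20])
        tables = [_fake_de_table(self.universe, up=degs) for _ in range(4)]
        sets = GeneSetCollection({"S": ("", degs)})
        freq = gene_set_frequency(tables, sets, self.universe)
        assert freq.set_index("set").loc["S", "frequency"] == 4

    def test_disjoint_set_never_counted(self):
        tables = [_fake_de_table(self.universe, up=tuple(self.universe[:20]))]
        sets = GeneSetCollection({"S": ("", self.universe[50:60])})
        freq = gene_set_frequency(tables, sets, self.universe)
        assert freq.set_index("set").loc["S", "frequency"] == 0

    def test_threshold_matches_exact_hypergeometric_oracle(self):
        # universe 100, set 10, DEGs 20, overlap 8: exact upper-tail p by
        # direct summation of the hypergeometric pmf
        set_genes = self.universe[:10]
        degs = tuple(self.universe[:8] + self.universe[20:32])  # overlap 8, 20 DEGs
        p_exact = sum(
            stats.hypergeom.pmf(k, 100, 10, 20) for k in range(8, 11)
        )
        tables = [_fake_de_table(self.universe, up=degs)]
        sets = GeneSetCollection({"S": ("", set_genes)})
        freq = gene_set_frequency(tables, sets, self.universe, alpha=0.05)
        counted = freq.set_index("set").loc["S", "frequency"] == 1
        assert counted == (p_exact <= 0.05)
        assert p_exact < 1e-4  # and indeed it is counted
        assert counted


class TestScaling:
    def test_single_batch_noop(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=(5, 8)), 4)
        scaled = scale_compendium([ds])
        np.testing.assert_allclose(scaled.expr.to_numpy(), ds.expr.to_numpy())

    def test_batch_means_equalized(self):
        a = make_dataset(np.full((2, 4), 5.0), 2, "A")
        b = make_dataset(np.full((2, 4), 7.0), 2, "B")
        scaled = scale_compendium([a, b])
        for batch in ("A", "B"):
            cols = scaled.batch.index[scaled.batch == batch]
            np.testing.assert_allclose(scaled.expr[cols].mean(axis=1), 6.0)

    def test_three_batch_group_centering_oracle(self):
        rng = np.random.default_rng(3)
        datasets = [make_dataset(rng.normal(size=(6, 10)), 5, f"D{i}") for i in range(3)]
        scaled = scale_compendium(datasets)
        merged = pd.concat([d.expr for d in datasets], axis=1)
        grand = merged.mean(axis=1)
        expected = merged.copy()
        for d in datasets:
            cols = d.expr.columns
            expected[cols] = merged[cols].sub(merged[cols].mean(axis=1), axis=0).add(
                grand, axis=0
            )
        np.testing.assert_allclose(scaled.expr.to_numpy(), expected.to_numpy())

    def test_within_batch_variance_preserved(self):
        rng = np.random.default_rng(4)
        datasets = [make_dataset(rng.normal(size=(6, 12)), 6, f"D{i}") for i in range(2)]
        scaled = scale_compendium(datasets)
        for d in datasets:
            cols = d.expr.columns
            np.testing.assert_allclose(
                scaled.expr[cols].var(axis=1), d.expr.var(axis=1), rtol=1e-12
            )

    def test_gene_intersection(self):
        a = make_dataset(np.zeros((3, 4)), 2, "A")
        b = make_dataset(np.zeros((3, 4)), 2, "B")
        b.expr.index = ["g1", "g2", "gX"]
        scaled = scale_compendium([a, b])
        assert list(scaled.expr.index) == ["g1", "g2"]
        c = make_dataset(np.zeros((2, 4)), 2, "C")
        c.expr.index = ["other1", "other2"]
        with pytest.raises(ValueError):
            scale_compendium([a, c])


def test_bh_adjustment_is_monotone_in_raw_p():
    rng = np.random.default_rng(0)
    ds = make_dataset(rng.normal(7, 1, size=(50, 12)), 6)
    tab = differential_expression(ds)
    order = tab["pval"].argsort()
    adj_sorted = tab["adj_pval"].to_numpy()[order]
    assert (np.diff(adj_sorted) >= -1e-12).all()
    assert (tab["adj_pval"] >= tab["pval"] - 1e-12).all()


def test_planted_effects_are_fully_consistent_across_datasets():
    cfg = CompendiumConfig(
        n_datasets=4, n_genes=120, samples_per_arm=20, n_deg=16,
        module_spec=((20, 0.7),), n_hub_switch=0, n_bridge=0, seed=21,
    )
    datasets, truth = generate_compendium(cfg)
    tables = [differential_expression(d) for d in datasets]
    occ = occurrence_ranking(tables)
    planted = occ.loc[truth.deg_ids]
    recurrent = planted[planted["occurrence"] >= 2]
    assert len(recurrent) > 0
    assert recurrent["consistent"].all()
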