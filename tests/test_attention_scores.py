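import numpy as np
import pandas as pd
import pytest

from ikgm import attention_scores as sc
from ikgm.han_classifier import AttentionOutput
from ikgm.io_formats import Manifest, ManifestRow


def _attn(protein_ids, weights):
    w = np.asarray(weights, dtype=float)
    return AttentionOutput(
        protein_ids=tuple(protein_ids),
        word_attn=[np.array([1.0])] * len(w),
        sent_attn=w,
        sentence_vectors=np.zeros((len(w), 4)),
        document_vector=np.zeros(4),
        probs=np.array([0.5, 0.5]),
    )


class TestComputePas:
    def test_scores_are_sentence_attentions(self):
        outs = {"s1": _attn(["p1", "p2", "p3"], [0.5, 0.3, 0.2])}
        pas = sc.compute_pas(outs, {"p1": "A", "p2": "A", "p3": "B"}, view=1)
        assert pas["score"].tolist() == [0.5, 0.3, 0.2]
        assert pas["gene_symbol"].tolist() == ["A", "A", "B"]
        assert pas.groupby("species_id")["score"].sum().iloc[0] == pytest.approx(1.0)

    def test_unmapped_protein_kept_with_empty_symbol(self):
        outs = {"s1": _attn(["p1", "p2"], [0.6, 0.4])}
        pas = sc.compute_pas(outs, {"p1": "A"}, view=1)
        assert pas.loc[pas.protein_id == "p2", "gene_symbol"].iloc[0] == ""

    def test_missing_species_rejected(self):
        outs = {"s1": _attn(["p1"], [1.0])}
        with pytest.raises(ValueError, match="missing"):
            sc.compute_pas(outs, None, view=1, species_ids=["s1", "s2"])


class TestAggregate:
    def test_gene_sums(self):
        outs = {"s1": _attn(["p1", "p2", "p3"], [0.5, 0.3, 0.2])}
        pas = sc.compute_pas(outs, {"p1": "A", "p2": "A", "p3": "B"}, view=1)
        mat = sc.aggregate_by_gene(pas)
        assert mat.loc["A", "s1"] == pytest.approx(0.8)
        assert mat.loc["B", "s1"] == pytest.approx(0.2)

    def test_absent_gene_gets_zero_and_column_sums_bounded(self):
        outs = {
            "s1": _attn(["p1", "p2"], [0.7, 0.3]),
            "s2": _attn(["q1"], [1.0]),
        }
        gene_map = {"p1": "A", "p2": "B", "q1": "A"}
        mat = sc.aggregate_by_gene(sc.compute_pas(outs, gene_map, view=1))
        assert mat.loc["B", "s2"] == 0.0
        assert (mat.sum(axis=0) <= 1.0 + 1e-12).all()

    def test_empty_symbol_rows_dropped(self):
        outs = {"s1": _attn(["p1", "p2"], [0.6, 0.4])}
        mat = sc.aggregate_by_gene(sc.compute_pas(outs, {"p1": "A"}, view=1))
        assert list(mat.index) == ["A"]
        assert mat.loc["A", "s1"] == pytest.approx(0.6)


class TestCosine:
    def test_orthogonal(self):
        assert sc.cosine_similarity([1, 0], [0, 1]) == 0.0

    def test_colinear(self):
        assert sc.cosine_similarity([2, 2, 2], [1, 1, 1]) == pytest.approx(1.0)

    def test_reference_value(self):
        # dot=32, norms sqrt(14)*sqrt(77)
        assert sc.cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(
            0.974632, abs=1e-6
        )

    def test_zero_vector_warns_zero(self):
        with pytest.warns(UserWarning, match="zero vector"):
            assert sc.cosine_similarity([0, 0], [1, 1]) == 0.0


def _matrix(data, species, view):
    df = pd.DataFrame(data, columns=species).T  # temp
    df = pd.DataFrame(data)
    df.columns = species
    df.attrs["view"] = view
    return df


class TestFusion:
    def test_colinear_rows_pass_through_mean(self):
        m1 = pd.DataFrame({"s1": [0.2], "s2": [0.4]}, index=["g"])
        m2 = pd.DataFrame({"s1": [0.4], "s2": [0.8]}, index=["g"])
        m1.attrs["view"], m2.attrs["view"] = 1, 2
        fused = sc.fuse_pas(m1, m2)
        np.testing.assert_allclose(fused.loc["g"], [0.3, 0.6])

    def test_discordant_rows_are_gated_to_zero(self):
        m1 = pd.DataFrame({"s1": [1.0], "s2": [0.0]}, index=["g"])
        m2 = pd.DataFrame({"s1": [0.0], "s2": [1.0]}, index=["g"])
        fused = sc.fuse_pas(m1, m2)
        np.testing.assert_allclose(fused.loc["g"], [0.0, 0.0])

    def test_arithmetic_reference(self):
        m1 = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["g"])
        m2 = pd.DataFrame({"s1": [4.0], "s2": [5.0], "s3": [6.0]}, index=["g"])
        fused = sc.fuse_pas(m1, m2)
        np.testing.assert_allclose(
            fused.loc["g"], 0.9746318462 * np.array([2.5, 3.5, 4.5]), rtol=1e-9
        )

    def test_matches_independent_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            G, S = rng.integers(2, 6), rng.integers(2, 5)
            a = rng.random((G, S))
            b = rng.random((G, S))
            genes = [f"g{i}" for i in range(G)]
            species = [f"s{j}" for j in range(S)]
            m1 = pd.DataFrame(a, index=genes, columns=species)
            m2 = pd.DataFrame(b, index=genes, columns=species)
            fused = sc.fuse_pas(m1, m2)
            # independent direct arithmetic per gene
            for i, g in enumerate(genes):
                sim = a[i] @ b[i] / (np.linalg.norm(a[i]) * np.linalg.norm(b[i]))
                np.testing.assert_allclose(
                    fused.loc[g].to_numpy(), sim * (a[i] + b[i]) / 2, atol=1e-9
                )

    def test_outer_join_with_zeros(self):
        m1 = pd.DataFrame({"s1": [0.5]}, index=["g1"])
        m2 = pd.DataFrame({"s1": [0.5, 0.5]}, index=["g1", "g2"])
        fused = sc.fuse_pas(m1, m2)
        assert set(fused.index) == {"g1", "g2"}
        # g2 is absent from view 1: its zero row gates the fused score to 0
        assert fused.loc["g2", "s1"] == 0.0

    def test_disjoint_gene_sets_rejected(self):
        m1 = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        m2 = pd.DataFrame({"s1": [1.0]}, index=["g2"])
        with pytest.raises(ValueError, match="disjoint"):
            sc.fuse_pas(m1, m2)


class TestGasDas:
    def _manifest(self):
        return Manifest(
            (
                ManifestRow("s1", "diurnal", "x"),
                ManifestRow("s2", "diurnal", "x"),
                ManifestRow("s3", "nocturnal", "x"),
            )
        )

    def test_gas_normalizes_within_taxon(self):
        mat = pd.DataFrame(
            {"s1": [0.8, 0.2], "s2": [0.4, 0.6], "s3": [0.5, 0.5]},
            index=["A", "B"],
        )
        mat.attrs["view"] = 1
        gas = sc.compute_gas(mat, self._manifest())
        d = gas[gas.taxon == "diurnal"].set_index("gene_symbol")["score"]
        assert d["A"] == pytest.approx(0.6)
        assert d["B"] == pytest.approx(0.4)
        for taxon in ("diurnal", "nocturnal"):
            assert gas[gas.taxon == taxon]["score"].sum() == pytest.approx(1.0)

    def test_das_sums_to_two(self):
        mat = pd.DataFrame(
            {"s1": [0.8, 0.2], "s2": [0.4, 0.6], "s3": [0.5, 0.5]},
            index=["A", "B"],
        )
        mat.attrs["view"] = 2
        das = sc.compute_das(sc.compute_gas(mat, self._manifest()))
        assert das["score"].sum() == pytest.approx(2.0, abs=1e-9)

    def test_das_addition_example(self):
        gas = pd.DataFrame(
            {
                "view": 1,
                "taxon": ["d", "d", "n", "n"],
                "gene_symbol": ["A", "B", "A", "B"],
                "score": [0.5, 0.5, 0.75, 0.25],
            }
        )
        das = sc.compute_das(gas).set_index("gene_symbol")["score"]
        assert das["A"] == pytest.approx(1.25)
        assert das["B"] == pytest.approx(0.75)

    def test_identical_taxa_give_flat_das(self):
        gas = pd.DataFrame(
            {
                "view": 1,
                "taxon": ["d", "d", "n", "n"],
                "gene_symbol": ["A", "B", "A", "B"],
                "score": [0.5, 0.5, 0.5, 0.5],
            }
        )
        das = sc.compute_das(gas)
        assert das["score"].nunique() == 1


class TestRanking:
    def _das(self, scores):
        return pd.DataFrame(
            {
                "view": 1,
                "gene_symbol": [f"g{i:03d}" for i in range(len(scores))],
                "score": scores,
            }
        )

    def test_ceil_of_top_fraction(self):
        das = self._das(np.linspace(1, 0, 300))
        assert len(sc.rank_top_fraction(das, 0.01)) == 3

    def test_full_fraction_returns_all(self):
        das = self._das([3.0, 1.0, 2.0])
        assert len(sc.rank_top_fraction(das, 1.0)) == 3

    def test_ties_broken_by_symbol(self):
        das = pd.DataFrame(
            {"view": 1, "gene_symbol": ["z", "a", "m"], "score": [5.0, 5.0, 1.0]}
        )
        assert sc.rank_top_fraction(das, 2 / 3) == ["a", "z"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sc.rank_top_fraction(self._das([]), 0.5)


class TestEnrichment:
    def test_hypergeometric_reference_value(self):
        background = [f"g{i}" for i in range(20)]
        selected = background[:4]
        genesets = {"set1": set(background[:3] + background[10:12])}  # K=5, x=3
        table = sc.geneset_enrichment(selected, background, genesets)
        assert table.loc[0, "overlap"] == 3
        assert table.loc[0, "p_value"] == pytest.approx(155 / 4845, abs=1e-12)

    def test_zero_overlap_upper_tail_is_one(self):
        background = [f"g{i}" for i in range(10)]
        genesets = {"s": set(background[5:8])}
        table = sc.geneset_enrichment(background[:2], background, genesets)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_disjoint_set_skipped_with_warning(self):
        background = ["a", "b"]
        with pytest.warns(UserWarning, match="skipped"):
            table = sc.geneset_enrichment(["a"], background, {"s": {"zzz"}})
        assert len(table) == 0

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(0)
        background = [f"g{i}" for i in range(50)]
        selected = background[:10]
        genesets = {
            f"s{j}": set(rng.choice(background, size=8, replace=False))
            for j in range(6)
        }
        table = sc.geneset_enrichment(selected, background, genesets)
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()

    def test_selected_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            sc.geneset_enrichment(["x"], ["a"], {"s": {"a"}})


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg2\n")
    sets = sc.read_gmt(p)
    assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g2"}}
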