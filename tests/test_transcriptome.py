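"""Expression transform/filter, Spearman pairs, PCA, gene sets, paired DE."""

import numpy as np
import pandas as pd
import pytest

from pdxfidelity import transcriptome as tx
from pdxfidelity.synthetic import CohortSpec, expression_to_fpkm, \
    simulate_expression_pair


def _matrix(values: dict, genes=None):
    df = pd.DataFrame(values, index=genes or
                      [f"g{i}" for i in range(len(next(iter(values.values()))))])
    pairing = []
    for col in df.columns:
        model, tissue = col.rsplit("-", 1)
        pairing.append({"sample_id": col, "model_id": model,
                        "tissue": {"PT": "primary", "X": "xenograft"}[tissue]})
    return df, pd.DataFrame(pairing)


class TestTransformFilter:
    def test_uniform_fpkm_one_excluded(self):
        # max log2(1.01) ~ 0.014 < 1 -> dropped
        df, pairing = _matrix({"A-PT": [1.0], "A-X": [1.0]})
        em = tx.transform_filter(df, pairing)
        assert len(em.values) == 0

    def test_single_sample_at_two_retained(self):
        # log2(2.01) ~ 1.007 >= 1 -> kept
        df, pairing = _matrix({"A-PT": [2.0], "A-X": [0.0]})
        em = tx.transform_filter(df, pairing)
        assert len(em.values) == 1
        assert em.values.iloc[0, 0] == pytest.approx(np.log2(2.01))

    def test_all_zero_gene_excluded(self):
        df, pairing = _matrix({"A-PT": [0.0, 5.0], "A-X": [0.0, 5.0]})
        em = tx.transform_filter(df, pairing)
        assert list(em.values.index) == ["g1"]

    def test_negative_input_rejected(self):
        df, pairing = _matrix({"A-PT": [-1.0], "A-X": [1.0]})
        with pytest.raises(ValueError, match="non-negative"):
            tx.transform_filter(df, pairing)

    def test_double_transform_guarded(self):
        df, pairing = _matrix({"A-PT": [5.0, 0.0], "A-X": [4.0, 8.0]})
        em = tx.transform_filter(df, pairing)
        with pytest.raises(ValueError):
            tx.transform_filter(em.values, pairing)


class TestSpearman:
    def test_identical_profiles_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(5, 2, 50)
        df, pairing = _matrix({"A-PT": v, "A-X": v})
        em = tx.ExpressionMatrix(values=df, pairing=pairing)
        corr, pairs, _ = tx.spearman_pair_analysis(em)
        assert pairs.loc["A", "spearman_r"] == pytest.approx(1.0)

    def test_rank_reversed_profiles_r_minus_one(self):
        v = np.arange(50, dtype=float)
        df, pairing = _matrix({"A-PT": v, "A-X": v[::-1].copy()})
        em = tx.ExpressionMatrix(values=df, pairing=pairing)
        _, pairs, _ = tx.spearman_pair_analysis(em)
        assert pairs.loc["A", "spearman_r"] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal(self):
        em, _ = simulate_expression_pair(CohortSpec(n_models=4, n_genes=300,
                                                    seed=1))
        corr, _, _ = tx.spearman_pair_analysis(em)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.to_numpy().min() >= -1 and corr.to_numpy().max() <= 1

    def test_monotone_transform_invariance(self):
        em, _ = simulate_expression_pair(CohortSpec(n_models=4, n_genes=300,
                                                    seed=2))
        corr1, _, _ = tx.spearman_pair_analysis(em)
        warped = tx.ExpressionMatrix(values=em.values * 3 + 1,
                                     pairing=em.pairing)
        corr2, _, _ = tx.spearman_pair_analysis(warped)
        assert np.allclose(corr1, corr2)

    def test_planted_low_fidelity_pairs_flagged(self):
        spec = CohortSpec(n_models=37, n_genes=600, n_low_fidelity=9, seed=3)
        em, _ = simulate_expression_pair(spec)
        _, pairs, threshold = tx.spearman_pair_analysis(em)
        flagged = set(pairs.index[pairs["lowest_quartile"]])
        planted = {f"SIM-{m:02d}" for m in range(9)}
        assert flagged == planted
        assert threshold is not None

    def test_few_pairs_disables_flagging(self):
        em, _ = simulate_expression_pair(CohortSpec(n_models=3, n_genes=300,
                                                    seed=4))
        with pytest.warns(UserWarning, match="fewer than 4"):
            _, pairs, threshold = tx.spearman_pair_analysis(em)
        assert threshold is None


class TestPCA:
    def test_variance_shares_sum_to_100_at_full_rank(self):
        em, _ = simulate_expression_pair(CohortSpec(n_models=4, n_genes=300,
                                                    seed=5))
        _, pct_var, _ = tx.pca_analysis(em, n_components=7)
        assert pct_var.sum() == pytest.approx(100.0, abs=1e-6)

    def test_duplicated_samples_rank_deficient(self):
        rng = np.random.default_rng(1)
        v = rng.normal(5, 2, 100)
        w = rng.normal(5, 2, 100)
        df = pd.DataFrame({"A-PT": v, "A-X": v, "B-PT": w, "B-X": w})
        pairing = pd.DataFrame(
            [{"sample_id": c, "model_id": c[0],
              "tissue": "primary" if c.endswith("PT") else "xenograft"}
             for c in df.columns])
        em = tx.ExpressionMatrix(values=df, pairing=pairing)
        _, pct_var, _ = tx.pca_analysis(em, n_components=3)
        assert pct_var[1] < 1e-10  # only one distinct direction

    def test_blastemal_shift_loads_leading_component(self):
        hits = 0
        for seed in range(10):
            spec = CohortSpec(n_models=10, n_genes=400, blastema_shift=2.0,
                              seed=seed)
            em, blastemal = simulate_expression_pair(spec)
            scores, _, _ = tx.pca_analysis(em, n_components=2)
            gs = tx.gene_set_score(em, blastemal)
            r = np.corrcoef(scores["PC1"], gs.loc[scores.index])[0, 1]
            if abs(r) > 0.8:
                hits += 1
        assert hits >= 9


class TestGeneSetScore:
    def test_constant_matrix_scores_zero(self):
        df, pairing = _matrix({"A-PT": [5.0, 5.0], "A-X": [5.0, 5.0]})
        em = tx.ExpressionMatrix(values=df, pairing=pairing)
        assert (tx.gene_set_score(em, ["g0", "g1"]) == 0).all()

    def test_shifted_set_higher_in_xenografts(self):
        spec = CohortSpec(n_models=6, n_genes=400, blastema_shift=1.5, seed=6)
        em, blastemal = simulate_expression_pair(spec)
        score = tx.gene_set_score(em, blastemal)
        for model, p, x in em.iter_pairs():
            assert score[x] > score[p]

    def test_invariant_to_non_member_genes(self):
        rng = np.random.default_rng(2)
        base = {"A-PT": rng.normal(5, 1, 50), "A-X": rng.normal(5, 1, 50)}
        df, pairing = _matrix(base)
        em_small = tx.ExpressionMatrix(values=df.iloc[:30], pairing=pairing)
        em_full = tx.ExpressionMatrix(values=df, pairing=pairing)
        members = [f"g{i}" for i in range(10)]
        assert tx.gene_set_score(em_small, members).equals(
            tx.gene_set_score(em_full, members))

    def test_zero_mean_across_samples(self):
        em, blastemal = simulate_expression_pair(
            CohortSpec(n_models=5, n_genes=300, seed=7))
        assert tx.gene_set_score(em, blastemal).mean() == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_empty_intersection_rejected(self):
        df, pairing = _matrix({"A-PT": [1.0], "A-X": [1.0]})
        em = tx.ExpressionMatrix(values=df, pairing=pairing)
        with pytest.raises(ValueError):
            tx.gene_set_score(em, ["absent"])


class TestPairedDE:
    def test_identical_tissues_null(self):
        rng = np.random.default_rng(3)
        cols, pairing = {}, []
        for m in range(5):
            v = rng.normal(5, 2, 80)
            cols[f"M{m}-PT"] = v
            cols[f"M{m}-X"] = v + rng.normal(0, 0.3, 80)
            pairing += [{"sample_id": f"M{m}-PT", "model_id": f"M{m}",
                         "tissue": "primary"},
                        {"sample_id": f"M{m}-X", "model_id": f"M{m}",
                         "tissue": "xenograft"}]
        em = tx.ExpressionMatrix(values=pd.DataFrame(cols),
                                 pairing=pd.DataFrame(pairing))
        de = tx.paired_de(em)
        assert (de["q"] < 0.05).sum() == 0

    def test_planted_effect_detected_with_power(self):
        # 50 genes shifted by ~2 within-pair SDs across 20 pairs
        rng = np.random.default_rng(4)
        cols, pairing = {}, []
        shift = np.zeros(300)
        shift[:50] = 0.6
        for m in range(20):
            v = rng.normal(5, 2, 300)
            cols[f"M{m:02d}-PT"] = v + rng.normal(0, 0.3, 300)
            cols[f"M{m:02d}-X"] = v + shift + rng.normal(0, 0.3, 300)
            pairing += [{"sample_id": f"M{m:02d}-PT", "model_id": f"M{m:02d}",
                         "tissue": "primary"},
                        {"sample_id": f"M{m:02d}-X", "model_id": f"M{m:02d}",
                         "tissue": "xenograft"}]
        em = tx.ExpressionMatrix(values=pd.DataFrame(
            cols, index=[f"g{i}" for i in range(300)]),
            pairing=pd.DataFrame(pairing))
        de = tx.paired_de(em)
        planted = [f"g{i}" for i in range(50)]
        assert (de.loc[planted, "q"] < 0.05).sum() >= 45

    def test_bh_stepup_hand_computation(self):
        # p = {0.01, 0.02, 0.03, 0.04}, m = 4 -> all q = 0.04
        from statsmodels.stats.multitest import multipletests
        _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(q, 0.04)

    def test_zero_variance_gene_flagged(self):
        cols, pairing = {}, []
        for m in range(4):
            cols[f"M{m}-PT"] = [5.0, float(m)]
            cols[f"M{m}-X"] = [6.0, float(m) + 0.1 * m]
            pairing += [{"sample_id": f"M{m}-PT", "model_id": f"M{m}",
                         "tissue": "primary"},
                        {"sample_id": f"M{m}-X", "model_id": f"M{m}",
                         "tissue": "xenograft"}]
        em = tx.ExpressionMatrix(values=pd.DataFrame(cols, index=["flat", "ok"]),
                                 pairing=pd.DataFrame(pairing))
        de = tx.paired_de(em)
        assert bool(de.loc["flat", "degenerate"])
        assert de.loc["flat", "p"] == 1.0


class TestRoundTrip:
    def test_fpkm_inverse_transform(self):
        em, _ = simulate_expression_pair(CohortSpec(n_models=3, n_genes=250,
                                                    seed=8))
        fpkm = expression_to_fpkm(em)
        back = tx.transform_filter(fpkm, em.pairing)
        kept = back.values.index
        assert np.allclose(back.values, em.values.loc[kept], atol=1e-9)
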