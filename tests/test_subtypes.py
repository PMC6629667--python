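import numpy as np
import pandas as pd
import pytest

from tactome.datatypes import ValidationError
from tactome.subtypes import (
    classification_agreement,
    classify_nearest_centroid,
    consensus_cluster,
    diana_cluster,
    subtype_de_genes,
    train_centroids,
)

from conftest import toy_matrix

# 8 genes × 6 samples; R cluster::diana on 1 − Pearson dissimilarities
# returns cutree k=2 → (1,1,1,2,2,2) and k=3 → (1,1,1,2,2,3)
DIANA_FIXTURE = np.array([
    [-0.848, -0.5766, -0.8228, 0.8892, 0.7207, 1.4487],
    [-1.9641, -0.8679, -1.4917, 1.7208, 1.6041, 0.5682],
    [-0.5945, -1.152, -0.8247, 0.033, 0.3882, 2.4317],
    [0.152, 0.2792, 0.2025, -1.2007, -1.3751, 0.6419],
    [0.7437, 0.5966, 0.5358, -1.0905, -0.8697, 0.845],
    [0.4141, 0.0145, -0.6357, 1.604, 1.4681, 0.8407],
    [-0.5873, -1.2618, -0.429, 0.2081, 0.1631, -0.6066],
    [-1.109, -0.7734, -1.3949, -1.9707, -1.833, -0.07],
])


def _two_group_matrix(n_per=6, n_genes=40, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, n_genes)
    b = rng.normal(0, 1, n_genes)
    cols = [a + rng.normal(0, noise, n_genes) for _ in range(n_per)]
    cols += [b + rng.normal(0, noise, n_genes) for _ in range(n_per)]
    return toy_matrix(np.column_stack(cols), allow_negative=True)


class TestCentroids:
    def _labeled(self, noise=0.0, n_per=3, seed=0):
        rng = np.random.default_rng(seed)
        profiles = {st: rng.normal(0, 1, 30) for st in ("Basal", "LumA")}
        cols, labels = [], {}
        i = 0
        for st, prof in profiles.items():
            for _ in range(n_per):
                cols.append(prof + rng.normal(0, noise, 30))
                labels[f"s{i}"] = st
                i += 1
        expr = toy_matrix(np.column_stack(cols), allow_negative=True)
        return expr, pd.Series(labels), profiles

    def test_zero_noise_centroid_equals_common_profile(self):
        expr, labels, profiles = self._labeled(noise=0.0)
        model = train_centroids(expr, labels, expr.gene_ids)
        np.testing.assert_allclose(model.centroids["Basal"], profiles["Basal"])

    def test_sample_order_invariance(self):
        expr, labels, _ = self._labeled(noise=0.2)
        perm = list(reversed(expr.sample_ids))
        model_a = train_centroids(expr, labels, expr.gene_ids)
        model_b = train_centroids(expr.subset_samples(perm), labels, expr.gene_ids)
        pd.testing.assert_frame_equal(model_a.centroids, model_b.centroids)

    def test_sample_equal_to_centroid_classified_with_corr_one(self):
        expr, labels, _ = self._labeled(noise=0.0)
        model = train_centroids(expr, labels, expr.gene_ids)
        probe = toy_matrix(
            model.centroids["LumA"].to_numpy()[:, None], allow_negative=True,
            samples=["probe"],
        )
        assigned, corr = classify_nearest_centroid(probe, model)
        assert assigned["probe"] == "LumA"
        assert corr.loc["probe", "LumA"] == pytest.approx(1.0)

    def test_noisy_holdouts_classify_back(self):
        expr, labels, profiles = self._labeled(noise=0.0)
        model = train_centroids(expr, labels, expr.gene_ids)
        rng = np.random.default_rng(1)
        cols = [profiles["Basal"] + rng.normal(0, 0.3, 30) for _ in range(20)]
        probes = toy_matrix(np.column_stack(cols), allow_negative=True)
        assigned, _ = classify_nearest_centroid(probes, model)
        assert (assigned == "Basal").mean() >= 0.95

    def test_too_few_panel_genes_rejected(self):
        expr, labels, _ = self._labeled()
        model = train_centroids(expr, labels, expr.gene_ids)
        model.gene_panel = model.gene_panel[:2]
        with pytest.raises(ValidationError):
            classify_nearest_centroid(expr, model)


class TestDiana:
    def test_matches_external_oracle_on_fixture(self):
        em = toy_matrix(DIANA_FIXTURE, allow_negative=True)
        assert diana_cluster(em, k=2).labels.tolist() == [1, 1, 1, 2, 2, 2]
        assert diana_cluster(em, k=3).labels.tolist() == [1, 1, 1, 2, 2, 3]

    def test_two_separated_groups_exact_recovery(self):
        em = _two_group_matrix()
        labels = diana_cluster(em, k=2).labels.to_numpy()
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_input_order_invariance_up_to_relabeling(self):
        em = _two_group_matrix(seed=3)
        res_a = diana_cluster(em, k=2)
        perm = list(np.random.default_rng(4).permutation(em.sample_ids))
        res_b = diana_cluster(em.subset_samples(perm), k=2)
        agree, _ = classification_agreement(
            res_a.labels.astype(str), res_b.labels.astype(str)
        )
        assert agree == 1.0

    def test_constant_sample_rejected_by_name(self):
        v = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        em = toy_matrix(v, samples=["ok", "flat"])
        with pytest.raises(ValidationError, match="flat"):
            diana_cluster(em, k=2)


class TestConsensus:
    def _four_clusters(self, n_per=15, n_genes=60, seed=0):
        rng = np.random.default_rng(seed)
        cols, truth = [], []
        for c in range(4):
            center = rng.normal(0, 2, n_genes)
            for _ in range(n_per):
                cols.append(center + rng.normal(0, 0.4, n_genes))
                truth.append(c)
        return toy_matrix(np.column_stack(cols), allow_negative=True), np.array(truth)

    def test_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        em, truth = self._four_clusters()
        res = consensus_cluster(em, k=4, reps=30, seed=17)
        assert adjusted_rand_score(truth, res.labels.to_numpy()) >= 0.9

    def test_consensus_matrix_is_a_similarity(self):
        em, _ = self._four_clusters(seed=1)
        res = consensus_cluster(em, k=4, reps=15, seed=17)
        c = res.consensus_matrix.to_numpy()
        np.testing.assert_allclose(c, c.T)
        assert c.min() >= 0.0 and c.max() <= 1.0 + 1e-12

    def test_same_seed_identical_matrix(self):
        em, _ = self._four_clusters(seed=2)
        a = consensus_cluster(em, k=4, reps=15, seed=17)
        b = consensus_cluster(em, k=4, reps=15, seed=17)
        pd.testing.assert_frame_equal(a.consensus_matrix, b.consensus_matrix)

    def test_too_few_reps_rejected(self):
        em, _ = self._four_clusters(seed=3)
        with pytest.raises(ValidationError):
            consensus_cluster(em, k=4, reps=5)


class TestDEGenes:
    def test_planted_markers_selected(self):
        rng = np.random.default_rng(5)
        n_per = 12
        genes = 80
        base = rng.normal(8, 0.2, genes)
        cols, labels = [], {}
        i = 0
        for st in ("Basal", "LumA", "LumB"):
            for _ in range(n_per):
                col = base + rng.normal(0, 0.3, genes)
                if st == "Basal":
                    col[:10] += 2.0  # the Basal markers
                cols.append(col)
                labels[f"s{i}"] = st
                i += 1
        expr = toy_matrix(np.column_stack(cols))
        out = subtype_de_genes(expr, pd.Series(labels), top_n=10)
        assert set(out["Basal"]) == {f"g{i}" for i in range(10)}

    def test_top_n_larger_than_genes_warns_and_returns_all(self):
        rng = np.random.default_rng(6)
        expr = toy_matrix(rng.normal(8, 1, (5, 12)))
        labels = pd.Series({f"s{i}": ("A" if i < 6 else "B") for i in range(12)})
        with pytest.warns(UserWarning, match="top_n"):
            out = subtype_de_genes(expr, labels, top_n=10)
        assert len(out["A"]) == 5


class TestAgreement:
    def test_identical_labelings(self):
        a = pd.Series({"s0": "x", "s1": "y"})
        assert classification_agreement(a, a)[0] == 1.0

    def test_renamed_labels_still_agree(self):
        a = pd.Series({"s0": "x", "s1": "y", "s2": "x"})
        b = pd.Series({"s0": "1", "s1": "2", "s2": "1"})
        assert classification_agreement(a, b)[0] == 1.0

    def test_brute_force_checked_example(self):
        # (A,A,B,B) vs (1,2,2,2): best matching gives 3/4 agreement
        a = pd.Series(dict(zip("abcd", ["A", "A", "B", "B"])))
        b = pd.Series(dict(zip("abcd", ["1", "2", "2", "2"])))
        assert classification_agreement(a, b)[0] == 0.75

    def test_disjoint_samples_rejected(self):
        a = pd.Series({"s0": "x"})
        b = pd.Series({"other": "y"})
        with pytest.raises(ValidationError):
            classification_agreement(a, b)
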