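import numpy as np
import pytest

from tactome.datatypes import ExpressionMatrix, ValidationError
from tactome.deconvolution import (
    _score_against,
    deconvolve_cohort,
    estimate_reference_and_purity,
    estimate_tac_profiles,
    estimate_tc_profiles,
    to_log2_with_floor,
)

from conftest import toy_matrix


def _simplex(v):
    v = np.asarray(v, dtype=float)
    return v / v.sum()


class TestStepOne:
    def test_known_reference_oracle_recovery(self):
        """Noise-free mixtures of a known reference and one normal profile:
        NNLS against the true two-column design recovers purity exactly."""
        rng = np.random.default_rng(0)
        G = 300
        m_star = _simplex(rng.lognormal(2, 1, G))
        h = _simplex(rng.lognormal(2, 1, G))
        ps = np.array([0.05, 0.3, 0.55, 0.8, 0.95])
        X = np.column_stack([p * m_star + (1 - p) * h for p in ps])
        p_est, _, _ = _score_against(X, h[:, None], m_star, 0.999, ridge_frac=0.0)
        np.testing.assert_allclose(p_est, ps, atol=1e-6)

    def test_pure_panel_column_scores_zero_purity(self):
        rng = np.random.default_rng(1)
        h = rng.lognormal(2, 1, 200)
        bulk = toy_matrix(h[:, None].copy(), space="linear")
        panel = toy_matrix(h[:, None].copy(), space="linear", samples=["n0"])
        _, p, theta, _ = estimate_reference_and_purity(bulk, panel)
        assert p[0] < 1e-6
        np.testing.assert_allclose(theta[0], [1.0], atol=1e-6)

    def test_objective_non_increasing(self, small_cohort):
        clin = small_cohort["clinical"].frame
        members = clin.index[clin["subtype"] == "Basal"].tolist()
        bulk = small_cohort["bulk"].subset_samples(members)
        _, _, _, conv = estimate_reference_and_purity(bulk, small_cohort["panel"])
        objs = conv["objectives"]
        # the simplex rescale after each NNLS pass permits sub-0.1% wiggles;
        # the sequence must still descend overall and never jump upward
        assert objs[-1] < objs[0]
        assert all(b <= a * (1 + 1e-3) for a, b in zip(objs, objs[1:]))

    def test_gene_misalignment_rejected(self):
        bulk = toy_matrix([[1.0], [2.0]], space="linear")
        panel = toy_matrix([[1.0], [2.0]], space="linear",
                           genes=["other0", "other1"])
        with pytest.raises(ValidationError, match="aligned"):
            estimate_reference_and_purity(bulk, panel)

    def test_all_zero_bulk_column_rejected(self):
        bulk = toy_matrix([[0.0], [0.0]], space="linear")
        panel = toy_matrix([[1.0], [2.0]], space="linear")
        with pytest.raises(ValidationError, match="all-zero"):
            estimate_reference_and_purity(bulk, panel)


class TestStepTwo:
    def test_huge_lambda_pulls_profiles_to_reference(self):
        rng = np.random.default_rng(2)
        G = 150
        m = _simplex(rng.lognormal(2, 1, G))
        h = _simplex(rng.lognormal(2, 1, G))
        bulk = toy_matrix((0.5 * m + 0.5 * h)[:, None] * 1e4, space="linear")
        panel = toy_matrix(h[:, None] * 1e4, space="linear", samples=["n0"])
        t = estimate_tc_profiles(bulk, panel, m, np.array([0.5]), lam=1e6)
        np.testing.assert_allclose(_simplex(t[:, 0]), m, atol=1e-8)

    def test_pure_sample_returns_its_own_profile(self):
        rng = np.random.default_rng(3)
        G = 150
        t_true = rng.lognormal(2, 1, G)
        h = _simplex(rng.lognormal(2, 1, G))
        bulk = toy_matrix(t_true[:, None].copy(), space="linear")
        panel = toy_matrix(h[:, None] * 100, space="linear", samples=["n0"])
        m = _simplex(t_true)
        # purity is capped at 0.999, so a sliver of panel signal remains
        t = estimate_tc_profiles(bulk, panel, m, np.array([0.999]), lam=0.3)
        np.testing.assert_allclose(t[:, 0], t_true, rtol=5e-2)

    def test_negative_lambda_rejected(self):
        bulk = toy_matrix([[1.0]], space="linear")
        with pytest.raises(ValidationError):
            estimate_tc_profiles(bulk, bulk, np.array([1.0]), np.array([0.5]), lam=-1)

    def test_purity_above_cap_rejected(self):
        bulk = toy_matrix([[1.0]], space="linear")
        with pytest.raises(ValidationError, match="degenerate"):
            estimate_tc_profiles(bulk, bulk, np.array([1.0]), np.array([1.5]))


class TestStepThree:
    def test_zero_purity_returns_bulk(self):
        bulk = toy_matrix([[5.0, 7.0]], space="linear")
        s = estimate_tac_profiles(bulk, np.array([[99.0, 99.0]]), np.zeros(2))
        np.testing.assert_array_equal(s, bulk.values)

    def test_hand_computed_inversion(self):
        # b = 10, t = 12, p = 0.5  →  s = (10 − 6)/0.5 = 8
        bulk = toy_matrix([[10.0]], space="linear")
        s = estimate_tac_profiles(bulk, np.array([[12.0]]), np.array([0.5]))
        assert s[0, 0] == pytest.approx(8.0)

    def test_reconstruction_identity_over_random_triples(self):
        rng = np.random.default_rng(4)
        n = 100_000
        b = rng.lognormal(3, 1, n)
        t = rng.lognormal(3, 1, n)
        p = rng.uniform(0.0, 0.99, n)
        bulk = toy_matrix(b[None, :], space="linear")
        s = estimate_tac_profiles(bulk, t[None, :], p)
        recon = p * t + (1 - p) * s[0]
        assert np.max(np.abs(recon - b) / b) <= 1e-10

    def test_singular_purity_names_sample(self):
        bulk = toy_matrix([[1.0]], space="linear", samples=["bad_sample"])
        with pytest.raises(ValidationError, match="bad_sample"):
            estimate_tac_profiles(bulk, np.array([[1.0]]), np.array([1.0]))


class TestLog2Floor:
    def test_negative_tac_replaced_by_global_min(self):
        bulk = toy_matrix([[1.5, 4.0]], space="linear")
        tc = toy_matrix([[2.0, 8.0]], space="linear")
        tac = toy_matrix([[-3.0, 4.0]], space="linear", allow_negative=True)
        _, _, s_log, floor = to_log2_with_floor(bulk, tc, tac)
        assert floor == 1.5
        assert s_log.values[0, 0] == pytest.approx(np.log2(1.5))
        assert s_log.values[0, 1] == pytest.approx(2.0)

    def test_all_positive_tac_unchanged(self):
        bulk = toy_matrix([[2.0]], space="linear")
        tc = toy_matrix([[4.0]], space="linear")
        tac = toy_matrix([[8.0]], space="linear", allow_negative=True)
        _, _, s_log, _ = to_log2_with_floor(bulk, tc, tac)
        assert s_log.values[0, 0] == pytest.approx(3.0)

    def test_monotone_on_positive_entries(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(1, 1, (20, 4))
        bulk = toy_matrix(vals, space="linear")
        tc = toy_matrix(vals * 2, space="linear")
        tac = toy_matrix(vals - vals.mean(), space="linear", allow_negative=True)
        _, _, s_log, _ = to_log2_with_floor(bulk, tc, tac)
        pos = tac.values > 0
        orig_order = np.argsort(tac.values[pos])
        new_order = np.argsort(s_log.values[pos])
        np.testing.assert_array_equal(orig_order, new_order)

    def test_requires_linear_inputs(self):
        log_mat = toy_matrix([[1.0]], space="log2")
        lin = toy_matrix([[1.0]], space="linear")
        with pytest.raises(ValidationError, match="linear"):
            to_log2_with_floor(log_mat, lin, lin)


class TestCohortLevel:
    def test_reconstruction_identity_on_deconvolved_cohort(self, small_cohort, deconvolved):
        res = deconvolved["result"]
        kept = list(res.purity.index)
        b = small_cohort["bulk"].subset_samples(kept).values
        p = res.purity.to_numpy()
        recon = p[None, :] * res.tc.values + (1 - p)[None, :] * res.tac.values
        assert np.max(np.abs(recon - b) / np.maximum(b, 1e-300)) <= 1e-10

    def test_purity_correlates_with_truth(self, small_cohort, deconvolved):
        res = deconvolved["result"]
        truth = small_cohort["truth"].purity.loc[res.purity.index]
        assert np.corrcoef(res.purity, truth)[0, 1] > 0.9

    def test_per_subtype_references_match_own_archetype(self, small_cohort, deconvolved):
        """Each subtype's estimated reference is closer (cosine) to its own
        true TC archetype than to any other subtype's."""
        res = deconvolved["result"]
        truth = small_cohort["truth"]
        clin = small_cohort["clinical"].frame

        def cosine(a, b):
            return a @ b / np.sqrt((a @ a) * (b @ b))

        true_means = {}
        for st in res.reference.columns:
            members = [s for s in res.purity.index if clin.loc[s, "subtype"] == st]
            cols = [truth.tc.sample_ids.index(s) for s in members]
            true_means[st] = truth.tc.values[:, cols].mean(axis=1)
        for st in res.reference.columns:
            m = res.reference[st].to_numpy()
            own = cosine(m, true_means[st])
            others = [cosine(m, true_means[o]) for o in res.reference.columns if o != st]
            assert own > max(others)

    def test_single_subtype_equals_direct_call(self, small_cohort):
        from tactome.config import RunConfig
        from tactome.deconvolution import run_deconvolution_by_subtype

        clin = small_cohort["clinical"]
        members = clin.frame.index[clin.frame["subtype"] == "Her2"].tolist()
        sub_clin = clin.subset(members)
        bulk = small_cohort["bulk"].subset_samples(members)
        by_subtype = run_deconvolution_by_subtype(
            bulk, small_cohort["panel"], sub_clin, RunConfig()
        )
        direct = deconvolve_cohort(bulk, small_cohort["panel"])
        np.testing.assert_allclose(
            by_subtype.purity.to_numpy(), direct.purity.to_numpy(), atol=1e-12
        )
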