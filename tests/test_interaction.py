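import numpy as np
import pandas as pd
import pytest

from tactome.interaction import (
    TERMS,
    classify_relationship,
    cox_interaction,
    four_group_classify,
    interaction_screen,
    logrank_four_groups,
    summarize_relationships,
)

from conftest import toy_clinical, toy_matrix


def term_table(hrs, qs, ph=1.0):
    t = pd.DataFrame(index=list(TERMS))
    t["beta"] = np.log2(hrs)
    t["hr"] = hrs
    t["p"] = qs
    t["q"] = qs
    t["ph_p"] = ph
    return t


class TestFourGroups:
    def test_threshold_rule_tc_high_samples_land_in_hh_hl(self):
        # TC median below the threshold, 79 samples above it → threshold
        # rule; those 79 are TC-high so they occupy only HH/HL
        tc = np.concatenate([np.full(81, 5.0), np.full(79, 9.0)])
        tac = np.random.default_rng(0).normal(8, 1, 160)
        groups, d_tc, _ = four_group_classify(tc, tac, threshold=6.5, min_above=79)
        assert d_tc.rule == "threshold"
        assert set(np.unique(groups[81:])) <= {"HH", "HL"}
        assert set(np.unique(groups[:81])) <= {"LH", "LL"}

    def test_independent_profiles_fill_quarters(self):
        rng = np.random.default_rng(1)
        n = 4000
        groups, _, _ = four_group_classify(rng.normal(8, 1, n), rng.normal(8, 1, n))
        counts = pd.Series(groups).value_counts(normalize=True)
        assert np.allclose(counts, 0.25, atol=0.03)

    def test_excluded_profile_excludes_gene(self):
        tc = np.full(200, 5.0)  # median below threshold, none above
        tac = np.random.default_rng(2).normal(8, 1, 200)
        groups, d_tc, _ = four_group_classify(tc, tac, threshold=6.5, min_above=79)
        assert groups is None and d_tc.rule == "excluded"


class TestLogrank:
    def _clin(self, t, e):
        return toy_clinical(t, e)

    def test_two_occupied_groups_reduce_to_two_sample(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(3)
        n = 200
        groups = np.where(rng.random(n) > 0.5, "HH", "LL")
        t = rng.exponential(1200, n)
        e = (rng.random(n) < 0.7).astype(int)
        clin = self._clin(t, e)
        p4 = logrank_four_groups(groups, clin)
        mask = groups == "HH"
        tt = np.minimum(t, 1826.25)
        ee = np.where(t <= 1826.25, e, 0)
        p2 = logrank_test(tt[mask], tt[~mask], ee[mask], ee[~mask]).p_value
        assert p4 == pytest.approx(p2, rel=1e-6)

    def test_strong_group_effect_detected(self):
        rng = np.random.default_rng(4)
        n = 800
        groups = np.array(["HH", "HL", "LH", "LL"])[rng.integers(0, 4, n)]
        eta = np.where(groups == "HH", np.log(4.0), 0.0)
        t_ev = rng.exponential(1 / (3.5e-4 * np.exp(eta)))
        c = rng.uniform(0, 3652.5, n)
        clin = self._clin(np.minimum(t_ev, c), (t_ev <= c).astype(int))
        assert logrank_four_groups(groups, clin) < 1e-3

    def test_single_group_unestimable(self):
        clin = self._clin([100.0] * 5, [1] * 5)
        assert np.isnan(logrank_four_groups(np.full(5, "HH"), clin))


class TestCoxInteraction:
    def test_single_occupied_tac_level_inestimable(self):
        clin = toy_clinical([100.0] * 6, [1] * 6)
        tc_high = np.array([True, False, True, False, True, False])
        tac_high = np.ones(6, dtype=bool)
        assert cox_interaction((tc_high, tac_high), clin) is None

    def test_pure_tc_effect_leaves_other_terms_null(self):
        rng = np.random.default_rng(5)
        n = 1500
        tc_high = rng.random(n) > 0.5
        tac_high = rng.random(n) > 0.5
        eta = np.log(3.0) * tc_high.astype(float)
        t_ev = rng.exponential(1 / (3.5e-4 * np.exp(eta - eta.mean())))
        c = rng.uniform(0, 3652.5, n)
        clin = toy_clinical(np.minimum(t_ev, c), (t_ev <= c).astype(int))
        terms = cox_interaction((tc_high, tac_high), clin)
        assert terms.loc["tc", "p"] < 1e-4
        assert terms.loc["tac", "p"] > 0.01
        assert terms.loc["interaction", "p"] > 0.01

    def test_null_interaction_ci_covers_zero_mostly(self):
        """β_int = 0 planted: the Wald test stays null in most replicates."""
        rng = np.random.default_rng(6)
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 400
            tc_high = rng.random(n) > 0.5
            tac_high = rng.random(n) > 0.5
            eta = np.log(2.0) * tc_high + np.log(1.5) * tac_high
            t_ev = rng.exponential(1 / (3.5e-4 * np.exp(eta - eta.mean())))
            c = rng.uniform(0, 3652.5, n)
            clin = toy_clinical(np.minimum(t_ev, c), (t_ev <= c).astype(int))
            terms = cox_interaction((tc_high, tac_high), clin)
            if terms is not None and terms.loc["interaction", "p"] > 0.05:
                hits += 1
        assert hits >= int(0.75 * reps)


class TestClassification:
    def test_saturation_worked_example(self):
        # protective TC dominates; the interaction caps the TAC gain
        t = term_table([0.48, 0.76, 1.4], [4.3e-7, 0.019, 1.9e-4])
        assert classify_relationship(t) == "saturation"

    def test_additive_worked_example(self):
        t = term_table([1.6, 0.73, 1.0], [1.4e-4, 0.040, 0.97])
        assert classify_relationship(t) == "additive"

    def test_antagonistic_worked_example(self):
        t = term_table([1.6, 0.93, 0.60], [2.3e-5, 0.60, 2.5e-3])
        assert classify_relationship(t) == "antagonistic"

    def test_all_null_is_none(self):
        assert classify_relationship(term_table([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])) == "none"

    def test_single_main_effects(self):
        assert classify_relationship(term_table([2.0, 1.0, 1.0], [1e-5, 0.9, 0.9])) == "tc_only"
        assert classify_relationship(term_table([1.0, 2.0, 1.0], [0.9, 1e-5, 0.9])) == "tac_only"

    def test_synergistic_geometry(self):
        t = term_table([2.0, 1.6, 2.2], [1e-4, 1e-3, 1e-3])
        assert classify_relationship(t) == "synergistic"

    def test_ph_failure_downgrades_term(self):
        t = term_table([2.0, 1.0, 1.0], [1e-5, 0.9, 0.9], ph=[0.05, 1.0, 1.0])
        assert classify_relationship(t) == "none"

    def test_swapping_compartments_swaps_main_classes(self):
        t = term_table([2.0, 1.0, 1.0], [1e-5, 0.9, 0.9])
        swapped = t.copy()
        swapped.loc["tc"], swapped.loc["tac"] = t.loc["tac"].copy(), t.loc["tc"].copy()
        assert classify_relationship(t) == "tc_only"
        assert classify_relationship(swapped) == "tac_only"

    def test_swap_preserves_symmetric_interaction_classes(self):
        for hrs, qs in [
            ([0.48, 0.76, 1.4], [4.3e-7, 0.019, 1.9e-4]),  # saturation
            ([1.6, 0.73, 1.0], [1.4e-4, 0.040, 0.97]),  # additive
            ([1.6, 0.93, 0.60], [2.3e-5, 0.60, 2.5e-3]),  # antagonistic
        ]:
            t = term_table(hrs, qs)
            swapped = term_table([hrs[1], hrs[0], hrs[2]], [qs[1], qs[0], qs[2]])
            assert classify_relationship(t) == classify_relationship(swapped)


class TestSummaries:
    def test_fractions_sum_to_one(self):
        from tactome.interaction import InteractionGeneResult

        results = []
        for i, cls in enumerate(["tc_only", "tc_only", "additive"]):
            r = InteractionGeneResult(gene=f"g{i}")
            r.terms = term_table([2.0, 1.0, 1.0], [1e-5, 0.9, 0.9])
            r.relationship = cls
            results.append(r)
        summary = summarize_relationships(results)
        assert summary["fraction"].sum() == pytest.approx(1.0)
        assert summary.loc["tc_only", "count"] == 2

    def test_empty_results_give_empty_table(self):
        assert summarize_relationships([]).empty
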