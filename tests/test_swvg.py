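"""Weighted voting: weights, scores, cutoff grids, stepwise signature."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survddg import (
    SWVgClassifier,
    apply_signature,
    build_signature,
    compute_weights,
    logrank_test,
    optimize_three_group,
    optimize_two_group,
    voting_score,
)
from survddg.ddg1d import fit_ddg1d
from survddg.swvg import THREE_GROUP_GRID_HI, THREE_GROUP_GRID_LO, TWO_GROUP_GRID


class TestWeights:
    def test_equal_p_split_evenly(self):
        np.testing.assert_allclose(compute_weights([0.01, 0.01]), [0.5, 0.5])

    def test_hand_arithmetic_base10(self):
        # -log10: 2 and 3 -> weights 2/5, 3/5
        np.testing.assert_allclose(compute_weights([0.01, 0.001]), [0.4, 0.6])

    def test_single_gene_and_sum_to_one(self):
        assert compute_weights([0.2]) == pytest.approx([1.0])
        w = compute_weights([0.03, 0.007, 0.2, 0.11])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()

    def test_p_of_one_rejected(self):
        with pytest.raises(ValueError):
            compute_weights([0.01, 1.0])


class TestVotingScore:
    def test_unanimous_votes(self):
        votes = np.full((4, 3), 1)
        np.testing.assert_allclose(voting_score(votes, [0.2, 0.3, 0.5]), 1.0)
        np.testing.assert_allclose(voting_score(np.full((4, 3), 2),
                                                [0.2, 0.3, 0.5]), 0.0)

    def test_hand_arithmetic(self):
        score = voting_score(np.array([[1, 2]]), [0.4, 0.6])
        assert score[0] == pytest.approx(0.4)

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError):
            voting_score(np.array([[1, 3]]), [0.5, 0.5])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_flipping_a_vote_to_low_risk_never_decreases_score(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = rng.integers(2, 6)
        votes = rng.integers(1, 3, size=(5, n_genes))
        w = compute_weights(rng.uniform(1e-6, 0.5, n_genes))
        base = voting_score(votes, w)
        i, j = rng.integers(0, 5), rng.integers(0, n_genes)
        flipped = votes.copy()
        flipped[i, j] = 1
        assert voting_score(flipped, w)[i] >= base[i] - 1e-12
        assert np.all((base >= 0) & (base <= 1))


def _two_level_cohort(rng, labels_high, n):
    """Survival times with clearly higher hazard for labels_high=True."""
    haz = np.where(labels_high, 1.0, 0.2)
    time = rng.exponential(1.0 / haz)
    event = (rng.uniform(size=n) < 0.8).astype(int)
    return time, event


class TestTwoGroupCutoff:
    def test_bimodal_ties_break_to_half(self):
        rng = np.random.default_rng(0)
        scores = np.array([0.1] * 40 + [0.9] * 60)
        time, event = _two_level_cohort(rng, scores < 0.5, 100)
        gc, labels, p = optimize_two_group(scores, time, event)
        assert gc == pytest.approx(0.50)
        np.testing.assert_array_equal(labels, np.where(scores > gc, 1, 2))

    def test_constant_scores_error(self):
        with pytest.raises(ValueError, match="10%"):
            optimize_two_group(np.full(50, 0.5), np.arange(1.0, 51.0),
                               np.ones(50, dtype=int))

    def test_grid_argmin_matches_independent_reevaluation(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=120)
        time, event = _two_level_cohort(rng, scores < 0.4, 120)
        gc, labels, p = optimize_two_group(scores, time, event)
        best = (np.inf, None)
        for g in TWO_GROUP_GRID:
            lab = np.where(scores > g, 1, 2)
            sizes = [(lab == 1).sum(), (lab == 2).sum()]
            if min(sizes) < 12:
                continue
            _, pp = logrank_test(time, event, lab)
            if pp < best[0]:
                best = (pp, g)
        assert p == pytest.approx(best[0], rel=1e-12)

    def test_min_group_fraction_respected(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(size=200)
        time, event = _two_level_cohort(rng, scores < 0.5, 200)
        _, labels, _ = optimize_two_group(scores, time, event)
        assert min((labels == 1).sum(), (labels == 2).sum()) >= 20


class TestThreeGroupCutoffs:
    def test_trimodal_modes_recovered(self):
        rng = np.random.default_rng(1)
        scores = np.array([0.1] * 30 + [0.5] * 40 + [0.9] * 30)
        haz = np.select([scores < 0.3, scores < 0.7], [2.0, 0.5], 0.1)
        time = rng.exponential(1.0 / haz)
        event = np.ones(100, dtype=int)
        gc1, gc2, labels, obj = optimize_three_group(scores, time, event)
        assert THREE_GROUP_GRID_LO[0] <= gc1 <= THREE_GROUP_GRID_LO[-1]
        assert THREE_GROUP_GRID_HI[0] <= gc2 <= THREE_GROUP_GRID_HI[-1]
        np.testing.assert_array_equal(labels[scores == 0.9], 1)
        np.testing.assert_array_equal(labels[scores == 0.5], 2)
        np.testing.assert_array_equal(labels[scores == 0.1], 3)
        assert gc1 < 0.5 < gc2

    def test_unfillable_high_risk_group_errors(self):
        scores = np.linspace(0.6, 1.0, 50)
        with pytest.raises(ValueError):
            optimize_three_group(scores, np.arange(1.0, 51.0),
                                 np.ones(50, dtype=int))

    def test_double_grid_argmin_matches_brute_force(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=90)
        haz = np.where(scores < 0.5, 1.5, 0.3)
        time = rng.exponential(1.0 / haz)
        event = (rng.uniform(size=90) < 0.8).astype(int)
        gc1, gc2, labels, obj = optimize_three_group(scores, time, event)
        best = np.inf
        for g1 in THREE_GROUP_GRID_LO:
            for g2 in THREE_GROUP_GRID_HI:
                lab = np.where(scores > g2, 1, np.where(scores > g1, 2, 3))
                if min((lab == k).sum() for k in (1, 2, 3)) < 9:
                    continue
                tot = 0.0
                for a, b in ((1, 2), (2, 3), (1, 3)):
                    m = np.isin(lab, (a, b))
                    tot += logrank_test(time[m], event[m], lab[m])[1]
                best = min(best, tot)
        assert obj == pytest.approx(best, rel=1e-12)


class TestSignature:
    def _ddg_results(self, cohorts):
        (Xtr, ctr, _), _ = cohorts
        t, e = ctr["time"].to_numpy(), ctr["event"].to_numpy()
        return [fit_ddg1d(Xtr.iloc[i].to_numpy(), t, e, gene_id=f"g{i:03d}")
                for i in range(len(Xtr))], Xtr, t, e

    def test_trace_covers_n_min_to_n_genes(self, signature_cohorts):
        results, Xtr, t, e = self._ddg_results(signature_cohorts)
        model = build_signature(results, t, e, mode="2group", n_min=3)
        assert list(model.trace["n_genes"]) == [3, 4, 5]
        assert model.n_opt == int(
            model.trace.loc[model.trace["objective"].idxmin(), "n_genes"])
        assert sum(model.weights) == pytest.approx(1.0, abs=1e-12)
        assert 0.2 <= model.g_c <= 0.8

    def test_extra_noise_gene_never_raises_optimum(self, signature_cohorts):
        results, Xtr, t, e = self._ddg_results(signature_cohorts)
        m5 = build_signature(results, t, e, mode="2group")
        rng = np.random.default_rng(99)
        noise = fit_ddg1d(rng.standard_normal(len(t)), t, e, gene_id="noise")
        pool = results + [noise] if noise is not None else results
        m6 = build_signature(pool, t, e, mode="2group")
        assert m6.objective <= m5.objective + 1e-15

    def test_too_few_genes_error(self, signature_cohorts):
        results, Xtr, t, e = self._ddg_results(signature_cohorts)
        with pytest.raises(ValueError, match="at least 3"):
            build_signature(results[:2], t, e)

    def test_apply_is_idempotent_on_training_cohort(self, signature_cohorts):
        (Xtr, ctr, _), _ = signature_cohorts
        clf = SWVgClassifier(mode="3group").fit(Xtr.T, ctr[["time", "event"]])
        strat = apply_signature(clf.model_, Xtr.T)
        np.testing.assert_array_equal(strat.labels, clf.predict(Xtr.T))
        assert min(strat.group_sizes.values()) >= 40  # 10% of 400
        assert np.all((strat.scores >= 0) & (strat.scores <= 1))
        assert clf.model_.g_c1 < 0.5 < clf.model_.g_c2

    def test_unanimously_high_risk_cohort(self, signature_cohorts):
        (Xtr, ctr, _), _ = signature_cohorts
        clf = SWVgClassifier(mode="2group").fit(Xtr.T, ctr[["time", "event"]])
        model = clf.model_
        # construct patients beyond every high-risk cutoff
        data = {}
        for g, cut, pat in zip(model.genes, model.cutoffs, model.patterns):
            data[g] = np.full(5, cut + 10.0 if pat == "pro-oncogenic" else cut - 10.0)
        strat = apply_signature(model, pd.DataFrame(data))
        assert (strat.labels == 2).all()
        np.testing.assert_allclose(strat.scores, 0.0)

    def test_missing_gene_named_in_error(self, signature_cohorts):
        (Xtr, ctr, _), _ = signature_cohorts
        clf = SWVgClassifier(mode="2group").fit(Xtr.T, ctr[["time", "event"]])
        bad = Xtr.T.drop(columns=[clf.model_.genes[0]])
        with pytest.raises(ValueError, match=clf.model_.genes[0]):
            apply_signature(clf.model_, bad)

    def test_signature_transfers_to_independent_cohort(self, signature_cohorts):
        (Xtr, ctr, _), (Xte, cte, _) = signature_cohorts
        clf = SWVgClassifier(mode="2group").fit(Xtr.T, ctr[["time", "event"]])
        labels = clf.predict(Xte.T)
        _, p = logrank_test(cte["time"].to_numpy(), cte["event"].to_numpy(),
                            labels)
        assert p < 0.05
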