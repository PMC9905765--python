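import numpy as np
import pandas as pd
import pytest

from oramark.containers import CohortMetadata, OtuTable, ValidationError
from oramark.markers import (
    RocResult,
    cv_error_curves,
    fit_final_model,
    rank_importance,
    roc_auc,
    select_optimal_set,
    validate_external,
)


def brute_force_auc(case, ctrl) -> float:
    wins = sum(1.0 * (c > h) + 0.5 * (c == h) for c in case for h in ctrl)
    return wins / (len(case) * len(ctrl))


def scores_meta(case, ctrl):
    ids = [f"c{i}" for i in range(len(case))] + [f"h{i}" for i in range(len(ctrl))]
    meta = CohortMetadata(
        pd.DataFrame({"group": ["case"] * len(case) + ["control"] * len(ctrl)}, index=ids)
    )
    pod = pd.DataFrame({"pod": list(case) + list(ctrl)}, index=ids)
    return pod, meta


def planted_cohort(n_case=30, n_control=30, n_null=50, seed=0):
    """One strongly separating OTU among null OTUs."""
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    counts = rng.integers(1, 60, size=(n, n_null + 1))
    counts[:n_case, 0] = rng.integers(400, 600, size=n_case)
    counts[n_case:, 0] = rng.integers(1, 20, size=n_control)
    ids = [f"s{i}" for i in range(n)]
    table = OtuTable(
        pd.DataFrame(counts, index=ids, columns=[f"o{j}" for j in range(n_null + 1)])
    )
    meta = CohortMetadata(
        pd.DataFrame({"group": ["case"] * n_case + ["control"] * n_control}, index=ids)
    )
    return table, meta


class TestRankImportance:
    def test_planted_otu_ranked_first_across_seeds(self):
        """A perfectly separating OTU among 50 null OTUs wins the Mean
        Decrease Accuracy ranking in >= 19/20 seeds."""
        hits = 0
        for seed in range(20):
            table, meta = planted_cohort(seed=seed)
            ranked = rank_importance(table, meta, n_trees=150, seed=seed)
            hits += ranked.index[0] == "o0"
        assert hits >= 19

    def test_null_importances_centred_at_zero(self):
        rng = np.random.default_rng(9)
        n = 40
        counts = rng.integers(1, 60, size=(n, 30))
        ids = [f"s{i}" for i in range(n)]
        table = OtuTable(pd.DataFrame(counts, index=ids, columns=[f"o{j}" for j in range(30)]))
        meta = CohortMetadata(
            pd.DataFrame({"group": ["case"] * 20 + ["control"] * 20}, index=ids)
        )
        ranked = rank_importance(table, meta, n_trees=300, seed=1)
        assert abs(ranked["importance"].mean()) < 0.02

    def test_same_seed_identical_ranking(self):
        table, meta = planted_cohort(seed=3)
        r1 = rank_importance(table, meta, n_trees=100, seed=5)
        r2 = rank_importance(table, meta, n_trees=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_candidates_rejected(self):
        table, meta = planted_cohort()
        with pytest.raises(ValidationError):
            rank_importance(table, meta, candidates=[])


class TestCvCurves:
    def test_curve_shape_and_repeat_count(self):
        table, meta = planted_cohort(seed=11)
        ranked = rank_importance(table, meta, n_trees=100, seed=11)
        sel = cv_error_curves(
            table, meta, ranked, n_trees=50, seed=2, max_set_size=6, n_repeats=5
        )
        assert sel.cv_curves.shape == (5, 6)
        assert sel.mean_curve.shape == (6,)
        assert 0 <= sel.cv_curves.min() and sel.cv_curves.max() <= 1

    def test_label_permuted_error_near_imbalance_rate(self):
        """With shuffled labels the held-out error approaches the minority
        class share (1/3 for 20 case vs 40 control)."""
        table, meta = planted_cohort(n_case=20, n_control=40, seed=13)
        rng = np.random.default_rng(13)
        frame = meta.frame.copy()
        frame["group"] = rng.permutation(frame["group"].to_numpy())
        meta_null = CohortMetadata(frame)
        ranked = rank_importance(table, meta_null, n_trees=100, seed=13)
        sel = cv_error_curves(
            table, meta_null, ranked, n_trees=50, seed=4, max_set_size=4
        )
        assert 0.15 <= sel.mean_curve.mean() <= 0.55

    def test_too_small_class_for_folds_rejected(self):
        table, meta = planted_cohort(n_case=3, n_control=30, seed=1)
        ranked = ["o0", "o1"]
        with pytest.raises(ValidationError):
            cv_error_curves(table, meta, ranked, n_folds=5)


class TestSelectOptimalSet:
    def test_hand_traced_rule(self):
        """Curve (0.30, 0.10, 0.09, 0.09) with sd 0.02 at the minimum:
        cutoff 0.11, smallest qualifying size 2."""
        cutoff, m, ids = select_optimal_set(
            [0.30, 0.10, 0.09, 0.09], 0.02, ["a", "b", "c", "d"]
        )
        assert cutoff == pytest.approx(0.11)
        assert m == 2
        assert ids == ["a", "b"]

    def test_flat_curve_sd_zero_picks_one(self):
        _, m, _ = select_optimal_set([0.2, 0.2, 0.2], 0.0)
        assert m == 1

    def test_strictly_decreasing_sd_zero_picks_argmin(self):
        _, m, _ = select_optimal_set([0.5, 0.4, 0.3], 0.0)
        assert m == 3


class TestPodModel:
    def test_resubstitution_separates_groups(self):
        table, meta = planted_cohort(seed=21)
        model = fit_final_model(table, meta, ["o0"], n_trees=200, seed=0)
        pod = model.pod(table)
        labels = meta.group_labels(table.sample_ids)
        assert pod.loc[labels == "case", "pod"].mean() > pod.loc[labels == "control", "pod"].mean()
        assert ((pod["pod"] >= 0) & (pod["pod"] <= 1)).all()

    def test_same_seed_identical_votes(self):
        table, meta = planted_cohort(seed=22)
        p1 = fit_final_model(table, meta, ["o0", "o1"], n_trees=100, seed=7).pod(table)
        p2 = fit_final_model(table, meta, ["o0", "o1"], n_trees=100, seed=7).pod(table)
        pd.testing.assert_frame_equal(p1, p2)

    def test_missing_marker_treated_as_zero_with_warning(self):
        table, meta = planted_cohort(seed=23)
        model = fit_final_model(table, meta, ["o0", "o1"], n_trees=100, seed=0)
        dropped = OtuTable(table.counts.drop(columns=["o1"]))
        with pytest.warns(UserWarning, match="o1"):
            pod = model.pod(dropped)
        assert len(pod) == table.n_samples

    def test_vote_share_and_odds_rank_identical(self):
        """POD as case-vote share and as case/control vote odds are monotone
        transforms of each other, hence identical AUC."""
        table, meta = planted_cohort(seed=24)
        model = fit_final_model(table, meta, ["o0"], n_trees=150, seed=1)
        pod = model.pod(table)
        finite = pod.replace(np.inf, 1e12)
        auc_share = roc_auc(pod, meta).auc
        auc_odds = roc_auc(finite[["pod_odds"]].rename(columns={"pod_odds": "pod"}), meta).auc
        assert auc_share == pytest.approx(auc_odds, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        pod, meta = scores_meta([0.9, 0.8, 0.7], [0.3, 0.2, 0.1])
        assert roc_auc(pod, meta).auc == 1.0

    def test_identical_scores_give_half(self):
        pod, meta = scores_meta([0.5] * 4, [0.5] * 4)
        assert roc_auc(pod, meta).auc == 0.5

    def test_brute_force_pair_counting_value(self):
        """Cases {0.9, 0.8, 0.4} vs controls {0.7, 0.3, 0.2}: exhaustive
        pair counting gives 8 wins of 9 pairs."""
        case, ctrl = [0.9, 0.8, 0.4], [0.7, 0.3, 0.2]
        pod, meta = scores_meta(case, ctrl)
        res = roc_auc(pod, meta)
        assert res.auc == pytest.approx(8 / 9, abs=1e-12)
        assert res.auc == pytest.approx(brute_force_auc(case, ctrl), abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            case = np.round(rng.uniform(size=rng.integers(3, 25)), 1)
            ctrl = np.round(rng.uniform(size=rng.integers(3, 25)), 1)
            pod, meta = scores_meta(case, ctrl)
            assert roc_auc(pod, meta).auc == pytest.approx(
                brute_force_auc(case, ctrl), abs=1e-12
            )

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(32)
        pod, meta = scores_meta(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        res = roc_auc(pod, meta)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0 <= res.ci_low and res.ci_high <= 1

    def test_single_class_rejected(self):
        pod = pd.DataFrame({"pod": [0.1, 0.2]}, index=["a", "b"])
        meta = CohortMetadata(pd.DataFrame({"group": ["case", "case"]}, index=["a", "b"]))
        with pytest.raises(ValidationError):
            roc_auc(pod, meta)


class TestExternalValidation:
    def test_leakage_guard(self):
        table, meta = planted_cohort(seed=41)
        model = fit_final_model(table, meta, ["o0"], n_trees=50, seed=0)
        with pytest.raises(ValidationError, match="sample id"):
            validate_external(model, table, meta)

    def test_same_process_external_cohort_similar_auc(self):
        table, meta = planted_cohort(seed=42)
        ext_table, ext_meta = planted_cohort(seed=43)
        ext_table = OtuTable(ext_table.counts.rename(index=lambda s: "x" + s))
        ext_meta = CohortMetadata(ext_meta.frame.rename(index=lambda s: "x" + s))
        model = fit_final_model(table, meta, ["o0"], n_trees=200, seed=0)
        roc_train = roc_auc(model.pod(table), meta)
        _, roc_ext = validate_external(model, ext_table, ext_meta)
        assert abs(roc_ext.auc - roc_train.auc) < 0.1

    def test_permuted_external_labels_null_auc(self):
        table, meta = planted_cohort(seed=44)
        ext_table, ext_meta = planted_cohort(seed=45)
        ext_table = OtuTable(ext_table.counts.rename(index=lambda s: "x" + s))
        rng = np.random.default_rng(46)
        frame = ext_meta.frame.rename(index=lambda s: "x" + s)
        frame["group"] = rng.permutation(frame["group"].to_numpy())
        ext_meta = CohortMetadata(frame)
        model = fit_final_model(table, meta, ["o0"], n_trees=200, seed=0)
        _, roc_ext = validate_external(model, ext_table, ext_meta)
        assert 0.3 <= roc_ext.auc <= 0.7
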