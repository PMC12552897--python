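"""Splitting, iterative fitting, merging, evaluation, and score categories."""

import numpy as np
import pandas as pd
import pytest

from drisleep import dri_si_model as dm
from drisleep import synthetic_cohort as sc
from drisleep._rng import child_rng


def _feature_cohort(n_cases=12, n_controls=12, nights=60, shift=0.0, seed=0,
                    shift_feature="EXITS"):
    """Night table with i.i.d. standard-normal features; optionally one
    feature shifted by class (a planted single-feature signal)."""
    rng = child_rng(seed, "features")
    rows = []
    for cls, n_part, label in ((1, n_cases, "C"), (0, n_controls, "K")):
        for i in range(n_part):
            X = rng.normal(0, 1, (nights, len(dm.DEFAULT_FEATURES)))
            df = pd.DataFrame(X, columns=dm.DEFAULT_FEATURES)
            if cls == 1:
                df[shift_feature] += shift
            df["participant_id"] = f"{label}-{i:03d}"
            df["night_date"] = pd.date_range("2021-01-04", periods=nights)
            df["is_case"] = cls
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestSplitMultilevel:
    def test_round_half_down_convention(self):
        # 83 case participants at fraction 0.1 -> 8 held out
        assert dm._round_half_down(83 * 0.1) == 8
        assert dm._round_half_down(85 * 0.1) == 8  # exactly .5 rounds down
        assert dm._round_half_down(86 * 0.1) == 9
        assert dm._round_half_down(90 * 0.1) == 9

    def test_partitions_are_disjoint_and_exhaustive(self):
        nights = _feature_cohort(n_cases=15, n_controls=20, nights=60)
        plan = dm.split_multilevel(nights, seed=0)
        parts = [set(plan.train_index), set(plan.horizon_index), set(plan.naive_index)]
        assert sum(len(p) for p in parts) == len(nights)
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2]) \
            and not (parts[1] & parts[2])

    def test_naive_participants_contribute_no_training_nights(self):
        nights = _feature_cohort(n_cases=15, n_controls=20, nights=60)
        plan = dm.split_multilevel(nights, seed=0)
        naive_pids = set(plan.naive_participants)
        train_pids = set(nights.loc[plan.train_index, "participant_id"])
        assert not (naive_pids & train_pids)

    def test_horizon_is_last_30_days_per_participant(self):
        nights = _feature_cohort(n_cases=15, n_controls=20, nights=60)
        plan = dm.split_multilevel(nights, horizon_days=30, seed=0)
        dates = pd.to_datetime(nights["night_date"])
        for pid, sub in nights.loc[plan.horizon_index].groupby("participant_id"):
            pmax = dates[nights["participant_id"] == pid].max()
            assert (pd.to_datetime(sub["night_date"])
                    > pmax - pd.Timedelta(days=30)).all()

    def test_same_seed_reproduces_plan(self):
        nights = _feature_cohort(n_cases=15, n_controls=20, nights=60)
        p1 = dm.split_multilevel(nights, seed=5)
        p2 = dm.split_multilevel(nights, seed=5)
        assert p1.naive_participants == p2.naive_participants
        assert np.array_equal(p1.train_index, p2.train_index)

    def test_too_few_participants_rejected(self):
        nights = _feature_cohort(n_cases=4, n_controls=20, nights=40)
        with pytest.raises(ValueError, match=">= 10 participants"):
            dm.split_multilevel(nights, seed=0)


class TestTemporalSampling:
    def test_van_der_corput_prefix(self):
        assert [dm.van_der_corput(i) for i in range(1, 5)] == [0.5, 0.25, 0.75, 0.125]

    def test_subsample_covers_all_blocks_each_pass(self):
        idx = dm.temporal_subsample(300, n_passes=1)
        blocks = set(i * 10 // 300 for i in idx)
        assert blocks == set(range(10))
        assert len(idx) == 10

    def test_subsample_is_sorted_and_unique(self):
        idx = dm.temporal_subsample(300, n_passes=3)
        assert (np.diff(idx) > 0).all()

    def test_short_timelines_used_fully(self):
        assert np.array_equal(dm.temporal_subsample(8, 3), np.arange(8))


class TestFitIteration:
    def test_undersampling_balances_classes(self):
        nights = _feature_cohort(n_cases=12, n_controls=30, nights=60)
        plan = dm.split_multilevel(nights, seed=0)
        train = nights.loc[plan.train_index]
        m = dm.fit_iteration(train, dm.DEFAULT_FEATURES, "is_case", 42)
        # the fitted sample is internal; verify via the member's stored rows:
        # the sampled universe must include both classes
        sampled = train.loc[np.intersect1d(m.sampled_night_index, train.index)]
        assert sampled["is_case"].nunique() == 2

    def test_different_seeds_draw_different_participants(self):
        nights = _feature_cohort(n_cases=12, n_controls=30, nights=60)
        plan = dm.split_multilevel(nights, seed=0)
        train = nights.loc[plan.train_index]
        samples = [frozenset(dm.fit_iteration(train, dm.DEFAULT_FEATURES,
                                              "is_case", s).sampled_night_index)
                   for s in range(8)]
        assert len(set(samples)) > 1


class TestMergeAndScore:
    def test_single_member_ensemble_equals_member(self):
        nights = _feature_cohort(n_cases=12, n_controls=12, nights=40, shift=2.0)
        plan = dm.split_multilevel(nights, seed=0)
        m = dm.fit_iteration(nights.loc[plan.train_index], dm.DEFAULT_FEATURES,
                             "is_case", 1)
        ens = dm.merge_ensemble([m], dm.DEFAULT_FEATURES)
        X = nights[dm.DEFAULT_FEATURES].to_numpy(float)
        assert np.allclose(ens.score(nights), m.model.predict_proba(X)[:, 1])

    def test_ensemble_score_is_mean_of_members(self):
        nights = _feature_cohort(n_cases=12, n_controls=12, nights=40, shift=2.0)
        plan = dm.split_multilevel(nights, seed=0)
        train = nights.loc[plan.train_index]
        members = [dm.fit_iteration(train, dm.DEFAULT_FEATURES, "is_case", s)
                   for s in range(3)]
        ens = dm.merge_ensemble(members, dm.DEFAULT_FEATURES)
        ten = nights.head(10)
        X = ten[dm.DEFAULT_FEATURES].to_numpy(float)
        by_hand = np.mean([m.model.predict_proba(X)[:, 1] for m in members], axis=0)
        assert np.allclose(ens.score(ten), by_hand)
        perm = dm.merge_ensemble(members[::-1], dm.DEFAULT_FEATURES)
        assert np.allclose(perm.score(ten), ens.score(ten))

    def test_constant_half_member_pulls_scores_toward_half(self):
        nights = _feature_cohort(n_cases=12, n_controls=12, nights=40, shift=2.0)
        plan = dm.split_multilevel(nights, seed=0)
        train = nights.loc[plan.train_index]
        members = [dm.fit_iteration(train, dm.DEFAULT_FEATURES, "is_case", s)
                   for s in range(2)]
        ens = dm.merge_ensemble(members, dm.DEFAULT_FEATURES)

        class _Half:
            n_features_in_ = len(dm.DEFAULT_FEATURES)

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        half = dm.MemberModel(model=_Half(), seed=0, sampled_night_index=np.array([]))
        widened = dm.merge_ensemble(members + [half], dm.DEFAULT_FEATURES)
        s0, s1 = ens.score(nights.head(50)), widened.score(nights.head(50))
        assert (np.abs(s1 - 0.5) <= np.abs(s0 - 0.5) + 1e-12).all()

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            dm.merge_ensemble([])


class TestEvaluate:
    def test_separable_features_reach_perfect_metrics(self):
        nights = _feature_cohort(n_cases=12, n_controls=12, nights=40, shift=8.0)
        ens, plan = dm.train_dri_si(nights, n_members=5, seed=0)
        rep = dm.evaluate(ens, nights.loc[plan.naive_index], with_dummy=False)
        assert rep.metrics["auc"] == pytest.approx(1.0, abs=1e-9)
        assert rep.metrics["mcc"] == pytest.approx(1.0, abs=1e-9)

    def test_f1_consistent_with_precision_and_recall(self):
        nights = _feature_cohort(n_cases=12, n_controls=12, nights=40, shift=1.0)
        ens, plan = dm.train_dri_si(nights, n_members=3, seed=0)
        rep = dm.evaluate(ens, nights.loc[plan.naive_index], with_dummy=False)
        p, r = rep.metrics["precision_pos"], rep.metrics["sensitivity"]
        assert rep.metrics["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_single_class_input_rejected(self):
        nights = _feature_cohort(n_cases=12, n_controls=12, nights=40)
        ens, plan = dm.train_dri_si(nights, n_members=2, seed=0)
        cases_only = nights[nights["is_case"] == 1]
        with pytest.raises(ValueError, match="both classes"):
            dm.evaluate(ens, cases_only)


class TestPermutationImportance:
    def test_reproducible_with_seed(self):
        nights = _feature_cohort(n_cases=12, n_controls=12, nights=40, shift=2.0)
        ens, plan = dm.train_dri_si(nights, n_members=3, seed=0)
        held = nights.loc[plan.naive_index]
        t1 = dm.permutation_importance(ens, held, n_repeats=3, seed=7)
        t2 = dm.permutation_importance(ens, held, n_repeats=3, seed=7)
        pd.testing.assert_frame_equal(t1, t2)


class TestCategorizeScores:
    def test_end_bins(self):
        assert dm.categorize_scores([0.05])[0] == 1
        assert dm.categorize_scores([0.99])[0] == 6
        assert dm.categorize_scores([1.0])[0] == 6  # top bin closed

    def test_half_open_boundary(self):
        assert dm.categorize_scores([1 / 6])[0] == 2

    def test_monotone_in_score(self):
        s = np.linspace(0, 1, 101)
        cats = dm.categorize_scores(s)
        assert (np.diff(cats) >= 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dm.categorize_scores([1.2])
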