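"""90-day window profiles, window/participant clustering, group effects."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from drisleep import clinical_windows as cw
from drisleep._rng import child_rng


def _night_labels(pid, start, states, **metrics):
    n = len(states)
    df = pd.DataFrame({
        "participant_id": pid,
        "night_date": [start + dt.timedelta(days=i) for i in range(n)],
        "state": states,
    })
    for k, v in metrics.items():
        df[k] = v
    return df


def _assessment(pid, date, scale="BADL", score=10.0):
    return pd.DataFrame({"participant_id": [pid], "assessment_date": [date],
                         "scale": [scale], "score": [score]})


class TestBuildWindows:
    START = dt.date(2021, 1, 1)

    def test_window_with_14_days_excluded(self):
        labels = _night_labels("P1", self.START, [1] * 14)
        out = cw.build_windows(_assessment("P1", self.START + dt.timedelta(days=30)),
                               labels, n_states=3)
        assert out == []

    def test_all_one_cluster_gives_indicator_vector(self):
        labels = _night_labels("P1", self.START, [2] * 40)
        out = cw.build_windows(_assessment("P1", self.START + dt.timedelta(days=50)),
                               labels, n_states=3)
        assert len(out) == 1
        assert np.allclose(out[0].state_proportions, [0, 1, 0])

    def test_equal_split_gives_thirds(self):
        states = [1] * 30 + [2] * 30 + [3] * 30
        labels = _night_labels("P1", self.START, states)
        out = cw.build_windows(_assessment("P1", self.START + dt.timedelta(days=90)),
                               labels, n_states=3)
        assert np.allclose(out[0].state_proportions, [1 / 3, 1 / 3, 1 / 3])

    def test_half_open_window_excludes_assessment_day(self):
        # a night on the assessment date itself is outside [t-90, t)
        labels = _night_labels("P1", self.START, [1] * 20)
        date = self.START + dt.timedelta(days=19)  # nights 0..18 in window
        out = cw.build_windows(_assessment("P1", date), labels, n_states=2)
        assert out[0].n_nights_with_data == 19

    def test_proportions_conserve_night_counts(self):
        rng = np.random.default_rng(0)
        states = rng.integers(1, 4, 60).tolist()
        labels = _night_labels("P1", self.START, states)
        out = cw.build_windows(_assessment("P1", self.START + dt.timedelta(days=70)),
                               labels, n_states=3)
        p = out[0]
        counts = p.state_proportions * 60
        assert counts.sum() == pytest.approx(60)

    def test_behavioral_means_and_scores_attached(self):
        labels = _night_labels("P1", self.START, [1] * 30, IBT=9.0, OBT=0.5,
                               EXITS=3, EXIT_DUR=10.0)
        assess = pd.concat([
            _assessment("P1", self.START + dt.timedelta(days=40), "BADL", 12.0),
            _assessment("P1", self.START + dt.timedelta(days=40), "NPI", 8.0),
        ])
        out = cw.build_windows(assess, labels, n_states=2)
        assert out[0].behavioral_means["IBT"] == pytest.approx(9.0)
        assert out[0].scores == {"BADL": 12.0, "NPI": 8.0}


def _archetype_profiles(rng, n_per=10, conc=120.0):
    archetypes = np.array([
        [0.70, 0.10, 0.10, 0.05, 0.05],
        [0.10, 0.70, 0.10, 0.05, 0.05],
        [0.05, 0.10, 0.70, 0.10, 0.05],
        [0.05, 0.05, 0.10, 0.10, 0.70],
    ])
    P, truth = [], []
    for k, a in enumerate(archetypes):
        P.append(rng.dirichlet(a * conc, n_per))
        truth.extend([k] * n_per)
    return np.vstack(P), np.array(truth)


class TestClusterWindows:
    def _profiles(self, P):
        return [
            cw.WindowProfile(f"P{i}", dt.date(2021, 1, 1), 90, row, {}, {})
            for i, row in enumerate(P)
        ]

    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        P, truth = _archetype_profiles(child_rng(0), n_per=15)
        labels, info = cw.cluster_windows(self._profiles(P))
        assert info["k"] == 4
        assert adjusted_rand_score(truth, labels) >= 0.85

    def test_identical_profiles_share_a_label(self):
        P, _ = _archetype_profiles(child_rng(1), n_per=5)
        P = np.vstack([P, P[:1]])  # duplicate first profile
        labels, _ = cw.cluster_windows(self._profiles(P))
        assert labels[0] == labels[-1]

    def test_order_invariant_up_to_renaming(self):
        from sklearn.metrics import adjusted_rand_score
        P, _ = _archetype_profiles(child_rng(2), n_per=5)
        perm = child_rng(3).permutation(len(P))
        l1, _ = cw.cluster_windows(self._profiles(P))
        l2, _ = cw.cluster_windows(self._profiles(P[perm]))
        assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)


class TestClusterParticipants:
    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        P, truth = _archetype_profiles(child_rng(4), n_per=10)
        df = pd.DataFrame(P, index=[f"P{i:02d}" for i in range(len(P))])
        labels, info = cw.cluster_participants(df)
        assert info["k"] == 4
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.85

    def test_single_archetype_flagged_as_weak_structure(self):
        rng = child_rng(5)
        P = rng.dirichlet(np.array([0.3, 0.3, 0.2, 0.1, 0.1]) * 200, 20)
        df = pd.DataFrame(P, index=[f"P{i:02d}" for i in range(20)])
        labels, info = cw.cluster_participants(df)
        assert info["weak_structure"]

    def test_too_few_participants_rejected(self):
        df = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 4"):
            cw.cluster_participants(df)


class TestWelchAnova:
    def test_identical_groups_give_f_near_zero(self):
        g = np.arange(20, dtype=float)
        F, _, _, p = cw.welch_anova_f([g, g.copy(), g.copy()])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_pingouin_closed_form(self):
        pg = pytest.importorskip("pingouin")
        rng = child_rng(6)
        groups = [rng.normal(0, 1, 20), rng.normal(0.5, 2, 35), rng.normal(1, 0.5, 15)]
        F, df1, df2, p = cw.welch_anova_f(groups)
        df = pd.DataFrame({"y": np.concatenate(groups),
                           "g": np.repeat([0, 1, 2], [20, 35, 15])})
        ref = pg.welch_anova(dv="y", between="g", data=df)
        assert F == pytest.approx(float(ref["F"].iloc[0]), abs=1e-9)
        assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-12)

    def test_type_one_error_calibrated_under_heteroscedastic_null(self):
        rng = child_rng(7)
        rej = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 15), rng.normal(0, 3, 25), rng.normal(0, 0.5, 40)]
            rej += cw.welch_anova_f(groups)[3] < 0.05
        assert rej / n_sim == pytest.approx(0.05, abs=0.02)


class TestGamesHowell:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = child_rng(8)
        groups = [rng.normal(0, 1, 20), rng.normal(0.5, 2, 35), rng.normal(1, 0.5, 15)]
        mine = cw.games_howell(groups)
        df = pd.DataFrame({"y": np.concatenate(groups),
                           "g": np.repeat([0, 1, 2], [20, 35, 15])})
        ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        assert np.allclose(mine["t"], ref["T"], atol=1e-9)
        assert np.allclose(mine["df"], ref["df"], atol=1e-9)
        assert np.allclose(mine["p_adjusted"], ref["pval"], atol=1e-9)
        assert np.allclose(mine["hedges_g"], ref["hedges"], atol=1e-3)

    def test_pairwise_row_count(self):
        rng = child_rng(9)
        groups = [rng.normal(0, 1, 10) for _ in range(5)]
        assert len(cw.games_howell(groups)) == 5 * 4 // 2

    def test_adjusted_p_monotone_in_statistic(self):
        rng = child_rng(10)
        groups = [rng.normal(m, 1, 25) for m in (0, 0.4, 1.2, 2.5)]
        gh = cw.games_howell(groups)
        order = gh.sort_values("p_adjusted")
        assert order["t"].abs().is_monotonic_decreasing


class TestGroupEffects:
    def _df(self, rng, shift=0.0):
        rows = []
        for g, m in enumerate([0.0, shift, 2 * shift]):
            for v in rng.normal(m, 1 + g, 30):
                rows.append({"group": g, "BADL": v, "NPI": v + rng.normal()})
        return pd.DataFrame(rows)

    def test_copied_groups_not_significant(self):
        rng = child_rng(11)
        base = rng.normal(0, 1, 30)
        df = pd.DataFrame({"group": np.repeat([0, 1, 2], 30),
                           "BADL": np.tile(base, 3)})
        rep = cw.group_effects(df, "group", ["BADL"])[0]
        assert rep.welch_f == pytest.approx(0.0, abs=1e-12)
        assert not rep.significant

    def test_bonferroni_inflates_p_over_family(self):
        rng = child_rng(12)
        reps = cw.group_effects(self._df(rng, shift=0.3), "group", ["BADL", "NPI"])
        for r in reps:
            assert r.bonferroni_p >= r.p
            assert len(r.pairwise) == 3

    def test_zero_variance_group_diagnosed(self):
        rng = child_rng(13)
        df = pd.DataFrame({"group": np.repeat([0, 1], 10),
                           "BADL": np.r_[np.full(10, 5.0), rng.normal(0, 1, 10)]})
        rep = cw.group_effects(df, "group", ["BADL"])[0]
        assert rep.zero_variance_groups == (0,)
        assert np.isfinite(rep.welch_f)
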