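"""Stay-probability analysis: design, tables, indices, fits, group stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep import (
    TrialRecord,
    build_stay_design,
    fdr_adjust,
    fit_subject_stay,
    group_effects,
    moderation_test,
    simple_indices,
    split_scores,
    stay_table,
)
from twostep.stay import StayCoefficients

from conftest import brute_force_bh


def _trials(a1s, rs, commons):
    return [
        TrialRecord(t, a1, a1 if c else 1 - a1, c, 0, r)
        for t, (a1, r, c) in enumerate(zip(a1s, rs, commons))
    ]


class TestDesign:
    def test_handmade_three_trial_log(self):
        trials = _trials([0, 0, 1], [1, 0, 0], [True, False, True])
        d = build_stay_design(trials)
        assert len(d) == 2
        assert d.iloc[0].tolist() == [1, 0.5, 0.5, 0.25]
        assert d.iloc[1].tolist() == [0, -0.5, -0.5, 0.25]

    def test_identical_choices_all_stay(self):
        trials = _trials([1] * 10, [0, 1] * 5, [True] * 10)
        assert (build_stay_design(trials)["stay"] == 1).all()

    def test_lag_structure_gives_t_minus_one_rows(self, simulated_trials):
        d = build_stay_design(simulated_trials)
        assert len(d) == len(simulated_trials) - 1
        assert set(np.unique(d["reward_prev"])) <= {-0.5, 0.5}

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            build_stay_design(_trials([0], [1], [True]))


class TestTable:
    def test_exact_fractions_by_enumeration(self):
        # 8 rows, two per cell, with known stay counts
        d = pd.DataFrame(
            {
                "stay": [1, 1, 1, 0, 0, 0, 1, 0],
                "reward_prev": [0.5, 0.5, 0.5, 0.5, -0.5, -0.5, -0.5, -0.5],
                "transition_prev": [0.5, 0.5, -0.5, -0.5, 0.5, 0.5, -0.5, -0.5],
            }
        )
        d["interaction"] = d["reward_prev"] * d["transition_prev"]
        tab = stay_table(d)
        assert tab.loc["rewarded", "common"] == 1.0
        assert tab.loc["rewarded", "rare"] == 0.5
        assert tab.loc["unrewarded", "common"] == 0.0
        assert tab.loc["unrewarded", "rare"] == 0.5

    def test_empty_cell_flagged_as_nan(self):
        d = pd.DataFrame(
            {
                "stay": [1, 0],
                "reward_prev": [0.5, 0.5],
                "transition_prev": [0.5, -0.5],
                "interaction": [0.25, -0.25],
            }
        )
        tab = stay_table(d)
        assert tab.loc["unrewarded"].isna().all()
        assert all(np.isnan(v) for v in simple_indices(tab))

    def test_cells_bounded(self, simulated_trials):
        tab = stay_table(build_stay_design(simulated_trials))
        assert ((tab >= 0) & (tab <= 1)).all().all()


class TestIndices:
    def _table(self, rc, rr, uc, ur):
        return pd.DataFrame(
            [[rc, rr], [uc, ur]],
            index=pd.Index(["rewarded", "unrewarded"], name="prev_reward"),
            columns=pd.Index(["common", "rare"], name="prev_transition"),
        )

    def test_reward_main_effect(self):
        mf, _, _ = simple_indices(self._table(0.8, 0.8, 0.6, 0.6))
        assert mf == pytest.approx(0.2)

    def test_interaction_contrast(self):
        _, mb, _ = simple_indices(self._table(0.9, 0.6, 0.6, 0.9))
        assert mb == pytest.approx(0.6)

    def test_flat_table_zeroes_everything(self):
        assert simple_indices(self._table(0.7, 0.7, 0.7, 0.7)) == (0.0, 0.0, 0.0)

    def test_w_repeat_is_difference(self):
        mf, mb, w = simple_indices(self._table(0.9, 0.5, 0.4, 0.6))
        assert w == pytest.approx(mb - mf)


class TestSubjectFit:
    def test_null_design_gives_near_zero_slopes(self):
        rng = np.random.default_rng(0)
        n = 4000
        d = pd.DataFrame(
            {
                "stay": rng.integers(0, 2, n),
                "reward_prev": rng.choice([0.5, -0.5], n),
                "transition_prev": rng.choice([0.5, -0.5], n),
            }
        )
        d["interaction"] = d["reward_prev"] * d["transition_prev"]
        c = fit_subject_stay(d)
        assert abs(c.b_rew) < 0.15 and abs(c.b_trans) < 0.15 and abs(c.b_rxt) < 0.15

    def test_matches_statsmodels_in_unpenalized_limit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 500
        rew = rng.choice([0.5, -0.5], n)
        tr = rng.choice([0.5, -0.5], n)
        eta = 0.3 + 0.8 * rew + 1.0 * rew * tr
        stay = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        d = pd.DataFrame(
            {"stay": stay, "reward_prev": rew, "transition_prev": tr,
             "interaction": rew * tr}
        )
        ours = fit_subject_stay(d, ridge=1e-10).to_array()
        X = sm.add_constant(d[["reward_prev", "transition_prev", "interaction"]])
        ref = sm.Logit(d["stay"], X).fit(disp=0).params.to_numpy()
        assert np.allclose(ours, ref, atol=1e-5)

    def test_separation_survives_with_ridge(self):
        d = pd.DataFrame(
            {
                "stay": [1, 1, 1, 1, 0, 0, 0, 0],
                "reward_prev": [0.5] * 4 + [-0.5] * 4,
                "transition_prev": [0.5, -0.5] * 4,
            }
        )
        d["interaction"] = d["reward_prev"] * d["transition_prev"]
        c = fit_subject_stay(d, ridge=0.1)
        assert np.isfinite(c.to_array()).all()

    def test_constant_stay_without_ridge_rejected(self):
        d = pd.DataFrame(
            {
                "stay": [1] * 8,
                "reward_prev": [0.5, -0.5] * 4,
                "transition_prev": [0.5] * 4 + [-0.5] * 4,
            }
        )
        d["interaction"] = d["reward_prev"] * d["transition_prev"]
        with pytest.raises(ValueError):
            fit_subject_stay(d, ridge=0.0)

    def test_too_short_design_rejected(self):
        d = pd.DataFrame(
            {"stay": [1, 0], "reward_prev": [0.5, -0.5],
             "transition_prev": [0.5, -0.5], "interaction": [0.25, 0.25]}
        )
        with pytest.raises(ValueError):
            fit_subject_stay(d)


class TestGroupEffects:
    def _coefs(self, B):
        return [StayCoefficients(*row) for row in B]

    def test_all_zero_coefficients(self):
        g = group_effects(self._coefs(np.zeros((5, 4))))
        assert (g["estimate"] == 0).all()
        assert (g["p"] == 1).all()

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        B = rng.normal(0.5, 0.3, size=(10, 4))
        g1 = group_effects(self._coefs(B))
        g2 = group_effects(self._coefs(-B))
        assert np.allclose(g1["estimate"], -g2["estimate"])
        assert np.allclose(g1["p"], g2["p"])

    def test_ci_coverage_near_nominal(self):
        """t-interval covers the true mean in about 95% of replications."""
        rng = np.random.default_rng(3)
        covered = 0
        reps = 500
        for _ in range(reps):
            B = rng.normal(0.7, 0.3, size=(27, 4))
            g = group_effects(self._coefs(B))
            row = g.loc["reward"]
            covered += row["ci_low"] <= 0.7 <= row["ci_high"]
        assert covered / reps >= 0.93

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_effects(self._coefs(np.zeros((2, 4))))


class TestModeration:
    def _coefs_from(self, b_rxt):
        return [StayCoefficients(0.2, 0.5, 0.0, v) for v in b_rxt]

    def test_quadratic_flag_false_omits_squared_term(self):
        rng = np.random.default_rng(4)
        res = moderation_test(
            self._coefs_from(rng.normal(0, 1, 27)), rng.normal(60, 10, 27),
            quadratic=False,
        )
        assert [r.term for r in res] == ["linear"]

    def test_detects_constructed_linear_moderation(self):
        rng = np.random.default_rng(5)
        ability = rng.normal(68, 16, 40)
        z = (ability - ability.mean()) / ability.std()
        res = moderation_test(
            self._coefs_from(1.0 + 0.8 * z + rng.normal(0, 0.2, 40)), ability,
            quadratic=False,
        )
        lin = res[0]
        assert lin.estimate == pytest.approx(0.8, abs=0.15)
        assert lin.p_unc < 1e-6

    def test_zero_variance_ability_rejected(self):
        with pytest.raises(ValueError):
            moderation_test(self._coefs_from(np.zeros(10)), np.full(10, 5.0))

    def test_detection_rate_matches_correlation_power(self):
        """Coefficients constructed with corr 0.45 to the ability at n = 29
        are detected at about the a-priori power of the correlation test
        (~71%)."""
        rng = np.random.default_rng(8)
        detected = 0
        reps = 300
        for _ in range(reps):
            ability = rng.normal(68, 16, 29)
            z = (ability - ability.mean()) / ability.std()
            b = 0.45 * z + np.sqrt(1 - 0.45**2) * rng.standard_normal(29)
            res = moderation_test(self._coefs_from(b), ability, quadratic=False)
            detected += res[0].p_unc < 0.05
        assert detected / reps == pytest.approx(0.71, abs=0.08)

    def test_null_p_values_are_uniform(self):
        """No linkage between behaviour and ability: p-values are U(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            res = moderation_test(
                self._coefs_from(rng.normal(0, 1, 27)), rng.normal(60, 10, 27),
                quadratic=False,
            )
            ps.append(res[0].p_unc)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFdr:
    def test_spec_of_step_up_on_small_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_degenerate_inputs(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_brute_force_step_up(self, p):
        assert np.allclose(fdr_adjust(p), brute_force_bh(p), atol=1e-12)


class TestSplits:
    def test_tertile_equal_thirds(self):
        labels = split_scores(np.arange(1, 10), "tertile")
        assert [np.sum(labels == g) for g in (0, 1, 2)] == [3, 3, 3]

    def test_median_equal_halves(self):
        labels = split_scores(np.arange(1, 11), "median")
        assert [np.sum(labels == g) for g in (0, 1)] == [5, 5]
        assert (np.arange(1, 11)[labels == 1] > 5).all()

    def test_boundaries_are_order_statistics(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(68.6, 15.9, 27)
        labels = split_scores(scores, "tertile")
        s = np.sort(scores)
        assert scores[labels == 0].max() <= s[9]
        assert scores[labels == 2].min() >= s[17]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            split_scores([1, 2, 3], "quartile")
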