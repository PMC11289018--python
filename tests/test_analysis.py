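"""Explanatory IRT fitting, Nakagawa R², parallel analysis, PCA composites."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from singrec.analysis import (
    TrialModel,
    fit_trial_model,
    nakagawa_r2,
    parallel_analysis,
    pca_composite,
    varimax,
)
from singrec.core import Melody
from singrec.features import ItemFeatures
from singrec.itembank import ItemBankEntry
from singrec.simulate import simulate_study

warnings.filterwarnings("ignore", message=".*boundary.*")


def synthetic_items(n_items, seed, ranges=None):
    """Items with independently drawn features, so every coefficient is identified."""
    r = {
        "N": (3, 16), "ie": (0.0, 1.0), "de": (0.0, 1.0),
        "ton": (0.4, 0.95), "scv": (0.1, 0.8), "lf": (-4.0, -1.0),
    }
    r.update(ranges or {})
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n_items):
        f = ItemFeatures(
            N=int(rng.integers(*r["N"])),
            i_entropy=float(rng.uniform(*r["ie"])),
            d_entropy=float(rng.uniform(*r["de"])),
            tonalness=float(rng.uniform(*r["ton"])),
            step_cont_loc_var=float(rng.uniform(*r["scv"])),
            log_freq=float(rng.uniform(*r["lf"])),
        )
        items.append(
            ItemBankEntry(f"s{i}", "synthetic", 0,
                          Melody.from_pitches([60] * f.N, 0.25), features=f)
        )
    return items


ARHYTHMIC_TRUTH = {"Intercept": 0.74, "N": -0.01, "step_cont_loc_var": -0.32,
                   "tonalness": 0.13, "log_freq": 0.02}


class TestTrialModel:
    def test_parameter_recovery_arhythmic(self):
        items = synthetic_items(20, seed=100)
        trials = simulate_study(100, items, ability_sd=0.1, model="arhythmic",
                                noise_sd=0.1, seed=11)
        res = fit_trial_model(trials, spec="arhythmic")
        for term, truth in ARHYTHMIC_TRUTH.items():
            assert abs(res.params[term] - truth) <= 2 * res.bse[term], term

    def test_parameter_recovery_combined(self):
        # joint check at the Bonferroni-adjusted 5% level over 8 terms
        items = synthetic_items(30, seed=300, ranges={"N": (3, 9), "scv": (0.05, 0.4),
                                                      "de": (0, 0.5), "ie": (0, 0.5)})
        parts = [
            simulate_study(80, items, ability_sd=0.05, model="combined", noise_sd=0.1,
                           seed=31, trial_type=tt)
            for tt in ("arhythmic", "rhythmic")
        ]
        res = fit_trial_model(pd.concat(parts, ignore_index=True), spec="combined")
        truth = {"Intercept": 0.64, "N": -0.01, "step_cont_loc_var": -0.38,
                 "tonalness": 0.10, "log_freq": 0.01, "melody_type_rhythmic": -0.15,
                 "arhythmic_x_d_entropy": -0.08, "rhythmic_x_d_entropy": -0.28}
        zcrit = norm.ppf(1 - 0.05 / (2 * len(truth)))
        for term, b in truth.items():
            assert abs(res.params[term] - b) <= zcrit * res.bse[term], term

    def test_zero_noise_conditional_r2_near_one(self):
        items = synthetic_items(15, seed=5)
        trials = simulate_study(40, items, ability_sd=0.05, model="arhythmic",
                                noise_sd=1e-4, seed=6)
        res = fit_trial_model(trials, spec="arhythmic")
        assert res.r2_conditional > 0.99

    def test_ability_recovery_and_shuffle_control(self):
        items = synthetic_items(20, seed=100)
        trials = simulate_study(200, items, ability_sd=0.1, model="arhythmic",
                                noise_sd=0.1, seed=12)
        res = fit_trial_model(trials, spec="arhythmic")
        true_ab = trials.groupby("participant_id")["ability_true"].first().sort_index()
        r = np.corrcoef(true_ab.values, res.abilities.loc[true_ab.index].values)[0, 1]
        assert r > 0.8
        # shuffling participant labels destroys the correlation
        rng = np.random.default_rng(1)
        shuffled = trials.copy()
        shuffled["participant_id"] = rng.permutation(shuffled["participant_id"].values)
        res_s = fit_trial_model(shuffled, spec="arhythmic")
        true_s = shuffled.groupby("participant_id")["ability_true"].first().sort_index()
        r_s = np.corrcoef(true_s.values, res_s.abilities.loc[true_s.index].values)[0, 1]
        assert abs(r_s) < 0.3

    def test_row_order_invariance(self):
        items = synthetic_items(10, seed=9)
        trials = simulate_study(25, items, ability_sd=0.1, model="arhythmic",
                                noise_sd=0.1, seed=13)
        res1 = fit_trial_model(trials, spec="arhythmic")
        res2 = fit_trial_model(trials.sample(frac=1.0, random_state=3), spec="arhythmic")
        assert np.allclose(res1.params.values, res2.params.values, atol=1e-8)

    def test_summary_and_ability_table(self):
        items = synthetic_items(10, seed=9)
        trials = simulate_study(25, items, ability_sd=0.1, model="arhythmic",
                                noise_sd=0.1, seed=13)
        res = TrialModel(trials, spec="arhythmic").fit()
        text = res.summary()
        assert "R2 marginal" in text and "Intercept" in text
        tab = res.ability_scores()
        assert len(tab) == 25 and "SAA_Ability_Arrhythmic" in tab.columns


class TestNakagawaR2:
    def test_closed_form(self):
        assert nakagawa_r2(1.0, 1.0, 2.0) == pytest.approx((0.25, 0.50))

    def test_no_random_variance(self):
        m, c = nakagawa_r2(1.0, 0.0, 1.0)
        assert m == c == pytest.approx(0.5)

    def test_zero_fixed(self):
        m, c = nakagawa_r2(0.0, 1.0, 1.0)
        assert m == 0.0 and c == pytest.approx(0.5)

    def test_ordering_invariant(self, rng):
        for _ in range(50):
            vf, vr, ve = rng.uniform(0.01, 2.0, 3)
            m, c = nakagawa_r2(vf, vr, ve)
            assert 0.0 <= m <= c <= 1.0


class TestParallelAnalysis:
    def test_pure_noise_retains_at_most_one(self, rng):
        assert parallel_analysis(rng.standard_normal((200, 7)), seed=2) <= 1

    def test_three_factor_structure(self, rng):
        F = rng.standard_normal((300, 3))
        L = np.zeros((6, 3))
        L[0, 0], L[1, 0] = 0.9, 0.85
        L[2, 1], L[3, 1] = 0.88, -0.9
        L[4, 2], L[5, 2] = -0.8, 0.92
        X = F @ L.T + rng.standard_normal((300, 6)) * 0.35
        assert parallel_analysis(X, seed=1) == 3

    def test_duplicated_single_factor(self, rng):
        f = rng.standard_normal(200)
        X = np.column_stack([f + rng.standard_normal(200) * 0.1 for _ in range(5)])
        assert parallel_analysis(X, seed=3) == 1

    def test_constant_column_rejected(self, rng):
        X = rng.standard_normal((100, 4))
        X[:, 2] = 1.0
        with pytest.raises(ValueError):
            parallel_analysis(X)


def congruence(a, b):
    return abs(a @ b) / np.sqrt((a @ a) * (b @ b))


class TestPCAComposite:
    def _three_factor_data(self, seed=5, n=300):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((n, 3))
        L = np.zeros((6, 3))
        L[0, 0], L[1, 0] = 0.9, 0.85  # accuracy-like pair
        L[2, 1], L[3, 1] = 0.88, -0.9  # volatility-like pair
        L[4, 2], L[5, 2] = -0.8, 0.92  # scoop-like pair
        L[4, 0] = 0.5  # cross-loading
        X = F @ L.T + rng.standard_normal((n, 6)) * 0.35
        cols = ["accuracy", "dtw", "autocorr", "runs", "ncpts", "second_cpt"]
        return pd.DataFrame(X, columns=cols), L

    def test_recovers_generating_structure(self):
        X, L_true = self._three_factor_data()
        model, scores = pca_composite(X, 3, rotation="varimax")
        for j in range(3):
            assert max(congruence(L_true[:, j], model.loadings.values[:, k])
                       for k in range(3)) > 0.9
        assert scores.shape == (len(X), 3)

    def test_low_communality_variable_dropped(self):
        X, _ = self._three_factor_data()
        rng = np.random.default_rng(8)
        X["var_hz"] = rng.standard_normal(len(X))  # unrelated indicator
        model, _ = pca_composite(X, 3, rotation="varimax", drop_below_h2=0.75)
        assert "var_hz" in model.dropped
        assert (model.communalities >= 0.75).all()

    def test_single_component_majority_variance(self, rng):
        f = rng.standard_normal(250)
        X = pd.DataFrame({c: f * w + rng.standard_normal(250) * 0.6
                          for c, w in [("a", 0.9), ("b", 0.8), ("c", 0.85)]})
        model, _ = pca_composite(X, 1, rotation="none")
        assert model.variance_explained[0] > 0.5

    def test_orthogonality_and_rotation_invariants(self):
        X, _ = self._three_factor_data(seed=6)
        plain, _ = pca_composite(X, 3, rotation="none")
        G = plain.loadings.values.T @ plain.loadings.values
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8  # unrotated principal axes orthogonal
        rot, _ = pca_composite(X, 3, rotation="varimax")
        # an orthogonal rotation leaves each variable's communality unchanged
        assert np.allclose(rot.communalities.values, plain.communalities.values, atol=1e-8)


def test_varimax_concentrates_loadings():
    rng = np.random.default_rng(2)
    L = np.array([[0.7, 0.7], [0.7, -0.7], [0.6, 0.6], [0.6, -0.6]])
    R = varimax(L)
    # varimax should push rows toward single-component structure
    simplicity = lambda M: np.sum(M**4)
    assert simplicity(R) >= simplicity(L) - 1e-12
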