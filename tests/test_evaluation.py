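import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pikasdm import evaluation as ev
from pikasdm import synthetic_data as sd


def pairwise_auc(pres, bg):
    """Independent O(nm) oracle: count presence>background pairs, ties half."""
    wins = ties = 0
    for p in pres:
        for b in bg:
            if p > b:
                wins += 1
            elif p == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pres) * len(bg))


class TestAuc:
    def test_perfect_separation(self):
        assert ev.auc([5, 6, 7], [1, 2, 3]) == 1.0

    def test_identical_sets_give_half(self):
        assert ev.auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pres = rng.integers(0, 6, size=5).astype(float)  # forced ties
            bg = rng.integers(0, 6, size=8).astype(float)
            assert ev.auc(pres, bg) == pytest.approx(pairwise_auc(pres, bg), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        pres, bg = rng.normal(1, 1, 30), rng.normal(0, 1, 60)
        base = ev.auc(pres, bg)
        for f in (np.exp, np.tanh, lambda v: v**3 + 2 * v):
            assert ev.auc(f(pres), f(bg)) == pytest.approx(base, abs=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ev.auc([], [1.0])


class TestTss:
    def test_perfect_separation_reaches_one(self):
        curve = ev.tss_curve([0.9, 0.8, 0.85], [0.1, 0.2, 0.05, 0.15])
        assert curve["tss"].max() == pytest.approx(1.0)

    def test_identical_scores_zero_interior(self):
        curve = ev.tss_curve([0.5] * 5, [0.5] * 7)
        interior = curve[(curve.threshold > 0.5) & (curve.threshold < 1.0)]
        np.testing.assert_allclose(interior["tss"], 0.0, atol=1e-12)

    def test_hand_tally_toy(self):
        # 6 presences, 10 pseudo-absences; tally at t=0.5 by hand:
        # presences >= 0.5: {0.9,0.7,0.55,0.5} -> TP=4, FN=2
        # absences >= 0.5: {0.6,0.5} -> FP=2, TN=8
        pres = [0.9, 0.7, 0.55, 0.5, 0.3, 0.1]
        absn = [0.6, 0.5, 0.45, 0.4, 0.35, 0.3, 0.2, 0.15, 0.1, 0.05]
        curve = ev.tss_curve(pres, absn)
        row = curve[curve.threshold == 0.5].iloc[0]
        assert row["sensitivity"] == pytest.approx(4 / 6)
        assert row["specificity"] == pytest.approx(8 / 10)
        assert row["tss"] == pytest.approx(4 / 6 + 8 / 10 - 1)
        # full-curve check against a brute-force tally at every threshold
        for _, r in curve.iterrows():
            t = r["threshold"]
            tp = sum(p >= t for p in pres)
            tn = sum(a < t for a in absn)
            assert r["tss"] == pytest.approx(tp / 6 + tn / 10 - 1)

    def test_optimal_threshold_and_tie_rule(self):
        curve = pd.DataFrame({"threshold": [0.0, 0.1, 0.2, 0.3],
                              "tss": [0.1, 0.5, 0.9, 0.4]})
        assert ev.optimal_threshold(curve) == (0.2, 0.9)
        flat = pd.DataFrame({"threshold": [0.0, 0.5, 1.0], "tss": [0.3, 0.3, 0.3]})
        assert ev.optimal_threshold(flat)[0] == 0.0  # ties -> smaller threshold

    def test_coarse_grid_never_beats_fine_grid(self):
        rng = np.random.default_rng(3)
        pres, absn = rng.beta(3, 1.2, 40), rng.beta(1.2, 3, 80)
        coarse = ev.tss_curve(pres, absn, np.linspace(0, 1, 11))
        fine = ev.tss_curve(pres, absn, np.linspace(0, 1, 1001))
        assert coarse["tss"].max() <= fine["tss"].max() + 1e-12


class TestWilcoxon:
    def test_identical_pairs(self):
        with pytest.warns(UserWarning, match="zero"):
            w, p, direction = ev.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0],
                                                      [1.0, 2.0, 3.0, 4.0, 5.0])
        assert (w, p, direction) == (0.0, 1.0, "none")

    def test_six_positive_differences_exact(self):
        # all-positive signs are 1 of 64 assignments in each tail
        a = [1.1, 2.2, 3.3, 4.1, 5.2, 6.3]
        b = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        w, p, direction = ev.wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(2 / 64)
        assert direction == "a"

    @pytest.mark.parametrize("trial", range(10))
    def test_exact_matches_full_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(6, 13))
        d = np.round(rng.normal(size=n), 1)  # rounding forces ties
        d = np.where(d == 0, 0.05, d)
        a = d
        b = np.zeros(n)
        _, p_mine, _ = ev.wilcoxon_signed_rank(a, b)
        # brute force over all 2^n sign assignments
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        count = 0
        for mask in range(2 ** n):
            w = sum(r for i, r in enumerate(ranks) if (mask >> i) & 1)
            if w <= min(w_obs, total - w_obs) + 1e-9 or w >= max(w_obs, total - w_obs) - 1e-9:
                count += 1
        assert p_mine == pytest.approx(min(count / 2 ** n, 1.0), abs=1e-12)

    def test_large_n_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.3, 1, 40)
        b = rng.normal(0.0, 1, 40)
        w, p, _ = ev.wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, correction=True, method="approx")
        assert w == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_nonzero_differences(self):
        with pytest.raises(ValueError, match=">= 5"):
            ev.wilcoxon_signed_rank([1, 2, 3, 4.0], [0, 0, 0, 0.0])


class TestGrade:
    @pytest.mark.parametrize(
        "value,scale,label",
        [
            (0.90, "auc", "good"),
            (0.95, "auc", "excellent"),
            (0.5, "auc", "worse than random"),
            (0.55, "auc", "failed"),
            (0.65, "auc", "poor"),
            (0.75, "auc", "fair"),
            (0.67, "tss", "good"),
            (0.62, "tss", "good"),
            (0.1, "tss", "bad"),
            (0.35, "tss", "poor"),
            (0.55, "tss", "fair"),
            (0.9, "tss", "excellent"),
        ],
    )
    def test_boundaries(self, value, scale, label):
        assert ev.grade(value, scale) == label

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            ev.grade(1.2, "auc")
        with pytest.raises(ValueError):
            ev.grade(-1.5, "tss")


class TestReplicates:
    def test_split_plan_sizes_and_pairing(self):
        plans = ev.make_split_plans(77, 4, seed=3)
        for p in plans:
            assert len(p.train_idx) == 38 and len(p.test_idx) == 39
            assert set(p.train_idx) | set(p.test_idx) == set(range(77))
            assert set(p.train_idx) & set(p.test_idx) == set()
        again = ev.make_split_plans(77, 4, seed=3)
        for p, q in zip(plans, again):
            np.testing.assert_array_equal(p.train_idx, q.train_idx)

    def test_same_seed_reproduces_report(self, default_study, fast_settings):
        pres = default_study.presences.features_presence
        bg = default_study.presences.features_background
        kinds = default_study.stack.kinds()
        r1 = ev.run_replicates(pres, bg, kinds, 2, seed=5, settings=fast_settings)
        r2 = ev.run_replicates(pres, bg, kinds, 2, seed=5, settings=fast_settings)
        pd.testing.assert_frame_equal(r1.replicates, r2.replicates)
        np.testing.assert_array_equal(r1.tss_mean_curve, r2.tss_mean_curve)

    def test_single_replicate_report_structure(self, default_study, fast_settings):
        pres = default_study.presences.features_presence
        bg = default_study.presences.features_background
        r = ev.run_replicates(pres, bg, default_study.stack.kinds(), 1, seed=2,
                              settings=fast_settings)
        assert len(r.replicates) == 1
        row = r.replicates.iloc[0]
        assert 0 <= row["train_auc"] <= 1 and 0 <= row["test_auc"] <= 1
        assert -1 <= row["max_tss"] <= 1
        assert row["opt_threshold"] in r.thresholds
        # with one replicate the mean curve IS the replicate curve
        assert r.tss_mean_curve.max() == pytest.approx(row["max_tss"])


class TestJackknifeContribution:
    def test_duplicate_variable_symmetric_noise_near_zero(self, fast_settings):
        rng = np.random.default_rng(11)
        n_bg = 400
        signal = rng.uniform(0, 20, n_bg)
        bg = pd.DataFrame({
            "signal": signal,
            "twin": signal.copy(),
            "noise": rng.normal(size=n_bg),
        })
        keep = rng.choice(n_bg, 60, replace=False, p=_soft(signal))
        pres = bg.iloc[keep].reset_index(drop=True)
        kinds = {c: "continuous" for c in bg.columns}
        jk = ev.jackknife(pres, bg, kinds, settings=fast_settings)
        g = dict(zip(jk.gains["variable"], jk.gains["gain_with_only"]))
        assert g["signal"] == pytest.approx(g["twin"], rel=0.05)  # symmetry
        assert g["noise"] < 0.2 * g["signal"]  # pure noise has little gain
        assert (jk.gains["gain_without"] <= jk.gain_all_variables + 1e-6).all()

    def test_contribution_sums_to_100_and_noise_excluded(self, fast_settings):
        rng = np.random.default_rng(21)
        n_bg = 400
        signal = rng.uniform(0, 20, n_bg)
        bg = pd.DataFrame({"signal": signal, "noise": rng.normal(size=n_bg)})
        keep = rng.choice(n_bg, 60, replace=False, p=_soft(signal))
        pres = bg.iloc[keep].reset_index(drop=True)
        kinds = {c: "continuous" for c in bg.columns}
        model, _ = ev._fit_gain(pres, bg, kinds, ["signal", "noise"], fast_settings)
        contrib = ev.contribution(model, pres, bg, seed=0)
        assert contrib.sum() == pytest.approx(100.0, abs=0.01)
        assert contrib["noise"] < 0.5  # below the exclusion line
        model1, _ = ev._fit_gain(pres, bg, kinds, ["signal"], fast_settings)
        only = ev.contribution(model1, pres[["signal"]], bg[["signal"]], seed=0)
        assert only["signal"] == pytest.approx(100.0)

    def test_select_variables_greedy_rule(self, fast_settings):
        rng = np.random.default_rng(31)
        n_bg = 300
        a = rng.uniform(0, 10, n_bg)
        b = a + rng.normal(0, 0.5, n_bg)  # r(a,b) ~ 0.99
        c = rng.normal(size=n_bg)
        bg = pd.DataFrame({"a": a, "b": b, "c": c})
        keep = rng.choice(n_bg, 50, replace=False, p=_soft(a))
        pres = bg.iloc[keep].reset_index(drop=True)
        kinds = {k: "continuous" for k in bg.columns}
        jk = ev.jackknife(pres, bg, kinds, settings=fast_settings)
        g = dict(zip(jk.gains["variable"], jk.gains["gain_with_only"]))
        retained = ev.select_variables(pres, bg, kinds, jk, r_cut=0.75,
                                       contribution_cut=0.0, settings=fast_settings)
        # exactly one of the correlated pair survives: the higher-gain one
        assert ("a" in retained) != ("b" in retained)
        winner = "a" if "a" in retained else "b"
        loser = "b" if winner == "a" else "a"
        assert g[winner] >= g[loser]
        assert "c" in retained  # uncorrelated variable survives

    def test_identical_layers_keep_exactly_one(self, fast_settings):
        rng = np.random.default_rng(41)
        n_bg = 200
        x = rng.uniform(0, 5, n_bg)
        bg = pd.DataFrame({"x1": x, "x2": x.copy()})
        pres = bg.iloc[rng.choice(n_bg, 30, replace=False, p=_soft(x))].reset_index(drop=True)
        kinds = {"x1": "continuous", "x2": "continuous"}
        jk = ev.jackknife(pres, bg, kinds, settings=fast_settings)
        retained = ev.select_variables(pres, bg, kinds, jk, contribution_cut=0.0,
                                       settings=fast_settings)
        assert len(retained) == 1


def _soft(x):
    w = np.exp(0.3 * (x - x.mean()))
    return w / w.sum()
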