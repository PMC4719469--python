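"""Peak responses, ESI, ANOVA effect sizes and contrast t-maps."""

import numpy as np
import pandas as pd
import pytest

from kalnirs.features import (
    compute_esi,
    contrast_tmap,
    difficulty_anova,
    extract_trial_features,
    order_levels,
    partial_eta_squared,
    peak_response,
)
from kalnirs.hrf import convolve_stimulus, hrf_kernel
from kalnirs.io import Recording
from kalnirs.simulate import NoiseConfig, ProtocolConfig, simulate_experiment

from conftest import make_features


class TestPeakResponse:
    def test_constant_signal_gives_zero(self):
        assert peak_response(np.full(100, 3.3), 5.0, fs=2.0) == 0.0

    def test_small_worked_example(self):
        sig = np.array([0.0, 0.2, 0.5, 0.3])
        assert peak_response(sig, 0.0, fs=2.0, window=1.5) == pytest.approx(0.5)

    def test_kernel_peak_recovered(self, params):
        k = hrf_kernel(params, 60.0)
        expected = 2.0 / params.tau * np.exp(-2.0)  # closed-form peak
        assert peak_response(k, 0.0, params.fs, window=30.0) == pytest.approx(
            expected, rel=1e-3)

    def test_min_mode(self):
        sig = np.array([0.0, -0.2, -0.5, -0.3])
        assert peak_response(sig, 0.0, fs=2.0, window=1.5, mode="min") == \
            pytest.approx(-0.5)

    def test_window_beyond_record_rejected(self):
        with pytest.raises(ValueError, match="window"):
            peak_response(np.zeros(50), 10.0, fs=2.0, window=30.0)


class TestExtractFeatures:
    def test_memorization_feature_count(self):
        proto = ProtocolConfig.memorization()
        noise = NoiseConfig.default(proto)
        rec, ev, _ = simulate_experiment(proto, noise, seed=0)
        feats = extract_trial_features(rec, ev)
        assert len(feats) == 27 * 16
        assert feats.groupby("level")["onset_s"].nunique().to_dict() == \
            {5: 9, 7: 9, 9: 9}

    def test_empty_events(self, atc_subject):
        rec, ev, _ = atc_subject
        feats = extract_trial_features(rec, ev.iloc[:0])
        assert feats.empty

    def test_known_amplitude_recovered_noise_free(self, params, model):
        beta = 0.8
        n = 200
        u = np.zeros(n)
        onset = 20.0
        u[int(onset * 2): int(onset * 2) + 12] = beta  # 6 s boxcar
        resp = convolve_stimulus(model, u)
        unit = convolve_stimulus(model, (u > 0).astype(float))
        cols = {"time_s": np.arange(n) / 2.0}
        for k in range(1, 17):
            cols[f"O{k}_HbO2"] = resp
            cols[f"O{k}_HHb"] = -0.3 * resp
        rec = Recording(pd.DataFrame(cols), fs=2.0, subject_id="S01")
        ev = pd.DataFrame({"onset": [onset], "duration": [6.0],
                           "condition": ["high"], "subject_id": ["S01"]})
        feats = extract_trial_features(rec, ev)
        expected = beta * peak_response(unit, onset, 2.0)
        assert feats["delta_hbo2"].to_numpy() == pytest.approx(expected, abs=1e-6)

    def test_trial_past_record_end_dropped(self, atc_subject, caplog):
        rec, ev, _ = atc_subject
        ev2 = pd.concat([ev, pd.DataFrame({
            "onset": [rec.duration - 5.0], "duration": [6.0],
            "condition": ["high"], "subject_id": ["S01"],
        })], ignore_index=True)
        with caplog.at_level("WARNING"):
            feats = extract_trial_features(rec, ev2)
        assert len(feats) == len(ev) * 16
        assert "dropping trial" in caplog.text


class TestESI:
    def test_three_level_worked_example(self):
        d = 0.1 / np.sqrt(2)  # two subjects at mu +/- d give sd = 0.1
        feats = make_features({
            5: [1 - d, 1 + d], 7: [2 - d, 2 + d], 9: [3 - d, 3 + d],
        })
        res = compute_esi(feats)
        assert res.esi == pytest.approx(0.8 + 0.8)
        assert res.means == pytest.approx((1.0, 2.0, 3.0))
        assert res.sds == pytest.approx((0.1, 0.1, 0.1))

    def test_identical_levels_give_minus_four_sigma(self):
        d = 0.25
        vals = [1 - d, 1 + d]
        s = np.std(vals, ddof=1)
        feats = make_features({5: vals, 7: vals, 9: vals})
        assert compute_esi(feats).esi == pytest.approx(-4 * s)

    def test_zero_sigma_telescopes_to_mean_spread(self):
        feats = make_features({5: [1.0, 1.0], 7: [1.5, 1.5], 9: [4.0, 4.0]})
        assert compute_esi(feats).esi == pytest.approx(4.0 - 1.0)

    def test_gap_bound(self):
        rng = np.random.default_rng(0)
        feats = make_features({
            lev: rng.normal(lev, 1.0, size=6) for lev in (5, 7, 9)
        })
        res = compute_esi(feats)
        assert res.esi <= res.means[-1] - res.means[0] + 1e-12

    def test_monotone_in_mean_gaps_and_sigmas(self):
        base = {5: [1.0, 1.2], 7: [2.0, 2.2], 9: [3.0, 3.2]}
        esi0 = compute_esi(make_features(base)).esi
        wider = {5: [1.0, 1.2], 7: [2.5, 2.7], 9: [4.0, 4.2]}
        assert compute_esi(make_features(wider)).esi > esi0
        noisier = {5: [0.5, 1.7], 7: [2.0, 2.2], 9: [3.0, 3.2]}
        assert compute_esi(make_features(noisier)).esi < esi0

    def test_pooled_trials_mode(self):
        feats = make_features({5: [1.0, 2.0], 7: [3.0, 4.0]})
        res = compute_esi(feats, by_subject=False)
        assert res.means == pytest.approx((1.5, 3.5))

    def test_single_observation_level_rejected(self):
        feats = make_features({5: [1.0, 2.0], 7: [3.0]})
        with pytest.raises(ValueError, match="level"):
            compute_esi(feats)

    def test_level_ordering(self):
        assert order_levels(["high", "low", "low"]) == ["low", "high"]
        assert order_levels([9, 5, 7]) == [5, 7, 9]
        assert order_levels(["9", "5", "7"]) == ["5", "7", "9"]


class TestPartialEtaSquared:
    def test_limits_and_formula(self):
        assert partial_eta_squared(0.0, 4.0) == 0.0
        assert partial_eta_squared(2.0, 0.0) == 1.0
        assert partial_eta_squared(3.0, 9.0) == pytest.approx(0.25)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(0.0, 0.0)
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 2.0)


class TestDifficultyAnova:
    def test_identical_cells_give_zero(self):
        feats = make_features({5: [1.0, 1.0, 1.0], 7: [1.0, 1.0, 1.0]})
        res = difficulty_anova(feats)
        assert res.pooled == 0.0

    def test_hand_worked_two_level_table(self):
        # 4 subjects x 2 levels, subject means (1,3), (2,4), (1,3), (2,5)
        lo, hi = [1.0, 2.0, 1.0, 2.0], [3.0, 4.0, 3.0, 5.0]
        feats = make_features({"low": lo, "high": hi})
        # by hand: level means 1.5 / 3.75, grand 2.625
        # SS_level = 4 * ((1.5-2.625)^2 + (3.75-2.625)^2) = 10.125
        # residuals (x - m_s - m_l + grand): per-subject diffs 2,2,2,3
        # SS_err = sum over cells = ((d_s - mean_d)/2)^2 summed * 2 = 0.375
        res = difficulty_anova(feats, design="repeated_measures")
        assert res.pooled_ss_effect == pytest.approx(10.125)
        assert res.pooled_ss_error == pytest.approx(0.375)
        assert res.pooled == pytest.approx(10.125 / (10.125 + 0.375))

    def test_matches_anova_rm_package(self):
        # independent route: statsmodels repeated-measures ANOVA
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(8)
        feats = make_features({
            lev: rng.normal(0.1 * lev, 1.0, size=6) for lev in (5, 7, 9)
        })
        res = difficulty_anova(feats)
        df = feats.rename(columns={"delta_hbo2": "resp"})
        fit = AnovaRM(df, "resp", "subject_id", within=["level"]).fit()
        f_ref = float(fit.anova_table["F Value"].iloc[0])
        df1, df2 = 2, 10
        f_mine = (res.pooled_ss_effect / df1) / (res.pooled_ss_error / df2)
        assert f_mine == pytest.approx(f_ref, rel=1e-10)

    def test_two_way_design_on_trials(self, atc_features):
        res = difficulty_anova(atc_features, design="two_way")
        assert 0.0 <= res.pooled <= 1.0
        assert len(res.per_optode) == 16

    def test_shuffling_labels_reduces_effect(self):
        rng = np.random.default_rng(12)
        better = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            feats = make_features({
                lev: r.normal(0.5 * i, 0.5, size=8)
                for i, lev in enumerate((5, 7, 9))
            })
            true_eta = difficulty_anova(feats).pooled
            shuf = feats.copy()
            for _, idx in shuf.groupby("subject_id").groups.items():
                shuf.loc[idx, "level"] = r.permutation(
                    shuf.loc[idx, "level"].to_numpy())
            better += difficulty_anova(shuf).pooled < true_eta
        assert better >= 9

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        feats = make_features({
            lev: rng.normal(lev, 1.0, size=5) for lev in (5, 7, 9)
        })
        res = difficulty_anova(feats).pooled
        scaled = feats.copy()
        scaled["delta_hbo2"] = 7.5 * scaled["delta_hbo2"] - 3.0
        assert difficulty_anova(scaled).pooled == pytest.approx(res, rel=1e-10)

    def test_single_level_rejected(self):
        feats = make_features({5: [1.0, 2.0]})
        with pytest.raises(ValueError):
            difficulty_anova(feats)


class TestContrastTMap:
    def test_identical_conditions_give_zero_t(self):
        feats = make_features({"low": [1.0, 2.0, 3.0], "high": [1.0, 2.0, 3.0]})
        tmap = contrast_tmap(feats, "high", "low")
        assert tmap.table["t"].to_numpy() == pytest.approx(0.0)
        assert not tmap.table["significant"].any()

    def test_constant_shift_with_jitter_all_significant(self):
        rng = np.random.default_rng(4)
        lo = [1.0, 2.0, 1.5, 1.2, 1.8]
        hi = [v + 2.0 + 1e-4 * rng.normal() for v in lo]
        tmap = contrast_tmap(make_features({"low": lo, "high": hi}),
                             "high", "low", alpha=0.01)
        assert tmap.table["significant"].all()

    def test_hand_computed_t_statistic(self):
        diffs = np.array([1.0, 2.0, 1.5, 1.2, 1.8])
        lo = np.zeros(5)
        tmap = contrast_tmap(make_features({"low": lo, "high": diffs}),
                             "high", "low")
        expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        assert tmap.table["t"].iloc[0] == pytest.approx(expected)

    def test_too_few_subjects_rejected(self):
        feats = make_features({"low": [1.0, 2.0], "high": [3.0, 4.0]})
        with pytest.raises(ValueError, match="subjects"):
            contrast_tmap(feats, "high", "low")

    def test_missing_label_rejected(self):
        feats = make_features({"low": [1.0, 2.0, 3.0], "high": [2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="missing"):
            contrast_tmap(feats, "extreme", "low")

    def test_grid_rendering_marks_significant(self):
        rng = np.random.default_rng(4)
        rows = []
        for k in range(1, 17):
            for s in range(4):
                for lev, off in (("low", 0.0), ("high", 3.0 if k == 2 else 0.0)):
                    rows.append({
                        "subject_id": f"S{s}", "optode": k, "level": lev,
                        "delta_hbo2": off + s * 0.5 + 1e-3 * rng.normal(),
                        "delta_hhb": 0.0, "onset_s": 0.0,
                    })
        tmap = contrast_tmap(pd.DataFrame(rows), "high", "low", alpha=0.01)
        grid = tmap.render_grid()
        assert grid.count("\n") == 1  # 16 cells over two rows
        assert "O02" in grid
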