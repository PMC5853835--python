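"""EEG conditioning, epoching, phase windows, and the split-plot ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from nirserp.erp import (PHASES, epoch_and_baseline, eog_correct, gg_epsilon,
                         lowpass_zero_phase, mixed_anova,
                         posthoc_grammaticality, reject_artifacts,
                         rejection_counts, rereference, window_amplitudes)
from nirserp.recordings import EEG_CHANNELS, EEG_SCALP, EEGRecording


def eeg_from(data=None, n=5000, seed=0):
    if data is None:
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 5, size=(len(EEG_CHANNELS), n))
    return EEGRecording(data=np.asarray(data, dtype=float))


class TestRereference:
    def test_zero_earlobes_identity(self):
        eeg = eeg_from()
        eeg.data[5:7] = 0.0
        out = rereference(eeg)
        np.testing.assert_array_equal(out.data[:5], eeg.data[:5])

    def test_constant_earlobes_shift(self):
        eeg = eeg_from()
        eeg.data[5] = 3.0
        eeg.data[6] = 3.0
        out = rereference(eeg)
        np.testing.assert_allclose(out.data[:5], eeg.data[:5] - 3.0)

    def test_matches_manual_subtraction(self):
        eeg = eeg_from(seed=1)
        out = rereference(eeg)
        expected = eeg.data[:5] - 0.5 * (eeg.data[5] + eeg.data[6])
        np.testing.assert_allclose(out.data[:5], expected)
        # EOG and earlobes untouched
        np.testing.assert_array_equal(out.data[5:], eeg.data[5:])


class TestEogCorrect:
    def test_zero_eog_is_identity(self):
        eeg = eeg_from()
        eeg.data[7] = 0.0
        with pytest.warns(UserWarning, match="flat"):
            out = eog_correct(eeg)
        np.testing.assert_array_equal(out.data, eeg.data)

    def test_removes_planted_leakage(self):
        rng = np.random.default_rng(2)
        n = 20000
        eog = rng.normal(0, 50, n)
        data = np.zeros((8, n))
        data[7] = eog
        for i in range(5):
            data[i] = 0.3 * eog + rng.normal(0, 5, n)
        out = eog_correct(eeg_from(data))
        for i in range(5):
            r = np.corrcoef(out.data[i], eog)[0, 1]
            assert abs(r) < 0.05

    def test_coefficient_equals_covariance_ratio(self):
        rng = np.random.default_rng(3)
        n = 5000
        eog = rng.normal(0, 30, n)
        ch = 0.45 * eog + rng.normal(0, 3, n)
        data = np.zeros((8, n))
        data[0] = ch
        data[7] = eog
        out = eog_correct(eeg_from(data))
        b = np.cov(ch, eog, ddof=0)[0, 1] / np.var(eog)
        np.testing.assert_allclose(out.data[0], ch - b * eog,
                                   atol=1e-6 * np.abs(ch).max())


class TestLowpass:
    def sine(self, freq, n=10000, rate=500.0):
        t = np.arange(n) / rate
        data = np.zeros((8, n))
        data[:5] = np.sin(2 * np.pi * freq * t)
        return eeg_from(data)

    def test_passband_sine_preserved(self):
        out = lowpass_zero_phase(self.sine(5.0))
        mid = out.data[0, 2000:8000]
        assert np.abs(mid).max() > 0.99

    def test_stopband_matches_transfer_function(self):
        freq, rate = 60.0, 500.0
        out = lowpass_zero_phase(self.sine(freq))
        mid = out.data[0, 4000:6000]
        got = np.abs(mid).max()
        # oracle: squared magnitude of the one-pass Butterworth response
        b, a = signal.butter(2, 30.0, btype="low", fs=rate)
        _, h = signal.freqz(b, a, worN=[freq], fs=rate)
        expected = np.abs(h[0]) ** 2  # forward + backward pass
        assert got == pytest.approx(expected, rel=0.05)

    def test_dc_unchanged(self):
        data = np.full((8, 4000), 7.0)
        out = lowpass_zero_phase(eeg_from(data))
        np.testing.assert_allclose(out.data[:5], 7.0, atol=1e-8)

    def test_zero_phase_keeps_pulse_latency(self):
        n, rate = 5000, 500.0
        data = np.zeros((8, n))
        pulse = signal.windows.gaussian(501, std=60)
        data[:5, 2000:2501] = pulse
        out = lowpass_zero_phase(eeg_from(data))
        assert abs(int(np.argmax(out.data[0])) - 2250) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_zero_phase(eeg_from(), cutoff_hz=300.0)


def onsets_frame(onsets, types=None):
    types = types or ["correct"] * len(onsets)
    return pd.DataFrame({"onset": onsets, "trial_type": types})


class TestEpoching:
    def test_epoch_length_600_samples(self):
        eeg = eeg_from(n=5000)
        ep = epoch_and_baseline(eeg, onsets_frame([2.0, 4.0]))
        assert ep.data.shape == (2, 5, 600)
        assert ep.times[0] == pytest.approx(-0.2)

    def test_constant_signal_baselines_to_zero(self):
        data = np.full((8, 3000), 7.0)
        ep = epoch_and_baseline(eeg_from(data), onsets_frame([2.0]))
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)

    def test_out_of_bounds_trial_flagged_not_extracted(self):
        eeg = eeg_from(n=1000)  # 2 s of data
        ep = epoch_and_baseline(eeg, onsets_frame([0.05, 1.0, 1.9]))
        assert ep.n_trials == 1
        assert ep.dropped == 2

    def test_injected_component_appears_at_its_latency(self):
        rate, n = 500.0, 5000
        data = np.zeros((8, n))
        onset = 4.0
        comp_idx = int((onset + 0.150) * rate)
        data[:5, comp_idx:comp_idx + 25] = -5.0
        ep = epoch_and_baseline(eeg_from(data), onsets_frame([onset]))
        lat = ep.times[np.argmin(ep.data[0, 0])]
        assert lat == pytest.approx(0.150, abs=1 / rate)


class TestRejection:
    def make_epochs(self, peaks):
        rate, n = 500.0, 20000
        data = np.zeros((8, n))
        onsets = [2.0 + 2.0 * i for i in range(len(peaks))]
        for onset, peak in zip(onsets, peaks):
            i = int((onset + 0.3) * rate)
            data[0, i] = peak
        return epoch_and_baseline(
            eeg_from(data),
            onsets_frame(onsets, ["correct", "incorrect"] * (len(peaks) // 2)))

    def test_single_sample_over_threshold_rejects_trial(self):
        ep = reject_artifacts(self.make_epochs([150.0, 50.0]))
        assert list(ep.rejected) == [True, False]
        assert "amplitude" in ep.reject_reason[0]

    def test_all_within_threshold_none_rejected(self):
        ep = reject_artifacts(self.make_epochs([99.0, -99.0, 42.0, -3.0]))
        assert not ep.rejected.any()

    def test_rejection_set_equals_planted_set(self, small_design):
        # generator with known artifact trials and no blinks/noise floor
        # high enough to cross threshold on its own
        from dataclasses import replace
        from nirserp.simulate import ERPEffectConfig, simulate_eeg
        eff = ERPEffectConfig(pink_sd=5.0, white_sd=1.0, blink_rate_hz=0.0,
                              artifact_fraction=0.3)
        eeg = simulate_eeg(small_design, "boy", seed=77, effects=eff)
        # find planted trials independently: peak before any filtering
        onsets = small_design.violation_onsets()
        ep_raw = epoch_and_baseline(eeg, onsets)
        planted = set(np.flatnonzero(
            np.abs(ep_raw.data).max(axis=(1, 2)) > 100.0))
        ep = reject_artifacts(epoch_and_baseline(eeg, onsets))
        assert set(np.flatnonzero(ep.rejected)) == planted
        assert 0 < len(planted) < ep.n_trials

    def test_counts_reported_per_condition(self):
        ep = reject_artifacts(self.make_epochs([150.0, 50.0, -120.0, 0.0]))
        counts = rejection_counts(ep).set_index("condition")
        assert counts.loc["correct", "n_rejected"] == 2
        assert counts.loc["incorrect", "n_rejected"] == 0


class TestWindowAmplitudes:
    def test_constant_epoch_gives_constant_means(self):
        rate, n = 500.0, 4000
        data = np.zeros((8, n))
        data[:5, 1000:1500] = 4.0  # exactly the 0..1 s post-onset window
        ep = epoch_and_baseline(eeg_from(data), onsets_frame([2.0]))
        wa = window_amplitudes(ep)
        # component spans the whole post-onset window: all phases equal 4
        for phase in PHASES:
            vals = wa[wa["phase"] == phase]["amplitude"]
            np.testing.assert_allclose(vals, 4.0, atol=1e-12)

    def test_window_means_match_direct_arithmetic(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(8, 4000))
        ep = epoch_and_baseline(eeg_from(data), onsets_frame([2.0, 4.0]))
        wa = window_amplitudes(ep)
        t_ms = ep.times * 1000
        m = (t_ms >= 300) & (t_ms < 450)
        expected = ep.data[:, 2, m].mean()
        got = wa.query("phase == 'phase2a' and electrode == 'Pz'")[
            "amplitude"].iloc[0]
        assert got == pytest.approx(expected)

    def test_negativity_confined_to_phase2b(self):
        rate, n = 500.0, 30000
        data = np.zeros((8, n))
        onsets, types = [], []
        for i in range(10):
            onset = 2.0 + 2.4 * i
            cond = "incorrect" if i % 2 else "correct"
            if cond == "incorrect":
                i0 = round((onset + 0.450) * rate)
                i1 = round((onset + 0.600) * rate)
                data[:5, i0:i1] += -6.0
            onsets.append(onset)
            types.append(cond)
        ep = epoch_and_baseline(eeg_from(data), onsets_frame(onsets, types))
        wa = window_amplitudes(ep)
        piv = wa.pivot_table(index="phase", columns="condition",
                             values="amplitude")
        diff = piv["incorrect"] - piv["correct"]
        assert diff["phase2b"] == pytest.approx(-6.0)
        for phase in ("phase1", "phase2a", "phase3"):
            assert diff[phase] == pytest.approx(0.0, abs=1e-12)

    def test_empty_condition_flagged_missing(self):
        ep = epoch_and_baseline(eeg_from(n=4000), onsets_frame([2.0]))
        ep.rejected[:] = True
        wa = window_amplitudes(ep)
        assert wa["missing"].all()


class TestGGEpsilon:
    def test_two_levels_epsilon_is_one(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert gg_epsilon(S) == 1.0

    def test_compound_symmetry_epsilon_is_one(self):
        k = 5
        S = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(40, 6))
        S = np.cov(A.T)
        k = 6
        # independent oracle: the eigenvalue form on the double-centered
        # covariance: (sum lam)^2 / ((k-1) * sum lam^2)
        P = np.eye(k) - np.ones((k, k)) / k
        lam = np.linalg.eigvalsh(P @ S @ P)
        expected = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
        assert gg_epsilon(S) == pytest.approx(expected, rel=1e-10)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        data = rng.normal(size=(25, 4)) @ np.diag([1.0, 1.5, 0.5, 2.0])
        df = pd.DataFrame(data, columns=list("abcd"))
        expected = pg.epsilon(df, correction="gg")
        assert gg_epsilon(np.cov(data.T)) == pytest.approx(expected,
                                                           rel=1e-6)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.array([[1.0]]))


def anova_fixture():
    """8 subjects x 2 sexes x (2 conditions x 3 electrodes)."""
    rng = np.random.default_rng(42)
    rows = []
    for s in range(8):
        sex = "boy" if s < 5 else "girl"
        for ci, cond in enumerate(["correct", "incorrect"]):
            for ei, el in enumerate(["Fz", "Cz", "Pz"]):
                amp = (rng.normal(0, 1) + 0.5 * ci + 0.3 * ei
                       + (0.8 * ci if sex == "girl" else 0))
                rows.append((f"S{s}", sex, cond, el, round(amp, 6)))
    return pd.DataFrame(rows, columns=["subject", "sex", "condition",
                                       "electrode", "amplitude"])


class TestMixedAnova:
    # oracle values from an independent multivariate-model split-plot
    # decomposition (R car::Anova, type III, univariate table with GG)
    ORACLE = {
        "sex": (13.5303, 1.0, 0.010351),
        "condition": (19.2349, 1.0, 0.004639),
        "sex*condition": (10.3807, 1.0, 0.018094),
        "electrode": (1.6458, 0.6447906, 0.2448338),
        "sex*electrode": (0.0384, 0.6447906, 0.9016398),
        "condition*electrode": (1.6171, 0.5191623, 0.2505395),
        "sex*condition*electrode": (0.8361, 0.5191623, 0.3992113),
    }

    def test_matches_independent_split_plot_oracle(self):
        res = mixed_anova(anova_fixture()).set_index("effect")
        for effect, (F, eps, p) in self.ORACLE.items():
            row = res.loc[effect]
            assert row["F"] == pytest.approx(F, abs=2e-4), effect
            assert row["epsilon"] == pytest.approx(eps, abs=1e-6), effect
            assert row["p_gg"] == pytest.approx(p, abs=2e-6), effect

    def test_all_equal_amplitudes_give_zero_F(self):
        df = anova_fixture()
        df["amplitude"] = 1.0
        res = mixed_anova(df)
        assert (res["F"] == 0.0).all()

    def test_partial_eta_squared_in_unit_interval(self):
        res = mixed_anova(anova_fixture())
        assert res["partial_eta_sq"].between(0, 1).all()

    def test_planted_interaction_detected_at_large_n(self):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(60):
            sex = "boy" if s < 30 else "girl"
            for ci, cond in enumerate(["correct", "incorrect"]):
                for el in ["Fz", "Cz", "Pz", "F5", "F6"]:
                    amp = rng.normal(0, 1.0)
                    if sex == "boy" and cond == "incorrect":
                        amp -= 1.5
                    rows.append((f"S{s}", sex, cond, el, amp))
        df = pd.DataFrame(rows, columns=["subject", "sex", "condition",
                                         "electrode", "amplitude"])
        res = mixed_anova(df).set_index("effect")
        assert res.loc["sex*condition", "p_gg"] < 0.001

    def test_missing_cell_names_subject(self):
        df = anova_fixture()
        df = df[~((df["subject"] == "S3") & (df["electrode"] == "Pz"))]
        with pytest.raises(ValueError, match="S3"):
            mixed_anova(df)

    def test_posthoc_paired_contrast(self):
        df = anova_fixture()
        ph = posthoc_grammaticality(df).set_index("sex")
        sub = (df.groupby(["subject", "sex", "condition"])["amplitude"]
               .mean().reset_index())
        for sex in ("boy", "girl"):
            w = sub[sub["sex"] == sex].pivot(index="subject",
                                             columns="condition",
                                             values="amplitude")
            expected = (w["incorrect"] - w["correct"]).mean()
            assert ph.loc[sex, "mean_diff"] == pytest.approx(expected)


class TestPipelineLinearity:
    def test_conditioning_chain_is_homogeneous(self):
        rng = np.random.default_rng(8)
        data = rng.normal(0, 10, size=(8, 6000))

        def chain(d):
            eeg = eeg_from(d.copy())
            eeg = lowpass_zero_phase(eog_correct(rereference(eeg)))
            ep = epoch_and_baseline(eeg, onsets_frame([3.0, 6.0]))
            return ep.data

        a = chain(3.0 * data)
        b = 3.0 * chain(data)
        np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)
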