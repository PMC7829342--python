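"""Signal processing: filtering, baseline correction, SCP amplitude,
artifact rejection, multitaper PSD, aggregation and extreme-value removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpflow.epochs import Epoch, EpochSet
from scpflow.features import (DEFAULT_BANDS, BandDefinition, aggregate_cells,
                              band_average, bandpass_filter, baseline_correct,
                              multitaper_psd, reject_artifacts, remove_extremes,
                              scp_amplitude, tukey_fences)
from scpflow.study import ValidationError

RATE = 128.0
T10 = np.arange(0, 10, 1 / RATE)


def _fft_amplitude(x, freq):
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), 1 / RATE)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestBandpassFilter:
    def test_zero_in_zero_out(self):
        out = bandpass_filter(np.zeros(1280), RATE, 0.01, 2.0)
        np.testing.assert_array_equal(out, np.zeros(1280))

    def test_passband_tone_preserved_within_1db(self):
        x = np.sin(2 * np.pi * 1.0 * T10)
        y = bandpass_filter(x, RATE, 0.01, 2.0)
        ratio = _fft_amplitude(y, 1.0) / _fft_amplitude(x, 1.0)
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_stopband_tone_attenuated_40db(self):
        x = np.sin(2 * np.pi * 20.0 * T10)
        y = bandpass_filter(x, RATE, 0.01, 2.0)
        ratio = _fft_amplitude(y, 20.0) / _fft_amplitude(x, 20.0)
        assert 20 * np.log10(ratio) < -40.0

    def test_psd_path_keeps_30hz(self):
        x = np.sin(2 * np.pi * 30.0 * T10)
        y = bandpass_filter(x, RATE, 0.01, 40.0)
        ratio = _fft_amplitude(y, 30.0) / _fft_amplitude(x, 30.0)
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_straight_line_passes_unchanged(self):
        line = -0.7 * T10
        out = bandpass_filter(line, RATE, 0.01, 2.0)
        np.testing.assert_allclose(out, line - line.mean(), atol=1e-10)

    def test_short_signal_error_names_minimum(self):
        with pytest.raises(ValidationError, match="minimum"):
            bandpass_filter(np.zeros(50), RATE, 0.01, 2.0)

    def test_invalid_edges(self):
        with pytest.raises(ValidationError):
            bandpass_filter(np.zeros(1280), RATE, 2.0, 1.0)


def _epoch(baseline, trial):
    return Epoch(participant="p", session=1, condition="feedback1",
                 task="negativity", baseline=np.asarray(baseline, float),
                 trial=np.asarray(trial, float), sampling_rate=RATE)


class TestBaselineCorrect:
    def test_constant_epoch_becomes_zero(self):
        e = baseline_correct(_epoch(np.full(256, 3.0), np.full(1024, 3.0)))
        assert np.all(e.baseline == 0) and np.all(e.trial == 0)

    def test_idempotent_on_centered_baseline(self):
        base = np.concatenate([np.ones(128), -np.ones(128)])
        trial = np.linspace(0, 1, 1024)
        e = baseline_correct(_epoch(base, trial))
        np.testing.assert_array_equal(e.trial, trial)

    def test_hand_arithmetic(self):
        e = baseline_correct(_epoch(np.full(256, 2.5), np.full(1024, 4.0)))
        np.testing.assert_allclose(e.trial, 1.5)
        assert e.baseline.mean() == 0.0

    def test_empty_window_error(self):
        with pytest.raises(ValidationError):
            baseline_correct(_epoch(np.array([]), np.ones(1024)))


class TestSCPAmplitude:
    def test_zero_trial(self):
        assert scp_amplitude(_epoch(np.zeros(256), np.zeros(1024))) == 0.0

    def test_linear_ramp_closed_form(self):
        # ramp 0 -> -8 uV over [0, 8) s: mean over the last 4 s on the
        # sample grid is -6 + half-sample correction (slope / (2 rate))
        t = np.arange(1024) / RATE
        amp = scp_amplitude(_epoch(np.zeros(256), -1.0 * t))
        assert amp == pytest.approx(-6.0 + 1.0 / (2 * RATE), abs=1e-12)

    def test_windowing_forced(self):
        trial = np.concatenate([np.full(512, 1.0), np.full(512, 3.0)])
        assert scp_amplitude(_epoch(np.zeros(256), trial)) == 3.0

    def test_wrong_length_error(self):
        with pytest.raises(ValidationError):
            scp_amplitude(np.zeros(1000), rate=RATE)


def _epoch_set(trials, participant="p", session=1):
    n = len(trials)
    meta = pd.DataFrame({
        "participant": [participant] * n, "session": [session] * n,
        "condition": ["feedback1"] * n, "task": ["negativity"] * n})
    return EpochSet(baseline=np.zeros((n, 256)), trial=np.asarray(trials, float),
                    meta=meta, sampling_rate=RATE)


def _spike_trial(p2p):
    t = np.zeros(1024)
    t[100] = p2p / 2
    t[101] = -p2p / 2
    return t


class TestArtifactRejection:
    def test_identical_epochs_none_rejected(self):
        eset = _epoch_set([_spike_trial(20.0)] * 10)
        kept, log = reject_artifacts(eset)
        assert len(kept) == 10
        assert log.n_rejected == 0

    def test_single_transient_rejected(self):
        rng = np.random.default_rng(1)
        trials = [_spike_trial(20.0 + rng.normal(0, 0.5)) for _ in range(99)]
        trials.append(_spike_trial(200.0))
        kept, log = reject_artifacts(_epoch_set(trials))
        assert len(kept) == 99
        # brute-force fence check: the rejected epoch is the transient
        p2p = np.array([t.max() - t.min() for t in trials])
        q1, q3 = np.quantile(p2p, [0.25, 0.75])
        assert p2p.max() > q3 + 1.5 * (q3 - q1)
        assert kept.trial.max() < 150.0

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(3)
        trials = np.array([_spike_trial(15 + 5 * rng.random()) for _ in range(20)])
        kept1, _ = reject_artifacts(_epoch_set(trials))
        kept2, _ = reject_artifacts(_epoch_set(trials * scale))
        pd.testing.assert_frame_equal(kept1.meta, kept2.meta)

    def test_small_group_error(self):
        with pytest.raises(ValidationError, match="at least 8"):
            reject_artifacts(_epoch_set([_spike_trial(20.0)] * 5))

    def test_rejection_never_alters_surviving_values(self):
        rng = np.random.default_rng(4)
        trials = [rng.normal(0, 5, 1024) for _ in range(20)]
        trials.append(_spike_trial(500.0))
        eset = _epoch_set(trials)
        kept, _ = reject_artifacts(eset)
        surviving = {tuple(np.round(row[:5], 9)) for row in kept.trial}
        original = {tuple(np.round(row[:5], 9)) for row in eset.trial}
        assert surviving <= original


class TestMultitaperPSD:
    def test_zero_signal_zero_psd(self):
        freqs, psd = multitaper_psd(np.zeros(512), RATE)
        assert np.all(psd == 0)
        assert freqs[0] == 0 and freqs[-1] == pytest.approx(RATE / 2)

    def test_sinusoid_concentrates_in_alpha(self):
        x = np.sin(2 * np.pi * 10.0 * np.arange(512) / RATE)
        freqs, psd = multitaper_psd(x, RATE)
        mask = (freqs >= 8) & (freqs <= 12)
        assert psd[mask].sum() / psd.sum() >= 0.90

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((500, 512))
        freqs, psd = multitaper_psd(x, RATE)
        mean_psd = psd.mean(axis=0)
        band = (freqs >= 5) & (freqs <= 30)
        levels = mean_psd[band]
        assert levels.max() / levels.min() < 1.10

    def test_variance_partition(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(512)
        freqs, psd = multitaper_psd(x, RATE)
        integral = np.trapezoid(psd, freqs)
        assert abs(integral / x.var() - 1.0) < 0.10

    def test_window_too_short_error(self):
        with pytest.raises(ValidationError):
            multitaper_psd(np.zeros(8), RATE, half_bandwidth=4)


class TestBandAverage:
    def test_constant_psd(self):
        freqs = np.linspace(0, 64, 257)
        for band in DEFAULT_BANDS:
            assert band_average(freqs, np.full(257, 3.5), band) == 3.5

    def test_single_bin_at_10hz(self):
        freqs = np.linspace(0, 64, 257)
        psd = np.zeros(257)
        psd[np.argmin(np.abs(freqs - 10.0))] = 7.0
        delta, theta, alpha = DEFAULT_BANDS
        assert band_average(freqs, psd, alpha) > 0
        assert band_average(freqs, psd, delta) == 0
        assert band_average(freqs, psd, theta) == 0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        freqs = np.fft.rfftfreq(512, 1 / RATE)
        psd = rng.random(freqs.size)
        for band in DEFAULT_BANDS:
            acc, n = 0.0, 0
            for f, v in zip(freqs, psd):
                inside = (f >= band.low) and (
                    f <= band.high if band.include_upper else f < band.high)
                if inside:
                    acc += v
                    n += 1
            assert band_average(freqs, psd, band) == pytest.approx(acc / n, rel=1e-12)

    def test_empty_band_error(self):
        freqs = np.array([0.0, 32.0, 64.0])
        with pytest.raises(ValidationError):
            band_average(freqs, np.ones(3), BandDefinition("delta", 0.5, 4.0))


class TestAggregation:
    def _values(self, vals, **keys):
        n = len(vals)
        base = {"participant": "p", "session": 1, "condition": "feedback1",
                "task": "negativity", "outcome_name": "scp_amplitude_uv"}
        base.update(keys)
        df = pd.DataFrame({k: [v] * n for k, v in base.items()})
        df["value"] = vals
        return df

    def test_single_epoch_passthrough(self):
        out = aggregate_cells(self._values([4.2]))
        assert out["value"].iloc[0] == 4.2
        assert out["n_epochs_aggregated"].iloc[0] == 1

    def test_simple_mean(self):
        out = aggregate_cells(self._values([-2.0, -4.0]))
        assert out["value"].iloc[0] == -3.0

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(5)
        frames = []
        for p in "ab":
            for t in ("negativity", "positivity"):
                frames.append(self._values(rng.normal(size=7), participant=p, task=t))
        df = pd.concat(frames, ignore_index=True)
        out = aggregate_cells(df).set_index(["participant", "task"])["value"]
        oracle = df.groupby(["participant", "task"])["value"].mean()
        for key, val in oracle.items():
            assert out.loc[key] == pytest.approx(val, rel=1e-12)

    def test_missing_cells_explicit_with_full_grid(self):
        grid = pd.concat([self._values([0.0]),
                          self._values([0.0], session=2)]).drop(columns="value")
        out = aggregate_cells(self._values([1.0]), full_grid=grid.reset_index(drop=True))
        assert len(out) == 2
        assert out["value"].isna().sum() == 1
        assert (out["n_epochs_aggregated"] == 0).sum() == 1


class TestRemoveExtremes:
    def _table(self, vals):
        return pd.DataFrame({
            "participant": [f"p{i}" for i in range(len(vals))],
            "session": 1, "condition": "feedback1", "task": "negativity",
            "outcome_name": "scp_amplitude_uv", "value": vals,
            "n_epochs_aggregated": 1, "outlier_flag": False})

    def test_gaussian_flag_rate_small(self):
        rng = np.random.default_rng(6)
        rates = []
        for _ in range(50):
            out = remove_extremes(self._table(rng.normal(size=200)))
            rates.append(out["outlier_flag"].mean())
        assert np.mean(rates) < 0.03
        assert max(rates) < 0.05

    def test_single_large_value_flagged(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95, 10.0]
        out = remove_extremes(self._table(vals))
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert 10.0 > q3 + 1.5 * (q3 - q1)  # brute-force fence confirms
        assert out["outlier_flag"].tolist() == [False] * 5 + [True]

    def test_all_equal_none_flagged(self):
        out = remove_extremes(self._table([2.0] * 10))
        assert not out["outlier_flag"].any()

    def test_values_never_altered(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        out = remove_extremes(self._table(vals))
        np.testing.assert_array_equal(out["value"], vals)

    def test_too_few_values_error(self):
        with pytest.raises(ValidationError):
            remove_extremes(self._table([1.0, 2.0, 3.0]))


class TestTukeyFences:
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=50),
           st.floats(0.5, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force(self, values, mult):
        lo, hi = tukey_fences(np.array(values), mult)
        q1, q3 = np.quantile(values, [0.25, 0.75])
        assert lo == pytest.approx(q1 - mult * (q3 - q1), abs=1e-9)
        assert hi == pytest.approx(q3 + mult * (q3 - q1), abs=1e-9)


class TestPipelineDeterminism:
    def test_identical_epochs_identical_table(self, small_design, small_truth):
        from scpflow.features import SCPFeatureExtractor
        from scpflow.simulate import simulate_epochs

        eset = simulate_epochs(small_design, small_truth, seed=3,
                               n_participants=2, sessions=[1, 2])
        t1 = SCPFeatureExtractor().transform(eset)
        t2 = SCPFeatureExtractor().transform(eset)
        pd.testing.assert_frame_equal(t1, t2)
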