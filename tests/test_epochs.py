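"""Epoching, averaging, objective criteria and stress-analysis binning."""

import numpy as np
import pytest

import hisbeat as hb


@pytest.fixture(scope="module")
def zero_jitter_series():
    cfg = hb.SimConfig(snr_db=20.0, seed=4)
    series, sgt = hb.simulate_beat_series(cfg, n_beats=200, rr_ms=750.0)
    return cfg, series, sgt


class TestDetectQrsOnsets:
    def test_recovers_all_onsets_within_5ms(self, zero_jitter_series):
        cfg, series, sgt = zero_jitter_series
        onsets = hb.detect_qrs_onsets(series)
        assert len(onsets) == len(sgt.qrs_onsets) == 200
        err_ms = (onsets - sgt.qrs_onsets) / cfg.fs * 1000.0
        assert np.abs(err_ms).max() <= 5.0

    def test_jittered_multichannel_recovery(self):
        cfg = hb.SimConfig(snr_db=20.0, seed=9)
        series, sgt = hb.simulate_beat_series(
            cfg, n_beats=50, rr_ms=800.0, rr_jitter_ms=40.0, multichannel=4
        )
        onsets = hb.detect_qrs_onsets(series, 2)
        assert len(onsets) == 50
        assert np.abs(onsets - sgt.qrs_onsets).max() <= 5

    def test_flat_series_raises(self):
        flat = hb.BeatSeries(np.zeros((1, 3000)), 1000.0)
        with pytest.raises(ValueError, match="no beats"):
            hb.detect_qrs_onsets(flat)

    def test_single_beat(self):
        cfg = hb.SimConfig(snr_db=np.inf)
        series, _ = hb.simulate_beat_series(cfg, n_beats=1, rr_ms=800.0)
        assert len(hb.detect_qrs_onsets(series)) == 1


class TestExtractPrEpochs:
    def test_window_arithmetic(self, zero_jitter_series):
        cfg, series, sgt = zero_jitter_series
        stack = hb.extract_pr_epochs(series, sgt.qrs_onsets, 0, 350.0)
        assert stack.m == 200
        assert stack.n_samples == 350
        assert stack.qrs_onset_idx == 350

    def test_early_beat_dropped(self, zero_jitter_series):
        _, series, sgt = zero_jitter_series
        onsets = np.concatenate([[100], sgt.qrs_onsets])
        with pytest.warns(UserWarning, match="dropped 1"):
            stack = hb.extract_pr_epochs(series, onsets, 0, 350.0)
        assert stack.m == 200  # the synthetic early beat was discarded

    def test_rows_bit_equal_series_slices(self, zero_jitter_series):
        _, series, sgt = zero_jitter_series
        stack = hb.extract_pr_epochs(series, sgt.qrs_onsets, 0, 350.0)
        trace = series.channel(0).samples
        for row, onset in zip(stack.epochs[:5], sgt.qrs_onsets[:5]):
            np.testing.assert_array_equal(row, trace[onset - 350 : onset])

    def test_all_dropped_is_error(self, zero_jitter_series):
        _, series, _ = zero_jitter_series
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            hb.extract_pr_epochs(series, np.array([10, 20]), 0, 350.0)


class TestSignalAverage:
    def test_identical_rows(self):
        row = np.sin(np.arange(100) / 7.0)
        stack = hb.EpochStack(np.tile(row, (8, 1)), 1000.0, 100)
        np.testing.assert_allclose(hb.signal_average(stack).samples, row)

    def test_noise_shrinks_as_sqrt_m(self):
        rng = np.random.default_rng(0)
        sds = []
        for _ in range(20):
            stack = hb.EpochStack(rng.standard_normal((200, 300)), 1000.0, 300)
            sds.append(hb.signal_average(stack).samples.std())
        assert np.mean(sds) == pytest.approx(1.0 / np.sqrt(200), rel=0.2)

    def test_single_epoch(self):
        row = np.arange(50, dtype=float)
        stack = hb.EpochStack(row[None, :], 1000.0, 50)
        np.testing.assert_array_equal(hb.signal_average(stack).samples, row)

    def test_zero_jitter_average_recovers_clean_epoch(self, zero_jitter_series):
        cfg, series, sgt = zero_jitter_series
        stack = hb.extract_pr_epochs(series, sgt.qrs_onsets, 0, 350.0)
        avg = hb.signal_average(stack).samples
        clean = sgt.epoch_truths[0].clean_epoch
        resid_sd = (avg - clean).std()
        assert resid_sd < 3 * cfg.noise_rms / np.sqrt(stack.m)


def _annotated_channels(n_channels: int):
    """Per-channel templates from a noiseless multichannel simulation."""
    cfg = hb.SimConfig(snr_db=30.0, seed=6)
    series, sgt = hb.simulate_beat_series(
        cfg, n_beats=40, rr_ms=800.0, multichannel=n_channels
    )
    templates = []
    for c in range(n_channels):
        stack = hb.extract_pr_epochs(series, sgt.qrs_onsets, c, 350.0)
        gt = sgt.epoch_truths[0]
        onset_ms = gt.hbs_onset_idx  # 1 kHz: sample index == ms
        templates.append(
            hb.TemplateAnnotation(
                avg_trace=hb.signal_average(stack).samples,
                fs=cfg.fs,
                t1_ms=onset_ms - 8.0,
                t2_ms=onset_ms + 14.0,
                hbs_onset_ms=float(onset_ms),
            )
        )
    return templates


class TestHbsCriteria:
    def test_multichannel_simulation_meets_all_criteria(self):
        report = hb.check_hbs_criteria(_annotated_channels(8))
        assert report.criterion1_above_noise
        assert report.criterion2_after_p_offset
        assert report.criterion3_ramps_both_sides
        assert report.criterion4_polarity_reversal is True

    def test_single_channel_criterion4_not_evaluable(self):
        report = hb.check_hbs_criteria(_annotated_channels(1))
        assert report.criterion4_polarity_reversal is None

    def test_bump_below_noise_floor_fails_criterion1(self):
        rng = np.random.default_rng(2)
        trace = rng.normal(scale=1.0, size=350)  # noise everywhere, no bump
        ann = hb.TemplateAnnotation(
            avg_trace=trace, fs=1000.0, t1_ms=280.0, t2_ms=310.0,
            hbs_onset_ms=290.0,
        )
        # bump ptp within the window is ~ noise ptp, below 2x RMS * margin?
        # force it: flatten the candidate window to a tiny residue
        trace[280:310] = 0.01 * trace[280:310]
        report = hb.check_hbs_criteria([ann])
        assert not report.criterion1_above_noise


class TestBinning:
    def test_180_beats_make_six_bins_of_30(self):
        stack = hb.EpochStack(np.zeros((180, 50)), 1000.0, 50)
        bins = hb.bin_epochs(stack, 30)
        assert len(bins) == 6
        assert all(b.m == 30 for b in bins)

    def test_trailing_partial_bin_dropped(self):
        stack = hb.EpochStack(np.zeros((200, 50)), 1000.0, 50)
        with pytest.warns(UserWarning, match="20"):
            bins = hb.bin_epochs(stack, 30)
        assert len(bins) == 6

    def test_too_few_beats_yield_no_bins(self):
        stack = hb.EpochStack(np.zeros((10, 50)), 1000.0, 50)
        with pytest.warns(UserWarning):
            assert hb.bin_epochs(stack, 30) == []

    def test_bins_partition_in_order(self):
        rows = np.arange(90, dtype=float)[:, None] * np.ones((90, 5))
        stack = hb.EpochStack(rows, 1000.0, 5)
        bins = hb.bin_epochs(stack, 30)
        rebuilt = np.vstack([b.epochs for b in bins])
        np.testing.assert_array_equal(rebuilt, rows)
        idx = np.concatenate([b.beat_indices for b in bins])
        np.testing.assert_array_equal(idx, np.arange(90))

    def test_bad_bin_size_rejected(self):
        stack = hb.EpochStack(np.zeros((10, 5)), 1000.0, 5)
        with pytest.raises(ValueError):
            hb.bin_epochs(stack, 0)


class TestHeartRate:
    @pytest.mark.parametrize("rr_ms, bpm", [(750, 80.0), (500, 120.0)])
    def test_known_rates(self, rr_ms, bpm):
        onsets = np.arange(10) * rr_ms  # fs = 1000 -> samples == ms
        np.testing.assert_allclose(hb.heart_rate_series(onsets, 1000.0), bpm)

    def test_constant_rr_constant_series(self):
        hr = hb.heart_rate_series(np.arange(5) * 612, 1000.0)
        assert np.ptp(hr) == 0.0

    def test_too_few_onsets_rejected(self):
        with pytest.raises(ValueError):
            hb.heart_rate_series(np.array([100]), 1000.0)
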