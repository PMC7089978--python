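"""Photon data model, I/O round trips, binning and histogramming."""

import numpy as np
import pytest

from zmwfcs.photon_data import (
    IRFModel,
    PhotonDataError,
    TCSPCHistogram,
    TTTRTrace,
    bin_intensity,
    build_tcspc_histogram,
    read_histogram_csv,
    read_photon_file,
    write_histogram_csv,
    write_photon_file,
)


class TestTTTRTraceValidation:
    def test_non_monotonic_macrotimes_rejected(self):
        with pytest.raises(PhotonDataError, match="non-decreasing"):
            TTTRTrace([0, 5, 3], [0, 0, 0], [0, 0, 0])

    def test_microtime_outside_sync_period_rejected(self):
        with pytest.raises(PhotonDataError, match="microtime"):
            TTTRTrace([0, 1], [0, 26_000], [0, 0], sync_rate=40e6)

    def test_duration_covers_last_photon(self):
        with pytest.raises(PhotonDataError, match="duration"):
            TTTRTrace([0, 4_000_000], [0, 0], [0, 0], sync_rate=40e6, duration=0.05)

    def test_empty_trace_valid(self):
        t = TTTRTrace([], [], [])
        assert t.n_photons == 0 and t.duration == 0.0


class TestPhotonFileIO:
    @pytest.mark.parametrize("fmt,suffix", [("text", ".txt"), ("hdf5", ".h5")])
    def test_round_trip_lossless(self, tmp_path, small_trace, fmt, suffix):
        path = tmp_path / f"trace{suffix}"
        write_photon_file(small_trace, path)
        back = read_photon_file(path)
        np.testing.assert_array_equal(back.macrotimes, small_trace.macrotimes)
        np.testing.assert_array_equal(back.microtimes, small_trace.microtimes)
        np.testing.assert_array_equal(back.channels, small_trace.channels)
        assert back.sync_rate == small_trace.sync_rate
        assert back.duration == pytest.approx(small_trace.duration)
        assert back.metadata == small_trace.metadata

    def test_empty_container_reads_back_empty(self, tmp_path):
        path = tmp_path / "empty.txt"
        write_photon_file(TTTRTrace([], [], []), path)
        assert read_photon_file(path).n_photons == 0

    def test_hand_written_text_records(self, tmp_path):
        # five hand-written records: parsed field by field, in order
        body = "\n".join(
            [
                "# sync_rate_hz=40000000",
                "3\t120\t0",
                "17\t4500\t1",
                "17\t24999\t0",
                "250\t0\t1",
                "1000\t12345\t0",
            ]
        )
        path = tmp_path / "hand.txt"
        path.write_text(body + "\n")
        t = read_photon_file(path)
        assert t.n_photons == 5
        np.testing.assert_array_equal(t.macrotimes, [3, 17, 17, 250, 1000])
        np.testing.assert_array_equal(t.microtimes, [120, 4500, 24999, 0, 12345])
        np.testing.assert_array_equal(t.channels, [0, 1, 0, 1, 0])

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# sync_rate_hz=40000000\n1\t2\t0\nnot-a-record\n")
        with pytest.raises(PhotonDataError, match="line 3"):
            read_photon_file(path)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_photon_file("/nonexistent/path.txt")


class TestBinIntensity:
    def test_no_photons_all_zero(self):
        out = bin_intensity(TTTRTrace([], [], []), 1e-3)
        assert out.total_counts == 0

    def test_degenerate_clustering_first_bin(self):
        t = TTTRTrace(np.arange(10), np.zeros(10), np.zeros(10), sync_rate=40e6)
        out = bin_intensity(t, 1e-3)
        assert out.counts[0] == 10 and out.counts[1:].sum() == 0

    def test_matches_brute_force_histogram(self, rng):
        times = np.sort(rng.uniform(0, 1.0, 10_000))
        macro = (times * 40e6).astype(np.int64)
        t = TTTRTrace(macro, np.zeros(len(macro)), np.zeros(len(macro)), duration=1.0)
        out = bin_intensity(t, 1e-3)
        # O(N * bins) direct count
        arrival = macro / 40e6
        brute = np.array(
            [((arrival >= k * 1e-3) & (arrival < (k + 1) * 1e-3)).sum() for k in range(out.n_bins)]
        )
        np.testing.assert_array_equal(out.counts, brute)
        assert out.total_counts == 10_000

    def test_bad_bin_width(self, small_trace):
        with pytest.raises(ValueError):
            bin_intensity(small_trace, 0.0)

    def test_conserves_counts(self, small_trace):
        for bw in (1e-4, 3.7e-3, 0.5):
            assert bin_intensity(small_trace, bw).total_counts == small_trace.n_photons


class TestTCSPCHistogram:
    def test_empty_histogram(self):
        h = build_tcspc_histogram(TTTRTrace([], [], []), 16.0)
        assert h.total_photons == 0
        # channel span covers one sync period
        assert h.n_channels * h.channel_width >= 25_000

    def test_identical_microtimes_single_channel(self):
        t = TTTRTrace(np.arange(50), np.full(50, 4321), np.zeros(50))
        h = build_tcspc_histogram(t, 16.0)
        assert h.counts[4321 // 16] == 50 and h.total_photons == 50

    def test_exponential_microtimes_brute_force_and_mle(self, rng):
        tau_ps = 4000.0
        n = 10_000
        micro = rng.exponential(tau_ps, n)
        micro = micro[micro < 25_000].astype(np.int64)
        t = TTTRTrace(np.arange(len(micro)), micro, np.zeros(len(micro)))
        h = build_tcspc_histogram(t, 16.0)
        brute = np.bincount(micro // 16, minlength=h.n_channels)
        np.testing.assert_array_equal(h.counts, brute)
        # censored-sample MLE of the exponential mean, within 3 sigma
        frac = 1 - np.exp(-25_000 / tau_ps)  # kept fraction, truncation correction small
        mle = micro.mean()
        expected = tau_ps - 25_000 * (1 - frac) / frac
        assert abs(mle - expected) < 3 * tau_ps / np.sqrt(len(micro))

    def test_bad_channel_width(self, small_trace):
        with pytest.raises(ValueError):
            build_tcspc_histogram(small_trace, -1.0)


class TestIRFModel:
    def test_gaussian_normalizes(self):
        irf = IRFModel(fwhm_ps=110.0, center_ps=2500.0)
        k = irf.discretize(16.0, 1563)
        assert k.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(k) == pytest.approx(2500 / 16, abs=2)

    def test_histogram_irf_normalizes_and_resamples(self):
        counts = np.zeros(1563, np.int64)
        counts[150:160] = 100
        irf = IRFModel(histogram=TCSPCHistogram(16.0, counts))
        k16 = irf.discretize(16.0, 1563)
        k32 = irf.discretize(32.0, 782)
        assert k16.sum() == pytest.approx(1.0)
        assert k32.sum() == pytest.approx(1.0)

    def test_exactly_one_representation(self):
        with pytest.raises(PhotonDataError):
            IRFModel()


def test_histogram_csv_round_trip(tmp_path, rng):
    h = TCSPCHistogram(16.0, rng.integers(0, 100, 1563))
    path = tmp_path / "hist.csv"
    write_histogram_csv(h, path)
    back = read_histogram_csv(path)
    assert back.channel_width == pytest.approx(16.0)
    np.testing.assert_array_equal(back.counts, h.counts)
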