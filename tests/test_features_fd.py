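import numpy as np
import pytest

from thermoseg import (band_average, extract_fd_table, generate_video,
                       make_band_layout, make_reference, wavelet_coherence)
from thermoseg.features.fd import WaveletCoherenceFeaturizer, _coi_seconds


class TestBandLayout:
    def test_sixty_contiguous_bands_cover_range(self):
        bands = make_band_layout()
        assert bands.n_bands == 60
        assert bands.f_low[0] == pytest.approx(0.015)
        assert bands.f_high[-1] == pytest.approx(2.0)
        assert np.allclose(bands.f_high[:-1], bands.f_low[1:])

    def test_band_of_cardiac_frequency(self):
        bands = make_band_layout()
        k = bands.band_of(0.71)
        assert bands.f_low[k] <= 0.71 < bands.f_high[k]
        assert 0.4 <= bands.f_low[k] and bands.f_high[k] <= 2.0

    def test_linear_spacing_option(self):
        bands = make_band_layout(spacing="linear")
        widths = bands.f_high - bands.f_low
        assert np.allclose(widths, widths[0])


class TestWaveletCoherence:
    def test_self_coherence_is_one_everywhere(self, rng):
        x = rng.standard_normal(600)
        coh, bands = wavelet_coherence(x, x, fs=5.0)
        assert np.nanmax(np.abs(coh - 1.0)) < 1e-6
        assert coh.shape == (bands.n_bands, 600)

    def test_symmetry(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        cxy, _ = wavelet_coherence(x, y, fs=5.0)
        cyx, _ = wavelet_coherence(y, x, fs=5.0)
        assert np.nanmax(np.abs(cxy - cyx)) < 1e-9

    def test_affine_rescaling_invariance(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        c1, _ = wavelet_coherence(x, y, fs=5.0)
        c2, _ = wavelet_coherence(3.0 * x + 2.0, y, fs=5.0)
        assert np.nanmax(np.abs(c1 - c2)) < 1e-6

    def test_independent_noise_coherence_below_half(self, rng):
        vals = []
        for _ in range(10):
            x = rng.standard_normal(900)
            y = rng.standard_normal(900)
            coh, _ = wavelet_coherence(x, y, fs=5.0)
            vals.append(np.nanmean(coh))
        assert np.mean(vals) < 0.5

    def test_shared_sine_peaks_at_its_band(self, rng):
        t = np.arange(900) / 5.0
        s = np.sin(2 * np.pi * 0.7 * t)
        x = s + 0.5 * rng.standard_normal(t.size)
        y = s + 0.5 * rng.standard_normal(t.size)
        coh, bands = wavelet_coherence(x, y, fs=5.0)
        band_mean = np.nanmean(coh, axis=1)
        k = bands.band_of(0.7)
        assert np.all(band_mean[k] > band_mean[bands.centers > 1.5])

    def test_bounded_on_random_pairs(self, rng):
        for _ in range(50):
            n = int(rng.integers(120, 400))
            coh, _ = wavelet_coherence(rng.standard_normal(n),
                                       rng.standard_normal(n), fs=5.0)
            valid = coh[np.isfinite(coh)]
            assert valid.size and valid.min() >= 0.0 and valid.max() <= 1.0

    def test_constant_trace_flagged_nan(self, rng):
        coh, _ = wavelet_coherence(np.full(300, 5.0),
                                   rng.standard_normal(300), fs=5.0)
        assert np.isnan(coh).all()

    def test_mismatched_lengths_raise(self, rng):
        with pytest.raises(ValueError):
            wavelet_coherence(rng.standard_normal(100),
                              rng.standard_normal(101), fs=5.0)


class TestBandAverage:
    def test_all_ones_map(self):
        bands = make_band_layout(n_bands=5, f_min=0.2, f_max=2.0)
        t = np.arange(300) / 5.0
        means, _ = band_average(np.ones((5, 300)), t, (0.0, 60.0), bands)
        assert np.allclose(means, 1.0)

    def test_window_split_map(self):
        bands = make_band_layout(n_bands=4, f_min=0.5, f_max=2.0)
        t = np.arange(600) / 5.0
        coh = np.where(t < 60.0, 1.0, 0.0)[None, :].repeat(4, axis=0)
        bl, _ = band_average(coh, t, (0.0, 60.0), bands)
        rec, _ = band_average(coh, t, (60.0, 120.0), bands)
        assert np.allclose(bl, 1.0) and np.allclose(rec, 0.0)

    def test_matches_loop_oracle(self, rng):
        bands = make_band_layout(n_bands=8, f_min=0.05, f_max=2.0)
        t = np.arange(500) / 5.0
        coh = rng.uniform(0, 1, size=(8, 500))
        window = (10.0, 70.0)
        means, reliable = band_average(coh, t, window, bands)
        for i in range(8):
            coi = _coi_seconds(bands.centers[i])
            vals = [coh[i, j] for j in range(500)
                    if window[0] <= t[j] < window[1]
                    and t[j] - t[0] >= coi and t[-1] - t[j] >= coi]
            if vals:
                assert means[i] == pytest.approx(np.mean(vals))
                assert reliable[i]
            else:
                sel = [coh[i, j] for j in range(500)
                       if window[0] <= t[j] < window[1]]
                assert means[i] == pytest.approx(np.mean(sel))
                assert not reliable[i]

    def test_empty_window_raises(self):
        bands = make_band_layout(n_bands=3, f_min=0.5, f_max=2.0)
        t = np.arange(100) / 5.0
        with pytest.raises(ValueError, match="window"):
            band_average(np.ones((3, 100)), t, (50.0, 60.0), bands)


class TestMakeReference:
    def test_fraction_one_is_tumor_mean(self, small_video_and_mask):
        video, mask = small_video_and_mask
        ref, chosen = make_reference(video, mask, fraction=1.0, seed=0)
        assert chosen.size == mask.sum()
        assert np.allclose(ref, video.traces()[mask.ravel()].mean(axis=0))

    def test_noiseless_reference_equals_single_pixel(self, noiseless_cfg):
        video, mask = generate_video(noiseless_cfg)
        ref, _ = make_reference(video, mask, fraction=0.3, seed=1)
        pixel = video.traces()[mask.ravel()][0]
        assert np.allclose(ref, pixel, atol=1e-4)

    def test_seed_changes_subset_not_statistics(self, small_video_and_mask):
        video, mask = small_video_and_mask
        r1, c1 = make_reference(video, mask, fraction=0.3, seed=1)
        r2, c2 = make_reference(video, mask, fraction=0.3, seed=2)
        assert not np.array_equal(c1, c2)
        rms = np.sqrt(np.mean((r1 - r2) ** 2))
        assert rms < 5.0 * video.meta["config"]["noise_sd"]

    def test_empty_mask_raises(self, small_video_and_mask):
        video, _ = small_video_and_mask
        with pytest.raises(ValueError, match="empty"):
            make_reference(video, np.zeros(video.frame_shape, bool))


class TestExtractFdTable:
    def test_bl_scope_has_sixty_feature_columns(self, small_video_and_mask):
        video, mask = small_video_and_mask
        table = extract_fd_table(video, mask, scope="bl", seed=0)
        cols = [c for c in table.columns if c.startswith("wcoh_")]
        assert len(cols) == 60
        assert all(c.startswith("wcoh_bl_") for c in cols)

    def test_values_bounded_and_reference_flagged(self, small_video_and_mask):
        video, mask = small_video_and_mask
        table = extract_fd_table(video, mask, scope="bl+rec", seed=0)
        cols = [c for c in table.columns if c.startswith("wcoh_")]
        assert len(cols) == 120
        vals = table[cols].to_numpy()
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0
        n_ref = int(np.ceil(0.2 * mask.sum()))
        assert table["in_reference"].sum() == n_ref
        assert (table.loc[table["in_reference"], "label"] == 1).all()

    def test_tumor_cardiac_coherence_exceeds_healthy(self, small_video_and_mask):
        video, mask = small_video_and_mask
        table = extract_fd_table(video, mask, scope="bl+rec", seed=0)
        bands = make_band_layout()
        k = bands.band_of(0.71)
        col = table[f"wcoh_rec_{k:02d}"]
        lab = table["label"]
        assert col[lab == 1].mean() > col[lab == 0].mean()

    def test_deterministic_under_seed(self, small_video_and_mask):
        video, mask = small_video_and_mask
        t1 = extract_fd_table(video, mask, scope="bl", seed=5)
        t2 = extract_fd_table(video, mask, scope="bl", seed=5)
        assert t1.equals(t2)


def test_featurizer_reference_rows_come_from_tumor(small_video_and_mask, rng):
    video, mask = small_video_and_mask
    traces = video.traces()
    labels = mask.ravel().astype(int)
    fz = WaveletCoherenceFeaturizer(video.timestamps, video.phases,
                                    scope="bl", fraction=0.5, seed=3)
    fz.fit(traces, labels)
    assert np.all(labels[fz.reference_rows_] == 1)
    assert fz.get_feature_names_out().shape == (60,)
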