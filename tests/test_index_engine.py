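"""Eco-acoustic index computation from audio."""

import numpy as np
import pandas as pd
import pytest

from soundflow import index_engine as ie
from soundflow.synthetic import gen_audio_segment

FS = 48000


def tone(freq, duration=1.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return ie.AudioSegment(amp * np.sin(2 * np.pi * freq * t), fs)


@pytest.fixture(scope="module")
def mixed_segment():
    """Chirps over low-frequency noise: exercises every index."""
    w = gen_audio_segment(1.5, 1.0, duration_s=5, seed=13)
    return ie.AudioSegment(w, FS)


# ---------------------------------------------------------------------------
# spectrogram
# ---------------------------------------------------------------------------

class TestSpectrogram:
    def test_pure_tone_has_single_dominant_bin(self):
        spec = ie.compute_spectrogram(tone(4000))
        peak_bins = spec.magnitudes.argmax(axis=0)
        assert np.all(np.abs(spec.freqs[peak_bins] - 4000) <= 94)

    def test_silence_gives_all_zero_matrix(self):
        seg = ie.AudioSegment(np.zeros(FS), FS)
        assert not ie.compute_spectrogram(seg).magnitudes.any()

    def test_parseval_energy_match_within_one_percent(self, rng):
        x = rng.normal(0, 0.1, 512 * 64)
        seg = ie.AudioSegment(x, FS)
        spec = ie.compute_spectrogram(seg, window="boxcar")
        # magnitudes carry a 2/N scale; invert it and apply Parseval
        n = spec.window_len
        spec_energy = (spec.magnitudes**2).sum() * n / 2 * (n / 2) ** 2 / n
        wave_energy = (x**2).sum() / 2 * n / 2  # rfft half-spectrum doubling
        assert spec_energy == pytest.approx(wave_energy, rel=0.01)

    def test_full_scale_sine_peaks_at_zero_dbfs(self):
        # 3 kHz is an exact bin center at 48 kHz / 512
        spec = ie.compute_spectrogram(tone(3000, amp=1.0))
        assert spec.magnitudes.max() == pytest.approx(1.0, abs=1e-6)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ie.compute_spectrogram(ie.AudioSegment(np.ones(100), FS))


# ---------------------------------------------------------------------------
# acoustic entropy H
# ---------------------------------------------------------------------------

class TestAcousticEntropy:
    def test_white_noise_approaches_one(self, rng):
        seg = ie.AudioSegment(np.clip(rng.normal(0, 0.2, 4 * FS), -1, 1), FS)
        assert ie.compute_H(seg) > 0.95

    def test_steady_tone_collapses_spectral_entropy(self):
        assert ie.compute_H(tone(4000, duration=2.0)) < 0.4

    def test_silence_flagged_not_zero(self):
        assert np.isnan(ie.compute_H(ie.AudioSegment(np.zeros(FS), FS)))

    def test_matches_independent_two_factor_computation(self, mixed_segment):
        from scipy.signal import hilbert

        spec = ie.compute_spectrogram(mixed_segment)
        env = np.abs(hilbert(mixed_segment.samples))

        def norm_entropy(v):
            p = v / v.sum()
            p = p[p > 0]
            return float(-(p * np.log2(p)).sum() / np.log2(v.size))

        expected = norm_entropy(env) * norm_entropy(spec.magnitudes.mean(1))
        assert ie.compute_H(mixed_segment, spec) == pytest.approx(
            expected, abs=1e-10
        )


# ---------------------------------------------------------------------------
# bioacoustic index BI
# ---------------------------------------------------------------------------

class TestBioacousticIndex:
    def test_silence_is_zero(self):
        assert ie.compute_BI(ie.AudioSegment(np.zeros(FS), FS)) == 0.0

    def test_band_confinement(self):
        assert ie.compute_BI(tone(5000)) > 0
        assert ie.compute_BI(tone(1000)) == pytest.approx(0.0, abs=1e-9)

    def test_two_tone_spectrum_matches_hand_integration(self):
        t = np.arange(2 * FS) / FS
        wave = 0.5 * np.sin(2 * np.pi * 3000 * t) + 0.25 * np.sin(
            2 * np.pi * 6000 * t
        )
        seg = ie.AudioSegment(wave, FS)
        spec = ie.compute_spectrogram(seg)
        mean = spec.magnitudes.mean(axis=1)
        db = np.maximum(20 * np.log10(mean / mean.max(), where=mean > 0,
                                      out=np.full_like(mean, -600.0)), -60.0)
        band = (spec.freqs >= 2000) & (spec.freqs < 8000)
        shifted = db[band] - db[band].min()
        khz = spec.freqs[band] / 1000.0
        expected = np.sum(
            (shifted[1:] + shifted[:-1]) / 2 * np.diff(khz)
        )  # trapezoid by hand
        assert ie.compute_BI(seg, spectrogram=spec) == pytest.approx(
            expected, abs=1e-9
        )


# ---------------------------------------------------------------------------
# remaining indices
# ---------------------------------------------------------------------------

class TestOtherIndices:
    def test_ndsi_band_extremes(self):
        assert ie.compute_NDSI(tone(5000)) == pytest.approx(1.0, abs=1e-6)
        assert ie.compute_NDSI(tone(1500)) == pytest.approx(-1.0, abs=1e-6)

    def test_ndsi_silence_flagged(self):
        assert np.isnan(ie.compute_NDSI(ie.AudioSegment(np.zeros(FS), FS)))

    def test_zcr_of_4khz_sine_is_one_sixth(self):
        assert ie.compute_ZCR(tone(4000)) == pytest.approx(1 / 6, abs=1e-3)

    def test_aci_zero_for_constant_amplitude_spectrogram(self):
        spec = ie.Spectrogram(
            magnitudes=np.full((10, 100), 0.3),
            freqs=np.linspace(0, 12000, 10),
            frame_times=np.arange(100) * 0.01,
            window_len=512,
            overlap=0.0,
        )
        seg = tone(3000)
        assert ie.compute_ACI(seg, spectrogram=spec) == 0.0

    def test_adi_uniform_occupancy_is_log_band_count(self, rng):
        seg = ie.AudioSegment(np.clip(rng.normal(0, 0.3, 2 * FS), -1, 1), FS)
        # loud white noise occupies all ten 1 kHz bands equally
        assert ie.compute_ADI(seg) == pytest.approx(np.log(10), abs=1e-3)
        assert ie.compute_AEI(seg) == pytest.approx(0.0, abs=1e-2)

    def test_adi_aei_zero_occupancy_flagged(self):
        quiet = ie.AudioSegment(np.full(FS, 1e-8), FS)  # below -50 dBFS
        assert np.isnan(ie.compute_ADI(quiet))
        assert np.isnan(ie.compute_AEI(quiet))

    def test_dsc_of_pure_tone_within_one_bin(self):
        assert ie.compute_DSC(tone(4000)) == pytest.approx(4000, abs=94)

    def test_dual_implementation_oracle_on_mixed_audio(self, mixed_segment):
        """Each spectral index equals a naive reference implementation."""
        spec = ie.compute_spectrogram(mixed_segment)
        mags = spec.magnitudes

        # ACI: loop over 5 s clumps and bins
        frames_per_clump = int(round(5.0 / spec.hop_s))
        aci_ref = 0.0
        for s in range(0, mags.shape[1], frames_per_clump):
            clump = mags[:, s : s + frames_per_clump]
            if clump.shape[1] < 2:
                continue
            for k in range(clump.shape[0]):
                tot = clump[k].sum()
                if tot > 0:
                    aci_ref += np.abs(np.diff(clump[k])).sum() / tot

        # occupancy per 1 kHz band
        db = 20 * np.log10(mags, where=mags > 0,
                           out=np.full_like(mags, -np.inf))
        occ = []
        for lo in range(0, 10000, 1000):
            m = (spec.freqs >= lo) & (spec.freqs < lo + 1000)
            occ.append((db[m] > -50).mean())
        occ = np.array(occ)
        p = occ / occ.sum()
        adi_ref = -(p[p > 0] * np.log(p[p > 0])).sum()
        gini = sum(
            abs(a - b) for a in occ for b in occ
        ) / (2 * len(occ) * occ.sum())

        power = (mags**2).mean(axis=1)
        bio = power[(spec.freqs >= 2000) & (spec.freqs < 8000)].sum()
        anthro = power[(spec.freqs >= 1000) & (spec.freqs < 2000)].sum()
        ndsi_ref = (bio - anthro) / (bio + anthro)

        centroids = []
        for j in range(mags.shape[1]):
            w = mags[:, j]
            if w.sum() > 0:
                centroids.append((spec.freqs * w).sum() / w.sum())
        dsc_ref = np.mean(centroids)

        assert ie.compute_ACI(mixed_segment, spectrogram=spec) == (
            pytest.approx(aci_ref, abs=1e-8)
        )
        assert ie.compute_ADI(mixed_segment, spectrogram=spec) == (
            pytest.approx(adi_ref, abs=1e-8)
        )
        assert ie.compute_AEI(mixed_segment, spectrogram=spec) == (
            pytest.approx(gini, abs=1e-8)
        )
        assert ie.compute_NDSI(mixed_segment, spectrogram=spec) == (
            pytest.approx(ndsi_ref, abs=1e-8)
        )
        assert ie.compute_DSC(mixed_segment, spec) == pytest.approx(
            dsc_ref, abs=1e-8
        )


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

class TestIndexProperties:
    def test_ranges_hold_on_1000_random_segments(self):
        """Declared index ranges hold for randomized audio content."""
        rng = np.random.default_rng(99)
        fs = 24000
        for _ in range(1000):
            kind = rng.integers(0, 3)
            n = int(0.5 * fs)
            if kind == 0:
                x = rng.normal(0, rng.uniform(0.01, 0.3), n)
            elif kind == 1:
                f = rng.uniform(100, 11000)
                x = rng.uniform(0.05, 0.9) * np.sin(
                    2 * np.pi * f * np.arange(n) / fs
                )
            else:
                x = gen_audio_segment(
                    rng.uniform(0, 3), rng.uniform(0, 3),
                    duration_s=0.5, sample_rate=fs,
                    seed=int(rng.integers(1 << 31)),
                )
            seg = ie.AudioSegment(np.clip(x, -1, 1), fs)
            if seg.is_silent:
                continue
            idx = ie.compute_all_indices(seg)
            assert np.isnan(idx["H"]) or 0 <= idx["H"] <= 1
            assert idx["ACI"] >= 0
            assert np.isnan(idx["ADI"]) or idx["ADI"] >= 0
            assert np.isnan(idx["AEI"]) or 0 <= idx["AEI"] <= 1
            assert np.isnan(idx["NDSI"]) or -1 <= idx["NDSI"] <= 1
            assert idx["BI"] >= 0
            assert np.isnan(idx["DSC"]) or 0 <= idx["DSC"] <= fs / 2
            assert 0 <= idx["ZCR"] <= 1

    def test_low_frequency_noise_raises_h_but_not_bi(self):
        """Adding traffic-band noise to a fixed chirp bed moves H and BI in
        opposite ways: H rises toward mid-range (spectrum more mixed), BI is
        nearly unchanged (noise sits below its 2 kHz band edge)."""
        chirps = gen_audio_segment(1.5, 0.0, duration_s=5, seed=21)
        noisy = chirps + gen_audio_segment(0.0, 0.5, duration_s=5, seed=22)
        a = ie.AudioSegment(chirps, FS)
        b = ie.AudioSegment(np.clip(noisy, -1, 1), FS)
        assert ie.compute_H(b) > ie.compute_H(a) + 0.02
        bi_a, bi_b = ie.compute_BI(a), ie.compute_BI(b)
        assert abs(bi_b - bi_a) / bi_a < 0.2


# ---------------------------------------------------------------------------
# series assembly
# ---------------------------------------------------------------------------

class TestAssembleSeries:
    @staticmethod
    def records(n, site="s1", start="2022-04-13 05:00", step_s=360):
        t0 = pd.Timestamp(start)
        rng = np.random.default_rng(0)
        for i in range(n):
            yield {
                "site_id": site,
                "timestamp": t0 + i * pd.Timedelta(seconds=step_s),
                **{name: float(rng.random()) for name in ie.INDEX_NAMES},
            }

    def test_continuous_310_minutes_gives_210_rows(self):
        df = ie.assemble_series(self.records(210, step_s=60))
        assert len(df) == 210

    def test_shuffled_input_assembles_identically(self):
        recs = list(self.records(50))
        ordered = ie.assemble_series(recs)
        rng = np.random.default_rng(1)
        shuffled = ie.assemble_series([recs[i] for i in
                                       rng.permutation(len(recs))])
        pd.testing.assert_frame_equal(ordered, shuffled)

    def test_duplicate_site_timestamp_rejected(self):
        recs = list(self.records(30))
        with pytest.raises(ValueError, match="duplicate"):
            ie.assemble_series(recs + recs[:1])

    def test_window_step_recorded_for_contiguity(self):
        df = ie.assemble_series(self.records(40, step_s=360))
        assert df.attrs["window_step_s"] == 360.0
        blocks = ie.contiguity_blocks(df["timestamp"], 360.0)
        assert blocks == [(0, 40)]

    def test_gap_splits_contiguity_blocks(self):
        recs = list(self.records(20)) + [
            r | {"timestamp": r["timestamp"] + pd.Timedelta(hours=5)}
            for r in self.records(20, start="2022-04-14 05:00")
        ]
        df = ie.assemble_series(recs)
        blocks = ie.contiguity_blocks(df["timestamp"], 360.0)
        assert len(blocks) == 2
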