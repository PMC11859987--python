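"""Eco-acoustic indices from 1-min audio segments.

Eight scalar summaries of a recording's spectro-temporal structure, computed
from a short-time magnitude spectrogram of the waveform:

====== ===================================================================
H      acoustic entropy: temporal entropy of the amplitude envelope times
       spectral entropy of the mean spectrum, each normalized by its
       log-cardinality, in [0, 1]
ACI    acoustic complexity index: per-frequency-bin relative temporal
       variation, accumulated over temporal clumps
ADI    acoustic diversity index: Shannon entropy (natural log) of per-1 kHz
       band occupancy above a dB threshold
AEI    acoustic evenness index: Gini coefficient of the same occupancy
NDSI   normalized difference soundscape index: (B - A)/(B + A) with B the
       biophony-band power (2-8 kHz) and A the anthrophony band (1-2 kHz)
BI     bioacoustic index: area under the minimum-referenced mean dB
       spectrum in the biophony band (2-8 kHz)
DSC    dynamic spectral centroid: time-average of the per-frame
       amplitude-weighted spectral centroid, in Hz
ZCR    zero crossing rate: sign changes per sample, in [0, 1]
====== ===================================================================

dB values are dBFS with a full-scale sine at 0 dB: spectrogram magnitudes
are scaled by 2 / sum(window) so a unit-amplitude sine peaks at 1.0.  BI and
ADI depend on this reference.  Frequency bands are half-open, [lo, hi).

Silence is never reported as a plain numeric 0 for H, NDSI, ADI, AEI or DSC:
those indices return NaN on silent input and the missing value propagates
flagged.  BI returns 0 on silence by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "AudioSegment",
    "Spectrogram",
    "compute_spectrogram",
    "compute_H",
    "compute_ACI",
    "compute_ADI",
    "compute_AEI",
    "compute_NDSI",
    "compute_BI",
    "compute_DSC",
    "compute_ZCR",
    "compute_all_indices",
    "assemble_series",
    "read_wav_segment",
]

INDEX_NAMES = ["H", "ACI", "ADI", "AEI", "NDSI", "BI", "DSC", "ZCR"]


@dataclass
class AudioSegment:
    """A mono waveform in [-1, 1] with its recording metadata."""

    samples: np.ndarray
    sample_rate: int = 48000
    start_time: pd.Timestamp | None = None
    site_id: object = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate < 16000:
            raise ValueError(
                "sample_rate must be >= 16 kHz (2x the 8 kHz biophony band)"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def is_silent(self) -> bool:
        return not np.any(self.samples)


def read_wav_segment(path, site_id=None, start_time=None) -> AudioSegment:
    """Load a RIFF PCM WAV file, scaling integer PCM to [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSegment(data.astype(float), rate, start_time, site_id)


@dataclass
class Spectrogram:
    """Short-time magnitude spectrum, full-scale-sine referenced."""

    magnitudes: np.ndarray  # (freq, frames), >= 0
    freqs: np.ndarray       # Hz, 0 .. Nyquist
    frame_times: np.ndarray  # s
    window_len: int
    overlap: float

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        """Half-open band selection [lo, hi) on bin-center frequencies."""
        return (self.freqs >= lo) & (self.freqs < hi)

    @property
    def hop_s(self) -> float:
        if len(self.frame_times) > 1:
            return float(self.frame_times[1] - self.frame_times[0])
        return float(self.window_len)


def compute_spectrogram(
    segment: AudioSegment,
    window_len: int = 512,
    overlap: float = 0.0,
    window: str = "hann",
) -> Spectrogram:
    """Magnitude STFT scaled so a full-scale sine peaks at 1.0 (0 dBFS)."""
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    x = segment.samples
    hop = max(int(round(window_len * (1.0 - overlap))), 1)
    win = sps.get_window(window, window_len, fftbins=True)
    n_frames = 1 + (len(x) - window_len) // hop if len(x) >= window_len else 0
    if n_frames == 0:
        raise ValueError("segment shorter than one analysis window")
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    mags = np.abs(np.fft.rfft(frames, axis=1)).T * (2.0 / win.sum())
    freqs = np.fft.rfftfreq(window_len, d=1.0 / segment.sample_rate)
    times = (hop * np.arange(n_frames) + window_len / 2) / segment.sample_rate
    return Spectrogram(mags, freqs, times, window_len, overlap)


def _spec(segment, spectrogram=None, **kw) -> Spectrogram:
    return spectrogram if spectrogram is not None else compute_spectrogram(
        segment, **kw
    )


# ---------------------------------------------------------------------------
# individual indices
# ---------------------------------------------------------------------------

def compute_H(segment: AudioSegment, spectrogram: Spectrogram | None = None
              ) -> float:
    """Acoustic entropy in [0, 1]; NaN on silence.

    Product of the temporal entropy of the normalized Hilbert amplitude
    envelope and the spectral entropy of the normalized mean spectrum, each
    divided by the log of its support size so a maximally flat signal scores
    1 and a steady pure tone scores near 0.
    """
    if segment.is_silent:
        return float("nan")
    env = np.abs(sps.hilbert(segment.samples))
    p_t = env / env.sum()
    nz = p_t[p_t > 0]
    h_t = float(-(nz * np.log2(nz)).sum()) / np.log2(p_t.size)
    spec = _spec(segment, spectrogram)
    mean_spectrum = spec.magnitudes.mean(axis=1)
    p_f = mean_spectrum / mean_spectrum.sum()
    nzf = p_f[p_f > 0]
    h_f = float(-(nzf * np.log2(nzf)).sum()) / np.log2(p_f.size)
    return h_t * h_f


def compute_ACI(
    segment: AudioSegment,
    clump_s: float = 5.0,
    spectrogram: Spectrogram | None = None,
) -> float:
    """Acoustic complexity index (>= 0); 0 for a temporally flat spectrogram.

    For each temporal clump and each frequency bin k:
    sum_t |I_{k,t} - I_{k,t+1}| / sum_t I_{k,t}, summed over bins and clumps.
    """
    spec = _spec(segment, spectrogram)
    mags = spec.magnitudes
    frames_per_clump = max(int(round(clump_s / spec.hop_s)), 2)
    total = 0.0
    for start in range(0, mags.shape[1], frames_per_clump):
        clump = mags[:, start : start + frames_per_clump]
        if clump.shape[1] < 2:
            continue
        diffs = np.abs(np.diff(clump, axis=1)).sum(axis=1)
        sums = clump.sum(axis=1)
        ok = sums > 0
        total += float((diffs[ok] / sums[ok]).sum())
    return total


def _occupancy(
    spec: Spectrogram, db_threshold: float, band_hz: float, max_freq: float
) -> np.ndarray:
    """Fraction of cells above the dBFS threshold per frequency band."""
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(spec.magnitudes, where=spec.magnitudes > 0,
                             out=np.full_like(spec.magnitudes, -np.inf))
    edges = np.arange(0.0, max_freq + band_hz, band_hz)
    occ = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = spec.band_mask(lo, hi)
        if not mask.any():
            continue
        occ.append(float((db[mask] > db_threshold).mean()))
    return np.asarray(occ)


def compute_ADI(
    segment: AudioSegment,
    db_threshold: float = -50.0,
    band_hz: float = 1000.0,
    max_freq: float = 10000.0,
    spectrogram: Spectrogram | None = None,
) -> float:
    """Acoustic diversity index (natural-log Shannon entropy of occupancy).

    Equals ln(n_bands) when every band is equally occupied; NaN when no band
    is occupied at all.
    """
    occ = _occupancy(_spec(segment, spectrogram), db_threshold, band_hz,
                     max_freq)
    if occ.sum() <= 0:
        return float("nan")
    p = occ / occ.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def compute_AEI(
    segment: AudioSegment,
    db_threshold: float = -50.0,
    band_hz: float = 1000.0,
    max_freq: float = 10000.0,
    spectrogram: Spectrogram | None = None,
) -> float:
    """Acoustic evenness index: Gini coefficient of band occupancy in [0, 1]."""
    occ = _occupancy(_spec(segment, spectrogram), db_threshold, band_hz,
                     max_freq)
    if occ.sum() <= 0:
        return float("nan")
    n = occ.size
    diffs = np.abs(occ[:, None] - occ[None, :]).sum()
    return float(diffs / (2.0 * n * occ.sum()))


def compute_NDSI(
    segment: AudioSegment,
    anthro_band: tuple = (1000.0, 2000.0),
    bio_band: tuple = (2000.0, 8000.0),
    spectrogram: Spectrogram | None = None,
) -> float:
    """Normalized difference soundscape index in [-1, 1]; NaN on silence."""
    spec = _spec(segment, spectrogram)
    power = (spec.magnitudes**2).mean(axis=1)
    b = float(power[spec.band_mask(*bio_band)].sum())
    a = float(power[spec.band_mask(*anthro_band)].sum())
    if b + a <= 0:
        return float("nan")
    return (b - a) / (b + a)


def compute_BI(
    segment: AudioSegment,
    band: tuple = (2000.0, 8000.0),
    db_floor: float = -60.0,
    spectrogram: Spectrogram | None = None,
) -> float:
    """Bioacoustic index (>= 0); 0 on silence by convention.

    Area (trapezoidal, frequency in kHz) under the max-referenced mean dB
    spectrum between 2 and 8 kHz after subtracting the in-band minimum, so a
    flat in-band spectrum scores 0.  ``db_floor`` caps the dynamic range so
    that spectral-leakage wiggles far below the signal do not register as
    in-band area (a band holding no energy above the floor scores exactly 0).
    """
    spec = _spec(segment, spectrogram)
    mean_spectrum = spec.magnitudes.mean(axis=1)
    if mean_spectrum.max() <= 0:
        return 0.0
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mean_spectrum / mean_spectrum.max())
    db = np.maximum(db, db_floor)
    mask = spec.band_mask(*band)
    if mask.sum() < 2:
        raise ValueError("biophony band covers fewer than 2 frequency bins")
    db_band = db[mask] - db[mask].min()
    return float(np.trapezoid(db_band, spec.freqs[mask] / 1000.0))


def compute_DSC(segment: AudioSegment,
                spectrogram: Spectrogram | None = None) -> float:
    """Dynamic spectral centroid (Hz): mean per-frame weighted centroid."""
    spec = _spec(segment, spectrogram)
    weights = spec.magnitudes.sum(axis=0)
    ok = weights > 0
    if not ok.any():
        return float("nan")
    centroids = (spec.freqs @ spec.magnitudes[:, ok]) / weights[ok]
    return float(centroids.mean())


def compute_ZCR(segment: AudioSegment) -> float:
    """Zero crossing rate: sign changes / (N - 1), in [0, 1]."""
    s = np.sign(segment.samples)
    # treat exact zeros as carrying the previous sign (no spurious crossing)
    for i in np.flatnonzero(s == 0):
        s[i] = s[i - 1] if i > 0 else 1.0
    return float((s[1:] != s[:-1]).mean())


def compute_all_indices(segment: AudioSegment, **spectrogram_kw) -> dict:
    """All eight indices from one shared spectrogram."""
    if segment.is_silent:
        return {
            "H": float("nan"), "ACI": 0.0, "ADI": float("nan"),
            "AEI": float("nan"), "NDSI": float("nan"), "BI": 0.0,
            "DSC": float("nan"), "ZCR": 0.0,
        }
    spec = compute_spectrogram(segment, **spectrogram_kw)
    return {
        "H": compute_H(segment, spec),
        "ACI": compute_ACI(segment, spectrogram=spec),
        "ADI": compute_ADI(segment, spectrogram=spec),
        "AEI": compute_AEI(segment, spectrogram=spec),
        "NDSI": compute_NDSI(segment, spectrogram=spec),
        "BI": compute_BI(segment, spectrogram=spec),
        "DSC": compute_DSC(segment, spec),
        "ZCR": compute_ZCR(segment),
    }


# ---------------------------------------------------------------------------
# series assembly
# ---------------------------------------------------------------------------

def assemble_series(records, protocol: str | None = None) -> pd.DataFrame:
    """Assemble per-segment index vectors into a long (site, time) matrix.

    ``records`` yields mappings with keys ``site_id``, ``timestamp`` and the
    eight index names.  Rows are ordered by site then time regardless of the
    input order; duplicate (site, timestamp) pairs are rejected.  The result
    carries the protocol label and, per site, the modal window step so
    downstream code can identify contiguity blocks.
    """
    df = pd.DataFrame(list(records))
    required = {"site_id", "timestamp", *INDEX_NAMES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing fields: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df.duplicated(subset=["site_id", "timestamp"]).any():
        dupes = df[df.duplicated(subset=["site_id", "timestamp"])]
        raise ValueError(
            f"duplicate (site, timestamp) rows: {dupes.iloc[0].tolist()[:2]}"
        )
    df = df.sort_values(["site_id", "timestamp"], kind="mergesort")
    df = df.reset_index(drop=True)[["site_id", "timestamp", *INDEX_NAMES]]
    if protocol is not None:
        df.attrs["protocol"] = protocol
    steps = df.groupby("site_id")["timestamp"].diff().dropna()
    if len(steps):
        df.attrs["window_step_s"] = float(
            steps.mode().iloc[0].total_seconds()
        )
    return df


def contiguity_blocks(
    timestamps: pd.Series, step_s: float
) -> list[tuple[int, int]]:
    """[start, stop) runs of consecutive windows exactly ``step_s`` apart."""
    ts = pd.to_datetime(pd.Series(timestamps).reset_index(drop=True))
    if len(ts) == 0:
        return []
    gaps = ts.diff().dt.total_seconds().to_numpy()[1:]
    breaks = np.flatnonzero(~np.isclose(gaps, step_s)) + 1
    bounds = np.concatenate([[0], breaks, [len(ts)]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
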