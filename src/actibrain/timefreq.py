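"""Short-time Fourier transform features of daytime activity segments.

A 720-sample daytime segment (1 sample/min, i.e. 0.0167 Hz) is analysed with a
60-min window, 50% overlap, and a 256-point transform — the default behaviour
of classical spectrogram routines for a 60-sample window.  The one-sided
spectrum has 129 bins; dropping the DC bin leaves 128 frequency indices, whose
time-averaged magnitudes are pooled into 64 features by averaging consecutive
pairs.

No scaling is applied to the magnitudes: the spectrogram entries are
``|rfft(window * frame, 256)|`` exactly, which keeps the brute-force windowed
DFT an unambiguous oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import boxcar, hamming

from .preprocess import SEGMENT_LENGTH, DaySegment

__all__ = ["StftConfig", "Spectrogram", "stft_magnitude", "tf_features",
           "tf_features_subject", "tf_feature_table", "TF_COLUMNS"]

TF_COLUMNS = [f"tf_{i:02d}" for i in range(1, 65)]


@dataclass(frozen=True)
class StftConfig:
    """Spectrogram parameters; defaults follow the common 60-sample-window case.

    window_length and overlap are in samples (= minutes at 1 sample/min);
    sampling interval is fixed at 1 min so the frequency axis is in
    cycles/min (0.0167 Hz sampling rate equivalent).
    """

    window_length: int = 60
    overlap: int = 30
    n_fft: int = 256
    window_shape: str = "hamming"  # or "rectangular"
    drop_bin: str = "dc"  # or "nyquist"

    def __post_init__(self) -> None:
        if self.window_length > SEGMENT_LENGTH:
            raise ValueError("window longer than segment")
        if not 0 <= self.overlap < self.window_length:
            raise ValueError("overlap must be < window_length")
        if self.n_fft < self.window_length:
            raise ValueError("n_fft must cover the window")
        if self.window_shape not in ("hamming", "rectangular"):
            raise ValueError("window_shape must be 'hamming' or 'rectangular'")
        if self.drop_bin not in ("dc", "nyquist"):
            raise ValueError("drop_bin must be 'dc' or 'nyquist'")

    @property
    def hop(self) -> int:
        return self.window_length - self.overlap

    def window(self) -> np.ndarray:
        if self.window_shape == "hamming":
            return hamming(self.window_length, sym=True)
        return boxcar(self.window_length)


@dataclass
class Spectrogram:
    magnitudes: np.ndarray  # n_freq x n_windows, >= 0
    frequencies: np.ndarray  # cycles/min
    times: np.ndarray  # window-centre offsets in minutes

    def __post_init__(self) -> None:
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")


def _segment_values(segment: DaySegment | np.ndarray) -> np.ndarray:
    values = segment.values if isinstance(segment, DaySegment) else np.asarray(segment, float)
    if values.ndim != 1:
        raise ValueError("segment must be 1-D")
    if values.shape[0] < 1:
        raise ValueError("empty segment")
    return values


def stft_magnitude(segment: DaySegment | np.ndarray, config: StftConfig | None = None) -> Spectrogram:
    """One-sided magnitude spectrogram of a segment.

    Frames start every ``hop`` samples; each is multiplied by the window and
    zero-padded to ``n_fft`` before the real FFT.  For the defaults on a
    720-sample segment this yields a 129 x 23 matrix.
    """
    config = config or StftConfig()
    values = _segment_values(segment)
    if values.shape[0] < config.window_length:
        raise ValueError("segment shorter than the analysis window")
    hop = config.hop
    n_frames = 1 + (values.shape[0] - config.window_length) // hop
    win = config.window()
    frames = np.lib.stride_tricks.sliding_window_view(values, config.window_length)[::hop]
    frames = frames[:n_frames] * win
    mags = np.abs(np.fft.rfft(frames, n=config.n_fft, axis=1)).T
    freqs = np.fft.rfftfreq(config.n_fft, d=1.0)  # cycles per minute
    times = np.arange(n_frames) * hop + (config.window_length - 1) / 2.0
    return Spectrogram(magnitudes=mags, frequencies=freqs, times=times)


def tf_features(segment: DaySegment | np.ndarray, config: StftConfig | None = None) -> np.ndarray:
    """64 time-frequency features for one day segment.

    Magnitudes are averaged over all time windows (129 values), the DC bin is
    dropped (128 frequency indices), and consecutive pairs are averaged down
    to 64 non-negative features.
    """
    config = config or StftConfig()
    spec = stft_magnitude(segment, config)
    mean_mag = spec.magnitudes.mean(axis=1)
    if config.drop_bin == "dc":
        mean_mag = mean_mag[1:]
    else:
        mean_mag = mean_mag[:-1]
    if mean_mag.shape[0] % 2:
        raise ValueError("frequency index count must be even for pairwise grouping")
    return mean_mag.reshape(-1, 2).mean(axis=1)


def tf_features_subject(
    segments: list[DaySegment] | list[np.ndarray], config: StftConfig | None = None
) -> np.ndarray:
    """Subject-level 64-vector: arithmetic mean of the per-day feature vectors."""
    if not segments:
        raise ValueError("subject has no retained day segments")
    return np.mean([tf_features(s, config) for s in segments], axis=0)


def tf_feature_table(
    segments_by_subject: dict[str, list[DaySegment]], config: StftConfig | None = None
) -> pd.DataFrame:
    """Subjects x 64 table with columns tf_01..tf_64 (index subject_id)."""
    rows = {
        sid: tf_features_subject(segs, config)
        for sid, segs in segments_by_subject.items()
        if segs
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=TF_COLUMNS)
    table.index.name = "subject_id"
    return table.sort_index()
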