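"""Sliding-window segmentation and Hudgins time-domain EMG features.

The raw eight-channel EMG is cut into overlapping analysis windows (128 ms
with a 50 ms step by default, i.e. a 20 Hz command cadence at 1 kHz
sampling). Per window and channel four classic time-domain features are
computed -- mean absolute value (MAV), zero-crossing count (ZC), waveform
length (WL) and slope-sign-change count (SSC) -- giving a 32-dimensional
feature vector that is z-normalized before reaching the regressor.

Feature ordering is channel-major and frozen for model serialization:
``[ch1 MAV, ch1 ZC, ch1 WL, ch1 SSC, ch2 MAV, ...]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recording import N_CHANNELS, EmgRecording

#: Default analysis-window length and step, milliseconds.
WINDOW_MS = 128.0
STEP_MS = 50.0

#: Names of the per-channel features in storage order.
FEATURE_NAMES = ("mav", "zc", "wl", "ssc")

#: Dimensionality of a full feature vector.
N_FEATURES = len(FEATURE_NAMES) * N_CHANNELS


@dataclass(frozen=True)
class Window:
    """A fixed-duration slice of an 8-channel recording.

    ``samples`` has shape (n_samples, 8); ``start_ms`` is the offset of the
    first sample into the source recording.
    """

    samples: np.ndarray
    start_ms: float

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def _to_samples(duration_ms: float, fs: float) -> int:
    """Convert a duration to a whole sample count, or fail loudly."""
    exact = duration_ms * fs / 1000.0
    n = round(exact)
    if abs(exact - n) > 1e-9:
        raise ValueError(
            f"duration {duration_ms} ms is not a whole number of samples "
            f"at fs={fs} Hz"
        )
    return int(n)


def segment_windows(
    recording: EmgRecording,
    window_ms: float = WINDOW_MS,
    step_ms: float = STEP_MS,
) -> list[Window]:
    """Cut a recording into overlapping fixed-length windows.

    Returns ``floor((N - W) / S) + 1`` windows for N samples, window length
    W and step S (in samples), ordered by start time. A recording shorter
    than one window yields an empty list and a warning.
    """
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window_ms and step_ms must be positive")
    w = _to_samples(window_ms, recording.fs)
    s = _to_samples(step_ms, recording.fs)
    n = recording.n_samples
    if n < w:
        warnings.warn(
            f"recording of {recording.duration_ms:.0f} ms is shorter than "
            f"one {window_ms:.0f} ms window; no windows produced",
            stacklevel=2,
        )
        return []
    return [
        Window(recording.signal[i : i + w], start_ms=i * 1000.0 / recording.fs)
        for i in range(0, n - w + 1, s)
    ]


def hudgins_features(
    window: Window | np.ndarray,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
) -> np.ndarray:
    """Compute the four Hudgins time-domain features per channel.

    Parameters
    ----------
    window : Window or ndarray of shape (n_samples, n_channels)
        At least two samples per channel are required (the differenced
        features are undefined otherwise).
    zc_threshold : float
        Amplitude deadband for zero crossings: a sign change between
        consecutive samples counts only if the amplitude gap
        ``|x[i] - x[i+1]|`` is at least this value.
    ssc_threshold : float
        Deadband for slope-sign changes: a local extremum at sample i counts
        only if ``(x[i]-x[i-1]) * (x[i]-x[i+1])`` exceeds this value.

    Returns
    -------
    ndarray, shape (4 * n_channels,)
        Channel-major (MAV, ZC, WL, SSC) values; all nonnegative.
    """
    x = window.samples if isinstance(window, Window) else np.asarray(window, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError(
            "hudgins_features requires at least 2 samples per channel"
        )
    d = np.diff(x, axis=0)
    mav = np.mean(np.abs(x), axis=0)
    wl = np.sum(np.abs(d), axis=0)
    sign_change = x[:-1] * x[1:] < 0
    zc = np.sum(sign_change & (np.abs(d) >= zc_threshold), axis=0)
    # (x[i]-x[i-1])*(x[i]-x[i+1]) = -d[i-1]*d[i]; > threshold keeps a flat
    # signal at zero counts for the default threshold of 0.
    ssc = np.sum(-d[:-1] * d[1:] > ssc_threshold, axis=0)
    return np.stack([mav, zc, wl, ssc], axis=1).ravel().astype(float)


def feature_matrix(
    windows: list[Window],
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
) -> np.ndarray:
    """Stack Hudgins features for a window sequence into an (n, 32) matrix."""
    if not windows:
        return np.empty((0, N_FEATURES))
    return np.stack(
        [hudgins_features(w, zc_threshold, ssc_threshold) for w in windows]
    )


def channel_rms(window: Window | np.ndarray) -> np.ndarray:
    """Root-mean-square amplitude per channel, the game-control signal."""
    x = window.samples if isinstance(window, Window) else np.asarray(window, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] == 0:
        raise ValueError("channel_rms of an empty window is undefined")
    return np.sqrt(np.mean(x * x, axis=0))


class Normalizer:
    """Frozen per-dimension z-scoring of feature vectors.

    Statistics are estimated once at training time and reused verbatim at
    inference; the standard deviation is floored at ``eps`` so that silent
    (constant) feature dimensions map to zero instead of blowing up.
    """

    def __init__(self, eps: float = 1e-8):
        self.eps = float(eps)
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("Normalizer.fit needs at least 2 feature vectors")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd < self.eps
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature dimension(s); "
                "standard deviation floored",
                stacklevel=2,
            )
        self.scale_ = np.maximum(sd, self.eps)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Normalizer used before fit")
        return (np.asarray(X, float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        if self.mean_ is None:
            raise RuntimeError("Normalizer not fitted")
        return {
            "eps": self.eps,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        norm = cls(eps=d["eps"])
        norm.mean_ = np.asarray(d["mean"], float)
        norm.scale_ = np.asarray(d["scale"], float)
        return norm


def plateau_windows(
    recording: EmgRecording,
    window_ms: float = WINDOW_MS,
    step_ms: float = STEP_MS,
    tol: float = 1e-6,
) -> list[Window]:
    """Windows lying entirely on the reference plateau of a recording.

    A window qualifies when the reference equals the recording's target
    level over its whole span (rest recordings, level 0, qualify
    everywhere).
    """
    w = _to_samples(window_ms, recording.fs)
    out = []
    for win in segment_windows(recording, window_ms, step_ms):
        i0 = _to_samples(win.start_ms, recording.fs)
        ref = recording.reference[i0 : i0 + w]
        if np.all(np.abs(ref - recording.level) <= tol):
            out.append(win)
    return out
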