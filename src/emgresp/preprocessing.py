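"""Trial preprocessing and steady-state segment selection.

Raw voluntary-contraction recordings are offset-removed, bandpass filtered
(20-450 Hz, 4th-order zero-phase Butterworth) and 60 Hz notch filtered, then
the single 3 s window with the lowest sample standard deviation is taken as
the steady-state analysis segment for feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import EmgTrial, InvalidConfigError

__all__ = [
    "PrepConfig",
    "SteadySegment",
    "SegmentTooShortError",
    "preprocess",
    "extract_steady_segment",
    "EmgPreprocessor",
    "SteadySegmentSelector",
]


class SegmentTooShortError(ValueError):
    """Trial shorter than the requested steady-state window."""


@dataclass
class PrepConfig:
    band_low: float = 20.0  # Hz
    band_high: float = 450.0  # Hz
    notch_freq: float = 60.0  # Hz
    notch_q: float = 30.0
    window_s: float = 3.0  # steady-state window length
    hop_s: float = 0.05  # search stride for the lowest-SD window

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low < self.band_high:
            raise InvalidConfigError("need 0 < band_low < band_high")
        if self.band_high >= fs / 2:
            raise InvalidConfigError("band_high must lie below Nyquist")
        if not self.band_low < self.notch_freq < self.band_high:
            raise InvalidConfigError("notch_freq must sit inside the passband")
        if self.notch_q <= 0:
            raise InvalidConfigError("notch_q must be positive")
        if self.window_s * fs < 2:
            raise InvalidConfigError("window_s too short for fs")
        if self.hop_s <= 0:
            raise InvalidConfigError("hop_s must be positive")


@dataclass
class SteadySegment:
    """The minimal-SD analysis window cut from one preprocessed MVC trial."""

    samples: np.ndarray
    start_index: int
    fs: float
    muscle_id: str = ""
    participant_id: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("segment must be a non-empty 1-D series")


def preprocess(trial: EmgTrial, cfg: PrepConfig | None = None) -> EmgTrial:
    """Offset removal + zero-phase bandpass + 60 Hz notch; length preserved."""
    cfg = cfg or PrepConfig()
    cfg.validate(trial.fs)
    x = trial.samples - trial.samples.mean()
    sos = sps.butter(
        4, [cfg.band_low, cfg.band_high], btype="bandpass", fs=trial.fs, output="sos"
    )
    x = sps.sosfiltfilt(sos, x)
    b, a = sps.iirnotch(cfg.notch_freq, cfg.notch_q, fs=trial.fs)
    x = sps.filtfilt(b, a, x)
    # zero-phase filtering leaves a small edge-effect offset; remove it so
    # the output is exactly mean-free
    return replace(trial, samples=x - x.mean())


def _window_sds(x: np.ndarray, win: int, starts: np.ndarray) -> np.ndarray:
    """Population SD of x[s:s+win] for each start, via cumulative sums."""
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[starts + win] - c1[starts]
    s2 = c2[starts + win] - c2[starts]
    var = s2 / win - (s1 / win) ** 2
    return np.sqrt(np.maximum(var, 0.0))


def extract_steady_segment(trial: EmgTrial, cfg: PrepConfig | None = None) -> SteadySegment:
    """Lowest-SD window of length ``window_s`` at ``hop_s`` stride.

    Ties (e.g. a constant trial) resolve to the earliest start. The final
    possible start is always a candidate so the trailing edge is covered.
    """
    cfg = cfg or PrepConfig()
    if cfg.window_s * trial.fs < 2 or cfg.hop_s <= 0:
        raise InvalidConfigError("window_s/hop_s invalid for this sampling rate")
    x = trial.samples
    win = int(round(cfg.window_s * trial.fs))
    if x.size < win:
        raise SegmentTooShortError(
            f"trial has {x.size} samples, window needs {win}"
        )
    hop = max(1, int(round(cfg.hop_s * trial.fs)))
    starts = np.arange(0, x.size - win + 1, hop)
    if starts[-1] != x.size - win:
        starts = np.append(starts, x.size - win)
    sds = _window_sds(x, win, starts)
    best = int(starts[int(np.argmin(sds))])  # argmin -> earliest on ties
    return SteadySegment(
        samples=x[best : best + win].copy(),
        start_index=best,
        fs=trial.fs,
        muscle_id=trial.muscle_id,
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
    )


class EmgPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer applying :func:`preprocess`."""

    def __init__(
        self,
        band_low: float = 20.0,
        band_high: float = 450.0,
        notch_freq: float = 60.0,
        notch_q: float = 30.0,
    ) -> None:
        self.band_low = band_low
        self.band_high = band_high
        self.notch_freq = notch_freq
        self.notch_q = notch_q

    def _config(self) -> PrepConfig:
        return PrepConfig(
            band_low=self.band_low,
            band_high=self.band_high,
            notch_freq=self.notch_freq,
            notch_q=self.notch_q,
        )

    def fit(self, X: Iterable[EmgTrial], y=None) -> "EmgPreprocessor":
        self.n_trials_seen_ = sum(1 for _ in X)
        return self

    def transform(self, X: Iterable[EmgTrial]) -> List[EmgTrial]:
        cfg = self._config()
        return [preprocess(t, cfg) for t in X]


class SteadySegmentSelector(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer applying :func:`extract_steady_segment`."""

    def __init__(self, window_s: float = 3.0, hop_s: float = 0.05) -> None:
        self.window_s = window_s
        self.hop_s = hop_s

    def fit(self, X: Iterable[EmgTrial], y=None) -> "SteadySegmentSelector":
        self.n_trials_seen_ = sum(1 for _ in X)
        return self

    def transform(self, X: Iterable[EmgTrial]) -> List[SteadySegment]:
        cfg = PrepConfig(window_s=self.window_s, hop_s=self.hop_s)
        return [extract_steady_segment(t, cfg) for t in X]
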