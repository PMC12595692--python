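"""The 24-feature surface-EMG descriptor bank.

Computed on the 3 s steady-state segment of each voluntary-contraction
trial. The bank follows the myoelectric pattern-recognition literature:
amplitude/energy descriptors (p2p, MAV, RMS, VAR, logD), first-difference
descriptors (DAMV, DVARV, wLen, M2), thresholded counts (ZERC, SSC, wAmp),
Welch-spectrum summaries (MeanF, MedF), Yule-Walker AR(4) coefficients and
the matching model cepstrum (ARCO1-4, Ceps1-4), a normalized amplitude
histogram (EMGH), and sample cardinality (Card).

Notation used in the docstrings: x_i are the segment samples, N the segment
length and dx_i = x_{i+1} - x_i the first differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.regression.linear_model import yule_walker

from .preprocessing import SteadySegment

__all__ = [
    "FeatureConfig",
    "DegenerateSegmentError",
    "amplitude_features",
    "difference_features",
    "threshold_counts",
    "spectral_features",
    "ar_and_cepstrum",
    "emg_histogram",
    "cardinality",
    "extract_feature_vector",
    "feature_names",
    "build_feature_table",
    "EmgFeatureExtractor",
]


class DegenerateSegmentError(ValueError):
    """Segment unusable for the requested feature (e.g. zero variance)."""


@dataclass
class FeatureConfig:
    deadzone_eps: float = 0.01  # mV threshold shared by ZERC/SSC/wAmp
    hist_bins: int = 9
    hist_range_sigmas: float = 3.0
    ar_order: int = 4
    cepstrum_order: int = 4
    welch_nperseg: int = 1024
    welch_overlap: float = 0.5
    card_tol: float = 1e-6  # mV
    log_floor: float = 1e-12  # mV, guards log(0) in logD

    def validate(self) -> None:
        if self.deadzone_eps < 0:
            raise ValueError("deadzone_eps must be >= 0")
        if self.hist_bins < 1 or self.hist_range_sigmas <= 0:
            raise ValueError("histogram parameters must be positive")
        if self.ar_order != 4 or self.cepstrum_order != 4:
            raise ValueError("AR and cepstrum orders are fixed at 4")
        if self.welch_nperseg < 2 or not 0 <= self.welch_overlap < 1:
            raise ValueError("invalid Welch parameters")
        if self.card_tol < 0 or self.log_floor <= 0:
            raise ValueError("card_tol must be >= 0 and log_floor > 0")


def _samples(segment) -> np.ndarray:
    x = segment.samples if isinstance(segment, SteadySegment) else np.asarray(segment, float)
    if x.size == 0:
        raise ValueError("empty segment")
    return np.asarray(x, dtype=float)


def amplitude_features(segment, cfg: FeatureConfig | None = None) -> Dict[str, float]:
    """p2p = max-min; MAV = mean|x|; RMS = sqrt(mean x^2);
    VAR = sum (x - mean)^2 / (N-1); logD = exp(mean log max(|x|, floor))."""
    cfg = cfg or FeatureConfig()
    x = _samples(segment)
    if x.size < 2:
        raise ValueError("amplitude features need N >= 2")
    return {
        "p2p": float(x.max() - x.min()),
        "MAV": float(np.mean(np.abs(x))),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "VAR": float(np.var(x, ddof=1)),
        "logD": float(np.exp(np.mean(np.log(np.maximum(np.abs(x), cfg.log_floor))))),
    }


def difference_features(segment, cfg: FeatureConfig | None = None) -> Dict[str, float]:
    """wLen = sum|dx|; DAMV = wLen/(N-1); DVARV = sum dx^2/(N-2); M2 = sum dx^2."""
    x = _samples(segment)
    n = x.size
    if n < 3:
        raise ValueError("difference features need N >= 3")
    dx = np.diff(x)
    m2 = float(np.sum(dx**2))
    return {
        "wLen": float(np.sum(np.abs(dx))),
        "DAMV": float(np.sum(np.abs(dx)) / (n - 1)),
        "DVARV": m2 / (n - 2),
        "M2": m2,
    }


def threshold_counts(segment, cfg: FeatureConfig | None = None) -> Dict[str, float]:
    """Deadzone-thresholded counts.

    ZERC counts sign changes with |x_i - x_{i+1}| >= eps; SSC counts interior
    samples with (x_i - x_{i-1})(x_i - x_{i+1}) >= eps; wAmp counts first
    differences with |dx| >= eps.
    """
    cfg = cfg or FeatureConfig()
    x = _samples(segment)
    if x.size < 3:
        raise ValueError("threshold counts need N >= 3")
    eps = cfg.deadzone_eps
    dx = np.diff(x)
    zerc = int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(dx) >= eps)))
    ssc = int(np.sum((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) >= eps))
    wamp = int(np.sum(np.abs(dx) >= eps))
    return {"ZERC": zerc, "SSC": ssc, "wAmp": wamp}


def _welch_psd(x: np.ndarray, fs: float, cfg: FeatureConfig):
    noverlap = int(round(cfg.welch_nperseg * cfg.welch_overlap))
    return sps.welch(
        x, fs=fs, window="hann", nperseg=cfg.welch_nperseg, noverlap=noverlap
    )


def spectral_features(segment, cfg: FeatureConfig | None = None) -> Dict[str, float]:
    """MeanF = sum f P / sum P; MedF = lowest f with cumulative PSD >= half total."""
    cfg = cfg or FeatureConfig()
    x = _samples(segment)
    if x.size < cfg.welch_nperseg:
        raise ValueError("segment shorter than one Welch block")
    fs = segment.fs if isinstance(segment, SteadySegment) else 1.0
    f, p = _welch_psd(x, fs, cfg)
    total = np.sum(p)
    if total <= 0:
        raise DegenerateSegmentError("zero-power segment has no spectral features")
    meanf = float(np.sum(f * p) / total)
    cum = np.cumsum(p)
    medf = float(f[int(np.searchsorted(cum, total / 2.0))])
    return {"MeanF": meanf, "MedF": medf}


def _ar_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """Yule-Walker AR coefficients, predictor convention x_t = sum a_k x_{t-k} + e."""
    rho, _sigma = yule_walker(x - x.mean(), order=order, method="mle")
    return np.asarray(rho, dtype=float)


def _ar_cepstrum(rho: np.ndarray, order: int) -> np.ndarray:
    """Cepstrum of the AR model spectrum via the LPC recursion.

    With polynomial coefficients a_k = -rho_k (A(z) = 1 + sum a_k z^-k):
    c_1 = -a_1 and c_n = -a_n - sum_{l<n} (1 - l/n) a_l c_{n-l}.
    """
    a = -rho
    c = np.zeros(order)
    for n in range(1, order + 1):
        acc = -a[n - 1]
        for l in range(1, n):
            acc -= (1.0 - l / n) * a[l - 1] * c[n - l - 1]
        c[n - 1] = acc
    return c


def ar_and_cepstrum(segment, cfg: FeatureConfig | None = None) -> Dict[str, float]:
    """AR(4) coefficients and the first four cepstral coefficients of the model."""
    cfg = cfg or FeatureConfig()
    x = _samples(segment)
    if x.size <= 8 * cfg.ar_order:
        raise ValueError("segment too short for AR(4) estimation")
    if np.ptp(x) == 0:
        raise DegenerateSegmentError("zero-variance segment has no AR model")
    rho = _ar_coefficients(x, cfg.ar_order)
    ceps = _ar_cepstrum(rho, cfg.cepstrum_order)
    out = {f"ARCO{k + 1}": float(rho[k]) for k in range(cfg.ar_order)}
    out.update({f"Ceps{k + 1}": float(ceps[k]) for k in range(cfg.cepstrum_order)})
    return out


def emg_histogram(segment, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Normalized amplitude histogram over +-hist_range_sigmas * SD(x).

    Counts are divided by N; samples outside the range are excluded, so the
    bin masses sum to <= 1. A zero-SD segment puts all mass in the centre bin.
    """
    cfg = cfg or FeatureConfig()
    x = _samples(segment)
    if x.size < 2:
        raise ValueError("histogram needs N >= 2")
    sd = float(np.std(x))
    out = np.zeros(cfg.hist_bins)
    if sd == 0.0:
        out[cfg.hist_bins // 2] = 1.0
        return out
    lim = cfg.hist_range_sigmas * sd
    counts, _edges = np.histogram(x, bins=cfg.hist_bins, range=(-lim, lim))
    return counts.astype(float) / x.size


def cardinality(segment, cfg: FeatureConfig | None = None) -> int:
    """Number of distinct sample values, identifying values within card_tol.

    Greedy pass over the sorted samples: a value starts a new cluster when it
    exceeds the current cluster anchor by more than the tolerance.
    """
    cfg = cfg or FeatureConfig()
    x = np.sort(_samples(segment))
    tol = cfg.card_tol
    if tol == 0.0:
        return int(np.unique(x).size)
    count = 1
    anchor = x[0]
    for v in x[1:]:
        if v - anchor > tol:
            count += 1
            anchor = v
    return int(count)


def feature_names(cfg: FeatureConfig | None = None) -> List[str]:
    """Column order of the expanded Full feature set (EMGH as EMGH_1..bins)."""
    cfg = cfg or FeatureConfig()
    names = [
        "p2p", "MAV", "RMS", "VAR", "DVARV", "DAMV", "logD",
        "ZERC", "SSC", "wLen", "wAmp", "M2", "MeanF", "MedF", "Card",
        "ARCO1", "ARCO2", "ARCO3", "ARCO4",
        "Ceps1", "Ceps2", "Ceps3", "Ceps4",
    ]
    names += [f"EMGH_{i + 1}" for i in range(cfg.hist_bins)]
    return names


def extract_feature_vector(
    segment, cfg: FeatureConfig | None = None
) -> Dict[str, float]:
    """Assemble the full named feature vector for one steady-state segment."""
    cfg = cfg or FeatureConfig()
    cfg.validate()
    out: Dict[str, float] = {}
    out.update(amplitude_features(segment, cfg))
    out.update(difference_features(segment, cfg))
    out.update(threshold_counts(segment, cfg))
    out.update(spectral_features(segment, cfg))
    out.update(ar_and_cepstrum(segment, cfg))
    out["Card"] = cardinality(segment, cfg)
    hist = emg_histogram(segment, cfg)
    for i, v in enumerate(hist):
        out[f"EMGH_{i + 1}"] = float(v)
    return {name: out[name] for name in feature_names(cfg)}


def build_feature_table(
    segments: Iterable[SteadySegment], cfg: FeatureConfig | None = None
) -> pd.DataFrame:
    """One row per (muscle, trial): id columns then the expanded feature bank."""
    cfg = cfg or FeatureConfig()
    rows = []
    for seg in segments:
        row = {
            "muscle_id": seg.muscle_id,
            "participant_id": seg.participant_id,
            "trial_index": seg.trial_index,
        }
        row.update(extract_feature_vector(seg, cfg))
        rows.append(row)
    return pd.DataFrame(rows)


class EmgFeatureExtractor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer mapping steady segments to the feature table."""

    def __init__(
        self,
        deadzone_eps: float = 0.01,
        hist_bins: int = 9,
        hist_range_sigmas: float = 3.0,
        welch_nperseg: int = 1024,
        welch_overlap: float = 0.5,
        card_tol: float = 1e-6,
        log_floor: float = 1e-12,
    ) -> None:
        self.deadzone_eps = deadzone_eps
        self.hist_bins = hist_bins
        self.hist_range_sigmas = hist_range_sigmas
        self.welch_nperseg = welch_nperseg
        self.welch_overlap = welch_overlap
        self.card_tol = card_tol
        self.log_floor = log_floor

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            deadzone_eps=self.deadzone_eps,
            hist_bins=self.hist_bins,
            hist_range_sigmas=self.hist_range_sigmas,
            welch_nperseg=self.welch_nperseg,
            welch_overlap=self.welch_overlap,
            card_tol=self.card_tol,
            log_floor=self.log_floor,
        )

    def fit(self, X: Iterable[SteadySegment], y=None) -> "EmgFeatureExtractor":
        self.feature_names_ = feature_names(self._config())
        return self

    def transform(self, X: Iterable[SteadySegment]) -> pd.DataFrame:
        return build_feature_table(X, self._config())
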