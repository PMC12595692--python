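"""Synthetic cohort generator for sEMG-based FES-responder modelling.

Emulates a small cervical-SCI cohort of the kind used to study muscle
response to functional electrical stimulation (FES) therapy: per-muscle
baseline surface-EMG recordings (one rest trial plus a few maximal
voluntary contraction trials), a longitudinal manual-muscle-testing (MMT)
trajectory over the therapy cycle, and participant/muscle clinical
covariates (AIS grade, neurological level of injury, myotome, etc.).

The EMG signal model is deliberately simple: band-shaped filtered Gaussian
noise standing in for the interference EMG, plus white sensor noise and a
60 Hz power-line component. It is a stand-in sufficient to exercise every
feature in the extraction bank, not a physiological motor-unit model.
Responder muscles receive a planted effect jointly in the spectrum (centre
frequency shift) and amplitude (gain ratio).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "InvalidConfigError",
    "SimConfig",
    "EmgTrial",
    "MmtTrajectory",
    "Participant",
    "Muscle",
    "Cohort",
    "simulate_emg_trial",
    "simulate_mmt_trajectory",
    "generate_cohort",
    "cohort_manifest",
]

AIS_GRADES = ("A", "B", "C", "D")
#: cervical levels usable as a neurological level of injury in this cohort
NLI_LEVELS = ("C2", "C3", "C4", "C5", "C6")
#: cervical myotomes innervating the recorded upper-extremity muscles
MYOTOME_LEVELS = ("C5", "C6", "C7", "C8")

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


class InvalidConfigError(ValueError):
    """Raised when a simulation or processing configuration is unusable."""


def _level_index(level: str) -> int:
    return int(level[1:])


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the emulated study: 17 participants with AIS grades
    distributed A/B/C/D = 2/5/2/8, 4-10 target muscles each, one 60 s rest
    trial and three 5 s MVC trials per muscle sampled at 4 kHz, ~30 MMT
    sessions across the therapy cycle, and ~33 % responder prevalence.
    """

    n_participants: int = 17
    muscles_min: int = 4
    muscles_max: int = 10
    mvc_trials: int = 3
    extra_trial_prob: float = 0.0  # probability of a 4th MVC attempt
    fs: float = 4000.0
    mvc_duration: float = 5.0
    rest_duration: float = 60.0
    n_sessions: int = 30
    responder_prevalence: float = 0.33
    ais_distribution: Dict[str, float] = field(
        default_factory=lambda: {"A": 2 / 17, "B": 5 / 17, "C": 2 / 17, "D": 8 / 17}
    )
    # EMG signal model
    base_spectral_center: float = 80.0  # Hz, non-responder interference EMG centre
    spectral_bandwidth: float = 120.0  # Hz, width of the band-shaped spectrum
    effect_medf_shift: float = 40.0  # Hz, responder spectral-centre shift
    effect_amp_gain: float = 1.5  # responder amplitude ratio
    base_amplitude: float = 0.02  # mV RMS of the muscle term at strength 0
    amplitude_per_grade: float = 0.03  # mV RMS added per MMT grade
    line_noise_amp: float = 0.005  # mV, 60 Hz sinusoid amplitude
    sensor_noise_sd: float = 0.004  # mV, white sensor noise SD
    # MMT trajectory model
    jitter_prob: float = 0.10  # per-session +-1 fluctuation probability
    responder_gain: int = 1  # minimum grades gained by a responder
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")
        if not (1 <= self.muscles_min <= self.muscles_max):
            raise InvalidConfigError("muscle count range invalid")
        if self.mvc_trials < 1:
            raise InvalidConfigError("mvc_trials must be >= 1")
        if self.fs <= 0 or self.mvc_duration <= 0 or self.rest_duration <= 0:
            raise InvalidConfigError("fs and durations must be strictly positive")
        if self.n_sessions < 2:
            raise InvalidConfigError("n_sessions must be >= 2")
        if not 0.0 <= self.responder_prevalence <= 1.0:
            raise InvalidConfigError("responder_prevalence must be in [0, 1]")
        if not 0.0 <= self.jitter_prob <= 1.0:
            raise InvalidConfigError("jitter_prob must be in [0, 1]")
        if not 0.0 <= self.extra_trial_prob <= 1.0:
            raise InvalidConfigError("extra_trial_prob must be in [0, 1]")
        if set(self.ais_distribution) != set(AIS_GRADES):
            raise InvalidConfigError("ais_distribution must cover grades A-D")
        if any(p < 0 for p in self.ais_distribution.values()):
            raise InvalidConfigError("ais_distribution proportions must be >= 0")
        if abs(sum(self.ais_distribution.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("ais_distribution must sum to 1")
        if self.responder_gain < 1:
            raise InvalidConfigError("responder_gain must be >= 1")


@dataclass
class EmgTrial:
    """One raw recording (rest or MVC) from one muscle."""

    samples: np.ndarray  # amplitude in mV
    fs: float  # Hz
    condition: str  # "rest" or "mvc"
    trial_index: int
    muscle_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("trial samples must be a non-empty 1-D series")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trial samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class MmtTrajectory:
    """Ordered (session, MMT score) pairs for one muscle across therapy."""

    sessions: np.ndarray  # strictly increasing, starting at 1
    scores: np.ndarray  # integers in 0..5

    def __post_init__(self) -> None:
        self.sessions = np.asarray(self.sessions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=int)
        if self.sessions.size != self.scores.size:
            raise ValueError("sessions and scores must have equal length")
        if self.sessions.size < 2:
            raise ValueError("trajectory needs at least two sessions")
        if self.sessions[0] < 1 or np.any(np.diff(self.sessions) <= 0):
            raise ValueError("sessions must be strictly increasing from >= 1")
        if self.scores.min() < 0 or self.scores.max() > 5:
            raise ValueError("MMT scores must lie in 0..5")

    def __len__(self) -> int:
        return int(self.sessions.size)


@dataclass
class Participant:
    participant_id: str
    ais: str
    nli: str
    months_post_injury: float
    lmn_category: Optional[str] = None


@dataclass
class Muscle:
    muscle_id: str
    participant_id: str
    myotome: str
    distance: int  # segments between myotome and NLI
    proximity: int  # 1 shoulder .. 4 finger
    baseline_mmt: int
    trials: List[EmgTrial] = field(default_factory=list)
    trajectory: Optional[MmtTrajectory] = None
    planted_label: str = NON_RESPONDER


@dataclass
class Cohort:
    config: SimConfig
    participants: List[Participant]
    muscles: List[Muscle]

    def muscles_of(self, participant_id: str) -> List[Muscle]:
        return [m for m in self.muscles if m.participant_id == participant_id]

    def participant(self, participant_id: str) -> Participant:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)


# ---------------------------------------------------------------------------
# signal model


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Generator keyed by (seed, *key): sub-entities reproducible on their own."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in key]])


def simulate_emg_trial(
    strength: int,
    condition: str,
    spectral_center: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    amp_gain: float = 1.0,
) -> EmgTrial:
    """Simulate one rest or MVC recording.

    MVC trials contain a band-shaped Gaussian-noise muscle term (4th-order
    Butterworth band edges at ``spectral_center`` +- bandwidth/2) scaled to an
    RMS of ``(base_amplitude + amplitude_per_grade * strength) * amp_gain``,
    plus white sensor noise and a 60 Hz line component. Rest trials contain
    only sensor noise and the line component.
    """
    cfg.validate()
    if condition not in ("rest", "mvc"):
        raise ValueError(f"unknown condition {condition!r}")
    if not 0 <= strength <= 5:
        raise ValueError("strength must be an MMT grade in 0..5")
    nyq = cfg.fs / 2.0
    if not (20.0 < spectral_center < min(450.0, nyq)):
        raise InvalidConfigError("spectral_center must lie inside (20, 450) Hz")

    duration = cfg.mvc_duration if condition == "mvc" else cfg.rest_duration
    n = int(round(duration * cfg.fs))
    if n <= 0:
        raise InvalidConfigError("non-positive trial length")
    t = np.arange(n) / cfg.fs

    phase = rng.uniform(0.0, 2.0 * np.pi)
    samples = cfg.sensor_noise_sd * rng.standard_normal(n)
    samples += cfg.line_noise_amp * np.sin(2.0 * np.pi * 60.0 * t + phase)

    if condition == "mvc":
        low = max(1.0, spectral_center - cfg.spectral_bandwidth / 2.0)
        high = min(nyq * 0.99, spectral_center + cfg.spectral_bandwidth / 2.0)
        sos = sps.butter(4, [low, high], btype="bandpass", fs=cfg.fs, output="sos")
        shaped = sps.sosfiltfilt(sos, rng.standard_normal(n))
        rms = np.sqrt(np.mean(shaped**2))
        target = (cfg.base_amplitude + cfg.amplitude_per_grade * strength) * amp_gain
        if rms > 0:
            samples += shaped * (target / rms)

    return EmgTrial(samples=samples, fs=cfg.fs, condition=condition, trial_index=0)


def simulate_mmt_trajectory(
    label: str,
    baseline: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> MmtTrajectory:
    """Simulate the per-session MMT strength profile of one muscle.

    Responders follow a monotone staircase gaining at least
    ``cfg.responder_gain`` grades over the cycle (capped at 5); both classes
    pick up transient +-1 fluctuations with probability ``cfg.jitter_prob``
    per session, emulating rater variability.
    """
    cfg.validate()
    if label not in (RESPONDER, NON_RESPONDER):
        raise ValueError(f"unknown label {label!r}")
    if not 0 <= baseline <= 5:
        raise ValueError("baseline must be an MMT grade in 0..5")
    if label == RESPONDER and baseline > 4:
        raise InvalidConfigError("responder target muscles require baseline <= 4")

    n = cfg.n_sessions
    sessions = np.arange(1, n + 1)
    base = np.full(n, baseline, dtype=int)

    if label == RESPONDER:
        max_gain = 5 - baseline
        gain = int(rng.integers(cfg.responder_gain, max_gain + 1)) if max_gain > cfg.responder_gain else cfg.responder_gain
        # one step per equal block of the central 60 % of the cycle: gains
        # confined to the first or last couple of sessions are not a
        # consistent trend (and no rank test could certify them)
        lo = max(2, int(round(0.2 * n)))
        hi = max(lo + 1, int(round(0.8 * n)))
        bounds = np.linspace(lo, hi + 1, gain + 1)
        step_at = np.array(
            [rng.integers(int(np.ceil(bounds[g])), int(bounds[g + 1])) for g in range(gain)]
        )
        for s in step_at:
            base[sessions >= s] += 1

    jitter = np.where(
        rng.random(n) < cfg.jitter_prob, rng.choice([-1, 1], size=n), 0
    )
    scores = np.clip(base + jitter, 0, 5)
    return MmtTrajectory(sessions=sessions, scores=scores)


# ---------------------------------------------------------------------------
# cohort assembly

#: sampling weights for covariates, shaped after the emulated cohort's tables
_NLI_WEIGHTS = {"C2": 1, "C3": 5, "C4": 7, "C5": 2, "C6": 2}
_MYOTOME_WEIGHTS = {"C5": 18, "C6": 48, "C7": 20, "C8": 46}
_BASELINE_MMT_WEIGHTS = {0: 16, 1: 33, 2: 21, 3: 31, 4: 31}


def _apportion(dist: Dict[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder apportionment of n items over the given proportions."""
    raw = {k: dist[k] * n for k in AIS_GRADES}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_rem = sorted(AIS_GRADES, key=lambda k: (counts[k] + 1 - raw[k], k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def _weighted_choice(rng: np.random.Generator, weights: Dict, keys=None):
    keys = list(weights) if keys is None else list(keys)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=w / w.sum()))]


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a full cohort with planted responder structure.

    Responder muscles receive a spectral-centre shift of
    ``cfg.effect_medf_shift`` Hz and an amplitude gain of
    ``cfg.effect_amp_gain`` in every MVC trial, plus an improving MMT
    trajectory; everything is deterministic in ``cfg.seed``.
    """
    cfg.validate()
    ais_counts = _apportion(cfg.ais_distribution, cfg.n_participants)
    grades: List[str] = [g for g in AIS_GRADES for _ in range(ais_counts[g])]

    participants: List[Participant] = []
    muscles: List[Muscle] = []
    for p_idx in range(cfg.n_participants):
        p_rng = _rng(cfg.seed, p_idx, 1)
        pid = f"P{p_idx + 1:02d}"
        nli = _weighted_choice(p_rng, _NLI_WEIGHTS)
        months = float(np.round(p_rng.lognormal(mean=np.log(20.0), sigma=1.0), 1))
        participants.append(
            Participant(participant_id=pid, ais=grades[p_idx], nli=nli, months_post_injury=months)
        )

        n_muscles = int(p_rng.integers(cfg.muscles_min, cfg.muscles_max + 1))
        for m_idx in range(n_muscles):
            m_rng = _rng(cfg.seed, p_idx, m_idx, 2)
            mid = f"{pid}-M{m_idx + 1:02d}"
            # myotome cannot sit above the level of injury for a target muscle
            candidates = [
                lv for lv in MYOTOME_LEVELS if _level_index(lv) >= _level_index(nli)
            ] or [MYOTOME_LEVELS[0]]
            myotome = _weighted_choice(m_rng, _MYOTOME_WEIGHTS, keys=candidates)
            distance = max(0, _level_index(myotome) - _level_index(nli))
            proximity = int(m_rng.integers(1, 5))
            baseline = _weighted_choice(m_rng, _BASELINE_MMT_WEIGHTS)
            label = (
                RESPONDER
                if m_rng.random() < cfg.responder_prevalence
                else NON_RESPONDER
            )
            is_resp = label == RESPONDER
            center = cfg.base_spectral_center + (cfg.effect_medf_shift if is_resp else 0.0)
            gain = cfg.effect_amp_gain if is_resp else 1.0

            trials: List[EmgTrial] = []
            rest = simulate_emg_trial(
                0, "rest", center, cfg, _rng(cfg.seed, p_idx, m_idx, 0, 3), amp_gain=gain
            )
            rest.trial_index, rest.muscle_id, rest.participant_id = 0, mid, pid
            trials.append(rest)
            n_mvc = cfg.mvc_trials + int(m_rng.random() < cfg.extra_trial_prob)
            for t_idx in range(1, n_mvc + 1):
                tr = simulate_emg_trial(
                    baseline,
                    "mvc",
                    center,
                    cfg,
                    _rng(cfg.seed, p_idx, m_idx, t_idx, 3),
                    amp_gain=gain,
                )
                tr.trial_index, tr.muscle_id, tr.participant_id = t_idx, mid, pid
                trials.append(tr)

            trajectory = simulate_mmt_trajectory(
                label, baseline, cfg, _rng(cfg.seed, p_idx, m_idx, 4)
            )
            muscles.append(
                Muscle(
                    muscle_id=mid,
                    participant_id=pid,
                    myotome=myotome,
                    distance=distance,
                    proximity=proximity,
                    baseline_mmt=baseline,
                    trials=trials,
                    trajectory=trajectory,
                    planted_label=label,
                )
            )

    return Cohort(config=replace(cfg), participants=participants, muscles=muscles)


def cohort_manifest(cohort: Cohort) -> Dict:
    """JSON-serializable manifest of a cohort, with per-trial signal digests.

    Two cohorts generated from identical configs serialize byte-identically
    (``json.dumps(cohort_manifest(c), sort_keys=True)``).
    """
    manifest: Dict = {
        "config": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in vars(cohort.config).items()
        },
        "participants": [vars(p).copy() for p in cohort.participants],
        "muscles": [],
    }
    for m in cohort.muscles:
        entry = {
            "muscle_id": m.muscle_id,
            "participant_id": m.participant_id,
            "myotome": m.myotome,
            "distance": m.distance,
            "proximity": m.proximity,
            "baseline_mmt": m.baseline_mmt,
            "planted_label": m.planted_label,
            "trajectory": {
                "sessions": m.trajectory.sessions.tolist(),
                "scores": m.trajectory.scores.tolist(),
            }
            if m.trajectory is not None
            else None,
            "trials": [
                {
                    "trial_index": t.trial_index,
                    "condition": t.condition,
                    "fs": t.fs,
                    "n_samples": int(t.samples.size),
                    "sha256": hashlib.sha256(
                        np.ascontiguousarray(t.samples).tobytes()
                    ).hexdigest(),
                }
                for t in m.trials
            ],
        }
        manifest["muscles"].append(entry)
    return manifest
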