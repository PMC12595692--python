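"""Responder labeling from MMT trajectories via Kendall's tau.

A muscle is a responder when its manual-muscle-testing scores show a
statistically reliable positive trend over therapy sessions: tau > 0 with
p < alpha (default 0.01). Scores are heavily tied ordinal grades, so the
tie-corrected tau-b is used. Muscles already at the MMT ceiling (baseline
score 5) are excluded before labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .simulate import NON_RESPONDER, RESPONDER, Cohort, MmtTrajectory

__all__ = [
    "LabelConfig",
    "LabelResult",
    "exclude_ceiling",
    "kendall_tau_b",
    "tau_p_value",
    "classify_responder",
    "label_cohort",
    "ResponderLabeler",
]


@dataclass
class LabelConfig:
    alpha: float = 0.01
    #: "exact_permutation", "asymptotic_tie_corrected", or "auto"
    #: (auto = exact below ``exact_below`` sessions, asymptotic otherwise)
    p_method: str = "auto"
    exact_below: int = 10

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.p_method not in ("auto", "exact_permutation", "asymptotic_tie_corrected"):
            raise ValueError(f"unknown p_method {self.p_method!r}")


@dataclass
class LabelResult:
    tau: float
    p_value: float
    label: str
    excluded: bool = False
    exclusion_reason: Optional[str] = None


def exclude_ceiling(baseline_mmt: int) -> bool:
    """Ceiling exclusion: a muscle already at the maximum grade cannot improve."""
    if not 0 <= int(baseline_mmt) <= 5:
        raise ValueError("baseline MMT must lie in 0..5")
    return int(baseline_mmt) == 5


def kendall_tau_b(trajectory: MmtTrajectory) -> float:
    """Tie-corrected tau-b between scores and session numbers.

    An all-tied score series (zero variance) is defined as tau = 0.
    """
    if len(trajectory) < 2:
        raise ValueError("trajectory needs at least two sessions")
    scores = trajectory.scores
    if np.all(scores == scores[0]):
        return 0.0
    tau, _p = stats.kendalltau(trajectory.sessions, scores, variant="b")
    return float(tau)


def _tau_numerator(scores: np.ndarray) -> int:
    """Concordance numerator S against an increasing session axis."""
    s = np.asarray(scores)
    diff = np.sign(s[None, :] - s[:, None])
    return int(np.triu(diff, k=1).sum())


def _exact_permutation_p(trajectory: MmtTrajectory) -> float:
    """Two-sided exact permutation p for tau-b.

    The tie structure of the scores is invariant under permutation, so the
    tau-b denominator is constant and the test can be run on the concordance
    numerator S. All n! orderings of the observed scores are enumerated
    (duplicate orderings occur with equal multiplicity, leaving the null
    distribution uniform).
    """
    from itertools import permutations

    scores = trajectory.scores
    s_obs = abs(_tau_numerator(scores))
    perms = np.array(list(permutations(scores.tolist())))
    # S for every permutation at once: sum of sign(s_j - s_i) over i < j
    n = scores.size
    iu, ju = np.triu_indices(n, k=1)
    s_all = np.sign(perms[:, ju] - perms[:, iu]).sum(axis=1)
    return float(np.mean(np.abs(s_all) >= s_obs))


def _asymptotic_p(trajectory: MmtTrajectory) -> float:
    _tau, p = stats.kendalltau(
        trajectory.sessions, trajectory.scores, variant="b", method="asymptotic"
    )
    return float(p)


def tau_p_value(trajectory: MmtTrajectory, cfg: LabelConfig | None = None) -> float:
    """Two-sided p-value for the tau trend; all-tied trajectories give p = 1."""
    cfg = cfg or LabelConfig()
    cfg.validate()
    scores = trajectory.scores
    if np.all(scores == scores[0]):
        return 1.0
    method = cfg.p_method
    if method == "auto":
        method = (
            "exact_permutation"
            if len(trajectory) < cfg.exact_below
            else "asymptotic_tie_corrected"
        )
    if method == "exact_permutation":
        return _exact_permutation_p(trajectory)
    return _asymptotic_p(trajectory)


def classify_responder(
    trajectory: MmtTrajectory,
    baseline_mmt: int,
    cfg: LabelConfig | None = None,
) -> LabelResult:
    """Ceiling exclusion, then the (tau > 0 and p < alpha) responder rule."""
    cfg = cfg or LabelConfig()
    cfg.validate()
    if exclude_ceiling(baseline_mmt):
        return LabelResult(
            tau=float("nan"),
            p_value=float("nan"),
            label=NON_RESPONDER,
            excluded=True,
            exclusion_reason="baseline MMT at ceiling (5)",
        )
    tau = kendall_tau_b(trajectory)
    p = tau_p_value(trajectory, cfg)
    label = RESPONDER if (tau > 0 and p < cfg.alpha) else NON_RESPONDER
    return LabelResult(tau=tau, p_value=p, label=label)


def label_cohort(cohort: Cohort, cfg: LabelConfig | None = None) -> pd.DataFrame:
    """Label every muscle; returns muscle_id, tau, p_value, label, excluded."""
    cfg = cfg or LabelConfig()
    rows = []
    for m in cohort.muscles:
        res = classify_responder(m.trajectory, m.baseline_mmt, cfg)
        rows.append(
            {
                "muscle_id": m.muscle_id,
                "participant_id": m.participant_id,
                "tau": res.tau,
                "p_value": res.p_value,
                "label": res.label,
                "excluded": res.excluded,
            }
        )
    return pd.DataFrame(rows)


class ResponderLabeler(BaseEstimator):
    """sklearn-style wrapper around the tau labeling rule.

    ``predict`` maps a sequence of (trajectory, baseline) pairs to labels.
    """

    def __init__(self, alpha: float = 0.01, p_method: str = "auto") -> None:
        self.alpha = alpha
        self.p_method = p_method

    def _config(self) -> LabelConfig:
        return LabelConfig(alpha=self.alpha, p_method=self.p_method)

    def fit(self, X=None, y=None) -> "ResponderLabeler":
        self.config_ = self._config()
        self.config_.validate()
        return self

    def predict(self, X: Iterable[tuple]) -> List[str]:
        cfg = self._config()
        return [classify_responder(traj, base, cfg).label for traj, base in X]
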