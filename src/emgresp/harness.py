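"""Leave-one-participant-out evaluation of responder classifiers.

Each fold holds out every trial of one participant; the remaining
participants' trials train the model. Feature curation (named subset, PCA,
or forward selection) and any standardization are fitted on the training
side only. Hyperparameter grids are small and fixed per classifier family;
the grid winner is chosen by nested, grouped cross-validated MCC on the
training side (a ``select_on_test`` mode mirrors picking the configuration
by test performance instead). Per-trial predictions are aggregated into one
muscle label by majority vote, with exact ties resolved to non-responder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .curation import (
    VarianceFractionPCA,
    feature_columns,
    forward_select,
    grouped_cv_mcc,
    select_named_set,
)
from .simulate import NON_RESPONDER, RESPONDER

__all__ = [
    "MODEL_FAMILIES",
    "ModelConfig",
    "PredictionRecord",
    "TrialDataset",
    "TrialVoteClassifier",
    "model_grid",
    "lopo_folds",
    "aggregate_votes",
    "run_lopo",
    "subgroup_run",
]

MODEL_FAMILIES = ("knn", "rf", "gb", "svm", "logistic")
#: families whose inputs are z-scored with training-fold statistics
_SCALED_FAMILIES = ("knn", "svm", "logistic")

SUBGROUPS = {
    "A-B": ("A", "B"),
    "C-D": ("C", "D"),
    "A-D": ("A", "B", "C", "D"),
}


@dataclass
class ModelConfig:
    family: str = "rf"
    seed: int = 0
    standardize: bool = True  # applies to distance/margin families only

    def validate(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class PredictionRecord:
    muscle_id: str
    participant_id: str
    trial_votes: List[str]
    final_label: str
    true_label: str


@dataclass
class TrialDataset:
    """Trial-level feature matrix with muscle/participant bookkeeping.

    ``X`` holds one row per MVC trial (feature columns only); ``y`` is the
    trial's muscle label (1 = responder); ``muscle_ids`` / ``participant_ids``
    align with the rows; ``ais`` maps participant id to AIS grade.
    """

    X: pd.DataFrame
    y: np.ndarray
    muscle_ids: np.ndarray
    participant_ids: np.ndarray
    ais: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.X)
        self.y = np.asarray(self.y, dtype=int)
        self.muscle_ids = np.asarray(self.muscle_ids)
        self.participant_ids = np.asarray(self.participant_ids)
        if not (self.y.size == self.muscle_ids.size == self.participant_ids.size == n):
            raise ValueError("dataset arrays must align with the feature rows")

    @classmethod
    def from_feature_table(
        cls,
        features: pd.DataFrame,
        muscle_labels: Dict[str, str],
        ais: Optional[Dict[str, str]] = None,
    ) -> "TrialDataset":
        """Build from a feature table with id columns plus a muscle->label map.

        Muscles absent from ``muscle_labels`` (e.g. ceiling-excluded) are
        dropped.
        """
        keep = features["muscle_id"].isin(muscle_labels)
        df = features.loc[keep].reset_index(drop=True)
        y = np.array(
            [1 if muscle_labels[m] == RESPONDER else 0 for m in df["muscle_id"]]
        )
        return cls(
            X=df[feature_columns(df)],
            y=y,
            muscle_ids=df["muscle_id"].to_numpy(),
            participant_ids=df["participant_id"].to_numpy(),
            ais=dict(ais or {}),
        )

    def restrict_participants(self, pids: Sequence[str]) -> "TrialDataset":
        mask = np.isin(self.participant_ids, list(pids))
        return TrialDataset(
            X=self.X.loc[mask].reset_index(drop=True),
            y=self.y[mask],
            muscle_ids=self.muscle_ids[mask],
            participant_ids=self.participant_ids[mask],
            ais={p: g for p, g in self.ais.items() if p in set(pids)},
        )


def model_grid(family: str, seed: int = 0, standardize: bool = True):
    """Ordered (name, factory) grid for one classifier family.

    KNN: k in 2..7 with Euclidean and cosine metrics, distance weighting;
    RF/GB: 100 and 200 estimators; SVM: linear and Gaussian kernels;
    logistic regression has no grid. Distance/margin families are wrapped
    with a training-fold StandardScaler when ``standardize`` is on.
    """
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")

    def wrap(est):
        if standardize and family in _SCALED_FAMILIES:
            return make_pipeline(StandardScaler(), est)
        return est

    grid: List[Tuple[str, Callable]] = []
    if family == "knn":
        for k in range(2, 8):
            for metric in ("euclidean", "cosine"):
                est = KNeighborsClassifier(n_neighbors=k, weights="distance", metric=metric)
                grid.append((f"knn(k={k},{metric})", lambda e=est: wrap(clone(e))))
    elif family == "rf":
        for n in (100, 200):
            est = RandomForestClassifier(n_estimators=n, random_state=seed)
            grid.append((f"rf(n={n})", lambda e=est: wrap(clone(e))))
    elif family == "gb":
        for n in (100, 200):
            est = GradientBoostingClassifier(n_estimators=n, random_state=seed)
            grid.append((f"gb(n={n})", lambda e=est: wrap(clone(e))))
    elif family == "svm":
        for kernel in ("linear", "rbf"):
            est = SVC(kernel=kernel, random_state=seed)
            grid.append((f"svm({kernel})", lambda e=est: wrap(clone(e))))
    else:
        est = LogisticRegression(max_iter=2000)
        grid.append(("logistic", lambda e=est: wrap(clone(e))))
    return grid


def lopo_folds(participant_ids: Sequence[str]):
    """One (held-out participant, train mask, test mask) triple per participant."""
    pids = np.asarray(participant_ids)
    uniq = sorted(np.unique(pids).tolist())
    if len(uniq) < 2:
        raise ValueError("leave-one-participant-out needs at least two participants")
    return [(p, pids != p, pids == p) for p in uniq]


def aggregate_votes(trial_votes: Sequence[str]) -> str:
    """Mode of trial predictions; an exact tie resolves to non-responder."""
    votes = list(trial_votes)
    if not votes:
        raise ValueError("no trial votes to aggregate")
    pos = sum(1 for v in votes if v == RESPONDER)
    return RESPONDER if pos > len(votes) - pos else NON_RESPONDER


class TrialVoteClassifier(ClassifierMixin, BaseEstimator):
    """Trial-level classifier with muscle-level majority-vote aggregation.

    Thin sklearn-style wrapper: ``fit``/``predict`` act on trials;
    ``predict_muscles`` groups trial predictions by muscle id and returns
    the vote-aggregated label per muscle.
    """

    def __init__(self, estimator: Optional[BaseEstimator] = None) -> None:
        self.estimator = estimator

    def fit(self, X, y) -> "TrialVoteClassifier":
        est = self.estimator if self.estimator is not None else LogisticRegression(max_iter=2000)
        self.estimator_ = clone(est)
        self.estimator_.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        self.classes_ = np.unique(np.asarray(y, dtype=int))
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator_.predict(np.asarray(X, dtype=float)), dtype=int)

    def predict_muscles(self, X, muscle_ids) -> Dict[str, Tuple[str, List[str]]]:
        muscle_ids = np.asarray(muscle_ids)
        trial_pred = self.predict(X)
        out: Dict[str, Tuple[str, List[str]]] = {}
        for mid in pd.unique(muscle_ids):
            votes = [
                RESPONDER if v == 1 else NON_RESPONDER
                for v in trial_pred[muscle_ids == mid]
            ]
            out[mid] = (aggregate_votes(votes), votes)
        return out


def _curate_fold(
    dataset: TrialDataset,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    featureset: str,
    fwd_columns: Optional[List[str]],
    fwd_splits: Optional[int],
    log: Dict,
) -> Tuple[np.ndarray, np.ndarray]:
    """Training-side-only curation; returns train/test design matrices."""
    if featureset == "PCA":
        reducer = VarianceFractionPCA(var_frac=0.90).fit(dataset.X[train_mask])
        log["n_components"] = reducer.n_components_
        return reducer.transform(dataset.X[train_mask]), reducer.transform(
            dataset.X[test_mask]
        )
    if featureset == "FWD":
        if fwd_columns is None:
            fwd_columns = forward_select(
                dataset.X[train_mask].reset_index(drop=True),
                dataset.y[train_mask],
                dataset.participant_ids[train_mask],
                muscle_ids=dataset.muscle_ids[train_mask],
                n_splits=fwd_splits,
            )
        log["selected_columns"] = list(fwd_columns)
        cols = fwd_columns or feature_columns(dataset.X)  # fall back to Full
        return (
            dataset.X.loc[train_mask, cols].to_numpy(),
            dataset.X.loc[test_mask, cols].to_numpy(),
        )
    sub = select_named_set(dataset.X, featureset)
    cols = list(sub.columns)
    log["selected_columns"] = cols
    return (
        dataset.X.loc[train_mask, cols].to_numpy(),
        dataset.X.loc[test_mask, cols].to_numpy(),
    )


def run_lopo(
    dataset: TrialDataset,
    featureset: str = "Full",
    model: ModelConfig | str = "rf",
    select_on_test: bool = False,
    inner_splits: int = 5,
    fwd_splits: Optional[int] = None,
    fwd_global: bool = False,
) -> Tuple[List[PredictionRecord], Dict]:
    """LOPO evaluation of one (feature set, classifier family) combination.

    Returns the per-muscle prediction records and a run log recording each
    fold's curation outcome and grid winner. Folds whose training side has a
    single class are skipped with a diagnostic entry.
    """
    cfg = ModelConfig(family=model) if isinstance(model, str) else model
    cfg.validate()
    grid = model_grid(cfg.family, seed=cfg.seed, standardize=cfg.standardize)

    global_fwd_cols: Optional[List[str]] = None
    if featureset == "FWD" and fwd_global:
        global_fwd_cols = forward_select(
            dataset.X,
            dataset.y,
            dataset.participant_ids,
            muscle_ids=dataset.muscle_ids,
            n_splits=fwd_splits,
        )

    records: List[PredictionRecord] = []
    run_log: Dict = {"featureset": featureset, "family": cfg.family, "folds": []}
    for held_out, train_mask, test_mask in lopo_folds(dataset.participant_ids):
        fold_log: Dict = {"participant": held_out}
        if np.unique(dataset.y[train_mask]).size < 2:
            fold_log["skipped"] = "single-class training labels"
            run_log["folds"].append(fold_log)
            continue
        Xtr, Xte = _curate_fold(
            dataset, train_mask, test_mask, featureset, global_fwd_cols, fwd_splits, fold_log
        )
        ytr = dataset.y[train_mask]

        if len(grid) == 1:
            winner_name, winner_factory = grid[0]
        elif select_on_test:
            best = None
            yte_muscle = {
                m: RESPONDER if dataset.y[test_mask][dataset.muscle_ids[test_mask] == m][0] else NON_RESPONDER
                for m in pd.unique(dataset.muscle_ids[test_mask])
            }
            for name, factory in grid:
                clf = TrialVoteClassifier(factory()).fit(Xtr, ytr)
                preds = clf.predict_muscles(Xte, dataset.muscle_ids[test_mask])
                hits = sum(preds[m][0] == yte_muscle[m] for m in preds)
                if best is None or hits > best[0]:
                    best = (hits, name, factory)
            _, winner_name, winner_factory = best
        else:
            best = None
            for name, factory in grid:
                score = grouped_cv_mcc(
                    Xtr,
                    ytr,
                    dataset.participant_ids[train_mask],
                    dataset.muscle_ids[train_mask],
                    factory,
                    n_splits=inner_splits,
                )
                if best is None or score > best[0]:
                    best = (score, name, factory)
            _, winner_name, winner_factory = best
        fold_log["grid_winner"] = winner_name

        clf = TrialVoteClassifier(winner_factory()).fit(Xtr, ytr)
        preds = clf.predict_muscles(Xte, dataset.muscle_ids[test_mask])
        for mid, (final, votes) in preds.items():
            truth = dataset.y[test_mask][dataset.muscle_ids[test_mask] == mid][0]
            records.append(
                PredictionRecord(
                    muscle_id=str(mid),
                    participant_id=held_out,
                    trial_votes=votes,
                    final_label=final,
                    true_label=RESPONDER if truth else NON_RESPONDER,
                )
            )
        run_log["folds"].append(fold_log)
    return records, run_log


def subgroup_run(
    dataset: TrialDataset,
    subgroup: str = "A-D",
    featureset: str = "Full",
    model: ModelConfig | str = "rf",
    **kwargs,
) -> Tuple[List[PredictionRecord], Dict]:
    """LOPO restricted to an AIS motor-completeness subgroup (A-B, C-D, A-D)."""
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    grades = SUBGROUPS[subgroup]
    pids = [p for p, g in dataset.ais.items() if g in grades]
    if len(set(pids) & set(dataset.participant_ids)) < 2:
        raise ValueError(f"subgroup {subgroup} has fewer than two participants")
    sub = dataset.restrict_participants(pids)
    records, log = run_lopo(sub, featureset=featureset, model=model, **kwargs)
    log["subgroup"] = subgroup
    return records, log
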