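"""Curated feature sets and leakage-safe dimensionality reduction.

Four curated sEMG sets are derived from the Full 24-feature bank —
Hudgins (MAV, ZERC, SSC, wLen), MD (ZERC, SSC, wAmp, MedF, EMGH, ARCO3,
features separating motor-neuron damage phenotypes), PCA (Full set
z-scored and projected onto the components explaining 90 % variance) and
FWD (greedy forward selection on the Full set) — plus the clinical-variable
candidate set used for the comparison models.

PCA statistics and forward-selection decisions are fitted on training rows
only, so the curation step can sit inside an outer cross-validation fold
without evaluation-fold leakage.
"""

from __future__ import annotations

import warnings
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .metrics import ConfusionCounts, mcc as _mcc
from .simulate import Cohort

__all__ = [
    "NAMED_FEATURE_SETS",
    "CLINICAL_CANDIDATES",
    "select_named_set",
    "expand_columns",
    "pca_reduce",
    "forward_select",
    "grouped_cv_mcc",
    "VarianceFractionPCA",
    "ForwardFeatureSelector",
    "clinical_table",
]

#: scalar members of each fixed named set; "EMGH" expands to its bins
NAMED_FEATURE_SETS: Dict[str, List[str]] = {
    "Hudgins": ["MAV", "ZERC", "SSC", "wLen"],
    "MD": ["ZERC", "SSC", "wAmp", "MedF", "EMGH", "ARCO3"],
}

CLINICAL_CANDIDATES = [
    "months_post_injury",
    "ais",
    "nli",
    "myotome",
    "distance",
    "baseline_mmt",
    "proximity",
]

_ID_COLUMNS = ("muscle_id", "participant_id", "trial_index")


def expand_columns(names: Sequence[str], available: Sequence[str]) -> List[str]:
    """Expand composite names (EMGH -> EMGH_1..k) against available columns."""
    out: List[str] = []
    for name in names:
        if name in available:
            out.append(name)
            continue
        bins = sorted(
            (c for c in available if c.startswith(f"{name}_")),
            key=lambda c: int(c.rsplit("_", 1)[1]),
        )
        if not bins:
            raise KeyError(f"feature column {name!r} missing from matrix")
        out.extend(bins)
    return out


def feature_columns(matrix: pd.DataFrame) -> List[str]:
    return [c for c in matrix.columns if c not in _ID_COLUMNS]


def select_named_set(matrix: pd.DataFrame, name: str) -> pd.DataFrame:
    """Column subset for a fixed named set, in spec order; Full is identity."""
    cols = feature_columns(matrix)
    if name == "Full":
        wanted = cols
    elif name in NAMED_FEATURE_SETS:
        wanted = expand_columns(NAMED_FEATURE_SETS[name], cols)
    elif name == "Clinical":
        wanted = expand_columns(CLINICAL_CANDIDATES, cols)
    else:
        raise KeyError(f"unknown feature set {name!r}")
    ids = [c for c in _ID_COLUMNS if c in matrix.columns]
    return matrix[ids + wanted]


class VarianceFractionPCA(TransformerMixin, BaseEstimator):
    """z-score + PCA keeping the smallest k with cumulative variance >= var_frac.

    Zero-variance training columns are dropped with a warning before
    standardization. All statistics come from the rows passed to ``fit``.
    """

    def __init__(self, var_frac: float = 0.90) -> None:
        self.var_frac = var_frac

    def fit(self, X, y=None) -> "VarianceFractionPCA":
        X = np.asarray(X, dtype=float)
        keep = X.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance column(s) before PCA",
                stacklevel=2,
            )
        if not keep.any():
            raise ValueError("no non-constant columns to decompose")
        self.keep_mask_ = keep
        self.scaler_ = StandardScaler().fit(X[:, keep])
        pca = PCA().fit(self.scaler_.transform(X[:, keep]))
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.var_frac - 1e-9) + 1)
        self.n_components_ = min(k, cum.size)
        self.explained_variance_fraction_ = float(cum[self.n_components_ - 1])
        self.pca_ = pca
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        X = np.asarray(X, dtype=float)
        z = self.scaler_.transform(X[:, self.keep_mask_])
        return self.pca_.transform(z)[:, : self.n_components_]


def pca_reduce(
    train_matrix, eval_matrix, var_frac: float = 0.90
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Fit a variance-fraction PCA on training rows, project both matrices."""
    reducer = VarianceFractionPCA(var_frac=var_frac).fit(train_matrix)
    return (
        reducer.transform(train_matrix),
        reducer.transform(eval_matrix),
        reducer.n_components_,
    )


def _default_model_factory():
    return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))


def _vote(labels: np.ndarray) -> int:
    """Majority vote over trial predictions; exact tie -> non-responder (0)."""
    pos = int(np.sum(labels == 1))
    return 1 if pos > labels.size - pos else 0


def grouped_cv_mcc(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    muscle_ids: np.ndarray,
    model_factory: Callable,
    n_splits: Optional[int] = None,
) -> float:
    """Muscle-level MCC of grouped-CV predictions pooled across folds.

    Splits by participant group (leave-one-group-out when ``n_splits`` is
    None), predicts every held-out trial, aggregates trial votes per muscle,
    and scores the pooled muscle labels with MCC. Folds whose training side
    is single-class are skipped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    muscle_ids = np.asarray(muscle_ids)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("grouped CV needs at least two groups")
    k = uniq.size if n_splits is None else min(n_splits, uniq.size)
    pred_by_muscle: Dict = {}
    true_by_muscle: Dict = {}
    for train_idx, test_idx in GroupKFold(n_splits=k).split(X, y, groups):
        if np.unique(y[train_idx]).size < 2:
            continue
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        pred = np.asarray(model.predict(X[test_idx]))
        for mid in np.unique(muscle_ids[test_idx]):
            mask = muscle_ids[test_idx] == mid
            pred_by_muscle[mid] = _vote(pred[mask])
            true_by_muscle[mid] = int(y[test_idx][mask][0])
    if not pred_by_muscle:
        raise ValueError("all CV folds degenerate (single-class training labels)")
    tp = fp = fn = tn = 0
    for mid, p in pred_by_muscle.items():
        t = true_by_muscle[mid]
        tp += p and t
        fp += p and not t
        fn += (not p) and t
        tn += (not p) and (not t)
    return _mcc(ConfusionCounts(tp, fp, fn, tn))


def forward_select(
    train_data: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    model_factory: Callable | None = None,
    muscle_ids: Optional[np.ndarray] = None,
    n_splits: Optional[int] = None,
) -> List[str]:
    """Greedy forward selection maximizing nested grouped-CV MCC.

    Starts from the empty set (score 0) and at each step adds the column
    with the best nested MCC, stopping when no candidate strictly improves
    the score. Score ties break lexicographically on the column name, so
    the procedure is deterministic.
    """
    model_factory = model_factory or _default_model_factory
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("forward selection needs both classes in the training labels")
    if muscle_ids is None:
        muscle_ids = np.arange(len(train_data))
    cols = list(train_data.columns)
    selected: List[str] = []
    best_score = 0.0
    while True:
        remaining = [c for c in cols if c not in selected]
        if not remaining:
            break
        scores = {}
        for c in sorted(remaining):
            trial = selected + [c]
            scores[c] = grouped_cv_mcc(
                train_data[trial].to_numpy(),
                labels,
                groups,
                muscle_ids,
                model_factory,
                n_splits=n_splits,
            )
        winner = max(sorted(scores), key=lambda c: scores[c])
        if scores[winner] <= best_score + 1e-12:
            break
        selected.append(winner)
        best_score = scores[winner]
    return selected


class ForwardFeatureSelector(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`forward_select`.

    ``fit`` expects a feature DataFrame (or array), labels, and participant
    groups; selected column names land in ``selected_columns_``.
    """

    def __init__(
        self,
        model_factory: Callable | None = None,
        n_splits: Optional[int] = None,
    ) -> None:
        self.model_factory = model_factory
        self.n_splits = n_splits

    def fit(self, X, y, groups=None, muscle_ids=None) -> "ForwardFeatureSelector":
        X = pd.DataFrame(X)
        if groups is None:
            raise ValueError("forward selection requires participant groups")
        self.selected_columns_ = forward_select(
            X,
            np.asarray(y),
            np.asarray(groups),
            model_factory=self.model_factory,
            muscle_ids=muscle_ids,
            n_splits=self.n_splits,
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "selected_columns_")
        return pd.DataFrame(X)[self.selected_columns_]


_AIS_ORDER = {"A": 0, "B": 1, "C": 2, "D": 3}


def clinical_table(cohort: Cohort, one_hot: bool = False) -> pd.DataFrame:
    """Per-muscle clinical covariates, ordinally encoded by default.

    AIS A<B<C<D and the cervical levels C2<..<C8 carry monotone trends in
    responder prevalence, so they are encoded as ordered integers; pass
    ``one_hot=True`` for indicator encoding of the categoricals instead.
    """
    rows = []
    for m in cohort.muscles:
        p = cohort.participant(m.participant_id)
        rows.append(
            {
                "muscle_id": m.muscle_id,
                "participant_id": m.participant_id,
                "months_post_injury": p.months_post_injury,
                "ais": p.ais,
                "nli": p.nli,
                "myotome": m.myotome,
                "distance": m.distance,
                "baseline_mmt": m.baseline_mmt,
                "proximity": m.proximity,
            }
        )
    df = pd.DataFrame(rows)
    if one_hot:
        return pd.get_dummies(df, columns=["ais", "nli", "myotome"], dtype=float)
    df["ais"] = df["ais"].map(_AIS_ORDER).astype(float)
    df["nli"] = df["nli"].str[1:].astype(float)
    df["myotome"] = df["myotome"].str[1:].astype(float)
    return df
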