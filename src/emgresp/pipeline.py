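"""End-to-end convenience layer: cohort -> features -> labels -> dataset.

Chains the preprocessing, steady-segment selection, feature extraction and
tau labeling stages so that a simulated (or loaded) cohort can be turned
into a trial-level dataset ready for the LOPO harness in one call.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import pandas as pd

from .curation import clinical_table
from .features import FeatureConfig, build_feature_table
from .harness import TrialDataset
from .labeling import LabelConfig, label_cohort
from .preprocessing import PrepConfig, extract_steady_segment, preprocess
from .simulate import Cohort

__all__ = ["cohort_features", "dataset_from_cohort"]


def cohort_features(
    cohort: Cohort,
    prep_cfg: Optional[PrepConfig] = None,
    feat_cfg: Optional[FeatureConfig] = None,
) -> pd.DataFrame:
    """Feature table over every MVC trial of the cohort.

    Each trial is preprocessed (bandpass + notch), its lowest-SD steady
    segment is cut, and the full feature bank is computed on that segment.
    """
    prep_cfg = prep_cfg or PrepConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    segments = []
    for m in cohort.muscles:
        for t in m.trials:
            if t.condition != "mvc":
                continue
            segments.append(extract_steady_segment(preprocess(t, prep_cfg), prep_cfg))
    return build_feature_table(segments, feat_cfg)


def dataset_from_cohort(
    cohort: Cohort,
    prep_cfg: Optional[PrepConfig] = None,
    feat_cfg: Optional[FeatureConfig] = None,
    label_cfg: Optional[LabelConfig] = None,
    clinical: bool = False,
) -> Tuple[TrialDataset, pd.DataFrame]:
    """Build the harness dataset plus the label table for a cohort.

    Labels come from the Kendall-tau rule on each muscle's MMT trajectory;
    ceiling-excluded muscles are dropped. With ``clinical=True`` the design
    matrix holds the encoded clinical covariates (replicated per trial)
    instead of the sEMG features.
    """
    labels = label_cohort(cohort, label_cfg or LabelConfig())
    kept = labels.loc[~labels["excluded"]]
    label_map: Dict[str, str] = dict(zip(kept["muscle_id"], kept["label"]))
    features = cohort_features(cohort, prep_cfg, feat_cfg)
    if clinical:
        clin = clinical_table(cohort)
        features = features[["muscle_id", "participant_id", "trial_index"]].merge(
            clin, on=["muscle_id", "participant_id"], how="left"
        )
    ais = {p.participant_id: p.ais for p in cohort.participants}
    return TrialDataset.from_feature_table(features, label_map, ais=ais), labels
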