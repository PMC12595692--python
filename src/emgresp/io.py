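"""Plain-text persistence for cohorts, features, labels and predictions.

Layout written by :func:`write_cohort` under a root directory:

- ``manifest.json`` — config, participants, muscle metadata, trial index
- ``participants.csv`` / ``muscles.csv`` / ``mmt_log.csv`` — metadata tables
- ``trials/<muscle_id>_t<k>.txt`` — two-column delimited text
  (``time_s`` and ``amplitude_mV``) per recording
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .harness import PredictionRecord
from .simulate import (
    Cohort,
    EmgTrial,
    MmtTrajectory,
    Muscle,
    Participant,
    SimConfig,
    cohort_manifest,
)

__all__ = ["write_cohort", "read_cohort", "write_predictions", "read_predictions"]


def _trial_path(root: Path, muscle_id: str, trial_index: int) -> Path:
    return root / "trials" / f"{muscle_id}_t{trial_index}.txt"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the cohort as delimited text plus a JSON manifest."""
    root = Path(out_dir)
    (root / "trials").mkdir(parents=True, exist_ok=True)

    manifest = cohort_manifest(cohort)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    pd.DataFrame([vars(p) for p in cohort.participants]).to_csv(
        root / "participants.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "muscle_id": m.muscle_id,
                "participant_id": m.participant_id,
                "myotome": m.myotome,
                "distance": m.distance,
                "proximity": m.proximity,
                "baseline_mmt": m.baseline_mmt,
                "planted_label": m.planted_label,
            }
            for m in cohort.muscles
        ]
    ).to_csv(root / "muscles.csv", index=False)

    mmt_rows = []
    for m in cohort.muscles:
        for s, sc in zip(m.trajectory.sessions, m.trajectory.scores):
            mmt_rows.append({"muscle_id": m.muscle_id, "session": int(s), "score": int(sc)})
    pd.DataFrame(mmt_rows).to_csv(root / "mmt_log.csv", index=False)

    for m in cohort.muscles:
        for t in m.trials:
            path = _trial_path(root, m.muscle_id, t.trial_index)
            time_s = np.arange(t.samples.size) / t.fs
            np.savetxt(
                path,
                np.column_stack([time_s, t.samples]),
                fmt="%.6f\t%.8f",
                header="time_s\tamplitude_mV",
                comments="",
            )
    return root


def read_cohort(root: str | Path) -> Cohort:
    """Reload a cohort written by :func:`write_cohort` (signals included)."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    cfg = SimConfig(**manifest["config"])
    participants = [Participant(**p) for p in manifest["participants"]]
    muscles: List[Muscle] = []
    for entry in manifest["muscles"]:
        trials: List[EmgTrial] = []
        for tr in entry["trials"]:
            data = np.loadtxt(
                _trial_path(root, entry["muscle_id"], tr["trial_index"]), skiprows=1
            )
            trials.append(
                EmgTrial(
                    samples=data[:, 1],
                    fs=tr["fs"],
                    condition=tr["condition"],
                    trial_index=tr["trial_index"],
                    muscle_id=entry["muscle_id"],
                    participant_id=entry["participant_id"],
                )
            )
        traj = entry["trajectory"]
        muscles.append(
            Muscle(
                muscle_id=entry["muscle_id"],
                participant_id=entry["participant_id"],
                myotome=entry["myotome"],
                distance=entry["distance"],
                proximity=entry["proximity"],
                baseline_mmt=entry["baseline_mmt"],
                trials=trials,
                trajectory=MmtTrajectory(traj["sessions"], traj["scores"])
                if traj
                else None,
                planted_label=entry["planted_label"],
            )
        )
    return Cohort(config=cfg, participants=participants, muscles=muscles)


def write_predictions(records: List[PredictionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "muscle_id": r.muscle_id,
                "participant_id": r.participant_id,
                "trial_votes": "|".join(r.trial_votes),
                "final_label": r.final_label,
                "true_label": r.true_label,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_predictions(path: str | Path) -> List[PredictionRecord]:
    df = pd.read_csv(path)
    return [
        PredictionRecord(
            muscle_id=str(row.muscle_id),
            participant_id=str(row.participant_id),
            trial_votes=str(row.trial_votes).split("|"),
            final_label=row.final_label,
            true_label=row.true_label,
        )
        for row in df.itertuples()
    ]
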