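"""Plain-text cohort I/O.

Directory layout (all CSV/JSON, inspectable with any text tool):

* ``ts_<subject>.csv`` — one per subject; first column ``roi`` (region
  name), remaining columns the timepoints.
* ``gm.csv``, ``wm.csv``, ``fa.csv``, ``rd.csv``, ``md.csv`` — subjects x
  ROIs; first column ``subject``, remaining columns ``<ROI>_<FEATURE>``.
* ``labels.csv`` — columns ``subject``, ``label`` (binary).
* ``ground_truth.json`` — written by the simulator only: the injected
  effect map (1-based ROI indices).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import SCALAR_MODALITIES, GroundTruth, MultimodalCohort


def _roi_names(n_roi: int) -> list[str]:
    from .features import aal90_names

    return aal90_names() if n_roi == 90 else [f"ROI{i + 1}" for i in range(n_roi)]


def write_cohort(
    cohort: MultimodalCohort,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roi_names = _roi_names(cohort.n_roi)
    for idx, sid in enumerate(cohort.subject_ids):
        df = pd.DataFrame(
            cohort.timeseries[idx],
            columns=[f"t{t + 1}" for t in range(cohort.timeseries.shape[2])],
        )
        df.insert(0, "roi", roi_names)
        df.to_csv(out / f"ts_{sid}.csv", index=False)
    for mod in SCALAR_MODALITIES:
        df = pd.DataFrame(
            cohort.scalars[mod],
            columns=[f"{r}_{mod.upper()}" for r in roi_names],
        )
        df.insert(0, "subject", cohort.subject_ids)
        df.to_csv(out / f"{mod}.csv", index=False)
    pd.DataFrame({"subject": cohort.subject_ids, "label": cohort.labels}).to_csv(
        out / "labels.csv", index=False
    )
    if truth is not None:
        payload = truth.to_dict()
        if seed is not None:
            payload["seed"] = seed
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    return out


def read_cohort(in_dir: str | Path) -> MultimodalCohort:
    src = Path(in_dir)
    labels_path = src / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"no labels.csv under {src}")
    labels_df = pd.read_csv(labels_path)
    if {"subject", "label"} - set(labels_df.columns):
        raise ValueError("labels.csv must have columns 'subject' and 'label'")
    if labels_df["label"].nunique() != 2:
        raise ValueError(
            f"binary design required; labels.csv has classes {sorted(labels_df['label'].unique())}"
        )
    subjects = labels_df["subject"].astype(str).tolist()

    ts_files = {p.stem[3:]: p for p in src.glob("ts_*.csv")}
    missing = sorted(set(subjects) - set(ts_files))
    extra = sorted(set(ts_files) - set(subjects))
    if missing or extra:
        raise ValueError(
            f"time-series/label subject mismatch: missing {missing}, unlabelled {extra}"
        )

    timeseries = None
    for i, sid in enumerate(subjects):
        df = pd.read_csv(ts_files[sid], float_precision="round_trip")
        vals = df.drop(columns=["roi"]).to_numpy(dtype=float)
        if timeseries is None:
            timeseries = np.empty((len(subjects), *vals.shape))
        if vals.shape != timeseries.shape[1:]:
            raise ValueError(
                f"{ts_files[sid].name}: shape {vals.shape} disagrees with "
                f"{tuple(timeseries.shape[1:])} of earlier subjects"
            )
        timeseries[i] = vals
    n_roi = timeseries.shape[1]

    scalars = {}
    for mod in SCALAR_MODALITIES:
        path = src / f"{mod}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing scalar modality file {path.name}")
        df = pd.read_csv(path, float_precision="round_trip")
        mod_subjects = df["subject"].astype(str).tolist()
        if set(mod_subjects) != set(subjects):
            diff = sorted(set(mod_subjects) ^ set(subjects))
            raise ValueError(f"{path.name}: subject set differs from labels.csv: {diff}")
        df = df.set_index("subject").loc[subjects]
        vals = df.to_numpy(dtype=float)
        if vals.shape[1] != n_roi:
            raise ValueError(
                f"{path.name}: {vals.shape[1]} ROIs but time series have {n_roi}"
            )
        scalars[mod] = vals

    return MultimodalCohort(
        timeseries=timeseries,
        scalars=scalars,
        labels=labels_df["label"].to_numpy(),
        subject_ids=subjects,
    )
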