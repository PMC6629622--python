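"""CSV/JSON readers and writers for the fixed pipeline formats.

All files are UTF-8, RFC-4180 CSV with "." decimals. Formats:

* monitoring CSV (long, per second):
  ``patient_id,t,resp_rate,etco2,rel_amplitude,waveform_present,artifact,
  spo2,pulse_detected,tcco2``
* intervals CSV: ``patient_id,state,start_s,end_s`` (half-open seconds)
* covariate CSV: one row per patient
* distance CSV: square matrix with patient_id header row/column, plus a
  JSON sidecar recording the metric and the pooled marginal weights.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DissimilarityMatrix

_BOOL_COLS = ("waveform_present", "artifact", "pulse_detected")


def read_monitoring_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            ).astype(bool)
    return df


def write_monitoring_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_covariates_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_intervals_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"patient_id", "state", "start_s", "end_s"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"intervals CSV missing columns {sorted(missing)}")
    return df


def write_sequences_csv(seqs, path: str | Path) -> None:
    """Long per-second state CSV: patient_id,t,state."""
    frames = [
        pd.DataFrame(
            {"patient_id": s.patient_id, "t": np.arange(len(s)), "state": s.states}
        )
        for s in seqs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_distance_csv(D: DissimilarityMatrix, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(D.values, index=D.ids, columns=D.ids).to_csv(
        path, index_label="patient_id"
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "metric": D.metric,
                "n_intervals": D.n_intervals,
                "marginal": D.marginal,
                "n": D.n,
            },
            indent=2,
        )
    )


def read_distance_csv(path: str | Path) -> DissimilarityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return DissimilarityMatrix(
        ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        metric=meta.get("metric", "unknown"),
        marginal=meta.get("marginal", {}),
        n_intervals=meta.get("n_intervals", 1),
    )
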