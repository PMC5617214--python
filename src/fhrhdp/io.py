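"""Plain-text readers and writers for recordings, metadata and feature tables.

Recordings travel as one-column CSV files (``fhr_bpm``, 4 Hz, 0 = missing)
with an optional sidecar CSV (``record_id, ph``) carrying the umbilical-cord
pH outcome.  Feature tables are CSVs with ``record_id, segment_index, u``
followed by the 14 canonical feature columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classify import HEALTHY, UNHEALTHY, RecordingFeatures
from .features import FEATURE_NAMES
from .preprocess import RawRecording


def read_recording_csv(path: str | Path, record_id: str | None = None,
                       ph: float | None = None) -> RawRecording:
    df = pd.read_csv(path)
    col = "fhr_bpm" if "fhr_bpm" in df.columns else df.columns[0]
    rid = record_id if record_id is not None else Path(path).stem
    return RawRecording(samples=df[col].to_numpy(dtype=float),
                        record_id=rid, ph=ph)


def write_recording_csv(path: str | Path, rec: RawRecording) -> None:
    pd.DataFrame({"fhr_bpm": rec.samples}).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    return {str(r.record_id): float(r.ph) for r in df.itertuples()}


def write_feature_table(path: str | Path, rows: list[dict]) -> None:
    """Rows: {record_id, segment_index, u, <14 feature values>}."""
    cols = ["record_id", "segment_index", "u", *FEATURE_NAMES]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def read_feature_table(
    path: str | Path, labels: dict[str, str] | None = None,
) -> list[RecordingFeatures]:
    """Load a feature CSV back into per-recording tables.

    ``labels`` maps record_id to "healthy"/"unhealthy"; unlabeled recordings
    get label -1.
    """
    df = pd.read_csv(path)
    out = []
    for rid, grp in df.groupby("record_id", sort=True):
        grp = grp.sort_values("segment_index")
        lab = -1
        if labels is not None and str(rid) in labels:
            lab = HEALTHY if labels[str(rid)] == "healthy" else UNHEALTHY
        out.append(RecordingFeatures(
            record_id=str(rid),
            X=grp[list(FEATURE_NAMES)].to_numpy(dtype=float),
            u=grp["u"].to_numpy(dtype=float),
            label=lab,
        ))
    return out
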