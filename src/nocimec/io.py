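"""CSV/JSON interchange and run configuration.

Dialects (comma separator, '.' decimal, UTF-8, times in seconds from
record start):

* waveforms — ``time,ecg,abp,ppg`` with an optional companion
  annotation CSV holding a single ``r_time`` column;
* events — ``event_type,time,current`` with ``event_type`` one of
  stimulus / incision / cautery (current empty off-stimulus);
* feature trace — ``beat_time,K,B,r_squared,valid,hr,sbp,ppg_amp``
  (K empty for quality-control-removed beats);
* cohort — ``subject_id,mec_k,mec_hr,mec_bp,mec_ppg,k_r80,roc_bp`` with
  the literal ``OOR`` for out-of-range cells.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import FEATURE_COLUMNS, WaveformRecord
from .response import OUT_OF_RANGE, IncisionWindow, StimulusEvent

logger = logging.getLogger("nocimec")

WAVEFORM_COLUMNS = ["time", "ecg", "abp", "ppg"]
EVENT_COLUMNS = ["event_type", "time", "current"]
COHORT_COLUMNS = ["subject_id", "mec_k", "mec_hr", "mec_bp", "mec_ppg",
                  "k_r80", "roc_bp"]
OOR_LITERAL = "OOR"
SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Analysis constants; the defaults are the study's own."""

    start_current: float = 10.0     # mA
    step_current: float = 10.0      # mA
    max_current: float = 80.0       # mA
    pre_window: float = 10.0        # s, pre-stimulus / pre-incision median
    post_window: float = 20.0       # s, post-stimulus extremum
    threshold_pct: float = 5.0      # % change defining an evoked response
    alpha: float = 0.05
    bonferroni_m: int = 4
    loa_multiplier: float = 1.96
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pre_window <= 0 or self.post_window <= 0:
            raise ValueError("analysis windows must be positive")
        if self.threshold_pct <= 0:
            raise ValueError("threshold_pct must be positive")

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def read_waveforms(path, annotations=None) -> WaveformRecord:
    """Load a waveform CSV (and optional R-wave annotation CSV)."""
    df = pd.read_csv(path)
    _require_columns(df, WAVEFORM_COLUMNS, path)
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(t) < 2 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    r_times = None
    if annotations is not None:
        ann = pd.read_csv(annotations)
        _require_columns(ann, ["r_time"], annotations)
        r_times = ann["r_time"].to_numpy(dtype=float)
    logger.info("read %d samples at %.1f samples/s from %s", len(df), fs, path)
    return WaveformRecord(
        sampling_rate=fs,
        ecg=df["ecg"].to_numpy(dtype=float),
        abp=df["abp"].to_numpy(dtype=float),
        ppg=df["ppg"].to_numpy(dtype=float),
        time_origin=float(t[0]),
        r_times=r_times,
    )


def write_waveforms(record: WaveformRecord, path, annotations=None) -> None:
    pd.DataFrame(
        {"time": record.times(), "ecg": record.ecg,
         "abp": record.abp, "ppg": record.ppg}
    ).to_csv(path, index=False)
    if annotations is not None and record.r_times is not None:
        pd.DataFrame({"r_time": record.r_times}).to_csv(annotations, index=False)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)
    bad = set(df["event_type"]) - {"stimulus", "incision", "cautery"}
    if bad:
        raise ValueError(f"{path}: unknown event_type(s) {sorted(bad)}")
    logger.info("read %d events from %s", len(df), path)
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.reindex(columns=EVENT_COLUMNS).to_csv(path, index=False)


def events_to_stimuli(events: pd.DataFrame) -> list[StimulusEvent]:
    rows = events[events["event_type"] == "stimulus"]
    return [StimulusEvent(float(r.time), float(r.current))
            for r in rows.itertuples()]


def events_to_incision_window(events: pd.DataFrame) -> IncisionWindow | None:
    inc = events.loc[events["event_type"] == "incision", "time"]
    cau = events.loc[events["event_type"] == "cautery", "time"]
    if inc.empty or cau.empty:
        return None
    return IncisionWindow(float(inc.iloc[0]), float(cau.iloc[0]))


# ---------------------------------------------------------------------------
# feature traces and cohorts
# ---------------------------------------------------------------------------

def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, FEATURE_COLUMNS, path)
    return df


def write_trace(trace: pd.DataFrame, path) -> None:
    trace.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    if df["subject_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject_id values")
    for c in ("mec_k", "mec_hr", "mec_bp", "mec_ppg"):
        df[c] = [OUT_OF_RANGE if str(v).strip() == OOR_LITERAL else float(v)
                 for v in df[c]]
    df["roc_bp"] = df["roc_bp"].astype(float)
    if not np.isfinite(df["roc_bp"]).all():
        raise ValueError(f"{path}: non-finite roc_bp values")
    logger.info("read %d subjects from %s", len(df), path)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for c in ("mec_k", "mec_hr", "mec_bp", "mec_ppg"):
        out[c] = [OOR_LITERAL if v == OUT_OF_RANGE else v for v in out[c]]
    out.reindex(columns=COHORT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(payload: dict, path) -> None:
    payload = dict(_jsonable(payload))
    payload.setdefault("schema_version", SCHEMA_VERSION)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
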