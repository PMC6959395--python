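"""CSV readers and writers for the pipeline's tabular interchange formats.

All timestamps are ISO-8601 UTC; dates are plain ``YYYY-MM-DD``. The symptom
diary carries eight yes/no columns, one per surveyed symptom.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SYMPTOM_NAMES = [
    "fever",
    "sore_throat",
    "cough",
    "shortness_of_breath",
    "headache",
    "muscle_pain",
    "malaise",
    "cold",
]

LOCATION_COLUMNS = [
    "user_id",
    "latitude",
    "longitude",
    "source",
    "accuracy_m",
    "timestamp_iso8601",
]


def read_locations(path) -> pd.DataFrame:
    """Read ``locations.csv`` into the in-memory point schema (``timestamp``
    parsed to tz-aware UTC datetimes)."""
    df = pd.read_csv(path, dtype={"user_id": str, "source": str})
    df["timestamp"] = pd.to_datetime(df["timestamp_iso8601"], utc=True)
    return df.drop(columns=["timestamp_iso8601"])


def write_locations(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    if "timestamp" in out.columns:
        out["timestamp_iso8601"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        out = out.drop(columns=["timestamp"])
    out = out[LOCATION_COLUMNS]
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_symptoms(path) -> pd.DataFrame:
    """Read ``symptoms.csv``; yes/no columns become booleans and an
    ``any_symptom`` OR-column is appended."""
    df = pd.read_csv(path, dtype={"user_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for s in SYMPTOM_NAMES:
        df[s] = df[s].map({"yes": True, "no": False}).astype(bool)
    df["any_symptom"] = df[SYMPTOM_NAMES].any(axis=1)
    return df


def write_symptoms(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    for s in SYMPTOM_NAMES:
        if out[s].dtype != object:
            out[s] = out[s].map({True: "yes", False: "no"})
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out = out[["user_id", "date"] + SYMPTOM_NAMES]
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_episodes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str})
    df["onset_date"] = pd.to_datetime(df["onset_date"]).dt.date
    return df


def write_episodes(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    out["onset_date"] = pd.to_datetime(out["onset_date"]).dt.strftime("%Y-%m-%d")
    path = Path(path)
    out[["user_id", "onset_date", "duration_days", "prodrome_days", "symptom_list"]].to_csv(
        path, index=False
    )
    return path


def write_stops(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    for c in ("t_arrival", "t_departure"):
        out[c] = out[c].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_stops(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str})
    for c in ("t_arrival", "t_departure"):
        df[c] = pd.to_datetime(df[c], utc=True)
    return df


def write_daily_features(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_daily_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df
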