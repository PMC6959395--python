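"""Windowed sample assembly, labelling, balancing and splitting.

A candidate sample is anchored at a (user, day t) pair. Its feature vector
holds the base daily metrics for every day of the history window
[t - t_hist, t] plus the window's rolling statistics; its binary label is
whether the user reported at least one of the eight symptoms on day
t + t_hor. A candidate is valid only when mobility rows exist for *every*
day of the window and a symptom record exists at t + t_hor — one sample set
is materialised per t_hor so the availability constraint is uniform within
a set.

Class imbalance (symptom-free days dominate) is handled by random
under-sampling of the majority class.
"""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit
from sklearn.model_selection import train_test_split as _sk_split

from .features import AGG_STATS, BASE_FEATURES, rolling_aggregates

LABEL_COLUMN = "label"
META_COLUMNS = ["user_id", "anchor_date", LABEL_COLUMN]


def feature_columns(t_hist: int) -> list:
    """Column order of the design matrix for a given history length: lagged
    base metrics (lag 0 = anchor day), their missingness flags, then the
    window aggregates."""
    cols = []
    for lag in range(t_hist + 1):
        cols += [f"lag{lag}__{f}" for f in BASE_FEATURES]
    for lag in range(t_hist + 1):
        cols += [f"lag{lag}__{f}_missing" for f in BASE_FEATURES]
    for f in BASE_FEATURES:
        cols += [f"{f}__{s}" for s in AGG_STATS]
    return cols


def build_samples(
    daily: pd.DataFrame,
    symptoms: pd.DataFrame,
    t_hist: int,
    t_hor: int,
    allow_extended_range: bool = False,
) -> pd.DataFrame:
    """Assemble the labelled sample table for one (t_hist, t_hor) setting.

    ``daily`` is the per-user-day metric table, ``symptoms`` the diary with
    an ``any_symptom`` column. Both t_hist and t_hor must lie in [0, 2]
    unless ``allow_extended_range`` is set. NaN metric values enter the
    matrix as 0 with the corresponding ``_missing`` flag set; aggregate NaNs
    (e.g. the std of a single-day window) are zero-filled likewise.
    """
    for name, v in (("t_hist", t_hist), ("t_hor", t_hor)):
        if not (0 <= v <= 2 or allow_extended_range):
            raise ValueError(f"{name}={v} outside the supported range [0, 2]")
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    sym = symptoms.set_index(["user_id", "date"])["any_symptom"]
    rows = []
    for user, user_daily in daily.groupby("user_id", sort=True):
        have = set(user_daily["date"])
        user_daily = user_daily.sort_values("date")
        by_date = user_daily.set_index("date")
        for t in sorted(have):
            window = [t - timedelta(days=k) for k in range(t_hist, -1, -1)]
            if set(window) - have:
                continue
            label_day = t + timedelta(days=t_hor)
            if (user, label_day) not in sym.index:
                continue
            row = {"user_id": user, "anchor_date": t,
                   LABEL_COLUMN: int(sym.loc[(user, label_day)])}
            for lag in range(t_hist + 1):
                day_row = by_date.loc[t - timedelta(days=lag)]
                for f in BASE_FEATURES:
                    v = day_row[f]
                    row[f"lag{lag}__{f}"] = 0.0 if pd.isna(v) else float(v)
                    row[f"lag{lag}__{f}_missing"] = float(pd.isna(v))
            agg = rolling_aggregates(user_daily, t, t_hist)
            for k, v in agg.items():
                row[k] = 0.0 if pd.isna(v) else float(v)
            rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + feature_columns(t_hist))


def split_xy(samples: pd.DataFrame):
    """(X, y) view of a sample table: the numeric design matrix and the
    0/1 label vector."""
    X = samples.drop(columns=META_COLUMNS)
    y = samples[LABEL_COLUMN].to_numpy()
    return X, y


def undersample(samples: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Balance the two classes exactly at the minority count by removing
    uniformly chosen majority samples; deterministic per seed."""
    counts = samples[LABEL_COLUMN].value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise ValueError("cannot balance: a class has no samples")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    kept = []
    for label, grp in samples.groupby(LABEL_COLUMN, sort=True):
        idx = grp.index.to_numpy()
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        kept.append(samples.loc[np.sort(idx)])
    return pd.concat(kept).sort_index()


def train_test_split(samples: pd.DataFrame, test_fraction: float, seed: int,
                     group_by_user: bool = False):
    """Seed-deterministic split into disjoint, exhaustive train and test
    tables.

    The default split is label-stratified and user-agnostic (samples of one
    user may land on both sides), matching a single pooled model over a
    small cohort. ``group_by_user=True`` keeps each user entirely on one
    side instead — stricter, at the cost of exact stratification.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if group_by_user:
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        tr_idx, te_idx = next(splitter.split(samples, groups=samples["user_id"]))
        return samples.iloc[tr_idx], samples.iloc[te_idx]
    train, test = _sk_split(
        samples,
        test_size=test_fraction,
        stratify=samples[LABEL_COLUMN],
        random_state=seed,
    )
    return train, test
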