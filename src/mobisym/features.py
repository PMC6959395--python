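"""Daily mobility metrics computed from stops and moving points.

Twelve base metrics are computed per user per calendar day (or per arbitrary
interval): total distance travelled over the merged stop+moving-point
sequence, its per-leg mean/spread, total/std/max displacement between
consecutive stops, dwell-time-weighted radius of gyration, maximum
displacement from home, visit counts (total, significant, unique),
moving-point count, and the normalised entropy ("diversity") of visits
across places. Rolling window statistics (mean, std, max, min, first-to-last
difference) summarise each metric over a short history window.

Distances are kilometres, dwell times seconds. A metric that is undefined on
a given day (e.g. the spread of displacements with fewer than two stop-to-
stop legs) is NaN, paired with an explicit ``*_missing`` flag column —
never a silent zero.
"""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .places import MOVING_ID, StopDetector, haversine_km

BASE_FEATURES = [
    "d_t",
    "sigma_d_t",
    "dis_t",
    "sigma_dis",
    "dis_m",
    "g",
    "dis_h",
    "n_dif",
    "n_sig",
    "n_moves",
    "n_unq",
    "div",
]

AGG_STATS = ["mean", "std", "max", "min", "diff"]


def _legs(lats, lons):
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(lats) < 2:
        return np.empty(0)
    return haversine_km(lats[:-1], lons[:-1], lats[1:], lons[1:])


def total_distance(lats, lons) -> float:
    """Sum of great-circle legs over a time-ordered point sequence; 0 with
    fewer than two points."""
    return float(np.sum(_legs(lats, lons)))


def distance_stats(lats, lons):
    """(average leg distance, sample std of leg distances).

    The average is total distance over the number of movements (points minus
    one); the std uses the n-1 denominator and needs at least two legs. NaN
    where undefined.
    """
    legs = _legs(lats, lons)
    avg = float(np.sum(legs) / len(legs)) if len(legs) >= 1 else np.nan
    sigma = float(np.std(legs, ddof=1)) if len(legs) >= 2 else np.nan
    return avg, sigma


def displacement_features(stop_lats, stop_lons):
    """(Dis_T, sigma_Dis, Dis_M) over consecutive stop centroids.

    Dis_T is 0 with fewer than two stops; the max and std are NaN when there
    is no leg / fewer than two legs.
    """
    legs = _legs(stop_lats, stop_lons)
    dis_t = float(np.sum(legs))
    sigma = float(np.std(legs, ddof=1)) if len(legs) >= 2 else np.nan
    dis_m = float(np.max(legs)) if len(legs) >= 1 else np.nan
    return dis_t, sigma, dis_m


def radius_of_gyration(stop_lats, stop_lons, dwell_s, weighted_centroid: bool = True) -> float:
    """Dwell-time-weighted RMS distance of visited places from their
    centroid; each visit contributes separately with weight = time spent.

    The reference centroid is the dwell-weighted mean of the stop coordinates
    (set ``weighted_centroid=False`` for the unweighted mean). NaN when total
    dwell time is zero.
    """
    lats = np.asarray(stop_lats, dtype=float)
    lons = np.asarray(stop_lons, dtype=float)
    w = np.asarray(dwell_s, dtype=float)
    T = w.sum()
    if len(lats) == 0 or T <= 0:
        return np.nan
    if weighted_centroid:
        c_lat, c_lon = float(np.average(lats, weights=w)), float(np.average(lons, weights=w))
    else:
        c_lat, c_lon = float(np.mean(lats)), float(np.mean(lons))
    d2 = haversine_km(lats, lons, np.full_like(lats, c_lat), np.full_like(lons, c_lon)) ** 2
    return float(np.sqrt(np.sum(w * d2) / T))


def max_displacement_from_home(stop_lats, stop_lons, home_lat, home_lon) -> float:
    """Largest great-circle distance of any visited stop from home; 0 when
    only home was visited, NaN when home is unknown or no stops exist."""
    if home_lat is None or (isinstance(home_lat, float) and np.isnan(home_lat)):
        return np.nan
    lats = np.asarray(stop_lats, dtype=float)
    if len(lats) == 0:
        return np.nan
    lons = np.asarray(stop_lons, dtype=float)
    d = haversine_km(lats, lons, np.full_like(lats, float(home_lat)), np.full_like(lons, float(home_lon)))
    return float(np.max(d))


def visit_counts(place_ids, significant_set):
    """(N_dif, N_sig, N_unq): total visits, visits at significant places,
    distinct places. One stop = one visit, so two stops at the same place
    count twice in N_dif."""
    ids = list(place_ids)
    n_dif = len(ids)
    n_sig = sum(1 for p in ids if p in significant_set)
    n_unq = len(set(ids))
    return n_dif, n_sig, n_unq


def n_moving_points(place_ids) -> int:
    return int(sum(1 for p in place_ids if p == MOVING_ID))


def diversity(place_ids) -> float:
    """Normalised Shannon entropy of visit counts across places, in [0, 1].

    1 means visits are spread perfectly evenly over k >= 2 places; defined as
    0 for k <= 1 (the log k = 0 degeneracy). The logarithm base cancels.
    """
    ids = np.asarray(list(place_ids))
    if ids.size == 0:
        return 0.0
    counts = np.unique(ids, return_counts=True)[1].astype(float)
    k = len(counts)
    if k <= 1:
        return 0.0
    v = counts / counts.sum()
    return float(-(v * np.log(v)).sum() / np.log(k))


def significant_places(stops: pd.DataFrame, top_n: int = 10) -> dict:
    """Per-user set of the top-N most frequently visited places over the full
    observation period; ties at the boundary break by earlier first visit."""
    out = {}
    for user, s in stops.groupby("user_id", sort=False):
        agg = s.groupby("place_id").agg(count=("place_id", "size"), first=("t_arrival", "min"))
        agg = agg.sort_values(["count", "first"], ascending=[False, True], kind="stable")
        out[user] = set(agg.index[:top_n].tolist())
    return out


def split_stops_at_midnight(stops: pd.DataFrame) -> pd.DataFrame:
    """Split stops crossing local midnight into per-day pieces so dwell time
    is attributed to the calendar day it falls in. Adds ``date`` and
    ``dwell_s`` columns."""
    if stops.empty:
        out = stops.copy()
        out["date"] = pd.Series(dtype=object)
        out["dwell_s"] = pd.Series(dtype=float)
        return out
    a_day = stops["t_arrival"].dt.normalize()
    d_day = stops["t_departure"].dt.normalize()
    n_pieces = ((d_day - a_day).dt.days + 1).to_numpy()
    idx = np.repeat(np.arange(len(stops)), n_pieces)
    # piece k of a stop covers calendar day (arrival day + k)
    k = np.arange(len(idx)) - np.repeat(np.cumsum(n_pieces) - n_pieces, n_pieces)
    out = stops.iloc[idx].reset_index(drop=True)
    day_start = a_day.iloc[idx].reset_index(drop=True) + pd.to_timedelta(k, unit="D")
    lo = np.maximum(out["t_arrival"], day_start)
    hi = np.minimum(out["t_departure"], day_start + pd.Timedelta(days=1))
    out["t_arrival"], out["t_departure"] = lo, hi
    out["date"] = lo.dt.date
    out["dwell_s"] = (hi - lo).dt.total_seconds()
    out = out[(hi > lo) | (n_pieces[idx] == 1)]
    return out.sort_values(["user_id", "t_arrival"], kind="stable").reset_index(drop=True)


def _interval_features_arrays(
    st_t, st_lat, st_lon, st_dwell, st_pid, mv_t, mv_lat, mv_lon, home, significant_set,
    weighted_centroid=True,
) -> dict:
    # numpy fast path shared by interval_features and daily_features
    t = np.concatenate([st_t, mv_t])
    order = np.argsort(t, kind="stable")
    lat = np.concatenate([st_lat, mv_lat])[order]
    lon = np.concatenate([st_lon, mv_lon])[order]
    d_t = total_distance(lat, lon)
    _, sigma_d_t = distance_stats(lat, lon)
    dis_t, sigma_dis, dis_m = displacement_features(st_lat, st_lon)
    g = radius_of_gyration(st_lat, st_lon, st_dwell, weighted_centroid=weighted_centroid)
    if home is not None:
        dis_h = max_displacement_from_home(st_lat, st_lon, home[0], home[1])
    else:
        dis_h = np.nan
    n_dif, n_sig, n_unq = visit_counts(st_pid, significant_set)
    return {
        "d_t": d_t,
        "sigma_d_t": sigma_d_t,
        "dis_t": dis_t,
        "sigma_dis": sigma_dis,
        "dis_m": dis_m,
        "g": g,
        "dis_h": dis_h,
        "n_dif": n_dif,
        "n_sig": n_sig,
        "n_moves": len(mv_t),
        "n_unq": n_unq,
        "div": diversity(st_pid),
    }


def interval_features(day_stops: pd.DataFrame, day_moves: pd.DataFrame, home, significant_set,
                      weighted_centroid: bool = True) -> dict:
    """All twelve base metrics for one user-interval.

    ``day_stops`` carries centroid coordinates, dwell seconds and place ids
    (a ``dwell_s`` column is derived when absent); ``day_moves`` the raw
    moving points; ``home`` is a (lat, lon) pair or None.
    """
    if "dwell_s" in day_stops.columns:
        dwell = day_stops["dwell_s"].to_numpy(dtype=float)
    else:
        dwell = (day_stops["t_departure"] - day_stops["t_arrival"]).dt.total_seconds().to_numpy()
    return _interval_features_arrays(
        day_stops["t_arrival"].astype("int64").to_numpy(),
        day_stops["centroid_lat"].to_numpy(dtype=float),
        day_stops["centroid_lon"].to_numpy(dtype=float),
        dwell,
        day_stops["place_id"].to_numpy(),
        day_moves["timestamp"].astype("int64").to_numpy(),
        day_moves["latitude"].to_numpy(dtype=float),
        day_moves["longitude"].to_numpy(dtype=float),
        home,
        significant_set,
        weighted_centroid=weighted_centroid,
    )


def daily_features(
    stops: pd.DataFrame,
    places: pd.DataFrame,
    annotated_points: pd.DataFrame,
    top_n: int = 10,
    weighted_centroid: bool = True,
) -> pd.DataFrame:
    """One row of the twelve base metrics per user per calendar day.

    Stops crossing midnight are split at 00:00 first; a day with neither a
    stop piece nor a moving point emits no row. Significant places are
    computed once per user over the whole observation period. ``*_missing``
    flag columns mark NaN metrics explicitly.
    """
    sig = significant_places(stops, top_n=top_n)
    split = split_stops_at_midnight(stops)
    homes = {}
    for _, row in places.loc[places["label"] == "home"].iterrows():
        homes[row["user_id"]] = (row["centroid_lat"], row["centroid_lon"])
    moves = annotated_points.loc[annotated_points["place_id"] == MOVING_ID].copy()
    moves["date"] = moves["timestamp"].dt.date
    st_arr = {
        "t": split["t_arrival"].astype("int64").to_numpy() if len(split) else np.empty(0, np.int64),
        "lat": split["centroid_lat"].to_numpy(dtype=float),
        "lon": split["centroid_lon"].to_numpy(dtype=float),
        "dwell": split["dwell_s"].to_numpy(dtype=float),
        "pid": split["place_id"].to_numpy(),
    }
    mv_arr = {
        "t": moves["timestamp"].astype("int64").to_numpy() if len(moves) else np.empty(0, np.int64),
        "lat": moves["latitude"].to_numpy(dtype=float),
        "lon": moves["longitude"].to_numpy(dtype=float),
    }
    stop_idx = split.groupby(["user_id", "date"], sort=False).indices
    move_idx = moves.groupby(["user_id", "date"], sort=False).indices
    none = np.empty(0, dtype=np.int64)
    rows = []
    for key in sorted(set(stop_idx) | set(move_idx)):
        user, date = key
        si = stop_idx.get(key, none)
        mi = move_idx.get(key, none)
        feats = _interval_features_arrays(
            st_arr["t"][si], st_arr["lat"][si], st_arr["lon"][si],
            st_arr["dwell"][si], st_arr["pid"][si],
            mv_arr["t"][mi], mv_arr["lat"][mi], mv_arr["lon"][mi],
            homes.get(user),
            sig.get(user, set()),
            weighted_centroid=weighted_centroid,
        )
        rows.append({"user_id": user, "date": date, **feats})
    daily = pd.DataFrame(rows, columns=["user_id", "date"] + BASE_FEATURES)
    for f in BASE_FEATURES:
        daily[f"{f}_missing"] = daily[f].isna()
    return daily


def rolling_aggregates(user_daily: pd.DataFrame, anchor, t_hist: int) -> dict:
    """Window statistics of each base metric over [anchor - t_hist, anchor].

    Requires a daily row for *every* day of the window (raises ValueError
    otherwise — sample validity is an upstream contract). Returns a flat dict
    ``{feature__stat: value}`` with stats mean/std/max/min/diff, where diff is
    value(anchor) - value(anchor - t_hist); std uses n-1 and is NaN for a
    single-day window. NaN metric values are skipped within a window.
    """
    anchor = pd.Timestamp(anchor).date()
    wanted = [anchor - timedelta(days=k) for k in range(t_hist, -1, -1)]
    if set(wanted) - set(user_daily["date"]):
        raise ValueError("window has days with no mobility data")
    sub = user_daily.set_index("date").reindex(wanted)
    out = {}
    for f in BASE_FEATURES:
        v = sub[f].to_numpy(dtype=float)
        finite = v[~np.isnan(v)]
        out[f"{f}__mean"] = float(np.mean(finite)) if len(finite) else np.nan
        out[f"{f}__std"] = float(np.std(finite, ddof=1)) if len(finite) >= 2 else np.nan
        out[f"{f}__max"] = float(np.max(finite)) if len(finite) else np.nan
        out[f"{f}__min"] = float(np.min(finite)) if len(finite) else np.nan
        out[f"{f}__diff"] = float(v[-1] - v[0])
    return out


class MobilityFeatureExtractor(BaseEstimator, TransformerMixin):
    """Raw location points in, daily mobility-metric table out.

    Chains :class:`~mobisym.places.StopDetector` with the per-day metric
    computation. Exposes the detector's parameters plus ``top_n`` (size of
    the significant-place list) and ``weighted_centroid`` (radius-of-gyration
    reference point).
    """

    def __init__(
        self,
        radius_m: float = 200.0,
        max_accuracy_m: float = 50.0,
        speed_threshold_kmh: float = 5.0,
        min_stop_min: float = 10.0,
        max_point_gap_min: float = 120.0,
        tz=None,
        home_rule: str = "dwell",
        top_n: int = 10,
        weighted_centroid: bool = True,
    ):
        self.radius_m = radius_m
        self.max_accuracy_m = max_accuracy_m
        self.speed_threshold_kmh = speed_threshold_kmh
        self.min_stop_min = min_stop_min
        self.max_point_gap_min = max_point_gap_min
        self.tz = tz
        self.home_rule = home_rule
        self.top_n = top_n
        self.weighted_centroid = weighted_centroid

    def _detector(self) -> StopDetector:
        return StopDetector(
            radius_m=self.radius_m,
            max_accuracy_m=self.max_accuracy_m,
            speed_threshold_kmh=self.speed_threshold_kmh,
            min_stop_min=self.min_stop_min,
            max_point_gap_min=self.max_point_gap_min,
            tz=self.tz,
            home_rule=self.home_rule,
        )

    def fit(self, X: pd.DataFrame, y=None):
        self.detector_ = self._detector().fit(X)
        self.daily_ = daily_features(
            self.detector_.stops_,
            self.detector_.places_,
            self.detector_.annotated_points_,
            top_n=self.top_n,
            weighted_centroid=self.weighted_centroid,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        det = self._detector().fit(X)
        return daily_features(
            det.stops_,
            det.places_,
            det.annotated_points_,
            top_n=self.top_n,
            weighted_centroid=self.weighted_centroid,
        )

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).daily_
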