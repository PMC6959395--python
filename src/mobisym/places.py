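"""Place identification from raw location points.

The pipeline turns a stream of noisy geo-samples into a sequence of *stops*
at identified *places*:

1. annotate each point with the speed relative to the previous point of the
   same user and flag it as moving when that speed reaches 5 km/h;
2. keep only stationary points with reported accuracy below 50 m as
   clustering candidates;
3. cluster the candidates incrementally in time order: a point joins the
   nearest existing cluster whose *current* centroid lies within 200 m,
   otherwise it seeds a new cluster; centroids are running means;
4. collapse maximal runs of consecutive same-cluster points into stops with
   arrival/departure times, discarding dwells shorter than a minimum
   duration;
5. label as *home* the place where the user spends the most late-evening and
   night time (7 pm - 7 am).

All of this is exposed both as functions and as the :class:`StopDetector`
transformer.
"""

from __future__ import annotations

import math
from datetime import timedelta

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

EARTH_RADIUS_KM = 6371.0

#: place_id used for points sampled while the user is moving
MOVING_ID = -1

STOP_COLUMNS = [
    "user_id",
    "place_id",
    "t_arrival",
    "t_departure",
    "centroid_lat",
    "centroid_lon",
    "label",
]
PLACE_COLUMNS = [
    "user_id",
    "place_id",
    "centroid_lat",
    "centroid_lon",
    "label",
    "n_members",
]


def _validate_coords(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")
    return lat, lon


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in kilometres (vectorised).

    Uses the haversine formula on a sphere of radius 6371.0 km, the standard
    choice for city-scale mobility work where the sub-0.5 % ellipsoidal error
    is irrelevant.
    """
    lat1, lon1 = _validate_coords(lat1, lon1)
    lat2, lon2 = _validate_coords(lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _haversine_scalar_rad(phi1, lmb1, phi2, lmb2):
    # radians in, km out; scalar math path for the clustering inner loop
    a = (
        math.sin((phi2 - phi1) / 2.0) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lmb2 - lmb1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(min(a, 1.0)))


def annotate_speed(points: pd.DataFrame, speed_threshold_kmh: float = 5.0) -> pd.DataFrame:
    """Add ``speed_kmh`` and ``moving`` columns.

    Speed is distance / elapsed time versus the previous point of the same
    user; the first point of a user gets speed 0 (no predecessor) and a zero
    time gap with a nonzero displacement counts as moving (infinite speed).
    A point is ``moving`` when its speed is at or above the threshold
    (stationary is strict-less).
    """
    out = points.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)
    grp = out.groupby("user_id", sort=False)
    prev_lat = grp["latitude"].shift()
    prev_lon = grp["longitude"].shift()
    dt_h = (out["timestamp"] - grp["timestamp"].shift()).dt.total_seconds() / 3600.0
    first = prev_lat.isna()
    dist = np.zeros(len(out))
    mask = ~first
    if mask.any():
        dist[mask.to_numpy()] = haversine_km(
            prev_lat[mask], prev_lon[mask], out.loc[mask, "latitude"], out.loc[mask, "longitude"]
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(dt_h.to_numpy() > 0, dist / dt_h.to_numpy(), np.where(dist > 0, np.inf, 0.0))
    speed[first.to_numpy()] = 0.0
    out["speed_kmh"] = speed
    out["moving"] = speed >= speed_threshold_kmh
    return out


def filter_points(points: pd.DataFrame, max_accuracy_m: float = 50.0) -> pd.DataFrame:
    """Stationary clustering candidates: accuracy strictly below the cap and
    not moving. Order is preserved; an empty result is fine."""
    keep = (points["accuracy_m"] < max_accuracy_m) & (~points["moving"])
    return points.loc[keep]


def cluster_locations(points: pd.DataFrame, radius_m: float = 200.0):
    """Incremental clustering of one user's stationary candidates.

    Points are consumed in timestamp order. Each point joins the *nearest*
    existing cluster whose current centroid is within ``radius_m``; if no
    centroid qualifies the point seeds a new cluster. Centroids are running
    means of member coordinates, so the pass is order-dependent by
    construction.

    Returns ``(assignments, places)`` where ``assignments`` is an int array of
    1-based place ids aligned with ``points`` and ``places`` is a DataFrame
    with one row per cluster.
    """
    radius_km = radius_m / 1000.0
    lats = points["latitude"].to_numpy(dtype=float)
    lons = points["longitude"].to_numpy(dtype=float)
    cen_lat: list[float] = []   # centroid in degrees (running mean)
    cen_lon: list[float] = []
    cen_phi: list[float] = []   # centroid in radians, kept in sync
    cen_lmb: list[float] = []
    counts: list[int] = []
    assign = np.empty(len(points), dtype=np.int64)
    for i in range(len(lats)):
        lat, lon = lats[i], lons[i]
        phi, lmb = math.radians(lat), math.radians(lon)
        best, best_d = -1, radius_km
        for j in range(len(cen_lat)):
            d = _haversine_scalar_rad(phi, lmb, cen_phi[j], cen_lmb[j])
            if d <= best_d:
                best, best_d = j, d
        if best < 0:
            cen_lat.append(lat)
            cen_lon.append(lon)
            cen_phi.append(phi)
            cen_lmb.append(lmb)
            counts.append(1)
            assign[i] = len(cen_lat)
        else:
            n = counts[best] + 1
            cen_lat[best] += (lat - cen_lat[best]) / n
            cen_lon[best] += (lon - cen_lon[best]) / n
            cen_phi[best] = math.radians(cen_lat[best])
            cen_lmb[best] = math.radians(cen_lon[best])
            counts[best] = n
            assign[i] = best + 1
    places = pd.DataFrame(
        {
            "place_id": np.arange(1, len(cen_lat) + 1),
            "centroid_lat": cen_lat,
            "centroid_lon": cen_lon,
            "n_members": counts,
        }
    )
    return assign, places


def build_stops(
    annotated: pd.DataFrame,
    max_accuracy_m: float = 50.0,
    radius_m: float = 200.0,
    min_stop_min: float = 10.0,
    max_point_gap_min: float = 120.0,
):
    """Cluster every user's candidate points and collapse them into stops.

    The merged per-user sequence contains the accuracy-filtered stationary
    points (carrying their cluster id) and all moving points (id -1).
    Maximal runs of consecutive points with the same positive id become one
    stop spanning first to last timestamp; an intervening moving point ends a
    run, while points dropped by the accuracy filter do not. A silent gap
    longer than ``max_point_gap_min`` minutes between consecutive points also
    ends a run, so a dwell never bridges a day with no data. Runs shorter
    than ``min_stop_min`` minutes are discarded.

    Returns ``(stops, places, assigned)`` where ``assigned`` is the annotated
    frame restricted to kept points with a ``place_id`` column (-1 = moving).
    """
    stops_parts = []
    places_parts = []
    assigned_parts = []
    for user, pts in annotated.groupby("user_id", sort=True):
        cand = filter_points(pts, max_accuracy_m=max_accuracy_m)
        assign, places = cluster_locations(cand, radius_m=radius_m)
        cand = cand.copy()
        cand["place_id"] = assign
        moving = pts.loc[pts["moving"]].copy()
        moving["place_id"] = MOVING_ID
        merged = (
            pd.concat([cand, moving])
            .sort_values("timestamp", kind="stable")
            .reset_index(drop=True)
        )
        assigned_parts.append(merged)
        places["user_id"] = user
        places_parts.append(places)
        if len(merged):
            gap_break = (
                merged["timestamp"].diff().dt.total_seconds() > max_point_gap_min * 60.0
            )
            run_id = (
                ((merged["place_id"] != merged["place_id"].shift()) | gap_break)
                .cumsum()
                .rename("run")
            )
            runs = merged.groupby(run_id).agg(
                place_id=("place_id", "first"),
                t_arrival=("timestamp", "first"),
                t_departure=("timestamp", "last"),
            )
            runs = runs[runs["place_id"] != MOVING_ID]
            dur_min = (runs["t_departure"] - runs["t_arrival"]).dt.total_seconds() / 60.0
            runs = runs[dur_min >= min_stop_min]
            runs = runs.merge(places[["place_id", "centroid_lat", "centroid_lon"]], on="place_id")
            runs["user_id"] = user
            stops_parts.append(runs)
    places_all = (
        pd.concat(places_parts, ignore_index=True)
        if places_parts
        else pd.DataFrame(columns=[c for c in PLACE_COLUMNS if c != "label"])
    )
    stops_all = (
        pd.concat(stops_parts, ignore_index=True).sort_values(
            ["user_id", "t_arrival"], kind="stable"
        )
        if stops_parts
        else pd.DataFrame(columns=[c for c in STOP_COLUMNS if c != "label"])
    )
    assigned_all = (
        pd.concat(assigned_parts, ignore_index=True)
        if assigned_parts
        else annotated.iloc[0:0].assign(place_id=pd.Series(dtype=np.int64))
    )
    stops_all = stops_all.reset_index(drop=True)
    if "label" not in stops_all.columns:
        stops_all["label"] = "other"
    return stops_all[STOP_COLUMNS], places_all, assigned_all


def night_overlap_seconds(t_arrival, t_departure, tz=None) -> float:
    """Seconds of [t_arrival, t_departure] falling inside the nightly
    7 pm - 7 am windows, in local time ``tz`` (None = use timestamps as-is).

    The window wraps midnight, so a stop's contribution is its intersection
    with [19:00, 24:00) of each day plus [00:00, 07:00) of the next.
    """
    a, d = pd.Timestamp(t_arrival), pd.Timestamp(t_departure)
    if tz is not None:
        a = a.tz_convert(tz) if a.tzinfo else a.tz_localize("UTC").tz_convert(tz)
        d = d.tz_convert(tz) if d.tzinfo else d.tz_localize("UTC").tz_convert(tz)
    total = 0.0
    day = a.normalize() - timedelta(days=1)
    while day <= d.normalize():
        w0 = day + timedelta(hours=19)
        w1 = day + timedelta(hours=31)  # 07:00 next day
        lo, hi = max(a, w0), min(d, w1)
        if hi > lo:
            total += (hi - lo).total_seconds()
        day += timedelta(days=1)
    return total


def label_home(stops: pd.DataFrame, places: pd.DataFrame, tz=None, rule: str = "dwell"):
    """Label each user's *home* place; every other place becomes ``other``.

    rule='dwell' (default): home is the place with the largest total dwell
    time inside the nightly 7 pm - 7 am window. rule='frequency': home is the
    place with the most stops touching that window. Ties break by larger
    member count, then smaller place id. Users with no night-time stop get no
    home label.
    """
    if rule not in ("dwell", "frequency"):
        raise ValueError(f"unknown home rule: {rule!r}")
    places = places.copy()
    places["label"] = "other"
    stops = stops.copy()
    if len(stops):
        stops["night_s"] = [
            night_overlap_seconds(a, d, tz=tz)
            for a, d in zip(stops["t_arrival"], stops["t_departure"])
        ]
    else:
        stops["night_s"] = pd.Series(dtype=float)
    for user, user_stops in stops.groupby("user_id", sort=False):
        nocturnal = user_stops[user_stops["night_s"] > 0]
        if nocturnal.empty:
            continue
        if rule == "dwell":
            score = nocturnal.groupby("place_id")["night_s"].sum()
        else:
            score = nocturnal.groupby("place_id").size().astype(float)
        cand = score.reset_index(name="score").merge(
            places.loc[places["user_id"] == user, ["place_id", "n_members"]], on="place_id"
        )
        cand = cand.sort_values(
            ["score", "n_members", "place_id"], ascending=[False, False, True], kind="stable"
        )
        home_id = int(cand.iloc[0]["place_id"])
        places.loc[
            (places["user_id"] == user) & (places["place_id"] == home_id), "label"
        ] = "home"
    stops = stops.drop(columns=["night_s", "label"], errors="ignore").merge(
        places[["user_id", "place_id", "label"]], on=["user_id", "place_id"], how="left"
    )
    return stops[STOP_COLUMNS], places[PLACE_COLUMNS]


class StopDetector(BaseEstimator, TransformerMixin):
    """Transformer from raw location points to stops at identified places.

    Parameters
    ----------
    radius_m : float, default 200
        Incremental-clustering radius; a point joins a cluster only if the
        current centroid is within this distance.
    max_accuracy_m : float, default 50
        Points with reported accuracy at or above this are excluded from
        clustering (strict less-than keeps a point).
    speed_threshold_kmh : float, default 5
        A point whose speed versus the previous point reaches this value is
        treated as collected while moving.
    min_stop_min : float, default 10
        Minimum dwell duration for a run of same-cluster points to count as a
        stop.
    max_point_gap_min : float, default 120
        A silent gap longer than this between consecutive points ends the
        current dwell run (a stop never bridges a data gap).
    tz : str or None, default None
        Local timezone for the 7 pm - 7 am home window; None uses the
        timestamps as stored (the bundled simulator emits UTC).
    home_rule : {'dwell', 'frequency'}, default 'dwell'
        Night dwell-time maximiser versus night visit-count maximiser.

    Attributes
    ----------
    places_ : DataFrame with one row per (user, place), centroids and labels.
    stops_ : DataFrame of detected stops.
    annotated_points_ : input points with speed/moving/place_id annotations.
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
    ):
        self.radius_m = radius_m
        self.max_accuracy_m = max_accuracy_m
        self.speed_threshold_kmh = speed_threshold_kmh
        self.min_stop_min = min_stop_min
        self.max_point_gap_min = max_point_gap_min
        self.tz = tz
        self.home_rule = home_rule

    def _run(self, X: pd.DataFrame):
        annotated = annotate_speed(X, speed_threshold_kmh=self.speed_threshold_kmh)
        stops, places, assigned = build_stops(
            annotated,
            max_accuracy_m=self.max_accuracy_m,
            radius_m=self.radius_m,
            min_stop_min=self.min_stop_min,
            max_point_gap_min=self.max_point_gap_min,
        )
        stops, places = label_home(stops, places, tz=self.tz, rule=self.home_rule)
        return stops, places, assigned

    def fit(self, X: pd.DataFrame, y=None):
        self.stops_, self.places_, self.annotated_points_ = self._run(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        stops, _, _ = self._run(X)
        return stops

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).stops_
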