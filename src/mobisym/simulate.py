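"""Coupled synthetic mobility-trace and symptom-diary generator.

Each agent has a home and a few anchor places (work, errands) visited with
per-anchor daily probabilities. A simulated day pins the agent at home
through the night and evening (so the 7 pm - 7 am home-labelling rule is
identifiable by construction), strings dwell episodes at visited anchors
through the daytime, and interpolates travel between them as straight-line
points sampled at a fixed interval at ~20 km/h — fast enough that the speed
filter discards them. Points get Gaussian positional noise and a mixture of
GPS (small reported accuracy) and NETWORK (large accuracy) sources, so the
50 m accuracy filter removes the network points.

Illness episodes are Poisson-placed per user. During an episode's prodrome
and symptomatic days, mobility contracts by the effect size delta: each
anchor visit survives with probability scaled by (1 - delta) and surviving
excursions are pulled toward home by the same factor. The symptom diary
reports yes for the episode's symptoms on days [onset, onset + duration);
the episode ground truth is kept in a separate table and never fed to the
pipeline. Day-level gaps are simulated independently for the location and
survey streams.

A fixed seed yields byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import io as mio
from .places import haversine_km

M_PER_DEG_LAT = 111_195.0  # 2*pi*R/360 with R = 6371 km, in metres


@dataclass
class SimulationConfig:
    """Study-condition knobs for :func:`simulate_cohort`.

    Defaults emulate a small urban cohort observed for two months: ~10 % of
    user-days missing from each stream, one illness episode per user-month,
    80 % GPS fixes within 5-20 m accuracy and network fixes at 60-300 m.
    ``effect_size`` is the fractional mobility contraction (0 = symptoms
    carry no mobility signal).
    """

    n_users: int = 50
    n_days: int = 60
    start_date: date = date(2023, 1, 2)
    seed: int = 0
    gps_noise_sd_m: float = 15.0
    gps_fraction: float = 0.8
    gps_accuracy_m: tuple = (5.0, 20.0)
    network_accuracy_m: tuple = (60.0, 300.0)
    episode_rate_per_month: float = 1.0
    effect_size: float = 0.0
    prodrome_days: int = 2
    gap_prob_location: float = 0.1
    gap_prob_survey: float = 0.1
    night_sample_min: float = 30.0
    dwell_sample_min: float = 20.0
    travel_sample_min: float = 5.0
    travel_speed_kmh: float = 20.0

    def validate(self) -> "SimulationConfig":
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if self.n_days < 5:
            raise ValueError("n_days must be >= 5 (minimum for one valid window)")
        for p in (self.gap_prob_location, self.gap_prob_survey, self.gps_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.prodrome_days < 0:
            raise ValueError("prodrome_days must be >= 0")
        return self


@dataclass
class AgentProfile:
    """One agent's geography and sampling behaviour: home, anchor places with
    daily visit probabilities, and day-level gap probabilities."""

    user_id: str
    home: tuple
    anchors: list  # (lat, lon, daily visit probability)
    base_points_per_day: int
    gap_prob_location: float
    gap_prob_survey: float

    def validate(self) -> "AgentProfile":
        if len(self.anchors) < 2:
            raise ValueError("need at least 2 anchors")
        pts = [self.home] + [(a[0], a[1]) for a in self.anchors]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d_m = float(haversine_km(pts[i][0], pts[i][1], pts[j][0], pts[j][1])) * 1000.0
                if d_m < 400.0:
                    raise ValueError("anchors must be >= 400 m apart and from home")
        for a in self.anchors:
            if not 0.0 <= a[2] <= 1.0:
                raise ValueError("visit probability must lie in [0, 1]")
        return self


@dataclass
class IllnessEpisode:
    user_id: str
    onset_day: date
    duration_days: int
    symptoms: list
    prodrome_days: int = 2
    effect_size: float = 0.0

    def validate(self) -> "IllnessEpisode":
        if not self.symptoms:
            raise ValueError("episode must have at least one symptom")
        if self.duration_days < 1:
            raise ValueError("duration_days must be positive")
        return self


def _offset(home, dist_m, bearing_rad):
    dlat = dist_m * np.cos(bearing_rad) / M_PER_DEG_LAT
    dlon = dist_m * np.sin(bearing_rad) / (M_PER_DEG_LAT * np.cos(np.radians(home[0])))
    return (home[0] + dlat, home[1] + dlon)


def _make_profile(idx: int, rng: np.random.Generator, config: SimulationConfig) -> AgentProfile:
    home = (45.9 + rng.uniform(-0.05, 0.05), 11.0 + rng.uniform(-0.07, 0.07))
    n_anchors = int(rng.integers(2, 5))
    anchors = []
    while len(anchors) < n_anchors:
        cand = _offset(home, rng.uniform(600.0, 4000.0), rng.uniform(0, 2 * np.pi))
        ok = all(
            float(haversine_km(cand[0], cand[1], p[0], p[1])) * 1000.0 >= 420.0
            for p in [home] + [(a[0], a[1]) for a in anchors]
        )
        if ok:
            prob = 0.85 if not anchors else float(rng.uniform(0.25, 0.55))
            anchors.append((cand[0], cand[1], prob))
    return AgentProfile(
        user_id=f"u{idx:03d}",
        home=home,
        anchors=anchors,
        base_points_per_day=int(24 * 60 / config.night_sample_min),
        gap_prob_location=config.gap_prob_location,
        gap_prob_survey=config.gap_prob_survey,
    ).validate()


def _make_episodes(profile, rng, config) -> list:
    n_ep = int(rng.poisson(config.episode_rate_per_month * config.n_days / 30.0))
    taken = np.zeros(config.n_days, dtype=bool)
    episodes = []
    for _ in range(n_ep):
        for _attempt in range(20):
            duration = int(rng.integers(3, 8))
            onset = int(rng.integers(config.prodrome_days, config.n_days))
            lo = max(0, onset - config.prodrome_days)
            hi = min(config.n_days, onset + duration)
            if not taken[lo:hi].any():
                taken[lo:hi] = True
                k = int(rng.integers(1, 5))
                symptoms = sorted(rng.choice(mio.SYMPTOM_NAMES, size=k, replace=False).tolist())
                episodes.append(
                    IllnessEpisode(
                        user_id=profile.user_id,
                        onset_day=config.start_date + timedelta(days=onset),
                        duration_days=duration,
                        symptoms=symptoms,
                        prodrome_days=config.prodrome_days,
                        effect_size=config.effect_size,
                    ).validate()
                )
                break
    return episodes


def _sample_times(start_s: float, end_s: float, step_min: float, include_start=True):
    step = step_min * 60.0
    t0 = start_s if include_start else start_s + step
    if t0 >= end_s:
        return np.empty(0)
    return np.arange(t0, end_s, step)


def _day_points(profile, contracted, delta, rng, config):
    """(times_s, lats, lons) for one non-gapped simulated day."""
    home = profile.home
    scale = (1.0 - delta) if contracted else 1.0
    segs = []  # (times, lat0, lon0, lat1, lon1) — dwell when endpoints equal

    def dwell(t0, t1, pos, step):
        t = _sample_times(t0, t1, step)
        if len(t):
            segs.append((t, np.full(len(t), pos[0]), np.full(len(t), pos[1])))

    def travel(t0, pos0, pos1):
        dist_km = float(haversine_km(pos0[0], pos0[1], pos1[0], pos1[1]))
        dur_s = dist_km / config.travel_speed_kmh * 3600.0
        t = _sample_times(t0, t0 + dur_s, config.travel_sample_min, include_start=False)
        if len(t):
            frac = (t - t0) / dur_s
            segs.append(
                (
                    t,
                    pos0[0] + frac * (pos1[0] - pos0[0]),
                    pos0[1] + frac * (pos1[1] - pos0[1]),
                )
            )
        return t0 + dur_s

    H = 3600.0
    visited = []
    for lat, lon, prob in profile.anchors:
        if rng.random() < prob * scale:
            visited.append((home[0] + (lat - home[0]) * scale, home[1] + (lon - home[1]) * scale))
    depart = 8.0 * H + rng.uniform(0.0, H)
    dwell(0.0, 7.0 * H, home, config.night_sample_min)
    dwell(7.0 * H, depart, home, config.dwell_sample_min)
    now, pos = depart, home
    for anchor in visited:
        stay = rng.uniform(1.0, 2.5) * H
        back_km = float(haversine_km(anchor[0], anchor[1], home[0], home[1]))
        if now + stay + back_km / config.travel_speed_kmh * 3600.0 > 18.5 * H:
            break
        now = travel(now, pos, anchor)
        dwell(now, now + stay, anchor, config.dwell_sample_min)
        now, pos = now + stay, anchor
    if pos != home:
        now = travel(now, pos, home)
    dwell(now, 24.0 * H, home, config.night_sample_min)
    times = np.concatenate([s[0] for s in segs])
    lats = np.concatenate([s[1] for s in segs])
    lons = np.concatenate([s[2] for s in segs])
    order = np.argsort(times, kind="stable")
    return times[order], lats[order], lons[order]


def generate_profiles(config: SimulationConfig) -> list:
    """The cohort's agent profiles (ground truth for recovery tests);
    drawn from a dedicated seed stream so they can be regenerated without
    re-simulating the point streams."""
    rng = np.random.default_rng([config.seed, 1])
    return [_make_profile(idx, rng, config) for idx in range(config.n_users)]


def simulate_cohort(config: SimulationConfig):
    """Generate (locations, symptoms, episodes) tables for one cohort.

    Location rows are sorted by (user, time); gap days emit no rows for the
    gapped stream; symptom rows carry yes for the active episode's symptoms
    on days [onset, onset + duration). Fixed config + seed reproduce the
    tables exactly.
    """
    config.validate()
    profiles = generate_profiles(config)
    rng = np.random.default_rng([config.seed, 2])
    start = pd.Timestamp(config.start_date, tz="UTC")
    loc_parts = []
    sym_rows = []
    ep_rows = []
    for idx in range(config.n_users):
        profile = profiles[idx]
        episodes = _make_episodes(profile, rng, config)
        contracted = np.zeros(config.n_days, dtype=bool)
        symptomatic = {}
        for ep in episodes:
            onset = (ep.onset_day - config.start_date).days
            contracted[max(0, onset - ep.prodrome_days): min(config.n_days, onset + ep.duration_days)] = True
            for d in range(onset, min(config.n_days, onset + ep.duration_days)):
                symptomatic.setdefault(d, set()).update(ep.symptoms)
            ep_rows.append(
                {
                    "user_id": ep.user_id,
                    "onset_date": ep.onset_day,
                    "duration_days": ep.duration_days,
                    "prodrome_days": ep.prodrome_days,
                    "symptom_list": ";".join(ep.symptoms),
                }
            )
        for d in range(config.n_days):
            loc_gap = rng.random() < profile.gap_prob_location
            srv_gap = rng.random() < profile.gap_prob_survey
            if not loc_gap:
                t, lat, lon = _day_points(
                    profile, bool(contracted[d]), config.effect_size, rng, config
                )
                n = len(t)
                is_gps = rng.random(n) < config.gps_fraction
                acc = np.where(
                    is_gps,
                    rng.uniform(*config.gps_accuracy_m, size=n),
                    rng.uniform(*config.network_accuracy_m, size=n),
                )
                noise_sd = np.where(is_gps, config.gps_noise_sd_m, acc / 3.0)
                lat = lat + rng.normal(0.0, 1.0, n) * noise_sd / M_PER_DEG_LAT
                lon = lon + rng.normal(0.0, 1.0, n) * noise_sd / (
                    M_PER_DEG_LAT * np.cos(np.radians(profile.home[0]))
                )
                loc_parts.append(
                    pd.DataFrame(
                        {
                            "user_id": profile.user_id,
                            "latitude": lat,
                            "longitude": lon,
                            "source": np.where(is_gps, "GPS", "NETWORK"),
                            "accuracy_m": np.round(acc, 1),
                            "timestamp": start
                            + pd.to_timedelta(d, unit="D")
                            + pd.to_timedelta(np.round(t).astype(np.int64), unit="s"),
                        }
                    )
                )
            if not srv_gap:
                active = symptomatic.get(d, set())
                row = {
                    "user_id": profile.user_id,
                    "date": config.start_date + timedelta(days=d),
                }
                for s in mio.SYMPTOM_NAMES:
                    row[s] = s in active
                sym_rows.append(row)
    locations = (
        pd.concat(loc_parts, ignore_index=True)
        if loc_parts
        else pd.DataFrame(
            columns=["user_id", "latitude", "longitude", "source", "accuracy_m", "timestamp"]
        )
    )
    locations = locations.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)
    symptoms = pd.DataFrame(sym_rows, columns=["user_id", "date"] + mio.SYMPTOM_NAMES)
    if len(symptoms):
        symptoms["any_symptom"] = symptoms[mio.SYMPTOM_NAMES].any(axis=1)
    else:
        symptoms["any_symptom"] = pd.Series(dtype=bool)
    episodes = pd.DataFrame(
        ep_rows,
        columns=["user_id", "onset_date", "duration_days", "prodrome_days", "symptom_list"],
    )
    return locations, symptoms, episodes


def write_fixture(tables, directory) -> dict:
    """Write (locations, symptoms, episodes) as the CSV interchange files;
    returns the paths. Round-trips losslessly through the readers."""
    from pathlib import Path

    locations, symptoms, episodes = tables
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return {
        "locations": mio.write_locations(locations, directory / "locations.csv"),
        "symptoms": mio.write_symptoms(symptoms, directory / "symptoms.csv"),
        "episodes": mio.write_episodes(episodes, directory / "episodes.csv"),
    }


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain dict (e.g. parsed YAML); unknown keys are
    rejected."""
    d = dict(d)
    if "start_date" in d and isinstance(d["start_date"], str):
        d["start_date"] = date.fromisoformat(d["start_date"])
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    for key in ("gps_accuracy_m", "network_accuracy_m"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d).validate()
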