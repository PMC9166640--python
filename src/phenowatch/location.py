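"""GPS stay points, places, home and the location outcome block.

A *stay point* is a temporal episode in which consecutive fixes remain
within ``radius_m`` (default 350 m) of the episode's **first** fix for at
least ``min_duration_min`` (default 60 min).  Detection is the classic
sequential first-fix-centered scan: open a candidate at fix *i* with center
*i*, extend while each later fix stays within the radius of that center,
close at the first fix outside, emit if the dwell met the duration
threshold, and resume at the closing fix.  A gap between consecutive fixes
longer than ``gap_close_min`` closes any open candidate the same way, so a
data hole can never fabricate a dwell.

Stay points are merged into *places* greedily in time order (a stay point
joins the first place whose founding center lies within ``merge_radius_m``,
else founds a new place), *home* is the place with the most dwell time
between 00:00 and 06:00 over the study, and *trajectories* are the
movement segments between consecutive stay points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._geo import haversine_km, haversine_m

NIGHT_WINDOW_H = (0, 6)
EVENING_START_H = 19
MINUTES_PER_DAY = 1440

STAY_POINT_COLUMNS = ["arrival", "departure", "latitude", "longitude",
                      "duration_min", "i_start", "i_end"]


# ---------------------------------------------------------------------------
# detection

def _scan_run(t_s: np.ndarray, lat: np.ndarray, lon: np.ndarray,
              a: int, b: int, radius_m: float, min_duration_s: float,
              out: list, chunk: int = 256) -> None:
    """Scan fixes a..b (inclusive, no internal gaps) and append (i, last_in)."""
    i = a
    while i < b:
        first_out = -1
        j = i + 1
        while j <= b:
            hi = min(j + chunk - 1, b)
            d = haversine_m(lat[i], lon[i], lat[j:hi + 1], lon[j:hi + 1])
            outside = np.flatnonzero(d > radius_m)
            if outside.size:
                first_out = j + int(outside[0])
                break
            j = hi + 1
        last_in = (first_out - 1) if first_out >= 0 else b
        if t_s[last_in] - t_s[i] >= min_duration_s:
            out.append((i, last_in))
        if first_out < 0:
            break
        i = first_out


class StayPointDetector(TransformerMixin, BaseEstimator):
    """Detect stay points in one participant's time-ordered GPS fixes.

    A stateless transformer: ``transform`` maps a fixes DataFrame
    (``timestamp``, ``latitude``, ``longitude``) to a stay-point DataFrame
    with the episode's arrival/departure, its center (the first fix),
    duration in minutes, and the member-fix index range (inclusive).

    Parameters
    ----------
    radius_m : float
        Cluster radius around the episode's first fix.
    min_duration_min : float
        Minimum dwell for an episode to count as a stay point.
    gap_close_min : float
        A fix-to-fix gap longer than this closes any open candidate.
    """

    def __init__(self, radius_m: float = 350.0, min_duration_min: float = 60.0,
                 gap_close_min: float = 30.0):
        self.radius_m = radius_m
        self.min_duration_min = min_duration_min
        self.gap_close_min = gap_close_min

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        fixes = X
        if len(fixes) < 2:
            return pd.DataFrame(columns=STAY_POINT_COLUMNS)
        ts = fixes["timestamp"]
        if not ts.is_monotonic_increasing:
            raise ValueError("fixes must be ordered by timestamp")
        t_s = ts.astype("int64").to_numpy() / 1e9
        lat = fixes["latitude"].to_numpy(dtype=float)
        lon = fixes["longitude"].to_numpy(dtype=float)

        episodes: list[tuple[int, int]] = []
        gap_idx = np.flatnonzero(np.diff(t_s) > self.gap_close_min * 60.0)
        run_starts = np.concatenate([[0], gap_idx + 1])
        run_ends = np.concatenate([gap_idx, [len(t_s) - 1]])
        for a, b in zip(run_starts, run_ends):
            _scan_run(t_s, lat, lon, int(a), int(b), self.radius_m,
                      self.min_duration_min * 60.0, episodes)

        rows = [{"arrival": ts.iloc[i], "departure": ts.iloc[j],
                 "latitude": lat[i], "longitude": lon[i],
                 "duration_min": (t_s[j] - t_s[i]) / 60.0,
                 "i_start": i, "i_end": j} for i, j in episodes]
        return pd.DataFrame(rows, columns=STAY_POINT_COLUMNS)


def detect_stay_points(fixes: pd.DataFrame, radius_m: float = 350.0,
                       min_duration_min: float = 60.0,
                       gap_close_min: float = 30.0) -> pd.DataFrame:
    return StayPointDetector(radius_m, min_duration_min, gap_close_min).transform(fixes)


# ---------------------------------------------------------------------------
# clock-window overlap

def window_overlap_minutes(start: pd.Timestamp, end: pd.Timestamp,
                           window_h: tuple[float, float] = NIGHT_WINDOW_H) -> float:
    """Minutes of [start, end] falling inside the daily clock window."""
    total = 0.0
    day = start.normalize()
    while day <= end:
        w0 = day + pd.Timedelta(hours=window_h[0])
        w1 = day + pd.Timedelta(hours=window_h[1])
        lo, hi = max(start, w0), min(end, w1)
        if hi > lo:
            total += (hi - lo).total_seconds() / 60.0
        day += pd.Timedelta(days=1)
    return total


def outside_office_overlap_minutes(start: pd.Timestamp, end: pd.Timestamp,
                                   evening_start_h: float = EVENING_START_H) -> float:
    """Minutes of [start, end] after the evening hour on weekdays or any
    time on Saturday/Sunday."""
    total = 0.0
    day = start.normalize()
    while day <= end:
        w0 = day if day.dayofweek >= 5 else day + pd.Timedelta(hours=evening_start_h)
        w1 = day + pd.Timedelta(days=1)
        lo, hi = max(start, w0), min(end, w1)
        if hi > lo:
            total += (hi - lo).total_seconds() / 60.0
        day += pd.Timedelta(days=1)
    return total


def _qualifies(sp_row, overlap_min: float, semantics: str, in_window_at_arrival: bool) -> bool:
    if semantics == "overlap":
        return overlap_min > 0
    if semantics == "arrival":
        return in_window_at_arrival
    raise ValueError(f"unknown window semantics: {semantics!r}")


# ---------------------------------------------------------------------------
# places, home, trajectories

def merge_places(stay_points: pd.DataFrame,
                 merge_radius_m: float = 350.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign stay points to places greedily in time order.

    Returns ``(stay_points_with_place_id, places)``; a place's
    representative center is the center of its founding stay point.
    """
    sp = stay_points.sort_values("arrival", kind="stable").reset_index(drop=True)
    centers_lat: list[float] = []
    centers_lon: list[float] = []
    assignment = np.empty(len(sp), dtype=int)
    for k, row in enumerate(sp.itertuples(index=False)):
        if centers_lat:
            d = haversine_m(np.array(centers_lat), np.array(centers_lon),
                            row.latitude, row.longitude)
            close = np.flatnonzero(d <= merge_radius_m)
            if close.size:
                assignment[k] = int(close[0])
                continue
        centers_lat.append(row.latitude)
        centers_lon.append(row.longitude)
        assignment[k] = len(centers_lat) - 1
    sp["place_id"] = assignment

    if len(sp):
        night = sp.apply(lambda r: window_overlap_minutes(r["arrival"], r["departure"]),
                         axis=1)
        places = (sp.assign(night_dwell_min=night)
                  .groupby("place_id")
                  .agg(n_visits=("place_id", "size"),
                       total_dwell_min=("duration_min", "sum"),
                       night_dwell_min=("night_dwell_min", "sum"),
                       first_arrival=("arrival", "min"))
                  .reset_index())
        places["latitude"] = np.array(centers_lat)[places["place_id"]]
        places["longitude"] = np.array(centers_lon)[places["place_id"]]
    else:
        places = pd.DataFrame(columns=["place_id", "n_visits", "total_dwell_min",
                                       "night_dwell_min", "first_arrival",
                                       "latitude", "longitude"])
    return sp, places


def infer_home(places: pd.DataFrame) -> int | None:
    """Place with the most 00:00-06:00 dwell over the study; ties broken by
    earliest first visit; ``None`` when no place has any night dwell."""
    if not len(places) or places["night_dwell_min"].max() <= 0:
        return None
    best = places[places["night_dwell_min"] == places["night_dwell_min"].max()]
    best = best.sort_values("first_arrival", kind="stable")
    return int(best["place_id"].iloc[0])


def build_trajectories(stay_points: pd.DataFrame, fixes: pd.DataFrame) -> pd.DataFrame:
    """Movement segments between consecutive stay points.

    Distance sums the haversine lengths of all fix-to-fix hops between the
    departure fix of one stay point and the arrival fix of the next; travel
    time is the departure-to-arrival clock gap.
    """
    rows = []
    lat = fixes["latitude"].to_numpy(dtype=float)
    lon = fixes["longitude"].to_numpy(dtype=float)
    sp = stay_points.reset_index(drop=True)
    for k in range(len(sp) - 1):
        i = int(sp.loc[k, "i_end"])
        j = int(sp.loc[k + 1, "i_start"])
        hop = float(np.sum(haversine_km(lat[i:j], lon[i:j], lat[i + 1:j + 1],
                                        lon[i + 1:j + 1]))) if j > i else 0.0
        rows.append({
            "from_sp": k, "to_sp": k + 1,
            "departure": sp.loc[k, "departure"], "arrival": sp.loc[k + 1, "arrival"],
            "distance_km": hop,
            "travel_min": (sp.loc[k + 1, "arrival"] - sp.loc[k, "departure"])
            .total_seconds() / 60.0})
    return pd.DataFrame(rows, columns=["from_sp", "to_sp", "departure", "arrival",
                                       "distance_km", "travel_min"])


def time_accounting(stay_points: pd.DataFrame, trajectories: pd.DataFrame,
                    window_start: pd.Timestamp, window_end: pd.Timestamp) -> dict[str, float]:
    """Decompose the observation window into dwell, travel and explicit gaps.

    The gaps are the lead-in before the first arrival and the tail after the
    last departure (between stay points, travel time covers the whole gap by
    definition), so dwell + travel + gap always reproduces the window.
    """
    total = (window_end - window_start).total_seconds() / 60.0
    dwell = float(stay_points["duration_min"].sum()) if len(stay_points) else 0.0
    travel = float(trajectories["travel_min"].sum()) if len(trajectories) else 0.0
    if len(stay_points):
        lead = (stay_points["arrival"].iloc[0] - window_start).total_seconds() / 60.0
        tail = (window_end - stay_points["departure"].iloc[-1]).total_seconds() / 60.0
    else:
        lead, tail = total, 0.0
    return {"dwell_min": dwell, "travel_min": travel, "gap_min": lead + tail,
            "total_min": total}


# ---------------------------------------------------------------------------
# the feature block

def location_features(stay_points: pd.DataFrame, places: pd.DataFrame,
                      trajectories: pd.DataFrame, fixes: pd.DataFrame,
                      participation_days: int, *,
                      semantics: str = "overlap",
                      evening_start_h: float = EVENING_START_H) -> dict[str, float]:
    """Location outcome block from detected entities.

    Home-relative outcomes are ``NaN`` when no home could be inferred; with
    no trajectories the per-day trajectory count is 0 and the travel
    distance/time summaries are ``NaN`` (zero-travel rule).  Counts are per
    day; dwell/travel summaries are study-level.
    """
    if participation_days < 1:
        raise ValueError(f"participation_days must be >= 1, got {participation_days}")
    days = float(participation_days)
    feats: dict[str, float] = {}
    n_sp = len(stay_points)
    n_places = len(places)
    home_id = infer_home(places)

    feats["loc_stay_points"] = n_sp / days
    feats["loc_unique_stay_points"] = n_places / days

    if n_sp:
        sp = stay_points.reset_index(drop=True)
        night_min = sp.apply(lambda r: window_overlap_minutes(r["arrival"], r["departure"]),
                             axis=1)
        ooh_min = sp.apply(lambda r: outside_office_overlap_minutes(
            r["arrival"], r["departure"], evening_start_h), axis=1)
        arr_h = sp["arrival"].dt.hour
        night_q = np.array([_qualifies(r, night_min[k], semantics,
                                       NIGHT_WINDOW_H[0] <= arr_h[k] < NIGHT_WINDOW_H[1])
                            for k, r in enumerate(sp.itertuples())])
        wknd = sp["arrival"].dt.dayofweek >= 5
        ooh_q = np.array([_qualifies(r, ooh_min[k], semantics,
                                     bool(wknd[k] or arr_h[k] >= evening_start_h))
                          for k, r in enumerate(sp.itertuples())])
        non_home = (sp["place_id"] != home_id).to_numpy()
    else:
        sp = stay_points
        night_q = ooh_q = non_home = np.array([], dtype=bool)

    if home_id is None:
        feats["loc_nightly_stay_points_excl_home"] = np.nan
        feats["loc_unique_nightly_stay_points"] = np.nan
        feats["loc_outside_office_hours_stay_points"] = np.nan
        feats["loc_unique_outside_office_hours_stay_points"] = np.nan
    else:
        feats["loc_nightly_stay_points_excl_home"] = int((night_q & non_home).sum()) / days
        feats["loc_unique_nightly_stay_points"] = (
            sp.loc[night_q & non_home, "place_id"].nunique() / days)
        feats["loc_outside_office_hours_stay_points"] = int((ooh_q & non_home).sum()) / days
        feats["loc_unique_outside_office_hours_stay_points"] = (
            sp.loc[ooh_q & non_home, "place_id"].nunique() / days)

    single = int((places["n_visits"] == 1).sum()) if n_places else 0
    feats["loc_single_visits"] = single / days
    feats["loc_pct_stay_points_visited_once"] = (100.0 * single / n_places
                                                 if n_places else np.nan)
    feats["loc_mean_time_stationary"] = (float(stay_points["duration_min"].mean())
                                         if n_sp else np.nan)

    feats["loc_trajectories"] = len(trajectories) / days
    if len(trajectories):
        daily = trajectories.assign(day=trajectories["departure"].dt.normalize()).groupby("day")
        dist = daily["distance_km"].sum()
        tmin = daily["travel_min"].sum()
        feats["loc_mean_distance_traveled"] = float(dist.mean())
        feats["loc_sd_distance_traveled"] = float(dist.std(ddof=1)) if len(dist) > 1 else np.nan
        feats["loc_mean_time_traveled"] = float(tmin.mean())
        feats["loc_sd_time_traveled"] = float(tmin.std(ddof=1)) if len(tmin) > 1 else np.nan
    else:
        for k in ("loc_mean_distance_traveled", "loc_sd_distance_traveled",
                  "loc_mean_time_traveled", "loc_sd_time_traveled"):
            feats[k] = np.nan

    if home_id is None:
        feats["loc_max_distance_from_home"] = np.nan
        feats["loc_avg_distance_from_home"] = np.nan
        feats["loc_pct_time_at_home"] = np.nan
        feats["loc_pct_time_at_home_window"] = np.nan
    else:
        hrow = places.set_index("place_id").loc[home_id]
        place_dist = pd.Series(
            haversine_km(places["latitude"].to_numpy(), places["longitude"].to_numpy(),
                         hrow["latitude"], hrow["longitude"]),
            index=places["place_id"].to_numpy())
        feats["loc_max_distance_from_home"] = float(place_dist.max())
        w = sp["duration_min"].to_numpy(dtype=float)
        d = place_dist.reindex(sp["place_id"]).to_numpy(dtype=float)
        feats["loc_avg_distance_from_home"] = float(np.average(d, weights=w))
        total_dwell = float(stay_points["duration_min"].sum())
        home_dwell = float(stay_points.loc[stay_points["place_id"] == home_id,
                                           "duration_min"].sum())
        feats["loc_pct_time_at_home"] = 100.0 * home_dwell / total_dwell
        feats["loc_pct_time_at_home_window"] = (100.0 * home_dwell
                                                / (days * MINUTES_PER_DAY))
    return feats


def location_block(fixes: pd.DataFrame, participation_days: int, *,
                   radius_m: float = 350.0, min_duration_min: float = 60.0,
                   merge_radius_m: float = 350.0, gap_close_min: float = 30.0,
                   semantics: str = "overlap",
                   evening_start_h: float = EVENING_START_H) -> dict[str, float]:
    """Full location block for one participant, or all-missing when the GPS
    stream is absent (fewer than 2 fixes)."""
    from .catalog import LOCATION_FEATURES
    if len(fixes) < 2:
        return {k: np.nan for k in LOCATION_FEATURES}
    fixes = fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)
    sp = detect_stay_points(fixes, radius_m, min_duration_min, gap_close_min)
    sp, places = merge_places(sp, merge_radius_m)
    traj = build_trajectories(sp, fixes)
    return location_features(sp, places, traj, fixes, participation_days,
                             semantics=semantics, evening_start_h=evening_start_h)
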