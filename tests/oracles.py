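"""Independent naive reference implementations used as test oracles.

Everything here deliberately re-derives results from first principles with
plain loops and its own great-circle formula, so agreement with the package
is evidence, not tautology.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np

R_EARTH_M = 6371008.8


def ref_distance_m(lat1, lon1, lat2, lon2):
    """Great-circle distance via the atan2 formulation (not haversine)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float))
                      for v in (lat1, lon1, lat2, lon2))
    dl = l2 - l1
    num = np.sqrt((np.cos(p2) * np.sin(dl)) ** 2
                  + (np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)) ** 2)
    den = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return R_EARTH_M * np.arctan2(num, den)


def ref_stay_points(t_s, lat, lon, radius_m=350.0, min_duration_s=3600.0,
                    gap_close_s=1800.0):
    """Exhaustive O(n^2) scan: every candidate recomputes all its distances.

    Returns a list of (first_fix_index, last_inside_index) episodes.
    """
    t_s = np.asarray(t_s, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    n = len(t_s)
    episodes = []
    i = 0
    while i < n - 1:
        # candidate ends at a gap, the sequence end, or the first far fix
        j = i + 1
        stop = n
        while j < n:
            if t_s[j] - t_s[j - 1] > gap_close_s:
                stop = j
                break
            j += 1
        d = ref_distance_m(lat[i], lon[i], lat[i + 1:stop], lon[i + 1:stop])
        outside = np.flatnonzero(d > radius_m)
        if outside.size:
            first_out = i + 1 + int(outside[0])
            last_in = first_out - 1
        else:
            first_out = None
            last_in = stop - 1
        if t_s[last_in] - t_s[i] >= min_duration_s:
            episodes.append((i, last_in))
        if first_out is not None:
            i = first_out
        elif stop < n:
            i = stop
        else:
            break
    return episodes


# ---------------------------------------------------------------------------
# communication features, one pass per feature

def ref_call_features(events: list[dict], days: int) -> dict:
    """events: dicts with direction, contact, duration_s."""
    out = {}
    for direction in ("incoming", "outgoing", "missed"):
        sub = [e for e in events if e["direction"] == direction]
        out[f"calls_{direction}_number"] = len(sub) / days
        counts: dict[str, int] = {}
        for e in sub:
            counts[e["contact"]] = counts.get(e["contact"], 0) + 1
        out[f"calls_{direction}_unique_contacts"] = len(counts) / days
        if direction != "missed":
            out[f"calls_{direction}_single_use_contacts"] = (
                sum(1 for v in counts.values() if v == 1) / days)
            out[f"calls_{direction}_duration"] = (
                sum(e["duration_s"] for e in sub) / days)
    out["calls_incoming_nonzero_duration_number"] = (
        sum(1 for e in events if e["direction"] == "incoming" and e["duration_s"] > 0)
        / days)
    out["calls_outgoing_nonresponse_number"] = (
        sum(1 for e in events if e["direction"] == "outgoing" and e["duration_s"] == 0)
        / days)
    all_contacts = {e["contact"] for e in events}
    out["calls_mean_repeated_contacts"] = (
        len(events) / len(all_contacts) if events else float("nan"))
    return out


def ref_app_features(sessions: list[dict], days: int) -> dict:
    """sessions: dicts with start, end (datetime), category."""
    out = {
        "apps_all_times_opened": len(sessions) / days,
        "apps_all_duration_opened": sum((s["end"] - s["start"]).total_seconds()
                                        for s in sessions) / days,
        "apps_all_times_opened_night": sum(1 for s in sessions
                                           if 0 <= s["start"].hour < 6) / days,
    }
    for cat in ("communication", "social_media", "entertainment", "news_magazines"):
        sub = [s for s in sessions if s["category"] == cat]
        out[f"apps_{cat}_times_opened"] = len(sub) / days
        total = sum((s["end"] - s["start"]).total_seconds() for s in sub)
        out[f"apps_{cat}_mean_duration"] = total / len(sub) if sub else float("nan")
    return out


# ---------------------------------------------------------------------------
# location block from scratch

def _overlap_night(start: dt.datetime, end: dt.datetime) -> float:
    """Minutes of [start, end] between 00:00 and 06:00, by day walking."""
    total = 0.0
    day = dt.datetime(start.year, start.month, start.day)
    while day <= end:
        lo = max(start, day)
        hi = min(end, day + dt.timedelta(hours=6))
        if hi > lo:
            total += (hi - lo).total_seconds() / 60.0
        day += dt.timedelta(days=1)
    return total


def _overlap_outside_office(start: dt.datetime, end: dt.datetime) -> float:
    total = 0.0
    day = dt.datetime(start.year, start.month, start.day)
    while day <= end:
        w0 = day if day.weekday() >= 5 else day + dt.timedelta(hours=19)
        lo = max(start, w0)
        hi = min(end, day + dt.timedelta(days=1))
        if hi > lo:
            total += (hi - lo).total_seconds() / 60.0
        day += dt.timedelta(days=1)
    return total


def ref_location_features(times: list[dt.datetime], lat, lon, days: int,
                          radius_m=350.0, min_duration_min=60.0,
                          merge_radius_m=350.0, gap_close_min=30.0) -> dict:
    """Full location block recomputed from raw fixes with naive loops."""
    nan = float("nan")
    keys = ["loc_stay_points", "loc_unique_stay_points",
            "loc_nightly_stay_points_excl_home", "loc_unique_nightly_stay_points",
            "loc_outside_office_hours_stay_points",
            "loc_unique_outside_office_hours_stay_points", "loc_single_visits",
            "loc_pct_stay_points_visited_once", "loc_mean_time_stationary",
            "loc_mean_distance_traveled", "loc_sd_distance_traveled",
            "loc_mean_time_traveled", "loc_sd_time_traveled", "loc_trajectories",
            "loc_max_distance_from_home", "loc_avg_distance_from_home",
            "loc_pct_time_at_home", "loc_pct_time_at_home_window"]
    if len(times) < 2:
        return {k: nan for k in keys}
    t_s = np.array([t.timestamp() for t in times])
    episodes = ref_stay_points(t_s, lat, lon, radius_m, min_duration_min * 60.0,
                               gap_close_min * 60.0)
    out = {k: nan for k in keys}
    out["loc_stay_points"] = len(episodes) / days
    sps = [{"i": i, "j": j, "arr": times[i], "dep": times[j],
            "lat": lat[i], "lon": lon[i], "dur": (t_s[j] - t_s[i]) / 60.0}
           for i, j in episodes]

    # greedy place assignment in time order
    centers: list[tuple[float, float]] = []
    for sp in sps:
        sp["place"] = None
        for pid, (clat, clon) in enumerate(centers):
            if ref_distance_m(clat, clon, sp["lat"], sp["lon"]) <= merge_radius_m:
                sp["place"] = pid
                break
        if sp["place"] is None:
            centers.append((sp["lat"], sp["lon"]))
            sp["place"] = len(centers) - 1
    out["loc_unique_stay_points"] = len(centers) / days

    visits: dict[int, int] = {}
    for sp in sps:
        visits[sp["place"]] = visits.get(sp["place"], 0) + 1
    single = sum(1 for v in visits.values() if v == 1)
    out["loc_single_visits"] = single / days
    out["loc_pct_stay_points_visited_once"] = (100.0 * single / len(centers)
                                               if centers else nan)
    out["loc_mean_time_stationary"] = (sum(sp["dur"] for sp in sps) / len(sps)
                                       if sps else nan)

    # home: most night dwell, earliest first visit breaks ties
    night_by_place: dict[int, float] = {}
    first_visit: dict[int, dt.datetime] = {}
    for sp in sps:
        night_by_place[sp["place"]] = (night_by_place.get(sp["place"], 0.0)
                                       + _overlap_night(sp["arr"], sp["dep"]))
        first_visit.setdefault(sp["place"], sp["arr"])
    home = None
    if night_by_place and max(night_by_place.values()) > 0:
        best = max(night_by_place.values())
        home = min((p for p, v in night_by_place.items() if v == best),
                   key=lambda p: first_visit[p])

    if home is not None:
        nightly = [sp for sp in sps if sp["place"] != home
                   and _overlap_night(sp["arr"], sp["dep"]) > 0]
        ooh = [sp for sp in sps if sp["place"] != home
               and _overlap_outside_office(sp["arr"], sp["dep"]) > 0]
        out["loc_nightly_stay_points_excl_home"] = len(nightly) / days
        out["loc_unique_nightly_stay_points"] = len({sp["place"] for sp in nightly}) / days
        out["loc_outside_office_hours_stay_points"] = len(ooh) / days
        out["loc_unique_outside_office_hours_stay_points"] = (
            len({sp["place"] for sp in ooh}) / days)
        hlat, hlon = centers[home]
        dists = [float(ref_distance_m(clat, clon, hlat, hlon)) / 1000.0
                 for clat, clon in centers]
        out["loc_max_distance_from_home"] = max(dists)
        wsum = sum(sp["dur"] for sp in sps)
        out["loc_avg_distance_from_home"] = (
            sum(dists[sp["place"]] * sp["dur"] for sp in sps) / wsum)
        home_dwell = sum(sp["dur"] for sp in sps if sp["place"] == home)
        out["loc_pct_time_at_home"] = 100.0 * home_dwell / wsum
        out["loc_pct_time_at_home_window"] = 100.0 * home_dwell / (days * 1440.0)

    # trajectories between consecutive stay points
    daily_dist: dict[dt.date, float] = {}
    daily_time: dict[dt.date, float] = {}
    n_traj = 0
    for a, b in zip(sps, sps[1:]):
        dist = sum(float(ref_distance_m(lat[k], lon[k], lat[k + 1], lon[k + 1])) / 1000.0
                   for k in range(a["j"], b["i"]))
        tmin = (b["arr"] - a["dep"]).total_seconds() / 60.0
        day = a["dep"].date()
        daily_dist[day] = daily_dist.get(day, 0.0) + dist
        daily_time[day] = daily_time.get(day, 0.0) + tmin
        n_traj += 1
    out["loc_trajectories"] = n_traj / days
    if n_traj:
        dvals = list(daily_dist.values())
        tvals = list(daily_time.values())
        out["loc_mean_distance_traveled"] = float(np.mean(dvals))
        out["loc_sd_distance_traveled"] = (float(np.std(dvals, ddof=1))
                                           if len(dvals) > 1 else nan)
        out["loc_mean_time_traveled"] = float(np.mean(tvals))
        out["loc_sd_time_traveled"] = (float(np.std(tvals, ddof=1))
                                       if len(tvals) > 1 else nan)
    return out


# ---------------------------------------------------------------------------
# random fix sequences for scanner stress tests

def random_fix_sequence(rng: np.random.Generator, max_fixes: int = 500):
    """A mixture of dwell phases, slow drifts and jumps, with variable
    sampling intervals and occasional long gaps; scales chosen so that many
    distances land near the 350 m radius."""
    n = int(rng.integers(2, max_fixes + 1))
    lat0, lon0 = 52.0 + rng.uniform(-1, 1), 4.0 + rng.uniform(-1, 1)
    t = np.cumsum(rng.choice([60.0, 300.0, 600.0, 2400.0], size=n,
                             p=[0.3, 0.5, 0.15, 0.05]))
    lat = np.empty(n)
    lon = np.empty(n)
    clat, clon = lat0, lon0
    deg_per_m = 1.0 / 111320.0
    for k in range(n):
        u = rng.random()
        if u < 0.55:      # jitter near the current anchor
            step = rng.normal(0, 80.0, 2)
        elif u < 0.85:    # drift near the radius scale
            step = rng.normal(0, 350.0, 2)
        else:             # jump far away
            step = rng.normal(0, 3000.0, 2)
        clat += step[0] * deg_per_m
        clon += step[1] * deg_per_m / math.cos(math.radians(clat))
        lat[k], lon[k] = clat, clon
    return t, lat, lon
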