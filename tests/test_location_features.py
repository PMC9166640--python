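"""Places, home inference, trajectories and the location outcome block."""

import numpy as np
import pandas as pd
import pytest

from phenowatch._geo import haversine_km, offset_latlon
from phenowatch.location import (
    build_trajectories,
    detect_stay_points,
    infer_home,
    location_block,
    location_features,
    merge_places,
    time_accounting,
)

T0 = pd.Timestamp("2019-03-04")  # a Monday


def _sp(arrival_h, departure_h, lat, lon, day=0):
    arr = T0 + pd.Timedelta(days=day, hours=arrival_h)
    dep = T0 + pd.Timedelta(days=day, hours=departure_h)
    return {"arrival": arr, "departure": dep, "latitude": lat, "longitude": lon,
            "duration_min": (dep - arr).total_seconds() / 60.0,
            "i_start": 0, "i_end": 0}


def test_same_coordinates_merge_into_one_place():
    sp = pd.DataFrame([_sp(10, 12, 52.0, 4.0, day=0), _sp(10, 12, 52.0, 4.0, day=1)])
    sp, places = merge_places(sp)
    assert len(places) == 1
    assert places.loc[0, "n_visits"] == 2
    assert (places["n_visits"] == 1).sum() == 0


def test_single_visit_share():
    # 3 places visited (1, 1, 2) times -> 2 single visits, 66.7% visited once
    lat2, _ = offset_latlon(52.0, 4.0, 0.0, 1.0)
    lat3, _ = offset_latlon(52.0, 4.0, 0.0, 2.0)
    sp = pd.DataFrame([
        _sp(1, 7, 52.0, 4.0, day=0),       # home, night dwell
        _sp(10, 12, lat2, 4.0, day=0),
        _sp(13, 15, lat3, 4.0, day=0),
        _sp(10, 12, 52.0, 4.0, day=1),     # home again
    ])
    sp, places = merge_places(sp)
    feats = location_features(sp, places, pd.DataFrame(), pd.DataFrame(), 2)
    assert feats["loc_single_visits"] == pytest.approx(2 / 2)
    assert feats["loc_pct_stay_points_visited_once"] == pytest.approx(100 * 2 / 3)


def test_home_is_place_with_most_night_dwell():
    lat2, _ = offset_latlon(52.0, 4.0, 0.0, 5.0)
    sp = pd.DataFrame([
        _sp(0, 6, 52.0, 4.0, day=0),        # 360 night minutes
        _sp(2, 4, lat2, 4.0, day=1),        # 120 night minutes elsewhere
        _sp(9, 20, lat2, 4.0, day=2),       # long but daytime
    ])
    sp, places = merge_places(sp)
    home = infer_home(places)
    assert places.set_index("place_id").loc[home, "latitude"] == 52.0


def test_no_night_dwell_means_no_home_and_missing_home_features():
    sp = pd.DataFrame([_sp(9, 11, 52.0, 4.0), _sp(12, 14, 52.0, 4.0)])
    sp, places = merge_places(sp)
    assert infer_home(places) is None
    feats = location_features(sp, places, pd.DataFrame(), pd.DataFrame(), 7)
    for k in ("loc_pct_time_at_home", "loc_max_distance_from_home",
              "loc_avg_distance_from_home", "loc_nightly_stay_points_excl_home"):
        assert np.isnan(feats[k])
    assert feats["loc_stay_points"] == pytest.approx(2 / 7)  # others computed


def test_home_tie_broken_by_earliest_first_visit():
    lat2, _ = offset_latlon(52.0, 4.0, 0.0, 5.0)
    sp = pd.DataFrame([
        _sp(0, 3, 52.0, 4.0, day=0),
        _sp(3, 6, lat2, 4.0, day=0),  # same 180 night minutes, later arrival
    ])
    sp, places = merge_places(sp)
    home = infer_home(places)
    assert places.set_index("place_id").loc[home, "latitude"] == 52.0


def test_homebound_participant(small_cohort):
    """No outings: ~100% of time at home, no trajectories, distances zero."""
    from phenowatch.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(n_per_group={"CN": 1}, seed=5, duration_days=(7, 7),
                    streams=("gps",))
    cfg.profiles["CN"].n_places = 0
    cfg.profiles["CN"].p_travel = 0.0
    cfg.profiles["CN"].night_out_rate = 0.0
    cohort, _ = simulate_cohort(cfg)
    fixes = cohort.gps.reset_index(drop=True)
    feats = location_block(fixes, 7)
    assert feats["loc_pct_time_at_home"] == pytest.approx(100.0)
    assert feats["loc_trajectories"] == 0.0
    assert np.isnan(feats["loc_mean_distance_traveled"])
    assert feats["loc_max_distance_from_home"] == pytest.approx(0.0)


def test_daily_round_trip_distances():
    """One place 5 km from home visited daily: ~10 km traveled per day and
    ~5 km maximum distance from home."""
    home = (52.0, 4.0)
    away = offset_latlon(*home, 5.0, 0.0)
    rows = []
    days = 7
    for d in range(days):
        day = T0 + pd.Timedelta(days=d)
        for m in range(0, 600, 5):           # home 00:00-10:00
            rows.append((day + pd.Timedelta(minutes=m), *home))
        for i, m in enumerate(range(600, 630, 5)):  # 30-min commute out
            frac = (m - 600) / 30
            rows.append((day + pd.Timedelta(minutes=m),
                         home[0] + frac * (away[0] - home[0]),
                         home[1] + frac * (away[1] - home[1])))
        for m in range(630, 750, 5):         # 2 h at the place
            rows.append((day + pd.Timedelta(minutes=m), *away))
        for m in range(750, 780, 5):         # commute back
            frac = (m - 750) / 30
            rows.append((day + pd.Timedelta(minutes=m),
                         away[0] + frac * (home[0] - away[0]),
                         away[1] + frac * (home[1] - away[1])))
        for m in range(780, 1440, 5):        # home for the rest of the day
            rows.append((day + pd.Timedelta(minutes=m), *home))
    fixes = pd.DataFrame(rows, columns=["timestamp", "latitude", "longitude"])
    feats = location_block(fixes, days)
    assert feats["loc_mean_distance_traveled"] == pytest.approx(10.0, rel=0.02)
    assert feats["loc_max_distance_from_home"] == pytest.approx(5.0, rel=0.02)
    assert feats["loc_trajectories"] == pytest.approx(2.0)
    assert feats["loc_mean_time_traveled"] == pytest.approx(60.0, rel=0.1)


def test_trajectory_distance_bounded_below_by_great_circle(small_cohort):
    _, cohort, _ = small_cohort
    pid = cohort.participants.index[0]
    fixes = cohort.gps[cohort.gps.participant_id == pid].reset_index(drop=True)
    sp = detect_stay_points(fixes)
    traj = build_trajectories(sp, fixes)
    for row in traj.itertuples():
        a, b = sp.iloc[row.from_sp], sp.iloc[row.to_sp]
        straight = float(haversine_km(a.latitude, a.longitude, b.latitude, b.longitude))
        assert row.distance_km >= straight - 0.1  # GPS-noise tolerance


def test_time_accounting_identity(small_cohort):
    """Dwell + travel + explicit gaps reproduce the observation window."""
    _, cohort, _ = small_cohort
    for pid in cohort.participants.index[:5]:
        fixes = cohort.gps[cohort.gps.participant_id == pid].reset_index(drop=True)
        sp = detect_stay_points(fixes)
        traj = build_trajectories(sp, fixes)
        first = cohort.participants.loc[pid, "first_day"]
        last = cohort.participants.loc[pid, "last_day"] + pd.Timedelta(days=1)
        acct = time_accounting(sp, traj, first, last)
        total = (last - first).total_seconds() / 60.0
        assert acct["dwell_min"] + acct["travel_min"] + acct["gap_min"] == \
            pytest.approx(total, abs=1e-6)
        assert acct["gap_min"] >= 0


def test_generator_place_count_and_home_recovered(small_cohort):
    """With jitter far below the merge radius, the number of places matches
    the anchors actually visited and the inferred home is the true one."""
    cfg, cohort, truth = small_cohort
    td = truth["true_dwells"]
    hits = 0
    n = 0
    for pid in cohort.participants.index:
        fixes = cohort.gps[cohort.gps.participant_id == pid].reset_index(drop=True)
        sp = detect_stay_points(fixes)
        sp, places = merge_places(sp)
        visited = td[td.participant_id == pid]["place"].nunique()
        assert len(places) == visited
        home_id = infer_home(places)
        true_home = truth["participants"][pid]["home"]
        hrow = places.set_index("place_id").loc[home_id]
        d_m = float(haversine_km(hrow["latitude"], hrow["longitude"],
                                 true_home[0], true_home[1])) * 1000
        hits += d_m < 350
        n += 1
    assert hits / n >= 0.99
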