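"""Synthetic three-group cohort generator for passive smartphone streams.

The generator emulates 7-42-day call, app-foreground and GPS streams for a
cohort of cognitively normal (CN), subjective-cognitive-decline (SCD) and
cognitively impaired (CI) older adults, with per-group behavioral profiles
that control the quantities the downstream pipeline measures: distinct call
contacts and how concentrated calls are on them, app-opening rates by
category, and mobility range.  Because no raw cohort of this kind is
publicly deposited, the generator is the test bed for the whole pipeline:
every stream satisfies the data-model invariants, and the mobility model is
built so that the true stay-point set is known exactly.

Model summary
-------------
* **Calls** — daily counts are Poisson with a participant-specific rate
  (group rate x mean-one lognormal frailty x an age effect); each call's
  direction is multinomial and its contact is drawn from a participant-level
  categorical whose weights are a symmetric Dirichlet draw.  The Dirichlet
  concentration interpolates between "nearly all calls to one contact"
  (concentration -> 0) and "uniform over the pool" (concentration -> inf),
  which is the axis along which the impaired group differs.  Talk durations
  are lognormal; stated fractions of outgoing calls are non-response
  (duration 0) and of incoming calls are zero-duration pickups.
* **App use** — per-category daily open counts are Poisson; session starts
  fall at night (00:00-06:00) with a small stated probability; durations are
  lognormal and sessions are de-overlapped so one app is in the foreground
  at a time.
* **Mobility** — each participant has a home anchor and a set of habitual
  places >= 1.5 km apart; days contain 0-3 outings (Poisson), occasional
  novel-place visits, and occasional overnight stays away from home.  All
  itinerary boundaries are snapped to the GPS fix grid (default 5 min) and
  all true dwells last >= 70 min, so the ground-truth stay points are exact
  by construction; optional short "noise" visits (< 45 min) along commutes
  exercise the detector's rejection rule.  Fixes are emitted on the grid
  with Gaussian jitter (default sigma 15 m << the 350 m stay-point radius).

The default configuration is the study condition set: group sizes
(209, 55, 24), observation windows uniform on [7, 42] days, demographics
(age, sex, education) per group, caregiver-rated neuropsychiatric-inventory
(NPI) totals for the SCD/CI groups, and CN behavioral rates anchored to the
control-group medians of the outcome catalogue.
"""

from __future__ import annotations

import math
from datetime import date

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from ._geo import haversine_km, offset_latlon
from .catalog import APP_CATEGORIES, GROUPS, NPI_DOMAINS
from .io import Cohort, SCHEMA_VERSION

MINUTES_PER_DAY = 1440


class GroupProfile(BaseModel):
    """Behavioral rates for one diagnostic group."""

    group: str
    contact_pool_size: int = Field(ge=1)
    call_rate: float = Field(ge=0, description="expected calls/day, all directions")
    p_incoming: float = 0.36
    p_outgoing: float = 0.52
    p_missed: float = 0.12
    repeat_concentration: float = Field(
        gt=0, description="symmetric Dirichlet concentration over the contact pool; "
                          "small = calls concentrated on few contacts")
    nonresponse_fraction: float = 0.15   # outgoing calls never answered (duration 0)
    incoming_zero_fraction: float = 0.10  # incoming pickups with zero talk time
    talk_median_s: float = 100.0
    talk_sigma: float = 1.0
    app_open_rate: dict[str, float]       # expected opens/day per category
    app_duration_median_s: dict[str, float]
    app_night_fraction: float = 0.02      # opens falling in [00:00, 06:00)
    app_sigma: float = 0.8
    n_places: int = Field(ge=0, description="habitual places besides home")
    p_travel: float = Field(ge=0, le=1, description="daily probability of a novel place")
    travel_scale_km: float = Field(gt=0)
    night_out_rate: float = Field(ge=0, description="expected nights not at home per week")
    outing_rate: float = 1.2              # expected outings/day

    @field_validator("app_open_rate", "app_duration_median_s")
    @classmethod
    def _known_categories(cls, v):
        unknown = set(v) - set(APP_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown app categories: {sorted(unknown)}")
        return v


class GroupDemographics(BaseModel):
    age_mean: float
    age_sd: float
    age_range: tuple[float, float] = (46.0, 83.0)
    female_prop: float = Field(ge=0, le=1)
    education_mean: float
    education_sd: float


class NpiModel(BaseModel):
    """Negative-binomial NPI totals split over the 12 symptom domains."""

    mean: float = Field(ge=0)
    sd: float = Field(gt=0)
    availability: float = Field(ge=0, le=1)


def default_profiles() -> dict[str, GroupProfile]:
    """The study-condition group profiles.

    CN rates are anchored to the control-group medians of the outcome
    catalogue; the CI profile encodes the impaired-group pattern (fewer
    distinct outgoing contacts, calls concentrated on fewer contacts, fewer
    app openings, reduced mobility range) and SCD sits close to CN except
    for fewer nights out.
    """
    cn_apps = {"communication": 13.7, "social_media": 1.0, "entertainment": 0.3,
               "news_magazines": 0.5, "other": 70.0}
    app_durs = {"communication": 55.0, "social_media": 85.0, "entertainment": 55.0,
                "news_magazines": 50.0, "other": 30.0}
    cn = GroupProfile(group="CN", contact_pool_size=15, call_rate=1.25,
                      repeat_concentration=1.0, app_open_rate=cn_apps,
                      app_duration_median_s=app_durs, n_places=4, p_travel=0.35,
                      travel_scale_km=5.0, night_out_rate=0.5)
    scd = cn.model_copy(update={"group": "SCD", "repeat_concentration": 0.8,
                                "night_out_rate": 0.2})
    ci = GroupProfile(group="CI", contact_pool_size=11, call_rate=0.95,
                      p_incoming=0.44, p_outgoing=0.42, p_missed=0.14,
                      repeat_concentration=0.5,
                      app_open_rate={"communication": 6.2, "social_media": 0.7,
                                     "entertainment": 0.25, "news_magazines": 0.2,
                                     "other": 42.0},
                      app_duration_median_s=app_durs, n_places=3, p_travel=0.30,
                      travel_scale_km=3.5, night_out_rate=0.4, outing_rate=1.0)
    return {"CN": cn, "SCD": scd, "CI": ci}


def default_demographics() -> dict[str, GroupDemographics]:
    return {
        "CN": GroupDemographics(age_mean=63, age_sd=8, female_prop=0.584,
                                education_mean=11, education_sd=2),
        "SCD": GroupDemographics(age_mean=61, age_sd=7, female_prop=0.618,
                                 education_mean=10, education_sd=2),
        "CI": GroupDemographics(age_mean=68, age_sd=8, female_prop=0.333,
                                education_mean=13, education_sd=5),
    }


def default_npi() -> dict[str, NpiModel]:
    return {"SCD": NpiModel(mean=7.7, sd=11.0, availability=0.35),
            "CI": NpiModel(mean=5.0, sd=5.6, availability=0.92)}


class SimConfig(BaseModel):
    """Full configuration of one simulated cohort (same seed => same bytes)."""

    n_per_group: dict[str, int] = Field(
        default_factory=lambda: {"CN": 209, "SCD": 55, "CI": 24})
    seed: int = 0
    duration_days: tuple[int, int] = (7, 42)
    start_date: date = date(2019, 3, 4)
    timezone: str = "Europe/Amsterdam"
    streams: tuple[str, ...] = ("calls", "apps", "gps")
    fix_interval_min: int = 5
    sigma_gps_m: float = 15.0
    commute_speed_kmh: float = 30.0
    noise_visit_prob: float = 0.15        # per commute leg long enough to host one
    noise_visit_minutes: tuple[int, int] = (15, 40)
    sigma_between: float = 0.6            # between-participant lognormal SD on rates
    age_rate_effect: float = 0.02         # log call/app rate decrease per year over 63
    npi_travel_effect: float = 0.025      # log travel-scale increase per NPI point
    home_center: tuple[float, float] = (52.36, 4.90)
    home_scatter_km: float = 20.0
    demographics: dict[str, GroupDemographics] = Field(default_factory=default_demographics)
    npi: dict[str, NpiModel] = Field(default_factory=default_npi)
    profiles: dict[str, GroupProfile] = Field(default_factory=default_profiles)

    @field_validator("n_per_group")
    @classmethod
    def _known_groups(cls, v):
        unknown = set(v) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        return v


# ---------------------------------------------------------------------------
# participant-level sampling

def _sample_participant_row(group: str, cfg: SimConfig, rng: np.random.Generator) -> dict:
    demo = cfg.demographics[group]
    lo, hi = demo.age_range
    while True:  # truncated normal by rejection
        age = rng.normal(demo.age_mean, demo.age_sd)
        if lo <= age <= hi:
            break
    sex = "female" if rng.random() < demo.female_prop else "male"
    education = float(np.clip(round(rng.normal(demo.education_mean, demo.education_sd)), 0, 25))
    row = {"group": group, "age": int(round(age)), "sex": sex,
           "education_years": education, "npi_total": np.nan}
    row.update({f"npi_{d}": np.nan for d in NPI_DOMAINS})
    npi_model = cfg.npi.get(group)
    if npi_model is not None and rng.random() < npi_model.availability:
        mu, sd = npi_model.mean, npi_model.sd
        var = sd ** 2
        # gamma-Poisson mixture per domain => negative-binomial total
        shape = mu ** 2 / max(var - mu, 1e-9)
        lam = rng.gamma(shape, mu / shape)
        domains = np.minimum(rng.poisson(lam / len(NPI_DOMAINS), size=len(NPI_DOMAINS)), 12)
        for d, s in zip(NPI_DOMAINS, domains):
            row[f"npi_{d}"] = float(s)
        row["npi_total"] = float(domains.sum())
    return row


# ---------------------------------------------------------------------------
# calls

def _call_day_arrays(profile: GroupProfile, n_contacts: int, weights: np.ndarray,
                     rng: np.random.Generator, rate_multiplier: float):
    n = rng.poisson(profile.call_rate * rate_multiplier)
    if n == 0:
        return None
    directions = rng.choice(np.array(["incoming", "outgoing", "missed"]), size=n,
                            p=[profile.p_incoming, profile.p_outgoing, profile.p_missed])
    contacts = rng.choice(n_contacts, size=n, p=weights)
    # call instants concentrated in waking hours
    minutes = np.clip(rng.normal(14.5 * 60, 4 * 60, size=n), 7 * 60, 23.5 * 60 - 1)
    durations = np.round(rng.lognormal(math.log(profile.talk_median_s),
                                       profile.talk_sigma, size=n))
    zero = rng.random(n)
    durations[(directions == "outgoing") & (zero < profile.nonresponse_fraction)] = 0
    durations[(directions == "incoming") & (zero < profile.incoming_zero_fraction)] = 0
    durations[directions == "missed"] = 0
    return minutes, directions, contacts, durations


def sample_call_day(profile: GroupProfile, contact_pool: list[str],
                    weights: np.ndarray, rng: np.random.Generator,
                    rate_multiplier: float = 1.0) -> list[dict]:
    """One day of call events (times as minutes into the day).

    The daily count is Poisson(call_rate x multiplier); contacts come from a
    categorical over the pool with the participant's Dirichlet weights;
    talk durations are lognormal; stated fractions of outgoing calls are
    non-response (0 s) and of incoming calls are zero-duration pickups;
    missed calls always have duration 0.
    """
    arrays = _call_day_arrays(profile, len(contact_pool), weights, rng, rate_multiplier)
    if arrays is None:
        return []
    minutes, directions, contacts, durations = arrays
    return [{"minute": float(m), "direction": d, "contact": contact_pool[c],
             "duration_s": float(s)}
            for m, d, c, s in zip(minutes, directions, contacts, durations)]


# ---------------------------------------------------------------------------
# apps

def _app_day_arrays(profile: GroupProfile, rng: np.random.Generator,
                    rate_multiplier: float):
    starts, cats, durs = [], [], []
    for cat in APP_CATEGORIES:
        rate = profile.app_open_rate.get(cat, 0.0) * rate_multiplier
        n = rng.poisson(rate)
        if n == 0:
            continue
        night = rng.random(n) < profile.app_night_fraction
        s = np.where(night, rng.uniform(0, 6 * 60, size=n),
                     rng.uniform(6 * 60, MINUTES_PER_DAY, size=n))
        d = rng.lognormal(math.log(profile.app_duration_median_s.get(cat, 40.0)),
                          profile.app_sigma, size=n)
        starts.append(s)
        durs.append(d)
        cats.extend([cat] * n)
    if not starts:
        return None
    start = np.concatenate(starts)
    dur = np.concatenate(durs)
    cat_arr = np.array(cats)
    order = np.argsort(start, kind="stable")
    start, dur, cat_arr = start[order], dur[order], cat_arr[order]
    end = start + dur / 60.0
    # one app in the foreground at a time: truncate at the next open
    end[:-1] = np.minimum(end[:-1], start[1:] - 1 / 60.0)
    end = np.minimum(end, MINUTES_PER_DAY - 1 / 60.0)
    keep = end - start >= 1 / 60.0  # drop sessions squeezed below one second
    return start[keep], end[keep], cat_arr[keep]


def sample_app_day(profile: GroupProfile, rng: np.random.Generator,
                   rate_multiplier: float = 1.0) -> list[dict]:
    """One day of foreground sessions (minutes into the day), non-overlapping.

    Category counts are Poisson; a stated fraction of opens falls at night;
    durations are lognormal; overlapping draws are resolved by truncating a
    session at the next session's start, so the foreground invariant holds.
    """
    arrays = _app_day_arrays(profile, rng, rate_multiplier)
    if arrays is None:
        return []
    start, end, cat_arr = arrays
    return [{"start_minute": float(s), "end_minute": float(e), "category": c}
            for s, e, c in zip(start, end, cat_arr)]


# ---------------------------------------------------------------------------
# mobility

def _sample_anchor(home: tuple[float, float], scale_km: float,
                   existing: list[tuple[float, float]], rng: np.random.Generator,
                   min_sep_km: float = 1.5) -> tuple[float, float]:
    """A place anchor >= min_sep_km from home and all existing anchors."""
    for _ in range(64):
        dist = 1.0 + min(rng.exponential(scale_km), 200.0)
        theta = rng.uniform(0, 2 * np.pi)
        lat, lon = offset_latlon(home[0], home[1], dist * np.cos(theta), dist * np.sin(theta))
        pts = [home, *existing]
        seps = haversine_km([p[0] for p in pts], [p[1] for p in pts], lat, lon)
        if np.min(seps) >= min_sep_km:
            return float(lat), float(lon)
    return float(lat), float(lon)  # pragma: no cover - rejection virtually never exhausts


def _snap_up(minutes: float, interval: int) -> float:
    return math.ceil(minutes / interval - 1e-9) * interval


class _Itinerary:
    """Absolute-time segments of one participant's window.

    Segments are ``("dwell", key, t0, t1)`` or ``("commute", key_from,
    key_to, t0, t1)`` with times in minutes since the window start; every
    boundary lies on the fix grid, so detection boundaries are unambiguous.
    """

    def __init__(self):
        self.segments: list[tuple] = []

    def add_dwell(self, key, t0, t1):
        if t1 > t0:
            self.segments.append(("dwell", key, t0, t1))

    def add_commute(self, key_from, key_to, t0, t1):
        if t1 > t0:
            self.segments.append(("commute", key_from, key_to, t0, t1))


def sample_mobility_window(profile: GroupProfile, cfg: SimConfig,
                           rng: np.random.Generator, duration_days: int,
                           travel_multiplier: float = 1.0,
                           outing_multiplier: float = 1.0):
    """Build the itinerary, anchors and ground-truth dwells for one participant.

    Returns ``(anchors, itinerary, true_dwells)`` where ``anchors`` maps
    place keys to (lat, lon), and ``true_dwells`` is a list of
    ``(key, t0_min, t1_min)`` for every intended dwell >= 60 min (noise
    visits are excluded by construction).
    """
    interval = cfg.fix_interval_min
    theta = rng.uniform(0, 2 * np.pi)
    r = cfg.home_scatter_km * math.sqrt(rng.random())
    hlat, hlon = offset_latlon(cfg.home_center[0], cfg.home_center[1],
                               r * math.cos(theta), r * math.sin(theta))
    anchors: dict[str, tuple[float, float]] = {"home": (float(hlat), float(hlon))}
    scale = profile.travel_scale_km * travel_multiplier
    for i in range(profile.n_places):
        anchors[f"place{i}"] = _sample_anchor(anchors["home"], scale,
                                              list(anchors.values()), rng)
    itin = _Itinerary()
    total_min = duration_days * MINUTES_PER_DAY
    cursor = 0.0  # at home
    n_novel = 0

    def commute_minutes(key_a, key_b):
        d = haversine_km(*anchors[key_a], *anchors[key_b])
        return max(_snap_up(d / cfg.commute_speed_kmh * 60.0, interval), interval), float(d)

    def travel(key_a, key_b, t0):
        """Emit commute key_a -> key_b starting at t0, with an optional noise stop."""
        leg, dist = commute_minutes(key_a, key_b)
        n_iv = int(leg / interval)
        if (n_iv >= 3 and rng.random() < cfg.noise_visit_prob):
            cut = interval * int(rng.integers(max(1, n_iv // 3), max(2, 2 * n_iv // 3 + 1)))
            frac = cut / leg
            a, b = anchors[key_a], anchors[key_b]
            nkey = f"noise@{t0:.0f}"
            anchors[nkey] = (a[0] + frac * (b[0] - a[0]), a[1] + frac * (b[1] - a[1]))
            lo, hi = cfg.noise_visit_minutes
            pause = interval * int(rng.integers(lo // interval, hi // interval + 1))
            itin.add_commute(key_a, nkey, t0, t0 + cut)
            itin.add_dwell(nkey, t0 + cut, t0 + cut + pause)
            itin.add_commute(nkey, key_b, t0 + cut + pause, t0 + leg + pause)
            return t0 + leg + pause
        itin.add_commute(key_a, key_b, t0, t0 + leg)
        return t0 + leg

    def pick_destination(novel: bool) -> str | None:
        nonlocal n_novel
        if novel:
            key = f"novel{n_novel}"
            n_novel += 1
            anchors[key] = _sample_anchor(anchors["home"], scale, list(anchors.values()), rng)
            return key
        if profile.n_places == 0:
            return None
        return f"place{int(rng.integers(profile.n_places))}"

    for day in range(duration_days):
        day0 = day * MINUTES_PER_DAY
        n_outings = min(int(rng.poisson(profile.outing_rate * outing_multiplier)), 3)
        novel_today = rng.random() < profile.p_travel
        night_out = rng.random() < profile.night_out_rate / 7.0
        if novel_today:
            n_outings = max(n_outings, 1)
        latest_start = day0 + (19 * 60 if night_out else 20.5 * 60)
        for j in range(n_outings):
            depart = max(cursor, day0 + 8 * 60) + interval * int(rng.integers(14, 37))
            if depart > latest_start or depart >= total_min:
                break
            dest = pick_destination(novel_today and j == 0)
            if dest is None:
                continue
            arrive = travel("home", dest, depart)
            dwell_end = arrive + interval * int(rng.integers(14, 35))
            itin.add_dwell(dest, arrive, dwell_end)
            cursor = travel(dest, "home", dwell_end)
        if night_out and (profile.n_places > 0 or profile.p_travel > 0):
            depart = max(cursor, day0 + 21.5 * 60)
            wake = day0 + MINUTES_PER_DAY + 6.5 * 60
            if depart + 2 * 60 <= min(wake - 60, total_min):
                dest = pick_destination(profile.n_places == 0)
                arrive = travel("home", dest, depart)
                end = min(wake, total_min)
                if end - arrive >= 60:
                    itin.add_dwell(dest, arrive, end)
                    cursor = travel(dest, "home", end) if end < total_min else total_min
                else:  # pragma: no cover - long commute ate the night
                    cursor = travel(dest, "home", arrive)

    # clip at the window end and fill every gap with a home dwell
    segments = []
    for seg in itin.segments:
        t0, t1 = seg[-2], seg[-1]
        if t0 >= total_min:
            continue
        segments.append((*seg[:-1], min(t1, total_min)))
    segments.sort(key=lambda s: s[-2])
    filled: list[tuple] = []
    t = 0.0
    for seg in segments:
        if seg[-2] > t:
            filled.append(("dwell", "home", t, seg[-2]))
        filled.append(seg)
        t = seg[-1]
    if t < total_min:
        filled.append(("dwell", "home", t, total_min))

    true_dwells = [(s[1], s[2], s[3]) for s in filled
                   if s[0] == "dwell" and not s[1].startswith("noise")
                   and s[3] - s[2] >= 60.0]
    return anchors, filled, true_dwells


def _emit_fixes(segments, anchors, cfg: SimConfig, duration_days: int,
                rng: np.random.Generator) -> np.ndarray:
    """GPS positions on the fix grid: (minute, lat, lon) per row."""
    n = duration_days * MINUTES_PER_DAY // cfg.fix_interval_min
    grid = np.arange(n, dtype=float) * cfg.fix_interval_min
    starts = np.array([s[-2] for s in segments])
    idx = np.clip(np.searchsorted(starts, grid, side="right") - 1, 0, len(segments) - 1)
    lat = np.empty(n)
    lon = np.empty(n)
    for k in np.unique(idx):
        seg = segments[k]
        sel = idx == k
        if seg[0] == "dwell":
            a = anchors[seg[1]]
            lat[sel], lon[sel] = a[0], a[1]
        else:
            a, b = anchors[seg[1]], anchors[seg[2]]
            frac = (grid[sel] - seg[-2]) / (seg[-1] - seg[-2])
            lat[sel] = a[0] + frac * (b[0] - a[0])
            lon[sel] = a[1] + frac * (b[1] - a[1])
    sigma_km = cfg.sigma_gps_m / 1000.0
    east = rng.normal(0, sigma_km, n)
    north = rng.normal(0, sigma_km, n)
    lat, lon = offset_latlon(lat, lon, east, north)
    return np.column_stack([grid, lat, lon])


# ---------------------------------------------------------------------------
# whole-cohort driver

def simulate_cohort(config: SimConfig) -> tuple[Cohort, dict]:
    """Generate a full cohort plus its ground truth.

    Returns ``(cohort, ground_truth)``; ``ground_truth`` holds, per
    participant, the home/place anchors, the true dwell episodes (as a
    DataFrame under ``"true_dwells"``), and the closed-form expected
    per-day rates under the participant's own multipliers.
    """
    rng = np.random.default_rng(config.seed)
    base = pd.Timestamp(config.start_date)
    dur_lo, dur_hi = config.duration_days

    part_rows, call_frames, app_frames, gps_frames = [], [], [], []
    truth: dict = {"participants": {}, "config_seed": config.seed}
    dwell_rows = []

    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        profile = config.profiles[group]
        for i in range(n):
            pid = f"{group}{i:04d}"
            row = _sample_participant_row(group, config, rng)
            days = int(rng.integers(dur_lo, dur_hi + 1))
            first = base
            last = base + pd.Timedelta(days=days - 1)
            row.update({"participant_id": pid, "first_day": first, "last_day": last})
            part_rows.append(row)

            sb = config.sigma_between
            frailty_call = math.exp(rng.normal(-sb ** 2 / 2, sb))
            frailty_app = math.exp(rng.normal(-sb ** 2 / 2, sb))
            frailty_out = math.exp(rng.normal(-(sb / 2) ** 2 / 2, sb / 2))
            age_mult = math.exp(-config.age_rate_effect * (row["age"] - 63))
            npi_total = row["npi_total"]
            travel_mult = (math.exp(config.npi_travel_effect * npi_total)
                           if np.isfinite(npi_total) else 1.0)

            if "calls" in config.streams and profile.call_rate > 0:
                pool = np.array([f"{pid}_c{j}" for j in range(profile.contact_pool_size)])
                alpha = np.full(profile.contact_pool_size, profile.repeat_concentration)
                weights = rng.dirichlet(alpha)
                parts = []
                for day in range(days):
                    arrays = _call_day_arrays(profile, len(pool), weights, rng,
                                              frailty_call * age_mult)
                    if arrays is not None:
                        minutes, directions, contacts, durations = arrays
                        parts.append((minutes + day * MINUTES_PER_DAY, directions,
                                      contacts, durations))
                if parts:
                    minutes = np.concatenate([p[0] for p in parts])
                    call_frames.append(pd.DataFrame({
                        "participant_id": pid,
                        "timestamp": first + pd.to_timedelta(
                            np.round(minutes * 60), unit="s"),
                        "direction": np.concatenate([p[1] for p in parts]),
                        "contact": pool[np.concatenate([p[2] for p in parts])],
                        "duration_s": np.concatenate([p[3] for p in parts])}))

            if "apps" in config.streams:
                parts = []
                for day in range(days):
                    arrays = _app_day_arrays(profile, rng, frailty_app * age_mult)
                    if arrays is not None:
                        s, e, c = arrays
                        parts.append((s + day * MINUTES_PER_DAY,
                                      e + day * MINUTES_PER_DAY, c))
                if parts:
                    app_frames.append(pd.DataFrame({
                        "participant_id": pid,
                        "start": first + pd.to_timedelta(
                            np.round(np.concatenate([p[0] for p in parts]) * 60), unit="s"),
                        "end": first + pd.to_timedelta(
                            np.round(np.concatenate([p[1] for p in parts]) * 60), unit="s"),
                        "category": np.concatenate([p[2] for p in parts])}))

            anchors = {}
            true_dwells: list = []
            if "gps" in config.streams:
                anchors, segments, true_dwells = sample_mobility_window(
                    profile, config, rng, days, travel_multiplier=travel_mult,
                    outing_multiplier=frailty_out)
                fixes = _emit_fixes(segments, anchors, config, days, rng)
                gps_frames.append(pd.DataFrame({
                    "participant_id": pid,
                    "timestamp": first + pd.to_timedelta(np.round(fixes[:, 0] * 60), unit="s"),
                    "latitude": fixes[:, 1], "longitude": fixes[:, 2]}))
                for key, t0, t1 in true_dwells:
                    dwell_rows.append({
                        "participant_id": pid, "place": key,
                        "latitude": anchors[key][0], "longitude": anchors[key][1],
                        "start": first + pd.Timedelta(minutes=t0),
                        "end": first + pd.Timedelta(minutes=t1)})

            truth["participants"][pid] = {
                "group": group, "duration_days": days,
                "home": anchors.get("home"),
                "anchors": {k: v for k, v in anchors.items() if not k.startswith("noise")},
                "n_true_dwells": len(true_dwells),
                "expected": expected_features(
                    profile, days, rate_multiplier=frailty_call * age_mult,
                    app_multiplier=frailty_app * age_mult),
            }

    participants = pd.DataFrame(part_rows).set_index("participant_id")
    calls = (pd.concat(call_frames, ignore_index=True) if call_frames
             else pd.DataFrame(columns=["participant_id", "timestamp", "direction",
                                        "contact", "duration_s"]))
    calls = (calls.sort_values(["participant_id", "timestamp"], kind="stable")
             .reset_index(drop=True))
    apps = (pd.concat(app_frames, ignore_index=True) if app_frames
            else pd.DataFrame(columns=["participant_id", "start", "end", "category"]))
    apps = (apps.sort_values(["participant_id", "start"], kind="stable")
            .reset_index(drop=True))
    gps = (pd.concat(gps_frames, ignore_index=True)
           .sort_values(["participant_id", "timestamp"], kind="stable")
           .reset_index(drop=True) if gps_frames
           else pd.DataFrame(columns=["participant_id", "timestamp", "latitude", "longitude"]))
    truth["true_dwells"] = pd.DataFrame(
        dwell_rows, columns=["participant_id", "place", "latitude", "longitude",
                             "start", "end"])
    cohort = Cohort(participants=participants, calls=calls, app_sessions=apps, gps=gps,
                    timezone=config.timezone, schema_version=SCHEMA_VERSION)
    return cohort, truth


# ---------------------------------------------------------------------------
# closed-form expectations

def expected_unique_contacts(pool_size: int, n_calls: float, concentration: float) -> float:
    """Expected distinct contacts after ``n_calls`` Dirichlet-categorical draws.

    For a symmetric Dirichlet the per-contact weight is Beta(a, (m-1)a), so
    E[distinct] = m * (1 - E[(1-w)^k]) with the Beta moment evaluated as the
    rising-factorial ratio prod_{j<k} ((m-1)a + j) / (m a + j).  In the
    concentration -> inf limit this tends to the classical occupancy value
    m * (1 - (1 - 1/m)^k).
    """
    m, a, k = pool_size, concentration, int(round(n_calls))
    if k <= 0 or m <= 0:
        return 0.0
    j = np.arange(k, dtype=float)
    log_ratio = np.sum(np.log((m - 1) * a + j) - np.log(m * a + j))
    return float(m * (1.0 - math.exp(log_ratio)))


def expected_features(profile: GroupProfile, duration_days: int,
                      rate_multiplier: float = 1.0,
                      app_multiplier: float = 1.0) -> dict[str, float]:
    """Closed-form expected values of the directly Poisson-governed features.

    Exact: per-day call counts by direction, non-response/zero-pickup rates,
    per-day app opens (overall, at night, per category).  Approximate (noted):
    talk-duration totals use the lognormal mean; unique contacts use the
    Dirichlet occupancy formula at the expected call count (Jensen gap is
    small at these rates); app durations ignore the de-overlap truncation.
    """
    r = profile.call_rate * rate_multiplier
    talk_mean = profile.talk_median_s * math.exp(profile.talk_sigma ** 2 / 2)
    total_calls = r * duration_days
    out: dict[str, float] = {
        "calls_incoming_number": r * profile.p_incoming,
        "calls_outgoing_number": r * profile.p_outgoing,
        "calls_missed_number": r * profile.p_missed,
        "calls_outgoing_nonresponse_number": r * profile.p_outgoing * profile.nonresponse_fraction,
        "calls_incoming_nonzero_duration_number": r * profile.p_incoming * (1 - profile.incoming_zero_fraction),
        "calls_incoming_duration": r * profile.p_incoming * (1 - profile.incoming_zero_fraction) * talk_mean,
        "calls_outgoing_duration": r * profile.p_outgoing * (1 - profile.nonresponse_fraction) * talk_mean,
        "calls_unique_contacts_study": expected_unique_contacts(
            profile.contact_pool_size, total_calls, profile.repeat_concentration),
    }
    app_total = sum(profile.app_open_rate.values()) * app_multiplier
    out["apps_all_times_opened"] = app_total
    out["apps_all_times_opened_night"] = app_total * profile.app_night_fraction
    for cat, rate in profile.app_open_rate.items():
        out[f"apps_{cat}_times_opened"] = rate * app_multiplier
    return out


# ---------------------------------------------------------------------------
# feature-level simulator (for statistical calibration studies)

def simulate_feature_cohort(n_per_group: dict[str, int],
                            effects: dict[str, dict[str, float]] | None = None,
                            *, seed: int = 0, sigma_log: float = 0.6,
                            age_effect: float = 0.02,
                            base_log: float = 0.0,
                            npi_effects: dict[str, float] | None = None,
                            demographics: dict[str, GroupDemographics] | None = None,
                            npi: dict[str, NpiModel] | None = None) -> pd.DataFrame:
    """Simulate raw outcome values directly, with effects in control-SD units.

    Each outcome is lognormal: ``log x = base - age_effect*(age-63)
    + shift_g * sigma_total + slope_npi * npi + N(0, sigma_log)`` where
    ``sigma_total`` is the population control-group SD of ``log x``
    (residual + age components), so an entry ``effects[outcome][group] = -0.7``
    injects a group shift of exactly -0.7 control-SD on the log scale — the
    scale on which the pipeline standardizes and fits.  Used to study type-I
    error and effect recovery of the inference stage under exactly known
    truth.  Returns a participants-by-(outcomes + demographics) DataFrame.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    npi_effects = npi_effects or {}
    demographics = demographics or default_demographics()
    npi = npi or default_npi()
    cfg = SimConfig(demographics=demographics, npi=npi)
    rows = []
    for group in GROUPS:
        for i in range(n_per_group.get(group, 0)):
            row = _sample_participant_row(group, cfg, rng)
            row["participant_id"] = f"{group}{i:04d}"
            rows.append(row)
    df = pd.DataFrame(rows).set_index("participant_id")

    age_sd_cn = demographics["CN"].age_sd
    sigma_total = math.sqrt(sigma_log ** 2 + (age_effect * age_sd_cn) ** 2)
    outcomes = sorted(set(effects) | set(npi_effects)) or ["outcome"]
    for outcome in outcomes:
        shift = df["group"].map(lambda g: effects.get(outcome, {}).get(g, 0.0)).astype(float)
        log_x = (base_log - age_effect * (df["age"] - 63.0)
                 + shift * sigma_total
                 + rng.normal(0, sigma_log, len(df)))
        slope = npi_effects.get(outcome, 0.0)
        if slope:
            log_x = log_x + slope * df["npi_total"].fillna(0.0)
        df[outcome] = np.exp(log_x)
    return df
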