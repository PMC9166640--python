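"""Canonical catalogue of passive-monitoring outcome variables.

The catalogue fixes, in one place, the set of outcomes the pipeline computes,
the order in which they appear in the feature table, the outcome cluster each
belongs to (``calls``, ``app_use``, ``location`` — the three families used for
the Bonferroni correction), and whether the variable is a per-day rate
(study total divided by days of participation) or a study-level summary.
"""

from __future__ import annotations

from dataclasses import dataclass

GROUPS = ("CN", "SCD", "CI")
SEXES = ("female", "male")
CALL_DIRECTIONS = ("incoming", "outgoing", "missed")
APP_CATEGORIES = ("communication", "social_media", "entertainment", "news_magazines", "other")
#: categories reported individually in the feature table ("other" only feeds the all-apps totals)
REPORTED_APP_CATEGORIES = APP_CATEGORIES[:-1]

NPI_DOMAINS = (
    "delusions",
    "hallucinations",
    "agitation",
    "depression",
    "anxiety",
    "euphoria",
    "apathy",
    "disinhibition",
    "irritability",
    "aberrant_motor",
    "sleep",
    "appetite",
)

CLUSTERS = ("calls", "app_use", "location")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    cluster: str
    per_day: bool
    description: str


FEATURE_CATALOG: tuple[FeatureDef, ...] = (
    # ---- calls -----------------------------------------------------------
    FeatureDef("calls_incoming_number", "calls", True, "incoming calls per day"),
    FeatureDef("calls_incoming_nonzero_duration_number", "calls", True,
               "incoming calls with talk time > 0 s per day"),
    FeatureDef("calls_incoming_duration", "calls", True, "incoming talk time (s) per day"),
    FeatureDef("calls_incoming_unique_contacts", "calls", True,
               "distinct incoming contacts per day"),
    FeatureDef("calls_incoming_single_use_contacts", "calls", True,
               "incoming contacts seen exactly once in the study, per day"),
    FeatureDef("calls_outgoing_number", "calls", True, "outgoing calls per day"),
    FeatureDef("calls_outgoing_duration", "calls", True, "outgoing talk time (s) per day"),
    FeatureDef("calls_outgoing_nonresponse_number", "calls", True,
               "outgoing calls never answered (0 s) per day"),
    FeatureDef("calls_outgoing_unique_contacts", "calls", True,
               "distinct outgoing contacts per day"),
    FeatureDef("calls_outgoing_single_use_contacts", "calls", True,
               "outgoing contacts called exactly once in the study, per day"),
    FeatureDef("calls_missed_number", "calls", True, "missed calls per day"),
    FeatureDef("calls_missed_unique_contacts", "calls", True,
               "distinct missed-call contacts per day"),
    FeatureDef("calls_mean_repeated_contacts", "calls", False,
               "total calls / unique contacts over all directions (>= 1)"),
    # ---- app use ---------------------------------------------------------
    FeatureDef("apps_all_times_opened", "app_use", True, "app openings per day"),
    FeatureDef("apps_all_duration_opened", "app_use", True, "foreground time (s) per day"),
    FeatureDef("apps_all_times_opened_night", "app_use", True,
               "app openings between 00:00 and 06:00 per day"),
    FeatureDef("apps_communication_times_opened", "app_use", True,
               "communication-app openings per day"),
    FeatureDef("apps_communication_mean_duration", "app_use", False,
               "mean communication-app session length (s)"),
    FeatureDef("apps_social_media_times_opened", "app_use", True,
               "social-media-app openings per day"),
    FeatureDef("apps_social_media_mean_duration", "app_use", False,
               "mean social-media-app session length (s)"),
    FeatureDef("apps_entertainment_times_opened", "app_use", True,
               "entertainment-app openings per day"),
    FeatureDef("apps_entertainment_mean_duration", "app_use", False,
               "mean entertainment-app session length (s)"),
    FeatureDef("apps_news_magazines_times_opened", "app_use", True,
               "news/magazine-app openings per day"),
    FeatureDef("apps_news_magazines_mean_duration", "app_use", False,
               "mean news/magazine-app session length (s)"),
    # ---- location --------------------------------------------------------
    FeatureDef("loc_stay_points", "location", True, "stay points per day"),
    FeatureDef("loc_unique_stay_points", "location", True, "distinct places per day"),
    FeatureDef("loc_nightly_stay_points_excl_home", "location", True,
               "night-time (00:00-06:00) stay points away from home, per day"),
    FeatureDef("loc_unique_nightly_stay_points", "location", True,
               "distinct non-home places visited at night, per day"),
    FeatureDef("loc_outside_office_hours_stay_points", "location", True,
               "non-home stay points after 19:00 on weekdays or any time at weekends, per day"),
    FeatureDef("loc_unique_outside_office_hours_stay_points", "location", True,
               "distinct non-home places visited outside office hours, per day"),
    FeatureDef("loc_single_visits", "location", True,
               "places visited exactly once in the study, per day"),
    FeatureDef("loc_pct_stay_points_visited_once", "location", False,
               "% of places visited exactly once"),
    FeatureDef("loc_mean_time_stationary", "location", False,
               "mean stay-point dwell time (min)"),
    FeatureDef("loc_mean_distance_traveled", "location", False,
               "mean of per-day summed trajectory distance (km)"),
    FeatureDef("loc_sd_distance_traveled", "location", False,
               "SD of per-day summed trajectory distance (km)"),
    FeatureDef("loc_mean_time_traveled", "location", False,
               "mean of per-day summed travel time (min)"),
    FeatureDef("loc_sd_time_traveled", "location", False,
               "SD of per-day summed travel time (min)"),
    FeatureDef("loc_trajectories", "location", True, "trajectories per day"),
    FeatureDef("loc_max_distance_from_home", "location", False,
               "maximum place-to-home distance (km)"),
    FeatureDef("loc_avg_distance_from_home", "location", False,
               "dwell-time-weighted mean place-to-home distance (km)"),
    FeatureDef("loc_pct_time_at_home", "location", False,
               "% of stay-point dwell time spent at home"),
    FeatureDef("loc_pct_time_at_home_window", "location", False,
               "% of the whole observation window spent at home"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURE_CATALOG)
_BY_NAME = {f.name: f for f in FEATURE_CATALOG}

CALL_FEATURES = tuple(n for n in FEATURE_NAMES if n.startswith("calls_"))
APP_FEATURES = tuple(n for n in FEATURE_NAMES if n.startswith("apps_"))
LOCATION_FEATURES = tuple(n for n in FEATURE_NAMES if n.startswith("loc_"))


def feature_def(name: str) -> FeatureDef:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown outcome variable: {name!r}") from None


def cluster_of(name: str) -> str:
    return feature_def(name).cluster
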