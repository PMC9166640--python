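"""Call and app-use outcome blocks.

All per-day quantities are study totals divided by the number of days of
participation — the nominal window length, not the count of days with data,
because the monitoring app records continuously and an empty day is an
informative zero.  Quantities undefined by zero (the repeated-contact ratio
with no calls, a category's mean session length with no opens) are returned
as ``NaN`` and propagate into the cohort table as missing values; the
pipeline reports per-variable missingness instead of imputing zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NIGHT_START_H = 0
NIGHT_END_H = 6

_REPORTED_CATEGORIES = ("communication", "social_media", "entertainment", "news_magazines")


def call_features(calls: pd.DataFrame, participation_days: int) -> dict[str, float]:
    """Call outcome block for one participant.

    ``calls`` needs columns ``direction``, ``contact``, ``duration_s``.
    Unique and single-use contacts are counted within direction (a contact
    both called and calling counts in each direction's tally); the
    repeated-contact ratio pools all directions: total calls divided by the
    number of distinct contacts over all calls, ``NaN`` when there are none.
    """
    if participation_days < 1:
        raise ValueError(f"participation_days must be >= 1, got {participation_days}")
    days = float(participation_days)
    out: dict[str, float] = {}

    for direction in ("incoming", "outgoing", "missed"):
        sub = calls[calls["direction"] == direction]
        out[f"calls_{direction}_number"] = len(sub) / days
        contact_calls = sub["contact"].value_counts()
        out[f"calls_{direction}_unique_contacts"] = len(contact_calls) / days
        if direction != "missed":
            out[f"calls_{direction}_single_use_contacts"] = int((contact_calls == 1).sum()) / days
            out[f"calls_{direction}_duration"] = float(sub["duration_s"].sum()) / days
    out["calls_incoming_nonzero_duration_number"] = int(
        ((calls["direction"] == "incoming") & (calls["duration_s"] > 0)).sum()) / days
    out["calls_outgoing_nonresponse_number"] = int(
        ((calls["direction"] == "outgoing") & (calls["duration_s"] == 0)).sum()) / days

    n_calls = len(calls)
    n_unique_all = calls["contact"].nunique()
    out["calls_mean_repeated_contacts"] = (n_calls / n_unique_all if n_calls else np.nan)
    return out


def app_features(sessions: pd.DataFrame, participation_days: int,
                 night_window: tuple[int, int] = (NIGHT_START_H, NIGHT_END_H)) -> dict[str, float]:
    """App-use outcome block for one participant.

    An "open" is a session start; a session counts as at night iff its
    start instant lies in the night window (a session straddling 06:00
    started at night).  Per-category mean session length is a study-level
    ratio: total category foreground seconds over total category opens,
    ``NaN`` when the category was never opened.  Raises on overlapping
    sessions, which violate the one-app-in-foreground model.
    """
    if participation_days < 1:
        raise ValueError(f"participation_days must be >= 1, got {participation_days}")
    days = float(participation_days)
    if len(sessions):
        s = sessions.sort_values("start", kind="stable")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError("overlapping foreground sessions")
        if (s["end"] <= s["start"]).any():
            raise ValueError("session end not after start")

    dur_s = ((sessions["end"] - sessions["start"]).dt.total_seconds()
             if len(sessions) else pd.Series(dtype=float))
    start_h = sessions["start"].dt.hour if len(sessions) else pd.Series(dtype=int)
    at_night = (start_h >= night_window[0]) & (start_h < night_window[1])

    out: dict[str, float] = {
        "apps_all_times_opened": len(sessions) / days,
        "apps_all_duration_opened": float(dur_s.sum()) / days,
        "apps_all_times_opened_night": int(at_night.sum()) / days,
    }
    for cat in _REPORTED_CATEGORIES:
        in_cat = sessions["category"] == cat if len(sessions) else pd.Series(dtype=bool)
        n_opens = int(in_cat.sum())
        out[f"apps_{cat}_times_opened"] = n_opens / days
        out[f"apps_{cat}_mean_duration"] = (
            float(dur_s[in_cat].sum()) / n_opens if n_opens else np.nan)
    return out
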