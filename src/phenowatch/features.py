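"""Cohort-level feature extraction: streams -> participants x outcomes table."""

from __future__ import annotations

import pandas as pd

from .catalog import FEATURE_NAMES, NPI_DOMAINS
from .communication import app_features, call_features
from .io import Cohort
from .location import location_block

DEMOGRAPHIC_COLUMNS = ["group", "age", "sex", "education_years", "npi_total"]


def extract_features(cohort: Cohort, *, radius_m: float = 350.0,
                     min_duration_min: float = 60.0, merge_radius_m: float = 350.0,
                     gap_close_min: float = 30.0,
                     semantics: str = "overlap") -> pd.DataFrame:
    """One row per participant: the full outcome catalogue plus demographics.

    Per-day outcomes divide study totals by the participant's nominal window
    length (last day - first day + 1).  Outcomes that are undefined for a
    participant (no calls, a never-opened app category, no usable GPS, no
    inferable home) are left missing rather than imputed as zero.
    """
    days = cohort.participation_days()
    calls_by = dict(tuple(cohort.calls.groupby("participant_id", sort=False)))
    apps_by = dict(tuple(cohort.app_sessions.groupby("participant_id", sort=False)))
    gps_by = dict(tuple(cohort.gps.groupby("participant_id", sort=False)))
    empty_calls = cohort.calls.iloc[0:0]
    empty_apps = cohort.app_sessions.iloc[0:0]
    empty_gps = cohort.gps.iloc[0:0]

    rows = []
    for pid in cohort.participants.index:
        d = int(days.loc[pid])
        row: dict[str, float] = {"participant_id": pid}
        row.update(call_features(calls_by.get(pid, empty_calls), d))
        row.update(app_features(apps_by.get(pid, empty_apps), d))
        row.update(location_block(gps_by.get(pid, empty_gps), d, radius_m=radius_m,
                                  min_duration_min=min_duration_min,
                                  merge_radius_m=merge_radius_m,
                                  gap_close_min=gap_close_min, semantics=semantics))
        rows.append(row)

    table = pd.DataFrame(rows).set_index("participant_id")
    table = table[[c for c in FEATURE_NAMES if c in table.columns]]
    demo = cohort.participants[
        [c for c in DEMOGRAPHIC_COLUMNS + [f"npi_{d}" for d in NPI_DOMAINS]
         if c in cohort.participants.columns]]
    return table.join(demo)


def completeness_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-outcome missing-data accounting: n and % of participants missing."""
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    n = len(table)
    missing = table[cols].isna().sum()
    return pd.DataFrame({
        "outcome": cols,
        "n_missing": missing.values,
        "pct_missing": (100.0 * missing / n).round(1).values if n else 0.0,
    })
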