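"""Raw-stream data model, CSV interchange format, and validation.

A cohort on disk is a directory of four CSV files plus a JSON sidecar:

``participants.csv``
    one row per participant: ``participant_id, group, age, sex,
    education_years, first_day, last_day, npi_total, npi_<domain>`` (12 domain
    columns; NPI cells empty when the inventory was not administered).
``calls.csv``
    ``participant_id, timestamp, direction, contact, duration_s`` — one row
    per call event; ``contact`` is an opaque pre-hashed identifier, the
    pipeline never sees phone numbers.
``app_sessions.csv``
    ``participant_id, start, end, category`` — foreground episodes; the
    sessions of one participant never overlap (one app in the foreground at
    a time).
``gps.csv``
    ``participant_id, timestamp, latitude, longitude`` — fixes strictly
    increasing in time per participant.
``meta.json``
    ``{"schema_version": ..., "timezone": ...}``; all timestamps are local
    wall-clock time in that single cohort-level timezone, because every
    day/night window in the outcome definitions is a wall-clock concept.

Validation is total: a file either loads or raises
:class:`CohortValidationError` naming file, line and field. The one soft
rule is the observation window: events timestamped outside a participant's
``[first_day, last_day]`` window are dropped and counted per stream in
``Cohort.exclusions`` rather than failing the load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import APP_CATEGORIES, CALL_DIRECTIONS, FEATURE_NAMES, GROUPS, NPI_DOMAINS, SEXES

SCHEMA_VERSION = "1.0"
TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"
DATE_FORMAT = "%Y-%m-%d"

MIN_PARTICIPATION_DAYS = 7
MAX_PARTICIPATION_DAYS = 42
MIN_AGE_YEARS = 45
NPI_TOTAL_MAX = 144

PARTICIPANT_COLUMNS = (
    ["participant_id", "group", "age", "sex", "education_years", "first_day", "last_day",
     "npi_total"] + [f"npi_{d}" for d in NPI_DOMAINS]
)
CALL_COLUMNS = ["participant_id", "timestamp", "direction", "contact", "duration_s"]
APP_COLUMNS = ["participant_id", "start", "end", "category"]
GPS_COLUMNS = ["participant_id", "timestamp", "latitude", "longitude"]


class CohortValidationError(ValueError):
    """Structured load failure: knows which file, line and field broke."""

    def __init__(self, message: str, *, file: str = "", line: int | None = None,
                 fld: str = ""):
        loc = file
        if line is not None:
            loc += f":{line}"
        if fld:
            loc += f" [{fld}]"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.file = file
        self.line = line
        self.field = fld


@dataclass
class Cohort:
    """In-memory cohort: a participant table plus three event streams.

    ``participants`` is indexed by participant_id; event streams are plain
    DataFrames with a ``participant_id`` column. ``exclusions`` counts events
    dropped for falling outside their participant's observation window.
    """

    participants: pd.DataFrame
    calls: pd.DataFrame
    app_sessions: pd.DataFrame
    gps: pd.DataFrame
    timezone: str = "Europe/Amsterdam"
    schema_version: str = SCHEMA_VERSION
    exclusions: dict[str, int] = field(default_factory=lambda: {"calls": 0, "app_sessions": 0, "gps": 0})

    def participation_days(self) -> pd.Series:
        days = (self.participants["last_day"] - self.participants["first_day"]).dt.days + 1
        return days.rename("participation_days")


# --------------------------------------------------------------------------
# parsing helpers

def _parse_times(raw: pd.Series, *, fmt: str, file: str, fld: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format=fmt, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError(
            f"malformed timestamp {raw.iloc[i]!r}", file=file, line=i + 2, fld=fld)
    if raw.isna().any():
        i = int(np.flatnonzero(raw.isna().to_numpy())[0])
        raise CohortValidationError("missing timestamp", file=file, line=i + 2, fld=fld)
    return parsed


def _check_enum(values: pd.Series, allowed, *, file: str, fld: str) -> None:
    bad = ~values.isin(allowed)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError(
            f"unknown value {values.iloc[i]!r} (allowed: {sorted(allowed)})",
            file=file, line=i + 2, fld=fld)


def _check_known_participants(events: pd.DataFrame, ids: pd.Index, *, file: str) -> None:
    bad = ~events["participant_id"].isin(ids)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError(
            f"unknown participant ID {events['participant_id'].iloc[i]!r}",
            file=file, line=i + 2, fld="participant_id")


def _require_columns(df: pd.DataFrame, columns, *, file: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing columns {missing}", file=file)


# --------------------------------------------------------------------------
# participants

def _validate_participants(df: pd.DataFrame, *, file: str) -> pd.DataFrame:
    _require_columns(df, PARTICIPANT_COLUMNS, file=file)
    df = df.copy()
    dup = df["participant_id"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortValidationError(
            f"duplicate participant ID {df['participant_id'].iloc[i]!r}",
            file=file, line=i + 2, fld="participant_id")
    _check_enum(df["group"], GROUPS, file=file, fld="group")
    _check_enum(df["sex"], SEXES, file=file, fld="sex")
    df["first_day"] = _parse_times(df["first_day"], fmt=DATE_FORMAT, file=file, fld="first_day")
    df["last_day"] = _parse_times(df["last_day"], fmt=DATE_FORMAT, file=file, fld="last_day")

    days = (df["last_day"] - df["first_day"]).dt.days + 1
    bad = (days < MIN_PARTICIPATION_DAYS) | (days > MAX_PARTICIPATION_DAYS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError(
            f"participation of {days.iloc[i]} days outside "
            f"[{MIN_PARTICIPATION_DAYS}, {MAX_PARTICIPATION_DAYS}]",
            file=file, line=i + 2, fld="last_day")

    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if (df["age"] < MIN_AGE_YEARS).any() or df["age"].isna().any():
        i = int(np.flatnonzero((df["age"].isna() | (df["age"] < MIN_AGE_YEARS)).to_numpy())[0])
        raise CohortValidationError(
            f"age {df['age'].iloc[i]} below minimum {MIN_AGE_YEARS} or missing",
            file=file, line=i + 2, fld="age")
    df["education_years"] = pd.to_numeric(df["education_years"], errors="coerce")
    if (df["education_years"] < 0).any():
        i = int(np.flatnonzero((df["education_years"] < 0).to_numpy())[0])
        raise CohortValidationError("negative education years", file=file, line=i + 2,
                                    fld="education_years")

    npi_cols = [f"npi_{d}" for d in NPI_DOMAINS]
    for c in ["npi_total", *npi_cols]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    out_of_range = (df["npi_total"] < 0) | (df["npi_total"] > NPI_TOTAL_MAX)
    if out_of_range.any():
        i = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise CohortValidationError(
            f"NPI total {df['npi_total'].iloc[i]} outside [0, {NPI_TOTAL_MAX}]",
            file=file, line=i + 2, fld="npi_total")
    # total must equal the sum of domain scores whenever both are recorded
    have_domains = df[npi_cols].notna().any(axis=1)
    check = have_domains & df["npi_total"].notna()
    if check.any():
        dom_sum = df.loc[check, npi_cols].sum(axis=1, skipna=True)
        mismatch = (dom_sum - df.loc[check, "npi_total"]).abs() > 1e-9
        if mismatch.any():
            i = int(mismatch.index[mismatch.to_numpy()][0])
            raise CohortValidationError(
                "NPI total does not equal the sum of domain scores",
                file=file, line=int(df.index.get_loc(i)) + 2, fld="npi_total")
    return df.set_index("participant_id")


# --------------------------------------------------------------------------
# event streams

def _window_filter(events: pd.DataFrame, participants: pd.DataFrame,
                   time_cols: list[str]) -> tuple[pd.DataFrame, int]:
    """Drop events outside [first_day 00:00, last_day 24:00); return count."""
    first = participants["first_day"].reindex(events["participant_id"]).to_numpy()
    last = (participants["last_day"] + pd.Timedelta(days=1)).reindex(
        events["participant_id"]).to_numpy()
    keep = np.ones(len(events), dtype=bool)
    for c in time_cols:
        t = events[c].to_numpy()
        keep &= (t >= first) & (t < last)
    return events.loc[keep].reset_index(drop=True), int((~keep).sum())


def _validate_calls(df: pd.DataFrame, participants: pd.DataFrame, *, file: str):
    _require_columns(df, CALL_COLUMNS, file=file)
    df = df.copy()
    _check_known_participants(df, participants.index, file=file)
    df["timestamp"] = _parse_times(df["timestamp"], fmt=TIMESTAMP_FORMAT, file=file,
                                   fld="timestamp")
    _check_enum(df["direction"], CALL_DIRECTIONS, file=file, fld="direction")
    df["duration_s"] = pd.to_numeric(df["duration_s"], errors="coerce")
    bad = df["duration_s"].isna() | (df["duration_s"] < 0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError("duration must be a number >= 0", file=file,
                                    line=i + 2, fld="duration_s")
    missed_with_talk = (df["direction"] == "missed") & (df["duration_s"] > 0)
    if missed_with_talk.any():
        i = int(np.flatnonzero(missed_with_talk.to_numpy())[0])
        raise CohortValidationError("missed call with nonzero duration", file=file,
                                    line=i + 2, fld="duration_s")
    df["contact"] = df["contact"].astype(str)
    return _window_filter(df, participants, ["timestamp"])


def _validate_apps(df: pd.DataFrame, participants: pd.DataFrame, *, file: str):
    _require_columns(df, APP_COLUMNS, file=file)
    df = df.copy()
    _check_known_participants(df, participants.index, file=file)
    df["start"] = _parse_times(df["start"], fmt=TIMESTAMP_FORMAT, file=file, fld="start")
    df["end"] = _parse_times(df["end"], fmt=TIMESTAMP_FORMAT, file=file, fld="end")
    _check_enum(df["category"], APP_CATEGORIES, file=file, fld="category")
    bad = df["end"] <= df["start"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError("session end not after start", file=file,
                                    line=i + 2, fld="end")
    # one app in the foreground at a time: sessions of a participant are disjoint
    by_start = df.sort_values(["participant_id", "start"], kind="stable")
    same = by_start["participant_id"].to_numpy()[1:] == by_start["participant_id"].to_numpy()[:-1]
    overlap = same & (by_start["start"].to_numpy()[1:] < by_start["end"].to_numpy()[:-1])
    if overlap.any():
        pos = int(np.flatnonzero(overlap)[0]) + 1
        raise CohortValidationError(
            "overlapping foreground sessions for one participant", file=file,
            line=int(by_start.index[pos]) + 2, fld="start")
    return _window_filter(df, participants, ["start", "end"])


def _validate_gps(df: pd.DataFrame, participants: pd.DataFrame, *, file: str):
    _require_columns(df, GPS_COLUMNS, file=file)
    df = df.copy()
    _check_known_participants(df, participants.index, file=file)
    df["timestamp"] = _parse_times(df["timestamp"], fmt=TIMESTAMP_FORMAT, file=file,
                                   fld="timestamp")
    for c, lim in (("latitude", 90.0), ("longitude", 180.0)):
        df[c] = pd.to_numeric(df[c], errors="coerce")
        bad = df[c].isna() | (df[c].abs() > lim)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(f"{c} outside [-{lim}, {lim}]", file=file,
                                        line=i + 2, fld=c)
    ordered = df.sort_values(["participant_id", "timestamp"], kind="stable")
    same = ordered["participant_id"].to_numpy()[1:] == ordered["participant_id"].to_numpy()[:-1]
    not_increasing = same & (ordered["timestamp"].to_numpy()[1:]
                             <= ordered["timestamp"].to_numpy()[:-1])
    if not_increasing.any():
        pos = int(np.flatnonzero(not_increasing)[0]) + 1
        raise CohortValidationError(
            "GPS timestamps not strictly increasing for one participant",
            file=file, line=int(ordered.index[pos]) + 2, fld="timestamp")
    df, n_excluded = _window_filter(df, participants, ["timestamp"])
    return df.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True), n_excluded


# --------------------------------------------------------------------------
# public API

def read_cohort(data_dir: str | Path, schema_version: str = SCHEMA_VERSION) -> Cohort:
    """Load and validate a cohort directory.

    Raises :class:`CohortValidationError` on any malformed content;
    out-of-window events are excluded (counted in ``Cohort.exclusions``).
    """
    data_dir = Path(data_dir)
    meta_path = data_dir / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("schema_version") != schema_version:
            raise CohortValidationError(
                f"schema version {meta.get('schema_version')!r} != expected {schema_version!r}",
                file=str(meta_path))
        timezone = meta.get("timezone", "Europe/Amsterdam")
    else:
        timezone = "Europe/Amsterdam"

    def load(name: str) -> pd.DataFrame:
        path = data_dir / name
        if not path.exists():
            raise CohortValidationError("file not found", file=str(path))
        return pd.read_csv(path, dtype={"participant_id": str, "contact": str})

    participants = _validate_participants(load("participants.csv"),
                                          file="participants.csv")
    calls, x_calls = _validate_calls(load("calls.csv"), participants, file="calls.csv")
    apps, x_apps = _validate_apps(load("app_sessions.csv"), participants,
                                  file="app_sessions.csv")
    gps, x_gps = _validate_gps(load("gps.csv"), participants, file="gps.csv")
    return Cohort(participants=participants, calls=calls, app_sessions=apps, gps=gps,
                  timezone=timezone, schema_version=schema_version,
                  exclusions={"calls": x_calls, "app_sessions": x_apps, "gps": x_gps})


def write_cohort(cohort: Cohort, data_dir: str | Path) -> None:
    """Write the cohort in the interchange format (second-precision timestamps)."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)

    p = cohort.participants.reset_index()
    p = p.reindex(columns=PARTICIPANT_COLUMNS)
    p["first_day"] = p["first_day"].dt.strftime(DATE_FORMAT)
    p["last_day"] = p["last_day"].dt.strftime(DATE_FORMAT)
    p.to_csv(data_dir / "participants.csv", index=False)

    calls = cohort.calls.reindex(columns=CALL_COLUMNS).copy()
    calls["timestamp"] = calls["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    calls.to_csv(data_dir / "calls.csv", index=False)

    apps = cohort.app_sessions.reindex(columns=APP_COLUMNS).copy()
    apps["start"] = apps["start"].dt.strftime(TIMESTAMP_FORMAT)
    apps["end"] = apps["end"].dt.strftime(TIMESTAMP_FORMAT)
    apps.to_csv(data_dir / "app_sessions.csv", index=False)

    gps = cohort.gps.reindex(columns=GPS_COLUMNS).copy()
    gps["timestamp"] = gps["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    gps.to_csv(data_dir / "gps.csv", index=False)

    (data_dir / "meta.json").write_text(json.dumps(
        {"schema_version": cohort.schema_version, "timezone": cohort.timezone},
        indent=2) + "\n")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a participants x outcomes table as CSV in catalogue column order.

    Missing values become empty cells. Extra (non-catalogue) columns such as
    demographics are appended after the catalogue block, in their existing
    order. Round-trips exactly through :func:`read_feature_table`.
    """
    table = table.copy()
    if table.index.name != "participant_id":
        raise ValueError("feature table must be indexed by participant_id")
    catalogue = [c for c in FEATURE_NAMES if c in table.columns]
    extra = [c for c in table.columns if c not in FEATURE_NAMES]
    table = table[catalogue + extra]
    table.to_csv(path, index=True, na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str}).set_index("participant_id")
    return df
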