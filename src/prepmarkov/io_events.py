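"""Reading MEMS-style event logs and reducing them to daily binary adherence states.

Electronic pill-container monitoring (MEMS) records a timestamp for every
container opening.  For a once-daily regimen the analysis unit is the calendar
day: a day counts as "dose taken" (state 1) if the container was opened at
least once on that date, and "dose missed" (state 0) otherwise.  Multiple
openings within one day collapse to a single dose-taking event.

Timestamps are taken at face value (no timezone conversion): within-day dose
timing is immaterial for a drug whose active moiety has a multi-day
intracellular half-life, and the monitored cohorts are single-region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EventLogParseError

logger = logging.getLogger(__name__)

#: Default truncation of the analysis window, in days from its start.
#: Covariate analysis is conducted on the first 12 months of follow-up.
DEFAULT_MAX_DAYS = 365


@dataclass(frozen=True)
class FollowUpWindow:
    """Observed follow-up period for one subject (closed date interval)."""

    subject_id: str
    start_date: date
    end_date: date

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise DataError(
                f"window for subject {self.subject_id!r}: start_date "
                f"{self.start_date} after end_date {self.end_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass
class AdherenceSeries:
    """One subject's daily binary dose states over a follow-up window.

    ``states[k]`` is the state of calendar day ``start_date + k`` and is 0
    (dose missed) or 1 (dose taken).
    """

    subject_id: str
    start_date: date
    states: np.ndarray
    n_events_outside: int = 0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise DataError("states must be a 1-d sequence")
        bad = ~np.isin(self.states, (0, 1))
        if bad.any():
            raise DataError(
                f"subject {self.subject_id!r}: states contain values outside {{0,1}}"
            )

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_days(self) -> int:
        return len(self.states)


def read_event_log(
    path,
    *,
    delimiter: str = ",",
    subject_col: str = "subject_id",
    timestamp_col: str = "timestamp",
) -> pd.DataFrame:
    """Read a MEMS event log into a frame of raw opening events.

    Parameters
    ----------
    path
        Delimited text file with one container opening per row.
    delimiter, subject_col, timestamp_col
        Dialect configuration.

    Returns
    -------
    DataFrame with columns ``subject_id`` (str) and ``timestamp``
    (datetime64), one row per opening event.

    Raises
    ------
    ConfigurationError
        If the configured columns are missing.
    EventLogParseError
        If any timestamp fails to parse; the error lists the offending
        1-based data line numbers rather than dropping rows silently.
    """
    raw = pd.read_csv(path, delimiter=delimiter, dtype=str, skipinitialspace=True)
    missing = {subject_col, timestamp_col} - set(raw.columns)
    if missing:
        raise ConfigurationError(
            f"event log {path}: missing column(s) {sorted(missing)}; "
            f"found {list(raw.columns)}"
        )
    if raw.empty:
        logger.warning("event log %s is empty", path)
        return pd.DataFrame({"subject_id": pd.Series(dtype=str),
                             "timestamp": pd.Series(dtype="datetime64[ns]")})
    ts = pd.to_datetime(raw[timestamp_col], errors="coerce", format="ISO8601")
    bad = ts.isna() | raw[subject_col].isna() | (raw[subject_col].str.len() == 0)
    if bad.any():
        lines = (raw.index[bad] + 1).tolist()  # 1-based data rows
        raise EventLogParseError(
            f"event log {path}: {len(lines)} unparseable row(s) at data line(s) "
            f"{lines[:20]}{'...' if len(lines) > 20 else ''}",
            bad_lines=lines,
        )
    return pd.DataFrame({
        "subject_id": raw[subject_col].astype(str),
        "timestamp": ts,
    })


def read_window_file(path, *, delimiter: str = ",") -> list[FollowUpWindow]:
    """Read per-subject follow-up windows (CSV: subject_id,start_date,end_date)."""
    raw = pd.read_csv(path, delimiter=delimiter, dtype=str, skipinitialspace=True)
    missing = {"subject_id", "start_date", "end_date"} - set(raw.columns)
    if missing:
        raise ConfigurationError(f"window file {path}: missing column(s) {sorted(missing)}")
    out = []
    for row in raw.itertuples(index=False):
        out.append(FollowUpWindow(
            subject_id=str(row.subject_id),
            start_date=pd.Timestamp(row.start_date).date(),
            end_date=pd.Timestamp(row.end_date).date(),
        ))
    return out


def daily_states(events: pd.DataFrame, window: FollowUpWindow) -> AdherenceSeries:
    """Collapse opening events to one binary state per calendar day of a window.

    A day's state is 1 iff at least one event falls on that calendar date
    inside the window; multiple openings on one day count once.  Events
    outside the window are ignored; their count is reported on the returned
    series (``n_events_outside``) and logged.
    """
    n_days = window.n_days
    states = np.zeros(n_days, dtype=np.int8)
    n_outside = 0
    if len(events):
        sub = events.loc[events["subject_id"].astype(str) == window.subject_id]
        if len(sub):
            days = (sub["timestamp"].dt.normalize()
                    - pd.Timestamp(window.start_date)).dt.days.to_numpy()
            inside = (days >= 0) & (days < n_days)
            n_outside = int((~inside).sum())
            states[np.unique(days[inside])] = 1
    if n_outside:
        logger.info("subject %s: %d event(s) outside follow-up window ignored",
                    window.subject_id, n_outside)
    return AdherenceSeries(window.subject_id, window.start_date, states,
                           n_events_outside=n_outside)


def build_series(
    events: pd.DataFrame,
    windows: list[FollowUpWindow],
    *,
    max_days: int | None = DEFAULT_MAX_DAYS,
) -> list[AdherenceSeries]:
    """Daily state series for every windowed subject, truncated to ``max_days``.

    Truncation mirrors restricting the covariate analysis to the first
    12 months of follow-up; pass ``max_days=None`` to keep full windows.
    Subjects with broken or lost devices are expected to be excluded from the
    window file upstream — no imputation happens here.
    """
    out = []
    for w in windows:
        if max_days is not None and w.n_days > max_days:
            w = FollowUpWindow(w.subject_id, w.start_date,
                               w.start_date + timedelta(days=max_days - 1))
        out.append(daily_states(events, w))
    return out


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

class CovariateTable:
    """Per-subject covariate values, optionally time-varying.

    Parameters
    ----------
    constant : DataFrame
        Wide table indexed by ``subject_id`` with one 0/1 indicator column per
        covariate (categorical covariates must already be indicator-coded
        against a declared reference level).
    intervals : DataFrame, optional
        Long table for time-varying covariates with columns ``subject_id``,
        ``covariate``, ``value``, ``interval_start_day``, ``interval_end_day``
        (1-based closed intervals in study days).  For each subject-covariate
        pair the intervals must be non-overlapping and cover the follow-up
        window.
    """

    def __init__(self, constant: pd.DataFrame, intervals: pd.DataFrame | None = None):
        constant = constant.copy()
        if constant.index.name != "subject_id":
            if "subject_id" in constant.columns:
                constant = constant.set_index("subject_id")
            else:
                raise ConfigurationError("covariate table needs a subject_id index/column")
        constant.index = constant.index.astype(str)
        self.constant = constant
        self.intervals = None
        if intervals is not None and len(intervals):
            need = {"subject_id", "covariate", "value",
                    "interval_start_day", "interval_end_day"}
            missing = need - set(intervals.columns)
            if missing:
                raise ConfigurationError(
                    f"interval covariate table: missing column(s) {sorted(missing)}")
            iv = intervals.copy()
            iv["subject_id"] = iv["subject_id"].astype(str)
            self.intervals = iv

    @property
    def names(self) -> list[str]:
        names = list(self.constant.columns)
        if self.intervals is not None:
            for c in self.intervals["covariate"].unique():
                if c not in names:
                    names.append(c)
        return names

    def resolve(self, series: AdherenceSeries) -> pd.DataFrame:
        """Per-day covariate matrix (n_days x covariates) for one subject.

        Subject-constant covariates broadcast to every day; time-varying
        covariates are looked up day by day in their intervals.
        """
        return resolve_covariates(self, series)


def read_covariate_table(path, *, interval_path=None, delimiter: str = ",") -> CovariateTable:
    """Read wide (and optionally long interval-format) covariate CSVs."""
    wide = pd.read_csv(path, delimiter=delimiter, dtype={"subject_id": str})
    if "subject_id" not in wide.columns:
        raise ConfigurationError(f"covariate table {path}: missing subject_id column")
    intervals = None
    if interval_path is not None:
        intervals = pd.read_csv(interval_path, delimiter=delimiter,
                                dtype={"subject_id": str})
    return CovariateTable(wide, intervals)


def resolve_covariates(table: CovariateTable, series: AdherenceSeries) -> pd.DataFrame:
    """Fixed-order numeric covariate vector for every day of a series.

    Raises :class:`DataError` if a time-varying covariate leaves any day of
    the series uncovered or covers a day twice.
    """
    n = series.n_days
    sid = str(series.subject_id)
    cols: dict[str, np.ndarray] = {}
    if sid in table.constant.index:
        row = table.constant.loc[sid]
        for name, value in row.items():
            cols[name] = np.full(n, float(value))
    elif len(table.constant.columns):
        raise DataError(f"subject {sid!r} absent from covariate table")
    if table.intervals is not None:
        for name, grp in table.intervals[table.intervals["subject_id"] == sid].groupby("covariate"):
            vec = np.full(n, np.nan)
            for row in grp.itertuples(index=False):
                lo = int(row.interval_start_day) - 1          # 1-based closed
                hi = min(int(row.interval_end_day), n)        # clip to window
                if lo < 0:
                    raise DataError(
                        f"subject {sid!r}, covariate {name!r}: interval starts "
                        f"before day 1")
                if lo < hi and not np.isnan(vec[lo:hi]).all():
                    raise DataError(
                        f"subject {sid!r}, covariate {name!r}: overlapping intervals")
                vec[lo:hi] = float(row.value)
            uncovered = np.flatnonzero(np.isnan(vec))
            if len(uncovered):
                raise DataError(
                    f"subject {sid!r}, covariate {name!r}: day "
                    f"{uncovered[0] + 1} not covered by any interval")
            cols[name] = vec
    order = [c for c in table.names if c in cols]
    return pd.DataFrame({c: cols[c] for c in order}, index=pd.RangeIndex(n))


# ---------------------------------------------------------------------------
# Series round trip
# ---------------------------------------------------------------------------

def series_to_frame(series_list: list[AdherenceSeries]) -> pd.DataFrame:
    """Long-format frame (subject_id, start_date, day, state), day 1-based."""
    parts = []
    for s in series_list:
        parts.append(pd.DataFrame({
            "subject_id": s.subject_id,
            "start_date": s.start_date.isoformat(),
            "day": np.arange(1, s.n_days + 1),
            "state": s.states,
        }))
    if not parts:
        return pd.DataFrame(columns=["subject_id", "start_date", "day", "state"])
    return pd.concat(parts, ignore_index=True)


def frame_to_series(frame: pd.DataFrame) -> list[AdherenceSeries]:
    out = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("day")
        if not (grp["day"].to_numpy() == np.arange(1, len(grp) + 1)).all():
            raise DataError(f"subject {sid!r}: day column is not 1..n")
        out.append(AdherenceSeries(
            str(sid),
            pd.Timestamp(grp["start_date"].iloc[0]).date(),
            grp["state"].to_numpy(),
        ))
    return out


def write_series(series_list: list[AdherenceSeries], path) -> None:
    series_to_frame(series_list).to_csv(path, index=False)


def read_series(path) -> list[AdherenceSeries]:
    return frame_to_series(pd.read_csv(path, dtype={"subject_id": str}))
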