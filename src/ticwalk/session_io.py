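"""Reading, validating and writing tic event time series.

A *session* is one fixed-duration observation window (nominally 300 s of
video) during which the onset time of every tic was recorded. Sessions are
exchanged as plain CSV with one row per tic; a session with no tics appears
as a single row with an empty ``tic_time_s`` field.

The observation window is half-open, ``[0, duration_s)``: an event stamped
exactly at the duration belongs to the next window and is rejected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import SessionFormatError, SessionValidationError

__all__ = [
    "Visit",
    "Condition",
    "TicEventSeries",
    "TicIndicator",
    "read_sessions",
    "write_sessions",
    "bin_events",
    "write_results",
    "read_results",
    "load_config",
]


class Visit(str, enum.Enum):
    """Study visit: within 6 months of tic onset, or at the 12-month anniversary."""

    SCREENING = "screening"
    TWELVE_MONTH = "twelve_month"


class Condition(str, enum.Enum):
    """Suppression condition under which the session was recorded.

    BASELINE
        Free to tic.
    VERBAL
        Verbal request not to tic.
    DRO
        Differential reinforcement of other behaviour: token rewards for
        tic-free intervals.
    NCR
        Non-contingent reinforcement: tokens on a fixed schedule regardless
        of tics.
    """

    BASELINE = "baseline"
    VERBAL = "verbal"
    DRO = "DRO"
    NCR = "NCR"


# Column order of the session CSV dialect (one row per tic).
SESSION_COLUMNS = ["subject_id", "visit", "condition", "rater_id",
                   "duration_s", "tic_time_s"]

# Column order of the per-session results CSV.
RESULT_COLUMNS = ["subject_id", "visit", "condition", "rater_id",
                  "n_tics", "D_f", "fit_r2", "f_lo", "f_hi"]


@dataclass
class TicEventSeries:
    """Tic onset times within one recorded session, with metadata.

    Event times are sorted on construction; duplicates are permitted (they
    collapse to a single grid bin once discretized by :func:`bin_events`).
    """

    subject_id: str
    visit: Visit
    condition: Condition
    rater_id: str
    duration_s: float = 300.0
    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.visit = Visit(self.visit)
        self.condition = Condition(self.condition)
        if not self.duration_s > 0:
            raise SessionValidationError(
                f"duration_s must be positive, got {self.duration_s}")
        t = np.asarray(self.event_times_s, dtype=float)
        t = np.sort(t)
        if t.size and (t[0] < 0 or t[-1] >= self.duration_s):
            bad = t[(t < 0) | (t >= self.duration_s)][0]
            raise SessionValidationError(
                f"event time {bad} outside the half-open window "
                f"[0, {self.duration_s}) for subject {self.subject_id}")
        self.event_times_s = t

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)

    def key(self) -> tuple:
        return (self.subject_id, self.visit.value, self.condition.value,
                self.rater_id)


@dataclass
class TicIndicator:
    """Boolean per-bin tic presence on the walk time grid.

    ``flags[j]`` is true iff at least one tic onset falls in
    ``[j*dt_s, (j+1)*dt_s)``. With the default 0.1 s step and a 300 s
    session there are N = 3000 bins.
    """

    dt_s: float
    flags: np.ndarray

    def __post_init__(self):
        if not self.dt_s > 0:
            raise ValueError(f"dt_s must be positive, got {self.dt_s}")
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_steps(self) -> int:
        return int(self.flags.size)


def bin_events(series: TicEventSeries, dt_s: float = 0.1) -> TicIndicator:
    """Discretize event times onto the walk grid: event t activates bin floor(t/dt).

    Multiple tics in one bin collapse to a single flag — a bin triggers at
    most one velocity reversal downstream.
    """
    if not dt_s > 0:
        raise ValueError(f"dt_s must be positive, got {dt_s}")
    n_float = series.duration_s / dt_s
    n = int(round(n_float))
    if abs(n - n_float) > 1e-9 * n_float:
        raise ValueError(
            f"dt_s={dt_s} does not divide duration_s={series.duration_s}")
    flags = np.zeros(n, dtype=bool)
    if series.n_events:
        idx = np.floor(series.event_times_s / dt_s).astype(int)
        # guard float edge: t just below duration must stay in the last bin
        idx = np.minimum(idx, n - 1)
        flags[idx] = True
    return TicIndicator(dt_s=dt_s, flags=flags)


def read_sessions(path, fmt: str = "csv") -> list[TicEventSeries]:
    """Read a sessions file into one :class:`TicEventSeries` per session.

    A session is one (subject_id, visit, condition, rater_id) group; the file
    has one row per tic, and zero-tic sessions appear as a row with an empty
    ``tic_time_s``.
    """
    if fmt != "csv":
        raise SessionFormatError(f"unsupported format {fmt!r}")
    df = pd.read_csv(path, dtype={"subject_id": str, "rater_id": str},
                     encoding="utf-8")
    for col in SESSION_COLUMNS:
        if col not in df.columns:
            raise SessionFormatError(f"missing required column {col!r}")
    out: list[TicEventSeries] = []
    keys = ["subject_id", "visit", "condition", "rater_id"]
    for key, grp in df.groupby(keys, sort=True):
        durations = grp["duration_s"].astype(float).unique()
        if len(durations) > 1:
            raise SessionValidationError(
                f"inconsistent duration_s for session {key}: {durations}")
        times = grp["tic_time_s"].dropna().astype(float).to_numpy()
        try:
            series = TicEventSeries(
                subject_id=str(key[0]), visit=Visit(key[1]),
                condition=Condition(key[2]), rater_id=str(key[3]),
                duration_s=float(durations[0]), event_times_s=times)
        except (ValueError, SessionValidationError) as exc:
            rows = grp.index.tolist()
            raise SessionValidationError(
                f"invalid session at rows {rows}: {exc}") from exc
        out.append(series)
    return out


def write_sessions(series_list, path) -> None:
    """Write sessions in the one-row-per-tic CSV dialect (round-trips with read)."""
    rows = []
    for s in series_list:
        if s.n_events == 0:
            rows.append((s.subject_id, s.visit.value, s.condition.value,
                         s.rater_id, s.duration_s, np.nan))
        for t in s.event_times_s:
            rows.append((s.subject_id, s.visit.value, s.condition.value,
                         s.rater_id, s.duration_s, t))
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def write_results(table: pd.DataFrame, path) -> None:
    """Write a per-session results table (one row per session) as CSV."""
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.12g",
                               encoding="utf-8")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "rater_id": str},
                       encoding="utf-8")


def load_config(path) -> dict:
    """Load a YAML config mapping (dt_s, duration_s, spectral settings, ...)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SessionFormatError(f"config {path} must be a YAML mapping")
    return cfg
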