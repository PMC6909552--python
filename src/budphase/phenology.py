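"""Dormancy phenology: bud-break forcing tests and stage-label assignment.

Endodormancy release is scored with a forcing test: branches sampled over
winter are moved to warm long-day conditions and the percentage of flower
buds reaching bud burst (BBCH stage 53) after 10 days is recorded. The
dormancy-release date is the earliest sampling date at which that
percentage reaches 50% (optionally, the linearly interpolated crossing).

The five-stage calendar then labels samples: organogenesis (midsummer
window), paradormancy (early autumn window), endodormancy from its onset
until shortly before release, a window around the release date, and
ecodormancy from there until flowering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BudphaseError, validate_metadata


@dataclass
class BudBreakSeries:
    """Forcing-test observations for one cultivar."""

    cultivar: str
    dates: pd.DatetimeIndex
    percents: np.ndarray  # % of buds at BBCH 53 after 10 d forcing

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.percents = np.asarray(self.percents, dtype=float)
        if len(self.dates) != len(self.percents):
            raise BudphaseError("dates and percentages must align")
        if not self.dates.is_monotonic_increasing or self.dates.duplicated().any():
            raise BudphaseError("observation dates must be strictly increasing")
        if ((self.percents < 0) | (self.percents > 100)).any():
            raise BudphaseError("bud-break percentages must lie in [0, 100]")


@dataclass
class StageCalendar:
    """Per-cultivar stage windows over one dormancy cycle.

    The organogenesis and paradormancy windows and the endodormancy onset
    are observational conventions (defaults follow the July/August —
    September — October delimitation); the release date comes from the
    forcing test.
    """

    cultivar: str
    organogenesis: tuple  # (start, end) inclusive
    paradormancy: tuple
    endodormancy_onset: pd.Timestamp
    release_date: pd.Timestamp
    flowering_date: pd.Timestamp
    release_window_days: int = 14

    def __post_init__(self) -> None:
        self.organogenesis = (pd.Timestamp(self.organogenesis[0]),
                              pd.Timestamp(self.organogenesis[1]))
        self.paradormancy = (pd.Timestamp(self.paradormancy[0]),
                             pd.Timestamp(self.paradormancy[1]))
        self.endodormancy_onset = pd.Timestamp(self.endodormancy_onset)
        self.release_date = pd.Timestamp(self.release_date)
        self.flowering_date = pd.Timestamp(self.flowering_date)
        ordered = (self.organogenesis[0] <= self.organogenesis[1]
                   < self.paradormancy[0] <= self.paradormancy[1]
                   < self.endodormancy_onset)
        if not ordered:
            raise BudphaseError("calendar windows must be ordered and non-overlapping")
        if not (self.endodormancy_onset < self.release_date < self.flowering_date):
            raise BudphaseError("release date must fall between endodormancy "
                                "onset and flowering")

    def to_dict(self) -> dict:
        fmt = lambda t: pd.Timestamp(t).strftime("%Y-%m-%d")
        return {
            "cultivar": self.cultivar,
            "organogenesis": [fmt(self.organogenesis[0]), fmt(self.organogenesis[1])],
            "paradormancy": [fmt(self.paradormancy[0]), fmt(self.paradormancy[1])],
            "endodormancy_onset": fmt(self.endodormancy_onset),
            "release_date": fmt(self.release_date),
            "flowering_date": fmt(self.flowering_date),
            "release_window_days": self.release_window_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageCalendar":
        return cls(cultivar=d["cultivar"],
                   organogenesis=tuple(d["organogenesis"]),
                   paradormancy=tuple(d["paradormancy"]),
                   endodormancy_onset=d["endodormancy_onset"],
                   release_date=d["release_date"],
                   flowering_date=d["flowering_date"],
                   release_window_days=int(d.get("release_window_days", 14)))


#: Sentinel returned when the bud-break series never reaches the threshold.
NOT_RELEASED = "not_released"


def estimate_dormancy_release(series: BudBreakSeries,
                              threshold: float = 50.0,
                              interpolate: bool = False,
                              strict: bool = False):
    """Date at which the forcing-test bud-break percentage reaches the threshold.

    Returns the earliest observation date with percent >= threshold
    (``strict=True`` demands >), or with ``interpolate=True`` the linear
    crossing date between the bracketing observations. Returns
    :data:`NOT_RELEASED` when the threshold is never reached.
    """
    if len(series.dates) < 2:
        raise BudphaseError("need >= 2 bud-break observations")
    hit = (series.percents > threshold) if strict else (series.percents >= threshold)
    if not hit.any():
        return NOT_RELEASED
    i = int(np.argmax(hit))
    date_i = series.dates[i]
    if not interpolate or i == 0:
        return date_i
    p0, p1 = series.percents[i - 1], series.percents[i]
    if p1 == p0:
        return date_i
    frac = (threshold - p0) / (p1 - p0)
    span = series.dates[i] - series.dates[i - 1]
    return series.dates[i - 1] + span * float(frac)


def assign_stage_labels(metadata: pd.DataFrame,
                        calendars: dict[str, StageCalendar]) -> pd.DataFrame:
    """Fill the ``stage`` column of a metadata table from stage calendars.

    Rules per sample date d (calendar of the sample's cultivar):
    organogenesis and paradormancy inside their windows; dormancy_release
    within +/- release_window_days/2 of the release date; endodormancy
    from onset to the start of the release window; ecodormancy from the
    end of the release window until flowering.
    """
    metadata = validate_metadata(metadata)
    out = metadata.copy()
    labels = []
    for _, row in out.iterrows():
        cal = calendars.get(row["cultivar"])
        if cal is None:
            raise BudphaseError(f"no stage calendar for cultivar {row['cultivar']!r}")
        labels.append(_stage_of(pd.Timestamp(row["date"]), cal))
    out["stage"] = labels
    return out


def _stage_of(d: pd.Timestamp, cal: StageCalendar) -> str:
    half = pd.Timedelta(days=cal.release_window_days / 2.0)
    if cal.organogenesis[0] <= d <= cal.organogenesis[1]:
        return "organogenesis"
    if cal.paradormancy[0] <= d <= cal.paradormancy[1]:
        return "paradormancy"
    if abs(d - cal.release_date) <= half:
        return "dormancy_release"
    if cal.endodormancy_onset <= d < cal.release_date - half:
        return "endodormancy"
    if cal.release_date + half < d <= cal.flowering_date:
        return "ecodormancy"
    raise BudphaseError(
        f"sample date {d.date()} outside all stage windows for "
        f"cultivar {cal.cultivar!r}")


def read_budbreak(path) -> dict[str, BudBreakSeries]:
    """CSV ``cultivar,date,percent_bbch53`` -> one series per cultivar."""
    df = pd.read_csv(path)
    required = {"cultivar", "date", "percent_bbch53"}
    missing = required - set(df.columns)
    if missing:
        raise BudphaseError(f"bud-break table missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    out = {}
    for cultivar, grp in df.groupby("cultivar", sort=True):
        grp = grp.sort_values("date")
        out[cultivar] = BudBreakSeries(cultivar, pd.DatetimeIndex(grp["date"]),
                                       grp["percent_bbch53"].to_numpy())
    return out


def write_budbreak(series_by_cultivar: dict[str, BudBreakSeries], path) -> None:
    rows = []
    for cultivar, series in series_by_cultivar.items():
        for d, p in zip(series.dates, series.percents):
            rows.append({"cultivar": cultivar, "date": d.strftime("%Y-%m-%d"),
                         "percent_bbch53": p})
    pd.DataFrame(rows).to_csv(path, index=False)
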