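"""Detection logs → presence time series.

A duty-cycled autonomous recorder produces one file per hourly cycle.
Manual annotation of those files yields a selection table of call
detections; acoustic presence is assessed per clock hour (1 if at least one
confident, non-chorus, species-specific detection falls in that hour's
recording), then aggregated to daily percentages and monthly positive-hour
counts. All detections are presence-only: the number of calls in an hour is
deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

SPECIES_LABELS = ("ABW", "FW", "HW", "SRW", "AMW", "O", "LS", "CS")

ANNOTATION_COLUMNS = [
    "file",
    "start_s",
    "end_s",
    "low_hz",
    "high_hz",
    "species",
    "certainty",
    "chorus",
]


@dataclass(frozen=True)
class DeploymentSpec:
    """One mooring deployment of a duty-cycled recorder.

    The recorder runs ``duty_on_min`` minutes at the start of every
    ``cycle_min``-minute cycle, cycles aligned to the top of the hour.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    duty_on_min: float = 8.0
    cycle_min: float = 60.0
    sampling_rate_hz: float = 32768.0
    lat: float = -60.4047
    lon: float = -45.9718
    recorder_depth_m: float = 286.0
    bottom_depth_m: float = 479.0
    gain_db: float = 16.0

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not 0 < self.duty_on_min <= self.cycle_min:
            raise ValueError("duty cycle must satisfy 0 < ON ≤ cycle length")
        if self.start >= self.end:
            raise ValueError("deployment start must precede end")

    def recording_hours(self) -> pd.DatetimeIndex:
        """Start times of every hourly recording cycle in the deployment."""
        first = self.start.floor("h")
        if first < self.start:
            first += pd.Timedelta(hours=1)
        return pd.date_range(first, self.end.floor("h"), freq="h", name="hour")

    def n_recording_days(self) -> int:
        """Inclusive calendar-day count of the recording period."""
        return (self.end.normalize() - self.start.normalize()).days + 1

    def file_id(self, hour: pd.Timestamp) -> str:
        return pd.Timestamp(hour).strftime("%Y%m%d_%H%M%S")

    def to_yaml(self, path) -> None:
        d = {
            "start": str(self.start),
            "end": str(self.end),
            "duty_on_min": self.duty_on_min,
            "cycle_min": self.cycle_min,
            "sampling_rate_hz": self.sampling_rate_hz,
            "lat": self.lat,
            "lon": self.lon,
            "recorder_depth_m": self.recorder_depth_m,
            "bottom_depth_m": self.bottom_depth_m,
            "gain_db": self.gain_db,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DeploymentSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# The two South Orkney deployments (AURAL M2, Coronation Trough).
DEPLOYMENT_2016 = DeploymentSpec(
    start=pd.Timestamp("2016-02-16"),
    end=pd.Timestamp("2016-08-23 23:59:59"),
    duty_on_min=12.0,
    lat=-(60 + 24.297 / 60),
    lon=-(45 + 57.548 / 60),
    recorder_depth_m=240.0,
    bottom_depth_m=470.0,
)
DEPLOYMENT_2017 = DeploymentSpec(
    start=pd.Timestamp("2017-02-10"),
    end=pd.Timestamp("2017-10-12 23:59:59"),
    duty_on_min=8.0,
    lat=-(60 + 24.281 / 60),
    lon=-(45 + 58.311 / 60),
    recorder_depth_m=286.0,
    bottom_depth_m=479.0,
)


def load_annotations(path) -> pd.DataFrame:
    """Read a selection-table CSV (columns as in ANNOTATION_COLUMNS)."""
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        return df
    bad_t = df["start_s"] >= df["end_s"]
    bad_f = df["low_hz"] >= df["high_hz"]
    if bad_t.any() or bad_f.any():
        raise ValueError(
            f"{int(bad_t.sum())} annotations with start ≥ end, "
            f"{int(bad_f.sum())} with low ≥ high frequency"
        )
    unknown = set(df["species"]) - set(SPECIES_LABELS)
    if unknown:
        raise ValueError(f"unknown species labels: {sorted(unknown)}")
    return df


def _file_hours(df: pd.DataFrame) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(pd.to_datetime(df["file"], format="%Y%m%d_%H%M%S")).floor("h")


def hourly_presence(
    annotations: pd.DataFrame,
    deployment: DeploymentSpec,
    *,
    keep_uncertain: bool = False,
    species: tuple[str, ...] = SPECIES_LABELS,
) -> pd.DataFrame:
    """Binary presence per recorded clock hour and species.

    An hour scores 1 for a species iff at least one confident (unless
    ``keep_uncertain``), non-chorus annotation of that species falls in the
    hour's recording. Annotations outside the deployment window are rejected
    and reported in the ``attrs['rejected']`` count.
    """
    hours = deployment.recording_hours()
    out = pd.DataFrame(0, index=hours, columns=list(species), dtype=int)
    out.attrs["rejected"] = 0
    if len(annotations) == 0:
        return out
    df = validate_annotations(annotations)
    if not keep_uncertain:
        df = df[df["certainty"].astype(str).str.lower() == "confident"]
    df = df[~df["chorus"].astype(bool)]
    if len(df) == 0:
        return out
    ann_hours = _file_hours(df)
    inside = ann_hours.isin(hours)
    out.attrs["rejected"] = int((~inside).sum())
    df = df[inside]
    ann_hours = ann_hours[inside]
    for hr, sp in zip(ann_hours, df["species"]):
        if sp in out.columns:
            out.loc[hr, sp] = 1
    return out


def daily_presence(hourly: pd.DataFrame) -> pd.DataFrame:
    """Per-day positive-hour counts and percentage presence.

    Tidy frame (date, species, positive_hours, recorded_hours, percent).
    The denominator is the number of hours actually recorded that day, so
    partial first/last days are handled gracefully. Days with no recorded
    hours do not appear.
    """
    if len(hourly) == 0:
        return pd.DataFrame(
            columns=["date", "species", "positive_hours", "recorded_hours", "percent"]
        )
    day = hourly.index.normalize()
    pos = hourly.groupby(day).sum()
    rec = hourly.groupby(day).size()
    tidy = pos.stack().rename("positive_hours").reset_index()
    tidy.columns = ["date", "species", "positive_hours"]
    tidy["recorded_hours"] = rec.reindex(tidy["date"]).values
    tidy["percent"] = 100.0 * tidy["positive_hours"] / tidy["recorded_hours"]
    return tidy


def community_matrix(daily: pd.DataFrame) -> pd.DataFrame:
    """Days × species matrix of positive hours (0–24), the ordination response."""
    return daily.pivot(index="date", columns="species", values="positive_hours")


def monthly_hours(hourly: pd.DataFrame, *, deployment: DeploymentSpec | None = None) -> pd.DataFrame:
    """Species × month positive-hour counts.

    Months inside the deployment with no positive hours report 0; months
    with no recording at all report NA (when ``deployment`` is given, every
    calendar month between start and end is included).
    """
    period = hourly.index.to_period("M")
    counts = hourly.groupby(period).sum()
    if deployment is not None:
        full = pd.period_range(
            deployment.start.to_period("M"), deployment.end.to_period("M"), freq="M"
        )
        recorded = set(period)
        counts = counts.reindex(full)
        counts.loc[[m for m in full if m not in recorded]] = np.nan
    return counts


def duty_cycle_audit(
    annotations: pd.DataFrame,
    *,
    mark_minutes: float = 8.0,
    file_duration_min: float = 12.0,
) -> pd.DataFrame:
    """Per-species audit of whether detections rely on minutes after a mark.

    For every (file, species) pair the pair counts as *before-mark* if any
    of its detections starts before ``mark_minutes``, and *only-after-mark*
    if all of them start later. Supports checking that a shorter duty cycle
    would not have lost species detections.
    """
    if mark_minutes > file_duration_min:
        raise ValueError("mark beyond file duration")
    df = validate_annotations(annotations)
    if len(df) == 0:
        return pd.DataFrame(columns=["before_mark_files", "only_after_mark_files"])
    mark_s = mark_minutes * 60.0
    grouped = df.groupby(["species", "file"])["start_s"].min()
    before = (grouped < mark_s).groupby("species").sum().astype(int)
    after = (grouped >= mark_s).groupby("species").sum().astype(int)
    out = pd.DataFrame(
        {"before_mark_files": before, "only_after_mark_files": after}
    ).fillna(0).astype(int)
    out.index.name = "species"
    return out
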