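"""Camera-trap record tables, detection histories, and survey summaries.

Record tables are plain :class:`pandas.DataFrame` objects with columns
``station``, ``species`` and ``timestamp`` (datetime64). Station effort is a
list of :class:`StationEffort`. Detection histories collapse records into
fixed-length occasions anchored at each station's deployment date.

Conventions
-----------
* Day offsets are 0-based: the deployment day is day 0.
* A station's duration in days is ``(retrieve - deploy).days + 1`` (both
  endpoint days count as operational).
* Inactive intervals ("gaps") are whole-day ranges, inclusive on both ends.
* An occasion is *missing* only when every day inside it is inactive;
  partially covered occasions stay 0/1 because detection remained possible.
* Timestamps are local clock time; no time-zone arithmetic is performed.
"""
from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

RECORD_COLUMNS = ("station", "species", "timestamp")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# station effort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationEffort:
    """Operational window for one camera station.

    Parameters
    ----------
    station_id : str
        Station label, referenced by record tables.
    deploy, retrieve : datetime
        First and last operational timestamps; ``deploy < retrieve``.
    inactive_intervals : tuple of (datetime, datetime)
        Non-overlapping failure gaps inside the window, whole-day inclusive.
    """

    station_id: str
    deploy: datetime
    retrieve: datetime
    inactive_intervals: tuple[tuple[datetime, datetime], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.deploy >= self.retrieve:
            raise ValidationError(
                f"station {self.station_id}: deploy must precede retrieve"
            )
        last_end: date | None = None
        for start, end in self.inactive_intervals:
            if start > end:
                raise ValidationError(
                    f"station {self.station_id}: inactive interval reversed"
                )
            if start < self.deploy or end > self.retrieve:
                raise ValidationError(
                    f"station {self.station_id}: inactive interval outside window"
                )
            if last_end is not None and start.date() <= last_end:
                raise ValidationError(
                    f"station {self.station_id}: overlapping inactive intervals"
                )
            last_end = end.date()

    @property
    def duration_days(self) -> int:
        return (self.retrieve.date() - self.deploy.date()).days + 1

    def day_active_mask(self) -> np.ndarray:
        """Boolean mask over day offsets 0..duration-1; False inside gaps."""
        mask = np.ones(self.duration_days, dtype=bool)
        d0 = self.deploy.date()
        for start, end in self.inactive_intervals:
            a = (start.date() - d0).days
            b = (end.date() - d0).days
            mask[a : b + 1] = False
        return mask

    @property
    def active_days(self) -> int:
        return int(self.day_active_mask().sum())

    def is_active(self, ts: datetime) -> bool:
        """True when ``ts`` falls on an operational day of this station."""
        if ts < self.deploy or ts > self.retrieve:
            return False
        offset = (ts.date() - self.deploy.date()).days
        return bool(self.day_active_mask()[offset])


def total_trap_nights(efforts: list[StationEffort]) -> int:
    """Effective trap nights: active station-days summed over stations."""
    return sum(e.active_days for e in efforts)


def read_efforts(path) -> list[StationEffort]:
    """Read a station effort CSV: ``station,deploy,retrieve[,gap_start,gap_end]*``."""
    efforts: list[StationEffort] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"{path}: empty effort file")
        for row in reader:
            if not row or not row[0].strip():
                continue
            station, deploy, retrieve, *gaps = [c.strip() for c in row]
            gaps = [g for g in gaps if g]
            if len(gaps) % 2:
                raise ValidationError(
                    f"station {station}: gap columns must come in start/end pairs"
                )
            intervals = tuple(
                (_parse_ts(gaps[i]), _parse_ts(gaps[i + 1]))
                for i in range(0, len(gaps), 2)
            )
            efforts.append(
                StationEffort(station, _parse_ts(deploy), _parse_ts(retrieve), intervals)
            )
    if not efforts:
        raise ValidationError(f"{path}: no stations found")
    return efforts


def write_efforts(efforts: list[StationEffort], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["station", "deploy", "retrieve", "gap_start", "gap_end"])
        for e in efforts:
            row = [e.station_id, e.deploy.isoformat(), e.retrieve.isoformat()]
            for start, end in e.inactive_intervals:
                row.extend([start.isoformat(), end.isoformat()])
            writer.writerow(row)


def _parse_ts(text: str) -> datetime:
    try:
        return datetime.fromisoformat(text)
    except ValueError as exc:
        raise ValidationError(f"unparseable timestamp {text!r}") from exc


# ---------------------------------------------------------------------------
# record tables
# ---------------------------------------------------------------------------

def read_records(path, efforts: list[StationEffort] | None = None,
                 delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a detection record table.

    When ``efforts`` is given, every record must name a known station and fall
    on an operational day; violations raise :class:`ValidationError` listing
    the offending rows.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no records")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable timestamp ({exc})") from exc
    df = df.loc[:, list(RECORD_COLUMNS)].copy()
    df["station"] = df["station"].astype(str)
    df["species"] = df["species"].astype(str)
    if efforts is not None:
        validate_records(df, efforts)
    return df


def validate_records(records: pd.DataFrame, efforts: list[StationEffort]) -> None:
    """Check station ids and operational windows; raise listing bad rows."""
    by_id = {e.station_id: e for e in efforts}
    unknown = sorted(set(records["station"]) - set(by_id))
    if unknown:
        raise ValidationError(f"unknown station ids: {unknown}")
    bad_rows = [
        int(idx)
        for idx, row in records.iterrows()
        if not by_id[row["station"]].is_active(row["timestamp"].to_pydatetime())
    ]
    if bad_rows:
        raise ValidationError(
            f"{len(bad_rows)} record(s) outside the station's operational "
            f"window, rows: {bad_rows}"
        )


def write_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, columns=list(RECORD_COLUMNS))


def independence_filter(records: pd.DataFrame, window_hours: float = 1.0) -> pd.DataFrame:
    """Keep only independent events per station x species.

    A record is retained iff its timestamp is at least ``window_hours`` after
    the last *retained* record of the same species at the same station
    (greedy scan; the comparison is inclusive, so a gap of exactly one hour
    keeps the record). The first record of each group is always kept.
    Idempotent by construction.
    """
    if window_hours < 0:
        raise ValueError("window_hours must be non-negative")
    window = timedelta(hours=window_hours)
    keep_idx: list = []
    ordered = records.sort_values(["station", "species", "timestamp"], kind="stable")
    for _, group in ordered.groupby(["station", "species"], sort=False):
        last_kept = None
        for idx, ts in zip(group.index, group["timestamp"]):
            if last_kept is None or ts - last_kept >= window:
                keep_idx.append(idx)
                last_kept = ts
    return records.loc[records.index.isin(keep_idx)].copy()


# ---------------------------------------------------------------------------
# detection histories
# ---------------------------------------------------------------------------

@dataclass
class DetectionHistory:
    """Sites x occasions detection matrix for one species.

    ``matrix`` is float with entries 1 (detected), 0 (surveyed, not
    detected), and NaN (station fully inactive for that occasion).
    """

    species: str
    station_ids: tuple[str, ...]
    occasion_length: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.station_ids):
            raise ValidationError("matrix rows must match station_ids")
        if self.occasion_length < 1:
            raise ValidationError("occasion_length must be >= 1")
        vals = self.matrix[~np.isnan(self.matrix)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("matrix entries must be 0, 1 or NaN")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    @property
    def active(self) -> np.ndarray:
        return ~np.isnan(self.matrix)

    def to_csv(self, path) -> None:
        cols = [f"occ_{k + 1}" for k in range(self.n_occasions)]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "station", list(self.station_ids))
        df.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path, species: str = "", occasion_length: int = 6
                 ) -> "DetectionHistory":
        df = pd.read_csv(path, na_values=["NA"])
        stations = tuple(df["station"].astype(str))
        mat = df.drop(columns=["station"]).to_numpy(dtype=float)
        return cls(species, stations, occasion_length, mat)


def n_occasions_for(efforts: list[StationEffort], occasion_length_days: int) -> int:
    longest = max(e.duration_days for e in efforts)
    return math.ceil(longest / occasion_length_days)


def build_history(records: pd.DataFrame, efforts: list[StationEffort],
                  species: str, occasion_length_days: int = 6) -> DetectionHistory:
    """Collapse independent records into a detection history.

    Occasion bins are anchored per station at its deployment date; a record
    ``d`` days after deployment (0-based) falls into occasion
    ``d // occasion_length_days``. A species absent from the records yields an
    all-{0,NaN} history.
    """
    length = int(occasion_length_days)
    if length < 1:
        raise ValueError("occasion_length_days must be >= 1")
    n_occ = n_occasions_for(efforts, length)
    n = len(efforts)
    matrix = np.full((n, n_occ), np.nan)
    index = {e.station_id: i for i, e in enumerate(efforts)}

    for i, eff in enumerate(efforts):
        day_mask = eff.day_active_mask()
        if not day_mask.any():
            warnings.warn(
                f"station {eff.station_id} has zero active days; row is all-missing",
                stacklevel=2,
            )
            continue
        for k in range(n_occ):
            days = day_mask[k * length : (k + 1) * length]
            if days.size and days.any():
                matrix[i, k] = 0.0

    sub = records.loc[records["species"] == species]
    for _, row in sub.iterrows():
        i = index.get(row["station"])
        if i is None:
            raise ValidationError(f"record references unknown station {row['station']}")
        eff = efforts[i]
        offset = (row["timestamp"].date() - eff.deploy.date()).days
        k = offset // length
        if 0 <= k < n_occ and not np.isnan(matrix[i, k]):
            matrix[i, k] = 1.0
        else:
            warnings.warn(
                f"record at {row['station']} falls in an inactive occasion; ignored",
                stacklevel=2,
            )
    return DetectionHistory(species, tuple(e.station_id for e in efforts),
                            length, matrix)


# ---------------------------------------------------------------------------
# survey summaries (capture rates / naive occupancy)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveySummary:
    species: str
    n_events: int
    trap_nights: int
    capture_rate: float
    naive_occupancy: float


def capture_rate(n_events: int, trap_nights: float) -> float:
    """Independent events per 100 effective trap nights."""
    if trap_nights <= 0:
        raise ValueError("trap_nights must be positive")
    return 100.0 * n_events / trap_nights


def survey_summary(records: pd.DataFrame, efforts: list[StationEffort],
                   species: str) -> SurveySummary:
    """Per-species event count, capture rate and naive occupancy.

    ``records`` is expected to be independence-filtered already.
    """
    nights = total_trap_nights(efforts)
    sub = records.loc[records["species"] == species]
    n_events = len(sub)
    occupied = sub["station"].nunique()
    return SurveySummary(
        species=species,
        n_events=n_events,
        trap_nights=nights,
        capture_rate=capture_rate(n_events, nights) if n_events else 0.0,
        naive_occupancy=occupied / len(efforts),
    )


def summarize_all(records: pd.DataFrame, efforts: list[StationEffort]) -> pd.DataFrame:
    """Survey summary table over every species present in the records."""
    rows = [
        survey_summary(records, efforts, sp).__dict__
        for sp in sorted(records["species"].unique())
    ]
    return pd.DataFrame(rows)
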