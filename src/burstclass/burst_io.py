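"""Reading, validating, labelling and persisting burst accelerometry and GPS tables.

A *burst* is one short fixed-length recording interval of a tri-axial
accelerometer operated on a duty cycle (here, by default, 110 samples per axis
at 33.33 Hz every 2 minutes, i.e. 3.3 s of signal). The canonical on-disk
layout is a long CSV with one row per sample::

    animal_id,burst_id,burst_start,t_index,x,y,z

A wide dialect (one row per burst, each axis a space-separated sample string)
is accepted via ``layout="wide"``. Acceleration values stay in device units
throughout; no g-calibration is applied because every downstream predictor is
scale-consistent.

Dropped or excluded records are never discarded silently: every reader accepts
a :class:`RunLog` that accumulates structured JSON-lines events.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LabelError, ParseError, SchemaError, ShapeError

DEFAULT_SAMPLING_RATE = 33.33
DEFAULT_BURST_LENGTH = 110

#: Behaviour catalogue used throughout: six mutually exclusive classes plus a
#: rejection category ("other") that is *not* part of the ethogram itself.
FOX_CLASSES = ("feeding", "grooming", "resting", "caching", "trotting", "walking")
OTHER_LABEL = "other"


@dataclass(frozen=True)
class Ethogram:
    """An ordered catalogue of discrete behaviour classes.

    The rejection class absorbs low-confidence or mixed assignments and must
    not itself be one of the ethogram classes.
    """

    classes: tuple[str, ...] = FOX_CLASSES
    descriptions: Mapping[str, str] = field(default_factory=dict)
    reject_class: str = OTHER_LABEL

    def __post_init__(self):
        if self.reject_class in self.classes:
            raise ValueError("reject_class must not be an ethogram class")

    def __contains__(self, name: str) -> bool:
        return name in self.classes


DEFAULT_ETHOGRAM = Ethogram()


@dataclass
class AccBurst:
    """One accelerometer recording interval.

    Attributes
    ----------
    animal_id : str
    burst_id : str
        Unique identifier within the dataset.
    burst_start : pandas.Timestamp
        UTC start of the burst.
    x, y, z : ndarray
        Equal-length axis sample sequences (device units). Axis convention:
        x = sway, y = surge, z = heave.
    sampling_rate : float
        Samples per second per axis.
    label : str or None
        Ethogram class, when ground-truthed.
    """

    animal_id: str
    burst_id: str
    burst_start: pd.Timestamp
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    label: str | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ShapeError(
                f"burst {self.burst_id}: axis lengths differ "
                f"({len(self.x)}, {len(self.y)}, {len(self.z)})"
            )
        if len(self.x) < 1:
            raise ShapeError(f"burst {self.burst_id}: empty burst")
        self.burst_start = pd.Timestamp(self.burst_start)
        if self.burst_start.tzinfo is None:
            self.burst_start = self.burst_start.tz_localize("UTC")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Burst duration in seconds (n / sampling_rate)."""
        return self.n / self.sampling_rate

    def samples(self) -> np.ndarray:
        """Return the (n, 3) sample array in axis order x, y, z."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass(frozen=True)
class GpsFix:
    """A single GPS location fix."""

    animal_id: str
    time: pd.Timestamp
    lat: float
    lon: float

    def __post_init__(self):
        t = pd.Timestamp(self.time)
        if t.tzinfo is None:
            t = t.tz_localize("UTC")
        object.__setattr__(self, "time", t)
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")


class RunLog:
    """Structured run log: a list of dict events, persisted as JSON lines."""

    def __init__(self):
        self.events: list[dict] = []

    def log(self, event: str, **fields):
        self.events.append({"event": event, **fields})

    def count(self, event: str) -> int:
        return sum(1 for e in self.events if e["event"] == event)

    def write(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.events:
                fh.write(json.dumps(e, default=str) + "\n")


_LONG_COLUMNS = ("animal_id", "burst_id", "burst_start", "t_index", "x", "y", "z")
_WIDE_COLUMNS = ("animal_id", "burst_id", "burst_start", "x", "y", "z")


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str]):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[c].iloc[row]!r} in column {c} at row {row}",
                row=row,
            )
        df[c] = converted
    return df


def read_bursts(
    path,
    schema: Mapping[str, str] | None = None,
    clock_offset: float = 0.0,
    n_expected: int | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    layout: str = "long",
    log: RunLog | None = None,
) -> list[AccBurst]:
    """Read bursts from CSV, dropping incomplete ones.

    Parameters
    ----------
    schema : mapping, optional
        Maps canonical column names to the file's column names, e.g.
        ``{"animal_id": "tag"}``.
    clock_offset : float
        Seconds added to every burst_start, compensating a per-collar clock
        shift established externally (drift correction itself is a
        human-in-the-loop step and is not automated here).
    n_expected : int, optional
        Required samples per axis. Defaults to the modal burst length in the
        file. Bursts with any axis length differing are dropped and logged.
    layout : {"long", "wide"}
        Long = one row per sample; wide = one row per burst with
        space-separated sample strings per axis.
    """
    log = log if log is not None else RunLog()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    df = _apply_schema(df, schema)

    bursts: list[AccBurst] = []
    if layout == "long":
        _require_columns(df, _LONG_COLUMNS)
        df = _numeric(df, ["t_index", "x", "y", "z"])
        for (animal, bid), grp in df.groupby(["animal_id", "burst_id"], sort=False):
            grp = grp.sort_values("t_index")
            arr = grp[["x", "y", "z"]].to_numpy(dtype=float)
            start = pd.Timestamp(grp["burst_start"].iloc[0])
            bursts.append(_make_burst(str(animal), str(bid), start, arr, sampling_rate))
    elif layout == "wide":
        _require_columns(df, _WIDE_COLUMNS)
        for i, row in df.iterrows():
            try:
                axes = [
                    np.array([float(v) for v in str(row[c]).split()]) for c in "xyz"
                ]
            except ValueError as exc:
                raise ParseError(f"non-numeric sample at row {i}: {exc}", row=int(i))
            lens = {len(a) for a in axes}
            if len(lens) != 1:
                log.log("burst_dropped", burst_id=str(row["burst_id"]),
                        reason="axis length mismatch")
                continue
            arr = np.column_stack(axes)
            bursts.append(
                _make_burst(str(row["animal_id"]), str(row["burst_id"]),
                            pd.Timestamp(row["burst_start"]), arr, sampling_rate)
            )
    else:
        raise SchemaError(f"unknown layout {layout!r}")

    if n_expected is None and bursts:
        lengths = [b.n for b in bursts]
        n_expected = int(pd.Series(lengths).mode().iloc[0])
    complete = []
    for b in bursts:
        if n_expected is not None and b.n != n_expected:
            log.log("burst_dropped", burst_id=b.burst_id, reason="incomplete",
                    n=b.n, n_expected=n_expected)
            continue
        complete.append(b)

    offset = pd.Timedelta(seconds=clock_offset)
    for b in complete:
        b.burst_start = b.burst_start + offset
    complete.sort(key=lambda b: (b.animal_id, b.burst_start))
    return complete


def _make_burst(animal, bid, start, arr, rate) -> AccBurst:
    return AccBurst(animal_id=animal, burst_id=bid, burst_start=start,
                    x=arr[:, 0], y=arr[:, 1], z=arr[:, 2], sampling_rate=rate)


def write_bursts(bursts: Iterable[AccBurst], path, layout: str = "long"):
    """Write bursts to CSV in the canonical long layout (or wide)."""
    rows = []
    if layout == "long":
        for b in bursts:
            for i in range(b.n):
                rows.append({
                    "animal_id": b.animal_id, "burst_id": b.burst_id,
                    "burst_start": b.burst_start.isoformat(), "t_index": i,
                    "x": b.x[i], "y": b.y[i], "z": b.z[i],
                })
    elif layout == "wide":
        for b in bursts:
            rows.append({
                "animal_id": b.animal_id, "burst_id": b.burst_id,
                "burst_start": b.burst_start.isoformat(),
                "x": " ".join(repr(float(v)) for v in b.x),
                "y": " ".join(repr(float(v)) for v in b.y),
                "z": " ".join(repr(float(v)) for v in b.z),
            })
    else:
        raise SchemaError(f"unknown layout {layout!r}")
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observations(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a ground-truthing observation table (animal_id, time, behaviour)."""
    df = pd.read_csv(path, dtype=str)
    df = _apply_schema(df, schema)
    _require_columns(df, ("animal_id", "time", "behaviour"))
    df["time"] = pd.to_datetime(df["time"], utc=True)
    return df


def attach_labels(
    bursts: Sequence[AccBurst],
    observations: pd.DataFrame,
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
    log: RunLog | None = None,
) -> list[AccBurst]:
    """Label bursts by exact timestamp match against observations.

    An observation listing more than one behaviour (semicolon-separated)
    marks a mixed burst, which is excluded from the returned sequence —
    mixed bursts are not characteristic of any single class and are removed
    before training. Bursts without a matching observation are kept
    unlabelled. Behaviours outside the ethogram raise :class:`LabelError`.
    """
    log = log if log is not None else RunLog()
    obs = observations.copy()
    obs["time"] = pd.to_datetime(obs["time"], utc=True)
    dup = obs.duplicated(subset=["animal_id", "time"], keep=False)
    if dup.any():
        raise LabelError("observation timestamps are not unique per animal")
    lookup = {(r.animal_id, r.time): r.behaviour for r in obs.itertuples()}

    out: list[AccBurst] = []
    for b in bursts:
        key = (b.animal_id, b.burst_start)
        if key not in lookup:
            out.append(b)
            continue
        behaviour = str(lookup[key])
        parts = [p.strip() for p in behaviour.split(";") if p.strip()]
        for p in parts:
            if p not in ethogram:
                raise LabelError(f"behaviour {p!r} not in ethogram")
        if len(parts) != 1:
            log.log("burst_excluded", burst_id=b.burst_id,
                    reason="multiple behaviours in burst", behaviours=parts)
            continue
        out.append(replace(b, label=parts[0]))
    return out


def read_gps(path, schema: Mapping[str, str] | None = None) -> list[GpsFix]:
    """Read GPS fixes (animal_id, time, lat, lon), sorted per animal by time."""
    df = pd.read_csv(path, dtype=str)
    df = _apply_schema(df, schema)
    _require_columns(df, ("animal_id", "time", "lat", "lon"))
    df = _numeric(df, ["lat", "lon"])
    df["time"] = pd.to_datetime(df["time"], utc=True)
    df = df.sort_values(["animal_id", "time"])
    return [GpsFix(str(r.animal_id), r.time, float(r.lat), float(r.lon))
            for r in df.itertuples()]


def write_gps(fixes: Iterable[GpsFix], path):
    pd.DataFrame(
        [{"animal_id": f.animal_id, "time": f.time.isoformat(),
          "lat": f.lat, "lon": f.lon} for f in fixes]
    ).to_csv(path, index=False)
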