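"""Indirect credibility checks for behaviour assignments on free-ranging animals.

When wild individuals cannot be observed, classified behaviour streams are
validated indirectly through four signatures:

1. **Diel composition** — behaviour proportions by month and time of day
   should match the species' known activity pattern (for a nocturnal-
   crepuscular carnivore: rest by day, locomotion at night).
2. **GPS-cluster coherence** — stationary behaviours (resting) should fall
   inside spatial clusters of consecutive GPS fixes; locomotion should not.
   A cluster is a maximal run of consecutive fixes all within a fixed radius
   (default 50 m) of the run's *first* fix; only clusters holding at least
   ``min_items`` classified bursts count as clustered.
3. **Speed coherence** — bursts recorded within a few seconds of a GPS fix
   inherit that fix's between-fix speed; resting should be slower than
   trotting (one-sided Wilcoxon rank-sum).
4. **Actograms** — day x time-of-day rasters of ODBA or a behaviour
   indicator, with sunrise/sunset overlays; movement intensity should
   concentrate in the dark hours.

Distances are haversine on a sphere of radius 6371.0088 km; at the 50 m
scale the ellipsoid correction is irrelevant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._solar import is_night, sunrise_sunset
from .burst_io import GpsFix
from .errors import DegenerateIntervalError
from .models import PredictionRecord

EARTH_RADIUS_M = 6_371_008.8


def haversine_m(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in metres between two WGS-84 coordinates."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


# ---------------------------------------------------------------------------
# GPS clusters
# ---------------------------------------------------------------------------

@dataclass
class GpsCluster:
    """A maximal run of consecutive fixes within ``radius_m`` of its anchor."""

    cluster_id: int
    anchor: GpsFix
    members: list[GpsFix]
    behaviour_counts: dict[str, int] = field(default_factory=dict)

    @property
    def start(self) -> pd.Timestamp:
        return self.anchor.time

    @property
    def end(self) -> pd.Timestamp:
        return self.members[-1].time

    def __len__(self) -> int:
        return len(self.members)


def segment_clusters(fixes: Sequence[GpsFix], radius_m: float = 50.0
                     ) -> list[GpsCluster]:
    """Sequential single-pass segmentation of a time-sorted fix sequence.

    A fix within ``radius_m`` of the current cluster's first fix extends the
    cluster; a farther fix closes it and anchors a new one. Singleton
    clusters are allowed. The clusters partition the fix sequence.
    """
    clusters: list[GpsCluster] = []
    for f in fixes:
        if clusters and haversine_m(clusters[-1].anchor.lat,
                                    clusters[-1].anchor.lon,
                                    f.lat, f.lon) <= radius_m:
            clusters[-1].members.append(f)
        else:
            clusters.append(GpsCluster(len(clusters), f, [f]))
    return clusters


def cluster_behaviour_coherence(
    predictions: Sequence[PredictionRecord],
    clusters: Sequence[GpsCluster],
    min_items: int = 10,
) -> dict[str, float]:
    """Per-behaviour fraction of assignments lying in qualifying clusters.

    Each prediction is assigned to the cluster whose time span (anchor time
    to last-member time, half-open at the right) contains its burst start.
    Clusters holding fewer than ``min_items`` assigned predictions do not
    count as spatially clustered.
    """
    counts: dict[str, int] = {}
    in_cluster: dict[str, int] = {}
    assigned: list[list[PredictionRecord]] = [[] for _ in clusters]
    starts = np.array([c.start.value for c in clusters])
    for r in predictions:
        counts[r.burst_class] = counts.get(r.burst_class, 0) + 1
        i = int(np.searchsorted(starts, r.burst_start.value, side="right")) - 1
        if i >= 0:
            c = clusters[i]
            if c.start <= r.burst_start < c.end:
                assigned[i].append(r)
    for c, recs in zip(clusters, assigned):
        c.behaviour_counts = {}
        for r in recs:
            c.behaviour_counts[r.burst_class] = \
                c.behaviour_counts.get(r.burst_class, 0) + 1
        if len(recs) >= min_items:
            for cls, k in c.behaviour_counts.items():
                in_cluster[cls] = in_cluster.get(cls, 0) + k
    return {cls: in_cluster.get(cls, 0) / n for cls, n in counts.items()}


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------

def gps_speed(fixes: Sequence[GpsFix]) -> pd.DataFrame:
    """Speed (m/s) of each interval between consecutive fixes.

    Columns: t_start, t_end, speed. Requires strictly increasing timestamps.
    """
    rows = []
    for a, b in zip(fixes[:-1], fixes[1:]):
        dt = (b.time - a.time).total_seconds()
        if dt <= 0:
            raise DegenerateIntervalError(
                f"non-increasing timestamps at {a.time} -> {b.time}")
        rows.append({"t_start": a.time, "t_end": b.time,
                     "speed": haversine_m(a.lat, a.lon, b.lat, b.lon) / dt})
    return pd.DataFrame(rows, columns=["t_start", "t_end", "speed"])


def match_speed_to_behaviour(
    predictions: Sequence[PredictionRecord],
    fixes: Sequence[GpsFix],
    max_dt: float = 10.0,
) -> pd.DataFrame:
    """Join bursts to the speed at their nearest GPS fix within ``max_dt`` s.

    A burst matches at most one fix (the nearest; boundary |dt| = max_dt
    included) and inherits the speed of the inter-fix interval ending at that
    fix (the first fix uses the interval that starts there). Unmatched bursts
    are dropped. Columns: burst_id, behaviour, speed, dt.
    """
    if len(fixes) < 2:
        return pd.DataFrame(columns=["burst_id", "behaviour", "speed", "dt"])
    speeds = gps_speed(fixes)
    fix_times = np.array([f.time.value for f in fixes])
    # speed attached to each fix: interval ending there; first fix -> first interval
    fix_speed = np.concatenate([[speeds["speed"].iloc[0]],
                                speeds["speed"].to_numpy()])
    rows = []
    for r in predictions:
        t = r.burst_start.value
        i = int(np.searchsorted(fix_times, t))
        best, best_dt = None, None
        for j in (i - 1, i):
            if 0 <= j < len(fixes):
                dt = abs(t - fix_times[j]) / 1e9
                if best_dt is None or dt < best_dt:
                    best, best_dt = j, dt
        if best is not None and best_dt <= max_dt:
            rows.append({"burst_id": r.burst_id, "behaviour": r.burst_class,
                         "speed": float(fix_speed[best]), "dt": best_dt})
    return pd.DataFrame(rows, columns=["burst_id", "behaviour", "speed", "dt"])


def speed_ranksum(matched: pd.DataFrame, slow: str = "resting",
                  fast: str = "trotting") -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum: is ``slow`` slower than ``fast``?

    Returns (W statistic, p-value) of the two-sample test with normal
    approximation and tie correction, alternative = slow < fast.
    """
    a = matched.loc[matched["behaviour"] == slow, "speed"].to_numpy()
    b = matched.loc[matched["behaviour"] == fast, "speed"].to_numpy()
    stat, p = mannwhitneyu(a, b, alternative="less", method="asymptotic")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# diel composition and actograms
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """Behaviour counts per (month, time-of-day bin).

    ``flagged_months`` lists months covering fewer than ``min_days`` distinct
    days; their panels are not interpretable.
    """

    counts: pd.DataFrame  # index (month, bin_minute), columns behaviours
    days_covered: dict[str, int]
    flagged_months: set[str]

    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0)


def diel_composition(predictions: Iterable, bin_minutes: int = 30,
                     min_days: int = 15) -> CompositionTable:
    """Tabulate behaviour counts by month and time-of-day bin.

    ``predictions`` is a sequence of :class:`PredictionRecord` or a DataFrame
    with columns ``time`` and ``behaviour``. Months with fewer than
    ``min_days`` covered days are flagged (at least half a month of data is
    needed for a readable panel).
    """
    if isinstance(predictions, pd.DataFrame):
        df = predictions.rename(columns={"burst_class": "behaviour"}).copy()
    else:
        df = pd.DataFrame([{"time": r.burst_start, "behaviour": r.burst_class}
                           for r in predictions])
    if df.empty:
        return CompositionTable(pd.DataFrame(), {}, set())
    df["time"] = pd.to_datetime(df["time"], utc=True)
    df["month"] = df["time"].dt.strftime("%Y-%m")
    minutes = df["time"].dt.hour * 60 + df["time"].dt.minute
    df["bin"] = (minutes // bin_minutes) * bin_minutes
    counts = (df.groupby(["month", "bin", "behaviour"]).size()
              .unstack(fill_value=0))
    days = df.groupby("month")["time"].apply(lambda s: s.dt.date.nunique())
    days_covered = days.to_dict()
    flagged = {m for m, d in days_covered.items() if d < min_days}
    return CompositionTable(counts, days_covered, flagged)


@dataclass
class ActogramGrid:
    """Day x time-of-day raster with optional sunrise/sunset overlays."""

    days: list  # ordinal dates (rows)
    bin_minutes: int
    values: np.ndarray  # (n_days, n_bins); NaN where no data
    sun_events: list[tuple[float | None, float | None]] | None = None

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def actogram(times, values, bin_minutes: int = 30, lat: float | None = None,
             lon: float | None = None) -> ActogramGrid:
    """Build a day x time-of-day grid of a timestamped scalar or indicator.

    Cells average all values in the bin (for a 0/1 behaviour indicator this
    is the occupancy fraction); days without data stay as blank NaN rows so
    the row count spans the full recording period. With a location given,
    per-day sunrise/sunset minutes (UTC) are attached.
    """
    t = pd.to_datetime(pd.Series(list(times)), utc=True)
    v = np.asarray(list(values), dtype=float)
    dates = t.dt.date
    d0, d1 = dates.min(), dates.max()
    all_days = pd.date_range(d0, d1, freq="D").date.tolist()
    day_index = {d: i for i, d in enumerate(all_days)}
    n_bins = (24 * 60) // bin_minutes
    sums = np.zeros((len(all_days), n_bins))
    counts = np.zeros((len(all_days), n_bins))
    bins = ((t.dt.hour * 60 + t.dt.minute) // bin_minutes).to_numpy()
    for d, b, val in zip(dates, bins, v):
        sums[day_index[d], b] += val
        counts[day_index[d], b] += 1
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    sun = None
    if lat is not None and lon is not None:
        sun = []
        for d in all_days:
            rise, sset = sunrise_sunset(d, lat, lon)
            sun.append((
                None if rise is None else rise.hour * 60 + rise.minute,
                None if sset is None else sset.hour * 60 + sset.minute,
            ))
    return ActogramGrid(all_days, bin_minutes, grid, sun)


def night_fraction(predictions: Sequence[PredictionRecord], behaviour: str,
                   lat: float, lon: float) -> float:
    """Fraction of a behaviour's assignments falling between sunset and sunrise."""
    times = [r.burst_start for r in predictions if r.burst_class == behaviour]
    if not times:
        return float("nan")
    flags = [is_night(t.to_pydatetime(), lat, lon) for t in times]
    return float(np.mean(flags))
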