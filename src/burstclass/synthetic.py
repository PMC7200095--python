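"""Synthetic burst accelerometry and GPS tracks with known ground truth.

No public accelerometer/GPS dataset accompanies the captive-training /
wild-application workflow this package implements, so every pipeline stage is
exercised on simulated data that mimics its structure: bursts of 110 samples
per axis at 33.33 Hz on a 2-minute duty cycle, six behaviour classes with
distinct posture/amplitude/periodicity signatures, a nocturnal-crepuscular
diel schedule, and GPS fixes every 4 minutes whose movement statistics follow
the behaviour state (stationary dwell during rest, sustained travel while
trotting).

Signal model per class: each axis is a constant orientation term (the static,
gravitational component, in device units of roughly 1 g) plus an optional
sinusoid (gait periodicity; frequency in Hz, amplitude split across axes by
fixed weights, random phase per burst, multiplicative amplitude jitter) plus
Gaussian noise. Resting is aperiodic and quiet; walking and trotting are
periodic at gait-like 1.5 and 3 Hz with increasing amplitude; grooming is
broadband (noise-dominated); feeding and caching are intermediate mixtures.
The defaults are chosen so the moment and spectral predictors separate the
classes — they emulate clean captive recordings, not the messier variability
of real collars.

All generators are pure functions of (parameters, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .burst_io import (AccBurst, DEFAULT_BURST_LENGTH, DEFAULT_SAMPLING_RATE,
                       FOX_CLASSES, GpsFix)
from .errors import ConfigError


@dataclass(frozen=True)
class BehaviourSignal:
    """Per-class signal parameters (device units ~ g)."""

    orientation: tuple[float, float, float]  # static component per axis x,y,z
    freq: float = 0.0          # gait frequency, Hz (0 = aperiodic)
    amp: float = 0.0           # sinusoid amplitude before axis weighting
    noise_sd: float = 0.05
    amp_jitter: float = 0.1    # multiplicative amplitude jitter (uniform +-)
    axis_weights: tuple[float, float, float] = (0.5, 1.0, 0.8)


#: Default six-class signal model. Classes are pairwise distinguishable by
#: (orientation, frequency, amplitude, noise); resting has zero periodic
#: amplitude.
DEFAULT_SIGNAL_MODEL: dict[str, BehaviourSignal] = {
    "resting":  BehaviourSignal((0.00, 0.00, 1.00), freq=0.0, amp=0.00,
                                noise_sd=0.03),
    "grooming": BehaviourSignal((0.35, 0.05, 0.90), freq=0.0, amp=0.00,
                                noise_sd=0.30),
    "feeding":  BehaviourSignal((0.15, 0.55, 0.80), freq=0.8, amp=0.15,
                                noise_sd=0.10),
    "caching":  BehaviourSignal((0.25, 0.15, 0.95), freq=2.2, amp=0.35,
                                noise_sd=0.12),
    "walking":  BehaviourSignal((0.00, 0.25, 0.95), freq=1.5, amp=0.25,
                                noise_sd=0.06),
    "trotting": BehaviourSignal((0.00, 0.45, 0.85), freq=3.0, amp=0.70,
                                noise_sd=0.10),
}

#: Class counts of the default captive training set (imbalance included).
CAPTIVE_COUNTS: dict[str, int] = {
    "feeding": 367, "grooming": 1140, "resting": 2114,
    "caching": 197, "trotting": 179, "walking": 162,
}


def generate_burst(
    behaviour: str,
    model: dict[str, BehaviourSignal] | None = None,
    n: int = DEFAULT_BURST_LENGTH,
    rate: float = DEFAULT_SAMPLING_RATE,
    rng: np.random.Generator | int | None = None,
    animal_id: str = "sim",
    burst_id: str = "b0",
    start=None,
) -> AccBurst:
    """Draw one labelled burst from the signal model."""
    model = model if model is not None else DEFAULT_SIGNAL_MODEL
    if behaviour not in model:
        raise ConfigError(f"unknown behaviour class {behaviour!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sig = model[behaviour]
    t = np.arange(n) / rate
    axes = []
    amp = sig.amp * (1.0 + rng.uniform(-sig.amp_jitter, sig.amp_jitter))
    for i in range(3):
        a = np.full(n, sig.orientation[i])
        if sig.freq > 0 and amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            a = a + amp * sig.axis_weights[i] * np.sin(
                2 * np.pi * sig.freq * t + phase)
        if sig.noise_sd > 0:
            a = a + rng.normal(0.0, sig.noise_sd, n)
        axes.append(a)
    if start is None:
        start = datetime(2023, 3, 20, tzinfo=timezone.utc)
    return AccBurst(animal_id=animal_id, burst_id=burst_id,
                    burst_start=pd.Timestamp(start), x=axes[0], y=axes[1],
                    z=axes[2], sampling_rate=rate, label=behaviour)


def generate_captive_dataset(
    counts: dict[str, int] | None = None,
    model: dict[str, BehaviourSignal] | None = None,
    seed: int = 0,
    animal_id: str = "captive",
    n: int = DEFAULT_BURST_LENGTH,
    rate: float = DEFAULT_SAMPLING_RATE,
    burst_period_s: float = 120.0,
) -> list[AccBurst]:
    """Labelled training bursts with the default (imbalanced) class counts.

    Counts are honoured exactly; bursts are timestamped on the duty-cycle
    cadence in a deterministic interleaved order.
    """
    counts = counts if counts is not None else CAPTIVE_COUNTS
    model = model if model is not None else DEFAULT_SIGNAL_MODEL
    rng = np.random.default_rng(seed)
    labels = [cls for cls in counts for _ in range(counts[cls])]
    rng.shuffle(labels)
    t0 = pd.Timestamp(datetime(2023, 1, 1, tzinfo=timezone.utc))
    bursts = []
    for i, cls in enumerate(labels):
        bursts.append(generate_burst(
            cls, model, n=n, rate=rate, rng=rng, animal_id=animal_id,
            burst_id=f"{animal_id}-{i:05d}",
            start=t0 + pd.Timedelta(seconds=i * burst_period_s)))
    return bursts


# ---------------------------------------------------------------------------
# wild scenario
# ---------------------------------------------------------------------------

def default_diel_schedule() -> pd.DataFrame:
    """Hour-of-day (UTC) behaviour probabilities for a nocturnal-crepuscular
    carnivore: rest-dominated daytime, locomotion-dominated night, mixed
    twilight. Rows sum to 1."""
    day = {"resting": 0.78, "grooming": 0.14, "feeding": 0.05,
           "caching": 0.02, "walking": 0.005, "trotting": 0.005}
    night = {"resting": 0.15, "grooming": 0.11, "feeding": 0.12,
             "caching": 0.05, "walking": 0.23, "trotting": 0.34}
    twilight = {"resting": 0.25, "grooming": 0.15, "feeding": 0.20,
                "caching": 0.05, "walking": 0.20, "trotting": 0.15}
    rows = {}
    for h in range(24):
        if 9 <= h <= 17:
            rows[h] = day
        elif h in (6, 7, 8, 18, 19):
            rows[h] = twilight
        else:
            rows[h] = night
    df = pd.DataFrame(rows).T[list(FOX_CLASSES)]
    return df


#: Travel speed per behaviour state, m/s (stationary states ~ 0).
DEFAULT_SPEEDS: dict[str, float] = {
    "resting": 0.0, "grooming": 0.02, "feeding": 0.15,
    "caching": 0.2, "walking": 1.0, "trotting": 3.0,
}


@dataclass
class WildScenario:
    """Configuration of a simulated free-ranging deployment."""

    days: int = 7
    schedule: pd.DataFrame = field(default_factory=default_diel_schedule)
    stickiness: float = 0.93      # P(repeat previous state) per burst slot
    burst_period_s: float = 120.0
    gps_period_s: float = 240.0
    speeds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPEEDS))
    dwell_radius_m: float = 10.0  # jitter radius of stationary bouts (< 50 m)
    start: datetime = datetime(2023, 3, 20, tzinfo=timezone.utc)
    lat: float = 52.52
    lon: float = 13.40
    seed: int = 0


_M_PER_DEG_LAT = 111_194.9  # spherical earth, R = 6371.0088 km


def generate_wild_track(
    scenario: WildScenario | None = None,
    model: dict[str, BehaviourSignal] | None = None,
) -> tuple[list[AccBurst], list[GpsFix], pd.DataFrame]:
    """Simulate an unlabelled wild deployment with withheld ground truth.

    The behaviour state evolves per burst slot: with probability
    ``stickiness`` the previous state persists, otherwise a fresh state is
    drawn from the hour's diel schedule (bout persistence creates the
    stationary dwells that become GPS clusters). The animal's position moves
    at the state's travel speed along a slowly-turning heading; stationary
    states jitter within ``dwell_radius_m`` of the current bout anchor.
    GPS fixes are taken every ``gps_period_s``.

    Returns (bursts without labels, fixes, truth table with columns
    burst_id, time, behaviour).
    """
    sc = scenario if scenario is not None else WildScenario()
    model = model if model is not None else DEFAULT_SIGNAL_MODEL
    rng = np.random.default_rng(sc.seed)
    classes = list(sc.schedule.columns)
    probs = sc.schedule.to_numpy()
    if not np.allclose(probs.sum(axis=1), 1.0):
        raise ConfigError("diel schedule rows must sum to 1")

    n_slots = int(sc.days * 86400 / sc.burst_period_s)
    t0 = pd.Timestamp(sc.start)

    # --- behaviour state sequence with bout persistence
    states: list[str] = []
    state = None
    for i in range(n_slots):
        hour = (t0 + pd.Timedelta(seconds=i * sc.burst_period_s)).hour
        if state is None or rng.uniform() >= sc.stickiness:
            state = classes[rng.choice(len(classes), p=probs[hour])]
        states.append(state)

    # --- position trace, sampled at burst resolution
    m_per_deg_lon = _M_PER_DEG_LAT * np.cos(np.radians(sc.lat))
    pos = np.zeros(2)          # metres east, north of the origin
    anchor = pos.copy()
    heading = rng.uniform(0, 2 * np.pi)
    moving_prev = False
    positions = np.zeros((n_slots, 2))
    for i, cls in enumerate(states):
        speed = sc.speeds.get(cls, 0.0)
        if speed > 0.3:
            heading += rng.normal(0, 0.4)
            step = speed * sc.burst_period_s
            pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
            moving_prev = True
        else:
            if moving_prev:
                anchor = pos.copy()
                moving_prev = False
            # slow states drift/jitter around the bout anchor
            drift = speed * sc.burst_period_s
            anchor = anchor + rng.normal(0, max(drift, 1e-9) / 2, 2)
            r = rng.uniform(0, sc.dwell_radius_m)
            th = rng.uniform(0, 2 * np.pi)
            pos = anchor + r * np.array([np.sin(th), np.cos(th)])
        positions[i] = pos

    # --- bursts
    bursts, truth_rows = [], []
    for i, cls in enumerate(states):
        start = t0 + pd.Timedelta(seconds=i * sc.burst_period_s)
        bid = f"wild-{i:05d}"
        b = generate_burst(cls, model, rng=rng, animal_id="wild",
                           burst_id=bid, start=start)
        b.label = None  # truth is withheld from the emitted data
        bursts.append(b)
        truth_rows.append({"burst_id": bid, "time": start, "behaviour": cls})

    # --- GPS fixes on their own cadence
    fixes = []
    step = int(round(sc.gps_period_s / sc.burst_period_s))
    for i in range(0, n_slots, max(step, 1)):
        east, north = positions[i]
        fixes.append(GpsFix(
            animal_id="wild",
            time=t0 + pd.Timedelta(seconds=i * sc.burst_period_s),
            lat=sc.lat + north / _M_PER_DEG_LAT,
            lon=sc.lon + east / m_per_deg_lon))

    return bursts, fixes, pd.DataFrame(truth_rows)


def mixed_burst(
    first: str, second: str,
    split: float = 0.5,
    model: dict[str, BehaviourSignal] | None = None,
    n: int = DEFAULT_BURST_LENGTH,
    rate: float = DEFAULT_SAMPLING_RATE,
    rng: np.random.Generator | int | None = None,
    burst_id: str = "mixed",
) -> AccBurst:
    """Splice two behaviours within one burst (tests the rejection path)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = int(round(split * n))
    a = generate_burst(first, model, n=n, rate=rate, rng=rng, burst_id=burst_id)
    b = generate_burst(second, model, n=n, rate=rate, rng=rng, burst_id=burst_id)
    out = AccBurst(animal_id=a.animal_id, burst_id=burst_id,
                   burst_start=a.burst_start,
                   x=np.concatenate([a.x[:k], b.x[k:]]),
                   y=np.concatenate([a.y[:k], b.y[k:]]),
                   z=np.concatenate([a.z[:k], b.z[k:]]),
                   sampling_rate=rate, label=None)
    return out
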