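"""Moving-window augmentation of bursts and leakage-safe stratified splitting.

The moving window multiplies training examples from short bursts while
preserving sample order (so spectral predictors remain meaningful): a window
of w consecutive samples slides along the burst one position at a time until
it includes the last sample, yielding n - w + 1 sub-windows of a length-n
burst (32 for the standard 110-sample burst at w = 79).

Splitting into train/test happens at *burst* level, per behaviour class,
before any windowing — windows of one burst are near-duplicates, and letting
them straddle the split would leak test information into training.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .burst_io import AccBurst, RunLog
from .errors import StratificationError, WindowTooLargeError
from .features import feature_matrix, feature_names


@dataclass(frozen=True)
class WindowPlan:
    """A moving-window configuration: window size and step (default 1)."""

    window_size: int
    step: int = 1

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def window_count(self, n: int) -> int:
        """Number of windows extracted from a length-n burst."""
        if self.window_size > n:
            raise WindowTooLargeError(
                f"window {self.window_size} exceeds burst length {n}")
        return (n - self.window_size) // self.step + 1

    def offsets(self, n: int) -> np.ndarray:
        return np.arange(0, n - self.window_size + 1, self.step)


def slide(burst: AccBurst, plan: WindowPlan) -> tuple[np.ndarray, np.ndarray]:
    """Extract all windows of a burst.

    Returns
    -------
    windows : ndarray, shape (k, w, 3)
    offsets : ndarray, shape (k,)
        0-based start index of each window within the burst.
    """
    n = burst.n
    if plan.window_size > n:
        raise WindowTooLargeError(
            f"window {plan.window_size} exceeds burst length {n}")
    arr = burst.samples()  # (n, 3)
    views = sliding_window_view(arr, plan.window_size, axis=0)  # (n-w+1, 3, w)
    offsets = plan.offsets(n)
    return np.moveaxis(views[offsets], 1, 2).copy(), offsets


def stratified_split(
    bursts: Sequence[AccBurst],
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[list[AccBurst], list[AccBurst]]:
    """Random per-class burst-level split preserving class proportions.

    Per-class train count is round-half-up of ``train_frac * class_count``,
    with at least one burst forced into each partition. Reproducible given
    the seed; no burst appears in both partitions.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    by_class: dict[str, list[int]] = {}
    for i, b in enumerate(bursts):
        if b.label is None:
            raise StratificationError(f"burst {b.burst_id} is unlabelled")
        by_class.setdefault(b.label, []).append(i)

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if idx.size < 2:
            raise StratificationError(
                f"class {label!r} has {idx.size} burst(s); need >= 2")
        rng.shuffle(idx)
        n_train = int(np.floor(train_frac * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return ([bursts[i] for i in sorted(train_idx)],
            [bursts[i] for i in sorted(test_idx)])


def expand(
    bursts: Sequence[AccBurst],
    plan: WindowPlan,
    log: RunLog | None = None,
) -> pd.DataFrame:
    """Moving-window feature table for a burst sequence.

    One row per window, carrying provenance (burst_id, window_offset) and the
    inherited burst label alongside the frozen predictor columns. All bursts
    must be at least window_size long.
    """
    names = feature_names(plan.window_size)
    meta_cols = ["burst_id", "animal_id", "burst_start", "window_offset", "label"]
    if not bursts:
        return pd.DataFrame(columns=meta_cols + names)

    stacks, meta = [], []
    for b in bursts:
        windows, offsets = slide(b, plan)
        stacks.append(windows)
        meta.append((b, offsets))
    feats = feature_matrix(np.concatenate(stacks, axis=0))

    frames = []
    for b, offsets in meta:
        frames.append(pd.DataFrame({
            "burst_id": b.burst_id,
            "animal_id": b.animal_id,
            "burst_start": b.burst_start,
            "window_offset": offsets,
            "label": b.label,
        }))
    out = pd.concat(frames, ignore_index=True)
    out = pd.concat([out, pd.DataFrame(feats, columns=names)], axis=1)
    return out


def split_features(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split an expanded table into (X, y) arrays for model fitting."""
    meta = {"burst_id", "animal_id", "burst_start", "window_offset", "label"}
    cols = [c for c in table.columns if c not in meta]
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy()
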