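"""Predictor set for a window of tri-axial acceleration samples.

Per axis: mean, standard deviation, inverse coefficient of variation
(mean/sd), variance, skewness and kurtosis. Combining all three axes:
q (mean vector magnitude), pitch and roll (posture angles from the static,
i.e. window-mean, component), and ODBA (overall dynamic body acceleration).
Finally, the whole one-sided FFT magnitude spectrum of each axis.

Conventions (fixed for reproducibility):

* moments are population moments (divide by n); skewness and kurtosis are
  the standardized 3rd / 4th central moments (Pearson kurtosis, not excess);
* a constant window (sd = 0) maps inv_cv, skewness and kurtosis to the
  sentinel 0 so feature vectors are always finite;
* ODBA subtracts the per-window mean as the static component (windows are
  at most a few seconds long, so no running-mean smoothing is defined);
* axis convention x = sway, y = surge, z = heave, so
  pitch = atan2(ybar, hypot(xbar, zbar)) and roll = atan2(xbar, hypot(ybar,
  zbar)), both in degrees;
* the FFT spectrum is the unnormalized one-sided magnitude spectrum
  including the DC bin: floor(w/2) + 1 values per axis.

For a window of length w the vector has ``3*6 + 4 + 3*(w//2 + 1)``
predictors (142 at w = 79). The column order is frozen; see
:func:`feature_names`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ShapeError, UndefinedOrientationError

logger = logging.getLogger(__name__)

_MOMENT_NAMES = ("mean", "sd", "inv_cv", "variance", "skewness", "kurtosis")
FEATURE_SET_VERSION = "1"


def feature_names(window_size: int) -> list[str]:
    """Frozen column order of the predictor vector for a given window size."""
    names = [f"{ax}_{m}" for ax in "xyz" for m in _MOMENT_NAMES]
    names += ["q", "pitch", "roll", "odba"]
    nbins = window_size // 2 + 1
    names += [f"fft_{ax}_{k:03d}" for ax in "xyz" for k in range(nbins)]
    return names


def n_features(window_size: int) -> int:
    return 18 + 4 + 3 * (window_size // 2 + 1)


def axis_moments(samples) -> tuple[float, float, float, float, float, float]:
    """(mean, sd, inv_cv, variance, skewness, kurtosis) of one axis window.

    Population moments; the sd = 0 degenerate case maps inv_cv, skewness and
    kurtosis to 0 so constant (deep-rest) windows stay classifiable.
    """
    a = np.asarray(samples, dtype=float)
    if a.size < 2:
        raise InsufficientDataError(f"need >= 2 samples, got {a.size}")
    mean = a.mean()
    d = a - mean
    var = float(np.mean(d**2))
    sd = float(np.sqrt(var))
    if sd == 0.0:
        logger.debug("constant window: inv_cv/skewness/kurtosis set to 0")
        return float(mean), 0.0, 0.0, 0.0, 0.0, 0.0
    t = d / sd  # standardized residuals: avoids underflow of sd**3 / var**2
    skew = float(np.mean(t**3))
    kurt = float(np.mean(t**4))
    return float(mean), sd, float(mean / sd), var, skew, kurt


def odba(x, y, z) -> float:
    """Overall dynamic body acceleration of a window.

    Static component per axis = window mean; ODBA is the mean over samples of
    the summed absolute dynamic components |dx| + |dy| + |dz|.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ShapeError("axis sequences have different lengths")
    return float(sum(np.mean(np.abs(a - a.mean())) for a in (x, y, z)))


def q_stat(x, y, z) -> float:
    """Mean vector magnitude: mean over samples of sqrt(x^2 + y^2 + z^2)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ShapeError("axis sequences have different lengths")
    return float(np.mean(np.sqrt(x**2 + y**2 + z**2)))


def pitch_roll(x, y, z) -> tuple[float, float]:
    """Posture angles (degrees) from the window-mean acceleration vector."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    xm, ym, zm = x.mean(), y.mean(), z.mean()
    if xm == 0.0 and ym == 0.0 and zm == 0.0:
        raise UndefinedOrientationError("all-zero mean acceleration vector")
    pitch = np.degrees(np.arctan2(ym, np.hypot(xm, zm)))
    roll = np.degrees(np.arctan2(xm, np.hypot(ym, zm)))
    return float(pitch), float(roll)


def fft_spectrum(samples) -> np.ndarray:
    """One-sided unnormalized FFT magnitude spectrum including the DC bin."""
    a = np.asarray(samples, dtype=float)
    return np.abs(np.fft.rfft(a))


@dataclass
class FeatureVector:
    """The full predictor set for one window, with provenance."""

    burst_id: str
    window_offset: int
    values: np.ndarray
    names: list[str]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def featurize(window, burst_id: str = "", window_offset: int = 0) -> FeatureVector:
    """Compute the full predictor vector for one (w, 3) window.

    ``window`` may be an (w, 3) array or an object with x/y/z attributes
    (e.g. an :class:`~burstclass.burst_io.AccBurst`).
    """
    if hasattr(window, "samples"):
        if not burst_id:
            burst_id = getattr(window, "burst_id", "")
        window = window.samples()
    arr = np.asarray(window, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ShapeError(f"expected (w, 3) window, got {arr.shape}")
    if arr.shape[0] < 2:
        raise InsufficientDataError("window length must be >= 2")
    mat = feature_matrix(arr[None, :, :])
    return FeatureVector(burst_id=burst_id, window_offset=window_offset,
                         values=mat[0], names=feature_names(arr.shape[0]))


def feature_matrix(windows: np.ndarray) -> np.ndarray:
    """Vectorized predictor computation for a stack of windows.

    Parameters
    ----------
    windows : ndarray, shape (m, w, 3)

    Returns
    -------
    ndarray, shape (m, n_features(w)), finite for finite input.
    """
    a = np.asarray(windows, dtype=float)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ShapeError(f"expected (m, w, 3) stack, got {a.shape}")
    m, w, _ = a.shape
    if w < 2:
        raise InsufficientDataError("window length must be >= 2")
    ax = np.moveaxis(a, 2, 1)  # (m, 3, w)

    mean = ax.mean(-1)
    d = ax - mean[..., None]
    var = np.mean(d**2, axis=-1)
    sd = np.sqrt(var)
    nz = sd > 0
    inv_cv = np.zeros_like(sd)
    skew = np.zeros_like(sd)
    kurt = np.zeros_like(sd)
    np.divide(mean, sd, out=inv_cv, where=nz)
    t = d / np.where(nz, sd, 1.0)[..., None]  # standardized; underflow-safe
    skew[nz] = np.mean(t**3, axis=-1)[nz]
    kurt[nz] = np.mean(t**4, axis=-1)[nz]
    moments = np.stack([mean, sd, inv_cv, var, skew, kurt], axis=-1)  # (m,3,6)

    q = np.mean(np.sqrt((a**2).sum(axis=2)), axis=1)
    xm, ym, zm = mean[:, 0], mean[:, 1], mean[:, 2]
    pitch = np.degrees(np.arctan2(ym, np.hypot(xm, zm)))
    roll = np.degrees(np.arctan2(xm, np.hypot(ym, zm)))
    odba_v = np.mean(np.abs(d), axis=-1).sum(axis=1)
    fft = np.abs(np.fft.rfft(ax, axis=-1))  # (m, 3, w//2+1)

    return np.hstack([
        moments.reshape(m, 18),
        np.column_stack([q, pitch, roll, odba_v]),
        fft.reshape(m, -1),
    ])
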