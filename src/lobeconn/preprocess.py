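"""Time-series denoising for regional signals.

The processing order is fixed and mirrors standard resting-state practice:
linear detrend, 0.01-0.08 Hz zero-phase band-pass, then nuisance regression
(24-parameter motion expansion, CSF/WM stand-ins, global signal).  Hemisphere
flipping relabels regions by their homotopic partner so right-lateralised
subjects can be pooled with left-lateralised ones.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .cohort import Parcellation, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "detrend_and_bandpass",
    "friston24",
    "nuisance_regress",
    "mean_fd",
    "flip_hemispheres",
]


def detrend_and_bandpass(
    ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> RoiTimeSeries:
    """Remove per-column linear trends, then band-pass with a zero-phase
    (forward-backward) Butterworth filter of effective order 4.

    The filter is applied with ``filtfilt``, so the pass band is phase-free
    and stop-band attenuation is squared relative to a single pass.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low ({low_hz}) < high ({high_hz})")
    if high_hz >= nyquist:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyquist} Hz")
    detrended = signal.detrend(ts.data, axis=0, type="linear")
    sos = signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, detrended, axis=0)
    return ts.with_data(filtered - filtered.mean(axis=0))


def friston24(motion: np.ndarray) -> np.ndarray:
    """24-parameter motion expansion: [m_t, m_t^2, m_{t-1}, m_{t-1}^2].

    ``motion`` is T x 6 (3 translations in mm, 3 rotations in radians); the
    lagged block's first row is backfilled with zeros.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, motion**2, lagged, lagged**2])


def nuisance_regress(ts: RoiTimeSeries, regressors: np.ndarray) -> RoiTimeSeries:
    """Residualise every regional series against the regressor columns.

    An intercept is always included.  Collinear regressor columns are handled
    by least squares on the column space (rank-deficiency is logged, not
    fatal); residuals are orthogonal to every regressor.
    """
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if regressors.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"regressors have {regressors.shape[0]} rows, time series has {ts.n_timepoints}"
        )
    design = np.hstack([np.ones((ts.n_timepoints, 1)), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "nuisance design is rank deficient (%d < %d); collinear columns are ignored",
            rank,
            design.shape[1],
        )
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return ts.with_data(ts.data - design @ beta)


def mean_fd(motion: np.ndarray, sphere_radius_mm: float = 50.0) -> float:
    """Mean frame-wise displacement.

    FD_t = sum |delta translations| + radius * sum |delta rotations|, averaged
    over the T-1 frame-to-frame differences.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + sphere_radius_mm * diffs[:, 3:].sum(axis=1)
    return float(fd.mean())


def flip_hemispheres(data: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Relabel regions by their homotopic partner (left-right flip).

    For a T x N time series the columns are permuted; for an N x N matrix both
    rows and columns are permuted.  Applying the flip twice is the identity.
    """
    perm = np.asarray(parcellation.partner)
    data = np.asarray(data)
    n = parcellation.n_rois
    if data.ndim == 2 and data.shape == (n, n):
        return data[np.ix_(perm, perm)]
    if data.ndim == 2 and data.shape[1] == n:
        return data[:, perm]
    raise ValueError(f"cannot flip array of shape {data.shape} with {n} ROIs")
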