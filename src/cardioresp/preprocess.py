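"""Signal conditioning: respiration band-pass, RRi stationarity check,
cubic tachogram interpolation, and anti-aliased downsampling.

The respiration band-pass is fixed by the physiology: 0.05-0.67 Hz, i.e.
3-40 breaths/min. RR intervals are interpolated onto a uniform grid (the
tachogram) so that signal-pair methods (Granger causality, transfer
entropy, lagged correlation) can operate sample-by-sample; both signals are
additionally kept at a 25 Hz decimated variant used by the costlier causal
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import interpolate, signal
from statsmodels.tsa.adfvalues import mackinnonp

__all__ = [
    "RESP_BAND_HZ",
    "Tachogram",
    "StationarityResult",
    "bandpass_resp",
    "check_stationarity",
    "phillips_perron",
    "tachogram_from_rri",
    "downsample",
]

#: Respiration passband in Hz — 3 and 40 breaths per minute.
RESP_BAND_HZ = (0.05, 0.67)


@dataclass
class Tachogram:
    """RR-interval series on a uniform time grid."""

    values: np.ndarray   # ms
    fs: float            # Hz
    t0: float            # time of the first grid sample, s
    source_rri: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs


class StationarityResult(NamedTuple):
    statistic: float
    p_value: float
    is_stationary: bool
    degenerate: bool


def bandpass_resp(
    raw: np.ndarray,
    fs: float,
    band: tuple = RESP_BAND_HZ,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the raw respiration signal.

    Forward-backward filtering keeps the phase response flat, which matters
    for the lag-sensitive coupling features downstream.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = band
    if fs <= 2.0 * hi:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    if len(raw) < 60.0 * fs:
        raise ValueError("need at least 60 s of signal for a stable band-pass")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, raw)


def phillips_perron(
    y: np.ndarray, lags: Optional[int] = None
) -> tuple[float, float]:
    """Phillips-Perron Z_tau unit-root test (regression with constant).

    OLS of y_t on (1, y_{t-1}); the t-statistic of (rho - 1) is corrected
    non-parametrically for serial correlation with a Newey-West (Bartlett
    kernel) long-run variance of the residuals. P-values come from the
    MacKinnon response surface shared with the ADF tau distribution.
    """
    y = np.asarray(y, dtype=float)
    n = len(y) - 1
    if n < 10:
        raise ValueError("series too short for a unit-root test")
    if lags is None:
        lags = int(np.ceil(4.0 * (n / 100.0) ** (2.0 / 9.0)))
    ylag = y[:-1]
    ycur = y[1:]
    X = np.column_stack([np.ones(n), ylag])
    beta, *_ = np.linalg.lstsq(X, ycur, rcond=None)
    u = ycur - X @ beta
    s2 = float(u @ u) / (n - 2)  # OLS regression variance
    xtx_inv = np.linalg.inv(X.T @ X)
    se_rho = float(np.sqrt(s2 * xtx_inv[1, 1]))
    t_rho = (beta[1] - 1.0) / se_rho

    gamma0 = float(u @ u) / n
    lam2 = gamma0
    for j in range(1, lags + 1):
        w = 1.0 - j / (lags + 1.0)
        lam2 += 2.0 * w * float(u[j:] @ u[:-j]) / n
    lam2 = max(lam2, 1e-300)
    lam = np.sqrt(lam2)
    z_tau = np.sqrt(gamma0 / lam2) * t_rho - 0.5 * (lam2 - gamma0) / lam * (
        n * se_rho / np.sqrt(s2)
    ) / lam
    p = float(mackinnonp(z_tau, regression="c", N=1))
    return float(z_tau), p


def check_stationarity(rri: np.ndarray, alpha: float = 0.05) -> StationarityResult:
    """Stationarity check of the beat-wise RR series (unit-root rejection).

    Non-fatal: callers log the outcome. A constant series is reported as
    (trivially) stationary with the degenerate flag set.
    """
    rri = np.asarray(rri, dtype=float)
    if len(rri) < 50:
        raise ValueError("need at least 50 beats")
    if np.ptp(rri) == 0.0:
        return StationarityResult(np.nan, 0.0, True, True)
    stat, p = phillips_perron(rri)
    return StationarityResult(stat, p, p < alpha, False)


def tachogram_from_rri(rri: np.ndarray, fs_target: float = 250.0) -> Tachogram:
    """Cubic interpolation of (beat time, RR) pairs onto a uniform grid.

    Beat time of interval n is the cumulative sum of intervals up to and
    including n; the grid spans first to last beat time (no extrapolation).
    """
    rri = np.asarray(rri, dtype=float)
    if len(rri) < 4:
        raise ValueError("cubic interpolation needs at least 4 beats")
    if np.any(rri <= 0):
        raise ValueError("RR intervals must be positive")
    beat_times = np.cumsum(rri) / 1000.0
    spline = interpolate.CubicSpline(beat_times, rri, extrapolate=False)
    n = int(np.floor((beat_times[-1] - beat_times[0]) * fs_target)) + 1
    grid = beat_times[0] + np.arange(n) / fs_target
    values = spline(grid)
    return Tachogram(values=values, fs=fs_target, t0=beat_times[0], source_rri=rri)


def downsample(x: np.ndarray, factor: int = 10) -> np.ndarray:
    """Anti-aliased decimation (zero-phase); 250 Hz -> 25 Hz by default."""
    x = np.asarray(x, dtype=float)
    if len(x) < factor:
        raise ValueError("signal shorter than the decimation factor")
    return signal.decimate(x, factor, ftype="fir", zero_phase=True)
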