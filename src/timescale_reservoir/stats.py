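"""Descriptive statistics of network dynamics.

Autocorrelations and their half-width-at-half-maximum (HWHM) timescales,
bistable dwell-time statistics with hysteresis, Welch power spectra with
per-population peak amplitudes, the spectral modulation index and its
crossover frequency, and lognormal fitting of timescale distributions.

The HWHM is the nonparametric timescale definition used throughout: the lag
at which an autocorrelation first falls to half its zero-lag value.  For an
exponential decay with time constant tau0 this equals tau0 * ln 2, which is
also the conversion factor bridging fitted decay constants to HWHM values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from . import rate as _rate
from .rate import Trajectory, ValidationError

__all__ = [
    "AutocorrResult",
    "SpectralResult",
    "autocorrelation",
    "hwhm",
    "hwhm_from_curve",
    "dwell_statistics",
    "psd",
    "peak_amplitudes",
    "modulation_index",
    "fit_timescale_distribution",
    "convert_decay_to_hwhm",
]

LN2 = math.log(2.0)


@dataclass
class AutocorrResult:
    """Time-averaged autocorrelation on a uniform lag grid."""

    lags: np.ndarray
    C: np.ndarray
    normalization: Literal["raw", "unit_peak"]
    n_samples: int
    degenerate: bool = False  # constant input after mean subtraction
    truncated: bool = False  # HWHM never reached within max_lag


@dataclass
class SpectralResult:
    """Welch power spectral density, optionally with per-population peaks."""

    frequencies: np.ndarray  # Hz
    power: np.ndarray  # density, signal units^2 / Hz
    peak_freqs: Optional[np.ndarray] = None
    peak_power: Optional[np.ndarray] = None


def autocorrelation(
    traj: Trajectory,
    units: Optional[Sequence[int]] = None,
    max_lag: float = 50.0,
    transform: Literal["phi", "identity"] = "phi",
    normalization: Literal["raw", "unit_peak"] = "raw",
    subtract_mean: bool = True,
) -> AutocorrResult:
    """Population-averaged autocorrelation of phi(x) (or x) after burn-in.

    The estimator is the unbiased time-average at each lag, averaged over
    the selected units.  The per-unit time mean is subtracted by default so
    the HWHM is well-defined also for signals with non-zero baseline.
    """
    y = traj.after_burn_in()
    if units is not None:
        y = y[np.asarray(units)]
    nlag = int(round(max_lag / traj.dt)) + 1
    if y.shape[1] < 10 * (nlag - 1):
        raise ValidationError(
            f"trajectory too short: {y.shape[1]} samples after burn-in, "
            f"need >= {10 * (nlag - 1)} for max_lag={max_lag}"
        )
    y = np.tanh(y) if transform == "phi" else np.asarray(y, float)
    degenerate = False
    if subtract_mean:
        y = y - y.mean(axis=1, keepdims=True)
        if np.allclose(y, 0.0):
            degenerate = True
    T = y.shape[1]
    M = 1
    while M < 2 * T:
        M *= 2
    # batch over units to bound FFT memory on long recordings
    C = np.zeros(nlag)
    batch = max(1, int(2**26 // M))
    for k in range(0, y.shape[0], batch):
        Y = np.fft.rfft(y[k : k + batch], n=M, axis=1)
        ac = np.fft.irfft((Y * Y.conj()).real, n=M, axis=1)[:, :nlag]
        C += ac.sum(axis=0)
    C /= y.shape[0] * (T - np.arange(nlag))
    if normalization == "unit_peak" and C[0] != 0:
        C = C / C[0]
    return AutocorrResult(
        lags=np.arange(nlag) * traj.dt,
        C=C,
        normalization=normalization,
        n_samples=T,
        degenerate=degenerate,
    )


def hwhm_from_curve(lags: np.ndarray, C: np.ndarray) -> float:
    """HWHM of a sampled curve: first crossing of C(0)/2, linearly
    interpolated; returns the last lag if the half level is never reached."""
    c0 = C[0]
    if c0 <= 0:
        return float("nan")
    below = np.nonzero(C <= 0.5 * c0)[0]
    if below.size == 0:
        return float(lags[-1])
    i = int(below[0])
    if i == 0:
        return 0.0
    frac = (0.5 * c0 - C[i - 1]) / (C[i] - C[i - 1])
    return float(lags[i - 1] + frac * (lags[i] - lags[i - 1]))


def hwhm(C: AutocorrResult) -> float:
    """HWHM timescale of an autocorrelation result (sets truncation flag)."""
    if C.C[0] <= 0:
        raise ValidationError("autocorrelation must have C(0) > 0")
    tau = hwhm_from_curve(C.lags, C.C)
    if tau == float(C.lags[-1]) and C.C[-1] > 0.5 * C.C[0]:
        C.truncated = True
    return tau


def convert_decay_to_hwhm(tau_decay: float | np.ndarray):
    """Exponential decay constant -> HWHM (multiply by ln 2)."""
    return tau_decay * LN2


def dwell_statistics(
    path: np.ndarray,
    dt: float,
    levels: tuple[float, float],
    hysteresis: float = 0.5,
) -> dict:
    """Dwell times of a bistable signal with hysteresis switch detection.

    ``levels`` = (x_minus, x_plus) are the two state centers.  A switch is
    registered only when the signal crosses the opposite threshold
    ``hysteresis * level``; the dwell time is the interval between
    successive switches.  Incomplete first/last dwells are discarded.
    Returns dict with 'dwells' (array, time units), 'mean', 'n_switches',
    and 'histogram' ((counts, edges)).
    """
    x = np.asarray(path, float).ravel()
    lo, hi = levels
    thr_lo, thr_hi = hysteresis * lo, hysteresis * hi
    state = 0  # -1 low, +1 high, 0 undetermined
    switch_times = []
    for k in range(x.size):
        if x[k] >= thr_hi and state != 1:
            if state == -1:
                switch_times.append(k * dt)
            state = 1
        elif x[k] <= thr_lo and state != -1:
            if state == 1:
                switch_times.append(k * dt)
            state = -1
    if len(switch_times) < 2:
        return {
            "dwells": np.array([]),
            "mean": float("nan"),
            "n_switches": len(switch_times),
            "histogram": (np.array([]), np.array([])),
            "diagnostic": "fewer than 2 switches detected",
        }
    dwells = np.diff(switch_times)
    hist = np.histogram(dwells, bins="auto")
    return {
        "dwells": dwells,
        "mean": float(dwells.mean()),
        "n_switches": len(switch_times),
        "histogram": hist,
    }


def psd(
    traj: Trajectory,
    unit_time_ms: float = _rate.DEFAULT_UNIT_TIME_MS,
    units: Optional[Sequence[int]] = None,
    transform: Literal["identity", "phi"] = "identity",
    n_segments: int = 8,
) -> SpectralResult:
    """Welch PSD in Hz, averaged over the selected units.

    Hann-windowed averaged periodogram with ``n_segments`` segments at 50%
    overlap; density scaling so that the integral over frequency equals the
    signal variance (Parseval).
    """
    y = traj.after_burn_in()
    if units is not None:
        y = y[np.asarray(units)]
    if transform == "phi":
        y = np.tanh(y)
    fs = 1000.0 / (traj.dt * unit_time_ms)  # Hz
    nper = y.shape[1] // (n_segments // 2 + 1) if n_segments > 1 else y.shape[1]
    f, P = sp_signal.welch(
        y,
        fs=fs,
        window="hann",
        nperseg=max(nper, 16),
        noverlap=None,  # 50%
        detrend="constant",
        scaling="density",
        axis=1,
    )
    return SpectralResult(frequencies=f, power=P.mean(axis=0))


def peak_amplitudes(
    spec: SpectralResult, stim_freqs_hz: Sequence[float]
) -> np.ndarray:
    """PSD values read at the bins nearest to the stimulus frequencies."""
    freqs = np.asarray(stim_freqs_hz, float)
    nyq = spec.frequencies[-1]
    if np.any(freqs > nyq):
        raise ValidationError(
            f"stimulus frequency beyond Nyquist ({nyq:.1f} Hz)"
        )
    idx = np.argmin(np.abs(spec.frequencies[None, :] - freqs[:, None]), axis=1)
    spec.peak_freqs = spec.frequencies[idx]
    spec.peak_power = spec.power[idx]
    return spec.peak_power


def modulation_index(
    P1: np.ndarray, P2: np.ndarray, freqs_hz: Optional[np.ndarray] = None
) -> dict:
    """Spectral modulation index m(f) = (P2 - P1)/(P2 + P1) and crossover.

    m > 0 means population 2 is more strongly entrained at f.  The
    crossover frequency f_c is the sign change of m, interpolated linearly
    in (log f, m).  Entries with P1 + P2 = 0 are flagged undefined (NaN).
    """
    P1 = np.asarray(P1, float)
    P2 = np.asarray(P2, float)
    if P1.shape != P2.shape:
        raise ValidationError("P1 and P2 must have equal length")
    denom = P1 + P2
    m = np.full_like(denom, np.nan)
    ok = denom > 0
    m[ok] = (P2[ok] - P1[ok]) / denom[ok]
    fc = None
    if freqs_hz is not None:
        freqs_hz = np.asarray(freqs_hz, float)
        for k in range(m.size - 1):
            if np.isnan(m[k]) or np.isnan(m[k + 1]):
                continue
            if m[k] > 0 >= m[k + 1]:
                lf1, lf2 = math.log(freqs_hz[k]), math.log(freqs_hz[k + 1])
                t = m[k] / (m[k] - m[k + 1])
                fc = math.exp(lf1 + t * (lf2 - lf1))
                break
    return {"m": m, "fc": fc}


def fit_timescale_distribution(timescales: np.ndarray) -> dict:
    """Maximum-likelihood lognormal fit of a sample of timescales.

    Returns dict with 'mu' and 'sigma' (parameters of log tau), and 'ks'
    (Kolmogorov-Smirnov distance between the sample and the fitted law).
    """
    t = np.asarray(timescales, float)
    if t.size == 0 or np.any(t <= 0):
        raise ValidationError("timescales must be positive and non-empty")
    logs = np.log(t)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    ks = sp_stats.kstest(
        t, sp_stats.lognorm(s=sigma, scale=math.exp(mu)).cdf
    ).statistic
    return {"mu": mu, "sigma": sigma, "ks": float(ks)}
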