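"""Embedding-delay and Renyi-order selection.

The characteristic time tau_s of a channel is the mean spacing between
local maxima of its normalized autocorrelation (lag 0 excluded); group-level
tau_s averages the per-channel values.  Complexity-vs-tau scans and the
complexity-maximizing Renyi order q_max follow the same averaging logic.
An Augmented Dickey-Fuller screen flags non-stationary channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .ordinal import TimeSeries, ordinal_distribution
from .quantifiers import ec_curve, mpr_complexity

__all__ = [
    "AutocorrResult",
    "TauScan",
    "QScanResult",
    "ADFResult",
    "autocorrelation",
    "characteristic_time",
    "complexity_tau_scan",
    "adf_screen",
    "q_max_scan",
]


@dataclass
class AutocorrResult:
    lags: np.ndarray
    R: np.ndarray
    peak_lags: np.ndarray
    mean_peak_spacing: float | None
    spacing_std: float | None

    @property
    def n_peaks(self) -> int:
        return self.peak_lags.size


def autocorrelation(series: TimeSeries | np.ndarray, max_lag: int | None = None) -> AutocorrResult:
    """Normalized autocorrelation and its local-maxima spacing.

    R is computed on the demeaned signal and normalized so R(0) = 1; peaks
    are strict local maxima over lags 1..max_lag (default half the signal
    length, lag 0 never counts as a peak).  With fewer than two peaks the
    characteristic spacing is undefined (None).
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    x = x - x.mean()
    n = x.size
    if max_lag is None:
        max_lag = n // 2
    full = sps.correlate(x, x, mode="full", method="fft")
    R = full[n - 1 : n + max_lag]
    if R[0] <= 0:  # constant signal
        return AutocorrResult(np.arange(max_lag + 1), np.zeros(max_lag + 1),
                              np.array([], int), None, None)
    R = R / R[0]
    peaks, _ = sps.find_peaks(R)  # strict local maxima, no prominence filter
    if peaks.size >= 2:
        d = np.diff(peaks)
        spacing, spread = float(d.mean()), float(d.std())
    else:
        spacing, spread = None, None
    return AutocorrResult(lags=np.arange(R.size), R=R, peak_lags=peaks,
                          mean_peak_spacing=spacing, spacing_std=spread)


def characteristic_time(channels, sampling_rate: float | None = None):
    """Group characteristic time tau_s: mean of per-channel peak spacings.

    Channels with fewer than two autocorrelation peaks are excluded (and
    counted).  Returns ``(tau_s_lags, tau_s_seconds, n_used)``;
    tau_s_seconds is None without a sampling rate.
    """
    spacings = []
    for ch in channels:
        res = ch if isinstance(ch, AutocorrResult) else autocorrelation(ch)
        if res.mean_peak_spacing is not None:
            spacings.append(res.mean_peak_spacing)
        if sampling_rate is None and isinstance(ch, TimeSeries) and ch.sampling_rate:
            sampling_rate = ch.sampling_rate
    if not spacings:
        raise ValueError("no channel has a defined peak spacing")
    tau_s = float(np.mean(spacings))
    secs = tau_s / sampling_rate if sampling_rate else None
    return tau_s, secs, len(spacings)


@dataclass
class TauScan:
    D_values: tuple
    tau_values: np.ndarray
    C: np.ndarray          # (len(D_values), len(tau_values)) mean MPR complexity
    argmax_tau: dict       # D -> tau maximizing mean complexity
    skipped: list = field(default_factory=list)


def complexity_tau_scan(series_set, D_values=(3, 4, 5, 6),
                        tau_range=range(1, 31)) -> TauScan:
    """Mean MPR complexity per (D, tau) across channels, with argmax tau.

    Channels too short for a given (D, tau) are skipped with a record,
    never silently truncated.
    """
    series_set = list(series_set)
    taus = np.asarray(list(tau_range), int)
    C = np.full((len(D_values), taus.size), np.nan)
    skipped = []
    for i, D in enumerate(D_values):
        for j, tau in enumerate(taus):
            vals = []
            for s_idx, s in enumerate(series_set):
                x = s.values if isinstance(s, TimeSeries) else np.asarray(s)
                if x.size - (D - 1) * tau < 1:
                    skipped.append((s_idx, D, int(tau)))
                    continue
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    dist = ordinal_distribution(x, D, int(tau))
                vals.append(mpr_complexity(dist).C)
            if vals:
                C[i, j] = float(np.mean(vals))
    argmax = {}
    for i, D in enumerate(D_values):
        row = C[i]
        if np.isfinite(row).any():
            argmax[D] = int(taus[np.nanargmax(row)])
    return TauScan(D_values=tuple(D_values), tau_values=taus, C=C,
                   argmax_tau=argmax, skipped=skipped)


@dataclass
class ADFResult:
    p_value: float | None
    stationary: bool
    degenerate: bool = False


def adf_screen(series: TimeSeries | np.ndarray, alpha: float = 0.05) -> ADFResult:
    """Augmented Dickey-Fuller unit-root screen.

    Stationary iff p < alpha (strict); lag order by AIC.  Constant series
    are flagged degenerate and treated as non-stationary for screening.
    """
    from statsmodels.tsa.stattools import adfuller

    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if np.ptp(x) == 0:
        return ADFResult(p_value=None, stationary=False, degenerate=True)
    p = float(adfuller(x, autolag="AIC")[1])
    return ADFResult(p_value=p, stationary=p < alpha)


@dataclass
class QScanResult:
    q_grid: np.ndarray
    mean_C: np.ndarray
    q_max: float


def q_max_scan(dists, q_grid=None) -> QScanResult:
    """Renyi order maximizing the mean complexity across distributions.

    Ties break toward smaller q (first grid index at the maximum).
    """
    dists = list(dists)
    if not dists:
        raise ValueError("need at least one distribution")
    curves = [ec_curve(d, q_grid) for d in dists]
    q = curves[0].q_grid
    mean_C = np.mean([c.C for c in curves], axis=0)
    return QScanResult(q_grid=q, mean_C=mean_C, q_max=float(q[int(np.argmax(mean_C))]))
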