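"""Aggregation kinetics from hydrodynamic-size time series.

The aggregation rate k is the slope dD/dt (nm/min) between consecutive
size measurements; the maximum interval slope characterises the fastest
aggregation phase, and a plateau is declared once the slope stays below a
tolerance for at least two consecutive intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SizeTimeSeries", "RateResult", "aggregation_rates", "smooth_series"]

#: Slope below which the series counts as stabilized (nm/min). The slowest
#: rate still called an aggregation phase in practice is ~0.44 nm/min.
PLATEAU_TOL = 1.0


@dataclass(frozen=True)
class SizeTimeSeries:
    """Mean hydrodynamic diameter (nm) versus time (min), optional replicate SD."""

    times: np.ndarray
    sizes: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sizes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sizes", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and sizes must be 1-D arrays of equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("sizes must be > 0")
        if self.replicate_sd is not None:
            sd = np.asarray(self.replicate_sd, dtype=float)
            object.__setattr__(self, "replicate_sd", sd)
            if sd.shape != t.shape:
                raise ValueError("replicate_sd must match times in length")


@dataclass(frozen=True)
class RateResult:
    """Per-interval slopes and summary statistics of an aggregation run."""

    interval_rates: np.ndarray  # nm/min
    interval_midtimes: np.ndarray  # min
    max_rate: float  # nm/min
    max_rate_time: float  # min, midpoint of the fastest interval
    plateau_size: float | None  # nm
    plateau_onset: float | None  # min


def aggregation_rates(
    series: SizeTimeSeries, plateau_tol: float = PLATEAU_TOL
) -> RateResult:
    """Consecutive-interval slopes dD/dt with plateau detection.

    The plateau is the first pair of consecutive intervals whose |slope|
    stays below ``plateau_tol``; the plateau size is the mean size from the
    start of that window to the end of the series.
    """
    t, d = series.times, series.sizes
    if t.size < 2:
        raise ValueError("need at least 2 time points to compute a slope")
    rates = np.diff(d) / np.diff(t)
    mid = 0.5 * (t[:-1] + t[1:])
    imax = int(np.argmax(rates))
    plateau_size = plateau_onset = None
    quiet = np.abs(rates) < plateau_tol
    for i in range(quiet.size - 1):
        if quiet[i] and quiet[i + 1]:
            plateau_onset = float(t[i])
            plateau_size = float(np.mean(d[i:]))
            break
    return RateResult(
        interval_rates=rates,
        interval_midtimes=mid,
        max_rate=float(rates[imax]),
        max_rate_time=float(mid[imax]),
        plateau_size=plateau_size,
        plateau_onset=plateau_onset,
    )


def smooth_series(series: SizeTimeSeries, window: int) -> SizeTimeSeries:
    """Centered moving average; endpoints use truncated windows.

    ``window`` must be odd and no larger than the series; window 1 is the
    identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    n = series.sizes.size
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return series
    half = window // 2
    smoothed = np.array(
        [
            series.sizes[max(0, i - half) : min(n, i + half + 1)].mean()
            for i in range(n)
        ]
    )
    return SizeTimeSeries(series.times.copy(), smoothed, series.replicate_sd)
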