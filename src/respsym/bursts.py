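"""Integrated-neurogram normalization, burst detection and resting MSNA.

The integrated MSNA signal is expressed in % of the tallest burst after
subtracting a robust baseline.  Bursts are local maxima that clear a
signal-to-noise threshold and fall a plausible neural conduction delay
after an R wave; each burst is assigned to the cardiac cycle that
generated it (at most one burst per cycle, the tallest candidate wins).
The mean R-wave-to-burst-peak delay is the subject's burst latency, used
to shift the neurogram backward so bursts align with their cycle of
origin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .params import AnalysisConfig
from .records import NormalizedNeurogram

__all__ = [
    "noise_sd_estimate",
    "normalize_neurogram",
    "detect_bursts",
    "mean_burst_latency",
    "shift_neurogram",
    "shifted_peak_times",
    "resting_metrics",
    "integrate_intervals",
]


def noise_sd_estimate(x: np.ndarray) -> float:
    """Robust baseline-noise SD from the lower half of the distribution.

    Bursts contaminate only the upper tail of an integrated neurogram,
    so the SD is taken as 1.4826x the median absolute deviation of the
    samples at or below the median (scaled to be consistent with a
    Gaussian SD).
    """
    x = np.asarray(x, dtype=float)
    med = float(np.median(x))
    lower = med - x[x <= med]
    sd = 1.4826 * float(np.median(lower))
    if sd <= 0:
        sd = float(np.std(x))
    return sd


def normalize_neurogram(
    msna: np.ndarray,
    fs: float,
    start_time: float = 0.0,
    config: AnalysisConfig | None = None,
) -> NormalizedNeurogram:
    """Express the integrated neurogram in % of the tallest burst.

    The baseline (median of sub-threshold samples) is subtracted first,
    then the trace is scaled so the tallest detected burst peak equals
    100%.  The result is invariant to multiplying the raw channel by any
    positive constant.
    """
    config = config or AnalysisConfig()
    x = np.asarray(msna, dtype=float)
    sd = noise_sd_estimate(x)
    med = float(np.median(x))
    threshold = med + config.snr_min * sd
    idx, _ = signal.find_peaks(x, height=threshold)
    if len(idx) == 0:
        raise ValueError(
            "no bursts detected above the SNR threshold; review msna channel "
            "or the snr_min setting"
        )
    baseline = float(np.median(x[x < threshold]))
    tallest = float(x[idx].max())
    scale = 100.0 / (tallest - baseline)
    return NormalizedNeurogram(
        samples=(x - baseline) * scale,
        fs=fs,
        start_time=start_time,
        shift_applied=0.0,
        noise_sd=sd * scale,
    )


def detect_bursts(
    neurogram: NormalizedNeurogram,
    r_times: np.ndarray,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Pulse-synchronous bursts from the (unshifted) normalized neurogram.

    Peak picking runs on a copy of the trace smoothed with a window
    matched to the burst envelope (``burst_smooth_s``), which suppresses
    baseline noise far more than it attenuates burst peaks; candidate
    maxima must clear ``snr_min`` times the smoothed trace's baseline
    noise SD.  Each candidate's peak time and amplitude are then refined
    on the unsmoothed trace.  A candidate is assigned to the most recent
    R wave whose lag (peak time minus R time) lies inside
    ``latency_window``; candidates with no such R wave are rejected, and
    when several candidates share a cardiac cycle only the tallest is
    kept.

    Returns one row per burst: ``peak_time`` (s, unshifted),
    ``cycle_index`` (index into ``r_times``), ``latency`` (s) and
    ``amplitude`` (% of the tallest burst).  May be empty.
    """
    config = config or AnalysisConfig()
    if neurogram.shift_applied != 0:
        raise ValueError("burst detection expects the unshifted neurogram")
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) == 0:
        raise ValueError("r_times must be nonempty")
    x = neurogram.samples
    fs = neurogram.fs
    lat_lo, lat_hi = config.latency_window

    n_win = max(int(round(config.burst_smooth_s * fs)), 1)
    if n_win > 1:
        kernel = np.hanning(n_win + 2)[1:-1]
        kernel /= kernel.sum()
        sm = signal.fftconvolve(x, kernel, mode="same")
    else:
        sm = x
    height = config.snr_min * noise_sd_estimate(sm)
    idx, _ = signal.find_peaks(sm, height=height)
    # refine each candidate on the raw trace
    half = max(n_win // 2, 1)
    refined = []
    for i in idx:
        a, b = max(i - half, 0), min(i + half + 1, len(x))
        refined.append(a + int(np.argmax(x[a:b])))
    idx = np.asarray(refined, dtype=int)
    times = neurogram.start_time + idx / fs

    best: dict[int, tuple[float, float, float]] = {}
    for t, i in zip(times, idx):
        j = int(np.searchsorted(r_times, t - lat_lo, side="right")) - 1
        if j < 0:
            continue
        lag = t - r_times[j]
        if lag > lat_hi:
            continue
        amp = float(x[i])
        if j not in best or amp > best[j][2]:
            best[j] = (t, lag, amp)

    rows = [
        (t, j, lag, amp) for j, (t, lag, amp) in sorted(best.items())
    ]
    return pd.DataFrame(
        rows, columns=["peak_time", "cycle_index", "latency", "amplitude"]
    ).astype({"cycle_index": int} if rows else {})


def mean_burst_latency(bursts: pd.DataFrame) -> float:
    """Arithmetic mean of the R-wave-to-burst-peak delays (s)."""
    if len(bursts) == 0:
        raise ValueError("no bursts: cannot estimate latency")
    return float(bursts["latency"].mean())


def shift_neurogram(
    neurogram: NormalizedNeurogram, mean_latency: float
) -> NormalizedNeurogram:
    """Shift the neurogram backward in time by ``mean_latency``.

    Sample at time t of the output equals the input at ``t + shift``;
    the trailing region with no source data becomes NaN.  Shifts
    compose additively on the valid region.
    """
    if mean_latency < 0:
        raise ValueError("mean_latency must be >= 0")
    k = int(round(mean_latency * neurogram.fs))
    x = neurogram.samples
    out = np.empty_like(x)
    if k == 0:
        out[:] = x
    else:
        out[:-k] = x[k:]
        out[-k:] = np.nan
    return NormalizedNeurogram(
        samples=out,
        fs=neurogram.fs,
        start_time=neurogram.start_time,
        shift_applied=neurogram.shift_applied + k / neurogram.fs,
        noise_sd=neurogram.noise_sd,
    )


def shifted_peak_times(bursts: pd.DataFrame, mean_latency: float) -> np.ndarray:
    """Burst peak times on the shifted timeline (aligned to cycle of origin)."""
    if len(bursts) == 0:
        return np.empty(0)
    return bursts["peak_time"].to_numpy() - mean_latency


def integrate_intervals(
    neurogram: NormalizedNeurogram, intervals: np.ndarray
) -> np.ndarray:
    """Area (%*s) of the neurogram over each half-open interval [start, end).

    Samples are assigned to intervals by sample index, negative
    excursions are clipped at zero (the burst area is a modulus) and
    NaN samples (invalid shifted tail) contribute nothing.
    """
    x = np.nan_to_num(np.clip(neurogram.samples, 0.0, None))
    fs = neurogram.fs
    t0 = neurogram.start_time
    cum = np.concatenate([[0.0], np.cumsum(x)]) / fs
    n = len(x)
    starts = np.clip(np.ceil((intervals[:, 0] - t0) * fs).astype(int), 0, n)
    ends = np.clip(np.ceil((intervals[:, 1] - t0) * fs).astype(int), 0, n)
    return cum[ends] - cum[starts]


def resting_metrics(
    bursts: pd.DataFrame,
    r_times: np.ndarray,
    neurogram: NormalizedNeurogram,
    window: tuple[float, float],
    grid_intervals: np.ndarray | None = None,
) -> dict[str, float]:
    """Whole-window resting MSNA: bursts/100 HB, bursts/min, total area/s.

    Burst area is accumulated over the supplied respiratory-interval
    grid (falling back to the whole window when no grid is given) and
    divided by the window duration, yielding a mean level in % of the
    tallest burst.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    r_times = np.asarray(r_times, dtype=float)
    n_hb = int(np.sum((r_times >= t0) & (r_times < t1)))
    if n_hb == 0:
        raise ValueError("no heartbeats in the analysis window")
    if len(bursts):
        origin = bursts["peak_time"].to_numpy() - bursts["latency"].to_numpy()
        n_bursts = int(np.sum((origin >= t0) & (origin < t1)))
    else:
        n_bursts = 0
    duration = t1 - t0
    if grid_intervals is None:
        grid_intervals = np.asarray([[t0, t1]])
    area = float(integrate_intervals(neurogram, grid_intervals).sum())
    return {
        "bursts_per_100hb": 100.0 * n_bursts / n_hb,
        "bursts_per_min": n_bursts / (duration / 60.0),
        "total_area_per_s": area / duration,
        "n_bursts": n_bursts,
        "n_heartbeats": n_hb,
    }
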