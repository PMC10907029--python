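"""Cardiac and respiratory landmark extraction and per-beat hemodynamics.

Implements the beat-to-beat and breath-by-breath bookkeeping every later
stage relies on: R-wave times, per-cycle systolic/diastolic/mean/pulse
pressures, and respiratory trough/peak segmentation with inspiration
defined trough -> peak and expiration peak -> trough.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .params import AnalysisConfig
from .records import SignalRecord

__all__ = [
    "detect_r_waves",
    "beat_hemodynamics",
    "detect_resp_cycles",
    "respiratory_summary",
]


def detect_r_waves(
    record: SignalRecord, config: AnalysisConfig | None = None
) -> np.ndarray:
    """Strictly increasing R-wave times from the ECG channel.

    Peak detection with an amplitude threshold (fraction of the channel
    maximum) and a refractory constraint between detections.  Explicit
    annotations attached to the record pass through unchanged.
    """
    config = config or AnalysisConfig()
    if record.r_annotations is not None:
        ann = np.asarray(record.r_annotations, dtype=float)
        if np.any(np.diff(ann) <= 0):
            raise ValueError("R-wave annotations must be strictly increasing")
        return ann
    if "ecg" not in record:
        raise ValueError("record has no ecg channel and no R annotations")
    ecg = record["ecg"]
    height = config.r_height_frac * ecg.max()
    if ecg.max() <= 0:
        raise ValueError("ecg channel unusable: no positive deflections")
    distance = max(int(round(config.r_refractory_s * record.fs)), 1)
    idx, _ = signal.find_peaks(ecg, height=height, distance=distance)
    if len(idx) == 0:
        # single-sample impulses have no neighbours below them; fall back
        # to thresholding isolated maxima
        idx = np.flatnonzero(ecg >= height)
        keep = []
        last = -distance
        for i in idx:
            if i - last >= distance:
                keep.append(i)
                last = i
        idx = np.asarray(keep, dtype=int)
    if len(idx) == 0:
        raise ValueError("no R waves detected; ecg channel unusable")
    return record.start_time + idx / record.fs


def beat_hemodynamics(
    record: SignalRecord, r_times: np.ndarray, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-cycle heart rate and pressures.

    For each cardiac cycle ``[r_i, r_{i+1})``: the diastolic point is the
    pressure minimum in a search window around the R wave
    (``[r_i - pre, r_i + post_frac * RR]``), systolic pressure is the
    maximum between adjacent diastolic points, and mean arterial
    pressure is the modulus (mean) of the waveform between adjacent
    diastolic points.  Heart rate is ``60 / RR``.

    Returns one row per complete cycle with columns
    ``r_time, rr, hr, sbp, dbp, map, pp, t_dbp``.
    """
    config = config or AnalysisConfig()
    if "pressure" not in record:
        raise ValueError("record has no pressure channel")
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < 2:
        raise ValueError("need at least two R waves")
    pres = record["pressure"]
    if np.ptp(pres) < 1.0:
        raise ValueError("pressure channel is flat (range < 1 mmHg)")
    fs = record.fs
    t0 = record.start_time
    n = len(pres)

    rr = np.diff(r_times)
    # diastolic search for every R wave (the last one closes the final beat)
    rr_ext = np.append(rr, rr[-1])
    d_idx = np.empty(len(r_times), dtype=int)
    for i, (r, rri) in enumerate(zip(r_times, rr_ext)):
        lo = max(int(np.floor((r - t0 - config.dbp_search_pre_s) * fs)), 0)
        hi = min(
            int(np.ceil((r - t0 + config.dbp_search_post_frac * rri) * fs)) + 1, n
        )
        if hi <= lo:
            lo, hi = max(hi - 1, 0), min(lo + 1, n)
        d_idx[i] = lo + int(np.argmin(pres[lo:hi]))

    rows = []
    for i in range(len(r_times) - 1):
        a, b = d_idx[i], d_idx[i + 1]
        if b <= a:
            continue
        seg = pres[a:b]
        rows.append(
            (
                r_times[i],
                rr[i],
                60.0 / rr[i],
                float(seg.max()),
                float(pres[a]),
                float(seg.mean()),
                t0 + a / fs,
            )
        )
    beats = pd.DataFrame(
        rows, columns=["r_time", "rr", "hr", "sbp", "dbp", "map", "t_dbp"]
    )
    beats["pp"] = beats["sbp"] - beats["dbp"]
    return beats[["r_time", "rr", "hr", "sbp", "dbp", "map", "pp", "t_dbp"]]


def detect_resp_cycles(
    record: SignalRecord, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Breath segmentation from the respiration channel.

    The trace is zero-phase low-pass filtered, then troughs and peaks
    are found by prominence-based extremum detection and forced into
    strict trough/peak alternation (the more extreme of two same-type
    neighbours wins).  Incomplete breaths at the record edges are
    discarded.  Inspiration is trough -> peak, expiration peak -> trough.

    Returns one row per complete breath:
    ``t_trough, t_peak, t_trough_next, period, insp_dur, exp_dur, amp,
    amp_norm`` where ``amp`` is the trough-to-peak excursion and
    ``amp_norm`` its percentage of the largest breath.
    """
    config = config or AnalysisConfig()
    if "respiration" not in record:
        raise ValueError("record has no respiration channel")
    x = record["respiration"]
    fs = record.fs
    if len(x) < int(2 * fs):
        raise ValueError("respiration trace too short")
    nyq = fs / 2
    cutoff = min(config.resp_lowpass_hz, 0.9 * nyq)
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    sm = signal.sosfiltfilt(sos, x)

    prom = config.resp_min_prominence_frac * np.ptp(sm)
    if prom <= 0:
        raise ValueError("respiration trace is flat")
    pk_idx, _ = signal.find_peaks(sm, prominence=prom)
    tr_idx, _ = signal.find_peaks(-sm, prominence=prom)
    # record edges can hide trough prominence: accept boundary minima
    # between consecutive peaks as troughs
    tr_set = set(tr_idx.tolist())
    for a, b in zip(pk_idx[:-1], pk_idx[1:]):
        if not any(a < t < b for t in tr_set):
            tr_set.add(a + int(np.argmin(sm[a:b])))
    tr_idx = np.asarray(sorted(tr_set), dtype=int)

    events = sorted(
        [(i, "peak") for i in pk_idx] + [(i, "trough") for i in tr_idx]
    )
    cleaned: list[tuple[int, str]] = []
    for i, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev = cleaned[-1][0]
            better = (sm[i] > sm[prev]) if kind == "peak" else (sm[i] < sm[prev])
            if better:
                cleaned[-1] = (i, kind)
        else:
            cleaned.append((i, kind))
    # trim to trough ... trough
    while cleaned and cleaned[0][1] != "trough":
        cleaned.pop(0)
    while cleaned and cleaned[-1][1] != "trough":
        cleaned.pop()
    # smoothing shifts the extrema of asymmetric breaths; refine each
    # landmark to the raw-trace extremum in a window around the candidate
    half = max(int(round(0.25 * fs)), 1)
    refined: list[tuple[int, str]] = []
    for i, kind in cleaned:
        a, b = max(i - half, 0), min(i + half + 1, len(x))
        j = a + int(np.argmax(x[a:b]) if kind == "peak" else np.argmin(x[a:b]))
        refined.append((j, kind))
    troughs = [i for i, kind in refined if kind == "trough"]
    peaks = [i for i, kind in refined if kind == "peak"]
    if len(troughs) < 3 or len(peaks) < 2:
        raise ValueError("fewer than two complete breaths detected")

    t0 = record.start_time
    rows = []
    for k in range(len(peaks)):
        a, p, b = troughs[k], peaks[k], troughs[k + 1]
        amp = float(sm[p] - sm[a])
        rows.append(
            (
                t0 + a / fs,
                t0 + p / fs,
                t0 + b / fs,
                (b - a) / fs,
                (p - a) / fs,
                (b - p) / fs,
                amp,
            )
        )
    cycles = pd.DataFrame(
        rows,
        columns=[
            "t_trough", "t_peak", "t_trough_next",
            "period", "insp_dur", "exp_dur", "amp",
        ],
    )
    cycles["amp_norm"] = 100.0 * cycles["amp"] / cycles["amp"].max()
    return cycles


def respiratory_summary(
    cycles: pd.DataFrame, window_duration: float
) -> tuple[float, float]:
    """Breathing rate (breaths/min) and mean normalized amplitude (%).

    ``amp_norm`` is each breath's trough-to-peak amplitude as a
    percentage of the subject's largest breath, so the mean is a
    within-subject quantity with the largest breath pinned at 100%.
    """
    if len(cycles) == 0:
        raise ValueError("no breaths")
    rate = len(cycles) / (window_duration / 60.0)
    return rate, float(cycles["amp_norm"].mean())
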