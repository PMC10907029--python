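"""Respiratory-phase analysis of MSNA.

Each respiratory period (inspiration: trough -> peak; expiration:
peak -> trough) is divided into five equal intervals.  Two composite
phases are then assembled per breath:

* inspiration/postinspiration: inspiratory intervals 4-5 (60-100% of
  inspiration) plus expiratory intervals 1-3 (0-60% of expiration) of
  the same breath;
* mid-late expiration: expiratory intervals 4-5 (60-100% of expiration)
  plus inspiratory intervals 1-3 (0-60% of inspiration) of the
  *following* breath (configurable to the same breath's inspiration).

Phase instances aligned with neurogram artifacts are excluded whole.
MSNA burst incidence (bursts/100 HB), burst frequency (bursts/min) and
burst area per second are computed per phase, along with the absolute
and percent change from mid-late expiration to inspiration/
postinspiration (negative percent change = inspiratory inhibition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bursts import integrate_intervals
from .params import AnalysisConfig
from .records import NormalizedNeurogram

__all__ = [
    "build_interval_grid",
    "exclude_artifact_intervals",
    "assemble_phases",
    "phase_metrics",
    "modulation_change",
    "PHASE_INSP",
    "PHASE_EXP",
]

PHASE_INSP = "inspiration_postinspiration"
PHASE_EXP = "mid_late_expiration"


def build_interval_grid(cycles: pd.DataFrame) -> pd.DataFrame:
    """Five equal intervals per respiratory period.

    Returns one row per interval with columns ``breath`` (index into
    ``cycles``), ``period`` ('insp'/'exp'), ``interval`` (1-5),
    ``start``, ``end``, ``excluded``, ``reason``.  Intervals of a period
    are contiguous and tile it exactly.  Breaths with a zero-length
    period are excluded with a reason rather than dropped.
    """
    if len(cycles) < 2:
        raise ValueError("need at least two complete breaths")
    rows = []
    for k, cyc in cycles.reset_index(drop=True).iterrows():
        degenerate = cyc.insp_dur <= 0 or cyc.period - cyc.insp_dur <= 0
        reason = "zero-length period" if degenerate else ""
        for period, a, b in (
            ("insp", cyc.t_trough, cyc.t_peak),
            ("exp", cyc.t_peak, cyc.t_trough_next),
        ):
            edges = np.linspace(a, b, 6)
            for j in range(5):
                rows.append(
                    (k, period, j + 1, edges[j], edges[j + 1], degenerate, reason)
                )
    return pd.DataFrame(
        rows,
        columns=["breath", "period", "interval", "start", "end", "excluded", "reason"],
    )


def exclude_artifact_intervals(
    grid: pd.DataFrame,
    neurogram: NormalizedNeurogram,
    config: AnalysisConfig | None = None,
    mask: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Flag intervals aligned with neurogram artifacts.

    An interval is flagged when any of its samples exceeds
    ``artifact_pct`` (% of the tallest burst) or when it overlaps a
    user-supplied artifact mask.  Any phase instance containing a
    flagged interval is later removed whole from all phase metrics.
    """
    config = config or AnalysisConfig()
    grid = grid.copy()
    x = neurogram.samples
    fs = neurogram.fs
    t0 = neurogram.start_time
    n = len(x)
    exceed = np.concatenate([[0], np.cumsum(np.nan_to_num(x) > config.artifact_pct)])
    for i, row in grid.iterrows():
        a = int(np.clip(np.ceil((row.start - t0) * fs), 0, n))
        b = int(np.clip(np.ceil((row.end - t0) * fs), 0, n))
        hit = exceed[b] > exceed[a]
        if not hit and mask:
            hit = any(row.start < m1 and row.end > m0 for m0, m1 in mask)
        if hit and not row.excluded:
            grid.loc[i, "excluded"] = True
            grid.loc[i, "reason"] = "artifact"
    return grid


def assemble_phases(
    grid: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Composite phase instances from the interval grid.

    Returns one row per member interval with columns ``phase``,
    ``instance`` (anchor breath index), ``start``, ``end``,
    ``excluded``.  An instance is excluded as a whole when any member
    interval carries an exclusion flag; boundary instances missing their
    cross-breath partner intervals are dropped.
    """
    config = config or AnalysisConfig()
    following = config.boundary_policy == "following"
    by_key = {
        (row.breath, row.period, row.interval): row for row in grid.itertuples()
    }
    breaths = sorted(grid["breath"].unique())
    rows = []
    for k in breaths:
        # inspiration/postinspiration: insp 4-5 + exp 1-3 of breath k
        members = [(k, "insp", 4), (k, "insp", 5)] + [
            (k, "exp", j) for j in (1, 2, 3)
        ]
        _append_instance(rows, PHASE_INSP, k, members, by_key)
        # mid-late expiration: exp 4-5 of breath k + insp 1-3 of the
        # following breath (or of breath k under the 'preceding' policy)
        partner = k + 1 if following else k
        members = [(k, "exp", 4), (k, "exp", 5)] + [
            (partner, "insp", j) for j in (1, 2, 3)
        ]
        _append_instance(rows, PHASE_EXP, k, members, by_key)
    return pd.DataFrame(
        rows, columns=["phase", "instance", "start", "end", "excluded"]
    )


def _append_instance(rows, phase, anchor, members, by_key) -> None:
    found = [by_key.get(m) for m in members]
    if any(f is None for f in found):
        return  # boundary instance missing its cross-breath partner
    excluded = any(f.excluded for f in found)
    for f in found:
        rows.append((phase, anchor, f.start, f.end, excluded))


def phase_metrics(
    phases: pd.DataFrame,
    burst_times_shifted: np.ndarray,
    r_times: np.ndarray,
    neurogram: NormalizedNeurogram,
) -> pd.DataFrame:
    """Per-phase MSNA metrics.

    Heartbeats are assigned to phases by raw R-wave time and bursts by
    their latency-shifted peak time (both half-open on interval
    boundaries); the neurogram must carry the same shift as the burst
    times.  Burst incidence = 100 * bursts / heartbeats, burst
    frequency = bursts per minute of phase time, total area/s = summed
    interval area divided by phase duration, mean area/s = mean of the
    per-interval area rates.
    """
    burst_times_shifted = np.sort(np.asarray(burst_times_shifted, dtype=float))
    r_times = np.sort(np.asarray(r_times, dtype=float))
    out = []
    for phase, sub in phases.groupby("phase"):
        sub = sub[~sub["excluded"]]
        if len(sub) == 0:
            out.append((phase, 0, 0, 0.0, np.nan, np.nan, np.nan, np.nan))
            continue
        iv = sub[["start", "end"]].to_numpy()
        duration = float((iv[:, 1] - iv[:, 0]).sum())
        n_hb = _count_in(r_times, iv)
        n_bursts = _count_in(burst_times_shifted, iv)
        areas = integrate_intervals(neurogram, iv)
        widths = iv[:, 1] - iv[:, 0]
        ok = widths > 0
        total_rate = float(areas.sum() / duration) if duration > 0 else np.nan
        mean_rate = float(np.mean(areas[ok] / widths[ok])) if ok.any() else np.nan
        incidence = 100.0 * n_bursts / n_hb if n_hb > 0 else np.nan
        frequency = n_bursts / (duration / 60.0) if duration > 0 else np.nan
        out.append(
            (phase, n_bursts, n_hb, duration, incidence, frequency,
             total_rate, mean_rate)
        )
    return pd.DataFrame(
        out,
        columns=[
            "phase", "n_bursts", "n_heartbeats", "duration_s",
            "incidence", "frequency", "total_area_per_s", "mean_area_per_s",
        ],
    ).set_index("phase")


def _count_in(times: np.ndarray, intervals: np.ndarray) -> int:
    lo = np.searchsorted(times, intervals[:, 0], side="left")
    hi = np.searchsorted(times, intervals[:, 1], side="left")
    return int((hi - lo).sum())


def modulation_change(metrics: pd.DataFrame) -> pd.DataFrame:
    """Absolute and percent change from mid-late expiration to
    inspiration/postinspiration, per metric.

    Negative values mean inspiratory inhibition.  Percent change is NaN
    when the expiratory-phase value is zero or missing.
    """
    for phase in (PHASE_INSP, PHASE_EXP):
        if phase not in metrics.index:
            raise ValueError(f"missing phase {phase!r} in metrics")
    rows = []
    for metric in ("incidence", "frequency", "total_area_per_s", "mean_area_per_s"):
        e = metrics.loc[PHASE_EXP, metric]
        i = metrics.loc[PHASE_INSP, metric]
        absolute = i - e
        pct = 100.0 * absolute / e if e and np.isfinite(e) and e != 0 else np.nan
        rows.append((metric, e, i, absolute, pct))
    return pd.DataFrame(
        rows, columns=["metric", "exp_value", "insp_value", "abs_change", "pct_change"]
    ).set_index("metric")
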