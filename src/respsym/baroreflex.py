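"""Spontaneous sympathetic baroreflex sensitivity (sBRS).

For each cardiac cycle's diastolic pressure it is determined whether a
burst occurred in the *following* cycle (occurrence) and what the mean
of the normalized, latency-shifted neurogram was in a +/-0.4 s window
around the following cycle's R wave (area).  Occurrence probability (%)
and mean area (%) are then aggregated in 1-mmHg diastolic bins, and the
slope of the count-weighted linear regression of each on bin pressure
is the subject's sBRS (% bursts/mmHg, or %/mmHg for area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AnalysisConfig
from .records import NormalizedNeurogram

__all__ = ["build_baro_table", "bin_by_dbp", "sbrs_slope", "SBRSFit"]


def build_baro_table(
    beats: pd.DataFrame,
    bursts: pd.DataFrame,
    neurogram: NormalizedNeurogram,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-beat table pairing DBP with next-cycle burst occurrence/area.

    ``beats`` row i corresponds to cardiac cycle i (the cycle starting
    at ``r_time`` i); ``bursts.cycle_index`` must index the same cycles.
    The last beat, having no follower, contributes no row.  The
    neurogram must already be latency-shifted.
    """
    config = config or AnalysisConfig()
    n = len(beats)
    if n < 2:
        raise ValueError("need at least two beats")
    occ_cycles = set(bursts["cycle_index"].tolist()) if len(bursts) else set()
    half = config.baro_area_halfwidth_s
    x = neurogram.samples
    fs = neurogram.fs
    t0 = neurogram.start_time
    n_samp = len(x)

    rows = []
    r = beats["r_time"].to_numpy()
    dbp = beats["dbp"].to_numpy()
    for i in range(n - 1):
        r_next = r[i + 1]
        a = max(int(np.round((r_next - half - t0) * fs)), 0)
        b = min(int(np.round((r_next + half - t0) * fs)) + 1, n_samp)
        seg = x[a:b]
        seg = seg[~np.isnan(seg)]
        area = float(seg.mean()) if len(seg) else np.nan
        rows.append((dbp[i], int((i + 1) in occ_cycles), area))
    table = pd.DataFrame(rows, columns=["dbp", "occurred", "area"])
    if len(table) < 10:
        raise ValueError("fewer than 10 usable beats for sBRS")
    return table


def bin_by_dbp(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the baroreflex table into 1-mmHg diastolic bins.

    Bins are ``[k, k+1)`` mmHg for integer k; empty bins are omitted.
    ``p_occurrence`` is the percentage of cycles with a burst in the
    following cycle, ``mean_area`` the mean sampled neurogram area.
    """
    if len(table) == 0:
        raise ValueError("empty baroreflex table")
    k = np.floor(table["dbp"].to_numpy()).astype(int)
    grouped = table.assign(bin=k).groupby("bin")
    out = grouped.agg(
        n=("occurred", "size"),
        p_occurrence=("occurred", lambda v: 100.0 * np.mean(v)),
        mean_area=("area", "mean"),
    ).reset_index()
    out["dbp_bin_center"] = out["bin"] + 0.5
    return out[["dbp_bin_center", "n", "p_occurrence", "mean_area"]]


@dataclass
class SBRSFit:
    """Weighted-regression result for one sBRS variant."""

    slope: float
    intercept: float
    weighted_r: float
    n_bins: int
    range_mmhg: float
    ok: bool

    def as_dict(self, prefix: str) -> dict[str, float]:
        return {
            f"{prefix}_slope": self.slope,
            f"{prefix}_r": self.weighted_r,
            f"{prefix}_n_bins": self.n_bins,
            f"{prefix}_range_mmhg": self.range_mmhg,
        }


def sbrs_slope(
    bins: pd.DataFrame,
    value: str = "p_occurrence",
    config: AnalysisConfig | None = None,
) -> SBRSFit:
    """Count-weighted linear regression of a binned variable on DBP.

    Solves the weighted normal equations directly (weights = bin counts)
    and reports the slope and the weighted correlation coefficient.
    With too few bins or too narrow a pressure range the fit is flagged
    unavailable (``ok=False``, NaN slope) rather than raising, mirroring
    per-subject missingness in a cohort.
    """
    config = config or AnalysisConfig()
    sub = bins.dropna(subset=[value])
    x = sub["dbp_bin_center"].to_numpy(dtype=float)
    y = sub[value].to_numpy(dtype=float)
    w = sub["n"].to_numpy(dtype=float)
    n_bins = len(sub)
    # pressure range covered by the bins: three adjacent 1-mmHg bins span 3 mmHg
    rng = float(x.max() - x.min()) + 1.0 if n_bins else 0.0
    if n_bins < config.baro_min_bins or rng < config.baro_min_range_mmhg:
        return SBRSFit(np.nan, np.nan, np.nan, n_bins, rng, False)
    wsum = w.sum()
    xbar = float(np.sum(w * x) / wsum)
    ybar = float(np.sum(w * y) / wsum)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    sxy = float(np.sum(w * (x - xbar) * (y - ybar)))
    syy = float(np.sum(w * (y - ybar) ** 2))
    if sxx == 0:
        return SBRSFit(np.nan, np.nan, np.nan, n_bins, rng, False)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    return SBRSFit(slope, intercept, float(r), n_bins, rng, True)
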