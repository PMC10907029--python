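"""Per-breath hemodynamic oscillations and their coupling to MSNA.

Respiratory sinus arrhythmia (RSA) is the maximum absolute change in
beat-to-beat heart rate between adjacent end-expiration points (the
respiratory troughs); Traube-Hering (TH) wave amplitude is the maximum
absolute change in beat-wise mean arterial pressure between one
end-expiration point and the next end-expiration point plus 1 s.
Respiratory-modulated MSNA is the integral of the original, unshifted
integrated neurogram over 1.5x the duration of inspiration from the
start of inspiration (V*s on the raw voltage scale).  Per-subject
correlations couple that measure to TH amplitude of the same breath and
of the adjacent breaths (lags -1, 0, +1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .params import AnalysisConfig

__all__ = [
    "rsa_per_breath",
    "th_per_breath",
    "resp_modulated_msna",
    "lagged_coupling",
    "coupling_analysis",
]

TH_EXTENSION_S = 1.0  # the TH window extends one second past the next trough


def rsa_per_breath(
    beats: pd.DataFrame, cycles: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-breath RSA (beats/min) and its mean over the window.

    Beats belong to breath k when their R time lies in
    ``[t_trough_k, t_trough_{k+1})``.  Breaths containing fewer than
    two beats have undefined RSA (NaN) and are excluded from the mean.
    """
    return _range_per_breath(beats, cycles, "hr", extension=0.0)


def th_per_breath(
    beats: pd.DataFrame, cycles: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-breath Traube-Hering amplitude (mmHg) and its mean.

    The membership window runs to the next end-expiration point plus
    one second, unlike RSA.
    """
    return _range_per_breath(beats, cycles, "map", extension=TH_EXTENSION_S)


def _range_per_breath(
    beats: pd.DataFrame, cycles: pd.DataFrame, column: str, extension: float
) -> tuple[pd.Series, float]:
    r = beats["r_time"].to_numpy()
    v = beats[column].to_numpy()
    out = np.full(len(cycles), np.nan)
    for k, cyc in cycles.reset_index(drop=True).iterrows():
        sel = (r >= cyc.t_trough) & (r < cyc.t_trough_next + extension)
        if sel.sum() >= 2:
            out[k] = float(v[sel].max() - v[sel].min())
    series = pd.Series(out, name=column)
    mean = float(series.dropna().mean()) if series.notna().any() else np.nan
    return series, mean


def resp_modulated_msna(
    msna: np.ndarray,
    fs: float,
    cycles: pd.DataFrame,
    start_time: float = 0.0,
    config: AnalysisConfig | None = None,
) -> pd.Series:
    """Per-breath MSNA: integral of the raw unshifted neurogram (V*s)
    over ``[t_trough_k, t_trough_k + 1.5 * insp_dur_k)``.

    Breaths whose integration window runs past the record end are
    dropped (NaN).
    """
    x = np.asarray(msna, dtype=float)
    n = len(x)
    cum = np.concatenate([[0.0], np.cumsum(x)]) / fs
    out = np.full(len(cycles), np.nan)
    for k, cyc in cycles.reset_index(drop=True).iterrows():
        t_end = cyc.t_trough + 1.5 * cyc.insp_dur
        a = int(np.ceil((cyc.t_trough - start_time) * fs))
        b = int(np.ceil((t_end - start_time) * fs))
        if a < 0 or b > n:
            continue
        out[k] = cum[b] - cum[a]
    return pd.Series(out, name="msna_resp")


def lagged_coupling(
    msna_resp: pd.Series,
    th: pd.Series,
    lag: int,
    config: AnalysisConfig | None = None,
) -> dict[str, float]:
    """Correlation of per-breath MSNA with TH amplitude at a breath lag.

    Pairs ``(msna_k, th_{k+lag})``; lag +1 couples a breath's MSNA to
    the following breath's TH wave.  Returns the coefficient, two-sided
    p-value, number of paired breaths and a ``significant_positive``
    flag (p < 0.05 and coefficient > 0).  A constant series yields an
    undefined (NaN) coefficient.
    """
    config = config or AnalysisConfig()
    x = np.asarray(msna_resp, dtype=float)
    y = np.asarray(th, dtype=float)
    if lag > 0:
        x, y = x[:-lag], y[lag:]
    elif lag < 0:
        x, y = x[-lag:], y[:lag]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired breaths")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"lag": lag, "r": np.nan, "p": np.nan, "n": n,
                "significant_positive": False}
    if config.coupling_estimator == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        r, p = stats.pearsonr(x, y)
    return {
        "lag": lag,
        "r": float(r),
        "p": float(p),
        "n": n,
        "significant_positive": bool(p < 0.05 and r > 0),
    }


def coupling_analysis(
    msna_resp: pd.Series, th: pd.Series, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Coupling at lags -1, 0, +1 as one table."""
    rows = [lagged_coupling(msna_resp, th, lag, config) for lag in (-1, 0, 1)]
    return pd.DataFrame(rows).set_index("lag")
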