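"""Per-subject end-to-end analysis and cohort aggregation.

``analyze_subject`` composes every stage — landmark extraction, burst
detection, latency shift, respiratory-phase metrics, sBRS, per-breath
RSA/TH/MSNA coupling — into one flat result row.  Stage failures are
recorded per subject (the affected fields stay NaN) so a cohort run
never dies on a single bad record.  ``analyze_cohort`` maps the
per-subject analysis over a synthetic or loaded cohort and returns the
tidy cohort table the statistics layer consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import baroreflex, bursts, coupling, landmarks, modulation
from .params import AnalysisConfig
from .records import SignalRecord
from .simulate import CohortSubject

__all__ = ["analyze_subject", "analyze_cohort", "SUBJECT_RESULT_COLUMNS"]

SUBJECT_RESULT_COLUMNS = [
    "subject_id", "group",
    # resting hemodynamics
    "hr_mean", "sbp_mean", "dbp_mean", "map_mean", "pp_mean",
    "breath_rate", "resp_amp_norm_mean", "resp_period_mean",
    # resting MSNA
    "msna_incidence", "msna_freq", "msna_total_area_per_s", "burst_latency",
    # sBRS
    "sbrs_occ_slope", "sbrs_occ_r", "sbrs_occ_n_bins", "sbrs_occ_range_mmhg",
    "sbrs_area_slope", "sbrs_area_r", "sbrs_area_n_bins", "sbrs_area_range_mmhg",
    # per-phase MSNA and its change
    "exp_incidence", "insp_incidence",
    "exp_frequency", "insp_frequency",
    "exp_total_area", "insp_total_area",
    "exp_mean_area", "insp_mean_area",
    "dincidence_abs", "dincidence_pct",
    "dfrequency_abs", "dfrequency_pct",
    "dtotal_area_abs", "dtotal_area_pct",
    "dmean_area_abs", "dmean_area_pct",
    # RSA / TH / coupling
    "rsa_mean", "th_mean", "msna_resp_mean",
    "coupling_r_lag0", "coupling_p_lag0", "coupling_sig_lag0",
    "coupling_r_lagp1", "coupling_p_lagp1", "coupling_sig_lagp1",
    "coupling_r_lagm1", "coupling_p_lagm1", "coupling_sig_lagm1",
    "errors",
]

_CHANGE_PREFIX = {
    "incidence": "dincidence",
    "frequency": "dfrequency",
    "total_area_per_s": "dtotal_area",
    "mean_area_per_s": "dmean_area",
}


def analyze_subject(
    record: SignalRecord,
    config: AnalysisConfig | None = None,
    subject_id: str = "subject",
    group: str = "",
    audit: dict | None = None,
) -> dict:
    """Run the full per-subject analysis; returns one flat result dict.

    Deterministic given the record and configuration.  When ``audit`` is
    a dict, every stage's intermediate table is stored in it under the
    stage name.
    """
    config = config or AnalysisConfig()
    out: dict = {c: np.nan for c in SUBJECT_RESULT_COLUMNS}
    out.update(subject_id=subject_id, group=group, errors="")
    errors: list[str] = []

    def note(stage: str, exc: Exception) -> None:
        errors.append(f"{stage}: {exc}")

    window = (record.start_time, record.end_time)
    duration = record.duration

    r_times = beats = cycles = None
    try:
        r_times = landmarks.detect_r_waves(record, config)
    except Exception as exc:
        note("r_waves", exc)
    if r_times is not None:
        try:
            beats = landmarks.beat_hemodynamics(record, r_times, config)
            out["hr_mean"] = beats["hr"].mean()
            out["sbp_mean"] = beats["sbp"].mean()
            out["dbp_mean"] = beats["dbp"].mean()
            out["map_mean"] = beats["map"].mean()
            out["pp_mean"] = beats["pp"].mean()
        except Exception as exc:
            note("hemodynamics", exc)
    try:
        cycles = landmarks.detect_resp_cycles(record, config)
        rate, amp_norm = landmarks.respiratory_summary(cycles, duration)
        out["breath_rate"] = rate
        out["resp_amp_norm_mean"] = amp_norm
        out["resp_period_mean"] = cycles["period"].mean()
    except Exception as exc:
        note("respiration", exc)

    ng = burst_df = ng_shift = None
    shifted_times = np.empty(0)
    if r_times is not None:
        try:
            ng = bursts.normalize_neurogram(
                record["msna"], record.fs, record.start_time, config
            )
            burst_df = bursts.detect_bursts(ng, r_times, config)
            latency = bursts.mean_burst_latency(burst_df)
            out["burst_latency"] = latency
            ng_shift = bursts.shift_neurogram(ng, latency)
            shifted_times = bursts.shifted_peak_times(burst_df, ng_shift.shift_applied)
        except Exception as exc:
            note("bursts", exc)

    grid = phases = None
    if cycles is not None and ng_shift is not None:
        try:
            grid = modulation.build_interval_grid(cycles)
            grid = modulation.exclude_artifact_intervals(grid, ng_shift, config)
            phases = modulation.assemble_phases(grid, config)
        except Exception as exc:
            note("phase_grid", exc)

    if burst_df is not None and ng_shift is not None and r_times is not None:
        try:
            grid_iv = (
                grid.loc[~grid["excluded"], ["start", "end"]].to_numpy()
                if grid is not None
                else None
            )
            resting = bursts.resting_metrics(
                burst_df, r_times, ng_shift, window, grid_iv
            )
            out["msna_incidence"] = resting["bursts_per_100hb"]
            out["msna_freq"] = resting["bursts_per_min"]
            out["msna_total_area_per_s"] = resting["total_area_per_s"]
        except Exception as exc:
            note("resting_msna", exc)

    if phases is not None and burst_df is not None:
        try:
            pm = modulation.phase_metrics(phases, shifted_times, r_times, ng_shift)
            for phase, short in (
                (modulation.PHASE_EXP, "exp"),
                (modulation.PHASE_INSP, "insp"),
            ):
                out[f"{short}_incidence"] = pm.loc[phase, "incidence"]
                out[f"{short}_frequency"] = pm.loc[phase, "frequency"]
                out[f"{short}_total_area"] = pm.loc[phase, "total_area_per_s"]
                out[f"{short}_mean_area"] = pm.loc[phase, "mean_area_per_s"]
            mc = modulation.modulation_change(pm)
            for metric, prefix in _CHANGE_PREFIX.items():
                out[f"{prefix}_abs"] = mc.loc[metric, "abs_change"]
                out[f"{prefix}_pct"] = mc.loc[metric, "pct_change"]
            if audit is not None:
                audit["phase_metrics"] = pm
                audit["modulation_change"] = mc
        except Exception as exc:
            note("phase_metrics", exc)

    if beats is not None and burst_df is not None and ng_shift is not None:
        try:
            table = baroreflex.build_baro_table(beats, burst_df, ng_shift, config)
            bins = baroreflex.bin_by_dbp(table)
            occ = baroreflex.sbrs_slope(bins, "p_occurrence", config)
            area = baroreflex.sbrs_slope(bins, "mean_area", config)
            out.update(occ.as_dict("sbrs_occ"))
            out.update(area.as_dict("sbrs_area"))
            if audit is not None:
                audit["baro_bins"] = bins
        except Exception as exc:
            note("baroreflex", exc)

    if beats is not None and cycles is not None:
        try:
            rsa, rsa_mean = coupling.rsa_per_breath(beats, cycles)
            th, th_mean = coupling.th_per_breath(beats, cycles)
            out["rsa_mean"] = rsa_mean
            out["th_mean"] = th_mean
            msna_resp = coupling.resp_modulated_msna(
                record["msna"], record.fs, cycles, record.start_time, config
            )
            out["msna_resp_mean"] = float(msna_resp.dropna().mean())
            cc = coupling.coupling_analysis(msna_resp, th, config)
            for lag, tag in ((0, "lag0"), (1, "lagp1"), (-1, "lagm1")):
                out[f"coupling_r_{tag}"] = cc.loc[lag, "r"]
                out[f"coupling_p_{tag}"] = cc.loc[lag, "p"]
                out[f"coupling_sig_{tag}"] = bool(cc.loc[lag, "significant_positive"])
            if audit is not None:
                audit["breath_table"] = pd.DataFrame(
                    {"rsa": rsa, "th": th, "msna_resp": msna_resp}
                )
        except Exception as exc:
            note("coupling", exc)

    if audit is not None:
        audit.update(
            r_times=r_times, beats=beats, cycles=cycles,
            bursts=burst_df, grid=grid, phases=phases,
        )
    out["errors"] = "; ".join(errors)
    return out


def analyze_cohort(
    subjects: list[CohortSubject], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-subject analysis over a cohort; one row per subject.

    Failed stages are flagged in the ``errors`` column, never dropped
    silently.
    """
    config = config or AnalysisConfig()
    rows = [
        analyze_subject(s.record, config, subject_id=s.subject_id, group=s.group)
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=SUBJECT_RESULT_COLUMNS)
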