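"""Synthetic synchronized ECG / pressure / respiration / MSNA recordings.

The generator produces 5-10 min resting recordings with the statistical
structure the analysis pipeline assumes, together with exact ground
truth, so every downstream estimator can be validated by parameter
recovery:

* quasi-periodic respiration built from raised-cosine breaths with
  breath-to-breath period and amplitude variability;
* R-wave times integrating an instantaneous heart rate modulated by
  respiratory phase (respiratory sinus arrhythmia);
* per-beat arterial pressure waveforms whose beat-wise mean pressure is
  additionally modulated at the respiratory frequency (Traube-Hering
  waves), with a configurable lag;
* pulse-synchronous MSNA bursts at a fixed neural latency after the
  R wave, whose per-cycle occurrence probability is gated by respiratory
  phase and by the preceding cycle's *non-respiratory* diastolic
  pressure deviation (baroreflex), on top of band-limited neurogram
  noise.

Arterial pressure carries three sources of beat-to-beat variation: the
respiratory (Traube-Hering) modulation, a slow Mayer-band oscillation,
and iid per-beat jitter.  Only the latter two — the non-respiratory
deviations — enter the baroreflex gating of burst probability: the
within-breath baroreflex action of the Traube-Hering wave itself is
already expressed by the two phase-gated probabilities, exactly as the
respiratory-phase analysis measures it.  This keeps the phase contrast
``burst_prob_insp``/``burst_prob_exp`` and the baroreflex slope
independently recoverable.

All respiratory modulation uses the waveform ``m(t) = -cos(2*pi*phase)``
of phase-within-breath, so heart rate and mean pressure peak near
mid-breath and reach their minima at the end-expiratory troughs.

Conventions that mirror the analysis:

* The phase window gating burst probability is the composite
  inspiration/postinspiration window (last 40% of inspiration plus
  first 60% of expiration) versus its complement (mid-late expiration),
  evaluated at the R-wave time of the cycle.
* Baroreflex gating acts on the *previous* cycle's diastolic pressure,
  matching the convention that a diastolic pressure predicts burst
  occurrence in the following cardiac cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .params import SubjectParams
from .records import GroundTruth, SignalRecord

__all__ = [
    "generate_respiration",
    "generate_cardiac",
    "generate_msna",
    "generate_subject",
    "generate_cohort",
    "GroupSpec",
    "default_cohort_spec",
    "CohortSubject",
    "respiratory_phase",
    "phase_modulation",
    "in_insp_post_window",
]


# ---------------------------------------------------------------------------
# respiratory phase helpers (shared by the cardiac and MSNA generators)

def respiratory_phase(t, landmarks: pd.DataFrame) -> np.ndarray:
    """Phase within breath (0 at trough, insp_fraction at peak, 1 at next trough).

    Times before the first trough or after the last are extrapolated with
    the nearest breath's period, which keeps the phase continuous.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    troughs = landmarks["t_trough"].to_numpy()
    periods = landmarks["period"].to_numpy()
    k = np.clip(np.searchsorted(troughs, t, side="right") - 1, 0, len(troughs) - 1)
    return (t - troughs[k]) / periods[k]


def phase_modulation(t, landmarks: pd.DataFrame) -> np.ndarray:
    """m(t) = -cos(2*pi*phase): -1 at end-expiratory troughs, +1 mid-breath."""
    return -np.cos(2 * np.pi * respiratory_phase(t, landmarks))


def in_insp_post_window(t, landmarks: pd.DataFrame) -> np.ndarray:
    """True where t lies in the inspiration/postinspiration composite window.

    The window spans the last 40% of inspiration and the first 60% of
    expiration of each breath; its complement is mid-late expiration
    (last 40% of expiration plus first 60% of the next inspiration).
    Interval membership is half-open, [start, end).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    troughs = landmarks["t_trough"].to_numpy()
    peaks = landmarks["t_peak"].to_numpy()
    periods = landmarks["period"].to_numpy()
    insp_dur = peaks - troughs
    exp_dur = periods - insp_dur
    k = np.clip(np.searchsorted(troughs, t, side="right") - 1, 0, len(troughs) - 1)
    dt = t - troughs[k]
    in_insp = dt < insp_dur[k]
    frac_insp = dt / insp_dur[k]
    frac_exp = (dt - insp_dur[k]) / exp_dur[k]
    return np.where(in_insp, frac_insp >= 0.6, frac_exp < 0.6)


# ---------------------------------------------------------------------------
# respiration

def generate_respiration(
    params: SubjectParams, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Raised-cosine respiratory trace with exact landmark times.

    Each breath rises monotonically trough -> peak over ``insp_fraction``
    of its period and falls monotonically peak -> trough over the rest;
    raised-cosine segments make both landmarks smooth stationary points.
    Breath periods and amplitudes are drawn independently with the
    configured means and coefficients of variation.

    Returns the sampled trace and a landmark table with one row per
    breath: ``t_trough, t_peak, t_trough_next, period, insp_dur, amp``.
    The last breath may extend past the end of the record.
    """
    params.validate()
    if params.duration_s < params.breath_period_mean:
        raise ValueError(
            "record shorter than one breath "
            f"({params.duration_s} s < {params.breath_period_mean} s)"
        )
    n = int(round(params.duration_s * params.fs))

    mean_t = params.breath_period_mean
    n_est = int(np.ceil(params.duration_s / mean_t * 1.6)) + 4
    periods = rng.normal(mean_t, params.breath_period_cv * mean_t, size=n_est)
    periods = np.clip(periods, 0.4 * mean_t, 2.5 * mean_t)
    amps = rng.normal(1.0, params.breath_amp_cv, size=n_est)
    amps = np.clip(amps, 0.15, None)

    troughs = np.concatenate([[0.0], np.cumsum(periods)])
    n_breaths = int(np.searchsorted(troughs[1:], params.duration_s, side="left")) + 1
    n_breaths = min(n_breaths, n_est)
    periods = periods[:n_breaths]
    amps = amps[:n_breaths]
    troughs = troughs[: n_breaths + 1]
    insp_dur = params.insp_fraction * periods
    peaks = troughs[:-1] + insp_dur

    resp = np.zeros(n)
    t = np.arange(n) / params.fs
    for k in range(n_breaths):
        i0 = int(np.ceil(troughs[k] * params.fs))
        i1 = min(int(np.ceil(peaks[k] * params.fs)), n)
        i2 = min(int(np.ceil(troughs[k + 1] * params.fs)), n)
        if i1 > i0:
            u = (t[i0:i1] - troughs[k]) / insp_dur[k]
            resp[i0:i1] = amps[k] * 0.5 * (1 - np.cos(np.pi * u))
        if i2 > i1:
            v = (t[i1:i2] - peaks[k]) / (periods[k] - insp_dur[k])
            resp[i1:i2] = amps[k] * 0.5 * (1 + np.cos(np.pi * v))

    landmarks = pd.DataFrame(
        {
            "t_trough": troughs[:-1],
            "t_peak": peaks,
            "t_trough_next": troughs[1:],
            "period": periods,
            "insp_dur": insp_dur,
            "amp": amps,
        }
    )
    return resp, landmarks


# ---------------------------------------------------------------------------
# cardiac: R waves and arterial pressure

def generate_cardiac(
    params: SubjectParams,
    landmarks: pd.DataFrame,
    rng: np.random.Generator,
    th_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """R-wave times, ECG impulse channel, pressure channel, per-beat truth.

    Instantaneous heart rate is ``hr_base + (rsa_amp/2) * m(t)``; R times
    advance by forward integration of this rate (each RR interval is set
    from the rate at the beat onset, so the recovered beat-to-beat heart
    rate point-samples the modulation waveform).

    Each cardiac cycle's pressure waveform is a raised-cosine upstroke
    (rise time 0.3 RR) from the cycle's diastolic pressure to its
    systolic pressure followed by a linear decay to the next cycle's
    diastolic pressure.  Beat-wise SBP and DBP are co-modulated by the
    respiratory term ``(th_amp/2) * m(t - th_lag_s)`` (the Traube-Hering
    wave, optionally scaled per breath by ``th_scale``), a slow
    sinusoidal Mayer-band wave (``bp_lf_amp``, random phase) and iid
    per-beat jitter (``dbp_jitter_sd``); a small per-beat offset makes
    the waveform's mean over the cycle equal the target beat-wise MAP
    exactly.

    Returns ``(r_times, ecg, pressure, beats)`` where ``beats`` has one
    row per complete cycle: ``r_time, rr, dbp, sbp, map, dbp_gate``
    (``dbp_gate`` is the non-respiratory part of the beat's diastolic
    pressure, the quantity that gates burst probability).
    """
    params.validate()
    n = int(round(params.duration_s * params.fs))
    fs = params.fs

    # --- R times: forward integration of the instantaneous rate
    r_list = [0.3]
    while True:
        hr = params.hr_base + 0.5 * params.rsa_amp * float(
            phase_modulation(r_list[-1], landmarks)[0]
        )
        nxt = r_list[-1] + 60.0 / hr
        if nxt >= params.duration_s - 1.0 / fs:
            break
        r_list.append(nxt)
    r_times = np.asarray(r_list)
    if len(r_times) < 3:
        raise ValueError("record too short for cardiac generation")

    ecg = np.zeros(n)
    ecg[np.round(r_times * fs).astype(int)] = 1.0

    # --- per-beat pressure targets
    n_beats = len(r_times) - 1
    t_mod = r_times - params.th_lag_s
    delta_resp = 0.5 * params.th_amp * phase_modulation(t_mod, landmarks)
    if th_scale is not None:
        troughs = landmarks["t_trough"].to_numpy()
        k = np.clip(
            np.searchsorted(troughs, t_mod, side="right") - 1, 0, len(th_scale) - 1
        )
        delta_resp = delta_resp * np.asarray(th_scale)[k]
    lf_phase = rng.uniform(0.0, 2 * np.pi)
    slow = 0.5 * params.bp_lf_amp * np.sin(
        2 * np.pi * r_times / params.bp_lf_period_s + lf_phase
    )
    jitter = rng.normal(0.0, params.dbp_jitter_sd, size=len(r_times)) \
        if params.dbp_jitter_sd > 0 else np.zeros(len(r_times))
    gate = slow + jitter                   # non-respiratory deviation
    delta = delta_resp + gate
    dbp = params.dbp_base + delta          # per-cycle diastolic targets
    sbp = params.sbp_base + delta

    pressure = np.full(n, params.dbp_base)
    idx = np.round(r_times * fs).astype(int)
    beat_rows = []
    for i in range(n_beats):
        i0, i1 = idx[i], idx[i + 1]
        seg = _beat_waveform(i1 - i0, fs, dbp[i], sbp[i], dbp[i + 1])
        base = _beat_waveform(
            i1 - i0, fs, params.dbp_base, params.sbp_base, params.dbp_base
        )
        target_map = base.mean() + delta[i]
        c = target_map - seg.mean()        # sub-mmHg beat-mean correction
        pressure[i0:i1] = seg + c
        rr = r_times[i + 1] - r_times[i]
        beat_rows.append(
            (r_times[i], rr, dbp[i] + c, sbp[i] + c, target_map, gate[i])
        )
    pressure[: idx[0]] = pressure[idx[0]]
    pressure[idx[-1] :] = pressure[idx[-1] - 1]

    beats = pd.DataFrame(
        beat_rows, columns=["r_time", "rr", "dbp", "sbp", "map", "dbp_gate"]
    )
    return r_times, ecg, pressure, beats


def _beat_waveform(
    n_samp: int, fs: float, dbp: float, sbp: float, dbp_next: float
) -> np.ndarray:
    """One cycle: raised-cosine upstroke (0.3 of the cycle), linear decay."""
    n_rise = max(int(round(0.3 * n_samp)), 1)
    n_fall = n_samp - n_rise
    u = np.arange(n_rise) / n_rise
    rise = dbp + (sbp - dbp) * 0.5 * (1 - np.cos(np.pi * u))
    if n_fall > 0:
        w = np.arange(1, n_fall + 1) / n_fall
        fall = sbp + (dbp_next - sbp) * w
        return np.concatenate([rise, fall])
    return rise


# ---------------------------------------------------------------------------
# MSNA

def generate_msna(
    params: SubjectParams,
    r_times: np.ndarray,
    landmarks: pd.DataFrame,
    per_beat_dbp: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Integrated-MSNA channel with phase- and pressure-gated bursts.

    For each complete cardiac cycle, a burst occurs with probability

        p = clip(p_phase + (baro_slope/100) * (DBP_prev - mean DBP), 0, 1)

    where ``p_phase`` is ``burst_prob_insp`` when the cycle's R wave lies
    in the inspiration/postinspiration window, else ``burst_prob_exp``,
    and ``DBP_prev`` is the previous cycle's gating diastolic pressure
    (a diastolic pressure gates the burst of the *following* cycle).
    ``per_beat_dbp`` should be the non-respiratory diastolic series
    (``beats.dbp_gate``): the within-breath baroreflex action of the
    Traube-Hering wave is already expressed by the phase probabilities.  An
    occurring burst is a raised-cosine pulse of width ``burst_width_s``
    centered ``burst_latency_s`` after the R wave with a gamma-distributed
    amplitude; band-limited Gaussian noise (SD ``noise_sd`` after
    low-pass shaping) and a constant baseline complete the channel.

    Returns the channel and a burst-truth table
    (``cycle_index, r_time, peak_time, amplitude``).
    """
    params.validate()
    if len(r_times) == 0:
        raise ValueError("r_times must be nonempty")
    n = int(round(params.duration_s * params.fs))
    fs = params.fs

    n_cycles = len(r_times) - 1
    per_beat_dbp = np.asarray(per_beat_dbp, dtype=float)
    dbp_dev = np.zeros(n_cycles)
    if len(per_beat_dbp):
        dev = per_beat_dbp - per_beat_dbp.mean()
        # cycle i is gated by the previous cycle's diastolic pressure
        dbp_dev[1 : min(n_cycles, len(dev) + 1)] = dev[: n_cycles - 1]

    insp_win = in_insp_post_window(r_times[:n_cycles], landmarks)
    p_phase = np.where(insp_win, params.burst_prob_insp, params.burst_prob_exp)
    p = np.clip(p_phase + params.baro_slope / 100.0 * dbp_dev, 0.0, 1.0)
    occurred = rng.random(n_cycles) < p

    if params.burst_amp_cv > 0:
        shape = 1.0 / params.burst_amp_cv**2
        amps = rng.gamma(shape, params.burst_amp_mean / shape, size=n_cycles)
    else:
        amps = np.full(n_cycles, params.burst_amp_mean)

    msna = np.full(n, params.msna_baseline)
    half_w = 0.5 * params.burst_width_s
    rows = []
    for i in np.flatnonzero(occurred):
        peak_t = r_times[i] + params.burst_latency_s
        if peak_t + half_w >= params.duration_s:
            continue  # burst would be clipped by the record edge
        i0 = max(int(np.ceil((peak_t - half_w) * fs)), 0)
        i1 = min(int(np.floor((peak_t + half_w) * fs)) + 1, n)
        tt = np.arange(i0, i1) / fs
        msna[i0:i1] += amps[i] * 0.5 * (
            1 + np.cos(2 * np.pi * (tt - peak_t) / params.burst_width_s)
        )
        rows.append((i, r_times[i], peak_t, amps[i]))

    if params.noise_sd > 0:
        # residual noise of a rectified, leaky-integrated neurogram:
        # band-limited but broader than the burst envelope bandwidth
        white = rng.standard_normal(n)
        cutoff = min(8.0, 0.4 * fs)
        sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
        smooth = signal.sosfiltfilt(sos, white)
        msna += params.noise_sd * smooth / smooth.std()

    bursts = pd.DataFrame(
        rows, columns=["cycle_index", "r_time", "peak_time", "amplitude"]
    )
    return msna, bursts


# ---------------------------------------------------------------------------
# composition

def generate_subject(params: SubjectParams) -> tuple[SignalRecord, GroundTruth]:
    """Generate one synthetic subject from a single top-level seed.

    The seed spawns three independent substreams (respiration, cardiac,
    MSNA) so that, e.g., changing the MSNA noise level cannot perturb
    the respiratory realization.

    With ``th_msna_coupling > 0`` each breath's Traube-Hering amplitude
    is additionally scaled by that breath's total burst mass (sum of
    true burst amplitudes, normalized to the cohort-mean mass and
    multiplied by the gain), coupling the pressure oscillation to the
    sympathetic outflow that physiologically drives it.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(3)
    rng_resp, rng_card, rng_msna = (np.random.default_rng(s) for s in children)

    resp, landmarks = generate_respiration(params, rng_resp)
    r_times, ecg, pressure, beats = generate_cardiac(params, landmarks, rng_card)
    msna, bursts = generate_msna(
        params, r_times, landmarks, beats["dbp_gate"].to_numpy(), rng_msna
    )

    if params.th_msna_coupling > 0 and len(bursts):
        # per-breath burst mass over the window the coupling analysis
        # samples: bursts peaking within 1.5x the inspiratory duration
        # from the start of inspiration
        troughs = landmarks["t_trough"].to_numpy()
        win_len = 1.5 * landmarks["insp_dur"].to_numpy()
        peaks_t = bursts["peak_time"].to_numpy()
        k = np.clip(
            np.searchsorted(troughs, peaks_t, side="right") - 1,
            0, len(landmarks) - 1,
        )
        in_win = peaks_t - troughs[k] < win_len[k]
        mass = np.zeros(len(landmarks))
        np.add.at(mass, k[in_win], bursts["amplitude"].to_numpy()[in_win])
        scale = params.th_msna_coupling * mass / mass.mean() if mass.mean() > 0 \
            else np.ones_like(mass)
        # regenerate pressure with the same cardiac substream so the slow
        # wave and jitter realizations are identical
        r_times, ecg, pressure, beats = generate_cardiac(
            params, landmarks, np.random.default_rng(children[1]), th_scale=scale
        )

    record = SignalRecord(
        fs=params.fs,
        channels={"ecg": ecg, "pressure": pressure, "respiration": resp, "msna": msna},
    )
    truth = GroundTruth(
        params=params,
        r_times=r_times,
        beats=beats,
        resp_landmarks=landmarks,
        bursts=bursts,
    )
    return record, truth


@dataclass
class GroupSpec:
    """One cohort group: label, size, and the subject-parameter distribution.

    Per-subject parameters are drawn as ``base`` plus independent normal
    deviates with the standard deviations in ``between_sd`` (absolute
    units, keyed by ``SubjectParams`` field name).  Probabilities are
    clipped to [0.02, 0.98] after drawing.
    """

    label: str
    n: int
    base: SubjectParams
    between_sd: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    record: SignalRecord
    truth: GroundTruth


_DEFAULT_BETWEEN_SD = {
    "hr_base": 5.0,
    "sbp_base": 8.0,
    "dbp_base": 6.0,
    "th_amp": 2.0,
    "rsa_amp": 1.0,
    "breath_period_mean": 0.4,
    "burst_prob_exp": 0.06,
    "burst_prob_insp": 0.06,
    "baro_slope": 1.0,
    "burst_latency_s": 0.05,
}

_PROB_FIELDS = ("burst_prob_exp", "burst_prob_insp")


def default_cohort_spec(
    duration_s: float = 300.0, fs: float = 250.0
) -> list[GroupSpec]:
    """Three-group resting cohort emulating young female, young male and
    postmenopausal female physiology: the postmenopausal group has higher
    resting burst probability, a much smaller inspiratory-expiratory
    contrast (~1/4 of the young groups'), smaller Traube-Hering waves and
    respiratory sinus arrhythmia, and a shallower baroreflex slope.
    """
    young_f = SubjectParams(
        duration_s=duration_s, fs=fs, hr_base=62, rsa_amp=6,
        breath_period_mean=4.1, sbp_base=136, dbp_base=78, th_amp=12,
        burst_prob_exp=0.65, burst_prob_insp=0.40, baro_slope=-5.3,
    )
    young_m = SubjectParams(
        duration_s=duration_s, fs=fs, hr_base=58, rsa_amp=8,
        breath_period_mean=4.5, sbp_base=125, dbp_base=69, th_amp=13,
        burst_prob_exp=0.62, burst_prob_insp=0.38, baro_slope=-7.1,
    )
    postmeno_f = SubjectParams(
        duration_s=duration_s, fs=fs, hr_base=64, rsa_amp=3,
        breath_period_mean=4.6, sbp_base=146, dbp_base=72, th_amp=6,
        burst_prob_exp=0.82, burst_prob_insp=0.74, baro_slope=-3.4,
    )
    return [
        GroupSpec("young_female", 12, young_f, dict(_DEFAULT_BETWEEN_SD)),
        GroupSpec("young_male", 12, young_m, dict(_DEFAULT_BETWEEN_SD)),
        GroupSpec("postmenopausal_female", 13, postmeno_f, dict(_DEFAULT_BETWEEN_SD)),
    ]


def draw_subject_params(
    spec: GroupSpec, rng: np.random.Generator, seed: int
) -> SubjectParams:
    """Draw one subject's parameters from a group distribution."""
    kwargs: dict[str, float] = {}
    for name, sd in spec.between_sd.items():
        val = getattr(spec.base, name) + rng.normal(0.0, sd)
        if name in _PROB_FIELDS:
            val = float(np.clip(val, 0.02, 0.98))
        elif name in ("hr_base", "breath_period_mean", "burst_latency_s"):
            val = max(val, 0.5 * getattr(spec.base, name))
        elif name in ("rsa_amp", "th_amp", "bp_lf_amp", "dbp_jitter_sd",
                      "noise_sd", "burst_amp_cv"):
            val = max(val, 0.0)
        kwargs[name] = val
    if "sbp_base" in kwargs or "dbp_base" in kwargs:
        sbp = kwargs.get("sbp_base", spec.base.sbp_base)
        dbp = kwargs.get("dbp_base", spec.base.dbp_base)
        if sbp - dbp < 20:  # keep a physiological pulse pressure
            kwargs["sbp_base"] = dbp + 20
    return spec.base.replace(seed=seed, **kwargs)


def generate_cohort(
    group_specs: list[GroupSpec], seed: int = 0
) -> list[CohortSubject]:
    """Generate a labelled synthetic cohort, deterministic under ``seed``."""
    if not group_specs:
        raise ValueError("group_specs must be nonempty")
    for spec in group_specs:
        if spec.n < 1:
            raise ValueError(f"group {spec.label!r} must have n >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 915)))
    subjects = []
    for spec in group_specs:
        for j in range(spec.n):
            subj_seed = int(rng.integers(0, 2**31 - 1))
            params = draw_subject_params(spec, rng, subj_seed)
            record, truth = generate_subject(params)
            subjects.append(
                CohortSubject(f"{spec.label}_{j:02d}", spec.label, record, truth)
            )
    return subjects
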