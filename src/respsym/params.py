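"""Generator parameters and analysis configuration.

``SubjectParams`` collects every quantity the synthetic-subject generator
needs, one field per physiological feature the downstream analysis
measures (heart rate and its respiratory modulation, per-beat pressures
and their respiratory modulation, phase-gated burst probability, the
baroreflex occurrence slope, burst latency/shape, and neurogram noise).

``AnalysisConfig`` collects every tunable of the analysis pipeline.
Both round-trip through plain dicts / YAML for the CLI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class SubjectParams:
    """Ground-truth parameters for one synthetic subject.

    Defaults describe a healthy young adult at semisupine rest over a
    5-min recording: heart rate ~64 beats/min with a 6-beats/min
    respiratory swing, breathing ~14 breaths/min, arterial pressure
    ~130/75 mmHg with a 10-mmHg respiratory (Traube-Hering) swing of
    mean pressure, MSNA bursts in ~65% of mid-late-expiratory and ~40%
    of inspiratory/postinspiratory cardiac cycles, a -5 %/mmHg
    baroreflex occurrence slope, and a 1.3-s neural conduction latency.
    """

    duration_s: float = 300.0
    fs: float = 250.0

    # cardiac
    hr_base: float = 64.0          # beats/min
    rsa_amp: float = 6.0           # beats/min, peak-to-peak HR swing per breath

    # respiration
    breath_period_mean: float = 4.4   # s
    breath_period_cv: float = 0.10
    insp_fraction: float = 0.40       # fraction of the breath that is inspiration
    breath_amp_cv: float = 0.15

    # arterial pressure
    sbp_base: float = 130.0        # mmHg
    dbp_base: float = 75.0         # mmHg
    th_amp: float = 10.0           # mmHg, peak-to-peak MAP swing per breath
    th_lag_s: float = 0.5          # lag of the MAP modulation behind respiration
    bp_lf_amp: float = 4.0         # mmHg, peak-to-peak slow (Mayer-band) BP wave
    bp_lf_period_s: float = 10.0   # s, period of the slow BP wave
    dbp_jitter_sd: float = 1.0     # mmHg, iid per-beat pressure variability
    th_msna_coupling: float = 0.0  # >0 scales each breath's TH wave by that
    #                                breath's MSNA burst mass (gain 1 = mean mass)

    # MSNA
    burst_prob_exp: float = 0.65   # P(burst) per cycle, mid-late expiration
    burst_prob_insp: float = 0.40  # P(burst) per cycle, inspiration/postinspiration
    baro_slope: float = -5.0       # Δ occurrence probability (%) per mmHg DBP
    burst_latency_s: float = 1.3   # s, R wave -> burst peak
    burst_width_s: float = 0.5     # s, full width of the burst envelope
    burst_amp_mean: float = 1.0    # V
    burst_amp_cv: float = 0.25
    noise_sd: float = 0.1          # V, SD of additive band-limited noise
    msna_baseline: float = 0.1     # V, constant offset of the integrated trace

    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.hr_base <= 0:
            raise ValueError("hr_base must be positive")
        if not 0 < self.insp_fraction < 1:
            raise ValueError("insp_fraction must lie in (0, 1)")
        for name in ("burst_prob_exp", "burst_prob_insp"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.burst_latency_s < 0:
            raise ValueError("burst_latency_s must be >= 0")
        for name in ("breath_period_mean", "burst_width_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("breath_period_cv", "breath_amp_cv", "burst_amp_cv",
                     "noise_sd", "rsa_amp", "th_amp", "bp_lf_amp",
                     "dbp_jitter_sd", "th_msna_coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sbp_base <= self.dbp_base:
            raise ValueError("sbp_base must exceed dbp_base")

    def replace(self, **kwargs: Any) -> "SubjectParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SubjectParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SubjectParams fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class AnalysisConfig:
    """Tunables of the analysis pipeline (all config-file exposed)."""

    # R-wave detection
    r_refractory_s: float = 0.25      # minimum spacing between detections
    r_height_frac: float = 0.5        # threshold as fraction of channel max

    # beat hemodynamics: diastolic search window [r - pre, r + post_frac*RR]
    dbp_search_pre_s: float = 0.1
    dbp_search_post_frac: float = 0.4

    # respiration
    resp_lowpass_hz: float = 1.0      # zero-phase low-pass before extrema
    resp_min_prominence_frac: float = 0.25  # of the smoothed trace range

    # MSNA burst detection
    snr_min: float = 3.0              # candidate threshold, multiples of noise SD
    latency_window: tuple[float, float] = (0.8, 1.8)  # s after the R wave
    burst_smooth_s: float = 0.2       # matched smoothing before peak picking

    # respiratory phases
    artifact_pct: float = 150.0       # % of tallest burst; higher -> artifact
    boundary_policy: str = "following"  # breath supplying early inspiration of
    #                                     the mid-late-expiration phase

    # baroreflex
    baro_min_bins: int = 3
    baro_min_range_mmhg: float = 3.0
    baro_area_halfwidth_s: float = 0.4

    # per-breath coupling
    coupling_estimator: str = "pearson"  # or "spearman"
    msna_resp_normalized: bool = False   # integrate normalized (%) instead of V

    # group statistics
    normality_alpha: float = 0.05
    padjust: str = "bonferroni"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["latency_window"] = list(d["latency_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if "latency_window" in d:
            d["latency_window"] = tuple(d["latency_window"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown AnalysisConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
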