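"""Core containers for synchronized cardiovascular/neural recordings.

The package passes four kinds of objects between stages:

``SignalRecord``
    Uniformly sampled, synchronized channels (``ecg``, ``pressure``,
    ``respiration``, ``msna``) with a common sample rate.
``NormalizedNeurogram``
    The integrated MSNA trace expressed in % of the tallest burst,
    optionally shifted backward in time by the mean burst latency.
Tabular results (beats, breaths, bursts, interval grids, cohort rows)
    are plain :class:`pandas.DataFrame` objects with documented columns;
    see the producing functions for the column rosters.
``GroundTruth``
    Generator-side truth attached to a synthetic ``SignalRecord``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .params import SubjectParams

CHANNEL_NAMES = ("ecg", "pressure", "respiration", "msna")


@dataclass
class SignalRecord:
    """Synchronized, uniformly sampled multichannel recording.

    Parameters
    ----------
    fs
        Sample rate in Hz (> 0).
    channels
        Mapping of channel name to 1-D sample array.  All channels must
        have equal length.  Conventional names/units: ``ecg`` (arbitrary
        units), ``pressure`` (mmHg), ``respiration`` (arbitrary units),
        ``msna`` (volts, integrated neurogram).
    start_time
        Time of the first sample, in seconds.
    r_annotations
        Optional explicit R-wave event times (seconds).  When present,
        R-wave detection passes them through unchanged.
    """

    fs: float
    channels: dict[str, np.ndarray]
    start_time: float = 0.0
    r_annotations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        self.channels = {
            name: np.asarray(x, dtype=float) for name, x in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass
class NormalizedNeurogram:
    """Integrated MSNA trace in % of the tallest burst.

    ``samples[i]`` is the neurogram at time ``start_time + i / fs`` after
    the backward shift ``shift_applied`` has been applied, i.e. sample i
    of a shifted neurogram equals sample at ``t + shift_applied`` of the
    unshifted one.  The trailing ``n_invalid`` samples carry NaN because
    the shift has no source data for them.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    shift_applied: float = 0.0
    noise_sd: float = np.nan  # baseline noise SD, normalized units (%)

    @property
    def n_invalid(self) -> int:
        bad = np.isnan(self.samples)
        if not bad.any():
            return 0
        # invalid region is a trailing block by construction
        return int(bad.sum())

    def time(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs

    def value_at(self, t: np.ndarray | float) -> np.ndarray:
        """Nearest-sample lookup (NaN outside the valid region)."""
        idx = np.round((np.asarray(t) - self.start_time) * self.fs).astype(int)
        idx = np.clip(idx, 0, len(self.samples) - 1)
        return self.samples[idx]


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic subject.

    Attributes
    ----------
    params
        The :class:`~respsym.params.SubjectParams` used for generation.
    r_times
        True R-wave times (s).
    beats
        One row per cardiac cycle: ``r_time, rr, dbp, sbp, map``
        (``map`` is the exact mean of the constructed pressure waveform
        over the cycle).
    resp_landmarks
        One row per breath: ``t_trough, t_peak, t_trough_next,
        period, insp_dur, amp``.
    bursts
        One row per true burst: ``cycle_index, r_time, peak_time,
        amplitude`` where ``peak_time = r_time + burst_latency_s``.
    """

    params: "SubjectParams"
    r_times: np.ndarray
    beats: pd.DataFrame
    resp_landmarks: pd.DataFrame
    bursts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def burst_times(self) -> np.ndarray:
        """True neural firing times (the R waves of bursting cycles)."""
        if len(self.bursts) == 0:
            return np.empty(0)
        return self.bursts["r_time"].to_numpy()
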