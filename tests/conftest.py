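"""Shared fixtures: small synthetic subjects with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from respsym.params import AnalysisConfig, SubjectParams
from respsym.pipeline import analyze_subject
from respsym.simulate import generate_subject


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_subject():
    """One 5-min subject at the default resting parameters."""
    params = SubjectParams(seed=42)
    record, truth = generate_subject(params)
    return params, record, truth


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free subject: no neurogram noise, no non-respiratory BP
    variability, no breath-to-breath variability."""
    params = SubjectParams(
        seed=7,
        noise_sd=0.0,
        bp_lf_amp=0.0,
        dbp_jitter_sd=0.0,
        breath_period_cv=0.0,
        breath_amp_cv=0.0,
        baro_slope=0.0,
    )
    record, truth = generate_subject(params)
    return params, record, truth


@pytest.fixture(scope="session")
def default_result(default_subject):
    _, record, _ = default_subject
    return analyze_subject(record, subject_id="default")


def match_events(detected: np.ndarray, truth: np.ndarray, tol: float):
    """Greedy one-to-one matching of event times within a tolerance.

    Returns (n_matched, n_detected, n_truth).
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    used = np.zeros(len(detected), dtype=bool)
    matched = 0
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            matched += 1
    return matched, len(detected), len(truth)
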