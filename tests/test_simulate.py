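"""Generator contracts: shapes, determinism, ground-truth self-consistency,
and recoverability of the built-in modulation parameters."""

import numpy as np
import pandas as pd
import pytest

from respsym.params import SubjectParams
from respsym.simulate import (
    GroupSpec,
    default_cohort_spec,
    generate_cardiac,
    generate_cohort,
    generate_msna,
    generate_respiration,
    generate_subject,
    in_insp_post_window,
)


def rng():
    return np.random.default_rng(123)


class TestRespiration:
    def test_zero_variance_breaths_are_identical(self):
        p = SubjectParams(
            duration_s=60, breath_period_mean=4.0, breath_period_cv=0.0,
            breath_amp_cv=0.0,
        )
        resp, lm = generate_respiration(p, rng())
        assert len(lm) == 15
        np.testing.assert_allclose(lm["t_trough"], 4.0 * np.arange(15), atol=1e-12)
        np.testing.assert_allclose(lm["amp"], 1.0)

    def test_insp_fraction_sets_inspiratory_duration(self):
        p = SubjectParams(
            duration_s=60, breath_period_mean=4.0, breath_period_cv=0.0,
            insp_fraction=0.3,
        )
        _, lm = generate_respiration(p, rng())
        np.testing.assert_allclose(lm["insp_dur"], 1.2, atol=1e-12)

    def test_same_seed_bit_identical(self):
        p = SubjectParams(duration_s=60, seed=5)
        r1, lm1 = generate_respiration(p, np.random.default_rng(9))
        r2, lm2 = generate_respiration(p, np.random.default_rng(9))
        np.testing.assert_array_equal(r1, r2)
        pd.testing.assert_frame_equal(lm1, lm2)

    def test_record_shorter_than_one_breath_errors(self):
        p = SubjectParams(duration_s=2.0, breath_period_mean=4.0)
        with pytest.raises(ValueError, match="shorter than one breath"):
            generate_respiration(p, rng())

    def test_trace_monotone_within_segments(self):
        p = SubjectParams(duration_s=30, breath_period_cv=0.0, breath_amp_cv=0.0)
        resp, lm = generate_respiration(p, rng())
        fs = p.fs
        row = lm.iloc[1]
        up = resp[int(row.t_trough * fs) + 1 : int(row.t_peak * fs)]
        down = resp[int(row.t_peak * fs) + 1 : int(row.t_trough_next * fs)]
        assert np.all(np.diff(up) >= 0)
        assert np.all(np.diff(down) <= 0)


class TestCardiac:
    def _landmarks(self, p):
        return generate_respiration(p, rng())[1]

    def test_zero_modulation_constant_rr_and_map(self):
        p = SubjectParams(
            duration_s=60, rsa_amp=0.0, th_amp=0.0, bp_lf_amp=0.0,
            dbp_jitter_sd=0.0,
        )
        r, _, _, beats = generate_cardiac(p, self._landmarks(p), rng())
        np.testing.assert_allclose(np.diff(r), 60.0 / p.hr_base, atol=1e-9)
        # one-sample differences in beat length leave sub-0.01 mmHg wiggle
        assert np.ptp(beats["map"]) < 0.01

    def test_th_amp_sets_map_swing(self):
        p = SubjectParams(
            duration_s=120, th_amp=6.0, bp_lf_amp=0.0, dbp_jitter_sd=0.0,
            breath_period_cv=0.0, breath_amp_cv=0.0,
        )
        _, _, _, beats = generate_cardiac(p, self._landmarks(p), rng())
        # beats subsample the within-breath modulation, so the record-wide
        # swing approaches th_amp from below and never exceeds it
        swing = np.ptp(beats["map"])
        assert 0.9 * p.th_amp < swing <= p.th_amp + 1e-9

    def test_sbp_exceeds_dbp_every_beat(self, default_subject):
        _, _, truth = default_subject
        assert (truth.beats["sbp"] > truth.beats["dbp"]).all()

    def test_nonpositive_hr_rejected(self):
        p = SubjectParams(duration_s=30)
        lm = self._landmarks(p)
        with pytest.raises(ValueError, match="hr_base"):
            generate_cardiac(p.replace(hr_base=-1.0), lm, rng())

    def test_pressure_sampled_at_fs(self):
        p = SubjectParams(duration_s=30)
        _, ecg, pressure, _ = generate_cardiac(p, self._landmarks(p), rng())
        assert len(pressure) == len(ecg) == round(p.duration_s * p.fs)


class TestMsna:
    def test_extreme_probabilities_follow_phase_windows(self):
        p = SubjectParams(
            duration_s=120, burst_prob_insp=0.0, burst_prob_exp=1.0,
            baro_slope=0.0,
        )
        lm = self._setup(p)
        r, _, _, beats = generate_cardiac(p, lm, rng())
        _, bursts = generate_msna(p, r, lm, beats["dbp_gate"].to_numpy(), rng())
        in_win = in_insp_post_window(r[:-1], lm)
        exp_cycles = set(np.flatnonzero(~in_win))
        burst_cycles = set(bursts["cycle_index"])
        # every burst in an expiratory-window cycle, none in inspiratory
        assert burst_cycles <= exp_cycles
        # all expiratory cycles fire (minus any record-edge clipping)
        missing = exp_cycles - burst_cycles
        assert all(
            r[i] + p.burst_latency_s + p.burst_width_s / 2 >= p.duration_s
            for i in missing
        )

    def test_noise_free_burst_peak_equals_amplitude(self):
        p = SubjectParams(
            duration_s=30, noise_sd=0.0, burst_prob_exp=1.0, burst_prob_insp=1.0,
            baro_slope=0.0,
        )
        lm = self._setup(p)
        r, _, _, beats = generate_cardiac(p, lm, rng())
        msna, bursts = generate_msna(p, r, lm, beats["dbp_gate"].to_numpy(), rng())
        fs = p.fs
        for row in bursts.itertuples():
            i = int(round(row.peak_time * fs))
            assert abs(msna[i] - (row.amplitude + p.msna_baseline)) < 0.02

    def test_baro_slope_recovered_by_brute_force_binning(self):
        # independent oracle: bin the simulated occurrence table by true
        # gating DBP and fit unweighted least squares to occurrence %
        slopes = []
        for seed in range(5):
            p = SubjectParams(
                duration_s=600, fs=125, seed=seed, burst_prob_exp=0.5,
                burst_prob_insp=0.5, baro_slope=-5.0, th_amp=0.0,
            )
            _, truth = generate_subject(p)
            gate = truth.beats["dbp_gate"].to_numpy()
            n_cyc = len(truth.r_times) - 1
            occurred = np.zeros(n_cyc)
            occurred[truth.bursts["cycle_index"]] = 1
            # cycle i was gated by beat i-1's pressure
            x = gate[: n_cyc - 1] - gate.mean()
            y = occurred[1:n_cyc]
            bins = np.floor(x)
            centers, rate = [], []
            for b in np.unique(bins):
                centers.append(b + 0.5)
                rate.append(100.0 * y[bins == b].mean())
            slopes.append(np.polyfit(centers, rate, 1)[0])
        assert abs(np.mean(slopes) - (-5.0)) < 1.5

    @staticmethod
    def _setup(p):
        return generate_respiration(p, rng())[1]


class TestSubjectAndCohort:
    def test_ground_truth_echoes_params_and_shapes(self, default_subject):
        params, record, truth = default_subject
        assert truth.params == params
        n = round(params.duration_s * params.fs)
        for name in ("ecg", "pressure", "respiration", "msna"):
            assert len(record[name]) == n

    def test_identical_seed_identical_record(self):
        p = SubjectParams(duration_s=40, seed=11)
        rec1, _ = generate_subject(p)
        rec2, _ = generate_subject(p)
        for name in rec1.channels:
            np.testing.assert_array_equal(rec1[name], rec2[name])

    def test_burst_latency_exact_in_truth(self, default_subject):
        params, _, truth = default_subject
        lat = truth.bursts["peak_time"] - truth.bursts["r_time"]
        np.testing.assert_allclose(lat, params.burst_latency_s, atol=1e-12)

    def test_burst_times_lie_in_their_cycle(self, default_subject):
        _, _, truth = default_subject
        r = truth.r_times
        for row in truth.bursts.itertuples():
            i = int(row.cycle_index)
            assert r[i] <= row.r_time < r[i + 1]

    def test_cohort_labels_and_determinism(self):
        base = SubjectParams(duration_s=30)
        specs = [GroupSpec("g1", 3, base, {})]
        subs = generate_cohort(specs, seed=4)
        assert [s.group for s in subs] == ["g1"] * 3
        # zero-variance distribution: identical params apart from seed
        p0 = subs[0].truth.params.to_dict()
        p1 = subs[1].truth.params.to_dict()
        p0.pop("seed"), p1.pop("seed")
        assert p0 == p1
        # distinct seeds give distinct noise realizations
        assert not np.array_equal(subs[0].record["msna"], subs[1].record["msna"])
        subs2 = generate_cohort(specs, seed=4)
        np.testing.assert_array_equal(
            subs[0].record["msna"], subs2[0].record["msna"]
        )

    def test_empty_cohort_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort([], seed=0)
        with pytest.raises(ValueError):
            generate_cohort([GroupSpec("g", 0, SubjectParams())], seed=0)

    def test_default_cohort_has_reduced_postmenopausal_contrast(self):
        specs = default_cohort_spec()
        by_label = {s.label: s.base for s in specs}
        contrast = {
            k: v.burst_prob_exp - v.burst_prob_insp for k, v in by_label.items()
        }
        assert contrast["postmenopausal_female"] < 0.5 * contrast["young_female"]
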