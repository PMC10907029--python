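"""Respiratory interval grids, composite phases, phase metrics and change."""

import numpy as np
import pandas as pd
import pytest

from respsym.modulation import (
    PHASE_EXP,
    PHASE_INSP,
    assemble_phases,
    build_interval_grid,
    exclude_artifact_intervals,
    modulation_change,
    phase_metrics,
)
from respsym.params import AnalysisConfig
from respsym.records import NormalizedNeurogram


def make_cycles(n=4, period=4.0, insp_frac=0.3):
    t0 = period * np.arange(n)
    insp = insp_frac * period
    return pd.DataFrame(
        {
            "t_trough": t0,
            "t_peak": t0 + insp,
            "t_trough_next": t0 + period,
            "period": period,
            "insp_dur": insp,
            "exp_dur": period - insp,
            "amp": 1.0,
            "amp_norm": 100.0,
        }
    )


def flat_neurogram(duration=20.0, fs=100.0, level=0.0):
    return NormalizedNeurogram(np.full(int(duration * fs), level), fs=fs)


class TestIntervalGrid:
    def test_five_equal_intervals(self):
        grid = build_interval_grid(make_cycles())
        insp0 = grid[(grid.breath == 0) & (grid.period == "insp")]
        widths = (insp0["end"] - insp0["start"]).to_numpy()
        np.testing.assert_allclose(widths, 0.24)
        row4 = insp0[insp0.interval == 4].iloc[0]
        assert row4.start == pytest.approx(0.72)
        assert row4.end == pytest.approx(0.96)

    def test_grid_tiles_breaths_exactly(self):
        cycles = make_cycles(n=6, period=3.7, insp_frac=0.42)
        grid = build_interval_grid(cycles)
        total = (grid["end"] - grid["start"]).sum()
        assert total == pytest.approx(cycles["period"].sum(), abs=1e-9)

    def test_degenerate_breath_excluded_not_fatal(self):
        cycles = make_cycles(n=3)
        cycles.loc[1, "t_peak"] = cycles.loc[1, "t_trough"]  # zero inspiration
        cycles.loc[1, "insp_dur"] = 0.0
        grid = build_interval_grid(cycles)
        assert grid.loc[grid.breath == 1, "excluded"].all()
        assert not grid.loc[grid.breath != 1, "excluded"].any()


class TestPhases:
    @pytest.mark.parametrize(
        "frac_of, frac, expected",
        [
            ("insp", 0.7, PHASE_INSP),   # 70% through inspiration
            ("exp", 0.3, PHASE_INSP),    # 30% through expiration
            ("exp", 0.8, PHASE_EXP),     # 80% through expiration
            ("insp", 0.3, PHASE_EXP),    # 30% through inspiration
        ],
    )
    def test_phase_membership(self, frac_of, frac, expected):
        cycles = make_cycles(n=4)
        phases = assemble_phases(build_interval_grid(cycles))
        # probe a time in breath 1 (interior, both phases complete)
        cyc = cycles.iloc[1]
        if frac_of == "insp":
            t = cyc.t_trough + frac * cyc.insp_dur
        else:
            t = cyc.t_peak + frac * cyc.exp_dur
        member = phases[(phases.start <= t) & (t < phases.end)]
        assert len(member) == 1
        assert member["phase"].iloc[0] == expected

    def test_phases_partition_interior_time(self):
        cycles = make_cycles(n=5, period=4.1, insp_frac=0.38)
        grid = build_interval_grid(cycles)
        phases = assemble_phases(grid)
        # instances are disjoint
        iv = phases.sort_values("start")[["start", "end"]].to_numpy()
        assert (iv[1:, 0] >= iv[:-1, 1] - 1e-12).all()
        # every interior interval belongs to exactly one phase instance
        n_breaths = cycles.shape[0]
        interior = grid[
            ~((grid.breath == 0) & (grid.period == "insp") & (grid.interval <= 3))
            & ~((grid.breath == n_breaths - 1) & (grid.period == "exp")
                & (grid.interval >= 4))
        ]
        assert (phases["end"] - phases["start"]).sum() == pytest.approx(
            (interior["end"] - interior["start"]).sum()
        )

    def test_preceding_policy_uses_same_breath(self):
        cycles = make_cycles(n=3)
        grid = build_interval_grid(cycles)
        cfg = AnalysisConfig(boundary_policy="preceding")
        phases = assemble_phases(grid, cfg)
        exp_inst = phases[(phases.phase == PHASE_EXP) & (phases.instance == 1)]
        # members stay within breath 1's span
        cyc = cycles.iloc[1]
        assert (exp_inst["start"] >= cyc.t_trough - 1e-12).all()
        assert (exp_inst["end"] <= cyc.t_trough_next + 1e-12).all()


class TestArtifacts:
    def test_spike_excludes_touching_instances(self):
        cycles = make_cycles(n=4)
        grid = build_interval_grid(cycles)
        ng = flat_neurogram()
        ng.samples[int(5.0 * ng.fs)] = 200.0  # spike in breath 1
        grid = exclude_artifact_intervals(grid, ng)
        phases = assemble_phases(grid)
        hit = phases[(phases.start <= 5.0) & (5.0 < phases.end)]
        assert hit["excluded"].all()

    def test_clean_record_has_no_exclusions(self):
        grid = build_interval_grid(make_cycles())
        grid = exclude_artifact_intervals(grid, flat_neurogram(level=10.0))
        assert not grid["excluded"].any()

    def test_mask_excludes_whole_breath_phases(self):
        cycles = make_cycles(n=4)
        grid = build_interval_grid(cycles)
        grid = exclude_artifact_intervals(
            grid, flat_neurogram(), mask=[(4.0, 8.0)]  # all of breath 1
        )
        phases = assemble_phases(grid)
        touching = phases[(phases.end > 4.0) & (phases.start < 8.0)]
        assert touching["excluded"].all()


class TestPhaseMetrics:
    def test_counts_and_rates(self):
        cycles = make_cycles(n=30, period=4.0, insp_frac=0.5)
        phases = assemble_phases(build_interval_grid(cycles))
        ng = flat_neurogram(duration=130.0)
        # place 10 bursts and 40 heartbeats inside insp/post instances
        insp = phases[(phases.phase == PHASE_INSP) & ~phases.excluded]
        starts = insp.groupby("instance")["start"].min().to_numpy()[:10]
        bursts_t = starts + 0.01
        r_times = np.concatenate([starts + 0.02 + 0.01 * k for k in range(4)])
        pm = phase_metrics(phases, bursts_t, r_times, ng)
        assert pm.loc[PHASE_INSP, "n_bursts"] == 10
        assert pm.loc[PHASE_INSP, "n_heartbeats"] == 40
        assert pm.loc[PHASE_INSP, "incidence"] == pytest.approx(25.0)

    def test_frequency_from_duration(self):
        cycles = make_cycles(n=62, period=4.0, insp_frac=0.5)
        phases = assemble_phases(build_interval_grid(cycles))
        sub = phases[(phases.phase == PHASE_EXP) & ~phases.excluded]
        dur = (sub["end"] - sub["start"]).sum()
        n = int(dur / 5)  # one burst per 5 s of phase time
        starts = sub.groupby("instance")["start"].min().to_numpy()
        bursts_t = (starts + 0.01)[:n]
        pm = phase_metrics(phases, bursts_t, np.array([0.02]), flat_neurogram(260.0))
        assert pm.loc[PHASE_EXP, "frequency"] == pytest.approx(
            n / (dur / 60.0), rel=1e-6
        )

    def test_conservation_without_exclusions(self, default_subject, config):
        """Phase heartbeat/burst counts sum to the totals in covered time."""
        from respsym.bursts import (
            detect_bursts, mean_burst_latency, normalize_neurogram,
            shift_neurogram, shifted_peak_times,
        )
        from respsym.landmarks import detect_r_waves, detect_resp_cycles

        _, record, _ = default_subject
        r = detect_r_waves(record)
        cycles = detect_resp_cycles(record)
        ng = normalize_neurogram(record["msna"], record.fs)
        det = detect_bursts(ng, r)
        lat = mean_burst_latency(det)
        ng_s = shift_neurogram(ng, lat)
        shifted = shifted_peak_times(det, ng_s.shift_applied)
        grid = build_interval_grid(cycles)
        phases = assemble_phases(grid, config)
        pm = phase_metrics(phases, shifted, r, ng_s)

        iv = phases[~phases.excluded][["start", "end"]].to_numpy()
        in_cover = lambda t: any(a <= t < b for a, b in iv)  # noqa: E731
        assert pm["n_heartbeats"].sum() == sum(in_cover(t) for t in r)
        assert pm["n_bursts"].sum() == sum(in_cover(t) for t in shifted)


class TestModulationChange:
    def make_metrics(self, exp, insp):
        cols = ["incidence", "frequency", "total_area_per_s", "mean_area_per_s"]
        return pd.DataFrame(
            [[exp] * 4, [insp] * 4], columns=cols,
            index=pd.Index([PHASE_EXP, PHASE_INSP], name="phase"),
        )

    def test_inhibition_is_negative(self):
        mc = modulation_change(self.make_metrics(80.0, 40.0))
        assert mc.loc["incidence", "abs_change"] == pytest.approx(-40.0)
        assert mc.loc["incidence", "pct_change"] == pytest.approx(-50.0)

    def test_equal_phases_zero_change(self):
        mc = modulation_change(self.make_metrics(50.0, 50.0))
        assert mc.loc["incidence", "abs_change"] == 0.0
        assert mc.loc["incidence", "pct_change"] == 0.0

    def test_paradoxical_rise_allowed(self):
        mc = modulation_change(self.make_metrics(50.0, 55.0))
        assert mc.loc["incidence", "abs_change"] == pytest.approx(5.0)
        assert mc.loc["incidence", "pct_change"] == pytest.approx(10.0)

    def test_zero_expiratory_value_flagged(self):
        mc = modulation_change(self.make_metrics(0.0, 10.0))
        assert np.isnan(mc.loc["incidence", "pct_change"])


def test_percent_change_recovers_probability_contrast():
    """Estimated %change converges to 100*(p_insp-p_exp)/p_exp."""
    from respsym.params import SubjectParams
    from respsym.pipeline import analyze_subject
    from respsym.simulate import generate_subject

    vals = []
    for seed in range(3):
        p = SubjectParams(seed=seed, duration_s=1290, fs=125,
                          burst_prob_exp=0.8, burst_prob_insp=0.2)
        rec, _ = generate_subject(p)
        vals.append(analyze_subject(rec)["dincidence_pct"])
    assert np.mean(vals) == pytest.approx(-75.0, abs=5.0)
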