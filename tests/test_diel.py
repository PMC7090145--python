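"""Diel phase summaries, CAM-onset and stomatal-inversion detection."""

import numpy as np
import pandas as pd
import pytest

from phenokit import (DielSimParams, DielTrace, PhaseSummary, SimConfig,
                      aperture_stats, detect_anticipation, detect_cam_onset,
                      detect_inversion, phase_summaries, simulate_diel_trace,
                      simulate_stomata)
from phenokit.diel import TraceGapError, TransitionReport


def constant_trace(value=5.0, n_days=3, samples_per_day=960):
    dt = 86400.0 / samples_per_day
    time = np.arange(n_days * samples_per_day) * dt
    return DielTrace.from_samples(time, np.full(time.size, value))


def summaries_from_nightly(means):
    return [PhaseSummary(day_index=i + 1, day_mean=8, day_max=8, day_min=8,
                         night_mean=m, night_max=m, night_min=m,
                         n_day=10, n_night=10)
            for i, m in enumerate(means)]


class TestPhaseSummaries:
    def test_constant_trace_is_constant_everywhere(self):
        summaries = phase_summaries(constant_trace(5.0))
        for s in summaries:
            assert s.day_mean == s.night_mean == 5.0
            assert s.day_min == s.day_max == 5.0

    def test_piecewise_constant_template_recovered_exactly(self):
        n = 96
        day_vals = np.where(np.arange(n) < 48, 8.0, -1.0)
        time = np.arange(2 * n) * (86400.0 / n)
        trace = DielTrace.from_samples(time, np.tile(day_vals, 2))
        for s in phase_summaries(trace):
            assert s.day_mean == 8.0 and s.night_mean == -1.0

    def test_every_sample_counted_exactly_once(self, salt_trace):
        summaries = phase_summaries(salt_trace)
        assert sum(s.n_day + s.n_night for s in summaries) == len(salt_trace)

    def test_control_summaries_match_reported_ranges(self, control_trace):
        summaries = phase_summaries(control_trace)
        for s in summaries:
            assert 6.0 <= s.day_mean <= 12.0
            assert -2.0 <= s.night_mean <= 0.0

    def test_gap_error_lists_interval(self):
        trace = constant_trace()
        trace.time[100:] += 7200.0  # 2-h hole
        with pytest.raises(TraceGapError, match="gap"):
            phase_summaries(trace)


class TestCamOnset:
    def test_control_never_crosses_threshold(self, control_trace):
        report = detect_cam_onset(phase_summaries(control_trace))
        assert report.onset_day is None

    def test_salt_defaults_onset_on_day_8(self, salt_trace):
        report = detect_cam_onset(phase_summaries(salt_trace))
        assert report.onset_day == 8

    def test_hand_scanned_nightly_means(self):
        report = detect_cam_onset(summaries_from_nightly([-1, -1, -0.05, 0.3]),
                                  threshold=-0.1)
        assert report.onset_day == 3
        assert isinstance(report, TransitionReport)

    def test_raising_threshold_never_advances_onset(self, salt_trace):
        summaries = phase_summaries(salt_trace)
        onsets = []
        for thr in [-0.5, -0.3, -0.1, 0.0, 0.2, 0.5]:
            day = detect_cam_onset(summaries, threshold=thr).onset_day
            onsets.append(np.inf if day is None else day)
        assert all(a <= b for a, b in zip(onsets, onsets[1:]))

    def test_requires_two_days(self):
        with pytest.raises(ValueError):
            detect_cam_onset(summaries_from_nightly([-1]))

    def test_detector_recovers_programmed_transition_day(self):
        """Seeded sweep: detected onset equals the generator's night-zero day."""
        hits = 0
        cases = [(zero_day, seed) for zero_day in (6, 7, 8, 9, 10)
                 for seed in range(5)]
        for i, (zero_day, seed) in enumerate(cases):
            params = DielSimParams(onset_ramp_start_day=zero_day - 2,
                                   night_zero_day=zero_day,
                                   inversion_spikes_from_day=zero_day + 1)
            trace = simulate_diel_trace(
                SimConfig(seed=100 + i, group="salt"), params)
            onset = detect_cam_onset(phase_summaries(trace)).onset_day
            hits += onset == zero_day
        assert hits >= 24


class TestAnticipation:
    def test_constant_trace_has_flat_edges(self):
        report = detect_anticipation(constant_trace(), day=2)
        assert report.light_on_delta == 0.0
        assert report.light_off_delta == 0.0
        assert not report.cam_like

    def test_salt_trace_flags_cam_after_spikes_start(self, salt_trace):
        for day in (9, 11, 14):
            report = detect_anticipation(salt_trace, day)
            assert report.cam_like
            assert report.pre_dawn_min < -2.0 and report.post_dawn_max > 2.0

    def test_salt_trace_pre_transition_day_not_flagged(self, salt_trace):
        assert not detect_anticipation(salt_trace, 3).cam_like

    def test_missing_day_rejected(self, salt_trace):
        with pytest.raises(ValueError, match="not present"):
            detect_anticipation(salt_trace, 99)

    def test_short_day_window_error(self):
        trace = constant_trace(n_days=1, samples_per_day=4)
        with pytest.raises(ValueError, match="window"):
            detect_anticipation(trace, 1)


class TestApertureStats:
    def test_uniform_open_population(self):
        df = pd.DataFrame({"day": 1, "timepoint": "4pm",
                           "aperture_um": [2.0] * 150})
        out = aperture_stats(df)
        assert out["open_proportion"].item() == 1.0
        assert out["mean_aperture_um"].item() == 2.0

    def test_half_open_population(self):
        df = pd.DataFrame({"day": 1, "timepoint": "4am",
                           "aperture_um": [2.0] * 75 + [0.9] * 75})
        assert aperture_stats(df)["open_proportion"].item() == 0.5

    def test_open_proportion_equals_count_division(self, salt_stomata):
        out = aperture_stats(salt_stomata, open_threshold=1.4)
        for row in out.itertuples():
            cell = salt_stomata[(salt_stomata["day"] == row.day)
                                & (salt_stomata["timepoint"] == row.timepoint)]
            brute = (cell["aperture_um"] >= 1.4).sum() / len(cell)
            assert row.open_proportion == brute

    def test_open_phase_means_in_reported_range(self, salt_stomata):
        out = aperture_stats(salt_stomata)
        truth_day = salt_stomata.attrs["truth"]["inversion_day"]
        for row in out.itertuples():
            open_phase = (row.timepoint == "4pm") == (row.day < truth_day)
            if open_phase:
                assert 1.7 <= row.mean_aperture_um <= 3.0


class TestInversion:
    def test_control_table_never_inverts(self, control_stomata):
        assert detect_inversion(aperture_stats(control_stomata)) is None

    def test_control_day_always_beats_night(self, control_stomata):
        out = aperture_stats(control_stomata)
        pivot = out.pivot(index="day", columns="timepoint",
                          values="mean_aperture_um")
        assert (pivot["4pm"] > pivot["4am"]).all()

    def test_salt_defaults_invert_on_day_7(self, salt_stomata):
        assert detect_inversion(aperture_stats(salt_stomata)) == 7

    def test_hand_constructed_means(self):
        stats = pd.DataFrame({
            "day": [1, 1, 2, 2],
            "timepoint": ["4pm", "4am", "4pm", "4am"],
            "mean_aperture_um": [2.0, 0.9, 0.9, 2.0],
        })
        assert detect_inversion(stats) == 2

    def test_degenerate_open_fraction(self):
        from phenokit import StomataSimParams
        table = simulate_stomata(
            SimConfig(seed=0, n_days=3, group="control"),
            StomataSimParams(open_fraction_when_open_phase=1.0))
        out = aperture_stats(table)
        open_rows = out[out["timepoint"] == "4pm"]
        assert (open_rows["open_proportion"] == 1.0).all()
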