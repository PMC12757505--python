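"""HR extraction, artifact repair, normalization and phase summaries."""

import numpy as np
import pytest

from venoppg.errors import UninterpretableError
from venoppg.heartrate import (GRID_STEP_S, HRSeries, NormalizedHRSeries,
                               extract_hr, hr_grid, normalize_hr,
                               phase_medians, repair_artifacts,
                               smooth_for_display)
from venoppg.phases import PhaseTimeline
from venoppg.synth import NoiseParams, SubjectParams, generate_recording


def grid_series(hr, valid=None, timeline=None):
    grid = hr_grid(timeline or PhaseTimeline())
    hr = np.broadcast_to(np.asarray(hr, dtype=float), grid.shape).copy()
    valid = np.ones(len(grid), bool) if valid is None else valid
    return HRSeries(times=grid, hr=hr, valid=valid,
                    interpolated=np.zeros(len(grid), bool))


class TestExtractHR:
    def test_grid_geometry(self, timeline):
        grid = hr_grid(timeline)
        assert len(grid) == 150  # 60 s span / 0.4 s
        assert grid[0] == -5.0
        np.testing.assert_allclose(np.diff(grid), GRID_STEP_S)

    def test_metronomic_train_reads_constant_hr(self):
        params = SubjectParams(group_label="control", baseline_hr=80.0,
                               phase_hr_effects={}, transition_peak=0.0,
                               hr_noise_sd=0.0)
        rec, _ = generate_recording(params, NoiseParams.none(), seed=4)
        series = extract_hr(rec.channels["ear"])
        assert np.all(np.abs(series.hr[series.valid] - 80.0) < 0.5)

    def test_tracks_generator_trajectory(self, venous_recording):
        """Grid HR follows the known trajectory within 2 bpm outside the
        transition exclusion windows."""
        rec, truth = venous_recording
        series = extract_hr(rec.channels["ear"], rec.timeline)
        true_hr = np.interp(series.times, truth.hr_times, truth.hr_bpm)
        _, excluded = rec.timeline.phase_of(series.times)
        mask = series.valid & ~excluded
        assert np.abs(series.hr[mask] - true_hr[mask]).max() < 2.0

    def test_pulseless_channel_is_uninterpretable(self):
        params = SubjectParams(group_label="uninterpretable",
                               arterial_rest_amp=0.0, phase_hr_effects={},
                               transition_peak=0.0, hr_noise_sd=0.0)
        rec, _ = generate_recording(params, NoiseParams(), seed=5)
        with pytest.raises(UninterpretableError):
            extract_hr(rec.channels["ear"])


class TestRepairArtifacts:
    def test_clean_series_unchanged(self):
        series = grid_series(80.0)
        repaired = repair_artifacts(series)
        np.testing.assert_array_equal(repaired.hr, series.hr)
        assert not repaired.interpolated.any()

    def test_single_missing_sample_interpolates_midpoint(self):
        series = grid_series(80.0)
        series.hr[70:] = 84.0
        series.hr[69] = np.nan
        series.valid[69] = False
        series.hr[:69] = 80.0
        # neighbours 80 and 84 -> interior gap repairs to 82
        repaired = repair_artifacts(series, max_step_bpm=30.0)
        assert repaired.hr[69] == pytest.approx(82.0)
        assert repaired.interpolated[69]

    def test_two_second_gap_repaired_close_to_truth(self, venous_recording):
        """A 2 s run of missing samples is bridged by interpolation to
        within 3 bpm of the generating trajectory."""
        rec, truth = venous_recording
        series = extract_hr(rec.channels["ear"], rec.timeline)
        gap = (series.times >= 10.0) & (series.times < 12.0)
        series.hr[gap] = np.nan
        series.valid[gap] = False
        repaired = repair_artifacts(series)
        true_hr = np.interp(series.times, truth.hr_times, truth.hr_bpm)
        assert np.abs(repaired.hr[gap] - true_hr[gap]).max() < 3.0
        assert repaired.interpolated[gap].all()

    def test_out_of_bounds_and_spikes_flagged(self):
        series = grid_series(80.0)
        series.hr[40] = 300.0   # physiologically impossible
        series.hr[80] = 110.0   # 30 bpm spike vs the 20 bpm step rule
        repaired = repair_artifacts(series)
        assert repaired.interpolated[40] and repaired.interpolated[80]
        np.testing.assert_allclose(repaired.hr, 80.0)

    def test_idempotent(self, noisy_recording):
        rec, _ = noisy_recording
        once = repair_artifacts(extract_hr(rec.channels["ear"], rec.timeline))
        twice = repair_artifacts(once)
        np.testing.assert_array_equal(once.hr, twice.hr)

    def test_mostly_invalid_is_uninterpretable(self):
        valid = np.zeros(150, bool)
        valid[:60] = True
        series = grid_series(80.0, valid=valid)
        with pytest.raises(UninterpretableError):
            repair_artifacts(series)


class TestNormalizeHR:
    def test_constant_series_gives_zero_deltas(self):
        normalized = normalize_hr(grid_series(70.0))
        np.testing.assert_allclose(normalized.delta_hr, 0.0, atol=1e-12)
        assert normalized.rest_median == 70.0

    def test_median_ignores_invalid_rest_samples(self, timeline):
        """An artifact-flagged rest sample does not pull the baseline."""
        series = grid_series(80.0)
        rest_idx = np.where(series.times < -2.0)[0]
        series.hr[rest_idx[0]] = 78.0
        series.hr[rest_idx[1]] = 200.0
        series.valid[rest_idx[1]] = False
        normalized = normalize_hr(series, timeline)
        valid_rest = np.delete(series.hr[rest_idx], 1)
        assert normalized.rest_median == pytest.approx(np.median(valid_rest))

    def test_rest_median_zero_invariant(self, noisy_recording):
        """After normalization the median of the (transition-excluded)
        valid rest samples is exactly zero."""
        rec, _ = noisy_recording
        series = repair_artifacts(extract_hr(rec.channels["ear"], rec.timeline))
        normalized = normalize_hr(series, rec.timeline)
        labels, excluded = rec.timeline.phase_of(normalized.times)
        rest = (labels == "Rest") & ~excluded & normalized.valid
        assert abs(np.median(normalized.delta_hr[rest])) < 1e-9

    def test_recovers_configured_su_offset(self, venous_recording):
        rec, truth = venous_recording
        series = repair_artifacts(extract_hr(rec.channels["ear"], rec.timeline))
        normalized = normalize_hr(series, rec.timeline)
        summary = phase_medians(normalized, rec.timeline)
        assert abs(summary.medians["Su"]
                   - truth.params.phase_hr_effects["Su"]) < 1.5

    def test_insufficient_rest_is_uninterpretable(self, timeline):
        valid = np.ones(150, bool)
        valid[:13] = False  # kills the usable rest samples
        series = grid_series(80.0, valid=valid)
        with pytest.raises(UninterpretableError):
            normalize_hr(series, timeline)


class TestPhaseMedians:
    def normalized(self, delta, timeline):
        grid = hr_grid(timeline)
        delta = np.broadcast_to(np.asarray(delta, float), grid.shape).copy()
        return NormalizedHRSeries(times=grid, delta_hr=delta,
                                  valid=np.ones(len(grid), bool),
                                  rest_median=80.0)

    def test_zero_series_gives_zero_medians(self, timeline):
        summary = phase_medians(self.normalized(0.0, timeline), timeline)
        assert all(v == 0.0 for v in summary.medians.values())

    def test_su_only_offset(self, timeline):
        grid = hr_grid(timeline)
        delta = np.where((grid >= 0) & (grid < 30), 5.0, 0.0)
        summary = phase_medians(self.normalized(delta, timeline), timeline)
        assert summary.medians == {"Rest": 0.0, "Su": 5.0, "Pra": 0.0,
                                   "End": 0.0}

    def test_matches_sort_based_oracle(self, timeline):
        """Phase medians equal the middle of the sorted usable samples
        for both odd and even counts."""
        rng = np.random.default_rng(7)
        series = self.normalized(rng.normal(0, 5, 150), timeline)
        labels, excluded = timeline.phase_of(series.times)
        summary = phase_medians(series, timeline)
        for phase, value in summary.medians.items():
            usable = np.sort(series.delta_hr[(labels == phase) & ~excluded])
            n = len(usable)
            oracle = (usable[n // 2] if n % 2 else
                      (usable[n // 2 - 1] + usable[n // 2]) / 2.0)
            assert value == pytest.approx(oracle)


class TestSmoothForDisplay:
    def test_constant_unchanged(self, timeline):
        series = TestPhaseMedians().normalized(3.0, timeline)
        out = smooth_for_display(series)
        np.testing.assert_allclose(out.delta_hr, 3.0)

    def test_single_spike_removed(self, timeline):
        series = TestPhaseMedians().normalized(0.0, timeline)
        series.delta_hr[75] = 50.0
        out = smooth_for_display(series)
        np.testing.assert_allclose(out.delta_hr, 0.0, atol=1e-12)

    def test_step_transition_width_bounded(self, timeline):
        grid = hr_grid(timeline)
        series = TestPhaseMedians().normalized(
            np.where(grid >= 20, 10.0, 0.0), timeline)
        out = smooth_for_display(series, window_s=6.0)
        # outside +/- half a window of the step the values are untouched
        assert np.all(out.delta_hr[grid < 17.0] == 0.0)
        assert np.all(out.delta_hr[grid > 23.0] == 10.0)
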