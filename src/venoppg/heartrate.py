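"""Instantaneous heart rate from the earlobe arterial PPG.

Beats are detected on the high-passed earlobe channel; instantaneous
HR = 60 / inter-beat interval is assigned at the midpoint of each beat
pair and resampled onto a fixed 0.4 s grid by previous-value hold
(tachogram semantics). Artifactual samples are repaired by linear
interpolation, each subject's series is normalized by subtracting the
median of their rest-phase HR, and per-phase medians (transition
windows excluded) summarise the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UninterpretableError
from .io import Channel
from .phases import PHASES, PhaseTimeline
from .pulse import detect_beats, highpass

GRID_STEP_S = 0.4
HR_BOUNDS = (30.0, 220.0)
MAX_STEP_BPM = 20.0
MAX_INVALID_FRACTION = 0.5
MIN_REST_SAMPLES = 5
MIN_PHASE_SAMPLES = 3


@dataclass
class HRSeries:
    """Heart rate on the 0.4 s export grid with validity flags."""

    times: np.ndarray
    hr: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)


@dataclass
class NormalizedHRSeries:
    """HR change relative to the subject's resting median."""

    times: np.ndarray
    delta_hr: np.ndarray
    valid: np.ndarray
    rest_median: float


@dataclass
class PhaseSummary:
    """Per-phase medians of normalized HR for one subject."""

    subject_id: str
    medians: dict  # phase -> bpm (Rest is 0 by construction)


def hr_grid(timeline: PhaseTimeline) -> np.ndarray:
    """The 0.4 s export grid covering [rest_start, record_end)."""
    lo, hi = timeline.span()
    n = int(round((hi - lo) / GRID_STEP_S))
    return lo + GRID_STEP_S * np.arange(n)


def extract_hr(ear: Channel, timeline: PhaseTimeline | None = None,
               highpass_cutoff_hz: float = 0.5) -> HRSeries:
    """Beat-to-beat HR from the earlobe channel on the 0.4 s grid.

    Grid samples before the first or after the last inter-beat midpoint
    are flagged invalid (no beat pair covers them).
    """
    timeline = timeline or PhaseTimeline()
    filtered = highpass(ear, highpass_cutoff_hz)
    beats = detect_beats(filtered)
    if len(beats) < 2:
        raise UninterpretableError("fewer than 2 beats on the earlobe channel")
    ibi = np.diff(beats.times)
    inst_hr = 60.0 / ibi
    midpoints = beats.times[:-1] + ibi / 2.0
    grid = hr_grid(timeline)
    idx = np.searchsorted(midpoints, grid, side="right") - 1
    valid = (idx >= 0) & (grid <= midpoints[-1])
    hr = inst_hr[np.clip(idx, 0, len(inst_hr) - 1)]
    hr[~valid] = np.nan
    return HRSeries(times=grid, hr=hr, valid=valid,
                    interpolated=np.zeros(len(grid), dtype=bool))


def repair_artifacts(series: HRSeries,
                     hr_bounds: tuple = HR_BOUNDS,
                     max_step_bpm: float = MAX_STEP_BPM) -> HRSeries:
    """Repair artifactual HR samples by linear interpolation.

    A sample is invalid when missing, outside ``hr_bounds``, or
    deviating more than ``max_step_bpm`` from a rolling median of the
    series (5 s window). The rolling-median criterion catches the same
    artifactual jumps a sample-to-sample step check would, but cannot
    lock onto an artifact value and cascade down the record. Interior
    invalid runs are linearly interpolated between valid neighbours;
    leading/trailing runs take the nearest valid value. Raises
    :class:`UninterpretableError` when more than half the samples are
    invalid. Idempotent: a repaired series passes its own checks.
    """
    from scipy import ndimage

    hr = series.hr.copy()
    ok = series.valid & np.isfinite(hr)
    ok &= np.where(np.isfinite(hr), (hr >= hr_bounds[0]) & (hr <= hr_bounds[1]),
                   False)
    if ok.any() and not ok.all():
        filled = hr.copy()
        filled[~ok] = np.interp(series.times[~ok], series.times[ok], hr[ok])
    else:
        filled = hr
    if ok.any():
        k = 2 * int(round(2.5 / GRID_STEP_S)) + 1  # ~5 s, odd
        rolling_med = ndimage.median_filter(filled, size=k, mode="nearest")
        ok &= np.abs(hr - rolling_med) <= max_step_bpm
    if ok.sum() < (1.0 - MAX_INVALID_FRACTION) * len(hr):
        raise UninterpretableError(
            f"more than {MAX_INVALID_FRACTION:.0%} of HR samples invalid")
    repaired = hr.copy()
    invalid = ~ok
    repaired[invalid] = np.interp(series.times[invalid], series.times[ok],
                                  hr[ok])
    return HRSeries(times=series.times.copy(), hr=repaired,
                    valid=np.ones(len(hr), dtype=bool),
                    interpolated=series.interpolated | invalid)


def normalize_hr(series: HRSeries,
                 timeline: PhaseTimeline | None = None) -> NormalizedHRSeries:
    """Subtract the median rest-phase HR (robust baseline) from the series.

    The rest median is computed over the same sample set that the
    per-phase summaries use (valid rest samples outside the transition
    exclusion window), which makes the Rest phase median exactly zero
    by construction.
    """
    timeline = timeline or PhaseTimeline()
    labels, excluded = timeline.phase_of(np.clip(series.times, *timeline.span()))
    rest_mask = (labels == "Rest") & ~excluded & series.valid
    if rest_mask.sum() < MIN_REST_SAMPLES:
        raise UninterpretableError(
            f"fewer than {MIN_REST_SAMPLES} valid rest samples for HR normalization")
    rest_median = float(np.median(series.hr[rest_mask]))
    return NormalizedHRSeries(times=series.times.copy(),
                              delta_hr=series.hr - rest_median,
                              valid=series.valid.copy(),
                              rest_median=rest_median)


def phase_medians(series: NormalizedHRSeries,
                  timeline: PhaseTimeline | None = None,
                  subject_id: str = "") -> PhaseSummary:
    """Median normalized HR per phase, transition windows excluded."""
    timeline = timeline or PhaseTimeline()
    labels, excluded = timeline.phase_of(np.clip(series.times, *timeline.span()))
    medians = {}
    for phase in PHASES:
        mask = (labels == phase) & ~excluded & series.valid
        if mask.sum() < MIN_PHASE_SAMPLES:
            raise UninterpretableError(
                f"phase {phase}: fewer than {MIN_PHASE_SAMPLES} usable HR samples")
        medians[phase] = float(np.median(series.delta_hr[mask]))
    return PhaseSummary(subject_id=subject_id, medians=medians)


def smooth_for_display(series: NormalizedHRSeries,
                       window_s: float = 6.0) -> NormalizedHRSeries:
    """Centered moving-median smoothing for plotting only.

    Robustness-consistent with the median-based normalization; never
    used for the statistics.
    """
    half = int(round(window_s / 2.0 / GRID_STEP_S))
    n = len(series.delta_hr)
    out = np.empty(n)
    for i in range(n):
        a, b = max(0, i - half), min(n, i + half + 1)
        seg = series.delta_hr[a:b][series.valid[a:b]]
        out[i] = np.median(seg) if len(seg) else np.nan
    return NormalizedHRSeries(times=series.times.copy(), delta_hr=out,
                              valid=series.valid.copy(),
                              rest_median=series.rest_median)
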