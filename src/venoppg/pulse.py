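"""Arterial pulse-amplitude analysis of fingertip PPG.

The raw optical signal mixes a cardiac pulsatile component with slow
volume drifts; a zero-phase high-pass filter isolates the pulsatile
part, beats are detected as systolic peaks, and the per-cycle pulse
amplitude A_pulse (peak minus trough within each cardiac cycle) is
smoothed with a trailing 10-point moving average. Windowed means of the
smoothed amplitude quantify how elevation changes pulsatility: in
normal limbs elevation raises A_pulse, while positional arterial
compression collapses it (remaining pulsatility < 25% of rest is the
arterial-compression screen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, UninterpretableError
from .io import Channel
from .phases import PhaseTimeline

#: Analysis windows (s, relative to manoeuvre start).
REST_WINDOW = (-20.0, -5.0)
REST_WINDOW_FALLBACK = (-5.0, 0.0)
SU_WINDOW = (5.0, 20.0)
PRA_WINDOW = (35.0, 40.0)

MIN_BEAT_DISTANCE_S = 60.0 / 220.0  # no two beats closer than at 220 bpm
SMOOTHING_POINTS = 10


@dataclass
class BeatSeries:
    """Detected beats: peak time plus per-cycle peak and trough values."""

    times: np.ndarray      # systolic peak times, s
    peak_values: np.ndarray
    trough_values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        self.trough_values = np.asarray(self.trough_values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("beat times must be strictly increasing")
        if np.any(self.peak_values <= self.trough_values):
            raise ConfigurationError("each beat needs peak > trough")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PulseAmplitudeSeries:
    """Per-beat A_pulse with its trailing moving-average smoothing."""

    times: np.ndarray
    amplitudes: np.ndarray
    smoothed: np.ndarray


@dataclass
class ApulseMetrics:
    """Windowed pulse-amplitude summary used for arterial screening."""

    rest_mean: float
    su_mean: float
    pra_mean: float
    su_vs_rest_percent: float        # percent change of Su vs rest
    remaining_pulsatility_percent: float  # 100 * su / rest
    su_normalized_to_pra: float      # 100 * su / pra


def _interp_invalid(ch: Channel) -> np.ndarray:
    """Fill dropped-out samples by linear interpolation over valid ones."""
    if ch.valid.all():
        return ch.values.copy()
    if not ch.valid.any():
        raise UninterpretableError(f"channel {ch.name}: no valid samples")
    return np.interp(ch.times, ch.times[ch.valid], ch.values[ch.valid])


def highpass(ch: Channel, cutoff_hz: float = 0.5, order: int = 2) -> Channel:
    """Zero-phase Butterworth high-pass isolating the pulsatile component.

    Applied forward-backward (``filtfilt``) so beat peaks are not
    shifted in time. Invalid samples are linearly interpolated before
    filtering; the validity mask is preserved on the output.
    """
    nyquist = ch.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    values = _interp_invalid(ch)
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=ch.sampling_rate,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, values)
    return Channel(ch.name, ch.sampling_rate, ch.times, filtered,
                   ch.valid.copy())


def detect_beats(filtered: Channel) -> BeatSeries:
    """Detect systolic peaks on a high-passed arterial channel.

    Local-maxima search with a minimum inter-peak distance of 60/220 s
    and a prominence threshold adaptive to the local signal amplitude
    (the signal is divided by a rolling RMS estimate so that slow
    envelope changes, e.g. amplitude collapse under compression, do not
    starve the detector). Implausibly irregular detections — the
    signature of a pulseless, noise-only record — raise
    :class:`UninterpretableError`.
    """
    x = _interp_invalid(filtered)
    fs = filtered.sampling_rate
    # rolling RMS over ~3 s tracks the local pulsatile envelope
    win = int(round(3.0 * fs)) | 1
    local_rms = np.sqrt(np.maximum(
        sps.convolve(x ** 2, np.ones(win) / win, mode="same"), 1e-30))
    norm = x / local_rms
    if not _is_periodic(norm, fs):
        raise UninterpretableError(
            f"channel {filtered.name}: no periodic pulsatile component "
            "(pulseless or noise-only signal)")
    distance = max(1, int(round(MIN_BEAT_DISTANCE_S * fs)))
    peaks, _ = sps.find_peaks(norm, distance=distance, prominence=1.0)
    if len(peaks) < 3:
        raise UninterpretableError(
            f"channel {filtered.name}: fewer than 2 beats detectable")
    ibi = np.diff(filtered.times[peaks])
    hr = 60.0 / ibi
    plausible = (hr >= 25.0) & (hr <= 230.0)
    if plausible.mean() < 0.7:
        raise UninterpretableError(
            f"channel {filtered.name}: detected rhythm implausible "
            f"(plausible IBI fraction {plausible.mean():.2f})")
    # the first peak has no preceding cycle to search for its trough, so
    # it anchors the second beat's cycle and is not itself reported
    troughs = np.empty(len(peaks) - 1)
    for k, (a, b) in enumerate(zip(peaks[:-1], peaks[1:])):
        troughs[k] = x[a:b + 1].min()
    kept = peaks[1:]
    times = filtered.times[kept] + _parabolic_offset(x, kept) / fs
    return BeatSeries(times=times, peak_values=x[kept],
                      trough_values=troughs)


def _parabolic_offset(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sub-sample peak refinement: vertex of the parabola through the
    sample maximum and its two neighbours, in samples (clipped to ±0.5)."""
    i = np.clip(peaks, 1, len(x) - 2)
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    offset = np.where(np.abs(denom) > 1e-12,
                      0.5 * (x[i - 1] - x[i + 1]) / np.where(denom == 0, 1, denom),
                      0.0)
    return np.clip(offset, -0.5, 0.5)


def _is_periodic(norm: np.ndarray, fs: float, slice_s: float = 10.0,
                 min_lag_s: float = 0.25, max_lag_s: float = 2.0,
                 threshold: float = 0.25) -> bool:
    """Does any 10 s slice show cardiac-band periodicity?

    The envelope-normalised signal of a pulsatile record has a strong
    autocorrelation peak at the beat period (lag 0.25-2 s, i.e. 30-240
    bpm); broadband noise does not. One periodic slice suffices — the
    rest of the record may be artifact-laden.
    """
    n_slice = int(slice_s * fs)
    lags = np.arange(int(min_lag_s * fs), int(max_lag_s * fs) + 1)
    for start in range(0, max(1, len(norm) - n_slice + 1), n_slice):
        seg = norm[start:start + n_slice]
        seg = seg - seg.mean()
        denom = float(seg @ seg)
        if denom <= 0 or len(seg) < lags[-1] * 2:
            continue
        ac = np.array([seg[:-k] @ seg[k:] for k in lags]) / denom
        if ac.max() >= threshold:
            return True
    return False


def exclude_transition_beats(beats: BeatSeries,
                             timeline: PhaseTimeline) -> BeatSeries:
    """Drop beats inside the transition exclusion windows.

    Motion artifacts occur systematically at arm elevation and lowering
    and masquerade as high-amplitude beats; removing them before the
    trailing smoothing keeps artifact amplitudes out of every window
    mean. Raises :class:`UninterpretableError` when fewer than two
    beats survive.
    """
    lo, hi = timeline.span()
    _, excluded = timeline.phase_of(np.clip(beats.times, lo, hi))
    keep = ~excluded
    if keep.sum() < 2:
        raise UninterpretableError("fewer than 2 beats outside transitions")
    return BeatSeries(times=beats.times[keep],
                      peak_values=beats.peak_values[keep],
                      trough_values=beats.trough_values[keep])


def pulse_amplitudes(beats: BeatSeries,
                     smoothing_points: int = SMOOTHING_POINTS) -> PulseAmplitudeSeries:
    """Per-beat A_pulse = peak - trough, smoothed by a trailing average.

    Smoothed value i is the mean of amplitudes [i-9, i]; the first nine
    values average over however many points are available (documented
    edge handling — the analysis windows never touch the record edge).
    """
    amps = beats.peak_values - beats.trough_values
    cums = np.concatenate([[0.0], np.cumsum(amps)])
    idx = np.arange(len(amps))
    start = np.maximum(0, idx - smoothing_points + 1)
    smoothed = (cums[idx + 1] - cums[start]) / (idx + 1 - start)
    return PulseAmplitudeSeries(times=beats.times.copy(), amplitudes=amps,
                                smoothed=smoothed)


def _window_mean(series: PulseAmplitudeSeries, window: tuple) -> float:
    mask = (series.times >= window[0]) & (series.times < window[1])
    if not mask.any():
        raise UninterpretableError(f"no beats in analysis window {window}")
    return float(series.smoothed[mask].mean())


def apulse_metrics(series: PulseAmplitudeSeries,
                   timeline: PhaseTimeline | None = None,
                   rest_window: tuple = REST_WINDOW,
                   su_window: tuple = SU_WINDOW,
                   pra_window: tuple = PRA_WINDOW) -> ApulseMetrics:
    """Windowed A_pulse means and the derived percent metrics.

    The rest window is [-20, -5] s when the recording extends that far
    back, otherwise the [-5, 0) calibration tail. Su uses [5, 20] s
    (clear of the elevation artifact), Pra uses [35, 40] s.
    """
    del timeline  # windows are absolute in manoeuvre-relative time
    has_early_rest = np.any((series.times >= rest_window[0])
                            & (series.times < rest_window[1]))
    rest = _window_mean(series, rest_window if has_early_rest
                        else REST_WINDOW_FALLBACK)
    su = _window_mean(series, su_window)
    pra = _window_mean(series, pra_window)
    if rest <= 0 or pra <= 0:
        raise UninterpretableError("non-positive reference amplitude")
    return ApulseMetrics(
        rest_mean=rest,
        su_mean=su,
        pra_mean=pra,
        su_vs_rest_percent=100.0 * (su - rest) / rest,
        remaining_pulsatility_percent=100.0 * su / rest,
        su_normalized_to_pra=100.0 * su / pra,
    )
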