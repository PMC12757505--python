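"""Forearm venous-volume analysis of the 4 Hz V-PPG channels.

The venous channel tracks slow forearm volume changes in arbitrary
units. The 5 s rest tail (arms down, full venous filling) defines zero
volume; increases from zero denote emptying. The maximum emptying over
the elevated phases (Su and Pra), expressed as a percentage of a
per-limb full-emptying reference, is the venous screening metric:
below 70% indicates venous entrapment, above 87% a normal response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, UninterpretableError
from .io import Channel
from .phases import PhaseTimeline

MIN_REST_SECONDS = 3.0
DEFAULT_SPIKE_FILTER_S = 0.5


@dataclass
class EmptyingSeries:
    """Rest-zeroed venous volume on the 4 Hz grid (raw units)."""

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


def calibrate_zero(venous, timeline: PhaseTimeline | None = None) -> EmptyingSeries:
    """Zero a venous channel on its rest-window mean.

    Accepts a raw :class:`~venoppg.io.Channel` or an already-zeroed
    :class:`EmptyingSeries` (in which case the operation is a no-op up
    to numerical precision — calibration is idempotent). Requires at
    least 3 s of valid rest samples.
    """
    timeline = timeline or PhaseTimeline()
    if isinstance(venous, EmptyingSeries):
        times, values, valid = venous.times, venous.values, venous.valid
        rate = venous.sampling_rate
    else:
        times, values, valid = venous.times, venous.values, venous.valid
        rate = venous.sampling_rate
    rest_mask = (times >= timeline.rest_start) & (times < timeline.su_start) & valid
    if rest_mask.sum() < MIN_REST_SECONDS * rate:
        raise UninterpretableError(
            f"fewer than {MIN_REST_SECONDS} s of valid rest samples "
            "for venous zero calibration")
    zero = float(values[rest_mask].mean())
    return EmptyingSeries(times=times.copy(), values=values - zero,
                          valid=valid.copy(), sampling_rate=rate)


def max_emptying_percent(zeroed: EmptyingSeries, reference: float,
                         timeline: PhaseTimeline | None = None,
                         spike_filter_s: float = DEFAULT_SPIKE_FILTER_S) -> float:
    """Maximum venous emptying over Su and Pra, as % of the reference.

    Transition-excluded samples are dropped, a short median prefilter
    (default 0.5 s) suppresses single-sample spikes, and negative
    maxima (net filling) clamp to 0.
    """
    timeline = timeline or PhaseTimeline()
    if not reference > 0:
        raise ConfigurationError("full-emptying reference must be > 0")
    values = zeroed.values
    if spike_filter_s > 0:
        k = max(1, int(round(spike_filter_s * zeroed.sampling_rate)) | 1)
        values = ndimage.median_filter(values, size=k, mode="nearest")
    labels, excluded = timeline.phase_of(
        np.clip(zeroed.times, *timeline.span()))
    in_window = np.isin(labels, ("Su", "Pra")) & ~excluded & zeroed.valid
    in_window &= (zeroed.times >= timeline.su_start) & (zeroed.times < timeline.end_start)
    if not in_window.any():
        raise UninterpretableError("no usable venous samples in the Su/Pra window")
    return max(0.0, 100.0 * float(values[in_window].max()) / reference)
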