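"""Manoeuvre phase timeline.

The provocative manoeuvre is segmented into four phases relative to the
start of arm elevation (t = 0):

* ``Rest`` — arms alongside the torso, 5 s calibration tail ([-5, 0) s);
* ``Su``   — "surrender" position (90 deg abduction, elbows flexed), 30 s;
* ``Pra``  — "prayer" position (arms raised in front), 15 s;
* ``End``  — arms lowered and immobilised, 10 s.

Motion at each positional change produces transient artifacts, so samples
within ``transition_exclusion_halfwidth`` seconds of a movement onset
(Su, Pra and End onsets) are flagged and excluded from phase statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

PHASES = ("Rest", "Su", "Pra", "End")


@dataclass(frozen=True)
class PhaseTimeline:
    """Phase boundaries in seconds relative to manoeuvre start."""

    rest_start: float = -5.0
    su_start: float = 0.0
    pra_start: float = 30.0
    end_start: float = 45.0
    record_end: float = 55.0
    transition_exclusion_halfwidth: float = 2.0

    def __post_init__(self):
        bounds = (self.rest_start, self.su_start, self.pra_start,
                  self.end_start, self.record_end)
        if not all(np.isfinite(bounds)):
            raise ConfigurationError("timeline boundaries must be finite")
        if not all(a < b for a, b in zip(bounds, bounds[1:])):
            raise ConfigurationError(
                f"timeline boundaries must be strictly increasing, got {bounds}")
        if self.transition_exclusion_halfwidth < 0:
            raise ConfigurationError("transition_exclusion_halfwidth must be >= 0")

    @property
    def movement_onsets(self) -> tuple[float, float, float]:
        """Times of positional changes (Su, Pra, End onsets)."""
        return (self.su_start, self.pra_start, self.end_start)

    def phase_bounds(self, phase: str) -> tuple[float, float]:
        starts = {"Rest": self.rest_start, "Su": self.su_start,
                  "Pra": self.pra_start, "End": self.end_start}
        ends = {"Rest": self.su_start, "Su": self.pra_start,
                "Pra": self.end_start, "End": self.record_end}
        if phase not in starts:
            raise ConfigurationError(f"unknown phase {phase!r}")
        return starts[phase], ends[phase]

    def span(self) -> tuple[float, float]:
        return self.rest_start, self.record_end

    def phase_of(self, t):
        """Phase label(s) at time(s) ``t``.

        Returns (labels, excluded) where ``excluded`` marks samples within
        ``transition_exclusion_halfwidth`` of a movement onset. Scalar in,
        scalar out; array in, arrays out.

        Raises
        ------
        ConfigurationError
            If any ``t`` lies outside [rest_start, record_end].
        """
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        t_arr = np.atleast_1d(t_arr)
        if np.any(t_arr < self.rest_start) or np.any(t_arr > self.record_end):
            raise ConfigurationError(
                f"time outside recording span [{self.rest_start}, {self.record_end}]")
        edges = [self.su_start, self.pra_start, self.end_start]
        idx = np.searchsorted(edges, t_arr, side="right")
        labels = np.array(PHASES, dtype=object)[idx]
        excluded = np.zeros(t_arr.shape, dtype=bool)
        for onset in self.movement_onsets:
            excluded |= np.abs(t_arr - onset) < self.transition_exclusion_halfwidth
        if scalar:
            return labels[0], bool(excluded[0])
        return labels, excluded

    def to_dict(self) -> dict:
        return {
            "rest_start": self.rest_start,
            "su_start": self.su_start,
            "pra_start": self.pra_start,
            "end_start": self.end_start,
            "record_end": self.record_end,
            "transition_exclusion_halfwidth": self.transition_exclusion_halfwidth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseTimeline":
        return cls(**d)


def phase_of(timeline: PhaseTimeline, t):
    """Functional alias for :meth:`PhaseTimeline.phase_of`."""
    return timeline.phase_of(t)
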