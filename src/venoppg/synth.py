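"""Synthetic PPG cohort generator with known ground truth.

Emulates the study conditions of a provocative upper-limb manoeuvre
("surrender" then "prayer") recorded with simultaneous arterial (125 Hz,
fingertips + earlobe) and venous (4 Hz, forearms) photoplethysmography:

* group-specific sustained heart-rate offsets per phase, plus transient
  exponentially decaying HR peaks at each positional change;
* arterial pulse trains built from a two-Gaussian systolic/dicrotic beat
  template, scaled by a phase-dependent amplitude envelope (elevation
  raises fingertip pulse amplitude in normal limbs and suppresses it
  under arterial compression);
* venous channels as first-order exponential approaches to a
  phase-dependent target volume (zero at rest, a subject-specific
  emptying plateau while the arms are elevated, refilling at the end);
* motion artifacts at positional changes, additive noise, and occasional
  sample dropout.

Every recording carries a :class:`GroundTruth` with the exact beat
times, amplitude envelope and emptying plateaus used, so downstream
beat detection, venous calibration, classification and statistics can
be validated against known values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (ARTERIAL_RATE_HZ, VENOUS_RATE_HZ, Channel, PPGRecording)
from .phases import PHASES, PhaseTimeline

GROUP_LABELS = ("venous", "control", "arterial_compressed", "grey_zone",
                "uninterpretable")

#: Fraction of the cardiac cycle at which the systolic peak of the beat
#: template sits; ground-truth peak times are onset + this fraction * period.
TEMPLATE_PEAK_FRACTION = 0.3


@dataclass
class SubjectParams:
    """Generating parameters for one synthetic subject.

    ``phase_hr_effects`` maps phase name to the sustained HR offset
    (bpm) added to ``baseline_hr`` during that phase; Rest is implicitly
    zero. ``transition_peak`` is the amplitude (bpm) of the transient HR
    surge at each positional change, decaying with time constant
    ``transition_tau`` (s). Venous emptying plateaus are percentages of
    the per-limb full-emptying reference.
    """

    group_label: str = "control"
    baseline_hr: float = 80.0
    phase_hr_effects: dict = field(default_factory=dict)
    transition_peak: float = 0.0
    transition_tau: float = 2.0
    venous_emptying_max_left: float = 95.0
    venous_emptying_max_right: float = 95.0
    venous_tau: float = 2.0
    arterial_rest_amp: float = 1.0
    arterial_su_amp_factor: float = 1.2
    arterial_pra_amp_factor: float = 1.2
    hr_noise_sd: float = 0.0

    def __post_init__(self):
        if self.group_label not in GROUP_LABELS:
            raise ConfigurationError(f"unknown group label {self.group_label!r}")
        scalars = [self.baseline_hr, self.transition_peak, self.transition_tau,
                   self.venous_emptying_max_left, self.venous_emptying_max_right,
                   self.venous_tau, self.arterial_rest_amp,
                   self.arterial_su_amp_factor, self.arterial_pra_amp_factor,
                   self.hr_noise_sd, *self.phase_hr_effects.values()]
        if not all(math.isfinite(v) for v in scalars):
            raise ConfigurationError("subject parameters must be finite")
        if not 30.0 <= self.baseline_hr <= 220.0:
            raise ConfigurationError("baseline_hr must lie in [30, 220] bpm")
        for side, v in (("left", self.venous_emptying_max_left),
                        ("right", self.venous_emptying_max_right)):
            if not 0.0 <= v <= 100.0:
                raise ConfigurationError(
                    f"venous_emptying_max_{side} must lie in [0, 100] %")
        if self.arterial_su_amp_factor <= 0 or self.arterial_pra_amp_factor <= 0:
            raise ConfigurationError("arterial amplitude factors must be > 0")
        if self.transition_tau <= 0 or self.venous_tau <= 0:
            raise ConfigurationError("time constants must be > 0")
        if self.arterial_rest_amp < 0 or self.hr_noise_sd < 0:
            raise ConfigurationError("amplitudes and noise SDs must be >= 0")
        unknown = set(self.phase_hr_effects) - set(PHASES)
        if unknown:
            raise ConfigurationError(f"unknown phases in phase_hr_effects: {unknown}")


@dataclass
class NoiseParams:
    """Measurement imperfections added on top of the clean signals."""

    arterial_noise_sd: float = 0.02
    venous_noise_sd: float = 0.05
    artifact_prob_per_transition: float = 1.0
    artifact_duration: float = 1.5
    artifact_amplitude_factor: float = 4.0
    dropout_prob: float = 0.005

    def __post_init__(self):
        for name in ("artifact_prob_per_transition", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if (self.arterial_noise_sd < 0 or self.venous_noise_sd < 0
                or self.artifact_duration < 0 or self.artifact_amplitude_factor < 0):
            raise ConfigurationError("noise SDs, durations and amplitudes must be >= 0")

    @classmethod
    def none(cls) -> "NoiseParams":
        """Noise-free configuration (clean signals, no artifacts, no dropout)."""
        return cls(arterial_noise_sd=0.0, venous_noise_sd=0.0,
                   artifact_prob_per_transition=0.0, dropout_prob=0.0)


@dataclass
class GroundTruth:
    """Exact generating quantities recorded alongside a synthetic recording."""

    subject_id: str
    params: SubjectParams
    beat_onset_times: np.ndarray
    beat_peak_times: np.ndarray
    beat_periods: np.ndarray
    beat_amplitudes: dict  # finger channel name -> per-beat envelope value
    emptying_plateau_percent: dict  # side -> configured plateau %
    hr_times: np.ndarray
    hr_bpm: np.ndarray

    @property
    def group_label(self) -> str:
        return self.params.group_label


def _sustained_offset(params: SubjectParams, timeline: PhaseTimeline,
                      t: np.ndarray) -> np.ndarray:
    """Sustained phase HR offset (bpm) at each time (Rest -> 0)."""
    labels, _ = timeline.phase_of(np.clip(t, *timeline.span()))
    out = np.zeros(len(t))
    for phase in PHASES:
        out[labels == phase] = params.phase_hr_effects.get(phase, 0.0)
    return out


def _transients(params: SubjectParams, timeline: PhaseTimeline,
                t: np.ndarray) -> np.ndarray:
    """Sum of exponentially decaying HR transients at movement onsets."""
    out = np.zeros(len(t))
    for onset in timeline.movement_onsets:
        dt = t - onset
        mask = dt >= 0
        out[mask] += params.transition_peak * np.exp(-dt[mask] / params.transition_tau)
    return out


def hr_trajectory(params: SubjectParams, timeline: PhaseTimeline | None = None,
                  rng: np.random.Generator | None = None,
                  sample_rate_hz: float = 10.0):
    """Instantaneous heart-rate trajectory sampled at ``sample_rate_hz``.

    HR(t) = baseline + sustained phase offset + decaying transients at
    each movement onset + white jitter (SD ``params.hr_noise_sd``).

    Returns ``(times, hr)``; HR is floored at 1 bpm so the trajectory is
    strictly positive even under extreme jitter.
    """
    timeline = timeline or PhaseTimeline()
    lo, hi = timeline.span()
    n = int(round((hi - lo) * sample_rate_hz)) + 1
    t = lo + np.arange(n) / sample_rate_hz
    hr = (params.baseline_hr
          + _sustained_offset(params, timeline, t)
          + _transients(params, timeline, t))
    if params.hr_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        hr = hr + rng.normal(0.0, params.hr_noise_sd, size=n)
    return t, np.maximum(hr, 1.0)


def beats_from_hr(t: np.ndarray, hr: np.ndarray) -> np.ndarray:
    """Beat onset times by integrate-and-fire on the instantaneous rate.

    The accumulator integrates HR/60 (beats per second); a beat fires at
    every unit threshold crossing. Crossing times are located by linear
    interpolation on a 1 kHz refinement of the trajectory.
    """
    fine_t = np.arange(t[0], t[-1], 1e-3)
    fine_hr = np.interp(fine_t, t, hr)
    phase = np.concatenate([[0.0], np.cumsum(
        (fine_hr[1:] + fine_hr[:-1]) / 2.0 * np.diff(fine_t) / 60.0)])
    n_beats = int(np.floor(phase[-1]))
    if n_beats < 1:
        return np.empty(0)
    thresholds = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(phase, thresholds)
    # linear interpolation of the crossing inside each fine step
    frac = (thresholds - phase[idx - 1]) / (phase[idx] - phase[idx - 1])
    return fine_t[idx - 1] + frac * (fine_t[idx] - fine_t[idx - 1])


# Two-Gaussian beat template (systolic peak + dicrotic wave) on the unit
# cycle, range-normalised so that max - min = 1 and min = 0.
_TPL_GRID = np.linspace(0.0, 1.0, 2001)


def _template_raw(u: np.ndarray) -> np.ndarray:
    return (np.exp(-0.5 * ((u - TEMPLATE_PEAK_FRACTION) / 0.10) ** 2)
            + 0.45 * np.exp(-0.5 * ((u - 0.65) / 0.14) ** 2))


_TPL_MIN = float(_template_raw(_TPL_GRID).min())
_TPL_RANGE = float(_template_raw(_TPL_GRID).max() - _TPL_MIN)


def beat_template(u: np.ndarray) -> np.ndarray:
    """Peak-normalised beat shape on the unit cycle (min 0, max 1)."""
    return (_template_raw(np.asarray(u, dtype=float)) - _TPL_MIN) / _TPL_RANGE


def _amplitude_envelope(params: SubjectParams, timeline: PhaseTimeline,
                        t: np.ndarray) -> np.ndarray:
    """Per-phase arterial amplitude at fingertip level."""
    labels, _ = timeline.phase_of(np.clip(t, *timeline.span()))
    amp = np.full(len(t), params.arterial_rest_amp)
    amp[labels == "Su"] = params.arterial_rest_amp * params.arterial_su_amp_factor
    amp[labels == "Pra"] = params.arterial_rest_amp * params.arterial_pra_amp_factor
    return amp


def _pulse_train(sample_t: np.ndarray, onsets: np.ndarray,
                 amplitudes: np.ndarray) -> np.ndarray:
    """Arterial waveform: template per cycle scaled by the beat amplitude.

    Cycles before the first and after the last onset reuse the adjacent
    period so the record has no flat gaps.
    """
    if len(onsets) < 2:
        return np.zeros(len(sample_t))
    periods = np.diff(onsets)
    # virtual beats pad the span ends so there are no flat gaps
    n_pre = max(0, int(np.ceil((onsets[0] - sample_t[0]) / periods[0])))
    pre = onsets[0] - periods[0] * np.arange(n_pre, 0, -1)
    n_post = max(0, int(np.ceil((sample_t[-1] - onsets[-1]) / periods[-1])))
    post = onsets[-1] + periods[-1] * np.arange(1, n_post + 1)
    ext_onsets = np.concatenate([pre, onsets, post])
    ext_periods = np.append(np.diff(ext_onsets), periods[-1])
    ext_amps = np.concatenate([
        np.full(n_pre, amplitudes[0]), amplitudes,
        np.full(n_post, amplitudes[-1])])
    cycle = np.clip(np.searchsorted(ext_onsets, sample_t, side="right") - 1,
                    0, len(ext_onsets) - 1)
    u = (sample_t - ext_onsets[cycle]) / ext_periods[cycle]
    return ext_amps[cycle] * beat_template(np.clip(u, 0.0, 1.0))


def _venous_curve(sample_t: np.ndarray, target_of_phase: dict,
                  timeline: PhaseTimeline, tau: float) -> np.ndarray:
    """Piecewise first-order exponential approach to per-phase targets."""
    bounds = [timeline.rest_start, timeline.su_start, timeline.pra_start,
              timeline.end_start, timeline.record_end]
    out = np.empty(len(sample_t))
    v0 = target_of_phase["Rest"]
    for phase, t0, t1 in zip(PHASES, bounds[:-1], bounds[1:]):
        target = target_of_phase[phase]
        mask = (sample_t >= t0 - 1e-12) & (sample_t < t1)
        out[mask] = target + (v0 - target) * np.exp(-(sample_t[mask] - t0) / tau)
        v0 = target + (v0 - target) * np.exp(-(t1 - t0) / tau)
    return out


def _artifact_wave(sample_t: np.ndarray, onset: float, duration: float,
                   amplitude: float) -> np.ndarray:
    """Motion artifact: a Hann-windowed burst starting at a movement onset."""
    if duration <= 0:
        return np.zeros(len(sample_t))
    rel = (sample_t - onset) / duration
    mask = (rel >= 0) & (rel <= 1)
    wave = np.zeros(len(sample_t))
    wave[mask] = amplitude * np.sin(np.pi * rel[mask]) ** 2
    return wave


def generate_recording(params: SubjectParams,
                       noise: NoiseParams | None = None,
                       seed: int = 0,
                       timeline: PhaseTimeline | None = None,
                       subject_id: str = "S000",
                       venous_reference: float = 20.0):
    """Simulate one multichannel PPG recording; returns (recording, truth).

    Arterial channels are pulse trains at 125 Hz (beat times from
    integrate-and-fire on the HR trajectory; fingertip amplitudes follow
    the phase envelope, the earlobe amplitude is positional-invariant).
    Venous channels are 4 Hz first-order emptying/refilling curves plus
    a constant baseline, expressed in arbitrary units against a per-limb
    full-emptying reference. A ``group_label`` of ``uninterpretable``
    zeroes the arterial pulse amplitude so no beats are detectable.
    """
    noise = noise if noise is not None else NoiseParams()
    timeline = timeline or PhaseTimeline()
    rng = np.random.default_rng(seed)

    hr_t, hr = hr_trajectory(params, timeline, rng=rng)
    onsets = beats_from_hr(hr_t, hr)
    if len(onsets) < 2:
        raise ConfigurationError("trajectory yields fewer than two beats")
    periods = np.diff(onsets)
    periods = np.append(periods, periods[-1])
    peak_times = onsets + TEMPLATE_PEAK_FRACTION * periods

    lo, hi = timeline.span()
    n_art = int(round((hi - lo) * ARTERIAL_RATE_HZ))
    art_t = lo + np.arange(n_art) / ARTERIAL_RATE_HZ
    n_ven = int(round((hi - lo) * VENOUS_RATE_HZ))
    ven_t = lo + np.arange(n_ven) / VENOUS_RATE_HZ

    rest_amp = params.arterial_rest_amp
    finger_amp = _amplitude_envelope(params, timeline, onsets)
    ear_amp = np.full(len(onsets), rest_amp)
    # slow respiratory/venous drift under the pulsatile component
    drift = 0.3 * rest_amp * np.sin(2 * np.pi * 0.05 * (art_t - lo)) + 2.0 * rest_amp

    channels: dict[str, Channel] = {}
    beat_amplitudes: dict[str, np.ndarray] = {}
    artifact_hit = {onset: rng.random() < noise.artifact_prob_per_transition
                    for onset in timeline.movement_onsets}
    for name in ("finger_left", "finger_right", "ear"):
        amps = ear_amp if name == "ear" else finger_amp
        sig = _pulse_train(art_t, onsets, amps) + drift
        for onset, hit in artifact_hit.items():
            if hit:
                sig = sig + _artifact_wave(
                    art_t, onset, noise.artifact_duration,
                    noise.artifact_amplitude_factor * max(rest_amp, 1e-3))
        if noise.arterial_noise_sd > 0:
            sig = sig + rng.normal(0.0, noise.arterial_noise_sd, size=n_art)
        valid = rng.random(n_art) >= noise.dropout_prob
        channels[name] = Channel(name, ARTERIAL_RATE_HZ, art_t, sig, valid)
        beat_amplitudes[name] = amps.copy()

    plateaus = {"left": params.venous_emptying_max_left,
                "right": params.venous_emptying_max_right}
    for side in ("left", "right"):
        target = venous_reference * plateaus[side] / 100.0
        targets = {"Rest": 0.0, "Su": target, "Pra": target, "End": 0.0}
        sig = _venous_curve(ven_t, targets, timeline, params.venous_tau)
        sig = sig + 0.05 * venous_reference  # device baseline offset
        if noise.venous_noise_sd > 0:
            sig = sig + rng.normal(0.0, noise.venous_noise_sd, size=n_ven)
        valid = rng.random(n_ven) >= noise.dropout_prob
        channels[f"venous_{side}"] = Channel(
            f"venous_{side}", VENOUS_RATE_HZ, ven_t, sig, valid)

    rec = PPGRecording(
        subject_id=subject_id,
        channels=channels,
        timeline=timeline,
        venous_full_emptying_reference_left=venous_reference,
        venous_full_emptying_reference_right=venous_reference,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        params=params,
        beat_onset_times=onsets,
        beat_peak_times=peak_times,
        beat_periods=periods,
        beat_amplitudes=beat_amplitudes,
        emptying_plateau_percent=plateaus,
        hr_times=hr_t,
        hr_bpm=hr,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort-level generation

def _norm(mean: float, sd: float, lo: float, hi: float):
    return {"mean": mean, "sd": sd, "lo": lo, "hi": hi}


#: Per-group generating distributions. HR parameters follow the study's
#: group summaries (sustained phase offsets and their SDs; absolute rest
#: HR); venous plateaus centre the entrapment group at 55% and the
#: normal response at 95%, with truncation keeping clear margins to the
#: 70%/87% classification thresholds. The transient surge defaults to
#: ~4.1 bpm so that, stacked on the sustained offset, peak HR reaches
#: roughly 11 bpm (venous) and 6 bpm (control) above baseline at the
#: elevation transition.
DEFAULT_GROUP_DISTRIBUTIONS: dict = {
    "venous": {
        "baseline_hr": _norm(81.5, 10.1, 45.0, 160.0),
        "su_offset": _norm(6.9, 7.1, -25.0, 40.0),
        "pra_offset": _norm(7.2, 8.4, -25.0, 40.0),
        "end_offset": _norm(6.3, 6.9, -25.0, 40.0),
        "transition_peak": _norm(4.1, 1.0, 0.0, 15.0),
        "emptying": _norm(55.0, 5.0, 30.0, 63.5),
        "su_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
        "pra_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
    },
    "control": {
        "baseline_hr": _norm(84.9, 13.4, 45.0, 160.0),
        "su_offset": _norm(1.9, 4.2, -25.0, 40.0),
        "pra_offset": _norm(4.3, 5.8, -25.0, 40.0),
        "end_offset": _norm(4.1, 6.1, -25.0, 40.0),
        "transition_peak": _norm(4.1, 1.0, 0.0, 15.0),
        "emptying": _norm(95.0, 3.0, 92.5, 100.0),
        "su_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
        "pra_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
    },
    "arterial_compressed": {
        "baseline_hr": _norm(84.9, 13.4, 45.0, 160.0),
        "su_offset": _norm(1.9, 4.2, -25.0, 40.0),
        "pra_offset": _norm(4.3, 5.8, -25.0, 40.0),
        "end_offset": _norm(4.1, 6.1, -25.0, 40.0),
        "transition_peak": _norm(4.1, 1.0, 0.0, 15.0),
        "emptying": _norm(50.0, 5.0, 40.0, 64.0),
        "su_amp_factor": _norm(0.05, 0.015, 0.02, 0.08),
        "pra_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
    },
    "grey_zone": {
        "baseline_hr": _norm(84.9, 13.4, 45.0, 160.0),
        "su_offset": _norm(1.9, 4.2, -25.0, 40.0),
        "pra_offset": _norm(4.3, 5.8, -25.0, 40.0),
        "end_offset": _norm(4.1, 6.1, -25.0, 40.0),
        "transition_peak": _norm(4.1, 1.0, 0.0, 15.0),
        "emptying": _norm(78.0, 2.0, 76.0, 81.0),
        "su_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
        "pra_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
    },
    "uninterpretable": {
        "baseline_hr": _norm(84.9, 13.4, 45.0, 160.0),
        "su_offset": _norm(1.9, 4.2, -25.0, 40.0),
        "pra_offset": _norm(4.3, 5.8, -25.0, 40.0),
        "end_offset": _norm(4.1, 6.1, -25.0, 40.0),
        "transition_peak": _norm(4.1, 1.0, 0.0, 15.0),
        "emptying": _norm(95.0, 3.0, 92.5, 100.0),
        "su_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
        "pra_amp_factor": _norm(1.2, 0.05, 1.05, 1.5),
    },
}

DEFAULT_HR_NOISE_SD = 1.5
DEFAULT_TRANSITION_TAU = 2.0
DEFAULT_VENOUS_TAU = 2.0

#: Ground-truth composition of the full referral cohort: 41 patients
#: with clean bilateral phenotypes (17 venous entrapment, 24 normal)
#: plus 75 excluded-category patients. The study flow-chart gives only
#: the total excluded count, so the split across the three exclusion
#: phenotypes is even (25/25/25).
STUDY_COHORT_COUNTS = {"venous": 17, "control": 24,
                       "arterial_compressed": 25, "grey_zone": 25,
                       "uninterpretable": 25}

#: Composition of the retained analysis cohort only.
ANALYSIS_COHORT_COUNTS = {"venous": 17, "control": 24}


@dataclass
class CohortConfig:
    """How many subjects per ground-truth group and how to draw them."""

    counts: dict = field(default_factory=dict)  # group label -> int
    distributions: dict = field(default_factory=lambda: DEFAULT_GROUP_DISTRIBUTIONS)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    hr_noise_sd: float = DEFAULT_HR_NOISE_SD

    def __post_init__(self):
        for label, n in self.counts.items():
            if label not in GROUP_LABELS:
                raise ConfigurationError(f"unknown group label {label!r}")
            if int(n) != n or n < 0:
                raise ConfigurationError(f"count for {label!r} must be a non-negative int")
        if self.hr_noise_sd < 0:
            raise ConfigurationError("hr_noise_sd must be >= 0")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.counts.values()))


def _draw(rng: np.random.Generator, spec: dict) -> float:
    return float(np.clip(rng.normal(spec["mean"], spec["sd"]),
                         spec["lo"], spec["hi"]))


def draw_subject_params(group: str, rng: np.random.Generator,
                        distributions: dict | None = None,
                        hr_noise_sd: float = DEFAULT_HR_NOISE_SD) -> SubjectParams:
    """Draw one subject's generating parameters from the group distribution."""
    dist = (distributions or DEFAULT_GROUP_DISTRIBUTIONS)[group]
    return SubjectParams(
        group_label=group,
        baseline_hr=_draw(rng, dist["baseline_hr"]),
        phase_hr_effects={
            "Su": _draw(rng, dist["su_offset"]),
            "Pra": _draw(rng, dist["pra_offset"]),
            "End": _draw(rng, dist["end_offset"]),
        },
        transition_peak=_draw(rng, dist["transition_peak"]),
        transition_tau=DEFAULT_TRANSITION_TAU,
        venous_emptying_max_left=_draw(rng, dist["emptying"]),
        venous_emptying_max_right=_draw(rng, dist["emptying"]),
        venous_tau=DEFAULT_VENOUS_TAU,
        arterial_rest_amp=0.0 if group == "uninterpretable" else 1.0,
        arterial_su_amp_factor=_draw(rng, dist["su_amp_factor"]),
        arterial_pra_amp_factor=_draw(rng, dist["pra_amp_factor"]),
        hr_noise_sd=hr_noise_sd,
    )


def generate_cohort(config: CohortConfig,
                    timeline: PhaseTimeline | None = None) -> list:
    """Generate a full cohort; returns a list of (recording, truth) pairs.

    Subject parameters and per-subject recording seeds derive
    deterministically from ``config.seed``, so identical configs
    reproduce identical cohorts bit for bit.
    """
    timeline = timeline or PhaseTimeline()
    master = np.random.default_rng(np.random.SeedSequence(config.seed))
    rec_seeds = np.random.SeedSequence(config.seed).generate_state(
        max(config.n_subjects, 1))
    out = []
    i = 0
    for group in GROUP_LABELS:
        for _ in range(int(config.counts.get(group, 0))):
            params = draw_subject_params(group, master, config.distributions,
                                         config.hr_noise_sd)
            rec, truth = generate_recording(
                params, config.noise, seed=int(rec_seeds[i]),
                timeline=timeline, subject_id=f"S{i + 1:03d}")
            out.append((rec, truth))
            i += 1
    return out


def ground_truth_table(cohort: list) -> pd.DataFrame:
    """Tabulate the generating ground truth of a cohort (one row/subject)."""
    rows = []
    for _, truth in cohort:
        p = truth.params
        rows.append({
            "subject_id": truth.subject_id,
            "group_label": p.group_label,
            "baseline_hr": p.baseline_hr,
            "su_offset": p.phase_hr_effects.get("Su", 0.0),
            "pra_offset": p.phase_hr_effects.get("Pra", 0.0),
            "end_offset": p.phase_hr_effects.get("End", 0.0),
            "transition_peak": p.transition_peak,
            "emptying_left": p.venous_emptying_max_left,
            "emptying_right": p.venous_emptying_max_right,
            "su_amp_factor": p.arterial_su_amp_factor,
            "n_beats": len(truth.beat_onset_times),
        })
    return pd.DataFrame(rows, columns=[
        "subject_id", "group_label", "baseline_hr", "su_offset", "pra_offset",
        "end_offset", "transition_peak", "emptying_left", "emptying_right",
        "su_amp_factor", "n_beats"])
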