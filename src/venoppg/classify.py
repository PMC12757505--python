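"""Per-limb and per-patient vascular-compression classification.

Each limb is screened with two metrics: remaining arterial pulsatility
during elevation (% of rest) and maximum venous emptying (% of the
full-emptying reference). Thresholds, applied as strict inequalities
exactly as printed:

* remaining pulsatility < 25%  -> arterial compression (dominates: an
  occluded artery invalidates the venous emptying reading);
* else venous emptying < 70%   -> venous compression;
* else venous emptying > 87%   -> normal;
* otherwise                    -> grey zone (70-87%).

Patients enter the venous group only with *bilateral* pure venous
compression and the control group only with bilaterally normal limbs;
every other pattern is excluded, mirroring the study's restrictive
selection flow-chart.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import math

ARTERIAL_REMAINING_THRESHOLD = 25.0
VENOUS_EMPTYING_LOW = 70.0
VENOUS_EMPTYING_HIGH = 87.0

LIMB_STATUSES = ("arterial_compression", "venous_compression", "normal",
                 "grey_zone", "uninterpretable")
GROUP_LABELS = ("V_group", "C_group", "excluded_arterial",
                "excluded_venous_unilateral_or_insufficient",
                "excluded_grey_zone", "excluded_uninterpretable")


@dataclass
class LimbStatus:
    """Screening metrics and the resulting status for one limb."""

    remaining_pulsatility_percent: float
    max_emptying_percent: float
    status: str

    @classmethod
    def uninterpretable(cls, reason: str = "") -> "LimbStatus":
        limb = cls(float("nan"), float("nan"), "uninterpretable")
        limb.reason = reason
        return limb


def classify_limb(remaining_pulsatility_percent: float,
                  max_emptying_percent: float) -> LimbStatus:
    """Deterministic partition of the (pulsatility, emptying) plane."""
    r, e = float(remaining_pulsatility_percent), float(max_emptying_percent)
    if not (math.isfinite(r) and math.isfinite(e)):
        return LimbStatus.uninterpretable("non-finite limb metrics")
    if r < ARTERIAL_REMAINING_THRESHOLD:
        status = "arterial_compression"
    elif e < VENOUS_EMPTYING_LOW:
        status = "venous_compression"
    elif e > VENOUS_EMPTYING_HIGH:
        status = "normal"
    else:
        status = "grey_zone"
    return LimbStatus(r, e, status)


def classify_patient(left: LimbStatus, right: LimbStatus) -> str:
    """Patient group from the two limb statuses (exactly one label)."""
    statuses = (left.status, right.status)
    if "uninterpretable" in statuses:
        return "excluded_uninterpretable"
    if "arterial_compression" in statuses:
        return "excluded_arterial"
    if "grey_zone" in statuses:
        return "excluded_grey_zone"
    if statuses == ("venous_compression", "venous_compression"):
        return "V_group"
    if statuses == ("normal", "normal"):
        return "C_group"
    return "excluded_venous_unilateral_or_insufficient"


def flowchart(group_labels) -> dict:
    """Flow-chart accounting: count of patients per group label.

    Accepts any iterable of patient group labels; returns a dict with
    every label (zero-filled) plus ``total`` and ``retained`` (patients
    entering either analysis group).
    """
    counts = Counter(group_labels)
    unknown = set(counts) - set(GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    out = {label: int(counts.get(label, 0)) for label in GROUP_LABELS}
    out["total"] = int(sum(counts.values()))
    out["retained"] = out["V_group"] + out["C_group"]
    return out


def flowchart_report(counts: dict) -> str:
    """Plain-text rendering of the selection flow-chart."""
    lines = [
        f"Patients analysed:                  {counts['total']:4d}",
        f"  excluded, arterial compression:   {counts['excluded_arterial']:4d}",
        f"  excluded, unilateral/mixed venous:{counts['excluded_venous_unilateral_or_insufficient']:4d}",
        f"  excluded, grey-zone emptying:     {counts['excluded_grey_zone']:4d}",
        f"  excluded, uninterpretable:        {counts['excluded_uninterpretable']:4d}",
        f"Retained for analysis:              {counts['retained']:4d}",
        f"  venous group (V):                 {counts['V_group']:4d}",
        f"  control group (C):                {counts['C_group']:4d}",
    ]
    return "\n".join(lines)
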