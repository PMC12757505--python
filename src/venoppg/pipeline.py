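"""End-to-end workflow: simulate -> analyze -> classify -> stats.

Each stage is a plain function over the library modules so it can be
driven from Python, the examples, or the thin command-line interface.
All stages are deterministic given (config, seed); ``run_simulate``
writes a manifest with content hashes so reruns can be verified.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, heartrate, pulse, venous
from .errors import UninterpretableError, VenoppgError
from .io import PPGRecording, read_recording, write_recording
from .phases import PHASES
from .stats import build_long_table, emm_contrasts, fit_group_phase_model
from .synth import CohortConfig, generate_cohort, ground_truth_table

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "subject_id",
    "remaining_left", "remaining_right",
    "emptying_left", "emptying_right",
    "limb_status_left", "limb_status_right",
    "group_label", "reason",
    "rest_median_hr",
    "median_delta_rest", "median_delta_su", "median_delta_pra",
    "median_delta_end",
]


def analyze_recording(rec: PPGRecording) -> dict:
    """Analyse one patient: limb metrics, classification, HR medians.

    Uninterpretable limbs or channels never abort the run; they
    propagate as an ``uninterpretable`` limb status / missing HR
    summary with a reason code.
    """
    timeline = rec.timeline
    row: dict = {c: np.nan for c in RESULT_COLUMNS}
    row["subject_id"] = rec.subject_id
    reasons = []
    limbs = {}
    for side in ("left", "right"):
        try:
            filtered = pulse.highpass(rec.channels[f"finger_{side}"])
            beats = pulse.exclude_transition_beats(
                pulse.detect_beats(filtered), timeline)
            amps = pulse.pulse_amplitudes(beats)
            metrics = pulse.apulse_metrics(amps, timeline)
            zeroed = venous.calibrate_zero(rec.channels[f"venous_{side}"],
                                           timeline)
            emptying = venous.max_emptying_percent(
                zeroed, rec.venous_reference(side), timeline)
            limb = classify.classify_limb(
                metrics.remaining_pulsatility_percent, emptying)
        except UninterpretableError as exc:
            limb = classify.LimbStatus.uninterpretable(str(exc))
            reasons.append(f"{side}: {exc}")
        limbs[side] = limb
        row[f"remaining_{side}"] = limb.remaining_pulsatility_percent
        row[f"emptying_{side}"] = limb.max_emptying_percent
        row[f"limb_status_{side}"] = limb.status
    row["group_label"] = classify.classify_patient(limbs["left"],
                                                   limbs["right"])
    try:
        hr = heartrate.extract_hr(rec.channels["ear"], timeline)
        hr = heartrate.repair_artifacts(hr)
        normalized = heartrate.normalize_hr(hr, timeline)
        summary = heartrate.phase_medians(normalized, timeline,
                                          subject_id=rec.subject_id)
        row["rest_median_hr"] = normalized.rest_median
        for phase in PHASES:
            row[f"median_delta_{phase.lower()}"] = summary.medians[phase]
    except UninterpretableError as exc:
        reasons.append(f"ear: {exc}")
        if row["group_label"] in ("V_group", "C_group"):
            row["group_label"] = "excluded_uninterpretable"
    row["reason"] = "; ".join(reasons)
    return row


def analyze_cohort(recordings) -> pd.DataFrame:
    """Per-subject results table for an iterable of recordings."""
    return pd.DataFrame([analyze_recording(rec) for rec in recordings],
                        columns=RESULT_COLUMNS)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulate(config: CohortConfig, out_dir, force: bool = False) -> Path:
    """Generate a cohort and write recordings + ground truth + manifest."""
    out = Path(out_dir)
    recordings_dir = out / "recordings"
    if recordings_dir.exists() and any(recordings_dir.iterdir()) and not force:
        raise VenoppgError(
            f"output directory {recordings_dir} is not empty (use force=True)")
    recordings_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    paths = []
    for rec, _ in cohort:
        paths.append(write_recording(rec, recordings_dir))
    truth = ground_truth_table(cohort)
    truth_path = out / "ground_truth.csv"
    truth.to_csv(truth_path, index=False, lineterminator="\n")
    manifest = {}
    for base in paths:
        for f in sorted(base.iterdir()):
            manifest[str(f.relative_to(out))] = _sha256(f)
    manifest[str(truth_path.relative_to(out))] = _sha256(truth_path)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("simulated %d subjects into %s", len(cohort), recordings_dir)
    return out


def run_analyze(recordings_dir, results_path=None) -> pd.DataFrame:
    """Analyse every recording directory under ``recordings_dir``.

    Unreadable recordings are retained as uninterpretable rows (reason
    logged), so one corrupt file never kills a cohort run.
    """
    recordings_dir = Path(recordings_dir)
    rows = []
    subject_dirs = sorted(p for p in recordings_dir.iterdir() if p.is_dir()) \
        if recordings_dir.exists() else []
    for sub in subject_dirs:
        try:
            rec = read_recording(sub)
            rows.append(analyze_recording(rec))
        except Exception as exc:
            logger.warning("recording %s unreadable: %s", sub.name, exc)
            row = {c: np.nan for c in RESULT_COLUMNS}
            row.update(subject_id=sub.name,
                       group_label="excluded_uninterpretable",
                       limb_status_left="uninterpretable",
                       limb_status_right="uninterpretable",
                       reason=f"unreadable recording: {exc}")
            rows.append(row)
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if results_path is not None:
        results.to_csv(results_path, index=False, lineterminator="\n")
    return results


def results_to_phase_summaries(results: pd.DataFrame):
    """Rebuild PhaseSummary objects and label map from a results table."""
    summaries = []
    labels = {}
    for _, row in results.iterrows():
        labels[row["subject_id"]] = row["group_label"]
        medians = {p: row[f"median_delta_{p.lower()}"] for p in PHASES}
        if all(np.isfinite(list(medians.values()))):
            summaries.append(heartrate.PhaseSummary(
                subject_id=row["subject_id"], medians=medians))
    return summaries, labels


def run_stats(results: pd.DataFrame, out_dir=None, single_family: bool = False,
              figures: bool = False):
    """Mixed-model contrasts + diagnostics (+ optional figures) from results."""
    summaries, labels = results_to_phase_summaries(results)
    table = build_long_table(summaries, labels)
    fit = fit_group_phase_model(table)
    contrasts = emm_contrasts(fit, single_family=single_family)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        contrasts.to_csv(out / "contrasts.csv", index=False,
                         lineterminator="\n")
        diag = {
            "emm": {g: {p: fit.emm.loc[g, p] for p in PHASES}
                    for g in fit.emm.index},
            "random_intercept_var": fit.random_intercept_var,
            "residual_var": fit.residual_var,
            "n_obs": fit.n_obs, "n_subjects": fit.n_subjects,
            "singular": fit.singular, **fit.diagnostics,
        }
        with open(out / "diagnostics.json", "w", encoding="utf-8") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)
            fh.write("\n")
        if figures:
            from .plots import plot_phase_distributions
            plot_phase_distributions(table, out / "phase_distributions.png")
    return fit, contrasts


def run_all(config: CohortConfig, out_dir, force: bool = False,
            single_family: bool = False, figures: bool = False):
    """simulate + analyze + classify + stats in one deterministic pass."""
    out = Path(out_dir)
    run_simulate(config, out, force=force)
    results = run_analyze(out / "recordings", out / "results.csv")
    counts = classify.flowchart(results["group_label"])
    with open(out / "flowchart.json", "w", encoding="utf-8") as fh:
        json.dump(counts, fh, indent=1, sort_keys=True)
        fh.write("\n")
    (out / "flowchart.txt").write_text(
        classify.flowchart_report(counts) + "\n", encoding="utf-8")
    fit, contrasts = run_stats(results, out / "stats",
                               single_family=single_family, figures=figures)
    return results, counts, fit, contrasts
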