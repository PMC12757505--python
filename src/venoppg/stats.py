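"""Group x phase mixed-model analysis of normalized heart rate.

Per-patient per-phase medians of normalized HR are modelled with a
linear mixed model: group, phase and their interaction as fixed
effects and a random intercept per patient (REML). Estimated marginal
means (EMMs) are the model-implied cell means at each group x phase
combination; pairwise EMM contrasts are reported between groups within
each phase and between phases within each group, with Holm step-down
adjustment of the p-values within each contrast family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.api as sm

from .errors import ConfigurationError
from .phases import PHASES

logger = logging.getLogger(__name__)

GROUPS = ("C", "V")  # C is the reference level
PHASE_PAIRS = [(b, a) for a, b in combinations(PHASES, 2)]  # later - earlier


def build_long_table(phase_summaries, group_labels: dict) -> pd.DataFrame:
    """Long-format table (subject, group, phase, median_delta_hr).

    Only patients labelled ``V_group`` or ``C_group`` are retained;
    everyone else is dropped with a logged warning. One row per
    subject x phase; Rest rows are zero by construction upstream.
    """
    rows = []
    for summary in phase_summaries:
        label = group_labels.get(summary.subject_id)
        if label not in ("V_group", "C_group"):
            logger.warning("subject %s has label %s; dropped from the model",
                           summary.subject_id, label)
            continue
        group = "V" if label == "V_group" else "C"
        for phase in PHASES:
            if phase not in summary.medians:
                logger.warning("subject %s missing phase %s; row omitted",
                               summary.subject_id, phase)
                continue
            rows.append({"subject_id": summary.subject_id, "group": group,
                         "phase": phase,
                         "median_delta_hr": summary.medians[phase]})
    return pd.DataFrame(rows, columns=["subject_id", "group", "phase",
                                       "median_delta_hr"])


def _design_row(group: str, phase: str) -> np.ndarray:
    """Fixed-effect design row (treatment coding, C/Rest reference)."""
    x = np.zeros(8)
    x[0] = 1.0
    x[1] = 1.0 if group == "V" else 0.0
    for j, p in enumerate(("Su", "Pra", "End")):
        if phase == p:
            x[2 + j] = 1.0
            x[5 + j] = x[1]
    return x


DESIGN_COLUMNS = ["Intercept", "group[V]", "phase[Su]", "phase[Pra]",
                  "phase[End]", "group[V]:phase[Su]", "group[V]:phase[Pra]",
                  "group[V]:phase[End]"]


@dataclass
class ModelFit:
    """Fitted group x phase mixed model with EMMs and diagnostics."""

    beta: np.ndarray
    cov_beta: np.ndarray
    random_intercept_var: float
    residual_var: float
    emm: pd.DataFrame            # index: group, columns: phase
    df_resid: float
    n_obs: int
    n_subjects: int
    singular: bool
    diagnostics: dict = field(default_factory=dict)


def fit_group_phase_model(table: pd.DataFrame) -> ModelFit:
    """REML fit of median normalized HR on group x phase + patient intercept.

    A singular or non-converging mixed fit (e.g. on noise-free
    fixtures with zero residual variance) falls back to ordinary least
    squares for the fixed effects, reported via ``singular`` in the
    result — never fatal. On complete balanced designs the EMMs equal
    the raw cell means.
    """
    for g in GROUPS:
        n_sub = table.loc[table["group"] == g, "subject_id"].nunique()
        if n_sub < 2:
            raise ConfigurationError(
                f"group {g}: need >= 2 subjects for the mixed model, got {n_sub}")
    X = np.vstack([_design_row(g, p)
                   for g, p in zip(table["group"], table["phase"])])
    y = table["median_delta_hr"].to_numpy(dtype=float)
    groups = table["subject_id"].to_numpy()
    singular = False
    beta = cov_beta = None
    re_var = resid_var = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            result = model.fit(reml=True)
        beta = np.asarray(result.fe_params)
        cov_beta = np.asarray(result.cov_params())[:8, :8]
        re_var = float(np.asarray(result.cov_re).ravel()[0])
        resid_var = float(result.scale)
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov_beta))):
            raise np.linalg.LinAlgError("non-finite mixed-model estimates")
        singular = bool(getattr(result, "converged", True) is False)
    except Exception as exc:  # singular / non-converged fits
        logger.warning("mixed model fit failed (%s); falling back to OLS", exc)
        singular = True
        ols = sm.OLS(y, X).fit()
        beta = np.asarray(ols.params)
        cov_beta = np.asarray(ols.cov_params())
        re_var = 0.0
        resid_var = float(ols.scale)
    emm = pd.DataFrame(
        {p: [float(_design_row(g, p) @ beta) for g in GROUPS] for p in PHASES},
        index=list(GROUPS))
    resid = y - X @ beta
    diagnostics = {"converged": not singular}
    try:
        if np.ptp(resid) > 0:
            w_stat, w_p = spstats.shapiro(resid)
            diagnostics["shapiro_w"] = float(w_stat)
            diagnostics["shapiro_p"] = float(w_p)
        cells = [resid[(table["group"] == g) & (table["phase"] == p)]
                 for g in GROUPS for p in PHASES]
        cells = [c for c in cells if len(c) > 1 and np.ptp(c) > 0]
        if len(cells) >= 2:
            l_stat, l_p = spstats.levene(*cells)
            diagnostics["levene_stat"] = float(l_stat)
            diagnostics["levene_p"] = float(l_p)
    except Exception as exc:
        diagnostics["diagnostic_error"] = str(exc)
    return ModelFit(
        beta=beta, cov_beta=cov_beta, random_intercept_var=re_var,
        residual_var=resid_var, emm=emm,
        df_resid=float(len(y) - len(beta)), n_obs=len(y),
        n_subjects=int(table["subject_id"].nunique()),
        singular=singular, diagnostics=diagnostics)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of one family of p-values.

    Sorted ascending, adjusted(i) = max_{j<=i} min(1, (m-j) * p(j))
    (0-based j), mapped back to the input order. Monotone and never
    below the raw p-value.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def emm_contrasts(fit: ModelFit, single_family: bool = False) -> pd.DataFrame:
    """Pairwise EMM contrasts with Holm-adjusted p-values.

    Three families by default: V - C within each phase (4 contrasts),
    and the 6 phase pairs within each group (two families of 6),
    matching the default family structure of pairwise EMM machinery.
    ``single_family`` pools all 16 contrasts into one Holm family.
    Degrees of freedom use the residual method (n_obs - n_fixed).
    """
    rows = []
    for phase in PHASES:
        c = _design_row("V", phase) - _design_row("C", phase)
        rows.append(("V_group - C_group", phase, "between", c))
    for g in GROUPS[::-1]:  # V block first, as conventionally reported
        for late, early in PHASE_PAIRS:
            c = _design_row(g, late) - _design_row(g, early)
            rows.append((f"{late} - {early}", f"{g}_group", f"within_{g}", c))
    records = []
    for label, reference, family, c in rows:
        est = float(c @ fit.beta)
        var = float(c @ fit.cov_beta @ c)
        se = float(np.sqrt(max(var, 0.0)))
        if se > 0:
            t = est / se
            p = 2.0 * float(spstats.t.sf(abs(t), fit.df_resid))
        else:  # degenerate (zero-variance) contrast, e.g. Rest rows
            t = 0.0 if est == 0 else np.inf * np.sign(est)
            p = 1.0 if est == 0 else 0.0
        records.append({"contrast": label, "reference": reference,
                        "estimate": est, "se": se, "df": fit.df_resid,
                        "t_ratio": t, "p_raw": p,
                        "family": "all" if single_family else family})
    out = pd.DataFrame(records)
    out["p_holm"] = np.nan
    for family in out["family"].unique():
        mask = out["family"] == family
        out.loc[mask, "p_holm"] = holm_adjust(out.loc[mask, "p_raw"])
    out["significance"] = [_stars(p) for p in out["p_holm"]]
    return out
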