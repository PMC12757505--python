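"""Mixed model, EMM contrasts and Holm adjustment."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from venoppg.errors import ConfigurationError
from venoppg.heartrate import PhaseSummary
from venoppg.phases import PHASES
from venoppg.stats import (build_long_table, emm_contrasts,
                           fit_group_phase_model, holm_adjust)


def make_table(means_v, means_c, n_v=6, n_c=8, subject_sd=0.0, resid_sd=0.0,
               seed=0):
    """Balanced long table with known cell means (+ optional noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, means, n in (("V", means_v, n_v), ("C", means_c, n_c)):
        for i in range(n):
            u = rng.normal(0, subject_sd) if subject_sd else 0.0
            for phase, mean in zip(PHASES, means):
                e = rng.normal(0, resid_sd) if resid_sd else 0.0
                rows.append({"subject_id": f"{group}{i}", "group": group,
                             "phase": phase, "median_delta_hr": mean + u + e})
    return pd.DataFrame(rows)


def cell_means(table):
    return table.groupby(["group", "phase"], sort=False)[
        "median_delta_hr"].mean()


class TestBuildLongTable:
    def summaries(self, n, offset=0.0):
        return [PhaseSummary(subject_id=f"P{i}",
                             medians={p: (0.0 if p == "Rest" else offset)
                                      for p in PHASES})
                for i in range(n)]

    def test_two_patients_give_eight_rows(self):
        labels = {"P0": "V_group", "P1": "C_group"}
        table = build_long_table(self.summaries(2), labels)
        assert len(table) == 8
        assert set(table["group"]) == {"V", "C"}

    def test_excluded_patients_dropped(self, caplog):
        labels = {"P0": "V_group", "P1": "excluded_grey_zone"}
        with caplog.at_level("WARNING"):
            table = build_long_table(self.summaries(2), labels)
        assert len(table) == 4
        assert "P1" in caplog.text

    def test_study_sized_cohort_gives_164_rows(self):
        labels = {f"P{i}": ("V_group" if i < 17 else "C_group")
                  for i in range(41)}
        table = build_long_table(self.summaries(41), labels)
        assert len(table) == 164


class TestFitGroupPhaseModel:
    def test_noise_free_emms_equal_cell_means(self):
        """Degenerate zero-variance fixture: EMMs still equal the cell
        means {0,5,5,5} vs {0,1,1,1} to 1e-6 (OLS fallback path)."""
        table = make_table([0, 5, 5, 5], [0, 1, 1, 1])
        fit = fit_group_phase_model(table)
        for phase, v in zip(PHASES, [0, 5, 5, 5]):
            assert fit.emm.loc["V", phase] == pytest.approx(v, abs=1e-6)
        for phase, c in zip(PHASES, [0, 1, 1, 1]):
            assert fit.emm.loc["C", phase] == pytest.approx(c, abs=1e-6)

    def test_balanced_emms_match_cell_mean_oracle(self):
        """On balanced data the mixed-model EMMs coincide with the raw
        cell means (saturated fixed-effects design)."""
        table = make_table([0, 6.9, 7.2, 6.3], [0, 1.9, 4.3, 4.1],
                           n_v=17, n_c=17, subject_sd=2.0, resid_sd=3.0,
                           seed=3)
        fit = fit_group_phase_model(table)
        oracle = cell_means(table)
        for (g, p), mean in oracle.items():
            assert fit.emm.loc[g, p] == pytest.approx(mean, abs=1e-6)

    def test_variance_components_recovered(self):
        """Simulating from the model (200 subjects, intercept var 4,
        residual var 1) recovers the random-intercept variance within
        30%."""
        table = make_table([0, 5, 5, 5], [0, 1, 1, 1], n_v=100, n_c=100,
                           subject_sd=2.0, resid_sd=1.0, seed=11)
        fit = fit_group_phase_model(table)
        assert not fit.singular
        assert fit.random_intercept_var == pytest.approx(4.0, rel=0.3)
        assert fit.residual_var == pytest.approx(1.0, rel=0.3)

    def test_too_few_subjects_rejected(self):
        table = make_table([0, 5, 5, 5], [0, 1, 1, 1], n_v=1, n_c=5)
        with pytest.raises(ConfigurationError):
            fit_group_phase_model(table)


class TestEmmContrasts:
    def test_sixteen_contrasts_in_three_families(self):
        table = make_table([0, 5, 5, 5], [0, 1, 1, 1], subject_sd=1.0,
                           resid_sd=1.0, seed=2)
        con = emm_contrasts(fit_group_phase_model(table))
        assert len(con) == 16
        assert con["family"].value_counts().to_dict() == {
            "between": 4, "within_V": 6, "within_C": 6}

    def test_estimates_match_cell_mean_differences(self):
        table = make_table([0, 6.9, 7.2, 6.3], [0, 1.9, 4.3, 4.1],
                           n_v=17, n_c=24, subject_sd=2.0, resid_sd=3.0,
                           seed=5)
        con = emm_contrasts(fit_group_phase_model(table))
        oracle = cell_means(table)
        for _, row in con.iterrows():
            if row["contrast"] == "V_group - C_group":
                expected = oracle[("V", row["reference"])] \
                    - oracle[("C", row["reference"])]
            else:
                late, early = row["contrast"].split(" - ")
                g = row["reference"][0]
                expected = oracle[(g, late)] - oracle[(g, early)]
            assert row["estimate"] == pytest.approx(expected, abs=1e-6)

    def test_rest_contrast_exactly_zero(self):
        """Both groups are normalized to zero at rest, so the between-
        group Rest contrast is identically 0 with p = 1."""
        table = make_table([0, 6.9, 7.2, 6.3], [0, 1.9, 4.3, 4.1],
                           n_v=10, n_c=10, subject_sd=1.0, seed=6)
        # Rest rows are exactly zero (no residual noise on Rest)
        table.loc[table["phase"] == "Rest", "median_delta_hr"] = 0.0
        con = emm_contrasts(fit_group_phase_model(table))
        rest = con[(con["contrast"] == "V_group - C_group")
                   & (con["reference"] == "Rest")].iloc[0]
        assert rest["estimate"] == pytest.approx(0.0, abs=1e-9)
        assert rest["p_holm"] == pytest.approx(1.0, abs=1e-6)

    def test_null_case_large_p(self):
        """Identical generating means in both groups: between-group
        estimates near zero, adjusted p near 1."""
        table = make_table([0, 3, 3, 3], [0, 3, 3, 3], n_v=20, n_c=20,
                           subject_sd=2.0, resid_sd=2.0, seed=7)
        con = emm_contrasts(fit_group_phase_model(table))
        between = con[con["family"] == "between"]
        assert np.abs(between["estimate"]).max() < 2.0
        assert between["p_holm"].min() > 0.2

    def test_single_family_mode(self):
        table = make_table([0, 5, 5, 5], [0, 1, 1, 1], subject_sd=1.0,
                           resid_sd=1.0, seed=8)
        con = emm_contrasts(fit_group_phase_model(table), single_family=True)
        assert set(con["family"]) == {"all"}


class TestHolmAdjust:
    def test_single_p_identity(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 7))
            adj = holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_reference_implementation(self):
        """Agreement with the independent step-down implementation in
        statsmodels for random families."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 7))
            np.testing.assert_allclose(
                holm_adjust(p), multipletests(p, method="holm")[1],
                atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            holm_adjust([0.5, 1.2])
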