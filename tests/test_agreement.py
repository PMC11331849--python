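"""Bland-Altman and absolute-agreement ICC: hand oracles, an independent
package cross-check, parameter recovery, and study-style stratification."""

import math

import numpy as np
import pandas as pd
import pytest

from octcaliper import (
    AgreementReport,
    InsufficientDataError,
    MeasurementRecord,
    PairedSample,
    bland_altman,
    icc_absolute,
    stratified_report,
)


def paired(a, b):
    a = np.asarray(a, dtype=float)
    return PairedSample(labels=tuple(f"u{i}" for i in range(a.size)), a=a, b=np.asarray(b, dtype=float))


def anova_icc_oracle(x):
    """Direct two-way ANOVA by explicit loops: the by-hand computation."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (row.mean() - grand) ** 2 for row in x)
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((v - grand) ** 2 for v in x.ravel())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestBlandAltman:
    def test_identical_series_perfect_agreement(self):
        r = bland_altman(paired([1, 2, 3, 4], [1, 2, 3, 4]))
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_hand_computed_limits(self):
        # differences {+10, -10}: sample SD = sqrt(200)
        r = bland_altman(paired([110.0, 90.0], [100.0, 100.0]))
        assert r.bias == 0.0
        assert r.loa_high == pytest.approx(1.96 * math.sqrt(200.0))
        assert r.loa_low == pytest.approx(-1.96 * math.sqrt(200.0))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(400, 30, 50), rng.normal(400, 30, 50)
        r0 = bland_altman(paired(a, b))
        c = 17.5
        r1 = bland_altman(paired(a, b + c))
        assert r1.bias == pytest.approx(r0.bias - c, abs=1e-10)
        assert (r1.loa_high - r1.loa_low) == pytest.approx(r0.loa_high - r0.loa_low, abs=1e-10)

    def test_plot_points_returned(self):
        r = bland_altman(paired([110.0, 90.0], [100.0, 100.0]))
        assert np.allclose(r.means, [105.0, 95.0])
        assert np.allclose(r.diffs, [10.0, -10.0])

    def test_single_pair_insufficient(self):
        with pytest.raises(InsufficientDataError):
            PairedSample(labels=("u0",), a=np.array([1.0]), b=np.array([2.0]))


class TestIccAbsolute:
    def test_toy_matrix_matches_by_hand_anova(self):
        # MS_R = 40/3, MS_C = 2, MS_E = 0 -> ICC = (40/3)/(40/3 + 1) = 40/43
        x = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], dtype=float)
        r = icc_absolute(x)
        assert r.icc == pytest.approx(40.0 / 43.0, abs=1e-12)
        assert r.ms_subjects == pytest.approx(40.0 / 3.0)
        assert r.ms_raters == pytest.approx(2.0)
        assert r.ms_error == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns_perfect_agreement(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc_absolute(x).icc == pytest.approx(1.0)

    def test_matches_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for n, k in [(6, 2), (10, 3), (25, 4)]:
            x = rng.normal(100, 10, (n, k)) + rng.normal(0, 5, (n, 1))
            assert icc_absolute(x).icc == pytest.approx(anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        # independent cross-check of estimate, CI, and F-test p-value
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(15)
        x = rng.normal(0, 3, (20, 3)) + rng.normal(0, 6, (20, 1))
        df = pd.DataFrame(x, columns=["r1", "r2", "r3"]).reset_index(names="subject")
        long = df.melt(id_vars="subject", var_name="rater", value_name="score")
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        row = ref[ref.Type.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        r = icc_absolute(x)
        assert r.icc == pytest.approx(row.ICC, abs=1e-9)
        # pingouin reports the CI rounded to 2 decimals
        assert r.ci_low == pytest.approx(row.CI95[0], abs=5.1e-3)
        assert r.ci_high == pytest.approx(row.CI95[1], abs=5.1e-3)
        assert r.p_value == pytest.approx(row.pval, rel=1e-6)

    def test_parameter_recovery_at_known_variance_components(self):
        # population ICC = s_subj / (s_subj + s_rater + s_err)
        rng = np.random.default_rng(100)
        n, k = 500, 2
        s_subj, s_rater, s_err = 100.0, 1.0, 4.0
        pop = s_subj / (s_subj + s_rater + s_err)
        subj = rng.normal(0, math.sqrt(s_subj), (n, 1))
        rater = rng.normal(0, math.sqrt(s_rater), (1, k))
        x = subj + rater + rng.normal(0, math.sqrt(s_err), (n, k))
        r = icc_absolute(x)
        assert abs(r.icc - pop) < 0.02
        assert r.ci_low <= r.icc <= r.ci_high
        assert r.p_value < 1e-6

    def test_invariant_to_subject_relabeling_and_global_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(50, 8, (12, 2))
        base = icc_absolute(x).icc
        assert icc_absolute(x[rng.permutation(12)]).icc == pytest.approx(base, abs=1e-12)
        assert icc_absolute(x + 1000.0).icc == pytest.approx(base, abs=1e-9)

    def test_rater_offset_strictly_reduces_absolute_agreement(self):
        rng = np.random.default_rng(4)
        # genuine subject variance so the baseline ICC is positive
        x = rng.normal(0, 2, (12, 2)) + rng.normal(50, 20, (12, 1))
        shifted = x.copy()
        shifted[:, 1] += 25.0
        assert icc_absolute(shifted).icc < icc_absolute(x).icc

    def test_constant_matrix_flagged_degenerate(self):
        r = icc_absolute(np.full((5, 2), 7.0))
        assert r.degenerate and math.isnan(r.icc)

    def test_shape_and_completeness_checks(self):
        with pytest.raises(InsufficientDataError):
            icc_absolute(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc_absolute(np.array([[1.0, np.nan], [2.0, 3.0]]))


def make_records(values):
    """values: dict (eye, machine, observer, parameter) -> value."""
    return [
        MeasurementRecord(e, m, o, p, v, 1.0) for (e, m, o, p), v in values.items()
    ]


def grid_records(n_eyes=8, machines=("A", "B"), observers=("o1", "o2"), f=None):
    vals = {}
    rng = np.random.default_rng(0)
    for i in range(n_eyes):
        for m in machines:
            for o in observers:
                for p in ("MLD", "BD", "HH_nasal", "HH_temporal"):
                    base = 100.0 * (i + 1) + {"MLD": 0, "BD": 200, "HH_nasal": 50, "HH_temporal": 60}[p]
                    v = base if f is None else f(i, m, o, p, base, rng)
                    vals[(f"eye{i}", m, o, p)] = v
    return make_records(vals)


class TestStratifiedReport:
    def test_study_shape_pair_counts(self):
        reports = stratified_report(grid_records(), stratify_by="observer", group_by="machine")
        by_label = {r.label: r for r in reports}
        assert by_label["A"].n_subjects == 32  # 8 eyes x 4 parameters
        assert by_label["B"].n_subjects == 32
        assert by_label["pooled"].n_subjects == 64

    def test_identical_observers_agree_perfectly(self):
        reports = stratified_report(grid_records(), stratify_by="observer")
        (pooled,) = reports
        assert pooled.bias == 0.0
        assert pooled.icc == pytest.approx(1.0)

    def test_machine_offset_breaks_absolute_but_not_consistency_agreement(self):
        recs = grid_records(f=lambda i, m, o, p, base, rng: base + (50.0 if m == "B" else 0.0))
        (pooled,) = stratified_report(recs, stratify_by="machine")
        assert pooled.bias == pytest.approx(-50.0)  # A - B
        assert pooled.icc < 1.0
        # consistency-type correlation is untouched by a constant offset
        a = np.array([v.value_um for v in recs if v.machine == "A" and v.observer == "o1"])
        b = np.array([v.value_um for v in recs if v.machine == "B" and v.observer == "o1"])
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_machine_mode_averages_observers_first(self):
        # observer readings differ by +-10 around the base; their mean equals
        # the base, so the machine comparison sees zero bias
        recs = grid_records(
            f=lambda i, m, o, p, base, rng: base + (10.0 if o == "o1" else -10.0)
        )
        (pooled,) = stratified_report(recs, stratify_by="machine")
        assert pooled.bias == pytest.approx(0.0, abs=1e-12)
        assert pooled.icc == pytest.approx(1.0)

    def test_parameter_grouping_emits_per_parameter_reports(self):
        reports = stratified_report(grid_records(), stratify_by="observer", group_by="parameter")
        labels = [r.label for r in reports]
        assert labels[:4] == ["MLD", "BD", "HH_nasal", "HH_temporal"]
        assert labels[-1] == "pooled"
        assert all(r.n_subjects == 16 for r in reports[:4])  # 8 eyes x 2 machines

    def test_filters_restrict_records(self):
        reports = stratified_report(
            grid_records(), stratify_by="observer", filters={"parameter": ["MLD"]}
        )
        assert reports[-1].n_subjects == 16

    def test_unmatched_units_logged_and_excluded(self):
        recs = grid_records()
        dropped = recs.pop(0)  # eye0/A/o1/MLD loses one side
        (pooled,) = stratified_report(recs, stratify_by="observer")
        assert pooled.n_subjects == 63
        assert any("eye0" in e and "MLD" in e for e in pooled.excluded)

    def test_insufficient_pairs_raises(self):
        recs = grid_records(n_eyes=8)
        only_two = [r for r in recs if r.eye_id == "eye0" and r.parameter == "MLD"]
        # a single (eye, machine, parameter) unit per machine -> 1 pair each
        with pytest.raises(InsufficientDataError):
            stratified_report(only_two, stratify_by="observer", group_by="machine")

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            stratified_report(grid_records(), stratify_by="grader")
        with pytest.raises(ValueError):
            stratified_report(grid_records(), stratify_by="machine", group_by="machine")

    def test_report_serialisable(self):
        (pooled,) = stratified_report(grid_records(), stratify_by="observer")
        d = pooled.to_dict()
        assert d["label"] == "pooled" and d["n_raters"] == 2
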