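"""Grading data model, usability arithmetic, rank/regression statistics."""

import json

import numpy as np
import pandas as pd
import pytest

from fivedct.errors import EmptyInputError, RankDeficiencyError, UndefinedCorrelationError
from fivedct.qa import (
    REPORT_ELEMENTS,
    GradeRecord,
    assemble_report,
    generate_grade_table,
    multiple_regression,
    spearman_ci,
    stp_proxy,
    usability_summary,
)


def brute_force_spearman(x, y):
    """Independent oracle: explicit average ranks + Pearson on the ranks."""

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx * rx).sum() * (ry * ry).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        rho, ci, p = spearman_ci([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        rho, _, _ = spearman_ci([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 5, 60)  # heavy ties, like a grade table
        y = np.clip(x + rng.integers(-1, 2, 60), 1, 4)
        rho, ci, p = spearman_ci(x, y)
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-8)
        assert ci[0] <= rho <= ci[1]

    def test_tied_heavy_table_recovers_latent_correlation(self):
        df = generate_grade_table(2000, seed=3)
        rho, _, _ = spearman_ci(df["dir_quality"], df["breathing_irregularity"])
        # latent Gaussian correlation 0.35; discretization attenuates it
        oracle = brute_force_spearman(df["dir_quality"], df["breathing_irregularity"])
        assert rho == pytest.approx(oracle, abs=1e-8)
        assert abs(rho - 0.35) < 0.1

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_ci([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_bootstrap_ci_contains_estimate(self):
        df = generate_grade_table(80, seed=4)
        rho, ci, _ = spearman_ci(df["dir_quality"], df["stp"],
                                 ci_method="bootstrap", seed=0)
        assert ci[0] <= rho <= ci[1]


class TestRegression:
    def test_perfect_fit(self):
        x = np.arange(1.0, 31.0)
        res = multiple_regression(2 * x, pd.DataFrame({"x": x}))
        assert res.params["x"] == pytest.approx(2.0)
        assert res.r2_adj == pytest.approx(1.0)
        assert res.std_beta["x"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        res = multiple_regression(y, X)
        D = np.column_stack([np.ones(40), X.to_numpy()])
        coef = np.linalg.solve(D.T @ D, D.T @ y)
        assert res.params["const"] == pytest.approx(coef[0], abs=1e-8)
        for k, name in enumerate("abc", start=1):
            assert res.params[name] == pytest.approx(coef[k], abs=1e-8)

    def test_null_model_has_small_standardized_betas(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        y = rng.normal(size=500)
        res = multiple_regression(y, X)
        assert all(abs(b) < 0.15 for b in res.std_beta.values())
        assert abs(res.r2_adj) < 0.05

    def test_planted_coefficients_covered_by_ci(self):
        """Coefficient recovery at the clinical sample size (n = 169)."""
        true_b = {"breathing_irregularity": 0.13, "fhfbct_quality": 0.29,
                  "dir_quality": 0.40}
        names = list(true_b)
        hits = {k: 0 for k in names}
        n_rep = 60
        for seed in range(n_rep):
            df = generate_grade_table(
                169, stp_coeffs=(1.0, 0.13, 0.29, 0.40), seed=seed)
            res = multiple_regression(df["stp_score"].to_numpy(), df[names])
            for k in names:
                lo, hi = res.conf_int[k]
                hits[k] += lo <= true_b[k] <= hi
        for k in names:
            assert hits[k] / n_rep >= 0.90

    def test_collinear_predictors_raise(self):
        x = np.arange(20.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RankDeficiencyError):
            multiple_regression(x, X)


class TestUsability:
    @staticmethod
    def _table(counts):
        """counts maps category -> n."""
        rows = []
        i = 0
        for cat, n in counts.items():
            for _ in range(n):
                rows.append({"case_id": f"c{i}", "breathing_irregularity": 2,
                             "fhfbct_quality": 1, "dir_quality": 1, "stp": 2,
                             "usability_category": cat,
                             "mean_residual": 1.2, "p95_residual": 2.5})
                i += 1
        return pd.DataFrame(rows)

    def test_clinical_category_counts_total(self):
        df = self._table({1: 100, 2: 18, 3: 15, 4: 6, 5: 10, 6: 10, 7: 10})
        out = usability_summary(df)
        assert out["total"] == 169
        assert out["groups"]["used"]["count"] == 118
        assert out["groups"]["backup"]["count"] == 21
        assert out["groups"]["other"]["count"] == 30

    def test_everything_used_is_100_percent(self):
        out = usability_summary(self._table({1: 25}))
        assert out["groups"]["used"]["percent"] == 100

    def test_reported_clinical_percentages(self):
        df = self._table({1: 120, 2: 19, 3: 16, 4: 5, 5: 9})
        out = usability_summary(df)
        assert out["groups"]["used"]["count"] == 139
        assert out["groups"]["used"]["percent"] == 82
        assert out["groups"]["backup"]["percent"] == 12

    def test_group_counts_sum_to_total(self):
        df = generate_grade_table(500, seed=9)
        out = usability_summary(df)
        assert sum(g["count"] for g in out["groups"].values()) == out["total"]

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            usability_summary(pd.DataFrame())

    def test_grade_record_validation(self):
        with pytest.raises(ValueError):
            GradeRecord("x", 5, 1, 1, 1, 1, 0.5, 1.0)
        with pytest.raises(ValueError):
            GradeRecord("x", 2, 1, 1, 1, 9, 0.5, 1.0)


class TestGradeGenerator:
    def test_marginals_within_3_percent(self):
        marg = {"breathing_irregularity": [0.14, 0.39, 0.28, 0.19],
                "fhfbct_quality": [0.62, 0.33, 0.04, 0.01],
                "dir_quality": [0.57, 0.27, 0.09, 0.06]}
        df = generate_grade_table(10_000, marginals=marg, seed=10)
        for col, probs in marg.items():
            observed = df[col].value_counts(normalize=True).sort_index()
            for g, p in enumerate(probs, start=1):
                assert abs(observed.get(g, 0.0) - p) < 0.03

    def test_seed_reproducibility(self):
        a = generate_grade_table(100, seed=1)
        b = generate_grade_table(100, seed=1)
        pd.testing.assert_frame_equal(a, b)


class TestSpearmanProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.integers(1, 4), min_size=5, max_size=60),
           st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_on_arbitrary_grades(self, xs, data):
        ys = data.draw(self.st.lists(self.st.integers(1, 4),
                                     min_size=len(xs), max_size=len(xs)))
        if len(set(xs)) == 1 or len(set(ys)) == 1:
            with pytest.raises(UndefinedCorrelationError):
                spearman_ci(xs, ys)
        else:
            rho, ci, _ = spearman_ci(xs, ys)
            assert rho == pytest.approx(brute_force_spearman(xs, ys), abs=1e-8)
            assert -1.0 <= ci[0] <= rho <= ci[1] <= 1.0


def test_stp_proxy_thresholds():
    assert [stp_proxy(v) for v in (0.5, 1.5, 3.0, 6.0)] == [1, 2, 3, 4]


class TestReport:
    def test_missing_sections_warn_and_round_trip(self, tmp_path):
        with pytest.warns(UserWarning, match="missing"):
            summary = assemble_report(tmp_path, acquisition={
                "scan_start_stop": {"n": 8}, "scan_ranges": {"modal": 24},
                "corrected_shifts": {}, "bellows_abdomen_correlation": 0.99})
        assert not summary["complete"]
        assert summary["elements_present"]["scan_start_stop"]
        assert not summary["elements_present"]["dir_overlays"]
        text1 = (tmp_path / "qa_summary.json").read_text()
        json.loads(text1)  # valid JSON
        reread = json.loads(text1)
        assert json.dumps(reread, indent=2, default=str) == json.dumps(
            json.loads(json.dumps(reread, indent=2, default=str)),
            indent=2, default=str)

    def test_element_manifest_covers_all_rows(self):
        assert len(REPORT_ELEMENTS) == 13
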