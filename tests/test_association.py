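"""Correlations, group contrasts and the linear-model battery."""

import numpy as np
import pandas as pd
import pytest

from somnocohort import association as A


class TestCorrelate:
    def test_identity_is_one(self):
        x = np.arange(10, dtype=float)
        assert A.correlate(x, x, "pearson").r == pytest.approx(1.0)
        assert A.correlate(x, x, "spearman").r == pytest.approx(1.0)

    def test_rank_invariance_of_spearman(self):
        y = np.arange(1, 20, dtype=float)
        x = np.exp(y / 3.0)  # monotone nonlinear transform
        assert A.correlate(x, y, "spearman").r == pytest.approx(1.0)
        assert A.correlate(x, y, "pearson").r < 1.0

    def test_antisorted_is_minus_one(self):
        x = np.arange(8, dtype=float)
        assert A.correlate(x, x[::-1], "spearman").r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            A.correlate(np.ones(5), np.arange(5.0), "pearson")

    def test_pairwise_complete(self):
        x = np.array([1, 2, np.nan, 4, 5.0])
        y = np.array([2, 4, 6, 8, np.nan])
        assert A.correlate(x, y, "pearson").n == 3


def _ols_oracle(X, y):
    """Closed-form normal-equations solution (independent of statsmodels)."""
    Xd = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


class TestFitLinearModel:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(12, 50))
            k = int(rng.integers(1, 6))
            X = rng.normal(size=(n, k))
            beta = rng.normal(size=k + 1)
            y = beta[0] + X @ beta[1:] + rng.normal(0, 0.5, n)
            data = pd.DataFrame(X, columns=[f"x{i}" for i in range(k)])
            data["y"] = y
            formula = "y ~ " + " + ".join(data.columns[:-1])
            results = A.fit_linear_model("m", data, formula)
            got = np.array([r.beta for r in results])
            expect = _ols_oracle(X, y)
            np.testing.assert_allclose(got, expect, rtol=1e-8)

    def test_planted_effect_near_noiseless(self):
        rng = np.random.default_rng(0)
        tst = rng.normal(6.5, 1, 400)
        data = pd.DataFrame({"tst_hours": tst,
                             "marker": 2.0 * tst + rng.normal(0, 1e-8, 400)})
        (_, r) = A.fit_linear_model("m", data, "marker ~ tst_hours")
        assert r.beta == pytest.approx(2.0, abs=1e-6)
        assert r.p < 1e-20
        assert r.ci_low <= r.beta <= r.ci_high

    def test_duplicate_covariate_is_rank_deficiency_error(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"x": rng.normal(size=30)})
        data["x2"] = data["x"]
        data["y"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear"):
            A.fit_linear_model("m", data, "y ~ x + x2")

    def test_listwise_deletion_reports_n(self):
        data = pd.DataFrame({"x": [1, 2, 3, np.nan, 5.0],
                             "y": [2, 4, 6, 8, 10.0]})
        results = A.fit_linear_model("m", data, "y ~ x")
        assert all(r.n == 4 for r in results)

    def test_unseen_factor_level_rejected(self):
        data = pd.DataFrame({
            "tst_hours": np.random.default_rng(2).normal(6.5, 1, 20),
            "age": 40, "gender": ["Female", "Male", "Unknown"] * 6 + ["Female"] * 2,
            "ethnicity": "Chinese",
        })
        with pytest.raises(ValueError, match="unregistered level"):
            A.fit_linear_model("m", data, A.MODEL_PRESETS["tst_demo"]())

    def test_reference_relabelling_leaves_betas_unchanged(self, monkeypatch):
        """Renaming factor labels while keeping the reference designation
        must not move any coefficient."""
        rng = np.random.default_rng(3)
        n = 120
        data = pd.DataFrame({
            "age": rng.integers(21, 70, n),
            "gender": rng.choice(["Female", "Male"], n),
            "ethnicity": rng.choice(["Chinese", "Indian", "Malay", "Others"], n),
            "tst_hours": rng.normal(6.5, 1, n),
        })
        before = A.fit_linear_model("m", data, A.MODEL_PRESETS["tst_demo"]())
        relabel = {"Female": "W", "Male": "M"}
        data2 = data.assign(gender=data["gender"].map(relabel))
        monkeypatch.setitem(A.FACTOR_LEVELS, "gender", ["W", "M"])
        after = A.fit_linear_model("m", data2, A.MODEL_PRESETS["tst_demo"]())
        np.testing.assert_allclose([r.beta for r in before], [r.beta for r in after],
                                   rtol=1e-12)


class TestCompareGroups:
    def test_identical_groups(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)])
        g = np.repeat(["a", "b"], 10)
        res = A.compare_groups(x, g)
        assert res.means[0] == res.means[1]
        assert res.p == pytest.approx(1.0)

    def test_paired_constant_shift(self):
        x = np.array([5.0, 6.5, 7.2, 8.0])
        res = A.compare_groups(x, paired_with=x + 0.3)
        assert res.means[1] - res.means[0] == pytest.approx(0.3)
        assert res.p < 1e-6  # zero-variance differences

    def test_chi_squared_on_categoricals(self):
        rng = np.random.default_rng(4)
        a = rng.choice(["x", "y"], 200)
        b = rng.choice(["p", "q"], 200)
        res = A.compare_groups(a, b, categorical=True)
        assert res.kind == "chi2" and 0 <= res.p <= 1

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            A.compare_groups(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))

    def test_planted_gender_gap_power(self):
        """A 0.28-h gap at the cohort's group sizes and SDs is detected at
        alpha=0.01 in most replicates."""
        rng = np.random.default_rng(5)
        hits = 0
        reps = 300
        for _ in range(reps):
            f = rng.normal(6.60, 1.00, 262)
            m = rng.normal(6.32, 0.98, 220)
            res = A.compare_groups(
                np.concatenate([f, m]), np.repeat(["F", "M"], [262, 220])
            )
            hits += res.p < 0.01
        assert hits / reps > 0.7


class TestCategorizeTST:
    @pytest.mark.parametrize(
        "hours,scheme,expected",
        [
            (4.9, "binary", "insufficient"),
            (8.0, "binary", "adequate"),
            (6.0, "binary", None),          # middle excluded from the contrast
            (7.0, "binary", None),          # adequate is strictly > 7
            (8.0, "three_level", "adequate"),
            (9.0, "three_level", "adequate"),  # >7 but <= 9
            (9.5, "three_level", "long"),
            (4.0, "three_level", "insufficient"),
            (5.0, "three_level", None),
        ],
    )
    def test_strata(self, hours, scheme, expected):
        assert A.categorize_tst(hours, scheme) == expected

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            A.categorize_tst(6, "quartiles")


class TestRunBattery:
    def test_deterministic_rerun(self, cohort_table):
        a = A.run_battery(cohort_table)
        b = A.run_battery(cohort_table)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_ltl_skipped_with_warning(self, cohort_table):
        table = cohort_table.drop(columns=["ltl_wgs_bp"])
        with pytest.warns(UserWarning, match="ltl_wgs_bp"):
            out = A.run_battery(table)
        assert not out["model_id"].str.contains("ltl_wgs_bp").any()
        assert out["model_id"].str.startswith("marker_m1").any()

    def test_missing_required_column_named(self, cohort_table):
        with pytest.raises(ValueError, match="tst_hours"):
            A.run_battery(cohort_table.drop(columns=["tst_hours"]))

    def test_recovers_planted_effect_directions(self, cohort_table):
        """On the default cohort, the planted TST effects carry the right
        signs: male and Malay negative, Indian and alcohol positive."""
        out = A.run_battery(cohort_table)
        demo = out[out["model_id"] == "tst_demo"].set_index("term")
        male = demo.loc[[t for t in demo.index if "Male" in t][0]]
        assert male["beta"] < 0
        malay = demo.loc[[t for t in demo.index if "Malay" in t][0]]
        indian = demo.loc[[t for t in demo.index if "Indian" in t][0]]
        assert malay["beta"] < 0 and indian["beta"] > 0
        alc = out[out["model_id"] == "tst_socio:alcohol"].set_index("term")
        assert alc.loc[[t for t in alc.index if "Yes" in t][0], "beta"] > 0
        grp = out[out["model_id"] == "ltl_group_binary:ltl_wgs_bp"].set_index("term")
        insufficient = grp.loc[[t for t in grp.index if "insufficient" in t][0]]
        assert insufficient["beta"] < 0  # shorter telomeres with short sleep
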