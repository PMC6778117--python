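"""Correlation, group-contrast and covariate-adjusted linear-model battery.

All regression models are Gaussian GLMs (ordinary least squares) fitted with
statsmodels through patsy formulas.  Categorical predictors are dummy-coded
against fixed, registered reference levels (:data:`FACTOR_LEVELS`): Female
for gender, Chinese for ethnicity, Public-housing for residence type, Others
for education, Manual-labor for occupation, "No" for alcohol / caffeine /
tea / green tea, Ex-smoker for smoking and Never/hardly for exercise.

Per fitted term the battery reports the coefficient, a Wald 95% CI
(beta +/- 1.96 * SE) and a two-sided p-value.  Rows with a missing value in
any model variable are dropped listwise and the per-fit n is reported.
p-values are raw: no multiple-testing adjustment is applied anywhere, and a
battery over many markers and factors will contain false positives at the
nominal rate.

Correlation conventions: Spearman rank correlation for a continuous value
against a discrete questionnaire response, Pearson for two continuous
values; both two-sided.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "CorrelationResult",
    "GroupComparison",
    "FACTOR_LEVELS",
    "MODEL_PRESETS",
    "MARKER_COLUMNS",
    "SOCIOECONOMIC_FACTORS",
    "LIFESTYLE_FACTORS",
    "correlate",
    "fit_linear_model",
    "compare_groups",
    "categorize_tst",
    "run_battery",
]

Z975 = 1.96  # Wald normal quantile for 95% CIs

#: Registered factor levels; the first level is the model reference.
FACTOR_LEVELS: dict[str, list[str]] = {
    "gender": ["Female", "Male"],
    "ethnicity": ["Chinese", "Indian", "Malay", "Others"],
    "residence_type": ["Public-housing", "Private"],
    "education": ["Others", "Secondary", "Tertiary"],
    "occupation": ["Manual-labor", "Service", "Office", "Unemployed-retired"],
    "income": ["Low", "Middle", "High"],
    "alcohol": ["No", "Yes"],
    "smoking": ["Ex-smoker", "Never", "Current"],
    "exercise": ["Never/hardly", "Sometimes", "Regular"],
    "caffeine": ["No", "Yes"],
    "tst_group_binary": ["adequate", "insufficient"],
    "tst_group_three": ["adequate", "insufficient", "long"],
}

#: CVD risk markers modelled against the sleep metrics.
MARKER_COLUMNS = [
    "bmi", "wc", "whtr", "bfp", "smp", "sbp", "dbp",
    "total_chol", "ldl", "hdl", "tg", "fbg", "resting_hr",
]
SOCIOECONOMIC_FACTORS = ["residence_type", "education", "occupation", "income"]
LIFESTYLE_FACTORS = ["alcohol", "smoking", "exercise", "caffeine"]


@dataclass(frozen=True)
class AssociationResult:
    model_id: str
    term: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    means: tuple[float, ...] | None
    statistic: float
    p: float
    kind: str


def _C(col: str) -> str:
    ref = FACTOR_LEVELS[col][0]
    return f"C({col}, Treatment(reference='{ref}'))"


def _base_covariates() -> str:
    return f"age + {_C('gender')} + {_C('ethnicity')}"


def _marker_formula(marker: str, sleep_terms: str) -> str:
    return f"{marker} ~ {_base_covariates()} + avg_daily_steps + {sleep_terms}"


#: Registered model presets.  Callables take the response (and, where needed,
#: the factor / sleep column) and return a patsy formula string.
MODEL_PRESETS = {
    # Marker ~ Age + Gender + Ethnicity + AverageDailyTotalSteps + TST
    "marker_m1": lambda marker: _marker_formula(marker, "tst_hours"),
    # ... + SE instead of TST
    "marker_m2": lambda marker: _marker_formula(marker, "se_pct"),
    # ... + TST + SE jointly
    "marker_m3": lambda marker: _marker_formula(marker, "tst_hours + se_pct"),
    # TST ~ Age + Gender + Ethnicity (+ SocioeconomicFactor)
    "tst_demo": lambda: f"tst_hours ~ {_base_covariates()}",
    "tst_socio": lambda factor: f"tst_hours ~ {_base_covariates()} + {_C(factor)}",
    # LTL ~ Age + Gender + Ethnicity + BMI + TST
    "ltl_tst": lambda ltl, tst="tst_hours": f"{ltl} ~ {_base_covariates()} + bmi + {tst}",
    "ltl_inter_age": lambda ltl: f"{ltl} ~ tst_hours * age + {_C('gender')} + {_C('ethnicity')} + bmi",
    "ltl_inter_gender": lambda ltl: f"{ltl} ~ tst_hours * {_C('gender')} + age + {_C('ethnicity')} + bmi",
    # LTL ~ covariates + TST stratum (adequate sleep as reference)
    "ltl_tst_group": lambda ltl, group_col: f"{ltl} ~ {_base_covariates()} + bmi + {_C(group_col)}",
}


def correlate(x, y, method: str) -> CorrelationResult:
    """Two-sided Spearman or Pearson correlation on pairwise-complete pairs."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        r, p = stats.pearsonr(x, y)
    return CorrelationResult(method=method, r=float(r), p=float(p), n=len(x))


def _validate_factor_levels(data: pd.DataFrame, formula: str) -> None:
    for col, levels in FACTOR_LEVELS.items():
        if f"C({col}," in formula and col in data.columns:
            seen = set(data[col].dropna().unique())
            unknown = seen - set(levels)
            if unknown:
                raise ValueError(
                    f"factor '{col}' has unregistered level(s) {sorted(unknown)}; "
                    f"registered levels are {levels}"
                )


def _check_rank(X: pd.DataFrame) -> None:
    # name columns involved in a linear dependency via QR with small R diagonal
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [
            X.columns[i]
            for i in range(arr.shape[1])
            if diag[i] < 1e-8 * max(diag.max(), 1.0)
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {list(bad)}")


def fit_linear_model(
    model_id: str, data: pd.DataFrame, formula: str
) -> list[AssociationResult]:
    """Fit one Gaussian GLM and return per-term results.

    Rows incomplete in any model variable are dropped (listwise); the
    retained n is reported on every term.  The intercept is reported like
    any other term.
    """
    _validate_factor_levels(data, formula)
    # listwise deletion before design construction, so factor levels present
    # only in incomplete rows do not leave all-zero dummy columns behind
    referenced = [c for c in data.columns
                  if re.search(rf"\b{re.escape(c)}\b", formula)]
    data = data.dropna(subset=referenced)
    y, X = patsy.dmatrices(formula, data, return_type="dataframe", NA_action="drop")
    _check_rank(X)
    model = sm.GLM(y, X, family=sm.families.Gaussian())
    fit = model.fit()
    n = int(fit.nobs)
    out = []
    for term in X.columns:
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        out.append(
            AssociationResult(
                model_id=model_id,
                term=term,
                beta=beta,
                ci_low=beta - Z975 * se,
                ci_high=beta + Z975 * se,
                p=float(fit.pvalues[term]),
                n=n,
            )
        )
    return out


def compare_groups(
    values,
    grouping=None,
    *,
    paired_with=None,
    categorical: bool = False,
) -> GroupComparison:
    """Two-sided Student's t-test (unpaired or paired) or chi-squared test.

    - ``values`` + ``grouping`` (two levels): unpaired t-test on the two
      groups; returns their means.
    - ``values`` + ``paired_with``: paired t-test; returns the two means.
    - ``categorical=True`` with ``values`` and ``grouping`` categorical:
      chi-squared test of independence on the contingency table.
    """
    if paired_with is not None:
        a = np.asarray(values, dtype=float)
        b = np.asarray(paired_with, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired vectors must have equal length")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        stat, p = stats.ttest_rel(a, b)
        return GroupComparison(
            means=(float(a.mean()), float(b.mean())),
            statistic=float(stat),
            p=float(p),
            kind="paired_t",
        )
    if grouping is None:
        raise ValueError("provide either grouping or paired_with")
    if categorical:
        table = pd.crosstab(pd.Series(values), pd.Series(grouping))
        stat, p, _, _ = stats.chi2_contingency(table)
        return GroupComparison(means=None, statistic=float(stat), p=float(p), kind="chi2")
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    levels = pd.unique(grouping[~pd.isna(grouping)])
    if len(levels) != 2:
        raise ValueError(f"unpaired t-test needs exactly 2 groups, got {len(levels)}")
    a = values[grouping == levels[0]]
    b = values[grouping == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    stat, p = stats.ttest_ind(a, b)
    return GroupComparison(
        means=(float(np.nanmean(a)), float(np.nanmean(b))),
        statistic=float(stat),
        p=float(p),
        kind="unpaired_t",
    )


def categorize_tst(tst_hours: float, scheme: str = "binary") -> str | None:
    """Sleep-duration stratum for the telomere contrasts.

    ``binary``: insufficient (<5 h) vs adequate (>7 h); the 5-7 h middle is
    excluded (None).  ``three_level``: insufficient (<5), adequate (>7 and
    <=9), long (>9); 5-7 h excluded.  Adequate sleep is the reference level
    in contrasts.
    """
    if scheme not in ("binary", "three_level"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if pd.isna(tst_hours):
        return None
    if tst_hours < 5:
        return "insufficient"
    if scheme == "binary":
        return "adequate" if tst_hours > 7 else None
    if tst_hours > 9:
        return "long"
    return "adequate" if tst_hours > 7 else None


def _results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_id": r.model_id,
                "term": r.term,
                "beta": r.beta,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n": r.n,
            }
            for r in results
        ],
        columns=["model_id", "term", "beta", "ci_low", "ci_high", "p", "n"],
    )


def run_battery(
    cohort_table: pd.DataFrame,
    markers: list[str] | None = None,
    significance: float = 0.05,
) -> pd.DataFrame:
    """Run every registered model over the merged cohort table.

    Fits, in deterministic order: the three marker models for each CVD
    marker present; the demographic TST model; one TST model per
    socioeconomic / lifestyle factor present; and, for each LTL column
    present (``ltl_wgs_bp``, ``ltl_qpcr_ts``), the continuous-TST model,
    the two interaction models and the sleep-stratum contrasts.  LTL models
    are skipped with a warning when the column is absent.

    Returns a tidy frame (model_id, term, beta, ci_low, ci_high, p, n) plus
    a ``significant`` flag at raw p < ``significance``.
    """
    required = ["age", "gender", "ethnicity", "tst_hours"]
    for col in required:
        if col not in cohort_table.columns:
            raise ValueError(f"missing required column '{col}'")
    data = cohort_table.copy()
    results: list[AssociationResult] = []

    if markers is None:
        markers = [m for m in MARKER_COLUMNS if m in data.columns]
    has_steps = "avg_daily_steps" in data.columns
    has_se = "se_pct" in data.columns
    for marker in markers:
        if not has_steps:
            break
        results += fit_linear_model(
            f"marker_m1:{marker}", data, MODEL_PRESETS["marker_m1"](marker)
        )
        if has_se:
            results += fit_linear_model(
                f"marker_m2:{marker}", data, MODEL_PRESETS["marker_m2"](marker)
            )
            results += fit_linear_model(
                f"marker_m3:{marker}", data, MODEL_PRESETS["marker_m3"](marker)
            )

    results += fit_linear_model("tst_demo", data, MODEL_PRESETS["tst_demo"]())
    for factor in SOCIOECONOMIC_FACTORS + LIFESTYLE_FACTORS:
        if factor in data.columns:
            results += fit_linear_model(
                f"tst_socio:{factor}", data, MODEL_PRESETS["tst_socio"](factor)
            )

    for ltl in ("ltl_wgs_bp", "ltl_qpcr_ts"):
        if ltl not in data.columns:
            warnings.warn(f"LTL column '{ltl}' absent; skipping its models")
            continue
        if "bmi" not in data.columns:
            warnings.warn("BMI column absent; skipping LTL models")
            continue
        results += fit_linear_model(f"ltl_tst:{ltl}", data, MODEL_PRESETS["ltl_tst"](ltl))
        results += fit_linear_model(
            f"ltl_inter_age:{ltl}", data, MODEL_PRESETS["ltl_inter_age"](ltl)
        )
        results += fit_linear_model(
            f"ltl_inter_gender:{ltl}", data, MODEL_PRESETS["ltl_inter_gender"](ltl)
        )
        for scheme, group_col in (("binary", "tst_group_binary"),
                                  ("three_level", "tst_group_three")):
            sub = data.copy()
            sub[group_col] = [
                categorize_tst(t, scheme) for t in sub["tst_hours"]
            ]
            sub = sub[sub[group_col].notna() & sub[ltl].notna()]
            if sub[group_col].nunique() < 2 or len(sub) < 10:
                warnings.warn(
                    f"too few volunteers in the TST strata for {ltl} "
                    f"({scheme}); contrast skipped"
                )
                continue
            results += fit_linear_model(
                f"ltl_group_{scheme}:{ltl}",
                sub,
                MODEL_PRESETS["ltl_tst_group"](ltl, group_col),
            )

    frame = _results_frame(results)
    frame["significant"] = frame["p"] < significance
    return frame
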