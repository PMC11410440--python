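"""Cohort-level statistics: group comparisons, correlations, regressions.

The analyses mirror a standard SPSS-style workflow on a two-group
observational cohort: two-sample t-tests (pooled or Welch) on the
morphometric parameters, a chi-square test on sex, within-DR-group Pearson
correlations of each parameter against age, retinopathy stage and diabetes
duration, and multivariate linear regression with backward elimination that
reduces to the significant predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInput, EmptyGroup, ZeroMarginal

# --------------------------------------------------------------------------
# domain records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselParams:
    """Morphometry of one vessel (µm, µm, µm, –, µm²)."""

    ld: float
    od: float
    wt: float
    wlr: float
    wcsa: float


@dataclass(frozen=True)
class PatientRecord:
    """One patient: covariates, retinopathy stage and vessel morphometry.

    ``dr_stage`` is 0 for NDR patients and 1–6 (stages I–VI) for DR patients.
    """

    id: str
    group: str  # "NDR" | "DR"
    sex: str  # "male" | "female"
    age: float
    bmi: float
    diabetes_duration: float
    dr_stage: int
    artery: VesselParams
    vein: VesselParams

    def __post_init__(self) -> None:
        if self.group not in ("NDR", "DR"):
            raise ValueError(f"unknown group {self.group!r}")
        if (self.group == "NDR") != (self.dr_stage == 0):
            raise ValueError("NDR patients must have dr_stage 0 and vice versa")
        if not (0 <= self.dr_stage <= 6):
            raise ValueError("dr_stage must be in 0..6")
        for v in (self.artery, self.vein):
            if not (v.od > v.ld > 0):
                raise ValueError("vessel morphometry must satisfy od > ld > 0")


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    mean_sd: dict  # group -> (mean, sd); chi2 rows use counts instead
    n: dict  # group -> sample size
    test: str  # "pooled_t" | "welch_t" | "chi2"
    statistic: float
    df: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    coefficients: dict  # retained predictor -> slope
    r_squared: float
    f_statistic: float
    p_values: dict  # retained predictor -> two-sided p
    n: int


# --------------------------------------------------------------------------
# elementary tests
# --------------------------------------------------------------------------


def two_sample_t_from_summary(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    mode: str = "pooled",
    parameter: str = "",
    group_names: tuple[str, str] = ("NDR", "DR"),
) -> GroupComparison:
    """Two-sample t-test from group summaries (mean, SD, n).

    ``mode='pooled'`` is the classical equal-variance Student's t with
    df = n1+n2−2; ``'welch'`` uses per-group variances with
    Welch–Satterthwaite df; ``'auto'`` picks Welch when a two-sided F-ratio
    test on the sample variances rejects equality at α = 0.05.
    """
    if n1 < 2 or n2 < 2:
        raise DegenerateInput("each group needs at least two observations")
    if not (s1 > 0 and s2 > 0):
        raise DegenerateInput("group SDs must be positive")
    if mode == "auto":
        mode = "welch" if _f_ratio_unequal_variance(s1, n1, s2, n2) else "pooled"
    v1, v2 = s1 * s1, s2 * s2
    if mode == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        test = "pooled_t"
    elif mode == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        test = "welch_t"
    else:
        raise ValueError(f"unknown t-test mode {mode!r}")
    if se == 0:
        raise DegenerateInput("zero standard error")
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(
        parameter=parameter,
        mean_sd={group_names[0]: (m1, s1), group_names[1]: (m2, s2)},
        n={group_names[0]: n1, group_names[1]: n2},
        test=test,
        statistic=float(t),
        df=df,
        p=float(p),
    )


def _f_ratio_unequal_variance(
    s1: float, n1: int, s2: float, n2: int, alpha: float = 0.05
) -> bool:
    """Two-sided F-ratio test for unequal variances from summaries."""
    if s1 >= s2:
        f, d1, d2 = (s1 / s2) ** 2, n1 - 1, n2 - 1
    else:
        f, d1, d2 = (s2 / s1) ** 2, n2 - 1, n1 - 1
    p = 2.0 * sps.f.sf(f, d1, d2)
    return min(p, 1.0) < alpha


def two_sample_t(
    x,
    y,
    mode: str = "auto",
    parameter: str = "",
    group_names: tuple[str, str] = ("NDR", "DR"),
) -> GroupComparison:
    """Two-sample t-test on raw samples.

    In ``auto`` mode a Levene test (centred on the mean) at α = 0.05 decides
    between the pooled and Welch variants.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateInput("each group needs at least two observations")
    if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        raise DegenerateInput("constant group")
    if mode == "auto":
        _, p_lev = sps.levene(x, y, center="mean")
        mode = "welch" if p_lev < 0.05 else "pooled"
    return two_sample_t_from_summary(
        float(np.mean(x)),
        float(np.std(x, ddof=1)),
        x.size,
        float(np.mean(y)),
        float(np.std(y, ddof=1)),
        y.size,
        mode=mode,
        parameter=parameter,
        group_names=group_names,
    )


def chi_square_2x2(
    a: int, b: int, c: int, d: int, parameter: str = "sex"
) -> GroupComparison:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1.

    Rows are groups, columns categories: ``[[a, b], [c, d]]``.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ZeroMarginal("empty table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ZeroMarginal("zero marginal")
    n = counts.sum()
    chi2 = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    p = float(sps.chi2.sf(chi2, 1))
    return GroupComparison(
        parameter=parameter,
        mean_sd={"row1": (a, b), "row2": (c, d)},
        n={"row1": a + b, "row2": c + d},
        test="chi2",
        statistic=float(chi2),
        df=1.0,
        p=p,
    )


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with its t statistic (df = n−2) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInput("need at least three paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInput("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    t, p = correlation_t_p(r, n)
    return CorrelationResult(r=r, n=n, t=t, p=p)


def correlation_t_p(r: float, n: int) -> tuple[float, float]:
    """t statistic and two-sided p for a Pearson r at sample size n."""
    if n < 3:
        raise DegenerateInput("need n >= 3")
    if abs(r) >= 1.0:
        return math.inf if r > 0 else -math.inf, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return t, p


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------


def _ols(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def simple_regression(y, x, predictor: str = "x") -> RegressionResult:
    """Ordinary least squares ``y = a + b·x`` with R², F and two-sided p."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise DegenerateInput("need at least three paired observations")
    if np.std(x) == 0:
        raise DegenerateInput("constant predictor")
    res = _ols(y, pd.DataFrame({predictor: x}))
    return RegressionResult(
        intercept=float(res.params["const"]),
        coefficients={predictor: float(res.params[predictor])},
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        p_values={predictor: float(res.pvalues[predictor])},
        n=int(y.size),
    )


def multivariate_regression_backward(
    y, predictors: dict, alpha: float = 0.05
) -> RegressionResult:
    """OLS with backward elimination of non-significant predictors.

    Fits the full model, then repeatedly drops the predictor with the largest
    p ≥ ``alpha`` until every retained predictor is significant. Returns the
    reduced model; an intercept-only result if nothing survives.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in predictors.items()})
    if len(X) != y.size or y.size < len(X.columns) + 2:
        raise DegenerateInput("n must exceed predictor count + 1")
    for name in X.columns:
        if X[name].std() == 0:
            raise DegenerateInput(f"constant predictor {name!r}")
    kept = list(X.columns)
    y_scale = max(float(np.std(y)), np.finfo(float).tiny)
    while kept:
        res = _ols(y, X[kept])
        pvals = res.pvalues.drop("const")
        # on (near-)exact fits residual variance underflows and p-values lose
        # meaning; a predictor with numerically negligible contribution is
        # treated as non-significant
        for name in kept:
            contrib = abs(res.params[name]) * float(X[name].std())
            if contrib <= 1e-10 * y_scale:
                pvals[name] = 1.0
        worst = pvals.idxmax()
        if pvals[worst] >= alpha:
            kept.remove(worst)
        else:
            break
    if not kept:
        return RegressionResult(
            intercept=float(np.mean(y)),
            coefficients={},
            r_squared=0.0,
            f_statistic=float("nan"),
            p_values={},
            n=int(y.size),
        )
    res = _ols(y, X[kept])
    return RegressionResult(
        intercept=float(res.params["const"]),
        coefficients={k: float(res.params[k]) for k in kept},
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        p_values={k: float(res.pvalues[k]) for k in kept},
        n=int(y.size),
    )


# --------------------------------------------------------------------------
# cohort report (layout of the reference study's result tables)
# --------------------------------------------------------------------------

MORPH_PARAMS = ("ld", "od", "wlr", "wt", "wcsa")
COVARIATES = ("age", "stage", "duration")


def _cohort_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {
            "id": p.id,
            "group": p.group,
            "sex": p.sex,
            "age": p.age,
            "bmi": p.bmi,
            "duration": p.diabetes_duration,
            "stage": p.dr_stage,
        }
        for vessel in ("artery", "vein"):
            v: VesselParams = getattr(p, vessel)
            for k in MORPH_PARAMS:
                row[f"{vessel}_{k}"] = getattr(v, k)
        rows.append(row)
    return pd.DataFrame(rows)


def build_cohort_report(
    cohort: list[PatientRecord],
    t_mode: str = "auto",
    alpha: float = 0.05,
) -> dict:
    """All cohort-level result tables for an NDR-vs-DR cohort.

    Returns a dict of DataFrames: ``demographics`` (sex chi-square, age and
    BMI t-tests), ``artery_comparison``/``vein_comparison`` (five parameters,
    group mean ± SD, t, p), ``artery_correlations``/``vein_correlations``
    (within-DR Pearson r of each parameter vs age/stage/duration), and
    ``artery_regressions``/``vein_regressions`` (backward-eliminated OLS of
    each parameter on stage, duration and age within the DR group).
    """
    df = _cohort_frame(cohort)
    ndr = df[df.group == "NDR"]
    dr = df[df.group == "DR"]
    if len(ndr) == 0 or len(dr) == 0:
        raise EmptyGroup("cohort must contain both NDR and DR patients")

    # demographics
    a = int((ndr.sex == "male").sum())
    b = int((ndr.sex == "female").sum())
    c = int((dr.sex == "male").sum())
    d = int((dr.sex == "female").sum())
    demo_rows = []
    sex = chi_square_2x2(a, b, c, d)
    demo_rows.append(
        {
            "parameter": "sex",
            "test": "chi2",
            "statistic": sex.statistic,
            "df": sex.df,
            "p": sex.p,
        }
    )
    for col in ("age", "bmi"):
        cmp = two_sample_t(ndr[col], dr[col], mode=t_mode, parameter=col)
        demo_rows.append(
            {
                "parameter": col,
                "test": cmp.test,
                "statistic": cmp.statistic,
                "df": cmp.df,
                "p": cmp.p,
            }
        )
    report = {"demographics": pd.DataFrame(demo_rows)}

    for vessel in ("artery", "vein"):
        comp_rows = []
        for k in MORPH_PARAMS:
            col = f"{vessel}_{k}"
            cmp = two_sample_t(ndr[col], dr[col], mode=t_mode, parameter=k)
            comp_rows.append(
                {
                    "parameter": k,
                    "ndr_mean": ndr[col].mean(),
                    "ndr_sd": ndr[col].std(ddof=1),
                    "dr_mean": dr[col].mean(),
                    "dr_sd": dr[col].std(ddof=1),
                    "n_ndr": len(ndr),
                    "n_dr": len(dr),
                    "test": cmp.test,
                    "t": cmp.statistic,
                    "df": cmp.df,
                    "p": cmp.p,
                }
            )
        report[f"{vessel}_comparison"] = pd.DataFrame(comp_rows)

        # correlations and regressions are within the DR group
        corr_rows = []
        for k in MORPH_PARAMS:
            for cov in COVARIATES:
                cr = pearson_correlation(dr[cov], dr[f"{vessel}_{k}"])
                corr_rows.append(
                    {
                        "parameter": k,
                        "covariate": cov,
                        "r": cr.r,
                        "n": cr.n,
                        "t": cr.t,
                        "p": cr.p,
                    }
                )
        report[f"{vessel}_correlations"] = pd.DataFrame(corr_rows)

        reg_rows = []
        for k in MORPH_PARAMS:
            rr = multivariate_regression_backward(
                dr[f"{vessel}_{k}"],
                {cov: dr[cov] for cov in COVARIATES},
                alpha=alpha,
            )
            reg_rows.append(
                {
                    "parameter": k,
                    "retained": ",".join(sorted(rr.coefficients)),
                    "intercept": rr.intercept,
                    **{f"b_{cov}": rr.coefficients.get(cov) for cov in COVARIATES},
                    "r_squared": rr.r_squared,
                    "f": rr.f_statistic,
                    "n": rr.n,
                }
            )
        report[f"{vessel}_regressions"] = pd.DataFrame(reg_rows)
    return report
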