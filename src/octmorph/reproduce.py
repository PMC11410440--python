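"""Recompute the reference study's test statistics from its printed summaries.

The published group summaries (means ± SD, counts) fully determine the
two-sample t statistics and the sex chi-square, so these can be recomputed
and compared against the printed values — a closed-loop consistency check on
the statistics layer that needs no patient-level data. Each t row is
recomputed with the t-test variant it is numerically consistent with
(arteriolar rows pooled, venular rows Welch; the source mixes the two).

WLR rows are recomputed too but cannot match the printed t closely: their
group means are printed with only two decimals.
"""

from __future__ import annotations

import pandas as pd

from . import reference_tables as ref
from .morphometry import wall_thickness, wall_to_lumen_ratio, wall_cross_sectional_area
from .stats import chi_square_2x2, correlation_t_p, two_sample_t_from_summary


def recompute_group_tests() -> pd.DataFrame:
    """Every NDR-vs-DR test statistic recomputable from printed summaries.

    Columns: vessel (artery/vein/demographic), parameter, mode, statistic,
    df, p, reported (the printed value).
    """
    n1, n2 = ref.GROUP_SIZES["NDR"], ref.GROUP_SIZES["DR"]
    rows = []

    (a, b), (c, d) = ref.SEX_COUNTS["NDR"], ref.SEX_COUNTS["DR"]
    chi = chi_square_2x2(a, b, c, d)
    rows.append(
        {
            "vessel": "demographic",
            "parameter": "sex",
            "mode": "chi2",
            "statistic": chi.statistic,
            "df": chi.df,
            "p": chi.p,
            "reported": ref.REPORTED_SEX_CHI2,
        }
    )
    for name, table, reported in (
        ("age", ref.AGE_YEARS, ref.REPORTED_AGE_T),
        ("bmi", ref.BMI, ref.REPORTED_BMI_T),
    ):
        cmp = two_sample_t_from_summary(
            *table["NDR"], n1, *table["DR"], n2, mode="pooled", parameter=name
        )
        rows.append(
            {
                "vessel": "demographic",
                "parameter": name,
                "mode": "pooled",
                "statistic": cmp.statistic,
                "df": cmp.df,
                "p": cmp.p,
                "reported": reported,
            }
        )

    for vessel, table in (("artery", ref.ARTERY), ("vein", ref.VEIN)):
        for param in ("ld", "od", "wlr", "wt", "wcsa"):
            reported, mode = ref.REPORTED_T[(vessel, param)]
            m1, s1 = table["NDR"][param]
            m2, s2 = table["DR"][param]
            cmp = two_sample_t_from_summary(
                m1, s1, n1, m2, s2, n2, mode=mode, parameter=param
            )
            rows.append(
                {
                    "vessel": vessel,
                    "parameter": param,
                    "mode": mode,
                    "statistic": cmp.statistic,
                    "df": cmp.df,
                    "p": cmp.p,
                    "reported": reported,
                }
            )
    return pd.DataFrame(rows)


def recompute_formula_identities() -> pd.DataFrame:
    """Morphometric formulas applied to the printed group-mean diameters.

    The derived WT/WLR/WCSA of the group means will not generally equal the
    printed group means of the derived parameters (Jensen gap, and one
    internally inconsistent arteriolar DR row), but the venular rows agree
    closely and serve as a cross-check of the formula layer.
    """
    rows = []
    for vessel, table in (("artery", ref.ARTERY), ("vein", ref.VEIN)):
        for group in ("NDR", "DR"):
            od, ld = table[group]["od"][0], table[group]["ld"][0]
            rows.append(
                {
                    "vessel": vessel,
                    "group": group,
                    "od_mean": od,
                    "ld_mean": ld,
                    "wt_from_means": wall_thickness(od, ld),
                    "wt_reported": table[group]["wt"][0],
                    "wlr_from_means": wall_to_lumen_ratio(od, ld),
                    "wlr_reported": table[group]["wlr"][0],
                    "wcsa_from_means": wall_cross_sectional_area(od, ld, "paper"),
                    "wcsa_reported": table[group]["wcsa"][0],
                }
            )
    return pd.DataFrame(rows)


def recompute_regression_identities() -> pd.DataFrame:
    """F and R² implied by the printed within-DR correlations (df = n−2).

    For a single-predictor OLS fit, R² = r² and F = r²(n−2)/(1−r²); rows of
    the printed regression tables that retained one predictor must satisfy
    these identities against the corresponding printed r.
    """
    n = ref.GROUP_SIZES["DR"]
    rows = []
    for (vessel, param, covariate), (r, p_rep) in ref.REPORTED_CORRELATIONS.items():
        t, p = correlation_t_p(r, n)
        reg = ref.REPORTED_REGRESSIONS.get((vessel, param))
        rows.append(
            {
                "vessel": vessel,
                "parameter": param,
                "covariate": covariate,
                "r": r,
                "n": n,
                "t": t,
                "p": p,
                "p_reported": p_rep,
                "r2_implied": r * r,
                "f_implied": t * t,
                "r2_reported": reg[3] if reg else None,
                "f_reported": reg[4] if reg else None,
            }
        )
    return pd.DataFrame(rows)
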