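"""Cohort-level analysis: QC filtering, myopia grouping, and statistics.

Groups are defined on spherical equivalent (SE): eyes at or below -6.0 D
form the high-myopia group, eyes between -6.0 D (exclusive) and -0.5 D the
mild-to-moderate group.  Group comparisons use the independent two-sample
t-test, association uses Spearman rank correlation, and the dropout-area
model is reported both as per-predictor simple fits (signed Pearson r with
its p) and as a joint ordinary-least-squares fit.

All tests are two-sided with significance at 0.05 and no multiple-testing
correction; eyes are the analysis units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import EyeRecord
from .metrics import EyeMetrics

__all__ = [
    "classify_group",
    "qc_filter",
    "compare_groups",
    "correlate",
    "regress_mvd",
    "prevalence",
    "summarize_cohort",
    "metrics_to_frame",
    "records_to_frame",
]

HIGH_MYOPIA_SE_CUTOFF = -6.0
SE_RANGE = (-10.0, -0.5)
MIN_QUALITY_SCORE = 6

#: covariates entering the dropout-area regression
REGRESSION_PREDICTORS = ("age", "SE", "AL", "ppa_beta_area_mm2")


class GroupingError(ValueError):
    """Raised for an SE outside the study's inclusion interval."""


class InsufficientDataError(ValueError):
    """Raised when a statistic is requested on too few eyes."""


def classify_group(se: float) -> str:
    """Myopia group from spherical equivalent.

    The shared interval endpoint -6.0 D goes to the high group (high myopia
    is conventionally SE <= -6.0 D).
    """
    lo, hi = SE_RANGE
    if not lo <= se <= hi:
        raise GroupingError(
            f"SE {se:+.2f} D outside inclusion range [{lo}, {hi}]"
        )
    return "high" if se <= HIGH_MYOPIA_SE_CUTOFF else "mild_moderate"


def qc_filter(
    records: Iterable[EyeRecord],
) -> tuple[list[EyeRecord], list[tuple[EyeRecord, str]]]:
    """Split eyes into retained and excluded-with-reason.

    Retained eyes have a scan quality score of at least 6/10 and no
    artifact flag (double-vessel pattern, motion, segmentation error over
    three lines).  Eyes already flagged at manifest reading keep their
    original exclusion reason.
    """
    retained: list[EyeRecord] = []
    excluded: list[tuple[EyeRecord, str]] = []
    for rec in records:
        if rec.excluded:
            excluded.append((rec, rec.exclusion_reason or "excluded at load"))
        elif rec.quality_score < MIN_QUALITY_SCORE:
            excluded.append(
                (rec, f"quality_score {rec.quality_score} < "
                      f"{MIN_QUALITY_SCORE}")
            )
        elif rec.artifact_flags:
            excluded.append((rec, ";".join(sorted(rec.artifact_flags))))
        else:
            retained.append(rec)
    return retained, excluded


@dataclass
class GroupComparison:
    t: float
    p: float
    group_stats: dict  # group -> {"n", "mean", "sd"}


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided independent two-sample t-test between the two groups.

    Student's test (pooled variance) by default, Welch with
    ``equal_var=False``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    if len(names) != 2:
        raise InsufficientDataError(
            f"expected exactly two groups, got {names}"
        )
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least two eyes")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    group_stats = {
        name: {
            "n": int(len(x)),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
        }
        for name, x in zip(names, (a, b))
    }
    return GroupComparison(t=float(t), p=float(p), group_stats=group_stats)


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p.

    Spearman uses average ranks for ties.  Constant input has no defined
    coefficient and raises rather than returning a silent 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass
class RegressionTable:
    """Dropout-area model: per-predictor simple fits and the joint OLS."""

    simple: pd.DataFrame  # index predictor; columns r, p, slope, intercept
    joint: pd.DataFrame  # index term; columns coef, se, t, p
    condition_number: float
    collinearity_warning: bool


def regress_mvd(
    df: pd.DataFrame,
    response: str = "mvd_total_area_beta_mm2",
    predictors: Sequence[str] = REGRESSION_PREDICTORS,
    condition_number_bound: float = 1e4,
) -> RegressionTable:
    """Model per-eye dropout area on clinical covariates.

    The per-predictor table reports the signed correlation coefficient r of
    each simple linear fit with its p-value; the joint table is the OLS fit
    of the response on all predictors at once.
    """
    if len(df) < 10:
        raise InsufficientDataError("regression needs at least 10 eyes")
    missing = [c for c in (response, *predictors) if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing}")
    if df[list(predictors) + [response]].isna().any().any():
        raise ValueError("missing covariate values in regression input")

    y = df[response].to_numpy(dtype=float)
    rows = {}
    for name in predictors:
        x = df[name].to_numpy(dtype=float)
        r, p = correlate(x, y, method="pearson")
        slope, intercept = np.polyfit(x, y, 1)
        rows[name] = {"r": r, "p": p, "slope": float(slope),
                      "intercept": float(intercept)}
    simple = pd.DataFrame.from_dict(rows, orient="index")

    X = sm.add_constant(df[list(predictors)].astype(float))
    fit = sm.OLS(y, X).fit()
    joint = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    cond = float(np.linalg.cond(X.to_numpy()))
    return RegressionTable(
        simple=simple,
        joint=joint,
        condition_number=cond,
        collinearity_warning=cond > condition_number_bound,
    )


def prevalence(metrics: pd.DataFrame | Sequence[EyeMetrics]) -> float:
    """Fraction of eyes with at least one detected dropout region."""
    df = metrics_to_frame(metrics)
    if len(df) == 0:
        raise InsufficientDataError("prevalence of an empty cohort")
    return float(df["mvd_present"].mean())


def metrics_to_frame(metrics) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        return metrics
    return pd.DataFrame([vars(m) for m in metrics])


def records_to_frame(records: Iterable[EyeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "eye_id": r.eye_id,
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "SE": r.se,
                "AL": r.al,
                "quality_score": r.quality_score,
                "group": r.group,
            }
        )
    return pd.DataFrame(rows)


#: metric/covariate columns summarized per group
_SUMMARY_COLUMNS = (
    "age",
    "SE",
    "AL",
    "ppa_beta_area_mm2",
    "ppa_alpha_area_mm2",
    "mvd_total_area_beta_mm2",
    "mvd_total_area_alpha_mm2",
    "density_beta",
    "density_alpha",
)


def summarize_cohort(
    metrics: pd.DataFrame | Sequence[EyeMetrics],
    manifest: pd.DataFrame | Sequence[EyeRecord],
) -> dict:
    """Full cohort summary: group stats, t-tests, prevalence, associations.

    Returns a plain (JSON-serializable) dict so it can be written directly
    as a run artifact.
    """
    mdf = metrics_to_frame(metrics)
    rdf = manifest if isinstance(manifest, pd.DataFrame) \
        else records_to_frame(manifest)
    df = mdf.merge(rdf, on="eye_id", how="inner", validate="one_to_one")
    if len(df) < len(mdf):
        raise ValueError("manifest does not cover every eye with metrics")

    summary: dict = {"n_eyes": int(len(df))}
    groups = df["group"]
    summary["group_n"] = groups.value_counts().to_dict()

    comparisons = {}
    group_stats: dict = {}
    for col in _SUMMARY_COLUMNS:
        if col not in df.columns:
            continue
        try:
            comp = compare_groups(df[col], groups)
        except InsufficientDataError:
            continue
        comparisons[col] = {"t": comp.t, "p": comp.p}
        for gname, gstats in comp.group_stats.items():
            group_stats.setdefault(gname, {})[col] = gstats
    summary["group_stats"] = group_stats
    summary["comparisons"] = comparisons

    summary["prevalence"] = prevalence(df)
    summary["prevalence_alpha"] = float(df["mvd_present_alpha"].mean())

    response = "mvd_total_area_beta_mm2"
    spearman = {}
    for name in REGRESSION_PREDICTORS:
        try:
            r, p = correlate(df[name], df[response], method="spearman")
            spearman[name] = {"rho": r, "p": p}
        except ValueError:
            spearman[name] = None
    summary["spearman"] = spearman

    reg = regress_mvd(df, response=response)
    summary["simple_fits"] = {
        name: {k: float(v) for k, v in row.items()}
        for name, row in reg.simple.iterrows()
    }
    summary["joint_ols"] = {
        name: {k: float(v) for k, v in row.items()}
        for name, row in reg.joint.iterrows()
    }
    summary["joint_ols_condition_number"] = reg.condition_number
    summary["collinearity_warning"] = bool(reg.collinearity_warning)
    return summary
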