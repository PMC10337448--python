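"""Verified 7-day point-prevalence abstinence and group-effect estimation.

Abstinence at a visit requires a self-report of no smoking in the prior
7 days and expired CO strictly below 10 ppm.  Under the ITT rule a
missing component counts as smoking; under the respondent-only (RO)
rule missing observations are excluded from the denominator.  Group
contrasts are estimated by logistic regression (odds ratio, Wald 95% CI)
with optional covariate adjustment and Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "CO_VERIFICATION_PPM",
    "ABSTINENT",
    "SMOKING",
    "MISSING",
    "AbstinenceAssessment",
    "EffectEstimate",
    "DataError",
    "point_prevalence",
    "abstinence_series",
    "abstinence_rate",
    "covariate_design",
    "fit_group_effect",
    "bonferroni",
    "build_compliance_subgroups",
    "effects_table",
    "MAIN_CONTRASTS",
    "SUBGROUP_CONTRASTS",
]

CO_VERIFICATION_PPM = 10.0

ABSTINENT = "abstinent"
SMOKING = "smoking"
MISSING = "missing"

RULES = ("ITT", "RO")
ADJUSTMENT_COVARIATES = ("age", "sex", "race", "education")
REFERENCE_LEVELS = {"race": "European American", "education": "some college"}

MAIN_CONTRASTS = (("SSNP", "EUC"), ("SS", "EUC"), ("SSNP", "SS"))
MAIN_FAMILY_SIZE = 3
SUBGROUP_CONTRASTS = (
    ("SSNP-compliant", "EUC"),
    ("SSNP-noncompliant", "EUC"),
    ("SS-compliant", "EUC"),
    ("SS-noncompliant", "EUC"),
    ("SSNP-compliant", "SS-compliant"),
)
SUBGROUP_FAMILY_SIZE = 10


class DataError(ValueError):
    """Raised when input data violate a structural expectation."""


@dataclass(frozen=True)
class AbstinenceAssessment:
    """One visit's raw abstinence components."""

    self_report_no_smoking_7d: bool | None
    co_ppm: float | None
    visit: str = "2wk"


@dataclass(frozen=True)
class EffectEstimate:
    contrast: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_bonferroni: float
    adjusted: bool
    population: str
    visit: str | None = None
    n_obs: int | None = None
    separation: bool = False


def _is_missing(value) -> bool:
    if value is None or value is pd.NA:
        return True
    try:
        return bool(np.isnan(value))
    except TypeError:
        return False


def point_prevalence(a: AbstinenceAssessment, rule: str = "ITT") -> str:
    """Tri-state verified abstinence for one assessment under a missing-data rule."""
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    sr_missing = _is_missing(a.self_report_no_smoking_7d)
    co_missing = _is_missing(a.co_ppm)
    if not co_missing and a.co_ppm < 0:
        raise DataError("negative CO reading")
    if sr_missing or co_missing:
        return SMOKING if rule == "ITT" else MISSING
    if bool(a.self_report_no_smoking_7d) and a.co_ppm < CO_VERIFICATION_PPM:
        return ABSTINENT
    return SMOKING


def abstinence_series(df: pd.DataFrame, visit: str, rule: str = "ITT") -> pd.Series:
    """0/1 abstinence outcomes for a visit with the missing-data rule applied.

    Under ITT missing values become 0 (smoking); under RO the rows are
    dropped, so the returned index may be a subset of ``df.index``.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    col = f"y_{visit}"
    if col not in df.columns:
        raise KeyError(f"no outcome column {col!r}")
    y = df[col]
    if rule == "ITT":
        return y.fillna(0).astype(int)
    return y.dropna().astype(int)


def abstinence_rate(df: pd.DataFrame, group, visit: str, rule: str = "ITT", group_col: str = "arm") -> float:
    y = abstinence_series(df[df[group_col] == group], visit, rule)
    if len(y) == 0:
        raise DataError(f"no observations for group {group!r}")
    return float(y.mean())


def covariate_design(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Numeric design columns (no intercept) for the requested covariates."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "age":
            cols.append(df["age"].to_numpy(dtype=float))
            names.append("age")
        elif cov == "sex":
            values = df["sex"]
            if values.dtype.kind in "if":
                cols.append(values.to_numpy(dtype=float))
            else:
                cols.append((values == "female").to_numpy(dtype=float))
            names.append("female")
        elif cov in ("race", "education"):
            ref = REFERENCE_LEVELS[cov]
            levels = [lv for lv in sorted(df[cov].dropna().unique()) if lv != ref]
            for lv in levels:
                cols.append((df[cov] == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
        else:
            raise ValueError(f"unsupported covariate {cov!r}")
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names


def fit_group_effect(
    df: pd.DataFrame,
    contrast: tuple[str, str],
    visit: str,
    rule: str = "ITT",
    covariates: Sequence[str] | None = None,
    group_col: str = "arm",
    m_comparisons: int = 1,
) -> EffectEstimate:
    """Logistic-regression odds ratio for ``contrast[0]`` vs ``contrast[1]``.

    Covariate-free fits reproduce the 2x2 cross-product odds ratio.
    Complete separation is reported via the ``separation`` flag rather
    than a silent failure.
    """
    g1, g0 = contrast
    sub = df[df[group_col].isin(contrast)]
    if (sub[group_col] == g1).sum() == 0 or (sub[group_col] == g0).sum() == 0:
        raise DataError(f"contrast {contrast} has an empty group")
    y = abstinence_series(sub, visit, rule)
    sub = sub.loc[y.index]

    treat = (sub[group_col] == g1).to_numpy(dtype=float)
    design = [np.ones(len(sub)), treat]
    names = ["intercept", "treat"]
    if covariates:
        extra, extra_names = covariate_design(sub, covariates)
        if extra.shape[1]:
            design.append(extra)
            names.extend(extra_names)
    X = np.column_stack(design)

    separation = False
    coef = np.nan
    se = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.to_numpy(dtype=float), X).fit(disp=0, maxiter=200)
        coef = float(res.params[1])
        se = float(res.bse[1])
        if not res.mle_retvals.get("converged", True) or abs(coef) > 15 or not np.isfinite(se):
            separation = True
    except Exception:  # PerfectSeparationError and numerical failures
        separation = True

    if separation:
        return EffectEstimate(
            contrast=f"{g1} vs {g0}",
            odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
            p_raw=np.nan, p_bonferroni=np.nan,
            adjusted=bool(covariates), population=rule, visit=visit,
            n_obs=len(sub), separation=True,
        )

    z = norm.ppf(0.975)
    p_raw = float(2 * norm.sf(abs(coef) / se)) if se > 0 else 1.0
    return EffectEstimate(
        contrast=f"{g1} vs {g0}",
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_raw=p_raw,
        p_bonferroni=min(1.0, m_comparisons * p_raw),
        adjusted=bool(covariates),
        population=rule,
        visit=visit,
        n_obs=len(sub),
    )


def bonferroni(p_values: Iterable[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p becomes min(1, m * p)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("family size m must be at least the number of tests")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    return [min(1.0, m * p) for p in p_values]


def build_compliance_subgroups(df: pd.DataFrame) -> pd.DataFrame:
    """Label the five analysis groups from arm and compliance class.

    Returns a copy with a ``subgroup`` column in {SSNP-compliant,
    SSNP-noncompliant, SS-compliant, SS-noncompliant, EUC}.  The
    compliant/noncompliant split partitions each scheduled arm.
    """
    out = df.copy()
    euc = out["arm"] == "EUC"
    if euc.any() and out.loc[euc, "complier"].fillna(0).astype(int).gt(0).any():
        raise DataError("EUC participants cannot carry a compliance label")
    scheduled = out["arm"].isin(("SSNP", "SS"))
    if out.loc[scheduled, "complier"].isna().any():
        raise DataError("scheduled-arm participants are missing compliance classification")

    labels = pd.Series(index=out.index, dtype=object)
    labels[euc] = "EUC"
    comp = out["complier"].fillna(0).astype(int) == 1
    labels[scheduled & comp] = out.loc[scheduled & comp, "arm"] + "-compliant"
    labels[scheduled & ~comp] = out.loc[scheduled & ~comp, "arm"] + "-noncompliant"
    out["subgroup"] = labels

    for arm in ("SSNP", "SS"):
        for suffix in ("compliant", "noncompliant"):
            if (out["arm"] == arm).any() and not (labels == f"{arm}-{suffix}").any():
                warnings.warn(f"subgroup {arm}-{suffix} is empty")
    return out


def effects_table(
    df: pd.DataFrame,
    visit: str,
    rule: str = "ITT",
    adjusted: bool = False,
    subgroups: bool = False,
) -> pd.DataFrame:
    """Estimate the standard contrast family for one visit.

    Main-effect tables use the three arm contrasts with a Bonferroni
    family of 3; subgroup tables use the five compliance contrasts with
    a family of 10.
    """
    covariates = ADJUSTMENT_COVARIATES if adjusted else None
    if subgroups:
        data = build_compliance_subgroups(df)
        contrasts, group_col, m = SUBGROUP_CONTRASTS, "subgroup", SUBGROUP_FAMILY_SIZE
    else:
        data, contrasts, group_col, m = df, MAIN_CONTRASTS, "arm", MAIN_FAMILY_SIZE

    rows = []
    for contrast in contrasts:
        est = fit_group_effect(
            data, contrast, visit, rule=rule, covariates=covariates,
            group_col=group_col, m_comparisons=m,
        )
        rows.append(
            {
                "contrast": est.contrast,
                "visit": visit,
                "population": est.population,
                "adjusted": est.adjusted,
                "odds_ratio": est.odds_ratio,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p_raw": est.p_raw,
                "p_bonferroni": est.p_bonferroni,
                "n_obs": est.n_obs,
                "separation": est.separation,
            }
        )
    return pd.DataFrame(rows)
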