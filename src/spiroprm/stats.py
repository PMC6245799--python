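"""Group comparisons, adjusted models, and diagnostic accuracy.

Reproduces the cohort-comparison machinery of the borderline-obstruction
analysis: per-group summaries with one-way ANOVA / chi-square overall
tests and pairwise t-tests (Welch form by default), covariate-adjusted
group tests via likelihood-ratio statistics (Gaussian profile likelihood
for continuous outcomes, logistic regression for binary ones) with
pairwise Wald contrasts, and sensitivity/specificity of FEV1/FVC
threshold rules against CT-defined disease.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticAccuracy",
    "ComparisonRow",
    "threshold_positive",
    "diagnostic_accuracy",
    "compare_continuous",
    "compare_categorical",
    "adjusted_group_test",
    "exacerbation_rate",
    "dichotomize_symptoms",
]

log = logging.getLogger(__name__)

THRESHOLD_RULES = ("fixed_0.70", "lln")


@dataclass(frozen=True)
class ContingencyTable2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticAccuracy:
    """Sensitivity/specificity of a threshold rule against CT truth.

    A proportion whose denominator is empty (no diseased, or no
    non-diseased subjects) is reported as None, not zero.
    """

    rule_name: str
    table: ContingencyTable2x2
    sensitivity: float | None
    specificity: float | None


@dataclass
class ComparisonRow:
    """One outcome row of a group-comparison table."""

    outcome_name: str
    kind: str  # "continuous" or "binary"
    group_order: tuple[str, ...]
    group_summary: dict[str, tuple[float, float] | float]  # (mean, sd) or pct
    group_n: dict[str, int]
    overall_p_unadjusted: float | None
    overall_p_adjusted: float | None = None
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_p_adjusted: dict[tuple[str, str], float] = field(default_factory=dict)
    statistic: float | None = None
    flagged: str | None = None


def threshold_positive(ratio, lln_ratio, rule: str):
    """Obstruction call of one FEV1/FVC threshold rule (strict <)."""
    ratio = np.asarray(ratio, dtype=float)
    lln_ratio = np.asarray(lln_ratio, dtype=float)
    if rule == "fixed_0.70":
        out = ratio < 0.70
    elif rule == "lln":
        out = ratio < lln_ratio
    else:
        raise ValueError(f"unknown threshold rule {rule!r}; expected {THRESHOLD_RULES}")
    return bool(out) if out.ndim == 0 else out


def diagnostic_accuracy(predicted, truth, rule_name: str = "rule") -> DiagnosticAccuracy:
    """2x2 table plus sensitivity and specificity of a binary rule."""
    predicted = np.asarray(predicted, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth vectors must have equal length")
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    if sens is None:
        log.warning("no diseased subjects: sensitivity undefined for %s", rule_name)
    if spec is None:
        log.warning("no non-diseased subjects: specificity undefined for %s", rule_name)
    return DiagnosticAccuracy(
        rule_name=rule_name,
        table=ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn),
        sensitivity=sens,
        specificity=spec,
    )


def compare_continuous(
    values_by_group: dict[str, np.ndarray],
    outcome_name: str = "outcome",
    *,
    welch: bool = True,
) -> ComparisonRow:
    """Mean +/- SD per group, one-way ANOVA overall p, pairwise t-tests."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[np.isfinite(v)] for k, v in groups.items()}
    order = tuple(groups)
    if len(order) < 2:
        raise ValueError("at least two groups are required")
    flagged = None
    for k, v in groups.items():
        if len(v) < 2:
            flagged = f"group {k} has n < 2"
        elif np.allclose(v, v[0]):
            flagged = flagged or f"group {k} has zero variance"
    summary = {k: (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0)
               for k, v in groups.items()}
    n = {k: int(len(v)) for k, v in groups.items()}
    stat = p = None
    if flagged is None:
        stat, p = sps.f_oneway(*groups.values())
        stat, p = float(stat), float(p)
    row = ComparisonRow(
        outcome_name=outcome_name,
        kind="continuous",
        group_order=order,
        group_summary=summary,
        group_n=n,
        overall_p_unadjusted=p,
        statistic=stat,
        flagged=flagged,
    )
    for a, b in itertools.combinations(order, 2):
        if len(groups[a]) >= 2 and len(groups[b]) >= 2:
            _, pp = sps.ttest_ind(groups[a], groups[b], equal_var=not welch)
            row.pairwise_p[(a, b)] = float(pp)
    return row


def compare_categorical(
    flags_by_group: dict[str, np.ndarray],
    outcome_name: str = "outcome",
) -> ComparisonRow:
    """Per-group percentages and a Pearson chi-square test over the R x 2 table."""
    groups = {k: np.asarray(v, dtype=bool) for k, v in flags_by_group.items()}
    order = tuple(groups)
    counts = np.array([[v.sum(), (~v).sum()] for v in groups.values()], dtype=float)
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("every group must be non-empty")
    summary = {k: 100.0 * float(v.mean()) for k, v in groups.items()}
    n = {k: int(len(v)) for k, v in groups.items()}
    stat = p = None
    flagged = None
    if np.any(counts.sum(axis=0) == 0):
        flagged = "a column total of the contingency table is zero"
    else:
        stat, p, _, expected = sps.chi2_contingency(counts, correction=False)
        stat, p = float(stat), float(p)
        if (expected < 1).any():
            warnings.warn(
                f"{outcome_name}: expected cell count below 1 in the chi-square "
                "table; the asymptotic p-value may be unreliable",
                stacklevel=2,
            )
    row = ComparisonRow(
        outcome_name=outcome_name,
        kind="binary",
        group_order=order,
        group_summary=summary,
        group_n=n,
        overall_p_unadjusted=p,
        statistic=stat,
        flagged=flagged,
    )
    for a, b in itertools.combinations(order, 2):
        sub = np.array(
            [[groups[a].sum(), (~groups[a]).sum()], [groups[b].sum(), (~groups[b]).sum()]],
            dtype=float,
        )
        if (sub.sum(axis=0) > 0).all():
            _, pp, _, _ = sps.chi2_contingency(sub, correction=False)
            row.pairwise_p[(a, b)] = float(pp)
    return row


def _encode_covariates(df: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        s = df[c]
        if s.dtype == bool:
            cols[c] = s.astype(float)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{c}[{lev}]"] = (s.astype(str) == lev).astype(float)
        else:
            cols[c] = s.astype(float)
    return pd.DataFrame(cols, index=df.index)


def _gaussian_llf(resid: np.ndarray) -> float:
    n = len(resid)
    rss = float(resid @ resid)
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def adjusted_group_test(
    df: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age", "sex", "race", "pack_years", "current_smoker"),
    family: str = "linear",
) -> dict:
    """Covariate-adjusted overall and pairwise group tests.

    Fits the full model (group indicators + covariates) and the reduced
    model (covariates only); the likelihood-ratio statistic is referred
    to chi-square with #groups - 1 degrees of freedom.  The linear family
    uses least squares with the Gaussian profile likelihood; the logistic
    family uses iteratively reweighted least squares (Newton) via
    statsmodels.  Pairwise adjusted comparisons are Wald tests on
    group-indicator contrasts.  Rows with missing values are dropped with
    a logged count (complete-case analysis).
    """
    cols = [outcome, group_col, *covariates]
    data = df[cols].dropna()
    if len(data) < len(df):
        log.info(
            "adjusted_group_test(%s): dropped %d incomplete rows",
            outcome,
            len(df) - len(data),
        )
    y = data[outcome].to_numpy(dtype=float)
    groups = sorted(data[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ref = groups[0]
    gdum = pd.DataFrame(
        {f"group[{g}]": (data[group_col].astype(str) == g).astype(float) for g in groups[1:]},
        index=data.index,
    )
    covs = _encode_covariates(data, covariates)
    intercept = pd.Series(1.0, index=data.index, name="intercept")
    X_red = pd.concat([intercept, covs], axis=1)
    X_full = pd.concat([intercept, gdum, covs], axis=1)
    df_lrt = len(groups) - 1

    def contrast_vec(a: str, b: str) -> np.ndarray:
        v = np.zeros(X_full.shape[1])
        names = list(X_full.columns)
        if a != ref:
            v[names.index(f"group[{a}]")] = 1.0
        if b != ref:
            v[names.index(f"group[{b}]")] = -1.0
        return v

    result: dict = {"family": family, "groups": groups, "n_used": len(data)}
    if family == "linear":
        Xf = X_full.to_numpy(float)
        Xr = X_red.to_numpy(float)
        bf, *_ = np.linalg.lstsq(Xf, y, rcond=None)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        resid_f = y - Xf @ bf
        resid_r = y - Xr @ br
        lrt = 2.0 * (_gaussian_llf(resid_f) - _gaussian_llf(resid_r))
        n, p = Xf.shape
        sigma2 = float(resid_f @ resid_f) / (n - p)
        XtX_inv = np.linalg.pinv(Xf.T @ Xf)
        cov_params = sigma2 * XtX_inv
        params = dict(zip(X_full.columns, bf))

        def wald_p(v: np.ndarray) -> float:
            est = float(v @ bf)
            se = float(np.sqrt(v @ cov_params @ v))
            z = est / se
            return float(2 * sps.t.sf(abs(z), n - p))

    elif family == "logistic":
        import statsmodels.api as sm

        yb = data[outcome].astype(float).to_numpy()
        if not set(np.unique(yb)) <= {0.0, 1.0}:
            raise ValueError("logistic family requires a 0/1 outcome")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_f = sm.Logit(yb, X_full.to_numpy(float)).fit(disp=0, maxiter=100)
                fit_r = sm.Logit(yb, X_red.to_numpy(float)).fit(disp=0, maxiter=100)
        except Exception as exc:  # non-convergence or separation
            raise RuntimeError(f"logistic fit failed for {outcome}: {exc}") from exc
        if not (fit_f.mle_retvals.get("converged", True) and fit_r.mle_retvals.get("converged", True)):
            raise RuntimeError(
                f"logistic fit for {outcome} did not converge; "
                f"iteration trace: {fit_f.mle_retvals}"
            )
        if np.any(np.abs(fit_f.params) > 15):
            result["separation_flagged"] = True
            log.warning("possible separation in logistic fit for %s", outcome)
        lrt = 2.0 * (fit_f.llf - fit_r.llf)
        params = dict(zip(X_full.columns, fit_f.params))
        cov_params = fit_f.cov_params()
        bf = fit_f.params

        def wald_p(v: np.ndarray) -> float:
            est = float(v @ bf)
            se = float(np.sqrt(v @ cov_params @ v))
            return float(2 * sps.norm.sf(abs(est / se)))

    else:
        raise ValueError(f"unknown family {family!r}")

    result["lrt_statistic"] = float(max(lrt, 0.0))
    result["p_lrt"] = float(sps.chi2.sf(max(lrt, 0.0), df_lrt))
    result["params"] = {k: float(v) for k, v in params.items()}
    result["pairwise_p"] = {
        (a, b): wald_p(contrast_vec(a, b))
        for a, b in itertools.combinations(groups, 2)
    }
    return result


def exacerbation_rate(events, observed_years=1.0):
    """Events per observed year (the study definition uses one year)."""
    events = np.asarray(events, dtype=float)
    years = np.asarray(observed_years, dtype=float)
    if np.any(events < 0):
        raise ValueError("event counts cannot be negative")
    if np.any(years <= 0):
        raise ValueError("observation time must be positive")
    out = events / years
    return float(out) if out.ndim == 0 else out


def dichotomize_symptoms(
    mmrc: int,
    cough_months: float,
    cough_years: float,
) -> dict[str, bool]:
    """Moderate-or-severe dyspnea (mMRC >= 2) and chronic bronchitis flags.

    Chronic bronchitis: cough with sputum for at least 3 months of the
    year for at least 2 years.
    """
    mmrc = int(mmrc)
    if not 0 <= mmrc <= 4:
        raise ValueError("mMRC score must be between 0 and 4")
    return {
        "dyspnea_mod_severe": mmrc >= 2,
        "chronic_bronchitis": (cough_months >= 3) and (cough_years >= 2),
    }
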