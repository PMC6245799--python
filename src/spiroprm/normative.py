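"""Quantile-regression normative models and upper limits of normal.

The covariate-specific upper limit of normal (ULN) of an imaging metric
is the conditional 95th percentile among healthy never-smokers, fitted
by linear quantile regression on age, sex, BMI and scanner (one-hot
against a reference scanner).  The fit minimizes the pinball (check)
loss

    sum_i rho_tau(y_i - x_i' beta),   rho_tau(u) = u * (tau - 1{u < 0})

via the standard linear-programming formulation

    min  tau * 1'u+ + (1 - tau) * 1'u-
    s.t. X beta + u+ - u- = y,   u+, u- >= 0,   beta free,

solved with a deterministic simplex/interior solver so results are
reproducible across platforms.  At the optimum the residual sign counts
satisfy the subgradient conditions #(y < Xb) <= tau*n and
#(y > Xb) <= (1-tau)*n, which the fitter verifies.  For an
intercept-only design the minimizer set is an order-statistic interval;
the lower endpoint is reported.

Presence of disease is the strict comparison observed > ULN, with the
ULN floored at zero (a percentage of lung cannot be negative).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "QuantileModel",
    "pinball_loss",
    "fit_quantile",
    "fit_normative",
    "build_design",
    "predict_uln",
    "classify_presence",
    "disease_flags",
]

_RESID_TOL = 1e-7


@dataclass
class QuantileModel:
    """A fitted linear conditional-quantile model."""

    tau: float
    outcome_name: str
    coef: dict[str, float]
    n_train: int
    reference_scanner: str | None = None
    scanner_levels: tuple[str, ...] = ()
    n_below: int = 0
    n_above: int = 0
    covariates: tuple[str, ...] = field(default_factory=tuple)

    @property
    def coef_array(self) -> np.ndarray:
        return np.array(list(self.coef.values()))

    def to_json(self, path=None) -> str:
        payload = {
            "tau": self.tau,
            "outcome_name": self.outcome_name,
            "coef": self.coef,
            "n_train": self.n_train,
            "reference_scanner": self.reference_scanner,
            "scanner_levels": list(self.scanner_levels),
            "n_below": self.n_below,
            "n_above": self.n_above,
            "covariates": list(self.covariates),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "QuantileModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        payload["scanner_levels"] = tuple(payload.get("scanner_levels", ()))
        payload["covariates"] = tuple(payload.get("covariates", ()))
        return cls(**payload)


def pinball_loss(y: np.ndarray, yhat: np.ndarray, tau: float) -> float:
    """Mean check-loss of predictions at quantile level tau."""
    u = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.mean(u * (tau - (u < 0))))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full column rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or names}"
        )


def fit_quantile(
    design,
    y,
    tau: float = 0.95,
    *,
    column_names: list[str] | None = None,
    outcome_name: str = "outcome",
) -> QuantileModel:
    """Fit a linear quantile-regression model by linear programming.

    ``design`` is an (n, p) matrix (or DataFrame) that already contains
    any intercept column.  Returns a :class:`QuantileModel`; the fitted
    residual sign counts are stored and checked against the subgradient
    conditions.
    """
    if isinstance(design, pd.DataFrame):
        column_names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if column_names is None:
            column_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("design and outcome lengths differ")
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} observations for {p} columns")
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie strictly between 0 and 1")
    if tau * n < 1:
        warnings.warn(
            f"tau*n = {tau * n:.2f} < 1: the {tau:g} quantile is poorly "
            "identified at this sample size",
            stacklevel=2,
        )
    _check_rank(X, column_names)

    is_intercept_only = p == 1 and np.allclose(X[:, 0], X[0, 0]) and X[0, 0] != 0
    if is_intercept_only:
        # order-statistic identity; lower endpoint of the minimizer interval
        beta = np.array([np.quantile(y, tau, method="inverted_cdf") / X[0, 0]])
    else:
        c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
        eye = sp.identity(n, format="csc")
        A_eq = sp.hstack([sp.csc_matrix(X), eye, -eye], format="csc")
        bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
        res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
        if not res.success:
            raise RuntimeError(f"quantile LP did not converge: {res.message}")
        beta = res.x[:p]

    resid = y - X @ beta
    scale = max(1.0, float(np.abs(y).max()))
    n_below = int((resid < -_RESID_TOL * scale).sum())
    n_above = int((resid > _RESID_TOL * scale).sum())
    if n_below > tau * n + 1e-9 or n_above > (1 - tau) * n + 1e-9:
        warnings.warn(
            "fitted quantile violates the subgradient sign conditions "
            f"(n_below={n_below}, n_above={n_above}, n={n}, tau={tau})",
            stacklevel=2,
        )
    return QuantileModel(
        tau=float(tau),
        outcome_name=outcome_name,
        coef=dict(zip(column_names, (float(b) for b in beta))),
        n_train=n,
        n_below=n_below,
        n_above=n_above,
        covariates=tuple(column_names),
    )


def build_design(
    df: pd.DataFrame,
    *,
    covariates: tuple[str, ...] = ("age", "bmi"),
    sex_col: str | None = "sex",
    scanner_col: str | None = "scanner",
    scanner_levels: tuple[str, ...] | None = None,
    reference_scanner: str | None = None,
    strict_scanners: bool = True,
) -> tuple[pd.DataFrame, tuple[str, ...], str | None]:
    """Design frame: intercept, numeric covariates, male indicator, scanner one-hots.

    Scanner levels not seen at fit time raise an error unless
    ``strict_scanners`` is false, in which case they are mapped to the
    reference scanner.
    """
    cols = {"intercept": np.ones(len(df))}
    for c in covariates:
        cols[c] = df[c].to_numpy(dtype=float)
    if sex_col is not None and sex_col in df.columns:
        cols["male"] = (df[sex_col].astype(str).str.lower() == "male").to_numpy(float)
    levels: tuple[str, ...] = ()
    ref = None
    if scanner_col is not None and scanner_col in df.columns:
        seen = tuple(sorted(df[scanner_col].astype(str).unique()))
        levels = scanner_levels if scanner_levels is not None else seen
        ref = reference_scanner if reference_scanner is not None else levels[0]
        unseen = set(seen) - set(levels)
        if unseen:
            if strict_scanners:
                raise ValueError(
                    f"scanner categories {sorted(unseen)} were not seen at fit "
                    "time; configure a reference-scanner fallback to proceed"
                )
            df = df.copy()
            df.loc[df[scanner_col].astype(str).isin(unseen), scanner_col] = ref
        for lev in levels:
            if lev == ref:
                continue
            cols[f"scanner[{lev}]"] = (
                df[scanner_col].astype(str) == lev
            ).to_numpy(float)
    return pd.DataFrame(cols, index=df.index), levels, ref


def fit_normative(
    df: pd.DataFrame,
    outcome: str,
    *,
    tau: float = 0.95,
    covariates: tuple[str, ...] = ("age", "bmi"),
    scanner_col: str | None = "scanner",
    reference_scanner: str | None = None,
) -> QuantileModel:
    """Fit the tau-quantile normative model of ``outcome`` on a healthy table."""
    design, levels, ref = build_design(
        df,
        covariates=covariates,
        scanner_col=scanner_col,
        reference_scanner=reference_scanner,
    )
    model = fit_quantile(design, df[outcome].to_numpy(float), tau, outcome_name=outcome)
    model.scanner_levels = levels
    model.reference_scanner = ref
    return model


def predict_uln(
    model: QuantileModel,
    cov: pd.DataFrame,
    *,
    strict_scanners: bool = True,
) -> np.ndarray:
    """Covariate-specific ULN under a fitted model, floored at zero."""
    numeric = tuple(
        c for c in model.covariates if c not in ("intercept", "male")
        and not c.startswith("scanner[")
    )
    design, _, _ = build_design(
        cov,
        covariates=numeric,
        scanner_col="scanner" if model.scanner_levels else None,
        scanner_levels=model.scanner_levels or None,
        reference_scanner=model.reference_scanner,
        strict_scanners=strict_scanners,
    )
    design = design.reindex(columns=list(model.covariates), fill_value=0.0)
    uln = design.to_numpy(float) @ model.coef_array
    return np.maximum(uln, 0.0)


def classify_presence(observed, uln) -> np.ndarray | bool:
    """Disease present iff the observed metric strictly exceeds the ULN."""
    observed = np.asarray(observed, dtype=float)
    uln = np.asarray(uln, dtype=float)
    if np.any(~np.isfinite(observed)) or np.any(~np.isfinite(uln)):
        raise ValueError("observed values and ULN must be finite")
    out = observed > uln
    return bool(out) if out.ndim == 0 else out


def disease_flags(emph_present, fsad_present) -> tuple[np.ndarray, np.ndarray]:
    """(either, both) combinations of the two presence flags."""
    e = np.asarray(emph_present, dtype=bool)
    f = np.asarray(fsad_present, dtype=bool)
    return e | f, e & f
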