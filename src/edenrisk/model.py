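"""Logistic risk model: maximum-likelihood fitting, odds ratios, factor tests.

`EdentulismRiskModel` is constructed from an analytic cohort and a model
specification (or directly from a design matrix and outcome vector); `fit()`
runs Newton-Raphson / IRLS and returns a `RiskModelResults` carrying the
coefficient estimates, their Wald standard errors and covariance, the
log-likelihood, odds-ratio tables, likelihood-ratio tests for whole factors,
and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from . import cohort as _cohort
from .cohort import CohortTable, ModelSpec, VARIABLE_TERMS, encode_design

__all__ = [
    "EdentulismRiskModel",
    "RiskModelResults",
    "PredictionEquation",
    "fit_logistic_arrays",
]

#: Newton-Raphson stopping rules: stop when the largest absolute coefficient
#: update or the log-likelihood change falls below tolerance.
MAX_ITER = 50
COEF_TOL = 1e-8
LOGLIK_TOL = 1e-10
#: A coefficient drifting beyond this magnitude signals (quasi-)complete
#: separation; the fit is flagged non-converged rather than returned silently.
SEPARATION_BOUND = 15.0


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic_arrays(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = MAX_ITER,
    coef_tol: float = COEF_TOL,
    loglik_tol: float = LOGLIK_TOL,
):
    """Newton-Raphson ML logistic fit on raw arrays (fast path).

    Returns ``(beta, cov, llf, converged, n_iter)``. Convergence is declared
    when the max absolute coefficient change < `coef_tol` or the
    log-likelihood change < `loglik_tol`. A fit whose largest coefficient
    exceeds the separation bound is flagged ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_events = y.sum()
    if n_events == 0 or n_events == len(y):
        raise ValueError("outcome is all-zero or all-one; logistic fit undefined")

    p_cols = X.shape[1]
    beta = np.zeros(p_cols)
    llf = _bernoulli_loglik(X @ beta, y)
    converged = False
    it = 0
    hess = None
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = linalg.solve(hess, score, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular information matrix; design columns are linearly "
                "dependent or the fit is degenerate"
            ) from exc
        beta = beta + step
        new_llf = _bernoulli_loglik(X @ beta, y)
        if np.max(np.abs(step)) < coef_tol or abs(new_llf - llf) < loglik_tol:
            llf = new_llf
            converged = True
            break
        llf = new_llf

    if np.max(np.abs(beta)) > SEPARATION_BOUND:
        converged = False

    eta = X @ beta
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = (X * w[:, None]).T @ X
    try:
        cov = linalg.inv(hess)
    except linalg.LinAlgError:
        cov = np.full((p_cols, p_cols), np.nan)
        converged = False
    return beta, cov, llf, converged, it


# --------------------------------------------------------------------------
# Prediction equation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionEquation:
    """A fitted logistic prediction rule: p = exp(L) / (1 + exp(L)).

    ``L`` is the intercept plus the dot product of `coefficients` with the
    corresponding design-matrix terms (0/1 indicators, age in decades for
    ``A``).
    """

    intercept: float
    coefficients: dict[str, float]

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def _term_matrix(self, rows) -> pd.DataFrame:
        if isinstance(rows, pd.Series):
            rows = rows.to_frame().T
        elif isinstance(rows, dict):
            rows = pd.DataFrame([rows])
        missing = [t for t in self.terms if t not in rows.columns]
        if missing:
            raise ValueError(f"row is missing required terms: {missing}")
        return rows

    def linear_predictor(self, rows) -> np.ndarray:
        rows = self._term_matrix(rows)
        L = np.full(len(rows), self.intercept)
        for term, coef in self.coefficients.items():
            L = L + coef * rows[term].to_numpy(dtype=float)
        return L

    def predict(self, rows) -> np.ndarray:
        """Predicted outcome probability for each row; strictly inside (0,1)."""
        return special.expit(self.linear_predictor(rows))

    def predict_cohort(self, cohort: CohortTable, spec: ModelSpec) -> np.ndarray:
        return self.predict(encode_design(cohort, spec))

    def odds_ratios(self) -> pd.Series:
        """exp(coefficient) per term (no interval; see RiskModelResults)."""
        return pd.Series({t: float(np.exp(b)) for t, b in self.coefficients.items()})


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

class EdentulismRiskModel:
    """Maximum-likelihood logistic model of 12-year incident edentulism.

    Parameters
    ----------
    endog : array-like of 0/1
        Outcome indicator (1 = became edentulous).
    exog : pandas.DataFrame
        Design matrix including an ``intercept`` column; build it with
        :func:`edenrisk.cohort.encode_design` or use :meth:`from_cohort`.
    spec : ModelSpec, optional
        The variable set behind `exog`; enables whole-factor tests.
    """

    def __init__(self, endog, exog: pd.DataFrame, spec: ModelSpec | None = None):
        self.endog = np.asarray(endog, dtype=float)
        if not isinstance(exog, pd.DataFrame):
            raise TypeError("exog must be a DataFrame with named term columns")
        self.exog = exog
        self.spec = spec
        if len(self.endog) != len(exog):
            raise ValueError("endog and exog lengths differ")

    @classmethod
    def from_cohort(cls, cohort: CohortTable, spec: ModelSpec) -> "EdentulismRiskModel":
        return cls(cohort.outcome, encode_design(cohort, spec), spec=spec)

    @property
    def term_names(self) -> list[str]:
        return list(self.exog.columns)

    def fit(self, **kwargs) -> "RiskModelResults":
        beta, cov, llf, converged, n_iter = fit_logistic_arrays(
            self.exog.to_numpy(dtype=float), self.endog, **kwargs
        )
        return RiskModelResults(self, beta, cov, llf, converged, n_iter)


class RiskModelResults:
    """Fit results: estimates, uncertainty, odds ratios, factor tests."""

    def __init__(self, model, beta, cov, llf, converged, iterations):
        self.model = model
        names = model.term_names
        self.params = pd.Series(beta, index=names)
        self.cov = pd.DataFrame(cov, index=names, columns=names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self.llf = llf
        self.converged = bool(converged)
        self.iterations = int(iterations)
        self.nobs = len(model.endog)

    def cov_params(self) -> pd.DataFrame:
        return self.cov

    def predict(self, exog: pd.DataFrame | None = None) -> np.ndarray:
        X = self.model.exog if exog is None else exog[self.params.index]
        return special.expit(X.to_numpy(dtype=float) @ self.params.to_numpy())

    def prediction_equation(self) -> PredictionEquation:
        coefs = self.params.drop("intercept")
        return PredictionEquation(
            intercept=float(self.params["intercept"]),
            coefficients={t: float(b) for t, b in coefs.items()},
        )

    # -- inference ----------------------------------------------------------

    def odds_ratios(self, confidence: float = 0.95) -> pd.DataFrame:
        """Odds ratio and Wald confidence bounds per non-intercept term.

        OR = exp(b); bounds exp(b ± z·SE) with z the standard-normal quantile
        for the requested two-sided confidence level.
        """
        if not self.converged:
            raise ValueError("odds ratios requested from a non-converged fit")
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        rows = []
        for term in self.params.index:
            if term == "intercept":
                continue
            b, se = self.params[term], self.bse[term]
            rows.append((term, np.exp(b), np.exp(b - z * se), np.exp(b + z * se)))
        return pd.DataFrame(rows, columns=["term", "odds_ratio", "lower", "upper"]
                            ).set_index("term")

    def lrt_factor(self, variable: str) -> tuple[float, int, float]:
        """Likelihood-ratio test of a whole factor given all other terms.

        Refits the model without every indicator term of `variable`;
        the statistic is 2·(llf_full − llf_reduced) on as many degrees of
        freedom as terms dropped (a "Type III"-style factor test).
        """
        if variable not in VARIABLE_TERMS:
            raise ValueError(f"unknown variable {variable!r}")
        dropped = [t for t, _ in VARIABLE_TERMS[variable]]
        present = [t for t in dropped if t in self.params.index]
        if not present:
            raise ValueError(f"variable {variable!r} is not in the model")
        keep = [t for t in self.params.index if t not in present]
        reduced = EdentulismRiskModel(self.model.endog, self.model.exog[keep]).fit()
        if not reduced.converged:
            raise ValueError(f"reduced fit without {variable!r} did not converge")
        stat = 2.0 * (self.llf - reduced.llf)
        df = len(present)
        p = float(stats.chi2.sf(stat, df))
        return float(stat), df, p

    def factor_tests(self) -> pd.DataFrame:
        """LRT for every variable in the model's specification."""
        if self.model.spec is None:
            raise ValueError("model was built without a ModelSpec")
        rows = []
        for var in self.model.spec.variables:
            stat, df, p = self.lrt_factor(var)
            rows.append((var, stat, df, p))
        return pd.DataFrame(rows, columns=["variable", "lr_stat", "df", "p_value"]
                            ).set_index("variable")

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Incident-edentulism logistic model",
            "=" * 66,
            f"observations: {self.nobs:>6d}    events: {int(self.model.endog.sum()):>5d}",
            f"log-likelihood: {self.llf:.4f}    converged: {self.converged} "
            f"({self.iterations} iterations)",
            "-" * 66,
            f"{'term':<10}{'coef':>10}{'std err':>10}{'OR':>8}{'[0.025':>10}{'0.975]':>10}",
        ]
        z = 1.959963984540054
        for term in self.params.index:
            b, se = self.params[term], self.bse[term]
            if term == "intercept":
                lines.append(f"{term:<10}{b:>10.3f}{se:>10.3f}{'':>8}{'':>10}{'':>10}")
            else:
                lines.append(
                    f"{term:<10}{b:>10.3f}{se:>10.3f}{np.exp(b):>8.2f}"
                    f"{np.exp(b - z * se):>10.2f}{np.exp(b + z * se):>10.2f}"
                )
        lines.append("=" * 66)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<RiskModelResults n={self.nobs} llf={self.llf:.2f} "
                f"converged={self.converged}>")
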