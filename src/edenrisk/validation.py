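"""Final-model recalibration and test-set validation.

The selected model is refitted ("recalibrated") on the full Selection set;
the resulting prediction equation is applied to the held-out Test set to
obtain the final AUC with a percentile-bootstrap confidence interval, the
ROC curve, and classification metrics at the prevalence cutpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, ModelSpec, RECORD_COLUMNS, encode_design
from .metrics import (
    BootstrapAUC,
    ClassificationMetrics,
    auc,
    bootstrap_auc,
    classification_metrics,
    roc_points,
)
from .model import EdentulismRiskModel, PredictionEquation, RiskModelResults

__all__ = [
    "ValidationReport",
    "validate_final",
    "build_validation_report",
    "risk_profile_table",
    "encode_profiles",
]


def validate_final(
    best: ModelSpec, selection: CohortTable, test: CohortTable
) -> tuple[PredictionEquation, np.ndarray, RiskModelResults]:
    """Recalibrate the selected model on Selection; score the Test records.

    Returns the recalibrated prediction equation, one predicted probability
    per Test record (strictly inside (0, 1)), and the underlying fit.
    """
    results = EdentulismRiskModel.from_cohort(selection, best).fit()
    if not results.converged:
        raise ValueError("recalibration fit on the Selection set did not converge")
    equation = results.prediction_equation()
    scores = equation.predict(encode_design(test, best))
    return equation, scores, results


@dataclass
class ValidationReport:
    """Test-set performance of the recalibrated final model."""

    model_label: str
    equation: PredictionEquation
    n_test: int
    observed_incidence: float
    point_auc: float
    bootstrap: BootstrapAUC
    roc: tuple[np.ndarray, np.ndarray] = field(repr=False)
    metrics: ClassificationMetrics = None

    @property
    def bootstrap_mean_auc(self) -> float:
        return self.bootstrap.mean_auc

    @property
    def ci_lower(self) -> float:
        return self.bootstrap.ci_lower

    @property
    def ci_upper(self) -> float:
        return self.bootstrap.ci_upper

    def to_dict(self) -> dict:
        m = self.metrics
        return {
            "model": self.model_label,
            "equation": {
                "intercept": self.equation.intercept,
                "coefficients": self.equation.coefficients,
            },
            "n_test": self.n_test,
            "observed_incidence": self.observed_incidence,
            "point_auc": self.point_auc,
            "bootstrap_mean_auc": self.bootstrap_mean_auc,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "bootstrap_B": self.bootstrap.B,
            "cutpoint": m.cutpoint,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "ppv": m.ppv,
            "npv": m.npv,
            "confusion": {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn},
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def build_validation_report(
    best: ModelSpec,
    selection: CohortTable,
    test: CohortTable,
    B: int = 1000,
    seed=None,
    cutpoint: float | None = None,
) -> ValidationReport:
    """Full test-set evaluation of the selected model.

    The classification cutpoint defaults to the exact (unrounded) observed
    outcome proportion of the Test set — the prevalence cutpoint.
    """
    equation, scores, _ = validate_final(best, selection, test)
    y = test.outcome
    if cutpoint is None:
        cutpoint = test.incidence
    boot = bootstrap_auc(scores, y, B=B, seed=seed)
    return ValidationReport(
        model_label=best.label,
        equation=equation,
        n_test=len(test),
        observed_incidence=test.incidence,
        point_auc=auc(scores, y),
        bootstrap=boot,
        roc=roc_points(scores, y),
        metrics=classification_metrics(scores, y, cutpoint),
    )


def encode_profiles(profiles, variables) -> pd.DataFrame:
    """Design-matrix rows for raw covariate profiles (dicts of field values)."""
    frame = pd.DataFrame(list(profiles))
    for col in RECORD_COLUMNS:
        if col not in frame.columns:
            if col == "dentate_2006":
                frame[col] = True
            elif col == "edentulous_2018":
                frame[col] = False
            elif col == "id":
                frame[col] = [f"profile{i}" for i in range(len(frame))]
            else:
                frame[col] = pd.NA
    shell = CohortTable(frame[list(RECORD_COLUMNS)], validate=False)
    return encode_design(shell, variables)


def risk_profile_table(eq: PredictionEquation, profiles) -> pd.DataFrame:
    """Predicted probability per covariate profile, sorted by descending risk.

    `profiles` is a DataFrame (or iterable of dicts) of design-matrix term
    values covering every term of the equation; an incomplete profile raises
    an error naming the missing terms.
    """
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame(list(profiles))
    probs = eq.predict(profiles)
    out = profiles.copy()
    out["probability"] = probs
    return out.sort_values("probability", ascending=False, kind="mergesort")
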