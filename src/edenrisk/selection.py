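"""Model enumeration, sample splitting, and Monte Carlo cross-validation.

The candidate space is the fixed core of six variables (age, race, gender,
education, smoking, dental visit) plus every subset of the five candidate
predictors — 2^5 = 32 models. The analytic cohort is split once into
Selection and Test sets; the Selection set is then repeatedly re-partitioned
into Training and Validation halves, every model is fitted on each Training
set, and validation AUCs are averaged per model. The best model is the most
parsimonious one whose mean AUC is within tolerance of the maximum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .cohort import (
    ALL_TERMS,
    CANDIDATE_VARIABLES,
    CohortTable,
    ModelSpec,
    encode_design,
)
from .metrics import auc
from .model import fit_logistic_arrays

__all__ = [
    "PartitionPlan",
    "MCCVSummary",
    "enumerate_models",
    "split_selection_test",
    "run_mccv",
    "select_best",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def enumerate_models() -> tuple[ModelSpec, ...]:
    """All 32 candidate models, ordered by candidate count then lexicographic."""
    specs = []
    for k in range(len(CANDIDATE_VARIABLES) + 1):
        for combo in itertools.combinations(sorted(CANDIDATE_VARIABLES), k):
            specs.append(ModelSpec(candidates=combo))
    return tuple(specs)


@dataclass(frozen=True)
class PartitionPlan:
    """Splitting settings for Selection/Test and the MCCV replicates.

    `validate_size` is an absolute count (not a fraction) so the validation
    half matches the Test-set size exactly; with the default cohort of 4,288
    this yields the 3,002 / 1,286 selection/test split and 1,716 / 1,286
    training/validation partitions.
    """

    selection_fraction: float = 0.70
    validate_size: int = 1286
    replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.selection_fraction < 1.0:
            raise ValueError("selection_fraction must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.validate_size < 1:
            raise ValueError("validate_size must be >= 1")


def _two_class_permutation(rng, y: np.ndarray, n_first: int, max_attempts: int = 100):
    """Random permutation whose two halves both contain events and non-events."""
    for attempt in range(max_attempts):
        perm = rng.permutation(len(y))
        first, second = y[perm[:n_first]], y[perm[n_first:]]
        if 0 < first.sum() < len(first) and 0 < second.sum() < len(second):
            return perm
        warnings.warn("re-drawing a single-class partition")
    raise RuntimeError(
        f"no two-class partition found in {max_attempts} attempts"
    )


def split_selection_test(
    cohort: CohortTable, plan: PartitionPlan
) -> tuple[CohortTable, CohortTable]:
    """One-time random Selection/Test split of the analytic cohort.

    The Selection set receives round(selection_fraction x n) records (halves
    rounded away from zero); membership is a simple random draw reproducible
    from the plan's seed. Halves that would contain a single outcome class
    are re-drawn.
    """
    n = len(cohort)
    if n < 10:
        raise ValueError("cohort too small to split")
    y = cohort.outcome
    if not 0 < y.sum() < n:
        raise ValueError("cohort must contain both outcome classes")
    n_selection = round_half_away(plan.selection_fraction * n)
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    perm = _two_class_permutation(rng, y, n_selection)
    return cohort.subset(perm[:n_selection]), cohort.subset(perm[n_selection:])


@dataclass
class MCCVSummary:
    """Per-model AUC distribution over the MCCV replicates."""

    models: tuple[ModelSpec, ...]
    auc_values: np.ndarray  # shape (n_models, replicates); NaN = failed fit
    train_size: int
    validate_size: int

    def __post_init__(self) -> None:
        if len(self.models) != self.auc_values.shape[0]:
            raise ValueError("models and auc_values shapes disagree")

    @property
    def replicates(self) -> int:
        return self.auc_values.shape[1]

    @property
    def mean_auc(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.auc_values, axis=1)

    @property
    def n_failed(self) -> np.ndarray:
        return np.isnan(self.auc_values).sum(axis=1)

    def table(self) -> pd.DataFrame:
        """Mean and 10th/90th percentile AUC per model."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p10 = np.nanpercentile(self.auc_values, 10, axis=1)
            p90 = np.nanpercentile(self.auc_values, 90, axis=1)
        return pd.DataFrame(
            {
                "label": [m.label for m in self.models],
                "n_variables": [m.n_variables for m in self.models],
                "mean_auc": self.mean_auc,
                "p10_auc": p10,
                "p90_auc": p90,
                "n_failed": self.n_failed,
            }
        ).set_index("label")


def run_mccv(
    selection: CohortTable,
    models: tuple[ModelSpec, ...] | None = None,
    plan: PartitionPlan | None = None,
) -> MCCVSummary:
    """Monte Carlo cross-validation of every candidate model.

    Each replicate draws one random Training/Validation partition of the
    Selection set (validation half of `plan.validate_size` records), shared
    by all models; each model is fitted to the Training records and its
    validation AUC recorded. A replicate whose fit does not converge is
    recorded as NaN for that model and excluded from its mean.

    Replicate r draws from a child seed of (plan.seed, r), so any replicate
    can be reproduced in isolation.
    """
    if models is None:
        models = enumerate_models()
    if plan is None:
        plan = PartitionPlan()
    n = len(selection)
    if plan.validate_size >= n:
        raise ValueError("validate_size must be smaller than the selection set")

    y = selection.outcome.astype(float)
    X_full = encode_design(selection, ModelSpec(candidates=CANDIDATE_VARIABLES))
    col_index = {name: i for i, name in enumerate(X_full.columns)}
    X = X_full.to_numpy(dtype=float)
    model_cols = [
        np.array([col_index["intercept"]] + [col_index[t] for t in m.terms])
        for m in models
    ]

    aucs = np.full((len(models), plan.replicates), np.nan)
    n_failed = 0
    for r in range(plan.replicates):
        rng = np.random.default_rng(np.random.SeedSequence((plan.seed, r)))
        perm = _two_class_permutation(rng, y, plan.validate_size)
        vidx, tidx = perm[: plan.validate_size], perm[plan.validate_size :]
        y_train, y_val = y[tidx], y[vidx]
        for m, cols in enumerate(model_cols):
            Xt = X[np.ix_(tidx, cols)]
            beta, _, _, converged, _ = fit_logistic_arrays(Xt, y_train)
            if not converged:
                n_failed += 1
                continue
            scores = special.expit(X[np.ix_(vidx, cols)] @ beta)
            aucs[m, r] = auc(scores, y_val)
    if n_failed:
        warnings.warn(f"{n_failed} (model, replicate) fits failed to converge")
    return MCCVSummary(
        models=tuple(models),
        auc_values=aucs,
        train_size=n - plan.validate_size,
        validate_size=plan.validate_size,
    )


def select_best(summary: MCCVSummary, parsimony_tolerance: float = 0.002) -> ModelSpec:
    """Most parsimonious model within tolerance of the best mean AUC.

    Among models whose mean validation AUC is at least (max - tolerance),
    returns the one with the fewest variables; remaining ties break to the
    earliest model in canonical enumeration order.
    """
    if parsimony_tolerance < 0:
        raise ValueError("parsimony_tolerance must be >= 0")
    means = summary.mean_auc
    if np.all(np.isnan(means)):
        raise ValueError("no model has a defined mean AUC")
    best_mean = np.nanmax(means)
    eligible = [
        (m.n_variables, i)
        for i, m in enumerate(summary.models)
        if not np.isnan(means[i]) and means[i] >= best_mean - parsimony_tolerance
    ]
    _, winner = min(eligible)
    return summary.models[winner]
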