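"""Synthetic cohort generator.

Draws cohorts with the marginal structure of the analytic sample — category
frequencies per covariate, truncated-normal integer ages — and a binary
outcome generated from a logistic "truth" (defaulting to the published final
prediction equation). Covariates are independent by default; a single latent
"disadvantage" factor can induce positive association among the
socioeconomic / health covariates via its loading (`dependence`).

Each record consumes a fixed block of uniforms from one seeded stream, so
the first k records of a size-n cohort are identical for every n >= k.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import published
from .cohort import CohortTable, RECORD_COLUMNS, VARIABLE_TERMS, encode_design

__all__ = ["SyntheticConfig", "generate_cohort"]

#: Uniform draws reserved per record (spares keep the layout stable).
_DRAWS_PER_RECORD = 16

#: Stream slot per use, within a record's block of uniforms.
_SLOT = {
    "latent": 0, "race": 1, "gender": 2, "education": 3, "smoking": 4,
    "dental_visit_2y": 5, "alcohol": 6, "self_rated_health": 7, "lonely": 8,
    "income": 9, "cognition_lt23": 10, "cognition_score": 11, "age": 12,
    "outcome": 13,
}

#: Category levels ordered by increasing disadvantage (latent-factor axis),
#: and whether the shared latent factor loads on the variable.
_LEVEL_ORDER: dict[str, tuple[tuple[str, ...], bool]] = {
    "race": (("Caucasian", "AfricanAmerican", "Hispanic", "Other"), False),
    "gender": (("Female", "Male"), False),
    "education": (("CollegePlus", "LessThanCollege", "NoHS"), True),
    "smoking": (("Never", "Former", "Current"), True),
    "dental_visit_2y": (("Within2y", "Over2y"), True),
    "alcohol": (("Drinks", "DoesNotDrink"), False),
    "self_rated_health": (("GoodPlus", "FairPoor"), True),
    "lonely": (("No", "Yes"), True),
    "income": (("Ge75k", "From25to75k", "Lt25k"), True),
    "cognition_lt23": (("Ge23", "Lt23"), True),
}

#: Integer cognition-score bands for the two risk levels.
_COG_LOW_BAND = (5, 22)
_COG_NORMAL_BAND = (23, 35)


def _default_marginals() -> dict[str, dict[str, float]]:
    return published.marginal_probabilities()


def _default_truth() -> dict[str, float]:
    return dict(published.FINAL_COEFFICIENTS)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the analytic-cohort conditions."""

    n: int = published.N_COHORT
    marginals: dict[str, dict[str, float]] = dc_field(default_factory=_default_marginals)
    age_mean: float = published.AGE_MEAN
    age_sd: float = published.AGE_SD
    age_floor: float = published.AGE_FLOOR
    intercept: float = published.FINAL_INTERCEPT
    true_coefficients: dict[str, float] = dc_field(default_factory=_default_truth)
    dependence: float = 0.0
    target_incidence: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.dependence < 1.0:
            raise ValueError("dependence must lie in [0, 1)")
        if self.target_incidence is not None and not (
            0.0 < self.target_incidence < 1.0
        ):
            raise ValueError("target_incidence must lie in (0, 1)")
        for var, probs in self.marginals.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal probabilities for {var!r} sum to {total}, not 1"
                )


def _draw_categorical(
    u_var: np.ndarray,
    z_latent: np.ndarray,
    levels: tuple[str, ...],
    probs: dict[str, float],
    loading: float,
) -> np.ndarray:
    """Draw category labels via latent-normal cutpoints.

    With loading 0 this reduces to independent inverse-CDF sampling from the
    marginal; a positive loading shifts each record's position along the
    disadvantage-ordered cutpoints by the shared latent factor.
    """
    cum = np.cumsum([probs[lv] for lv in levels])[:-1]
    cutpoints = stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    z_own = stats.norm.ppf(np.clip(u_var, 1e-15, 1 - 1e-15))
    z = loading * z_latent + np.sqrt(1.0 - loading**2) * z_own
    idx = np.searchsorted(cutpoints, z, side="left")
    return np.asarray(levels, dtype=object)[idx]


def _truth_variables(coefficients: dict[str, float]) -> list[str]:
    term_to_var = {
        term: var
        for var, terms in VARIABLE_TERMS.items()
        for term, _ in terms
    }
    variables = []
    for term in coefficients:
        if term not in term_to_var:
            raise ValueError(f"unknown design term {term!r} in true_coefficients")
        var = term_to_var[term]
        if var not in variables:
            variables.append(var)
    return variables


def generate_cohort(config: SyntheticConfig | None = None, **overrides) -> CohortTable:
    """Generate a synthetic analytic cohort.

    Covariates come from `config.marginals` (optionally tied by the latent
    factor), age from a truncated Normal(age_mean, age_sd) bounded below at
    `age_floor` and rounded to whole years, and the outcome from
    Bernoulli(p) with logit p given by the configured truth. When
    `target_incidence` is set, the intercept is re-solved by monotone
    root-finding so the cohort's expected incidence matches it.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    U = rng.random((config.n, _DRAWS_PER_RECORD))
    z_latent = stats.norm.ppf(np.clip(U[:, _SLOT["latent"]], 1e-15, 1 - 1e-15))

    data: dict[str, np.ndarray] = {
        "id": np.array([f"P{i:07d}" for i in range(config.n)], dtype=object),
        "dentate_2006": np.ones(config.n, dtype=bool),
    }

    for var, (levels, loaded) in _LEVEL_ORDER.items():
        loading = config.dependence if loaded else 0.0
        labels = _draw_categorical(
            U[:, _SLOT[var]], z_latent, levels, config.marginals[var], loading
        )
        if var == "cognition_lt23":
            low = labels == "Lt23"
            lo_a, lo_b = _COG_LOW_BAND
            hi_a, hi_b = _COG_NORMAL_BAND
            u_score = U[:, _SLOT["cognition_score"]]
            score = np.where(
                low,
                lo_a + np.floor(u_score * (lo_b - lo_a + 1)),
                hi_a + np.floor(u_score * (hi_b - hi_a + 1)),
            )
            data["cognition_score"] = score.astype(int)
        else:
            data[var] = labels

    # age: truncated normal, lower bound age_floor, integer years
    lower = stats.norm.cdf(
        (config.age_floor - config.age_mean) / config.age_sd
    )
    u_age = lower + U[:, _SLOT["age"]] * (1.0 - lower)
    age = stats.norm.ppf(
        np.clip(u_age, 1e-15, 1 - 1e-15), loc=config.age_mean, scale=config.age_sd
    )
    data["age"] = np.rint(age).astype(int)

    # outcome from the logistic truth
    frame = pd.DataFrame(data)
    frame["edentulous_2018"] = False  # placeholder until the outcome is drawn
    shell = CohortTable(frame[list(RECORD_COLUMNS)], validate=False)
    p = special.expit(_linear_predictor(config, shell))
    outcome = U[:, _SLOT["outcome"]] < p
    frame["edentulous_2018"] = outcome
    return CohortTable(frame[list(RECORD_COLUMNS)])


def _linear_predictor(config: SyntheticConfig, cohort: CohortTable) -> np.ndarray:
    """Truth linear predictor over a cohort's covariates, with the intercept
    re-solved by Brent root-finding when a target incidence is requested."""
    variables = _truth_variables(config.true_coefficients)
    X = encode_design(cohort, variables)
    eta = np.full(len(cohort), float(config.intercept))
    for term, coef in config.true_coefficients.items():
        eta += coef * X[term].to_numpy()

    if config.target_incidence is not None:
        target = config.target_incidence

        def gap(delta: float) -> float:
            return float(np.mean(special.expit(eta + delta))) - target

        delta = optimize.brentq(gap, -30.0, 30.0, xtol=1e-12)
        eta = eta + delta
    return eta


def expected_incidence(config: SyntheticConfig, cohort: CohortTable | None = None) -> float:
    """Mean outcome probability implied by the truth over a cohort's covariates."""
    if cohort is None:
        cohort = generate_cohort(config)
    return float(np.mean(special.expit(_linear_predictor(config, cohort))))
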