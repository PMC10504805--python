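"""Cohort data model: eligibility filtering and design-matrix coding.

The analytic cohort is one row per participant, baseline-dentate, with a
binary 12-year incident-edentulism outcome and eleven baseline covariates
(six core demographic/behavioural variables plus five candidate predictors).
Analysis is complete-case: any record missing an analysis variable is
excluded, and every exclusion is attributed to exactly one reason.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Variable vocabulary
# --------------------------------------------------------------------------

#: Category levels per categorical field; the first level is the reference.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "race": ("Caucasian", "AfricanAmerican", "Hispanic", "Other"),
    "gender": ("Female", "Male"),
    "education": ("CollegePlus", "LessThanCollege", "NoHS"),
    "smoking": ("Never", "Former", "Current"),
    "dental_visit_2y": ("Within2y", "Over2y"),
    "alcohol": ("Drinks", "DoesNotDrink"),
    "self_rated_health": ("GoodPlus", "FairPoor"),
    "lonely": ("No", "Yes"),
    "income": ("Ge75k", "From25to75k", "Lt25k"),
}

#: Cognition score below this value codes the at-risk indicator C = 1.
COGNITION_CUTOFF = 23

#: Model variables -> record fields.
VARIABLE_FIELDS: dict[str, str] = {
    "age": "age",
    "race": "race",
    "gender": "gender",
    "education": "education",
    "smoking": "smoking",
    "dental_visit": "dental_visit_2y",
    "alcohol": "alcohol",
    "self_rated_health": "self_rated_health",
    "loneliness": "lonely",
    "income": "income",
    "cognition": "cognition_score",
}

#: Six variables present in every candidate model.
CORE_VARIABLES: tuple[str, ...] = (
    "age", "race", "gender", "education", "smoking", "dental_visit",
)

#: Five variables whose subsets define the 32 candidate models.
CANDIDATE_VARIABLES: tuple[str, ...] = (
    "alcohol", "cognition", "income", "loneliness", "self_rated_health",
)

#: Design-matrix terms per variable.  Categorical terms carry the non-reference
#: level they indicate; ``A`` is age in decades and ``C`` the low-cognition flag.
VARIABLE_TERMS: dict[str, tuple[tuple[str, str | None], ...]] = {
    "race": (("R1", "AfricanAmerican"), ("R2", "Hispanic"), ("R3", "Other")),
    "gender": (("G", "Male"),),
    "age": (("A", None),),
    "education": (("E0", "NoHS"), ("E1", "LessThanCollege")),
    "smoking": (("S0", "Current"), ("S1", "Former")),
    "dental_visit": (("D", "Over2y"),),
    "cognition": (("C", None),),
    "alcohol": (("AL", "DoesNotDrink"),),
    "self_rated_health": (("H", "FairPoor"),),
    "loneliness": (("LN", "Yes"),),
    "income": (("I1", "Lt25k"), ("I2", "From25to75k")),
}

#: Canonical column order of the full design matrix.
ALL_TERMS: tuple[str, ...] = (
    "R1", "R2", "R3", "G", "A", "E0", "E1", "S0", "S1", "D", "C",
    "AL", "H", "LN", "I1", "I2",
)

#: Record fields required to be non-missing in the analytic cohort, in the
#: fixed order used to attribute a multiply-missing record to one reason.
EXCLUSION_FIELD_ORDER: tuple[str, ...] = (
    "cognition_score", "lonely", "income", "smoking", "alcohol",
    "dental_visit_2y", "self_rated_health", "age", "race", "gender",
    "education",
)

RECORD_COLUMNS: tuple[str, ...] = (
    "id", "dentate_2006", "edentulous_2018", "age", "race", "gender",
    "education", "smoking", "dental_visit_2y", "alcohol", "cognition_score",
    "self_rated_health", "lonely", "income",
)


# --------------------------------------------------------------------------
# Model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: the fixed core six plus a subset of the candidates."""

    candidates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.candidates) - set(CANDIDATE_VARIABLES)
        if unknown:
            raise ValueError(f"unknown candidate variables: {sorted(unknown)}")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("duplicate candidate variables")
        object.__setattr__(
            self, "candidates",
            tuple(sorted(self.candidates)),
        )

    @property
    def variables(self) -> tuple[str, ...]:
        return CORE_VARIABLES + self.candidates

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def terms(self) -> tuple[str, ...]:
        terms = []
        for var in self.variables:
            terms.extend(t for t, _ in VARIABLE_TERMS[var])
        return tuple(t for t in ALL_TERMS if t in terms)

    @property
    def label(self) -> str:
        if not self.candidates:
            return "core6"
        return "core6+" + "+".join(self.candidates)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


# --------------------------------------------------------------------------
# Cohort container
# --------------------------------------------------------------------------

class CohortTable:
    """Analytic cohort: complete-case, baseline-dentate records with outcome.

    Wraps a :class:`pandas.DataFrame` with one row per participant. The
    ``outcome`` column is 1 where a baseline-dentate participant was
    edentulous twelve years later.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        data = data.reset_index(drop=True)
        if "outcome" not in data.columns:
            data = data.assign(
                outcome=data["edentulous_2018"].astype(bool).astype(int)
            )
        self.data = data
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.data
        if len(df) == 0:
            raise ValueError("cohort is empty")
        if not df["dentate_2006"].astype(bool).all():
            raise ValueError("cohort contains baseline-edentulous records")
        for fld in EXCLUSION_FIELD_ORDER:
            if df[fld].isna().any():
                raise ValueError(f"cohort has missing values in {fld!r}")
        if df["outcome"].isna().any():
            raise ValueError("cohort has missing outcomes")
        if not df["outcome"].isin([0, 1]).all():
            raise ValueError("outcome must be binary 0/1")

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=int)

    @property
    def incidence(self) -> float:
        """Observed outcome proportion."""
        return float(self.data["outcome"].mean())

    def subset(self, index: Sequence[int]) -> "CohortTable":
        """Row subset by positional index (partitioning helper)."""
        return CohortTable(self.data.iloc[list(index)], validate=False)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        raw = read_records(path)
        cohort, _ = apply_eligibility(raw)
        return cohort

    def to_csv(self, path) -> None:
        write_records(self.data.drop(columns=["outcome"]), path)


# --------------------------------------------------------------------------
# CSV dialect
# --------------------------------------------------------------------------

def read_records(path) -> pd.DataFrame:
    """Read a participant table (comma-separated, missing = empty string)."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype=str)
    missing_cols = set(RECORD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"input is missing columns: {sorted(missing_cols)}")
    for col in ("dentate_2006", "edentulous_2018"):
        df[col] = df[col].map(
            {"1": True, "0": False, "True": True, "False": False,
             "true": True, "false": False}
        )
    for col in ("age", "cognition_score"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_records(df: pd.DataFrame, path) -> None:
    """Write a participant table; booleans as 1/0, missing as empty string."""
    out = df.copy()
    for col in ("dentate_2006", "edentulous_2018"):
        if col in out:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else int(bool(v)))
    out.to_csv(path, index=False, na_rep="")


# --------------------------------------------------------------------------
# Eligibility
# --------------------------------------------------------------------------

@dataclass
class ExclusionLog:
    """Per-reason tally of excluded records.

    Each excluded record is counted once, under the first matching reason in
    the fixed order: baseline dentate status, outcome, then the covariates in
    :data:`EXCLUSION_FIELD_ORDER`.
    """

    counts: dict[str, int] = field(default_factory=dict)
    order: tuple[str, ...] = EXCLUSION_FIELD_ORDER
    retained: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"counts": self.counts, "order": list(self.order),
             "retained": self.retained},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def apply_eligibility(raw: pd.DataFrame) -> tuple[CohortTable, ExclusionLog]:
    """Filter raw records down to the complete-case analytic cohort.

    Exclusion reasons, attributed first-match: already edentulous at baseline
    (``baseline_edentulous``), missing baseline dentate status
    (``missing:dentate_2006``), missing outcome (``outcome_missing``), then
    ``missing:<variable>`` following :data:`EXCLUSION_FIELD_ORDER`.
    """
    if len(raw) == 0:
        raise ValueError("no input records")
    raw = raw.reset_index(drop=True)

    reasons = pd.Series(pd.NA, index=raw.index, dtype=object)

    def mark(mask: pd.Series, reason: str) -> None:
        mask = mask & reasons.isna()
        reasons[mask] = reason

    mark(raw["dentate_2006"].isna(), "missing:dentate_2006")
    mark(raw["dentate_2006"] == False, "baseline_edentulous")  # noqa: E712
    mark(raw["edentulous_2018"].isna(), "outcome_missing")
    for fld in EXCLUSION_FIELD_ORDER:
        mark(raw[fld].isna(), f"missing:{fld}")

    kept = raw[reasons.isna()]
    counts = reasons.value_counts().to_dict()
    log = ExclusionLog(counts={k: int(v) for k, v in counts.items()},
                       retained=len(kept))
    if len(kept) == 0:
        raise ValueError("no records remain after eligibility filtering")
    cohort = CohortTable(kept)
    assert log.retained + log.n_excluded == len(raw)
    return cohort, log


# --------------------------------------------------------------------------
# Design-matrix coding
# --------------------------------------------------------------------------

def _field_values(cohort: CohortTable, variable: str) -> pd.Series:
    return cohort.data[VARIABLE_FIELDS[variable]]


def _check_categories(values: pd.Series, field_name: str) -> None:
    allowed = set(CATEGORIES[field_name])
    bad = ~values.isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown category {values.iloc[row]!r} in field {field_name!r} "
            f"at row {row}"
        )


def encode_design(cohort: CohortTable, spec: ModelSpec | Iterable[str]) -> pd.DataFrame:
    """Build the design matrix for a model specification.

    Coding follows the final prediction equation: 0/1 indicators for every
    non-reference category level, age entered as years divided by 10 (``A``),
    and the low-cognition flag ``C`` = 1 when the cognition score is below
    :data:`COGNITION_CUTOFF`. Reference levels produce all-zero indicators.
    """
    variables = spec.variables if isinstance(spec, ModelSpec) else tuple(spec)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    for var in variables:
        if var not in VARIABLE_TERMS:
            raise ValueError(f"unknown model variable {var!r}")
        values = _field_values(cohort, var)
        if var == "age":
            cols["A"] = values.to_numpy(dtype=float) / 10.0
        elif var == "cognition":
            score = values.to_numpy(dtype=float)
            cols["C"] = (score < COGNITION_CUTOFF).astype(float)
        else:
            _check_categories(values, VARIABLE_FIELDS[var])
            for term, level in VARIABLE_TERMS[var]:
                cols[term] = (values == level).to_numpy(dtype=float)
    order = ["intercept"] + [t for t in ALL_TERMS if t in cols]
    return pd.DataFrame({t: cols[t] for t in order}, index=cohort.data.index)


def decode_design(X: pd.DataFrame, variables: Iterable[str]) -> pd.DataFrame:
    """Invert :func:`encode_design` back to category labels (round-trip check).

    Age is recovered in years; cognition only as the binary risk level, so it
    is reported as ``Lt23`` / ``Ge23``.
    """
    out: dict[str, np.ndarray] = {}
    for var in variables:
        if var == "age":
            out["age"] = np.round(X["A"].to_numpy() * 10).astype(int)
            continue
        if var == "cognition":
            out["cognition"] = np.where(X["C"] == 1, "Lt23", "Ge23")
            continue
        field_name = VARIABLE_FIELDS[var]
        reference = CATEGORIES[field_name][0]
        labels = np.full(len(X), reference, dtype=object)
        for term, level in VARIABLE_TERMS[var]:
            labels[X[term].to_numpy() == 1] = level
        out[field_name] = labels
    return pd.DataFrame(out, index=X.index)


def iter_category_profiles(variables: Iterable[str]) -> Iterable[dict]:
    """All combinations of category levels for the given variables.

    Age is held at 67 and cognition swept over the two risk levels; useful
    for exhaustive coding checks and risk-profile tables.
    """
    axes = []
    for var in variables:
        if var == "age":
            axes.append(("age", (67,)))
        elif var == "cognition":
            axes.append(("cognition_score", (20, 30)))
        else:
            fld = VARIABLE_FIELDS[var]
            axes.append((fld, CATEGORIES[fld]))
    names = [a for a, _ in axes]
    for combo in itertools.product(*(lv for _, lv in axes)):
        yield dict(zip(names, combo))
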