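"""Published reference constants for the 12-year incident-edentulism model.

The final 7-variable prediction equation reported for the US Health and
Retirement Study analytic cohort (n = 4,288, 2006 baseline, 2018 outcome),
and the baseline frequency distribution of that cohort by outcome status.
These serve as the default truth for the synthetic-cohort generator and as
fixtures for exact checks.
"""

from __future__ import annotations

from .model import PredictionEquation

#: Coefficients of the published final prediction equation
#: L = -4.866 + 0.472*R1 + 0.322*R2 - 0.130*R3 + 0.078*G + 0.158*A
#:     + 0.908*E0 + 0.646*E1 + 1.261*S0 + 0.389*S1 + 0.850*D + 0.599*C
#: with A = age/10 and 0/1 indicators otherwise.
FINAL_INTERCEPT: float = -4.866
FINAL_COEFFICIENTS: dict[str, float] = {
    "R1": 0.472,   # African American vs Caucasian
    "R2": 0.322,   # Hispanic vs Caucasian
    "R3": -0.130,  # Other race vs Caucasian
    "G": 0.078,    # Male vs Female
    "A": 0.158,    # per 10 years of age
    "E0": 0.908,   # no high-school degree vs college+
    "E1": 0.646,   # less than college vs college+
    "S0": 1.261,   # current vs never smoker
    "S1": 0.389,   # former vs never smoker
    "D": 0.850,    # last dental visit > 2 y vs within 2 y
    "C": 0.599,    # cognition score < 23 vs >= 23
}

FINAL_EQUATION = PredictionEquation(
    intercept=FINAL_INTERCEPT, coefficients=dict(FINAL_COEFFICIENTS)
)

#: Baseline characteristics by 2018 dentate status: (dentate, edentulous)
#: counts per category. Row totals give the cohort marginals.
TABLE1_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "race": {
        "Caucasian": (2964, 234),
        "AfricanAmerican": (454, 93),
        "Hispanic": (363, 78),
        "Other": (91, 11),
    },
    "gender": {"Female": (2265, 226), "Male": (1607, 190)},
    "education": {
        "NoHS": (491, 124),
        "LessThanCollege": (2222, 252),
        "CollegePlus": (1159, 40),
    },
    "smoking": {
        "Current": (299, 99),
        "Former": (1616, 180),
        "Never": (1957, 137),
    },
    "dental_visit_2y": {"Within2y": (3096, 223), "Over2y": (776, 193)},
    "alcohol": {"Drinks": (2302, 188), "DoesNotDrink": (1570, 228)},
    "cognition_lt23": {"Lt23": (1188, 236), "Ge23": (2684, 180)},
    "self_rated_health": {"GoodPlus": (3268, 290), "FairPoor": (604, 126)},
    "income": {
        "Lt25k": (837, 174),
        "From25to75k": (1816, 186),
        "Ge75k": (1219, 56),
    },
    "lonely": {"Yes": (494, 88), "No": (3378, 328)},
}

#: Cohort size and outcome counts.
N_COHORT = 4288
N_EDENTULOUS = 416
N_DENTATE = 3872

#: Baseline age distribution (dentate group mean/SD; the cohort is >50 y).
AGE_MEAN = 66.3
AGE_SD = 8.4
AGE_FLOOR = 51

#: Selection / test partition arithmetic used throughout.
SELECTION_FRACTION = 0.70
N_SELECTION = 3002
N_TEST = 1286
N_TRAIN = 1716


def marginal_probabilities() -> dict[str, dict[str, float]]:
    """Category marginal frequencies of the analytic cohort (sum to 1)."""
    out: dict[str, dict[str, float]] = {}
    for var, rows in TABLE1_COUNTS.items():
        totals = {cat: sum(cells) for cat, cells in rows.items()}
        n = sum(totals.values())
        out[var] = {cat: t / n for cat, t in totals.items()}
    return out
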