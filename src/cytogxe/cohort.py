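"""Maternal-symptom scoring, covariate assembly and the subject-inclusion cascade.

The environment exposure is the Edinburgh Postnatal Depression Scale (EPDS):
ten self-report items rated 0-3, of which items 3 and 5-10 are reverse scored,
giving a total in [0, 30] where higher means more depressive symptomatology.
Internal consistency is summarized by Cronbach's alpha.  Inclusion applies
birth-outcome thresholds (gestational age, birth weight, 5-minute APGAR) and
data-availability checks in a configured order with a per-criterion audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EPDS_ITEMS = [f"epds_item_{i}" for i in range(1, 11)]
#: 1-based indices of reverse-scored items
EPDS_REVERSED = (3, 5, 6, 7, 8, 9, 10)

#: ordered maternal-education ladder, coded 0-4
EDUCATION_LEVELS = [
    "primary",
    "secondary",
    "pre_university",
    "university",
    "postgraduate",
]

DEFAULT_COVARIATES = [
    "sex",
    "age_at_mri_weeks",
    "total_brain_volume_cm3",
    "maternal_education",
    "ethnicity",
]


def score_epds(items) -> float | np.ndarray:
    """Total EPDS score from the ten raw item responses.

    Items 1, 2 and 4 count their raw value; items 3 and 5-10 count (3 - raw).
    Accepts a length-10 sequence (returns a float) or an n x 10 array /
    DataFrame (returns a vector).  Missing items or values outside {0..3}
    raise; no imputation is attempted.
    """
    arr = np.asarray(items, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 10:
        raise ValueError(f"expected 10 EPDS items, got {arr.shape[1]}")
    if np.isnan(arr).any():
        raise ValueError("missing EPDS item (no imputation is performed)")
    if np.any((arr < 0) | (arr > 3)) or np.any(arr != np.round(arr)):
        raise ValueError("EPDS item values must be integers in {0,1,2,3}")
    scored = arr.copy()
    rev = [i - 1 for i in EPDS_REVERSED]
    scored[:, rev] = 3.0 - scored[:, rev]
    total = scored.sum(axis=1)
    return float(total[0]) if squeeze else total


def reverse_score_items(items) -> np.ndarray:
    """Apply the reverse-scoring map; applying it twice returns the input."""
    arr = np.atleast_2d(np.asarray(items, dtype=float)).copy()
    rev = [i - 1 for i in EPDS_REVERSED]
    arr[:, rev] = 3.0 - arr[:, rev]
    return arr


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of an n x k matrix of scored items.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total).
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need an n x k matrix with n >= 2")
    k = arr.shape[1]
    item_var = arr.var(axis=0, ddof=1)
    if (item_var > 0).sum() < 2:
        raise ValueError("need at least two items with positive variance")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass
class InclusionCriteria:
    """Inclusion thresholds and the order in which exclusions are attributed."""

    min_gestational_age: float = 34.0  # weeks
    min_birth_weight: float = 2000.0  # grams
    min_apgar: float = 9.0  # 5-minute score
    required_fields: tuple = ("sex", "ethnicity", "maternal_education")
    #: audit order; each subject is attributed to its first failing criterion
    order: tuple = ("genotype", "epds", "demographics",
                    "gestational_age", "birth_weight", "apgar")

    def __post_init__(self):
        if min(self.min_gestational_age, self.min_birth_weight, self.min_apgar) <= 0:
            raise ValueError("inclusion thresholds must be positive")


def _criterion_fail_mask(df: pd.DataFrame, name: str, c: InclusionCriteria):
    if name == "genotype":
        col = "has_genotype"
        if col not in df.columns:
            raise KeyError("cohort table lacks 'has_genotype'")
        return ~df[col].astype(bool).to_numpy()
    if name == "epds":
        if "epds_total" in df.columns:
            return df["epds_total"].isna().to_numpy()
        return df[EPDS_ITEMS].isna().any(axis=1).to_numpy()
    if name == "demographics":
        missing = [f for f in c.required_fields if f not in df.columns]
        if missing:
            raise KeyError(f"cohort table lacks required columns {missing}")
        return df[list(c.required_fields)].isna().any(axis=1).to_numpy()
    if name == "gestational_age":
        return (df["gestational_age_weeks"] < c.min_gestational_age).to_numpy()
    if name == "birth_weight":
        return (df["birth_weight_g"] < c.min_birth_weight).to_numpy()
    if name == "apgar":
        return (df["apgar_5min"] < c.min_apgar).to_numpy()
    raise ValueError(f"unknown inclusion criterion {name!r}")


def apply_exclusions(
    cohort: pd.DataFrame, criteria: InclusionCriteria | None = None
) -> tuple[pd.DataFrame, dict]:
    """Drop subjects failing any inclusion criterion, with a stepwise audit.

    Criteria are evaluated in ``criteria.order``; the audit reports, for each
    criterion, the number removed among survivors of the previous steps, so
    kept + sum(removed) equals the input size.
    """
    c = criteria or InclusionCriteria()
    n_in = len(cohort)
    alive = np.ones(n_in, dtype=bool)
    audit = {"input": n_in, "removed": {}, "kept": None}
    for name in c.order:
        fail = _criterion_fail_mask(cohort, name, c) & alive
        audit["removed"][name] = int(fail.sum())
        alive &= ~fail
    audit["kept"] = int(alive.sum())
    assert audit["kept"] + sum(audit["removed"].values()) == n_in
    return cohort.loc[alive].reset_index(drop=True), audit


def encode_covariates(
    cohort: pd.DataFrame,
    covariates: list | None = None,
    education_as_ordinal: bool = True,
) -> pd.DataFrame:
    """Design-matrix columns (without intercept) for the model covariates.

    Categorical fields are dummy-coded against the alphabetically first level;
    maternal education is ordinal-coded 0-4 by default; continuous fields
    pass through.  Column names are deterministic.  Unseen education levels
    raise.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    missing = [v for v in covariates if v not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks covariates {missing}")
    sub = cohort[covariates]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing covariate values in {bad}")
    cols = {}
    for name in covariates:
        s = cohort[name]
        if name == "maternal_education" and education_as_ordinal:
            if s.dtype == object:
                unseen = sorted(set(s) - set(EDUCATION_LEVELS))
                if unseen:
                    raise ValueError(f"unseen education levels: {unseen}")
                codes = s.map({l: i for i, l in enumerate(EDUCATION_LEVELS)})
            else:
                codes = s
            cols[name] = codes.to_numpy(dtype=float)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s))
            for lev in levels[1:]:  # alphabetically first level is reference
                cols[f"{name}_{lev}"] = (s == lev).to_numpy(dtype=float)
        else:
            arr = s.to_numpy(dtype=float)
            if np.allclose(arr, arr[0]):
                logger.warning(
                    "covariate %r is constant; retained (model drops by rank)", name
                )
            cols[name] = arr
    return pd.DataFrame(cols, index=cohort.index)


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV and derive epds_total from items when present."""
    df = pd.read_csv(path)
    if "epds_total" not in df.columns and set(EPDS_ITEMS).issubset(df.columns):
        items = df[EPDS_ITEMS].to_numpy(dtype=float)
        ok = ~np.isnan(items).any(axis=1)
        total = np.full(len(df), np.nan)
        if ok.any():
            total[ok] = score_epds(items[ok])
        df["epds_total"] = total
    return df
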