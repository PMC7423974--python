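"""Clinical cohort table: parsing, subgroup labels, and summary statistics.

The cohort table records, per patient: age at blood collection, sex,
cutaneous subtype (limited LcSSc / diffuse DcSSc), autoantibody status
(anti-centromere ACA / anti-topoisomerase-I Topo-I / none), disease
duration in years from the first non-Raynaud's symptom, medication, organ
involvement codes (ILD = interstitial lung disease), modified Rodnan skin
score, and percent-predicted FVC/DLCO (possibly missing).

A reference 23-patient table is packaged with the module and loaded by
default. Summaries round half-up to the precision conventionally printed
in cohort descriptions: % female and mean onset age to the nearest
integer, mean disease duration to one decimal. Onset age is derived as
age - duration (age is taken at blood collection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("F", "M")
SUBTYPES = ("LcSSc", "DcSSc")
AUTOANTIBODIES = ("ACA", "Topo-I", "No")
SCHEMES = ("ILD", "subtype", "early_late")
EARLY_LATE_CUT_YEARS = 3.0

_REQUIRED = ["patient_id", "age", "sex", "subtype", "autoantibody",
             "disease_duration", "organ_involvement", "skin_score"]


@dataclass
class CohortSummary:
    """Cohort-level descriptive statistics."""

    n: int
    pct_female: int
    mean_onset_age: int
    mean_disease_duration: float
    subtype_counts: dict[str, int]
    autoantibody_counts: dict[str, int]
    ild_counts: dict[str, int]
    early_late_counts: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pct_female": self.pct_female,
            "mean_onset_age": self.mean_onset_age,
            "mean_disease_duration": self.mean_disease_duration,
            "subtype_counts": dict(self.subtype_counts),
            "autoantibody_counts": dict(self.autoantibody_counts),
            "ild_counts": dict(self.ild_counts),
            "early_late_counts": dict(self.early_late_counts),
        }


def _round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def load_cohort_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate a cohort table CSV (packaged reference by default).

    ``organ_involvement`` is parsed from a ;-separated code string into a
    frozenset per patient.
    """
    if path is None:
        ref = resources.files("cytoarch").joinpath("data/cohort_table.csv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    missing_cols = [c for c in _REQUIRED if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns {missing_cols}")
    for _, row in table.iterrows():
        problems = [c for c in _REQUIRED if pd.isna(row[c])]
        if problems:
            raise ValueError(f"patient {row['patient_id']}: missing required "
                             f"fields {problems}")
    table = table.copy()
    table["organ_involvement"] = table["organ_involvement"].map(
        lambda s: frozenset(str(s).split(";")) if s else frozenset())
    bad_sex = set(table["sex"]) - set(SEXES)
    bad_sub = set(table["subtype"]) - set(SUBTYPES)
    bad_ab = set(table["autoantibody"]) - set(AUTOANTIBODIES)
    if bad_sex or bad_sub or bad_ab:
        raise ValueError(f"closed-vocabulary violations: sex {bad_sex or '{}'}, "
                         f"subtype {bad_sub or '{}'}, autoantibody {bad_ab or '{}'}")
    if (table["disease_duration"] < 0).any():
        raise ValueError("disease_duration must be >= 0")
    if (table["age"] <= table["disease_duration"]).any():
        raise ValueError("age must exceed disease duration")
    if (table["skin_score"] < 0).any():
        raise ValueError("skin_score must be >= 0")
    return table


def subgroup_labels(table: pd.DataFrame, scheme: str) -> pd.Series:
    """Per-patient subgroup label under one of the clinical schemes.

    ``ILD``: ILD / no-ILD by organ-involvement code. ``subtype``:
    LcSSc / DcSSc. ``early_late``: early (< 3 years disease duration) vs
    late (> 3 years); a duration of exactly 3 is assigned to late and
    logged.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; allowed {SCHEMES}")
    if scheme == "ILD":
        labels = table["organ_involvement"].map(
            lambda codes: "ILD" if "ILD" in codes else "no-ILD")
    elif scheme == "subtype":
        labels = table["subtype"].astype(str)
    else:
        at_cut = table["disease_duration"] == EARLY_LATE_CUT_YEARS
        if at_cut.any():
            logger.info("early_late: %d patients at exactly %.0f years "
                        "assigned to 'late'", int(at_cut.sum()),
                        EARLY_LATE_CUT_YEARS)
        labels = table["disease_duration"].map(
            lambda d: "early" if d < EARLY_LATE_CUT_YEARS else "late")
    labels.index = table["patient_id"]
    return labels.rename(scheme)


def summarize(table: pd.DataFrame) -> CohortSummary:
    """Cohort summary statistics at the conventional printed precision."""
    if len(table) < 1:
        raise ValueError("cohort table must have at least one row")
    n = len(table)
    pct_female = int(_round_half_up(100.0 * (table["sex"] == "F").mean()))
    duration = table["disease_duration"]
    onset = table["age"] - duration
    return CohortSummary(
        n=n,
        pct_female=pct_female,
        mean_onset_age=int(_round_half_up(float(onset.mean()))),
        mean_disease_duration=_round_half_up(float(duration.mean()), 1),
        subtype_counts=table["subtype"].value_counts().to_dict(),
        autoantibody_counts=table["autoantibody"].value_counts().to_dict(),
        ild_counts=subgroup_labels(table, "ILD").value_counts().to_dict(),
        early_late_counts=subgroup_labels(table, "early_late")
            .value_counts().to_dict(),
    )
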