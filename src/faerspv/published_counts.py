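"""Cohort reconstruction from published summary counts.

Summary tables of published spontaneous-report analyses print marginal
counts: reports per drug, events per drug, per-level demographic and
outcome counts over "data available" denominators, and 2x2 splits behind
univariable odds ratios.  These marginals fully determine the statistics
computed from them, so a cohort table realizing the printed counts lets the
package's own summary and regression code reproduce the published numbers
end to end — a desk-scale consistency check that needs no raw extract.

The reference counts bundled here come from a real-world renal-safety
analysis of the three calcineurin inhibitors (cyclosporine, tacrolimus,
voclosporin) in FAERS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CNI_DRUGS",
    "REPORT_COUNTS",
    "SEX_COUNTS",
    "AGE_COUNTS",
    "OUTCOME_COUNTS",
    "GENDER_2X2",
    "exposure_event_cohort",
    "characteristics_cohort",
    "gender_2x2_cohort",
]

CNI_DRUGS = ("cyclosporine", "tacrolimus", "voclosporin")

#: (total reports, renal-event reports) per drug
REPORT_COUNTS = {
    "cyclosporine": (44_451, 9_141),
    "tacrolimus": (57_436, 15_652),
    "voclosporin": (4_792, 1_235),
}

#: (female, male) among event reports with known sex
SEX_COUNTS = {
    "cyclosporine": (2_088, 2_909),
    "tacrolimus": (4_285, 5_679),
    "voclosporin": (631, 143),
}

#: (<18, 18-65, >=65) among event reports with known age
AGE_COUNTS = {
    "cyclosporine": (654, 2_851, 783),
    "tacrolimus": (1_100, 6_436, 1_626),
    "voclosporin": (1, 358, 26),
}

#: (Died, Life threatening, Hospitalized, Disabled, Other outcomes)
OUTCOME_COUNTS = {
    "cyclosporine": (1_173, 229, 1_748, 22, 2_205),
    "tacrolimus": (1_537, 630, 4_156, 49, 4_351),
    "voclosporin": (4, 1, 135, 0, 265),
}

#: cyclosporine gender split behind the univariable male-sex odds ratio:
#: (no-event, event) for female and male exposed reports
GENDER_2X2 = {"F": (8_579, 715), "M": (5_053, 894)}

_OUTCOME_LEVELS = ("Died", "Life threatening", "Hospitalized", "Disabled",
                   "Other outcomes")
_AGE_LEVELS = ("<18", "18-65", ">=65")
_AGE_REPRESENTATIVE = {"<18": 10.0, "18-65": 40.0, ">=65": 70.0}


def _blank_columns(n: int) -> dict:
    return {
        "sex": [None] * n,
        "age_years": np.full(n, np.nan),
        "age_bin": [None] * n,
        "weight_kg": np.full(n, np.nan),
        "weight_bin": [None] * n,
        "reporter": [None] * n,
        "country": [None] * n,
        "indication_group": [None] * n,
        "outcome_group": [None] * n,
        "year": [None] * n,
    }


def exposure_event_cohort(rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per report across all three drugs, exposure disjoint.

    Realizes the printed (total, event) report counts so that per-drug
    reporting proportions and the pooled event total follow from the
    package's own cohort functions.
    """
    frames = []
    for drug, (total, events) in REPORT_COUNTS.items():
        df = pd.DataFrame({"event": [True] * events + [False] * (total - events)})
        for d in CNI_DRUGS:
            df[f"exp_{d}"] = d == drug
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    for col, vals in _blank_columns(len(cohort)).items():
        cohort[col] = vals
    for d in CNI_DRUGS:
        cohort[f"onset_{d}"] = np.nan
    if rng is not None:
        cohort = cohort.sample(frac=1.0, random_state=np.random.RandomState(
            rng.integers(0, 2**31 - 1))).reset_index(drop=True)
    return cohort


def characteristics_cohort(rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Event-report cohort realizing the printed characteristic counts.

    Each characteristic block is filled for exactly its "data available"
    rows (values assigned independently per block, which preserves every
    printed marginal) and missing elsewhere.
    """
    frames = []
    for drug in CNI_DRUGS:
        n = REPORT_COUNTS[drug][1]
        cols = _blank_columns(n)
        f, m = SEX_COUNTS[drug]
        cols["sex"] = ["F"] * f + ["M"] * m + [None] * (n - f - m)
        age_counts = AGE_COUNTS[drug]
        age_bin: list = []
        age_years: list = []
        for level, k in zip(_AGE_LEVELS, age_counts):
            age_bin += [level] * k
            age_years += [_AGE_REPRESENTATIVE[level]] * k
        pad = n - len(age_bin)
        cols["age_bin"] = age_bin + [None] * pad
        cols["age_years"] = np.array(age_years + [np.nan] * pad)
        out_counts = OUTCOME_COUNTS[drug]
        grp: list = []
        for level, k in zip(_OUTCOME_LEVELS, out_counts):
            grp += [level] * k
        cols["outcome_group"] = grp + [None] * (n - len(grp))
        df = pd.DataFrame(cols)
        df["event"] = True
        for d in CNI_DRUGS:
            df[f"exp_{d}"] = d == drug
            df[f"onset_{d}"] = np.nan
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    if rng is not None:
        cohort = cohort.sample(frac=1.0, random_state=np.random.RandomState(
            rng.integers(0, 2**31 - 1))).reset_index(drop=True)
    return cohort


def gender_2x2_cohort(rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Cyclosporine-exposed cohort realizing the printed gender 2x2 split."""
    rows = {"sex": [], "event": []}
    for sex, (n0, n1) in GENDER_2X2.items():
        rows["sex"] += [sex] * (n0 + n1)
        rows["event"] += [False] * n0 + [True] * n1
    df = pd.DataFrame(rows)
    for col, vals in _blank_columns(len(df)).items():
        if col != "sex":
            df[col] = vals
    for d in CNI_DRUGS:
        df[f"exp_{d}"] = d == "cyclosporine"
        df[f"onset_{d}"] = np.nan
    if rng is not None:
        df = df.sample(frac=1.0, random_state=np.random.RandomState(
            rng.integers(0, 2**31 - 1))).reset_index(drop=True)
    return df
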