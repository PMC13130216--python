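"""Signal classification, PT-level scans and descriptive summaries.

Positivity thresholds follow the conventional pharmacovigilance criteria:
ROR positive when the case count is >= 3 and the 95% CI lower bound exceeds
1; PRR positive when cases >= 3, PRR >= 2 and chi-square >= 4; BCPNN
positive when cases >= 3 and IC025 > 0; MGPS positive when EBGM > 2 (EB05
selectable).  Joint classification: a pair positive on at least two
algorithms is a *valid* signal, on all four a *strong* signal — the joint
rule offsets the biases of any single estimator.

PT-level scans test each Preferred Term separately and control the
family-wise error with Bonferroni on the chi-square p-values; both raw and
adjusted p-values are reported.  A separate, laxer per-PT flag
(``ror_point_gt1``) marks a ROR point estimate above 1, as used when ranking
frequently reported terms — it is deliberately named apart from the
CI-based criterion to avoid conflating the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from ._util import percent
from .disproportionality import (
    BCPNNHyperParams,
    MGPSResults,
    SignalStats,
    compute_signal_stats,
    contingency,
)
from .onset import median_iqr

__all__ = [
    "SignalThresholds",
    "SignalVerdict",
    "evaluate_signal",
    "smq_signal_table",
    "pt_level_scan",
    "top_k_events",
    "reporting_proportion",
    "descriptive_summary",
    "annual_counts",
    "onset_histogram",
]


@dataclass(frozen=True)
class SignalThresholds:
    min_cases: int = 3
    ror_lo_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm_min: float = 2.0
    ebgm_criterion: str = "ebgm"  # or "eb05"
    valid_min_algorithms: int = 2

    def __post_init__(self) -> None:
        if self.ebgm_criterion not in {"ebgm", "eb05"}:
            raise ValueError("ebgm_criterion must be 'ebgm' or 'eb05'")
        if not 1 <= self.valid_min_algorithms <= 4:
            raise ValueError("valid_min_algorithms must be in 1..4")


@dataclass(frozen=True)
class SignalVerdict:
    ror_pos: bool
    prr_pos: bool
    bcpnn_pos: bool
    mgps_pos: bool
    classification: str  # none / valid / strong

    @property
    def n_positive(self) -> int:
        return sum((self.ror_pos, self.prr_pos, self.bcpnn_pos, self.mgps_pos))


def evaluate_signal(stats: SignalStats, thresholds: SignalThresholds | None = None) -> SignalVerdict:
    """Per-algorithm positivity and the joint valid/strong classification.

    The case-count gate applies to all four algorithms; NaN statistics are
    never positive.
    """
    t = thresholds or SignalThresholds()
    gate = stats.cases >= t.min_cases
    ror_pos = bool(gate and stats.ror_lo > t.ror_lo_gt)
    prr_pos = bool(gate and stats.prr >= t.prr_min and stats.chi2 >= t.chi2_min)
    bcpnn_pos = bool(gate and stats.ic025 > t.ic025_gt)
    mgps_value = stats.ebgm if t.ebgm_criterion == "ebgm" else stats.eb05
    mgps_pos = bool(gate and mgps_value > t.ebgm_min)
    n_pos = sum((ror_pos, prr_pos, bcpnn_pos, mgps_pos))
    if n_pos == 4:
        cls = "strong"
    elif n_pos >= t.valid_min_algorithms:
        cls = "valid"
    else:
        cls = "none"
    return SignalVerdict(ror_pos, prr_pos, bcpnn_pos, mgps_pos, cls)


def smq_signal_table(
    cohort: pd.DataFrame,
    drugs: list[str],
    prior: MGPSResults | None = None,
    thresholds: SignalThresholds | None = None,
    hyper: BCPNNHyperParams | None = None,
    include_total: bool = True,
) -> pd.DataFrame:
    """SMQ-level signal statistics per drug (plus a pooled Total row).

    The Total row treats exposure to any study drug as the target; its
    comparator is the remaining reports of the batch.
    """
    rows = []
    work = cohort
    drop_total = False
    if include_total:
        work = cohort.copy()
        work["exp__total"] = np.column_stack(
            [cohort[f"exp_{d}"].to_numpy(bool) for d in drugs]
        ).any(axis=1)
        drop_total = True
    for label in list(drugs) + (["_total"] if include_total else []):
        table = contingency(work, label, "smq")
        st = compute_signal_stats(table, prior=prior, hyper=hyper)
        verdict = evaluate_signal(st, thresholds)
        rows.append(
            {"drug": "Total" if label == "_total" else label,
             "a": table.a, "b": table.b, "c": table.c, "d": table.d,
             **st.as_dict(),
             "ror_pos": verdict.ror_pos, "prr_pos": verdict.prr_pos,
             "bcpnn_pos": verdict.bcpnn_pos, "mgps_pos": verdict.mgps_pos,
             "classification": verdict.classification}
        )
    if drop_total:
        del work
    return pd.DataFrame(rows)


def pt_level_scan(
    cohort: pd.DataFrame,
    drug: str,
    pt_list,
    thresholds: SignalThresholds | None = None,
    prior: MGPSResults | None = None,
    hyper: BCPNNHyperParams | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-PT disproportionality scan with family-wise error control.

    Each PT is tested as its own event definition against the whole cohort;
    the chi-square p-value (1 df) is Bonferroni-adjusted over the
    ``m = len(pt_list)`` terms scanned.  Rows are sorted by descending ROR
    (undefined RORs last).
    """
    pts = [str(p).strip().casefold() for p in pt_list]
    if not pts:
        raise ValueError("empty PT list")
    if correction not in {"bonferroni", "none"}:
        raise ValueError(f"unknown correction {correction!r}")
    m = len(pts)
    rows = []
    for pt in pts:
        table = contingency(cohort, drug, pt)
        st = compute_signal_stats(table, prior=prior, hyper=hyper)
        verdict = evaluate_signal(st, thresholds)
        if np.isfinite(st.chi2):
            p_raw = float(_sps.chi2.sf(st.chi2, df=1))
        else:
            p_raw = float("nan")
        adj = min(1.0, m * p_raw) if correction == "bonferroni" else p_raw
        rows.append(
            {"pt": pt, "a": table.a, "b": table.b, "c": table.c, "d": table.d,
             **st.as_dict(),
             "p_raw": p_raw, "adj_p": adj,
             "ror_pos": verdict.ror_pos, "prr_pos": verdict.prr_pos,
             "bcpnn_pos": verdict.bcpnn_pos, "mgps_pos": verdict.mgps_pos,
             "classification": verdict.classification,
             "undefined": not np.isfinite(st.ror)}
        )
    df = pd.DataFrame(rows)
    df = df.sort_values("ror", ascending=False, na_position="last", kind="mergesort")
    return df.reset_index(drop=True)


def top_k_events(cohort: pd.DataFrame, drug: str, k: int = 30) -> pd.DataFrame:
    """Most frequently reported SMQ PTs among a drug's exposed reports.

    Ranked by report count descending, ties broken alphabetically.  Each row
    carries the PT's ROR for this drug and the lax point-estimate flag
    ``ror_point_gt1`` used when counting "positive" terms in a frequency
    ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    exposed = cohort[cohort[f"exp_{drug}"]]
    counts: dict[str, int] = {}
    for pts in exposed["matched_pts"]:
        for pt in pts:
            counts[pt] = counts.get(pt, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    rows = []
    for rank, (pt, count) in enumerate(ranked, start=1):
        r = compute_signal_stats(contingency(cohort, drug, pt))
        rows.append(
            {"rank": rank, "pt": pt, "count": count, "ror": r.ror,
             "ror_lo": r.ror_lo, "ror_hi": r.ror_hi,
             "ror_point_gt1": bool(np.isfinite(r.ror) and r.ror > 1.0)}
        )
    return pd.DataFrame(rows)


def reporting_proportion(cohort: pd.DataFrame, drug: str) -> float:
    """Share of a drug's reports that are SMQ events (0..1).

    The published rendering is this value as a percentage with one decimal.
    """
    exposed = cohort[f"exp_{drug}"].to_numpy(bool)
    n_exposed = int(exposed.sum())
    if n_exposed == 0:
        raise ValueError(f"no exposed reports for {drug!r}")
    return float((cohort["event"].to_numpy(bool) & exposed).sum() / n_exposed)


_OUTCOME_ORDER = ["Died", "Life threatening", "Hospitalized", "Disabled", "Other outcomes"]
_REPORTER_ORDER = ["physician", "pharmacist", "other_health", "consumer"]


def _characteristic_block(sub: pd.DataFrame, col: str, levels) -> list[dict]:
    known = sub[sub[col].notna()]
    denom = len(known)
    rows = []
    for level in levels:
        n = int((known[col] == level).sum())
        rows.append({"level": level, "count": n, "pct": percent(n, denom) if denom else float("nan")})
    rows.append({"level": "Data available", "count": denom, "pct": float("nan")})
    return rows


def descriptive_summary(
    cohort: pd.DataFrame,
    drugs: list[str] | None = None,
    event_only: bool = True,
    top_countries: int = 10,
) -> pd.DataFrame:
    """Characteristics table: per-drug counts and percentages.

    Percentages use the "data available" denominator of each characteristic
    (reports with the field missing are excluded from that block only).
    Long format: characteristic, level, drug, count, pct.  Medians (age,
    weight) and onset quartiles are emitted as value rows with NaN counts.
    ``event_only`` restricts to SMQ-event reports, the usual universe of a
    characteristics table.
    """
    drugs = drugs or [c[4:] for c in cohort.columns if c.startswith("exp_")]
    work = cohort[cohort["event"]] if event_only else cohort
    out = []

    def _append(characteristic, drug_label, rows):
        for r in rows:
            out.append({"characteristic": characteristic, "drug": drug_label, **r})

    subsets = [(d, work[work[f"exp_{d}"]]) for d in drugs]
    any_exp = np.column_stack(
        [work[f"exp_{d}"].to_numpy(bool) for d in drugs]
    ).any(axis=1)
    subsets.append(("Total", work[any_exp]))

    for drug_label, sub in subsets:
        _append("sex", drug_label, _characteristic_block(sub, "sex", ["F", "M"]))
        _append("age", drug_label, _characteristic_block(sub, "age_bin", ["<18", "18-65", ">=65"]))
        ages = sub["age_years"].dropna()
        _append("age", drug_label, [{"level": "Median", "count": np.nan,
                                     "pct": float(ages.median()) if len(ages) else float("nan")}])
        _append("weight", drug_label, _characteristic_block(sub, "weight_bin", ["<50", "50-80", ">=80"]))
        wts = sub["weight_kg"].dropna()
        _append("weight", drug_label, [{"level": "Median", "count": np.nan,
                                        "pct": float(wts.median()) if len(wts) else float("nan")}])
        _append("reporter", drug_label, _characteristic_block(sub, "reporter", _REPORTER_ORDER))
        _append("outcome", drug_label, _characteristic_block(sub, "outcome_group", _OUTCOME_ORDER))
        # top countries by count over the Total column's ranking
        known_c = sub[sub["country"].notna()]
        denom_c = len(known_c)
        top = known_c["country"].value_counts().head(top_countries)
        rows_c = [{"level": c, "count": int(n), "pct": percent(int(n), denom_c)}
                  for c, n in top.items()]
        rows_c.append({"level": "Data available", "count": denom_c, "pct": float("nan")})
        _append("country", drug_label, rows_c)
        # onset quartiles pooled over this drug's onset column(s)
        if drug_label == "Total":
            onset_vals = pd.concat(
                [sub[f"onset_{d}"][sub[f"exp_{d}"]] for d in drugs], axis=0
            ).dropna()
        else:
            onset_vals = sub[f"onset_{drug_label}"].dropna()
        if len(onset_vals):
            med, q1, q3 = median_iqr(onset_vals)
        else:
            med = q1 = q3 = float("nan")
        _append("time_to_onset", drug_label, [
            {"level": "Median", "count": np.nan, "pct": med},
            {"level": "q1", "count": np.nan, "pct": q1},
            {"level": "q3", "count": np.nan, "pct": q3},
            {"level": "n", "count": len(onset_vals), "pct": float("nan")},
        ])
    return pd.DataFrame(out, columns=["characteristic", "drug", "level", "count", "pct"])


def annual_counts(cohort: pd.DataFrame, drugs: list[str] | None = None,
                  event_only: bool = True) -> pd.DataFrame:
    """Reports per calendar year (FDA receipt year) per drug."""
    drugs = drugs or [c[4:] for c in cohort.columns if c.startswith("exp_")]
    work = cohort[cohort["event"]] if event_only else cohort
    work = work[work["year"].notna()]
    rows = []
    for year, sub in work.groupby("year"):
        row = {"year": int(year)}
        for d in drugs:
            row[d] = int(sub[f"exp_{d}"].sum())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


ONSET_BINS = ((0, 30), (31, 90), (91, 180), (181, 360), (361, None))


def onset_histogram(times) -> pd.DataFrame:
    """Onset counts in the conventional 0-30/31-90/91-180/181-360/>360 bins."""
    arr = np.asarray(list(times), dtype=float)
    rows = []
    for lo, hi in ONSET_BINS:
        if hi is None:
            mask = arr > lo - 1
            label = f">{lo - 1}"
        else:
            mask = (arr >= lo) & (arr <= hi)
            label = f"{lo}-{hi}"
        n = int(mask.sum())
        rows.append({"bin": label, "count": n,
                     "pct": percent(n, arr.size) if arr.size else float("nan")})
    return pd.DataFrame(rows)
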