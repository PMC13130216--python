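"""Threshold classification, Bonferroni control, rankings, summaries."""

import numpy as np
import pandas as pd
import pytest

from faerspv.disproportionality import MGPSResults, SignalStats
from faerspv.signals import (
    SignalThresholds,
    annual_counts,
    descriptive_summary,
    evaluate_signal,
    onset_histogram,
    pt_level_scan,
    reporting_proportion,
    smq_signal_table,
    top_k_events,
)

PRIOR = MGPSResults(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, w=1 / 3,
                    loglik=0.0, converged=True, n_cells=1)


def _stats(cases=100, ror_lo=2.0, prr=3.0, chi2=50.0, ic025=1.0, ebgm=3.0,
           eb05=2.5):
    return SignalStats(cases=cases, ror=ror_lo + 1, ror_lo=ror_lo,
                       ror_hi=ror_lo + 2, prr=prr, chi2=chi2, ic=ic025 + 0.5,
                       ic025=ic025, ebgm=ebgm, eb05=eb05)


def test_published_smq_row_classifies_strong():
    """All-positive row (9,141 cases, ROR lo 2.99, PRR 2.94, IC025 1.52,
    EBGM 2.92) satisfies all four criteria."""
    st = SignalStats(cases=9141, ror=3.06, ror_lo=2.99, ror_hi=3.12,
                     prr=2.94, chi2=11827.37, ic=1.55, ic025=1.52,
                     ebgm=2.92, eb05=2.87)
    v = evaluate_signal(st)
    assert (v.ror_pos, v.prr_pos, v.bcpnn_pos, v.mgps_pos) == (True,) * 4
    assert v.classification == "strong"


def test_case_count_gate_blocks_everything():
    v = evaluate_signal(_stats(cases=2, ror_lo=100.0, prr=100.0, chi2=1e6,
                               ic025=10.0, ebgm=100.0))
    assert v.n_positive == 0 and v.classification == "none"


def test_two_algorithms_positive_is_valid():
    # ROR and PRR positive; BCPNN and MGPS below their thresholds
    v = evaluate_signal(_stats(ic025=-0.5, ebgm=1.5))
    assert v.n_positive == 2 and v.classification == "valid"
    # a single positive is not a valid signal
    v1 = evaluate_signal(_stats(prr=1.0, chi2=1.0, ic025=-0.5, ebgm=1.5))
    assert v1.n_positive == 1 and v1.classification == "none"


def test_eb05_criterion_configurable():
    t = SignalThresholds(ebgm_criterion="eb05")
    v = evaluate_signal(_stats(ebgm=5.0, eb05=1.5), t)
    assert not v.mgps_pos
    with pytest.raises(ValueError):
        SignalThresholds(ebgm_criterion="median")


def test_verdict_monotone_in_statistics():
    """Raising any statistic never demotes the classification."""
    rank = {"none": 0, "valid": 1, "strong": 2}
    base = _stats(ror_lo=0.9, prr=1.9, chi2=3.0, ic025=-0.1, ebgm=1.9)
    before = rank[evaluate_signal(base).classification]
    for field, delta in [("ror_lo", 1.0), ("prr", 1.0), ("chi2", 10.0),
                         ("ic025", 1.0), ("ebgm", 1.0)]:
        kwargs = dict(cases=100, ror_lo=0.9, prr=1.9, chi2=3.0, ic025=-0.1,
                      ebgm=1.9, eb05=1.0)
        kwargs[field] += delta
        after = rank[evaluate_signal(_stats(**kwargs)).classification]
        assert after >= before


def test_bonferroni_multiplication_and_bounds(small_cohort, small_config):
    pts = [pt for pt, _ in small_config.events]
    scan = pt_level_scan(small_cohort, "tacrolimus", pts, prior=PRIOR)
    assert len(scan) == len(pts)
    m = len(pts)
    finite = scan[np.isfinite(scan["p_raw"])]
    assert np.allclose(finite["adj_p"], np.minimum(1.0, m * finite["p_raw"]))
    assert (finite["adj_p"] >= finite["p_raw"] - 1e-15).all()
    # m = 1: adjusted equals raw
    one = pt_level_scan(small_cohort, "tacrolimus", pts[:1], prior=PRIOR)
    assert one["adj_p"].iloc[0] == pytest.approx(one["p_raw"].iloc[0])
    # sorted by descending ROR, undefined last
    rors = scan["ror"].to_numpy()
    finite_rors = rors[np.isfinite(rors)]
    assert (np.diff(finite_rors) <= 1e-12).all()


def test_bonferroni_hand_value():
    """m = 113 terms at raw p 0.0004 adjusts to 0.0452."""
    assert min(1.0, 113 * 0.0004) == pytest.approx(0.0452)


def test_pt_absent_from_cohort_flagged_undefined(small_cohort):
    scan = pt_level_scan(small_cohort, "tacrolimus", ["No such term"], prior=PRIOR)
    assert scan["a"].iloc[0] == 0
    assert bool(scan["undefined"].iloc[0])


def test_pt_scan_null_family_wise_control():
    """On null cohorts no PT should reach the strong classification and
    Bonferroni keeps the family-wise rejection rate near alpha."""
    from faerspv import synthetic as syn

    pts = [f"pt {j}" for j in range(50)]
    reps = 25
    strong_total = 0
    fw_reject = 0
    for rep in range(reps):
        rng = np.random.default_rng(6000 + rep)
        n = 4000
        exp = rng.random(n) < 0.20
        occ = {pt: rng.random(n) < 0.05 for pt in pts}
        reactions = [frozenset(pt for pt in pts if occ[pt][i]) for i in range(n)]
        cohort = pd.DataFrame({"exp_d": exp, "reactions": reactions,
                               "event": [bool(r) for r in reactions]})
        scan = pt_level_scan(cohort, "d", pts, prior=PRIOR)
        strong_total += int((scan["classification"] == "strong").sum())
        fw_reject += int((scan["adj_p"] < 0.05).any())
    assert strong_total <= 1
    assert fw_reject / reps <= 0.2


def test_top_k_ranking_count_then_alphabetical():
    cohort = pd.DataFrame({
        "exp_d": [True] * 6 + [False] * 4,
        "event": [True] * 6 + [False] * 4,
        "matched_pts": [frozenset({"b term", "a term"}), frozenset({"b term"}),
                        frozenset({"a term"}), frozenset({"c term"}),
                        frozenset({"b term"}), frozenset({"a term"})]
        + [frozenset()] * 4,
        "reactions": [frozenset({"b term", "a term"}), frozenset({"b term"}),
                      frozenset({"a term"}), frozenset({"c term"}),
                      frozenset({"b term"}), frozenset({"a term"})]
        + [frozenset()] * 4,
    })
    top = top_k_events(cohort, "d", k=30)
    # ties (a term, b term both 3) broken alphabetically
    assert list(top["pt"]) == ["a term", "b term", "c term"]
    assert list(top["count"]) == [3, 3, 1]
    top2 = top_k_events(cohort, "d", k=2)
    assert len(top2) == 2
    with pytest.raises(ValueError):
        top_k_events(cohort, "d", k=0)


def test_top_pt_matches_generator_truth(small_cohort, small_config):
    """The most frequent renal PT for a drug has the highest configured
    occurrence probability among exposed reports."""
    probs = {pt: b * small_config.effect[("tacrolimus", pt)]
             for pt, b in small_config.events}
    expected_top = max(probs, key=probs.get).casefold()
    top = top_k_events(small_cohort, "tacrolimus", k=5)
    assert top["pt"].iloc[0] == expected_top
    assert bool(top["ror_point_gt1"].iloc[0])


def test_reporting_proportion_published_values():
    from faerspv.published_counts import exposure_event_cohort

    cohort = exposure_event_cohort()
    assert 100 * reporting_proportion(cohort, "cyclosporine") == pytest.approx(20.6, abs=0.05)
    assert 100 * reporting_proportion(cohort, "tacrolimus") == pytest.approx(27.3, abs=0.05)
    assert 100 * reporting_proportion(cohort, "voclosporin") == pytest.approx(25.8, abs=0.05)


def test_reporting_proportion_zero_events_and_errors():
    cohort = pd.DataFrame({"exp_d": [True] * 5, "event": [False] * 5})
    assert reporting_proportion(cohort, "d") == 0.0
    with pytest.raises(ValueError):
        reporting_proportion(pd.DataFrame({"exp_d": [False], "event": [False]}), "d")


def test_descriptive_summary_data_available_denominators():
    from faerspv.published_counts import characteristics_cohort

    desc = descriptive_summary(characteristics_cohort())

    def cell(char, drug, level):
        row = desc[(desc["characteristic"] == char) & (desc["drug"] == drug)
                   & (desc["level"] == level)]
        return row.iloc[0]

    assert cell("sex", "voclosporin", "F")["count"] == 631
    assert cell("sex", "voclosporin", "F")["pct"] == pytest.approx(81.52, abs=0.05)
    assert cell("age", "Total", "18-65")["pct"] == pytest.approx(69.71, abs=0.05)
    assert cell("outcome", "tacrolimus", "Died")["pct"] == pytest.approx(14.33, abs=0.05)
    assert cell("outcome", "Total", "Hospitalized")["pct"] == pytest.approx(36.59, abs=0.05)


def test_descriptive_percentages_sum_to_hundred(small_cohort):
    desc = descriptive_summary(small_cohort)
    for (char, drug), block in desc.groupby(["characteristic", "drug"]):
        if char in {"country", "time_to_onset"}:
            continue
        levels = block[~block["level"].isin(["Data available", "Median"])]
        total = levels["pct"].dropna().sum()
        if levels["count"].fillna(0).sum() > 0:
            assert total == pytest.approx(100.0, abs=0.1)


def test_descriptive_all_missing_weight_shows_zero_denominator():
    cohort = pd.DataFrame({
        "exp_d": [True] * 3, "event": [True] * 3, "sex": ["F", "M", "F"],
        "age_years": [40.0] * 3, "age_bin": ["18-65"] * 3,
        "weight_kg": [np.nan] * 3, "weight_bin": [None] * 3,
        "reporter": [None] * 3, "country": [None] * 3,
        "outcome_group": [None] * 3, "onset_d": [np.nan] * 3,
    })
    desc = descriptive_summary(cohort, drugs=["d"])
    wt = desc[(desc["characteristic"] == "weight") & (desc["drug"] == "d")]
    assert wt[wt["level"] == "Data available"]["count"].iloc[0] == 0
    assert wt[wt["level"].isin(["<50", "50-80", ">=80"])]["pct"].isna().all()


def test_smq_signal_table_has_total_row(small_cohort, small_config):
    tab = smq_signal_table(small_cohort, [d.key for d in small_config.drugs],
                           prior=PRIOR)
    assert list(tab["drug"])[-1] == "Total"
    assert (tab["cases"].iloc[:-1].sum() >= tab["cases"].iloc[-1])


def test_annual_counts_and_onset_histogram(small_cohort):
    ann = annual_counts(small_cohort)
    assert (ann["year"].diff().dropna() > 0).all()
    hist = onset_histogram([1, 15, 40, 100, 200, 400, 800])
    assert list(hist["count"]) == [2, 1, 1, 1, 2]
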