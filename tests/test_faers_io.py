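"""Quarterly ASCII parsing, deduplication, drug/SMQ matching, cohorting."""

import datetime as dt
import random

import pandas as pd
import pytest

from faerspv import (
    SMQDefinition,
    build_cohort,
    deduplicate,
    map_smq,
    match_drug,
    parse_quarter,
    write_quarter,
)
from faerspv.faers_io import ConfigurationError, CovariateScheme, ParseError, load_smq
from faerspv.records import DrugEntry, ReportRecord, TherapyEntry

LEXICON = {
    "tacrolimus": frozenset({"tacrolimus", "prograf"}),
    "cyclosporine": frozenset({"cyclosporine", "neoral"}),
}
SMQ = SMQDefinition("renal", frozenset({"Proteinuria", "Acute kidney injury"}))


def _write(tmp_path, name, header, rows):
    path = tmp_path / f"{name}.txt"
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


def _fixture_quarter(tmp_path):
    demo = _write(tmp_path, "DEMO",
                  "primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$occp_cod$occr_country",
                  ["1001$100$20230301$20230111$F$45$YR$70$KG$MD$US",
                   "1002$101$20230302$$M$60$YR$$$PH$JP",
                   "1003$102$20230305$20230215$$6$MON$$$CN$FR"])
    drug = _write(tmp_path, "DRUG", "primaryid$drug_seq$drugname$role_cod",
                  ["1001$1$PROGRAF$PS", "1001$2$Prednisone$C",
                   "1002$1$ Neoral $PS", "1003$1$Tacrolimus$C"])
    reac = _write(tmp_path, "REAC", "primaryid$pt",
                  ["1001$Proteinuria", "1001$Headache", "1002$Nausea"])
    outc = _write(tmp_path, "OUTC", "primaryid$outc_cod", ["1001$HO", "1002$DE"])
    ther = _write(tmp_path, "THER", "primaryid$dsg_drug_seq$start_dt$end_dt",
                  ["1001$1$20230101$"])
    indi = _write(tmp_path, "INDI", "primaryid$indi_drug_seq$indi_pt",
                  ["1001$1$Renal transplant"])
    return demo, drug, reac, outc, ther, indi


def test_parse_quarter_joins_satellites(tmp_path):
    """Each DEMO row yields one record with its satellite rows attached."""
    records, stats = parse_quarter(*_fixture_quarter(tmp_path), return_stats=True)
    assert len(records) == 3
    by_pid = {r.primary_id: r for r in records}
    assert by_pid[1001].reactions == ["Proteinuria", "Headache"]
    assert by_pid[1001].outcomes == {"HO"}
    assert by_pid[1001].therapies[0].start_date == dt.date(2023, 1, 1)
    assert by_pid[1001].indications == ["Renal transplant"]
    assert by_pid[1002].sex == "M"
    # reports without REAC rows are kept, flagged in stats
    assert by_pid[1003].reactions == []
    assert stats.empty_reaction_reports == 1
    # unit conversion: 6 months -> 0.5 years
    assert by_pid[1003].age_years == pytest.approx(0.5)


def test_parse_quarter_missing_mandatory_column(tmp_path):
    paths = list(_fixture_quarter(tmp_path))
    bad = _write(tmp_path, "DEMO_BAD", "pid$caseid$fda_dt", ["1$1$20230101"])
    paths[0] = bad
    with pytest.raises(ParseError, match="primaryid"):
        parse_quarter(*paths)


def test_parse_onset_from_ther_dates(tmp_path):
    """THER start 20230101 with event 20230111 gives a 10-day onset."""
    from faerspv.onset import onset_days

    records = parse_quarter(*_fixture_quarter(tmp_path))
    rec = next(r for r in records if r.primary_id == 1001)
    assert onset_days(rec, "tacrolimus", LEXICON) == 10.0


def _rec(pid, cid, fda_key):
    return ReportRecord(primary_id=pid, case_id=cid, fda_date_key=fda_key,
                        reactions=["Nausea"])


def test_deduplicate_latest_fda_date_then_highest_pid():
    survivors = deduplicate([_rec(1, 100, 20230101), _rec(2, 100, 20230301)])
    assert [r.primary_id for r in survivors] == [2]
    survivors = deduplicate([_rec(3, 100, 20230301), _rec(2, 100, 20230301)])
    assert [r.primary_id for r in survivors] == [3]
    assert deduplicate([]) == []


def test_deduplicate_permutation_invariant_and_idempotent():
    """Brute-force max per case agrees for any input permutation."""
    rnd = random.Random(5)
    records = []
    for cid in range(1, 101):
        for v in range(rnd.randint(1, 4)):
            records.append(_rec(cid * 10 + v, cid, 20200101 + v * 31))
    expected = {}
    for r in records:  # independent brute-force oracle
        key = (r.fda_date_key, r.primary_id)
        if r.case_id not in expected or key > expected[r.case_id]:
            expected[r.case_id] = key
    for _ in range(5):
        rnd.shuffle(records)
        out = deduplicate(records)
        assert len(out) == len({r.case_id for r in records})
        assert {r.case_id: (r.fda_date_key, r.primary_id) for r in out} == expected
        assert deduplicate(out) == out


@pytest.mark.parametrize(
    "name,role,expected",
    [
        ("PROGRAF", "PS", True),          # brand synonym
        ("prograf", "C", False),          # concomitant filtered out by default
        (" Tacrolimus ", "PS", True),     # trim + case-fold
        ("Neoral", "PS", False),          # other drug's name
    ],
)
def test_match_drug_normalization_and_roles(name, role, expected):
    rec = ReportRecord(primary_id=1, case_id=1,
                       drugs=[DrugEntry(seq=1, name=name, role=role)])
    assert match_drug(rec, LEXICON)["tacrolimus"] is expected


def test_match_drug_empty_lexicon_is_configuration_error():
    rec = ReportRecord(primary_id=1, case_id=1)
    with pytest.raises(ConfigurationError):
        match_drug(rec, {})


def test_map_smq_set_semantics():
    assert map_smq(["Proteinuria", "Headache"], SMQ) == {"proteinuria"}
    assert map_smq(["Headache"], SMQ) == frozenset()
    # duplicate PT on one report counts once
    assert map_smq(["proteinuria", "PROTEINURIA"], SMQ) == {"proteinuria"}


def test_load_smq_comments_and_folding(tmp_path):
    p = tmp_path / "pts.txt"
    p.write_text("# renal PT list\nProteinuria\nAcute kidney injury  # narrow\n\n")
    smq = load_smq(p)
    assert smq.pts == {"proteinuria", "acute kidney injury"}


def test_covariate_bins():
    s = CovariateScheme()
    assert s.age_bin(70.0) == ">=65"
    assert s.age_bin(17.9) == "<18"
    assert s.age_bin(None) is None
    assert s.weight_bin(49.9) == "<50"
    assert s.weight_bin(80.0) == ">=80"


def test_build_cohort_row_count_and_event_iff_match(small_cohort, small_records):
    deduped_n = len({r.case_id for r in small_records})
    assert len(small_cohort) == deduped_n
    assert (small_cohort["event"] == small_cohort["matched_pts"].map(bool)).all()


def test_build_cohort_exposure_prevalence(small_cohort, small_config):
    """Exposure prevalence sits within binomial noise of the configured rate."""
    for spec in small_config.drugs:
        p_hat = small_cohort[f"exp_{spec.key}"].mean()
        se = (spec.exposure_prob * (1 - spec.exposure_prob) / len(small_cohort)) ** 0.5
        assert abs(p_hat - spec.exposure_prob) < 4 * se + 1e-9


def test_roundtrip_serialize_reparse_identical_cohort(tmp_path, small_config, small_records):
    """Writing the ASCII dialect and re-parsing reproduces the same cohort."""
    deduped = deduplicate(small_records)
    paths = write_quarter(deduped, tmp_path)
    reparsed = parse_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"],
                             paths["OUTC"], paths["THER"], paths["INDI"])
    smq = SMQDefinition("renal", frozenset(r[0] for r in small_config.events))
    lex = small_config.lexicon()
    c1 = build_cohort(deduped, lex, smq).sort_values("primary_id").reset_index(drop=True)
    c2 = build_cohort(reparsed, lex, smq).sort_values("primary_id").reset_index(drop=True)
    for col in ["primary_id", "case_id", "event", "sex", "age_bin", "weight_bin",
                "reporter", "country", "indication_group", "outcome_group",
                "matched_pts", "year"] + [f"exp_{d}" for d in lex] + [
                    f"onset_{d}" for d in lex]:
        pd.testing.assert_series_equal(c1[col], c2[col], check_names=False)
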