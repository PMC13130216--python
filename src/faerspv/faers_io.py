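"""Reading FAERS-style quarterly ASCII extracts and building analysis cohorts.

The quarterly extract is a set of ``$``-delimited text tables sharing a
``primaryid`` key: DEMO (one row per report version), DRUG, REAC, OUTC, THER
and INDI (many rows per report).  This module parses them into
:class:`~faerspv.records.ReportRecord` objects, applies the FDA
deduplication rule (keep, per case, the version with the latest FDA receipt
date, ties broken by the highest primary id), and assembles the flat cohort
table that every downstream analysis consumes.

Drug-name matching is exact on case-folded, whitespace-trimmed strings
against a user-supplied lexicon of generic and brand names; handling
free-text spelling variants is the lexicon's job, not the matcher's.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import fold, parse_faers_date
from .onset import onset_days_flagged
from .records import (
    OUTCOME_CODES,
    ROLE_CODES,
    DrugEntry,
    ReportRecord,
    SMQDefinition,
    TherapyEntry,
)

logger = logging.getLogger(__name__)

DELIM = "$"

_AGE_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_WT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}

_OCCP_TO_REPORTER = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other_health",
    "HP": "other_health",
    "CN": "consumer",
}


class ParseError(ValueError):
    """A mandatory column is missing from an input table."""


class ConfigurationError(ValueError):
    """An invalid analysis configuration (e.g. an empty drug lexicon)."""


@dataclass
class ParseStats:
    """Row-level bookkeeping from one parsed quarter."""

    demo_rows: int = 0
    malformed: dict[str, int] = field(default_factory=dict)
    orphan_rows: dict[str, int] = field(default_factory=dict)
    empty_reaction_reports: int = 0


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=DELIM, dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{Path(path).name}: missing mandatory column {col!r}")
    return df


def _to_float(s: str) -> float | None:
    s = s.strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def parse_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path,
    ther_path: str | Path,
    indi_path: str | Path,
    return_stats: bool = False,
):
    """Parse one quarterly extract into report records.

    One record is produced per DEMO row; the satellite tables are joined on
    ``primaryid``.  Malformed rows (non-integer ids, unknown codes) are
    counted and logged, never fatal.  Unknown columns are ignored.
    """
    stats = ParseStats()

    demo = _read_table(demo_path, ("primaryid", "caseid"))
    drug = _read_table(drug_path, ("primaryid",))
    reac = _read_table(reac_path, ("primaryid",))
    outc = _read_table(outc_path, ("primaryid",))
    ther = _read_table(ther_path, ("primaryid",))
    indi = _read_table(indi_path, ("primaryid",))

    records: dict[int, ReportRecord] = {}
    for row in demo.itertuples(index=False):
        d = row._asdict()
        try:
            pid = int(d["primaryid"])
            cid = int(d["caseid"])
        except (ValueError, KeyError):
            stats.malformed["DEMO"] = stats.malformed.get("DEMO", 0) + 1
            continue
        fda_date, fda_key = parse_faers_date(d.get("fda_dt", ""))
        event_date, _ = parse_faers_date(d.get("event_dt", ""))
        sex = d.get("sex", "").strip().upper()
        if sex not in {"F", "M"}:
            sex = "unknown"
        age = _to_float(d.get("age", ""))
        age_cod = d.get("age_cod", "YR").strip().upper() or "YR"
        age_years = None
        if age is not None:
            factor = _AGE_TO_YEARS.get(age_cod)
            age_years = age * factor if factor is not None else None
            if age_years is not None and age_years < 0:
                age_years = None
        wt = _to_float(d.get("wt", ""))
        wt_cod = d.get("wt_cod", "KG").strip().upper() or "KG"
        weight_kg = None
        if wt is not None:
            factor = _WT_TO_KG.get(wt_cod)
            weight_kg = wt * factor if factor is not None else None
            if weight_kg is not None and weight_kg <= 0:
                weight_kg = None
        reporter = _OCCP_TO_REPORTER.get(d.get("occp_cod", "").strip().upper(), "unknown")
        country = d.get("occr_country", "").strip().upper() or None
        if country is not None and len(country) != 2:
            country = None
        if pid in records:
            stats.malformed["DEMO"] = stats.malformed.get("DEMO", 0) + 1
            logger.warning("duplicate primaryid %s in DEMO; keeping first", pid)
            continue
        records[pid] = ReportRecord(
            primary_id=pid,
            case_id=cid,
            fda_date_key=fda_key,
            fda_date=fda_date,
            event_date=event_date,
            sex=sex,
            age_years=age_years,
            weight_kg=weight_kg,
            reporter=reporter,
            country=country,
        )
    stats.demo_rows = len(demo)

    def _satellite(df: pd.DataFrame, name: str, handler) -> None:
        for row in df.itertuples(index=False):
            d = row._asdict()
            try:
                pid = int(d["primaryid"])
            except ValueError:
                stats.malformed[name] = stats.malformed.get(name, 0) + 1
                continue
            rec = records.get(pid)
            if rec is None:
                stats.orphan_rows[name] = stats.orphan_rows.get(name, 0) + 1
                continue
            try:
                handler(rec, d)
            except (ValueError, KeyError):
                stats.malformed[name] = stats.malformed.get(name, 0) + 1

    def _on_drug(rec: ReportRecord, d: dict) -> None:
        seq = int(d.get("drug_seq") or len(rec.drugs) + 1)
        role = d.get("role_cod", "").strip().upper()
        if role not in ROLE_CODES:
            raise ValueError(role)
        name = d.get("drugname", "").strip()
        if not name:
            raise ValueError("empty drugname")
        rec.drugs.append(DrugEntry(seq=seq, name=name, role=role))

    def _on_reac(rec: ReportRecord, d: dict) -> None:
        pt = d.get("pt", "").strip()
        if not pt:
            raise ValueError("empty pt")
        rec.reactions.append(pt)

    def _on_outc(rec: ReportRecord, d: dict) -> None:
        code = d.get("outc_cod", "").strip().upper()
        if code not in OUTCOME_CODES:
            raise ValueError(code)
        rec.outcomes.add(code)

    def _on_ther(rec: ReportRecord, d: dict) -> None:
        seq = int(d.get("dsg_drug_seq") or d.get("drug_seq") or 1)
        start, _ = parse_faers_date(d.get("start_dt", ""))
        end, _ = parse_faers_date(d.get("end_dt", ""))
        if start is not None and end is not None and start > end:
            raise ValueError("start after end")
        rec.therapies.append(TherapyEntry(drug_seq=seq, start_date=start, end_date=end))

    def _on_indi(rec: ReportRecord, d: dict) -> None:
        pt = d.get("indi_pt", "").strip()
        if not pt:
            raise ValueError("empty indi_pt")
        rec.indications.append(pt)

    _satellite(drug, "DRUG", _on_drug)
    _satellite(reac, "REAC", _on_reac)
    _satellite(outc, "OUTC", _on_outc)
    _satellite(ther, "THER", _on_ther)
    _satellite(indi, "INDI", _on_indi)

    out = list(records.values())
    stats.empty_reaction_reports = sum(1 for r in out if not r.reactions)
    if stats.empty_reaction_reports:
        logger.warning(
            "%d report(s) have no REAC rows attached", stats.empty_reaction_reports
        )
    if return_stats:
        return out, stats
    return out


def write_quarter(records: list[ReportRecord], out_dir: str | Path) -> dict[str, Path]:
    """Serialize records back to the quarterly ASCII dialect.

    Used to round-trip synthetic batches through the parser and to emit
    shareable fixtures.  Returns the mapping table-name -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _fmt_date(date, key):
        if date is not None:
            return date.strftime("%Y%m%d")
        if key is not None:
            return str(key)
        return ""

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows, indi_rows = (
        [] for _ in range(6)
    )
    for r in records:
        demo_rows.append(
            {
                "primaryid": r.primary_id,
                "caseid": r.case_id,
                "fda_dt": _fmt_date(r.fda_date, r.fda_date_key),
                "event_dt": _fmt_date(r.event_date, None),
                "sex": r.sex if r.sex in {"F", "M"} else "",
                "age": f"{r.age_years:.2f}" if r.age_years is not None else "",
                "age_cod": "YR" if r.age_years is not None else "",
                "wt": f"{r.weight_kg:.2f}" if r.weight_kg is not None else "",
                "wt_cod": "KG" if r.weight_kg is not None else "",
                "occp_cod": {
                    "physician": "MD",
                    "pharmacist": "PH",
                    "other_health": "OT",
                    "consumer": "CN",
                }.get(r.reporter, ""),
                "occr_country": r.country or "",
            }
        )
        for dr in r.drugs:
            drug_rows.append(
                {
                    "primaryid": r.primary_id,
                    "drug_seq": dr.seq,
                    "drugname": dr.name,
                    "role_cod": dr.role,
                }
            )
        for pt in r.reactions:
            reac_rows.append({"primaryid": r.primary_id, "pt": pt})
        for code in sorted(r.outcomes):
            outc_rows.append({"primaryid": r.primary_id, "outc_cod": code})
        for th in r.therapies:
            ther_rows.append(
                {
                    "primaryid": r.primary_id,
                    "dsg_drug_seq": th.drug_seq,
                    "start_dt": _fmt_date(th.start_date, None),
                    "end_dt": _fmt_date(th.end_date, None),
                }
            )
        for pt in r.indications:
            indi_rows.append({"primaryid": r.primary_id, "indi_drug_seq": 1, "indi_pt": pt})

    tables = {
        "DEMO": (demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
                             "age_cod", "wt", "wt_cod", "occp_cod", "occr_country"]),
        "DRUG": (drug_rows, ["primaryid", "drug_seq", "drugname", "role_cod"]),
        "REAC": (reac_rows, ["primaryid", "pt"]),
        "OUTC": (outc_rows, ["primaryid", "outc_cod"]),
        "THER": (ther_rows, ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"]),
        "INDI": (indi_rows, ["primaryid", "indi_drug_seq", "indi_pt"]),
    }
    paths: dict[str, Path] = {}
    for name, (rows, cols) in tables.items():
        path = out_dir / f"{name}.txt"
        df = pd.DataFrame(rows, columns=cols)
        df.to_csv(path, sep=DELIM, index=False)
        paths[name] = path
    return paths


def deduplicate(records: list[ReportRecord]) -> list[ReportRecord]:
    """FDA deduplication rule: one record per case id.

    Per ``case_id`` the surviving version maximizes ``(fda_date, primary_id)``
    lexicographically — latest receipt date first, highest primary id as the
    tie-break.  Input order is irrelevant; output is sorted by case id.
    """
    best: dict[int, ReportRecord] = {}
    for rec in records:
        key = (rec.fda_date_key or 0, rec.primary_id)
        cur = best.get(rec.case_id)
        if cur is None or key > (cur.fda_date_key or 0, cur.primary_id):
            best[rec.case_id] = rec
    return [best[cid] for cid in sorted(best)]


def load_lexicon(source: str | Path | dict) -> dict[str, frozenset[str]]:
    """Load a drug lexicon: study-drug key -> set of case-folded names.

    Accepts a YAML mapping file (``key: [name, ...]``) or an in-memory dict.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict) or not source:
        raise ConfigurationError("drug lexicon must be a non-empty mapping")
    out: dict[str, frozenset[str]] = {}
    for key, names in source.items():
        if isinstance(names, str):
            names = [names]
        folded = frozenset(fold(n) for n in names if str(n).strip())
        if not folded:
            raise ConfigurationError(f"lexicon entry {key!r} has no names")
        out[str(key)] = folded
    return out


def load_smq(path: str | Path, name: str = "smq", scope: str = "broad") -> SMQDefinition:
    """Load an SMQ PT list: one PT per line, ``#`` comments allowed."""
    pts = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                pts.append(line)
    if not pts:
        raise ConfigurationError(f"SMQ PT list {path} is empty")
    return SMQDefinition(name=name, pts=frozenset(pts), scope=scope)


def match_drug(
    record: ReportRecord,
    lexicon: dict[str, frozenset[str]],
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
) -> dict[str, bool]:
    """Per-study-drug exposure flags for one report.

    A flag is true iff any drug entry's case-folded, trimmed name is in the
    lexicon set for that study drug AND the entry's role code is in *roles*
    (default: primary suspect only).
    """
    if not lexicon:
        raise ConfigurationError("empty drug lexicon")
    names_by_role = [fold(d.name) for d in record.drugs if d.role in roles]
    return {key: any(n in names for n in names_by_role) for key, names in lexicon.items()}


def map_smq(reactions: list[str], smq: SMQDefinition) -> frozenset[str]:
    """Case-folded intersection of a report's reaction PTs with the SMQ."""
    return frozenset(fold(r) for r in reactions) & smq.pts


@dataclass(frozen=True)
class CovariateScheme:
    """Binning scheme for cohort covariates.

    Age bins are ``[0, 18) / [18, 65) / [65, inf)`` years and weight bins
    ``[0, 50) / [50, 80) / [80, inf)`` kg, following the usual FAERS summary
    strata.  ``indication_map`` maps case-folded indication PTs to a group
    label; unmapped indications fall into ``indication_other_label``.
    """

    age_edges: tuple[float, float] = (18.0, 65.0)
    age_labels: tuple[str, str, str] = ("<18", "18-65", ">=65")
    weight_edges: tuple[float, float] = (50.0, 80.0)
    weight_labels: tuple[str, str, str] = ("<50", "50-80", ">=80")
    indication_map: tuple[tuple[str, str], ...] = (
        ("systemic lupus erythematosus", "autoimmune"),
        ("lupus nephritis", "autoimmune"),
        ("rheumatoid arthritis", "autoimmune"),
        ("psoriasis", "autoimmune"),
        ("dermatomyositis", "autoimmune"),
        ("renal transplant", "transplant"),
        ("liver transplant", "transplant"),
        ("cardiac transplant", "transplant"),
        ("bone marrow transplant", "transplant"),
        ("prophylaxis against transplant rejection", "transplant"),
    )
    indication_other_label: str = "other"
    #: level order used as the categorical coding (reference level first)
    indication_levels: tuple[str, ...] = ("autoimmune", "transplant", "other")

    def age_bin(self, age: float | None) -> str | None:
        if age is None:
            return None
        lo, hi = self.age_edges
        if age < lo:
            return self.age_labels[0]
        if age < hi:
            return self.age_labels[1]
        return self.age_labels[2]

    def weight_bin(self, wt: float | None) -> str | None:
        if wt is None:
            return None
        lo, hi = self.weight_edges
        if wt < lo:
            return self.weight_labels[0]
        if wt < hi:
            return self.weight_labels[1]
        return self.weight_labels[2]

    def indication_group(self, indications: list[str]) -> str | None:
        if not indications:
            return None
        mapping = dict(self.indication_map)
        groups = [mapping.get(fold(i), self.indication_other_label) for i in indications]
        # transplant dominates for mixed reports: the strongest risk stratum
        if "transplant" in groups:
            return "transplant"
        if "autoimmune" in groups:
            return "autoimmune"
        return groups[0]


def build_cohort(
    records: list[ReportRecord],
    lexicon: dict[str, frozenset[str]],
    smq: SMQDefinition,
    scheme: CovariateScheme | None = None,
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
) -> pd.DataFrame:
    """Assemble the flat analysis table: one row per deduplicated report.

    Columns: ``primary_id``, ``case_id``, ``year``, per-drug exposure flags
    ``exp_<key>``, ``event`` (any SMQ PT matched), ``matched_pts`` and
    ``reactions`` (case-folded frozensets), binned covariates, ``outcomes``
    and ``outcome_group``, and per-drug onset columns ``onset_<key>`` in days
    (same-day onsets mapped to 0.5 so Weibull support holds).
    """
    scheme = scheme or CovariateScheme()
    if not lexicon:
        raise ConfigurationError("empty drug lexicon")
    rows = []
    anomalies = 0
    for rec in records:
        exposure = match_drug(rec, lexicon, roles)
        matched = map_smq(rec.reactions, smq)
        row = {
            "primary_id": rec.primary_id,
            "case_id": rec.case_id,
            "year": (rec.fda_date_key // 10000) if rec.fda_date_key else None,
            "event": bool(matched),
            "matched_pts": matched,
            "reactions": frozenset(fold(r) for r in rec.reactions),
            "sex": rec.sex if rec.sex in {"F", "M"} else None,
            "age_years": rec.age_years,
            "age_bin": scheme.age_bin(rec.age_years),
            "weight_kg": rec.weight_kg,
            "weight_bin": scheme.weight_bin(rec.weight_kg),
            "reporter": rec.reporter if rec.reporter != "unknown" else None,
            "country": rec.country,
            "indication_group": scheme.indication_group(rec.indications),
            "outcomes": frozenset(rec.outcomes),
            "outcome_group": rec.outcome_group(),
        }
        for key in lexicon:
            row[f"exp_{key}"] = exposure[key]
            onset, anomaly = onset_days_flagged(rec, key, lexicon, roles)
            anomalies += anomaly
            row[f"onset_{key}"] = onset
        rows.append(row)
    if anomalies:
        logger.warning("%d negative onset interval(s) treated as missing", anomalies)
    cohort = pd.DataFrame(rows)
    cohort.attrs["n_records"] = len(records)
    cohort.attrs["drugs"] = list(lexicon)
    cohort.attrs["roles"] = sorted(roles)
    cohort.attrs["onset_anomalies"] = anomalies
    return cohort
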