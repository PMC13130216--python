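"""End-to-end orchestration: config -> parsed records -> cohort -> outputs.

A run produces plain CSV tables plus a JSON metadata file (config echo,
seed, schema version, and the record counts at each stage:
parsed -> deduplicated -> cohort).  Either a directory of quarterly ASCII
tables or a synthetic-generator configuration can be the input; exactly one
must be set.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic as syn
from .disproportionality import MGPSModel, mgps_cells_from_records
from .faers_io import (
    CovariateScheme,
    build_cohort,
    deduplicate,
    load_lexicon,
    load_smq,
    parse_quarter,
    write_quarter,
)
from .onset import WeibullTTOModel, median_iqr
from .records import SMQDefinition
from .risk import multivariable_table, univariable_table
from .signals import (
    SignalThresholds,
    annual_counts,
    descriptive_summary,
    onset_histogram,
    pt_level_scan,
    smq_signal_table,
    top_k_events,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    message: str


@dataclass
class PipelineConfig:
    """Validated configuration of one analysis run."""

    output_dir: str = "faerspv_output"
    seed: int = 0
    quarter_dir: str | None = None
    synthetic: dict | None = None
    lexicon_path: str | None = None
    smq_path: str | None = None
    thresholds: dict = field(default_factory=dict)
    roles: tuple[str, ...] = ("PS",)
    top_k: int = 30
    min_onset_n: int = 10
    emit_ascii: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "roles" in raw:
            raw["roles"] = tuple(raw["roles"])
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Static checks on a configuration; findings are data, not exceptions."""
    findings: list[Finding] = []
    real = config.quarter_dir is not None
    synth = config.synthetic is not None
    if real == synth:
        findings.append(Finding("error", "exactly one of quarter_dir / synthetic must be set"))
    if real:
        qdir = Path(config.quarter_dir)
        if not qdir.is_dir():
            findings.append(Finding("error", f"quarter_dir {qdir} does not exist"))
        if config.lexicon_path is None:
            findings.append(Finding("error", "real-input mode requires lexicon_path"))
        elif not Path(config.lexicon_path).is_file():
            findings.append(Finding("error", f"lexicon {config.lexicon_path} not found"))
        if config.smq_path is None:
            findings.append(Finding("error", "real-input mode requires smq_path"))
        elif not Path(config.smq_path).is_file():
            findings.append(Finding("error", f"SMQ list {config.smq_path} not found"))
    if synth:
        try:
            syn.default_config(**(config.synthetic or {}))
        except Exception as exc:  # configuration errors become findings
            findings.append(Finding("error", f"synthetic config invalid: {exc}"))
    try:
        t = SignalThresholds(**config.thresholds)
        if t.min_cases < 0 or t.prr_min < 0 or t.chi2_min < 0 or t.ebgm_min < 0:
            findings.append(Finding("error", "thresholds must be non-negative"))
    except (TypeError, ValueError) as exc:
        findings.append(Finding("error", f"invalid thresholds: {exc}"))
    if not set(config.roles) <= {"PS", "SS", "C", "I"}:
        findings.append(Finding("error", f"unknown role codes in {config.roles}"))
    if config.top_k < 1:
        findings.append(Finding("error", "top_k must be >= 1"))
    return findings


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the mapping output-name -> path."""
    findings = validate_config(config)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise ValueError("; ".join(f.message for f in errors))

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    meta: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "roles": list(config.roles),
        "thresholds": dataclasses.asdict(SignalThresholds(**config.thresholds)),
        "chi2_correction": "pearson_no_yates",
        "counts": {},
    }

    stage = "input"
    try:
        if config.synthetic is not None:
            syn_cfg = syn.default_config(**{**config.synthetic, "seed": config.seed})
            records = syn.generate(syn_cfg)
            lexicon = syn_cfg.lexicon()
            smq = SMQDefinition("renal injury (synthetic)",
                                frozenset(syn.renal_pt_list(syn_cfg)))
            meta["mode"] = "synthetic"
            if config.emit_ascii:
                write_quarter(records, out_dir / "ascii")
                outputs["ascii"] = out_dir / "ascii"
        else:
            qdir = Path(config.quarter_dir)
            records = parse_quarter(
                qdir / "DEMO.txt", qdir / "DRUG.txt", qdir / "REAC.txt",
                qdir / "OUTC.txt", qdir / "THER.txt", qdir / "INDI.txt",
            )
            lexicon = load_lexicon(config.lexicon_path)
            smq = load_smq(config.smq_path)
            meta["mode"] = "real"
        meta["counts"]["parsed"] = len(records)

        stage = "deduplicate"
        deduped = deduplicate(records)
        meta["counts"]["deduplicated"] = len(deduped)

        stage = "cohort"
        cohort = build_cohort(deduped, lexicon, smq, CovariateScheme(),
                              roles=frozenset(config.roles))
        meta["counts"]["cohort"] = len(cohort)
        meta["counts"]["events"] = int(cohort["event"].sum())
        drugs = list(lexicon)

        stage = "mgps_prior"
        counts, expected, _ = mgps_cells_from_records(deduped, lexicon=lexicon)
        prior = MGPSModel(counts, expected).fit()
        meta["mgps_prior"] = {
            "alpha1": prior.alpha1, "beta1": prior.beta1,
            "alpha2": prior.alpha2, "beta2": prior.beta2,
            "w": prior.w, "loglik": prior.loglik, "n_cells": prior.n_cells,
        }

        thresholds = SignalThresholds(**config.thresholds)

        stage = "smq_signals"
        sig = smq_signal_table(cohort, drugs, prior=prior, thresholds=thresholds)
        outputs["signals_smq"] = out_dir / "signals_smq.csv"
        sig.to_csv(outputs["signals_smq"], index=False)

        stage = "pt_scan"
        pts = sorted(smq.pts)
        for drug in drugs:
            scan = pt_level_scan(cohort, drug, pts, thresholds, prior=prior)
            path = out_dir / f"pt_scan_{drug}.csv"
            scan.to_csv(path, index=False)
            outputs[f"pt_scan_{drug}"] = path

        stage = "top_events"
        for drug in drugs:
            top = top_k_events(cohort, drug, k=config.top_k)
            path = out_dir / f"top_events_{drug}.csv"
            top.to_csv(path, index=False)
            outputs[f"top_events_{drug}"] = path

        stage = "descriptive"
        desc = descriptive_summary(cohort, drugs)
        outputs["descriptive_summary"] = out_dir / "descriptive_summary.csv"
        desc.to_csv(outputs["descriptive_summary"], index=False)
        ann = annual_counts(cohort, drugs)
        outputs["annual_counts"] = out_dir / "annual_counts.csv"
        ann.to_csv(outputs["annual_counts"], index=False)

        stage = "weibull"
        rows = []
        hist_rows = []
        for drug in drugs:
            sub = cohort[cohort[f"exp_{drug}"] & cohort["event"]]
            times = sub[f"onset_{drug}"].dropna().to_numpy()
            row = {"drug": drug, "n": int(times.size)}
            if times.size >= config.min_onset_n and not bool(
                (times == times[0]).all()
            ):
                med, q1, q3 = median_iqr(times)
                fit = WeibullTTOModel(times).fit()
                row.update(
                    median=med, q1=q1, q3=q3,
                    alpha=fit.alpha, alpha_lo=fit.alpha_ci[0], alpha_hi=fit.alpha_ci[1],
                    beta=fit.beta, beta_lo=fit.beta_ci[0], beta_hi=fit.beta_ci[1],
                    failure_type=fit.failure_type,
                )
                hist = onset_histogram(times)
                hist["drug"] = drug
                hist_rows.append(hist)
            rows.append(row)
        outputs["weibull_tto"] = out_dir / "weibull_tto.csv"
        pd.DataFrame(rows).to_csv(outputs["weibull_tto"], index=False)
        if hist_rows:
            outputs["onset_histogram"] = out_dir / "onset_histogram.csv"
            pd.concat(hist_rows, ignore_index=True).to_csv(
                outputs["onset_histogram"], index=False)

        stage = "risk_factors"
        uni_rows, multi_rows = [], []
        for drug in drugs:
            try:
                uni = univariable_table(cohort, drug)
                uni["drug"] = drug
                uni_rows.append(uni)
                multi = multivariable_table(cohort, drug)
                multi["drug"] = drug
                multi_rows.append(multi)
            except (ValueError, RuntimeError) as exc:
                logger.warning("risk-factor model skipped for %s: %s", drug, exc)
        if uni_rows:
            outputs["risk_univariable"] = out_dir / "risk_univariable.csv"
            pd.concat(uni_rows, ignore_index=True).to_csv(
                outputs["risk_univariable"], index=False)
        if multi_rows:
            outputs["risk_multivariable"] = out_dir / "risk_multivariable.csv"
            pd.concat(multi_rows, ignore_index=True).to_csv(
                outputs["risk_multivariable"], index=False)
    except Exception as exc:
        meta["failed_stage"] = stage
        (out_dir / "run_metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True, default=str))
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    outputs["run_metadata"] = out_dir / "run_metadata.json"
    outputs["run_metadata"].write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str))
    return outputs
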