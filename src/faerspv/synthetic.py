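"""Synthetic FAERS-like report generator with known ground truth.

The generator emulates the structure a quarterly spontaneous-report extract
has after parsing: per-report drug exposures with generic/brand name
variants and role codes, MedDRA-PT-coded reactions with configurable
baseline reporting probabilities, per-(drug, PT) true reporting-ratio
effects, demographics with missing-completely-at-random gaps, seriousness
outcomes, therapy start / event dates with Weibull-distributed onset, and
injected duplicate case versions.  Because every probability is configured,
the implied 2x2 odds ratios are available in closed form
(:func:`true_ror`) and double as recovery oracles for the analysis stack.

Event mechanics: a PT occurs on a report with probability
``min(1, rho_eff * baseline)`` where ``rho_eff`` is the maximum reporting
ratio over the report's exposed study drugs (1 when unexposed or when no
effect is configured for the pair).  ``rho = 1`` is the null, ``rho = 0``
makes the event impossible among reports exposed only to that drug.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .disproportionality import ContingencyTable
from .records import DrugEntry, ReportRecord, TherapyEntry

__all__ = [
    "DrugSpec",
    "SyntheticConfig",
    "default_config",
    "generate",
    "true_ror",
    "simulate_contingency",
    "renal_pt_list",
]

EPOCH = _dt.date(2004, 1, 1)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DrugSpec:
    """One study drug: exposure probability, name lexicon, onset model."""

    key: str
    exposure_prob: float
    names: tuple[str, ...]
    onset_scale: float  # Weibull alpha, days
    onset_shape: float  # Weibull beta
    indication_probs: tuple[tuple[str, float], ...] = ()


@dataclass
class SyntheticConfig:
    """Full parameterization of the generator.

    Probabilities are per report; ``effect`` maps ``(drug_key, pt)`` to the
    true reporting ratio rho.  ``outcome_probs`` are conditional on the
    report being an SMQ event, with the residual mass going to ``OT``.
    """

    n_reports: int = 20_000
    drugs: tuple[DrugSpec, ...] = ()
    events: tuple[tuple[str, float], ...] = ()  # SMQ (renal) PTs: (pt, baseline)
    background_events: tuple[tuple[str, float], ...] = ()
    background_drugs: tuple[str, ...] = ()
    effect: dict[tuple[str, str], float] = field(default_factory=dict)
    sex_split: float = 0.55  # P(male)
    sex_missing: float = 0.40
    age_mean: float = 50.0
    age_sd: float = 17.0
    age_missing: float = 0.45
    weight_mean: float = 62.0
    weight_sd: float = 18.0
    weight_missing: float = 0.80
    reporter_probs: tuple[tuple[str, float], ...] = (
        ("physician", 0.30), ("pharmacist", 0.04),
        ("other_health", 0.40), ("consumer", 0.16),
    )
    country_probs: tuple[tuple[str, float], ...] = (
        ("US", 0.34), ("JP", 0.12), ("FR", 0.07), ("GB", 0.05), ("DE", 0.04),
        ("ES", 0.04), ("CA", 0.04), ("IT", 0.03), ("CN", 0.03), ("IN", 0.03),
    )
    country_missing: float = 0.35
    outcome_probs: tuple[tuple[str, float], ...] = (
        ("DE", 0.16), ("LT", 0.05), ("HO", 0.37), ("DS", 0.005),
    )
    outcome_missing: float = 0.35
    start_date_missing: float = 0.45
    event_date_missing: float = 0.35
    concomitant_rate: float = 0.10  # extra role-C study-drug mention
    duplicate_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigurationError("n_reports must be positive")
        for p, label in [
            (self.sex_split, "sex_split"), (self.sex_missing, "sex_missing"),
            (self.age_missing, "age_missing"), (self.weight_missing, "weight_missing"),
            (self.country_missing, "country_missing"),
            (self.outcome_missing, "outcome_missing"),
            (self.start_date_missing, "start_date_missing"),
            (self.event_date_missing, "event_date_missing"),
            (self.duplicate_rate, "duplicate_rate"),
        ]:
            if not 0.0 <= p < 1.0 and not (label == "sex_split" and p == 1.0):
                raise ConfigurationError(f"{label}={p} outside [0, 1)")
        for d in self.drugs:
            if not 0.0 < d.exposure_prob < 1.0:
                raise ConfigurationError(f"exposure_prob for {d.key} outside (0,1)")
            if d.onset_scale <= 0 or d.onset_shape <= 0:
                raise ConfigurationError(f"Weibull parameters for {d.key} must be > 0")
        for pt, b in list(self.events) + list(self.background_events):
            if not 0.0 < b < 1.0:
                raise ConfigurationError(f"baseline_prob for {pt!r} outside (0,1)")
        for (dk, pt), rho in self.effect.items():
            if not math.isfinite(rho) or rho < 0:
                raise ConfigurationError(f"effect ratio for ({dk}, {pt}) invalid")
        if sum(p for _, p in self.outcome_probs) > 1.0 + 1e-9:
            raise ConfigurationError("outcome probabilities sum beyond 1")

    def lexicon(self) -> dict[str, frozenset[str]]:
        return {d.key: frozenset(n.casefold() for n in d.names) for d in self.drugs}

    def renal_pts(self) -> list[str]:
        return [pt for pt, _ in self.events]


#: Default renal-injury PT set (a synthetic stand-in for a licensed
#: renal-SMQ PT list; real analyses supply their own).
RENAL_PTS: tuple[tuple[str, float], ...] = (
    ("Acute kidney injury", 0.008),
    ("Renal impairment", 0.007),
    ("Blood creatinine increased", 0.007),
    ("Renal failure", 0.005),
    ("Proteinuria", 0.004),
    ("Glomerular filtration rate decreased", 0.003),
    ("Nephropathy toxic", 0.002),
    ("Renal tubular necrosis", 0.0015),
    ("Thrombotic microangiopathy", 0.0015),
    ("Anuria", 0.001),
)

BACKGROUND_PTS: tuple[tuple[str, float], ...] = (
    ("Nausea", 0.05), ("Headache", 0.045), ("Diarrhoea", 0.04),
    ("Fatigue", 0.04), ("Pyrexia", 0.035), ("Vomiting", 0.03),
    ("Rash", 0.03), ("Dizziness", 0.028), ("Dyspnoea", 0.025),
    ("Pruritus", 0.02), ("Drug ineffective", 0.06), ("Anaemia", 0.02),
    ("Hypertension", 0.02), ("Tremor", 0.015), ("Infection", 0.015),
    ("Arthralgia", 0.015), ("Insomnia", 0.012), ("Cough", 0.012),
    ("Abdominal pain", 0.018), ("Oedema peripheral", 0.012),
)

BACKGROUND_DRUGS: tuple[str, ...] = (
    "Paracetamol", "Ibuprofen", "Amoxicillin", "Metformin", "Atorvastatin",
    "Omeprazole", "Prednisone", "Methotrexate", "Hydroxychloroquine",
    "Mycophenolate mofetil", "Azathioprine", "Rituximab", "Adalimumab",
    "Infliximab", "Lisinopril", "Amlodipine", "Furosemide", "Warfarin",
    "Aspirin", "Levothyroxine", "Sertraline", "Gabapentin", "Insulin",
    "Fluconazole", "Valganciclovir",
)


def default_config(**overrides) -> SyntheticConfig:
    """The package's default study conditions: three calcineurin inhibitors
    with renal-event reporting ratios of the magnitude seen in spontaneous
    -report analyses and Weibull onset at the fitted real-data values."""
    drugs = (
        DrugSpec(
            key="cyclosporine", exposure_prob=0.050,
            names=("Cyclosporine", "Ciclosporin", "Neoral", "Sandimmune", "Gengraf"),
            onset_scale=225.0, onset_shape=0.47,
            indication_probs=(
                ("Systemic lupus erythematosus", 0.20), ("Psoriasis", 0.15),
                ("Rheumatoid arthritis", 0.10), ("Renal transplant", 0.25),
                ("Liver transplant", 0.10), ("Dry eye", 0.10),
            ),
        ),
        DrugSpec(
            key="tacrolimus", exposure_prob=0.060,
            names=("Tacrolimus", "Prograf", "Protopic", "Envarsus", "Astagraf"),
            onset_scale=241.0, onset_shape=0.48,
            indication_probs=(
                ("Renal transplant", 0.35), ("Liver transplant", 0.20),
                ("Cardiac transplant", 0.10), ("Systemic lupus erythematosus", 0.10),
                ("Atopic dermatitis", 0.15),
            ),
        ),
        DrugSpec(
            key="voclosporin", exposure_prob=0.008,
            names=("Voclosporin", "Lupkynis"),
            onset_scale=216.0, onset_shape=0.88,
            indication_probs=(("Lupus nephritis", 0.95),),
        ),
    )
    # reporting ratios vary across PTs within each drug, as real signal
    # profiles do; the spread also keeps the empirical-Bayes prior's signal
    # component from degenerating to a point mass
    effect = {}
    bases = {"cyclosporine": 4.0, "tacrolimus": 5.5, "voclosporin": 6.5}
    for i, (pt, _) in enumerate(RENAL_PTS):
        for j, key in enumerate(bases):
            m = 0.55 + 0.15 * ((3 * i + 7 * j) % 10)
            effect[(key, pt)] = round(bases[key] * m, 3)
    # voclosporin's signature: proteinuria / filtration-rate terms dominate
    effect[("voclosporin", "Proteinuria")] = 20.0
    effect[("voclosporin", "Glomerular filtration rate decreased")] = 18.0
    cfg = SyntheticConfig(
        drugs=drugs, events=RENAL_PTS, background_events=BACKGROUND_PTS,
        background_drugs=BACKGROUND_DRUGS, effect=effect,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def renal_pt_list(config: SyntheticConfig | None = None) -> list[str]:
    """The SMQ PT list matching the generator's renal events."""
    return [pt for pt, _ in (config.events if config else RENAL_PTS)]


# ---------------------------------------------------------------------------


def _rho_eff(config: SyntheticConfig, exposures: dict[str, np.ndarray], pt: str) -> np.ndarray:
    """Per-report effective reporting ratio for one PT (vectorized max)."""
    n = len(next(iter(exposures.values())))
    rho = np.ones(n)
    any_exposed = np.zeros(n, dtype=bool)
    cur = np.full(n, -np.inf)
    for d in config.drugs:
        r = config.effect.get((d.key, pt), 1.0)
        mask = exposures[d.key]
        cur = np.where(mask, np.maximum(cur, r), cur)
        any_exposed |= mask
    rho = np.where(any_exposed, cur, 1.0)
    return rho


def _sample_exposure_events(config: SyntheticConfig, rng: np.random.Generator):
    """Exposure flags per study drug and occurrence flags per SMQ PT."""
    n = config.n_reports
    exposures = {d.key: rng.random(n) < d.exposure_prob for d in config.drugs}
    occurrences = {}
    for pt, baseline in config.events:
        p = np.minimum(1.0, baseline * _rho_eff(config, exposures, pt))
        occurrences[pt] = rng.random(n) < p
    return exposures, occurrences


def simulate_contingency(config: SyntheticConfig, drug: str, seed: int) -> ContingencyTable:
    """Fast path: the SMQ-level 2x2 table of one simulated batch.

    Skips record construction entirely; used for replicate studies of
    estimator calibration.
    """
    rng = np.random.default_rng(seed)
    exposures, occurrences = _sample_exposure_events(config, rng)
    event = np.logical_or.reduce([v for v in occurrences.values()])
    exp = exposures[drug]
    return ContingencyTable(
        int((exp & event).sum()), int((exp & ~event).sum()),
        int((~exp & event).sum()), int((~exp & ~event).sum()),
    )


def true_ror(config: SyntheticConfig, drug: str, pt: str) -> float:
    """Closed-form odds ratio implied by the generative probabilities.

    Enumerates exposure combinations of the drugs whose configured effect
    touches *pt* (all other drugs leave the event probability unchanged and
    marginalize out), accumulates the four cell probabilities of the
    (target drug, pt) table, and returns ``p11 p00 / (p10 p01)``.
    """
    keys = [d.key for d in config.drugs]
    if drug not in keys:
        raise KeyError(f"unknown drug {drug!r}")
    baselines = dict(config.events)
    if pt not in baselines:
        raise KeyError(f"unknown event {pt!r}")
    b = baselines[pt]
    relevant = sorted(
        {dk for (dk, p), rho in config.effect.items() if p == pt and rho != 1.0}
        | {drug}
    )
    probs = {d.key: d.exposure_prob for d in config.drugs}
    p11 = p10 = p01 = p00 = 0.0
    for combo in itertools.product((0, 1), repeat=len(relevant)):
        w = 1.0
        exposed = []
        for dk, bit in zip(relevant, combo):
            w *= probs[dk] if bit else 1.0 - probs[dk]
            if bit:
                exposed.append(dk)
        if exposed:
            rho = max(config.effect.get((dk, pt), 1.0) for dk in exposed)
        else:
            rho = 1.0
        pe = min(1.0, rho * b)
        if drug in exposed:
            p11 += w * pe
            p10 += w * (1.0 - pe)
        else:
            p01 += w * pe
            p00 += w * (1.0 - pe)
    if p11 == 0.0:
        return 0.0
    return (p11 * p00) / (p10 * p01)


def _categorical(rng, n, pairs, missing=0.0):
    """Draw labels (or None) from (label, prob) pairs + residual None mass."""
    labels = [lab for lab, _ in pairs] + [None]
    probs = np.array([p for _, p in pairs], dtype=float) * (1.0 - missing)
    probs = np.append(probs, 1.0 - probs.sum())
    idx = rng.choice(len(labels), size=n, p=probs)
    return [labels[i] for i in idx]


def generate(config: SyntheticConfig | None = None, seed: int | None = None) -> list[ReportRecord]:
    """Generate a reproducible batch of report records.

    ``duplicate_rate`` of the cases are emitted as 2-3 versions with
    increasing FDA date / primary id — the last version is the intended
    record, so FDA-rule deduplication recovers exactly the configured case
    count.  Primary ids encode ``case_id * 10 + version``.
    """
    config = config or default_config()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_reports

    exposures, occurrences = _sample_exposure_events(config, rng)
    bg_occ = {pt: rng.random(n) < p for pt, p in config.background_events}

    sex_male = rng.random(n) < config.sex_split
    sex_miss = rng.random(n) < config.sex_missing
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.0, 105.0)
    age_miss = rng.random(n) < config.age_missing
    weights = np.clip(rng.normal(config.weight_mean, config.weight_sd, n), 2.0, 250.0)
    wt_miss = rng.random(n) < config.weight_missing
    reporters = _categorical(rng, n, config.reporter_probs)
    countries = _categorical(rng, n, config.country_probs, config.country_missing)

    outcome_pairs = list(config.outcome_probs)
    residual = 1.0 - sum(p for _, p in outcome_pairs)
    outcome_pairs.append(("OT", residual))
    outcome_draw = _categorical(rng, n, outcome_pairs, config.outcome_missing)

    start_days = rng.integers(0, 7200, n)  # offsets from 2004-01-01
    start_miss = rng.random(n) < config.start_date_missing
    event_miss = rng.random(n) < config.event_date_missing
    fda_lag = rng.integers(10, 200, n)
    dup_u = rng.random(n)
    dup_extra = rng.random(n) < 0.5  # 2 vs 3 versions for duplicated cases
    conc_u = rng.random(n)
    conc_pick = rng.integers(0, len(config.drugs), n)
    bg_pick = rng.integers(0, max(1, len(config.background_drugs)), n)
    name_pick = rng.integers(0, 1_000_000, n)
    onset_u = rng.random(n)  # uniform for per-drug Weibull inverse transform

    event_any = np.logical_or.reduce([v for v in occurrences.values()])

    # pre-draw indication choices per drug (terms + residual "unknown")
    ind_terms: dict[str, list[str]] = {}
    ind_idx: dict[str, np.ndarray] = {}
    for d in config.drugs:
        if not d.indication_probs:
            continue
        terms = [t for t, _ in d.indication_probs]
        ps = np.array([p for _, p in d.indication_probs], dtype=float)
        terms.append("Product used for unknown indication")
        ps = np.append(ps, max(0.0, 1.0 - ps.sum()))
        ps = ps / ps.sum()
        ind_terms[d.key] = terms
        ind_idx[d.key] = rng.choice(len(terms), size=n, p=ps)

    records: list[ReportRecord] = []
    drug_by_key = {d.key: d for d in config.drugs}
    for i in range(n):
        case_id = i + 1
        exposed_keys = [d.key for d in config.drugs if exposures[d.key][i]]
        drugs: list[DrugEntry] = []
        seq = 1
        onset_drug: DrugSpec | None = None
        for key in exposed_keys:
            spec = drug_by_key[key]
            name = spec.names[name_pick[i] % len(spec.names)]
            drugs.append(DrugEntry(seq=seq, name=name, role="PS"))
            if onset_drug is None:
                onset_drug = spec
            seq += 1
        if not drugs and config.background_drugs:
            drugs.append(DrugEntry(
                seq=seq, name=config.background_drugs[bg_pick[i]], role="PS"))
            seq += 1
        if conc_u[i] < config.concomitant_rate:
            spec = config.drugs[conc_pick[i]]
            if spec.key not in exposed_keys:
                drugs.append(DrugEntry(seq=seq, name=spec.names[0], role="C"))
                seq += 1

        reactions = [pt for pt, _ in config.events if occurrences[pt][i]]
        reactions += [pt for pt, _ in config.background_events if bg_occ[pt][i]]
        if not reactions:
            reactions = ["Drug ineffective"]

        start_date = EPOCH + _dt.timedelta(days=int(start_days[i]))
        if event_any[i] and onset_drug is not None:
            # inverse-transform Weibull draw, rounded up to >= 1 day
            onset = onset_drug.onset_scale * (-np.log1p(-onset_u[i])) ** (
                1.0 / onset_drug.onset_shape
            )
            onset_days_i = max(1, int(np.ceil(onset)))
        else:
            onset_days_i = 1 + int(onset_u[i] * 364)
        event_date = start_date + _dt.timedelta(days=onset_days_i)
        fda_date = event_date + _dt.timedelta(days=int(fda_lag[i]))

        therapies = []
        if not start_miss[i]:
            for d in drugs:
                if d.role == "PS":
                    therapies.append(TherapyEntry(drug_seq=d.seq, start_date=start_date))

        indications = []
        for key in exposed_keys:
            if key in ind_terms:
                indications.append(ind_terms[key][ind_idx[key][i]])

        outcomes = set()
        if event_any[i] and outcome_draw[i] is not None:
            outcomes.add(outcome_draw[i])

        base = ReportRecord(
            primary_id=case_id * 10,
            case_id=case_id,
            fda_date_key=int(fda_date.strftime("%Y%m%d")),
            fda_date=fda_date,
            event_date=None if event_miss[i] else event_date,
            sex=("unknown" if sex_miss[i] else ("M" if sex_male[i] else "F")),
            age_years=None if age_miss[i] else float(round(ages[i], 1)),
            weight_kg=None if wt_miss[i] else float(round(weights[i], 1)),
            reporter=reporters[i] or "unknown",
            country=countries[i],
            drugs=drugs,
            reactions=reactions,
            outcomes=outcomes,
            therapies=therapies,
            indications=indications,
        )
        n_versions = 1
        if dup_u[i] < config.duplicate_rate:
            n_versions = 3 if dup_extra[i] else 2
        for v in range(n_versions):
            back = (n_versions - 1 - v) * 35  # earlier receipt for older versions
            fda_v = fda_date - _dt.timedelta(days=back)
            rec = ReportRecord(
                primary_id=case_id * 10 + v,
                case_id=case_id,
                fda_date_key=int(fda_v.strftime("%Y%m%d")),
                fda_date=fda_v,
                event_date=base.event_date,
                sex=base.sex, age_years=base.age_years, weight_kg=base.weight_kg,
                reporter=base.reporter, country=base.country,
                drugs=list(base.drugs), reactions=list(base.reactions),
                outcomes=set(base.outcomes), therapies=list(base.therapies),
                indications=list(base.indications),
            )
            records.append(rec)
    return records
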