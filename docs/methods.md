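# Methods

## Report model and cohorting

A spontaneous report is one version of one case: demographics, drugs with
reporter-assigned role codes (PS/SS/C/I), MedDRA-PT-coded reactions,
seriousness outcomes (DE/LT/HO/DS/CA/RI/OT), therapy date ranges and
indications. Deduplication follows the FDA rule: per `case_id` the
surviving version maximizes `(fda_date, primary_id)` lexicographically.
The rule needs a total order on dates, while onset arithmetic needs day
precision, so partial dates (YYYYMM, YYYY) are padded with 01s for the
dedup sort key but treated as missing for onset computation.

Exposure matching is exact on case-folded, whitespace-trimmed drug names
against a user-supplied lexicon of generic and brand names; no fuzzy
matching is attempted — reconciling FAERS free-text spelling variants is
the lexicon's job, and silent fuzzy matches would be untraceable. The
default role filter is primary suspect (PS) only, configurable, and the
choice is echoed in the run metadata. Event status is the case-folded
intersection of a report's reaction PTs with the SMQ PT set; a report is
one unit in 2×2 counts regardless of how many SMQ PTs it carries
(PT-level scans count per-PT instead). A report exposed to several study
drugs contributes to each drug's exposed margin, matching per-drug
analyses of the same universe.

Covariate bins: age <18 / 18–65 / ≥65 years (age unit codes DEC/YR/MON/
WK/DY converted to years), weight <50 / 50–80 / ≥80 kg, indications
mapped to autoimmune / transplant / other groups by a configurable term
map (transplant takes precedence on mixed reports, being the strongest
risk stratum). Outcome display groups fold CA and RI into "Other
outcomes"; when a report carries several codes the most serious (DE > LT
> HO > DS > other) defines its group, so outcome percentages sum to 100.

## Disproportionality statistics

All four estimators consume the same table: `a` target drug & event, `b`
drug only, `c` event only, `d` neither, with the comparator being every
other report in the loaded batch. Zero cells leave the affected statistic
NaN; no continuity corrections are applied, because they silently inflate
signals exactly where the data are weakest.

* ROR = ad/bc, CI = exp(ln ROR ± z√(1/a+1/b+1/c+1/d)), z = 1.96.
* PRR = [a/(a+b)]/[c/(c+d)]; χ² is the Pearson statistic
  N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], uncorrected by default with Yates
  available behind a flag (the choice is recorded in run metadata).
* BCPNN: the closed-form single-drug/single-event information component
  with the standard priors α₁ = β₁ = γ₁₁ = 1, α = β = 2 and γ chosen so
  the prior IC is centred at zero. IC is the log₂ ratio of posterior-mean
  probabilities; the variance combines the three Beta posterior variances
  on the log scale and IC025 = IC − z√V. z defaults to 1.96 (95% bounds);
  2.0 is available by configuration.
* MGPS: cell counts are modelled as Poisson(λE) with E = n_drug·n_event/N
  and λ drawn from a two-gamma mixture prior. The prior is fitted by
  maximizing the negative-binomial marginal likelihood over the full
  drug×event grid of the batch — all drugs, not only study drugs, since
  shrinkage targets require the ensemble. Verbatim names matching a study
  drug's lexicon are pooled to the ingredient level first, so the study
  drugs' cells carry their real counts rather than being split across
  brand names. EBGM = exp(E[ln λ | a]) via the digamma closed form; EB05
  is the posterior 5th percentile by bracketed root-finding on the
  mixture CDF.

### MGPS optimization

The marginal likelihood is maximized over (α₁, β₁, α₂, β₂, w) in
log/logit parameterization with L-BFGS-B (box constraints 1e−6…1e8,
ftol 1e−8) from DuMouchel's classical start (0.2, 0.1, 2, 4, 1/3) plus
three further deterministic starts, followed by a bounded Nelder-Mead
polish. The multi-start is load-bearing: the likelihood has a ridge along
which a component degenerates to a point mass (both gamma parameters
large at fixed ratio), and a single quasi-Newton run can stall there.
Objective evaluations that return non-finite or positive log-likelihoods
(pmf > 1, numerically broken regions at extreme parameters) are rejected.
A known behavior, not a defect: when per-cell evidence is weak and the
true λ ensemble is nearly discrete, the fitted components can legitimately
become very tight, and EB05 may then approach (or, for two-point
posteriors, slightly exceed) EBGM; on dispersed real-data grids the fitted
components are wide and EB05 < EBGM holds.

## Signal classification

Positivity: ROR — cases ≥ 3 and CI lower bound > 1; PRR — cases ≥ 3,
PRR ≥ 2, χ² ≥ 4; BCPNN — cases ≥ 3 and IC025 > 0; MGPS — EBGM > 2
(EB05 > 2 selectable). Valid = positive on ≥ 2 algorithms, strong = all
four. The case-count gate applies to every algorithm, so no statistic can
rescue a 2-case pair. PT-level scans Bonferroni-adjust the χ² p-values
(the only frequentist p-value in the stack) with m = number of PTs
scanned; both raw and adjusted p are reported. Frequency rankings carry a
separate, deliberately laxer flag — ROR point estimate > 1 — named
`ror_point_gt1` to keep it from being confused with the CI-based
criterion. Percentages are rendered with half-up rounding at the printed
precision; descriptive tables use "data available" denominators per
characteristic, which is why different blocks of the same table can have
different row totals.

## Weibull time-to-onset

Onset is event date minus the earliest therapy start among entries whose
drug sequence maps to the matched drug; negative intervals are counted as
anomalies and treated as missing; same-day onsets are mapped to 0.5 days
because the Weibull support excludes zero. Quartiles use linear
interpolation between order statistics (rank 1+(n−1)p).

The fit is exact ML on f(t) = (β/α)(t/α)^(β−1)exp(−(t/α)^β): the scale is
profiled, α̂(β) = (Σtᵢ^β/n_u)^{1/β}, and the profile score is solved for β
by Brent's method (xtol 1e−10) with bracket expansion; times are rescaled
by their geometric mean for conditioning. Right-censored observations
contribute survival terms; with no censoring flags the same code path
equals the complete-data likelihood exactly. Complete-case analysis is
the default because spontaneous reports carry no usable censoring times.
CIs are Wald on the natural (untransformed) parameters from a
central-difference observed information matrix — interval symmetry about
the estimate is the convention of published onset tables. Failure typing
uses the CI position relative to 1, not the point estimate: early if the
shape CI upper bound < 1, wear-out if the lower bound > 1, random
otherwise. All-equal samples (shape unbounded) and samples with fewer than
10 uncensored observations (configurable floor) are errors.

## Logistic risk factors

Outcome is event occurrence among a drug's exposed reports. Covariates
are reference-coded indicators (female, <18, <50 kg and the first
configured indication group as references). Univariable models use each
covariate's own complete cases; the multivariable model uses joint
complete cases — reproducing the differing row totals of published
risk-factor tables. Fitting is IRLS with convergence at max |score| <
1e−8 or deviance change < 1e−10 within 50 iterations; no regularization.
(Quasi-)separation — a diverging linear predictor or a coefficient
exceeding 15 in absolute value at convergence — raises an error naming
the offending column; the pipeline logs and skips that drug's table,
which is the honest outcome for sparse strata. Covariates with one
observed level are dropped with a warning, which automatically reproduces
the single-indication behavior of a drug approved for one disease.

## Synthetic generator

The generator emulates the post-parse structure of a FAERS quarter with
fully configured probabilities so every downstream stage has a
ground-truth oracle. Default study conditions: three calcineurin
inhibitors with exposure probabilities 0.050 / 0.060 / 0.008, ten renal
PTs with baselines 0.001–0.008, per-(drug, PT) reporting ratios spread
over roughly 2–9 (deterministically varied per pair — real signal
profiles are heterogeneous, and the spread also keeps the MGPS prior
identifiable), Weibull onset at scale/shape 225/0.47, 241/0.48 and
216/0.88 days, 10% duplicated cases emitted as 2–3 versions with
increasing FDA date and primary id, and missing-completely-at-random
demographic gaps matching the availability fractions typical of FAERS
characteristics tables (sex 60%, age 55%, weight 20% available).

Event mechanics: a PT occurs with probability min(1, ρ_eff·baseline)
where ρ_eff is the maximum configured ratio over the report's exposed
study drugs (1 when unexposed or unconfigured). ρ = 1 is the null and
ρ = 0 makes the event impossible among reports exposed only to that drug.
`true_ror` computes the implied odds ratio in closed form by enumerating
exposure combinations of the drugs whose effect touches the PT. Onset
days are drawn by inverse transform and rounded up to ≥ 1 day; this
day-resolution truncation removes the extreme-left tail that small-shape
Weibulls rely on and biases a fitted shape of 0.48 up by roughly +0.05 at
the default scale — calibration tests of the fitter therefore use
continuous draws, while generator-based tests allow the discretization
bias. What the generator does not emulate: drug co-prescription
structure, informative missingness, country-specific reporting behavior,
secular reporting trends. Passing tests therefore demonstrate correctness
of the statistical machinery under MCAR, independent-exposure conditions,
not robustness to real FAERS reporting artifacts.

## Reproducibility and problem sizes

All randomness flows from a single seed (numpy Generator); equal seeds
give bit-identical batches and byte-identical pipeline outputs. Test and
validation problem sizes are chosen so the whole suite runs in about a
minute on one core: 4,000-report session fixtures for cohort mechanics,
20,000-report batches for rate recovery, 500 replicates for ROR CI
coverage, 200 replicates of n = 2,000 for Weibull shape coverage, 5,000
cells for MGPS likelihood-dominance, 10⁶ Monte-Carlo draws per table for
the BCPNN oracle. Ties in frequency rankings break alphabetically;
undefined statistics sort last.

## Known limitations

* The background universe for c and d is the loaded batch, not all of
  FAERS; absolute statistic values therefore depend on the extract used.
* MGPS is unstratified (no age/sex strata) and single-item.
* Wald logistic and Weibull intervals are first-order; profile-likelihood
  intervals are not implemented.
* The IQR convention is interpolated quantiles; nearest-rank conventions
  give slightly different quartiles on small samples.
* SMQ handling is a flat PT set; hierarchical or weighted (algorithmic)
  queries are out of scope, and PT lists are user-supplied inputs.
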