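"""Disproportionality statistics for 2x2 spontaneous-report tables.

Every statistic starts from the same contingency table for a (drug, event)
pair against the background of all other reports in the loaded batch:

    =============  ============  ============
                   target event  other events
    target drug         a             b
    other drugs         c             d
    =============  ============  ============

with N = a+b+c+d, row margin n1 = a+b and column margin n_1 = a+c.

Four estimators are provided:

* ROR, the reporting odds ratio ``ad / bc`` with a log-normal Wald CI;
* PRR, the proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-square statistic of the table;
* the BCPNN information component IC, a shrunken log2 observed-to-expected
  ratio under independent Beta posteriors for the cell and margin
  probabilities (closed-form single-drug/single-event formulation with the
  standard priors);
* MGPS/EBGM, the empirical-Bayes geometric mean of the posterior reporting
  ratio under a two-component gamma mixture prior fitted by marginal maximum
  likelihood across the whole drug-by-event cell grid (DuMouchel's
  gamma-Poisson shrinker), with EB05 its posterior 5th percentile.

Zero cells make the frequentist interval estimates undefined; they are
reported as NaN rather than patched with continuity corrections, which would
silently inflate signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ContingencyTable",
    "contingency",
    "ror",
    "prr",
    "BCPNNHyperParams",
    "bcpnn_ic",
    "MGPSModel",
    "MGPSResults",
    "mgps_cells_from_records",
    "mgps_cells_from_cohort",
    "SignalStats",
    "compute_signal_stats",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one (drug, event) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:  # n1. row margin
        return self.a + self.b

    @property
    def n_event(self) -> int:  # n.1 column margin
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Independence-expected count for cell a: n1. * n.1 / N."""
        return self.n_drug * self.n_event / self.n


def contingency(cohort, drug: str, event) -> ContingencyTable:
    """Build the 2x2 table for *drug* against an event definition.

    *event* is either the string ``"smq"`` (report-level: the cohort's
    ``event`` flag, i.e. any SMQ PT matched) or a single PT term (the report
    counts as an event iff that case-folded PT is among its reactions).
    The comparator is always every other report in the cohort.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    exposed = cohort[f"exp_{drug}"].to_numpy(dtype=bool)
    if event == "smq":
        ev = cohort["event"].to_numpy(dtype=bool)
    else:
        term = str(event).strip().casefold()
        ev = np.fromiter(
            (term in r for r in cohort["reactions"]), dtype=bool, count=len(cohort)
        )
    a = int(np.sum(exposed & ev))
    b = int(np.sum(exposed & ~ev))
    c = int(np.sum(~exposed & ev))
    d = int(np.sum(~exposed & ~ev))
    return ContingencyTable(a, b, c, d)


class RorResult(NamedTuple):
    ror: float
    lo: float
    hi: float


def ror(table: ContingencyTable, z: float = 1.96) -> RorResult:
    """Reporting odds ratio with log-normal Wald CI.

    The point estimate is defined when ``b*c > 0``; the CI additionally
    requires all four cells positive, otherwise NaN flags it undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    point = (a * d) / (b * c) if b * c > 0 else float("nan")
    if min(a, b, c, d) > 0:
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = float(np.exp(np.log(point) - z * se))
        hi = float(np.exp(np.log(point) + z * se))
    else:
        lo = hi = float("nan")
    return RorResult(float(point), lo, hi)


class PrrResult(NamedTuple):
    prr: float
    chi2: float


def prr(table: ContingencyTable, yates: bool = False) -> PrrResult:
    """Proportional reporting ratio and Pearson chi-square (1 df).

    Chi-square is uncorrected by default; Yates' continuity correction is
    available behind the flag.  Zero margins yield NaN.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if (a + b) == 0 or (c + d) == 0 or c == 0:
        point = float("nan")
    else:
        point = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        chi2 = float("nan")
    else:
        diff = abs(a * d - b * c)
        if yates:
            diff = max(0.0, diff - n / 2.0)
        chi2 = n * diff * diff / denom
    return PrrResult(float(point), float(chi2))


@dataclass(frozen=True)
class BCPNNHyperParams:
    """Priors of the closed-form BCPNN: Beta margins and cell.

    ``alpha1``/``beta1`` are the prior pseudo-counts of the drug and event
    margins, ``alpha``/``beta`` the corresponding totals, ``gamma11`` the
    joint-cell pseudo-count; ``gamma`` itself is derived so that the prior
    IC is centred at zero.  ``z`` scales the credible interval (1.96 for the
    conventional 95% bounds).
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0
    z: float = 1.96


class IcResult(NamedTuple):
    ic: float
    ic025: float


def bcpnn_ic(table: ContingencyTable, hyper: BCPNNHyperParams | None = None) -> IcResult:
    """Information component and its lower credible bound (closed form)."""
    h = hyper or BCPNNHyperParams()
    a = table.a
    n = table.n
    n1 = table.n_drug
    n_1 = table.n_event
    gamma = h.gamma11 * (n + h.alpha) * (n + h.beta) / ((n1 + h.alpha1) * (n_1 + h.beta1))
    ic = np.log2(
        (a + h.gamma11) * (n + h.alpha) * (n + h.beta)
        / ((n + gamma) * (n1 + h.alpha1) * (n_1 + h.beta1))
    )
    var = (
        (n - a + gamma - h.gamma11) / ((a + h.gamma11) * (1 + n + gamma))
        + (n - n1 + h.alpha - h.alpha1) / ((n1 + h.alpha1) * (1 + n + h.alpha))
        + (n - n_1 + h.beta - h.beta1) / ((n_1 + h.beta1) * (1 + n + h.beta))
    ) / (LN2**2)
    return IcResult(float(ic), float(ic - h.z * np.sqrt(var)))


# ---------------------------------------------------------------------------
# MGPS: two-component gamma mixture prior over the reporting ratio lambda,
# fitted by maximizing the negative-binomial marginal likelihood of the
# observed cell counts given their independence-expected counts.
# ---------------------------------------------------------------------------

DUMOUCHEL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class MGPSConvergenceError(RuntimeError):
    def __init__(self, message, best=None, grad_norm=None):
        super().__init__(message)
        self.best = best
        self.grad_norm = grad_norm


def _nb_logpmf(a, shape, rate, expected):
    """log P(a) when a ~ Poisson(lambda*E), lambda ~ Gamma(shape, rate)."""
    p = rate / (rate + expected)
    return stats.nbinom.logpmf(a, shape, p)


@dataclass
class MGPSResults:
    """Fitted MGPS prior and the posterior functionals it induces.

    The posterior of the reporting ratio for a cell with count ``a`` and
    expected ``E`` is the mixture
    ``Q Gamma(alpha1+a, beta1+E) + (1-Q) Gamma(alpha2+a, beta2+E)`` with
    posterior weight ``Q``; EBGM is ``exp(E[log lambda])`` and EB05 the 5th
    posterior percentile.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float
    converged: bool
    n_cells: int
    degenerate: bool = False

    def posterior_weight(self, a, expected):
        l1 = np.log(self.w) + _nb_logpmf(a, self.alpha1, self.beta1, expected)
        l2 = np.log1p(-self.w) + _nb_logpmf(a, self.alpha2, self.beta2, expected)
        m = np.maximum(l1, l2)
        return np.exp(l1 - m) / (np.exp(l1 - m) + np.exp(l2 - m))

    def ebgm(self, a, expected):
        """Empirical-Bayes geometric mean of the posterior reporting ratio."""
        expected = np.asarray(expected, dtype=float)
        if np.any(expected <= 0):
            raise ValueError("expected count must be positive")
        q = self.posterior_weight(a, expected)
        mean_log = q * (special.digamma(self.alpha1 + a) - np.log(self.beta1 + expected))
        mean_log += (1 - q) * (
            special.digamma(self.alpha2 + a) - np.log(self.beta2 + expected)
        )
        return np.exp(mean_log)

    def eb_quantile(self, a, expected, prob: float = 0.05) -> float:
        """Posterior quantile by bracketed root-finding on the mixture CDF."""
        if expected <= 0:
            raise ValueError("expected count must be positive")
        q = float(self.posterior_weight(a, expected))
        g1 = stats.gamma(self.alpha1 + a, scale=1.0 / (self.beta1 + expected))
        g2 = stats.gamma(self.alpha2 + a, scale=1.0 / (self.beta2 + expected))

        def cdf(x):
            return q * g1.cdf(x) + (1 - q) * g2.cdf(x) - prob

        lo = min(g1.ppf(prob), g2.ppf(prob))
        hi = max(g1.ppf(prob), g2.ppf(prob))
        if lo == hi or cdf(lo) >= 0 or cdf(hi) <= 0:
            # degenerate/near-point-mass components: widen until bracketed
            for _ in range(200):
                if cdf(lo) < 0:
                    break
                lo *= 0.5
            for _ in range(200):
                if cdf(hi) > 0:
                    break
                hi *= 2.0
            if cdf(lo) >= 0:
                return float(lo)
            if cdf(hi) <= 0:
                return float(hi)
        return float(optimize.brentq(cdf, lo, hi, xtol=1e-12, rtol=1e-10))

    def eb05(self, a, expected) -> float:
        return self.eb_quantile(a, expected, 0.05)


class MGPSModel:
    """Marginal-likelihood fit of the two-gamma MGPS prior.

    Parameters
    ----------
    counts, expected : arrays of per-cell observed counts ``a`` and
        independence-expected counts ``E`` over the full drug-by-event grid
        of the batch (shrinkage needs the ensemble, not just study drugs).
    """

    def __init__(self, counts, expected):
        self.counts = np.asarray(counts, dtype=float)
        self.expected = np.asarray(expected, dtype=float)
        if self.counts.shape != self.expected.shape:
            raise ValueError("counts and expected lengths differ")
        if self.counts.size == 0:
            raise ValueError("no cells")
        if np.any(self.expected < 0):
            raise ValueError("negative expected count")

    def loglik(self, alpha1, beta1, alpha2, beta2, w) -> float:
        l1 = np.log(w) + _nb_logpmf(self.counts, alpha1, beta1, self.expected)
        l2 = np.log1p(-w) + _nb_logpmf(self.counts, alpha2, beta2, self.expected)
        return float(np.sum(np.logaddexp(l1, l2)))

    def fit(self, start=DUMOUCHEL_START, tol: float = 1e-8, maxiter: int = 500) -> MGPSResults:
        degenerate = bool(np.all(self.counts == 0) and np.all(self.expected < 1e-3))

        def unpack(theta):
            a1, b1, a2, b2 = np.exp(theta[:4])
            w = 1.0 / (1.0 + np.exp(-theta[4]))
            return a1, b1, a2, b2, w

        def pack(a1, b1, a2, b2, w):
            return np.array([np.log(a1), np.log(b1), np.log(a2), np.log(b2),
                             np.log(w / (1.0 - w))])

        def nll(theta):
            a1, b1, a2, b2, w = unpack(theta)
            w = min(max(w, 1e-12), 1 - 1e-12)
            val = -self.loglik(a1, b1, a2, b2, w)
            # a pmf cannot exceed 1: non-finite or negative nll marks a
            # numerically broken region, not a better optimum
            if not np.isfinite(val) or val < 0:
                return 1e12
            return val

        # the marginal likelihood has a point-mass ridge (both gamma
        # parameters jointly large); deterministic multi-start keeps the
        # optimizer from collapsing onto it when a genuine null+tail
        # mixture fits better
        starts = [
            pack(*start),
            pack(50.0, 50.0, 1.0, 0.3, 0.9),  # tight null + diffuse tail
            pack(start[2], start[3], start[0], start[1], 1.0 - start[4]),
            pack(1.0, 1.0, 2.0, 0.2, 0.5),
        ]
        bounds = [(np.log(1e-6), np.log(1e8))] * 4 + [(-13.8, 13.8)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "gtol": 1e-10, "maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success)
        grad_norm = float(np.max(np.abs(best.jac)))
        x, fun = best.x, float(best.fun)
        polish = optimize.minimize(
            nll, x, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 6000},
        )
        if polish.fun <= fun:
            x, fun = polish.x, float(polish.fun)
            converged = converged or bool(polish.success)
        a1, b1, a2, b2, w = unpack(x)
        out = MGPSResults(
            alpha1=a1, beta1=b1, alpha2=a2, beta2=b2, w=w,
            loglik=-fun, converged=converged,
            n_cells=int(self.counts.size), degenerate=degenerate,
        )
        if not converged and not degenerate:
            raise MGPSConvergenceError(
                "MGPS prior fit did not converge", best=out, grad_norm=grad_norm,
            )
        return out


def mgps_cells_from_records(records, lexicon=None) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-(drug, event) cells ``(a, E)`` over the full grid of a batch.

    Counting is report-level: ``a`` is the number of reports carrying both
    the drug and the PT.  ``E = n_drug * n_event / N``.  When a *lexicon*
    is given, verbatim names matching a study drug's synonym set are pooled
    under the study-drug key (ingredient-level cells); other names stay
    verbatim.  Returns ``(counts, expected, index)`` with ``index`` mapping
    ``(drug, pt) -> position``.
    """
    from ._util import fold

    n = len(records)
    if n == 0:
        raise ValueError("no records")
    name_map: dict[str, str] = {}
    if lexicon:
        for key, names in lexicon.items():
            for nm in names:
                name_map[fold(nm)] = key
    drug_reports: dict[str, set[int]] = {}
    event_reports: dict[str, set[int]] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(records):
        dnames = {name_map.get(fold(d.name), fold(d.name)) for d in rec.drugs}
        pts = {fold(p) for p in rec.reactions}
        for dn in dnames:
            drug_reports.setdefault(dn, set()).add(i)
        for pt in pts:
            event_reports.setdefault(pt, set()).add(i)
        for dn in dnames:
            for pt in pts:
                pair_counts[(dn, pt)] = pair_counts.get((dn, pt), 0) + 1
    index = {}
    counts = np.zeros(len(pair_counts))
    expected = np.zeros(len(pair_counts))
    for pos, ((dn, pt), a) in enumerate(sorted(pair_counts.items())):
        index[(dn, pt)] = pos
        counts[pos] = a
        expected[pos] = len(drug_reports[dn]) * len(event_reports[pt]) / n
    return counts, expected, index


def mgps_cells_from_cohort(cohort, drugs, pts) -> tuple[np.ndarray, np.ndarray, dict]:
    """Cells for the study drugs x given PTs from a cohort table."""
    n = len(cohort)
    counts, expected, index = [], [], {}
    for drug in drugs:
        for pt in pts:
            t = contingency(cohort, drug, pt)
            index[(drug, pt)] = len(counts)
            counts.append(t.a)
            expected.append(t.expected)
    return np.asarray(counts, float), np.asarray(expected, float), index


@dataclass(frozen=True)
class SignalStats:
    """All four algorithms' values for one (drug, event) pair."""

    cases: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    eb05: float

    def as_dict(self) -> dict:
        return {
            "cases": self.cases, "ror": self.ror, "ror_lo": self.ror_lo,
            "ror_hi": self.ror_hi, "prr": self.prr, "chi2": self.chi2,
            "ic": self.ic, "ic025": self.ic025, "ebgm": self.ebgm, "eb05": self.eb05,
        }


def compute_signal_stats(
    table: ContingencyTable,
    prior: MGPSResults | None = None,
    hyper: BCPNNHyperParams | None = None,
    z: float = 1.96,
    yates: bool = False,
) -> SignalStats:
    """ROR, PRR/chi2, IC/IC025 and EBGM/EB05 for one table.

    The MGPS prior must have been fitted on the batch's cell grid; without
    one the empirical-Bayes columns are NaN.
    """
    r = ror(table, z=z)
    p = prr(table, yates=yates)
    ic = bcpnn_ic(table, hyper)
    if prior is not None and table.expected > 0:
        ebgm_v = float(prior.ebgm(table.a, table.expected))
        eb05_v = float(prior.eb05(table.a, table.expected))
    else:
        ebgm_v = eb05_v = float("nan")
    return SignalStats(
        cases=table.a, ror=r.ror, ror_lo=r.lo, ror_hi=r.hi,
        prr=p.prr, chi2=p.chi2, ic=ic.ic, ic025=ic.ic025,
        ebgm=ebgm_v, eb05=eb05_v,
    )
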