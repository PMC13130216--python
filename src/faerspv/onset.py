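"""Time-to-onset analysis: onset intervals and Weibull failure modelling.

Time-to-onset (TTO) is the number of days from the earliest therapy start of
the matched drug to the adverse-event date.  TTO samples from spontaneous
reports are modelled with a two-parameter Weibull distribution,

    f(t) = (beta/alpha) * (t/alpha)^(beta-1) * exp(-(t/alpha)^beta),

whose shape parameter ``beta`` encodes how the reporting hazard evolves:
``beta < 1`` means a declining hazard — most events cluster soon after the
start of therapy ("early failure"); ``beta = 1`` is a memoryless constant
hazard ("random failure"); ``beta > 1`` an increasing hazard ("wear-out").
The failure type is assigned from the position of the 95% Wald interval for
``beta`` relative to 1, so a point estimate below 1 whose interval crosses 1
is still classified as random.

Estimation is exact maximum likelihood: the scale is profiled out,
``alpha(beta) = (sum t_i^beta / n_uncensored)^(1/beta)``, and the profile
score is solved for ``beta`` by bracketed root-finding.  Right-censored
observations contribute survival terms; with no censoring the same code path
reduces to the complete-data likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._util import fold

__all__ = [
    "onset_days",
    "onset_days_flagged",
    "median_iqr",
    "WeibullTTOModel",
    "WeibullTTOResults",
    "classify_failure",
]


def onset_days_flagged(record, drug_key, lexicon, roles=frozenset({"PS"})):
    """Onset in days plus an anomaly flag for negative intervals.

    Returns ``(days, anomaly)``.  ``days`` is ``event_date`` minus the
    earliest therapy start among entries whose drug sequence maps to a
    lexicon-matched drug of an accepted role; ``None`` when either date is
    absent.  A negative interval (therapy starting after the event) yields
    ``(None, True)``.  A same-day event is mapped to 0.5 days so that the
    value stays inside the Weibull support.
    """
    if record.event_date is None:
        return None, False
    names = lexicon[drug_key]
    seqs = {d.seq for d in record.drugs if d.role in roles and fold(d.name) in names}
    starts = [
        t.start_date
        for t in record.therapies
        if t.drug_seq in seqs and t.start_date is not None
    ]
    if not starts:
        return None, False
    delta = (record.event_date - min(starts)).days
    if delta < 0:
        return None, True
    return (0.5 if delta == 0 else float(delta)), False


def onset_days(record, drug_key, lexicon, roles=frozenset({"PS"})):
    """Onset interval in days for one report, or ``None`` when unavailable."""
    value, _ = onset_days_flagged(record, drug_key, lexicon, roles)
    return value


def median_iqr(times) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics.

    Uses the convention where the p-th quantile sits at rank ``1 + (n-1) p``.
    """
    arr = np.asarray(list(times), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of empty sample")
    med, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75], method="linear")
    return float(med), float(q1), float(q3)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class WeibullTTOResults:
    """Fitted Weibull TTO model: estimates, Wald CIs and failure type."""

    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    alpha_se: float
    beta_se: float
    n: int
    n_censored: int
    loglik: float

    @property
    def failure_type(self) -> str:
        return classify_failure(self)

    def summary(self) -> str:
        lines = [
            "Weibull time-to-onset model",
            f"  n = {self.n} ({self.n_censored} censored), loglik = {self.loglik:.3f}",
            f"  scale alpha = {self.alpha:.2f}  95% CI ({self.alpha_ci[0]:.2f}, {self.alpha_ci[1]:.2f})",
            f"  shape beta  = {self.beta:.3f}  95% CI ({self.beta_ci[0]:.3f}, {self.beta_ci[1]:.3f})",
            f"  failure type: {self.failure_type}",
        ]
        return "\n".join(lines)


def classify_failure(fit: WeibullTTOResults) -> str:
    """Early/random/wear-out typing from the shape CI's position vs 1."""
    lo, hi = fit.beta_ci
    if hi < 1.0:
        return "early"
    if lo > 1.0:
        return "wearout"
    return "random"


class WeibullTTOModel:
    """Two-parameter Weibull model for time-to-onset samples.

    Parameters
    ----------
    times : array-like of positive floats (days)
    censored : optional boolean array, True where the time is right-censored.
        Defaults to all-uncensored (complete-case analysis).
    min_n : minimum number of uncensored observations required to fit.
    """

    def __init__(self, times, censored=None, min_n: int = 10):
        self.times = np.asarray(list(times), dtype=float)
        if censored is None:
            censored = np.zeros(self.times.shape, dtype=bool)
        self.censored = np.asarray(censored, dtype=bool)
        if self.times.shape != self.censored.shape:
            raise ValueError("times and censored lengths differ")
        if np.any(self.times <= 0):
            raise ValueError("times must be positive")
        self.n_uncensored = int((~self.censored).sum())
        if self.n_uncensored < min_n:
            raise ValueError(
                f"need >= {min_n} uncensored observations, got {self.n_uncensored}"
            )

    # log-likelihood with right-censoring
    def loglik(self, alpha: float, beta: float) -> float:
        t, cens = self.times, self.censored
        z = (t / alpha) ** beta
        ll = -np.sum(z)
        tu = t[~cens]
        ll += np.sum(np.log(beta) - beta * np.log(alpha) + (beta - 1.0) * np.log(tu))
        return float(ll)

    def _profile_alpha(self, beta: float) -> float:
        return float((np.sum(self.times**beta) / self.n_uncensored) ** (1.0 / beta))

    def _profile_score(self, beta: float) -> float:
        t = self.times
        tu = t[~self.censored]
        tb = t**beta
        return (
            self.n_uncensored / beta
            + np.sum(np.log(tu))
            - self.n_uncensored * np.sum(tb * np.log(t)) / np.sum(tb)
        )

    def fit(self, z: float = 1.96, tol: float = 1e-10) -> WeibullTTOResults:
        t = self.times
        if np.allclose(t, t[0]):
            raise ConvergenceError("all times equal: shape parameter unbounded")
        # work on scaled times for numerical stability; alpha scales back
        scale = float(np.exp(np.mean(np.log(t))))
        scaled = WeibullTTOModel(t / scale, self.censored, min_n=1)
        lo, hi = 1e-3, 10.0
        while scaled._profile_score(hi) > 0 and hi < 1e6:
            hi *= 4.0
        while scaled._profile_score(lo) < 0 and lo > 1e-12:
            lo /= 4.0
        if scaled._profile_score(lo) < 0 or scaled._profile_score(hi) > 0:
            raise ConvergenceError("profile score has no sign change")
        beta = float(optimize.brentq(scaled._profile_score, lo, hi, xtol=tol))
        alpha = scaled._profile_alpha(beta) * scale

        # observed information from a central-difference Hessian of loglik
        h_a = max(1e-6, 1e-5 * alpha)
        h_b = max(1e-8, 1e-5 * beta)

        def ll(a, b):
            return self.loglik(a, b)

        d2a = (ll(alpha + h_a, beta) - 2 * ll(alpha, beta) + ll(alpha - h_a, beta)) / h_a**2
        d2b = (ll(alpha, beta + h_b) - 2 * ll(alpha, beta) + ll(alpha, beta - h_b)) / h_b**2
        dab = (
            ll(alpha + h_a, beta + h_b)
            - ll(alpha + h_a, beta - h_b)
            - ll(alpha - h_a, beta + h_b)
            + ll(alpha - h_a, beta - h_b)
        ) / (4 * h_a * h_b)
        info = -np.array([[d2a, dab], [dab, d2b]])
        cov = np.linalg.inv(info)
        if cov[0, 0] <= 0 or cov[1, 1] <= 0:
            raise ConvergenceError("observed information not positive definite")
        se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        return WeibullTTOResults(
            alpha=alpha,
            beta=beta,
            alpha_ci=(alpha - z * se_a, alpha + z * se_a),
            beta_ci=(beta - z * se_b, beta + z * se_b),
            alpha_se=se_a,
            beta_se=se_b,
            n=int(t.size),
            n_censored=int(self.censored.sum()),
            loglik=self.loglik(alpha, beta),
        )


def fit_weibull(times, censored=None, min_n: int = 10) -> WeibullTTOResults:
    """Convenience wrapper: ``WeibullTTOModel(times, censored).fit()``."""
    return WeibullTTOModel(times, censored, min_n=min_n).fit()
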