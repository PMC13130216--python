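"""Logistic risk-factor analysis of event occurrence among exposed reports.

For each study drug, the outcome is whether an exposed report is an SMQ
event (0 = no event, 1 = event) and the predictors are categorical
demographics coded against a reference level: sex (female = 0), age bin
(<18 = 0), weight bin (<50 kg = 0) and indication group (first configured
level = 0).  Univariable models are fitted per covariate on that
covariate's own complete cases; the multivariable model on joint complete
cases — which is why the two columns of a published risk-factor table can
have different row totals.

Fitting is plain maximum likelihood via iteratively reweighted least
squares (IRLS) with Wald intervals; there is no regularization, and perfect
separation raises an error naming the offending column rather than being
silently penalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LogisticModel",
    "LogisticResults",
    "SeparationError",
    "build_design",
    "univariable_table",
    "multivariable_table",
]

#: reference-first level orders for the standard covariates
DEFAULT_LEVELS = {
    "sex": ("F", "M"),
    "age_bin": ("<18", "18-65", ">=65"),
    "weight_bin": ("<50", "50-80", ">=80"),
    "indication_group": ("autoimmune", "transplant", "other"),
}

DEFAULT_COVARIATES = ("sex", "age_bin", "weight_bin", "indication_group")


class SeparationError(RuntimeError):
    def __init__(self, column: str):
        super().__init__(f"perfect separation detected on column {column!r}")
        self.column = column


class IRLSConvergenceError(RuntimeError):
    def __init__(self, message: str, deviances: list[float]):
        super().__init__(message)
        self.deviances = deviances


@dataclass
class LogisticResults:
    """ML logistic fit: coefficients, covariance and the OR table."""

    params: np.ndarray
    cov: np.ndarray
    names: list[str]
    n_used: int
    converged: bool
    iterations: int
    deviances: list[float] = field(repr=False, default_factory=list)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviances[-1]

    def or_table(self, z: float = 1.96) -> pd.DataFrame:
        """Odds ratios with Wald 95% CIs and two-sided p-values per term."""
        from scipy import stats

        se = self.bse
        wald = self.params / se
        p = 2 * stats.norm.sf(np.abs(wald))
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": self.params,
                "se": se,
                "or": np.exp(self.params),
                "or_lo": np.exp(self.params - z * se),
                "or_hi": np.exp(self.params + z * se),
                "p": p,
            }
        )

    def summary(self) -> str:
        tab = self.or_table()
        lines = [
            f"Logistic regression (IRLS), n = {self.n_used}, "
            f"{self.iterations} iterations, deviance = {self.deviances[-1]:.3f}",
        ]
        for _, r in tab.iterrows():
            lines.append(
                f"  {r['term']:<28} OR {r['or']:>8.3f}"
                f" ({r['or_lo']:.3f}-{r['or_hi']:.3f})  p={r['p']:.4g}"
            )
        return "\n".join(lines)


class LogisticModel:
    """Binary-outcome logistic model fitted by IRLS.

    Parameters
    ----------
    y : 0/1 outcome vector.
    X : design matrix including the intercept column.
    names : column names (same length as X's second axis).
    """

    def __init__(self, y, X, names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("incompatible y/X shapes")
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(self.X.shape[1])
        ]
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError("outcome has a single class")
        if self.X.shape[0] <= self.X.shape[1]:
            raise ValueError("more columns than informative rows")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, covariates, levels=None):
        y, X, names, _ = build_design(df, outcome, covariates, levels)
        return cls(y, X, names)

    def _deviance(self, p):
        eps = 1e-12
        return float(
            -2.0
            * np.sum(
                self.y * np.log(np.clip(p, eps, 1))
                + (1 - self.y) * np.log(np.clip(1 - p, eps, 1))
            )
        )

    def fit(self, max_iter: int = 50, score_tol: float = 1e-8,
            dev_tol: float = 1e-10) -> LogisticResults:
        X, y = self.X, self.y
        beta = np.zeros(X.shape[1])
        deviances: list[float] = []
        for it in range(1, max_iter + 1):
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1 - p)
            score = X.T @ (y - p)
            deviances.append(self._deviance(p))
            if np.max(np.abs(score)) < score_tol or (
                len(deviances) > 1 and abs(deviances[-2] - deviances[-1]) < dev_tol
            ):
                if np.max(np.abs(beta)) > 15:
                    # coefficient drifting to +/- inf: (quasi-)separated data
                    j = int(np.argmax(np.abs(beta[1:])) + 1) if len(beta) > 1 else 0
                    raise SeparationError(self.names[j])
                info = X.T @ (X * w[:, None])
                cov = np.linalg.inv(info)
                return LogisticResults(
                    params=beta, cov=cov, names=self.names, n_used=len(y),
                    converged=True, iterations=it, deviances=deviances,
                )
            if np.max(np.abs(eta)) > 30:
                # diverging linear predictor: data separable along some column
                j = int(np.argmax(np.abs(beta[1:])) + 1) if len(beta) > 1 else 0
                raise SeparationError(self.names[j])
            winfo = X.T @ (X * np.clip(w, 1e-10, None)[:, None])
            try:
                step = np.linalg.solve(winfo, score)
            except np.linalg.LinAlgError as exc:
                raise IRLSConvergenceError(f"singular IRLS system: {exc}", deviances)
            beta = beta + step
        raise IRLSConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", deviances
        )


def build_design(df: pd.DataFrame, outcome: str, covariates, levels=None,
                 drop_single_level: bool = False):
    """Complete-case design matrix with reference-coded indicators.

    Returns ``(y, X, names, used_covariates)``.  Rows with any missing
    modelled covariate are dropped.  A covariate observed at a single level
    is an error unless ``drop_single_level`` (then it is skipped with a
    warning, as happens naturally for a drug approved for one indication).
    """
    levels = {**DEFAULT_LEVELS, **(levels or {})}
    covariates = list(covariates)
    work = df[[outcome, *covariates]].dropna()
    used = []
    cols = [np.ones(len(work))]
    names = ["intercept"]
    for cov in covariates:
        lv = [l for l in levels.get(cov, tuple(sorted(work[cov].unique())))
              if l in set(work[cov])]
        if len(lv) < 2:
            if drop_single_level:
                warnings.warn(f"covariate {cov!r} has a single observed level; skipped")
                continue
            raise ValueError(f"covariate {cov!r} has a single observed level")
        used.append(cov)
        for level in lv[1:]:
            cols.append((work[cov] == level).to_numpy(dtype=float))
            names.append(f"{cov}[{level}]")
    if not used:
        raise ValueError("no usable covariates")
    # re-drop rows only for used covariates
    work = df[[outcome, *used]].dropna()
    cols = [np.ones(len(work))]
    names = ["intercept"]
    for cov in used:
        lv = [l for l in levels.get(cov, tuple(sorted(work[cov].unique())))
              if l in set(work[cov])]
        for level in lv[1:]:
            cols.append((work[cov] == level).to_numpy(dtype=float))
            names.append(f"{cov}[{level}]")
    y = work[outcome].astype(float).to_numpy()
    X = np.column_stack(cols)
    return y, X, names, used


def _event_frame(cohort: pd.DataFrame, drug: str) -> pd.DataFrame:
    sub = cohort[cohort[f"exp_{drug}"]].copy()
    sub["_event"] = sub["event"].astype(int)
    return sub


def _level_counts(work: pd.DataFrame, cov: str, levels) -> dict[str, tuple[int, int]]:
    out = {}
    for level in levels:
        mask = work[cov] == level
        out[level] = (
            int(((work["_event"] == 0) & mask).sum()),
            int(((work["_event"] == 1) & mask).sum()),
        )
    return out


def univariable_table(cohort: pd.DataFrame, drug: str,
                      covariates=DEFAULT_COVARIATES, levels=None) -> pd.DataFrame:
    """One single-covariate logistic model per covariate.

    Each model uses its own complete cases.  Covariates with one observed
    level are skipped with a warning.  For a binary covariate the fitted OR
    equals the sample cross-product ratio of its 2x2 table.
    """
    levels = {**DEFAULT_LEVELS, **(levels or {})}
    sub = _event_frame(cohort, drug)
    rows = []
    for cov in covariates:
        work = sub[["_event", cov]].dropna()
        lv = [l for l in levels.get(cov, tuple(sorted(work[cov].unique())))
              if l in set(work[cov])]
        if len(lv) < 2:
            warnings.warn(f"covariate {cov!r} has a single observed level; skipped")
            continue
        counts = _level_counts(work, cov, lv)
        res = LogisticModel.from_dataframe(work, "_event", [cov], levels).fit()
        tab = res.or_table().set_index("term")
        n0, n1 = counts[lv[0]]
        rows.append({"covariate": cov, "level": lv[0], "n_outcome0": n0,
                     "n_outcome1": n1, "or": np.nan, "or_lo": np.nan,
                     "or_hi": np.nan, "p": np.nan, "n_used": res.n_used})
        for level in lv[1:]:
            term = f"{cov}[{level}]"
            n0, n1 = counts[level]
            rows.append({"covariate": cov, "level": level, "n_outcome0": n0,
                         "n_outcome1": n1, "or": tab.loc[term, "or"],
                         "or_lo": tab.loc[term, "or_lo"],
                         "or_hi": tab.loc[term, "or_hi"],
                         "p": tab.loc[term, "p"], "n_used": res.n_used})
    return pd.DataFrame(rows)


def multivariable_table(cohort: pd.DataFrame, drug: str,
                        covariates=DEFAULT_COVARIATES, levels=None) -> pd.DataFrame:
    """Joint logistic model over all covariates (joint complete cases)."""
    levels = {**DEFAULT_LEVELS, **(levels or {})}
    sub = _event_frame(cohort, drug)
    y, X, names, used = build_design(sub, "_event", list(covariates), levels,
                                     drop_single_level=True)
    res = LogisticModel(y, X, names).fit()
    tab = res.or_table().set_index("term")
    work = sub[["_event", *used]].dropna()
    rows = []
    for cov in used:
        lv = [l for l in levels.get(cov, tuple(sorted(work[cov].unique())))
              if l in set(work[cov])]
        counts = _level_counts(work, cov, lv)
        n0, n1 = counts[lv[0]]
        rows.append({"covariate": cov, "level": lv[0], "n_outcome0": n0,
                     "n_outcome1": n1, "or": np.nan, "or_lo": np.nan,
                     "or_hi": np.nan, "p": np.nan, "n_used": res.n_used})
        for level in lv[1:]:
            term = f"{cov}[{level}]"
            n0, n1 = counts[level]
            rows.append({"covariate": cov, "level": level, "n_outcome0": n0,
                         "n_outcome1": n1, "or": tab.loc[term, "or"],
                         "or_lo": tab.loc[term, "or_lo"],
                         "or_hi": tab.loc[term, "or_hi"],
                         "p": tab.loc[term, "p"], "n_used": res.n_used})
    return pd.DataFrame(rows)
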