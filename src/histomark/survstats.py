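"""Survival-analysis primitives for prognostic screening and evaluation.

Cox proportional-hazards fitting (Breslow ties, Wald inference), a
Schoenfeld-residual test of the proportional-hazards assumption,
Benjamini-Hochberg multiple-testing correction, Harrell's concordance
index, the two-group log-rank test, the Kaplan-Meier estimator, and the
exact 1-D two-cluster cutoff used to split patients into low/high
expression risk groups.

Model fitting is delegated to statsmodels (PHReg) and the residual-based
diagnostics to lifelines; the 1-D k-means cutoff is solved exactly by
scanning all sorted split points rather than by iterative clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit",
    "PHTestResult",
    "StratificationResult",
    "fit_cox",
    "ph_test",
    "bh_adjust",
    "concordance_index",
    "logrank_test",
    "km_estimate",
    "kmeans2_cutoff",
    "stratify",
]


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed to converge."""


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Breslow tie handling)."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray  # on the HR scale
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    separation_flag: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "CI_low": self.ci_low,
                "CI_high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.coef

    def ci_excludes_null(self, covariate: int | str = 0) -> bool:
        """True when the 95% CI for the coefficient excludes beta = 0
        (equivalently, the HR interval excludes 1)."""
        i = self.names.index(covariate) if isinstance(covariate, str) else covariate
        return bool(self.ci_low[i] > 1.0 or self.ci_high[i] < 1.0)


@dataclass
class PHTestResult:
    """Per-covariate Schoenfeld-residual test of proportional hazards."""

    names: list
    statistic: np.ndarray
    p: np.ndarray

    def worst_p(self) -> float:
        return float(np.min(self.p))


@dataclass
class StratificationResult:
    """Low/high risk-group split of one gene with its survival statistics."""

    gene: str
    cutoff: float
    labels: np.ndarray  # 1 = high-expression group
    hr: float
    ci_low: float
    ci_high: float
    p: float
    logrank_p: float
    cindex: float
    cox: CoxFit


def fit_cox(times, events, covariates, names=None) -> CoxFit:
    """Maximize the Breslow partial likelihood; Wald CIs beta +/- 1.96 SE.

    Raises on an event-free dataset or non-finite covariates; monotone
    likelihood (perfect separation) is flagged on the result rather than
    returned silently.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != times.size:
        x = x.T
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite covariate values")
    if events.sum() < 1:
        raise ValueError("Cox regression requires at least one event")
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]

    # constant covariates carry no partial-likelihood information: their
    # coefficient is structurally zero (HR = 1) with infinite SE
    informative = np.ptp(x, axis=0) > 0
    coef = np.zeros(x.shape[1])
    se = np.full(x.shape[1], np.inf)
    pvals = np.ones(x.shape[1])
    loglik = np.nan
    if informative.any():
        model = PHReg(times, x[:, informative], status=events, ties="breslow")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=False, maxiter=200)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(
                "singular information matrix (monotone likelihood / "
                "perfect separation)"
            ) from err
        sub_coef = np.asarray(res.params, dtype=float)
        grad_norm = float(np.linalg.norm(model.score(sub_coef)))
        converged = grad_norm < 1e-4 * max(1.0, events.sum())
        if not converged and grad_norm > 1.0:
            raise ConvergenceError(f"score norm {grad_norm:.3g} after fitting")
        coef[informative] = sub_coef
        se[informative] = np.asarray(res.bse, dtype=float)
        pvals[informative] = np.asarray(res.pvalues, dtype=float)
        loglik = float(model.loglike(sub_coef))
    else:
        converged = True
    z = stats.norm.ppf(0.975)
    with np.errstate(invalid="ignore"):
        ci_low = np.exp(coef - z * se)
        ci_high = np.exp(coef + z * se)
    return CoxFit(
        names=list(names),
        coef=coef,
        se=se,
        hr=np.exp(coef),
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        loglik=loglik,
        converged=converged,
        separation_flag=bool(np.any(np.abs(coef) > 20)),
    )


def ph_test(times, events, covariates, names=None) -> PHTestResult:
    """Correlation test of scaled Schoenfeld residuals against rank-
    transformed event time, one chi-square (1 df) per covariate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 3:
        raise ValueError("proportional-hazards test requires at least 3 events")
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != times.size:
        x = x.T
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]
    df = pd.DataFrame(x, columns=names)
    df["_t"] = times
    df["_e"] = events
    cph = CoxPHFitter(penalizer=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_t", event_col="_e")
        from lifelines.statistics import proportional_hazard_test

        res = proportional_hazard_test(cph, df, time_transform="rank")
    summ = res.summary.loc[names]
    return PHTestResult(
        names=list(names),
        statistic=summ["test_statistic"].to_numpy(),
        p=np.clip(summ["p"].to_numpy(), 0.0, 1.0),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's C over admissible pairs; higher score = higher risk.

    Ties in the risk score count one half.  Raises if no pair is admissible
    (an admissible pair is one where the shorter time ends in an event).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    if not (times.shape == events.shape == risk.shape):
        raise ValueError("length mismatch")
    try:
        # lifelines scores "higher = longer survival"; negate for risk.
        return float(_ll_concordance(times, -risk, events))
    except ZeroDivisionError as err:
        raise ValueError("no admissible pairs for concordance") from err


def logrank_test(times, events, groups):
    """Two-group log-rank chi-square (1 df).  Returns (statistic, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("logrank_test requires exactly two non-empty groups")
    m0, m1 = groups == labels[0], groups == labels[1]
    res = _ll_logrank(times[m0], times[m1], events[m0], events[m1])
    return float(res.test_statistic), float(res.p_value)


def km_estimate(times, events):
    """Product-limit survival curve.  Returns (time, survival) step arrays,
    starting at (0, 1); the curve drops only at event times."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def kmeans2_cutoff(values):
    """Exact two-cluster split of a 1-D sample.

    Scans all n-1 sorted split points for the minimum within-cluster sum of
    squares (the optimal 1-D 2-means solution is always a threshold rule)
    and returns ``(cutoff, labels)`` with the cutoff at the midpoint of the
    two cluster means and labels 1 for the high cluster.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("constant input cannot be split into two clusters")
    s = np.sort(v)
    n = s.size
    csum = np.cumsum(s)
    csq = np.cumsum(s**2)
    k = np.arange(1, n)
    left = csq[:-1] - csum[:-1] ** 2 / k
    rsum = csum[-1] - csum[:-1]
    rsq = csq[-1] - csq[:-1]
    right = rsq - rsum**2 / (n - k)
    wcss = left + right
    # avoid splitting between equal values (zero-width boundary)
    valid = s[1:] > s[:-1]
    wcss = np.where(valid, wcss, np.inf)
    i = int(np.argmin(wcss)) + 1
    mean_low, mean_high = s[:i].mean(), s[i:].mean()
    cutoff = 0.5 * (mean_low + mean_high)
    return float(cutoff), (v > cutoff).astype(int)


def stratify(gene_values, clinical: pd.DataFrame, gene: str = "gene") -> StratificationResult:
    """Split patients at the k-means cutoff of one gene's expression and
    evaluate the high-vs-low group in a covariate-adjusted Cox model.

    The Cox model uses (group, age, sex, stage); the log-rank p-value is
    unadjusted (group only); the C-index scores the fitted linear predictor.
    The identical code path serves real and predicted expression — only the
    value vector differs.
    """
    v = np.asarray(gene_values, dtype=float)
    cutoff, labels = kmeans2_cutoff(v)
    times = clinical["os_months"].to_numpy(dtype=float)
    events = clinical["os_event"].to_numpy(dtype=int)
    x = np.column_stack(
        [
            labels.astype(float),
            (clinical["age"].to_numpy(dtype=float) - 65.0) / 10.0,
            clinical["sex"].to_numpy(dtype=float),
            clinical["stage"].to_numpy(dtype=float) - 1.0,
        ]
    )
    fit = fit_cox(times, events, x, names=["group", "age", "sex", "stage"])
    _, logrank_p = logrank_test(times, events, labels)
    cindex = concordance_index(times, events, fit.linear_predictor(x))
    return StratificationResult(
        gene=gene,
        cutoff=cutoff,
        labels=labels,
        hr=float(fit.hr[0]),
        ci_low=float(fit.ci_low[0]),
        ci_high=float(fit.ci_high[0]),
        p=float(fit.p[0]),
        logrank_p=logrank_p,
        cindex=cindex,
        cox=fit,
    )
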