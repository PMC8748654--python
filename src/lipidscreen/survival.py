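"""Prognostic survival analysis on median-dichotomized lipid markers.

Concentrations are converted to binary codes (0 below the cohort median,
1 above; ties to 0), survival in the two strata is estimated with the
Kaplan-Meier product-limit estimator and compared with the two-sided
log-rank test, and hazard ratios with 95% confidence intervals come from a
Cox proportional-hazards model fit by Newton-Raphson partial-likelihood
maximization (Breslow tie handling by default, Efron optional).  A hazard
ratio above 1 indicates poorer survival for the above-median stratum.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAX_NEWTON_ITER = 100
Z_95 = 1.959963984540054


def dichotomize_by_median(values) -> tuple[np.ndarray, float]:
    """Binary code per value: 1 if strictly above the median else 0.

    The median is computed over all supplied samples; values equal to the
    median are coded 0 (the convention is configurable only by recoding).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    med = float(np.median(v))
    return (v > med).astype(int), med


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_fit(time, event) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step-function table with one row per distinct event time:
    columns time, at_risk, events, censored, survival.  S(0) = 1 and the
    estimate is non-increasing; right-censoring only reduces the risk set.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty group")
    if np.any(time < 0):
        raise ValueError("negative survival times")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    rows = [dict(time=0.0, at_risk=int(time.size), events=0, censored=0, survival=1.0)]
    s = 1.0
    n_at_risk = time.size
    for t in np.unique(time):
        mask = time == t
        d = int(event[mask].sum())
        c = int(mask.sum() - d)
        if d > 0:
            s *= 1.0 - d / n_at_risk
            rows.append(
                dict(time=float(t), at_risk=int(n_at_risk), events=d, censored=c, survival=s)
            )
        n_at_risk -= int(mask.sum())
    return pd.DataFrame(rows)


def km_by_group(time, event, group) -> dict:
    """Kaplan-Meier curves per stratum of a binary (or labeled) group."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    out = {}
    for g in np.unique(group):
        mask = group == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        out[g] = km_fit(time[mask], event[mask])
    return out


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided p).

    Standard Mantel-Haenszel form with the hypergeometric variance at each
    distinct event time; 1 degree of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    g1 = group == labels[1]

    observed = 0.0
    expected = 0.0
    variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(event[(time == t)].sum())
        d1 = int(event[(time == t) & g1].sum())
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox model estimates for one or more covariates."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    iterations: int

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - Z_95 * self.se)
        hi = np.exp(self.beta + Z_95 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


def _cox_loglik_breslow(beta, time, event, X):
    """Breslow partial log-likelihood with gradient and information."""
    order = np.argsort(-time, kind="stable")  # reverse time for running sums
    t_s, e_s, X_s = time[order], event[order], X[order]
    n, p = X_s.shape
    eta = X_s @ beta
    r = np.exp(eta)

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        # add all subjects with this (tied) time to the risk set
        j = i
        while j < n and t_s[j] == t_s[i]:
            s0 += r[j]
            s1 += r[j] * X_s[j]
            s2 += r[j] * np.outer(X_s[j], X_s[j])
            j += 1
        deaths = [kk for kk in range(i, j) if e_s[kk] == 1]
        d = len(deaths)
        if d:
            xbar = s1 / s0
            loglik += float(eta[deaths].sum() - d * np.log(s0))
            grad += X_s[deaths].sum(axis=0) - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return loglik, grad, info


def _cox_loglik_efron(beta, time, event, X):
    """Efron tie-corrected partial log-likelihood, gradient, information."""
    order = np.argsort(-time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], X[order]
    n, p = X_s.shape
    eta = X_s @ beta
    r = np.exp(eta)

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            s0 += r[j]
            s1 += r[j] * X_s[j]
            s2 += r[j] * np.outer(X_s[j], X_s[j])
            j += 1
        deaths = [kk for kk in range(i, j) if e_s[kk] == 1]
        d = len(deaths)
        if d:
            rd = r[deaths].sum()
            s1d = (r[deaths, None] * X_s[deaths]).sum(axis=0)
            s2d = sum(r[kk] * np.outer(X_s[kk], X_s[kk]) for kk in deaths)
            loglik += float(eta[deaths].sum())
            for ell in range(d):
                f = ell / d
                denom = s0 - f * rd
                num1 = s1 - f * s1d
                num2 = s2 - f * s2d
                xbar = num1 / denom
                loglik -= np.log(denom)
                grad_part = xbar
                grad -= grad_part
                info += num2 / denom - np.outer(xbar, xbar)
            grad += X_s[deaths].sum(axis=0)
        i = j
    return loglik, grad, info


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    ties: str = "breslow",
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Standard errors come from the inverse observed information; the sign
    convention is such that a positive coefficient (HR > 1) means poorer
    survival for larger covariate values.  Raises on non-convergence,
    separation (diverging coefficients), or a singular information matrix
    (e.g. duplicated covariates).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = (
        list(covariates.columns)
        if isinstance(covariates, pd.DataFrame)
        else [f"x{i}" for i in range(X.shape[1])]
    )
    if event.sum() == 0:
        raise ValueError("no events observed")
    if np.any(np.std(X, axis=0) == 0):
        constant = [names[i] for i in range(X.shape[1]) if np.std(X[:, i]) == 0]
        raise ValueError(f"constant covariates: {constant}")

    fn = {"breslow": _cox_loglik_breslow, "efron": _cox_loglik_efron}.get(ties)
    if fn is None:
        raise ValueError("ties must be 'breslow' or 'efron'")

    beta = np.zeros(X.shape[1])
    loglik_old = -np.inf
    for it in range(1, MAX_NEWTON_ITER + 1):
        loglik, grad, info = fn(beta, time, event, X)
        cond = np.linalg.cond(info)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                "singular information matrix (collinear or duplicated covariates)"
            )
        step = np.linalg.solve(info, grad)
        # step-halving to guarantee monotone log-likelihood
        for _ in range(20):
            cand = beta + step
            ll_cand, _, _ = fn(cand, time, event, X)
            if ll_cand >= loglik or np.allclose(step, 0):
                break
            step = step / 2.0
        beta = beta + step
        # a coefficient this large (HR > e^20) only arises under monotone
        # likelihood, i.e. a covariate that perfectly orders the deaths
        if np.max(np.abs(beta)) > 20:
            raise ValueError("separation detected: coefficients diverge")
        if np.max(np.abs(step)) < 1e-9 or abs(ll_cand - loglik_old) < 1e-12:
            loglik_old = ll_cand
            break
        loglik_old = ll_cand
    else:
        raise ValueError(
            f"Newton-Raphson did not converge in {MAX_NEWTON_ITER} iterations "
            f"(last log-likelihood {loglik_old:.4f})"
        )

    _, _, info = fn(beta, time, event, X)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return CoxFit(
        names=names,
        beta=beta,
        se=se,
        loglik=float(loglik_old),
        n=len(time),
        n_events=int(event.sum()),
        iterations=it,
    )


def cox_score_test(time, event, covariate, ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) test of beta = 0 for a single covariate.

    With no tied event times this coincides with the log-rank chi-square
    for a binary covariate.
    """
    X = np.asarray(covariate, dtype=float)[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    fn = {"breslow": _cox_loglik_breslow, "efron": _cox_loglik_efron}[ties]
    _, grad, info = fn(np.zeros(1), time, event, X)
    if info[0, 0] <= 0:
        return 0.0, 1.0
    chi2 = float(grad[0] ** 2 / info[0, 0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


def forest_table(fits: dict[str, CoxFit] | list[CoxFit]) -> pd.DataFrame:
    """One row per covariate: hazard ratio, 95% CI, p value, export-ready."""
    if isinstance(fits, dict):
        items = list(fits.values())
    else:
        items = list(fits)
    if not items:
        raise ValueError("no fits supplied")
    rows = []
    for fit in items:
        ci = fit.ci95
        for i, name in enumerate(fit.names):
            rows.append(
                dict(
                    name=name,
                    hazard_ratio=float(fit.hazard_ratio[i]),
                    ci_low=float(ci[i, 0]),
                    ci_high=float(ci[i, 1]),
                    p_value=float(fit.p_values[i]),
                    n=fit.n,
                    n_events=fit.n_events,
                )
            )
    return pd.DataFrame(rows)


def univariate_lipid_survival(
    samples: pd.DataFrame,
    matrix_values: pd.DataFrame,
    species: list[str],
    ties: str = "breslow",
) -> tuple[pd.DataFrame, dict]:
    """Per-lipid median-dichotomized KM + log-rank + univariate Cox.

    Medians are computed over all supplied samples (cases and controls);
    models are fit on samples with observed survival fields.  Returns the
    forest table (with log-rank p values added) and the per-species KM
    curves.
    """
    has_surv = samples["os_months"].notna() & samples["event"].notna()
    if not has_surv.any():
        raise ValueError("no samples with survival data")
    surv = samples.loc[has_surv]
    time = surv["os_months"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)

    fits = []
    km_curves = {}
    logrank_p = []
    for name in species:
        codes_all, _med = dichotomize_by_median(matrix_values[name].dropna())
        codes = pd.Series(codes_all, index=matrix_values[name].dropna().index)
        z = codes.reindex(surv.index).to_numpy(dtype=float)
        fit = cox_fit(time, event, pd.DataFrame({name: z}), ties=ties)
        fits.append(fit)
        km_curves[name] = km_by_group(time, event, z.astype(int))
        chi2, p = logrank_test(time, event, z.astype(int))
        logrank_p.append(p)
    table = forest_table(fits)
    table["logrank_p"] = logrank_p
    return table, km_curves
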