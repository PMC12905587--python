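"""Survival-analysis primitives: Cox fits, Harrell C, KM/log-rank, BH-FDR,
and maximally selected cutoffs.

The Cox proportional-hazards solver is implemented here directly: a
Newton-Raphson maximizer of the partial likelihood with Efron handling of tied
event times, converging when the largest score component falls below 1e-7 (cap
50 iterations, with step halving so the log likelihood never decreases). A
vectorized single-covariate variant (`univariate_cox_scan`) fits every gene at
once, which makes stepwise selection and bootstrap stability screening cheap.

Kaplan-Meier curves and the log-rank test are delegated to lifelines, the
concordance index to scikit-survival, and BH adjustment to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2, norm
from sksurv.metrics import concordance_index_censored
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit",
    "fit_cox",
    "univariate_cox_scan",
    "harrell_c",
    "km_logrank",
    "bh_fdr",
    "optimal_cutoff",
]


@dataclass
class CoxFit:
    beta: pd.Series
    se: pd.Series
    p: pd.Series
    loglik: float
    converged: bool
    n: int
    n_events: int

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.beta, "HR": self.hr, "se": self.se,
            "z": self.beta / self.se, "p": self.p,
        })


def _validate_surv(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(data["time"], dtype=float)
    d = np.asarray(data["event"], dtype=int)
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("survival times must be nonnegative and non-missing")
    if d.sum() == 0:
        raise ValueError("no events in survival data")
    return t, d


def _untied_quantities(beta: np.ndarray, t: np.ndarray, d: np.ndarray,
                       X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Vectorized partial-likelihood quantities when no event times are tied
    (Efron and Breslow coincide)."""
    eta = X @ beta
    eta -= eta.max()
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    ev = d == 1
    loglik = float(eta[ev].sum() - np.log(S0[ev]).sum())
    mean_r = S1[ev] / S0[ev, None]
    grad = X[ev].sum(axis=0) - mean_r.sum(axis=0)
    # sum_i S2_i / S0_i = X^T diag(w * A) X with A_j = sum_{events i <= j} 1/S0_i
    A = np.cumsum(np.where(ev, 1.0 / S0, 0.0))
    info = X.T @ (X * (w * A)[:, None]) - mean_r.T @ mean_r
    return loglik, grad, info


def _efron_quantities(beta: np.ndarray, t: np.ndarray, d: np.ndarray,
                      X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score and information with Efron ties."""
    ev_times = t[d == 1]
    if len(np.unique(ev_times)) == len(ev_times):
        return _untied_quantities(beta, t, d, X)
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums over the time-ascending ordering = risk-set sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        tied = np.arange(i, j)[d[i:j] == 1]
        m = tied.size
        if m:
            phi_r0, phi_r1, phi_r2 = S0[i], S1[i], S2[i]
            wD = w[tied]
            phi_d0 = wD.sum()
            phi_d1 = wx[tied].sum(axis=0)
            phi_d2 = wxx[tied].sum(axis=0)
            loglik += eta[tied].sum()
            grad += X[tied].sum(axis=0)
            for l in range(m):
                c = l / m
                den0 = phi_r0 - c * phi_d0
                den1 = phi_r1 - c * phi_d1
                den2 = phi_r2 - c * phi_d2
                loglik -= np.log(den0)
                grad -= den1 / den0
                info += den2 / den0 - np.outer(den1, den1) / den0 ** 2
        i = j
    return loglik, grad, info


def fit_cox(data: pd.DataFrame, covariates: list[str],
            tol: float = 1e-7, max_iter: int = 50) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson (Efron ties).

    ``data`` must carry ``time`` and ``event`` columns plus the covariates.
    Monotone likelihood (perfect separation) is reported as non-converged.
    """
    t, d = _validate_surv(data)
    X = data[covariates].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        bad = [c for c in covariates if data[c].std(ddof=0) == 0]
        raise ValueError(f"constant covariates: {bad}")
    order = np.argsort(t, kind="stable")
    t, d, X = t[order], d[order], X[order]
    Xc = X - X.mean(axis=0)

    beta = np.zeros(len(covariates))
    loglik, grad, info = _efron_quantities(beta, t, d, Xc)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step halving: the partial log likelihood must not decrease
        for _ in range(20):
            cand = beta + step
            ll_new, g_new, i_new = _efron_quantities(cand, t, d, Xc)
            if ll_new >= loglik - 1e-12:
                beta, loglik, grad, info = cand, ll_new, g_new, i_new
                break
            step /= 2.0
        else:
            break
    if np.max(np.abs(beta)) > 50:
        converged = False  # monotone likelihood / separation
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(covariates), np.nan)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * norm.sf(np.abs(z))
    idx = pd.Index(covariates)
    return CoxFit(beta=pd.Series(beta, idx), se=pd.Series(se, idx),
                  p=pd.Series(pvals, idx), loglik=float(loglik),
                  converged=converged, n=len(t), n_events=int(d.sum()))


def univariate_cox_scan(time: np.ndarray, event: np.ndarray, X: pd.DataFrame,
                        tol: float = 1e-7, max_iter: int = 30) -> pd.DataFrame:
    """Fit a univariate Cox model per column of ``X`` (samples x genes) at once.

    Breslow risk-set sums (synthetic and bulk survival times are effectively
    untied); Newton steps are clipped at 2 per iteration for stability.
    Returns a DataFrame with ``beta``, ``se``, ``z``, ``p`` per gene.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if d.sum() == 0:
        raise ValueError("no events in survival data")
    V = X.to_numpy(dtype=float)
    V = V - V.mean(axis=0)
    sd = V.std(axis=0)
    sd[sd == 0] = 1.0
    order = np.argsort(t, kind="stable")
    t, d, V = t[order], d[order], V[order]
    # map each row to the first row of its tie group (risk set entry point)
    first = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        first[i] = first[i - 1] if t[i] == t[first[i - 1]] else i
    ev = d == 1
    fe = first[ev]

    G = V.shape[1]
    beta = np.zeros(G)
    active = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        eta = V * beta
        w = np.exp(eta - eta.max(axis=0))
        S0 = np.cumsum(w[::-1], axis=0)[::-1]
        S1 = np.cumsum((w * V)[::-1], axis=0)[::-1]
        S2 = np.cumsum((w * V * V)[::-1], axis=0)[::-1]
        mean_r = S1[fe] / S0[fe]
        grad = (V[ev] - mean_r).sum(axis=0)
        infm = (S2[fe] / S0[fe] - mean_r ** 2).sum(axis=0)
        infm = np.clip(infm, 1e-12, None)
        step = np.clip(grad / infm, -2.0, 2.0)
        beta = np.where(active, beta + step, beta)
        active = np.abs(grad) >= tol
        if not active.any():
            break
    se = 1.0 / np.sqrt(infm)
    z = beta / se
    return pd.DataFrame({"beta": beta, "se": se, "z": z, "p": 2 * norm.sf(np.abs(z))},
                        index=X.columns)


def harrell_c(data: pd.DataFrame, risk) -> float:
    """Harrell concordance index of a risk score against observed survival.

    Usable pairs are those where the shorter time carries an event; risk ties
    count 0.5. ``risk`` is an array aligned with ``data`` or a mapping from
    sample id to score.
    """
    t, d = _validate_surv(data)
    if isinstance(risk, dict):
        r = np.asarray([risk[s] for s in data.index], dtype=float)
    else:
        r = np.asarray(pd.Series(risk).reindex(data.index)
                       if isinstance(risk, pd.Series) else risk, dtype=float)
    try:
        cindex = concordance_index_censored(d.astype(bool), t, r)[0]
    except Exception as exc:  # no comparable pairs
        raise ValueError(f"concordance undefined: {exc}") from exc
    return float(cindex)


def km_logrank(data: pd.DataFrame, groups) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the log-rank test across groups.

    Returns ``(curves, chi2_statistic, p_value)`` where each curve is a
    DataFrame with a ``survival`` column indexed by time.
    """
    t, d = _validate_surv(data)
    g = pd.Series(np.asarray(groups), index=data.index)
    curves: dict[str, pd.DataFrame] = {}
    for label, idx in g.groupby(g).groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {label!r} has no subjects")
        sub = data.loc[idx]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        curves[str(label)] = kmf.survival_function_.rename(
            columns={kmf._label: "survival"})
    res = multivariate_logrank_test(t, g.to_numpy(), d)
    return curves, float(res.test_statistic), float(res.p_value)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _logrank_stat_two_group(t: np.ndarray, d: np.ndarray, in_high: np.ndarray) -> float:
    """Two-group log-rank chi-square statistic (hypergeometric variance)."""
    order = np.argsort(t, kind="stable")
    t, d, g = t[order], d[order], in_high[order].astype(float)
    times, idx = np.unique(t, return_index=True)
    n_total = len(t)
    # at-risk counts just before each unique time
    at_risk = n_total - idx
    cum_high = np.concatenate(([0.0], np.cumsum(np.add.reduceat(g, idx))))
    at_risk_high = g.sum() - cum_high[:-1]
    deaths = np.add.reduceat(d.astype(float), idx)
    deaths_high = np.add.reduceat(d * g, idx)
    frac = at_risk_high / at_risk
    expected = deaths * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = deaths * frac * (1 - frac) * (at_risk - deaths) / (at_risk - 1)
    var = np.where(at_risk > 1, var, 0.0)
    o_minus_e = float((deaths_high - expected).sum())
    v = float(np.nansum(var))
    return 0.0 if v <= 0 else o_minus_e ** 2 / v


def optimal_cutoff(data: pd.DataFrame, marker, min_frac: float = 0.1) -> float:
    """Maximally selected log-rank cutoff for a continuous marker.

    Candidate cutoffs are midpoints between consecutive distinct marker values
    that leave at least ``min_frac`` of samples in each arm; the cutoff with the
    largest two-group log-rank statistic is returned.
    """
    t, d = _validate_surv(data)
    if isinstance(marker, dict):
        m = np.asarray([marker[s] for s in data.index], dtype=float)
    else:
        m = np.asarray(pd.Series(marker).reindex(data.index)
                       if isinstance(marker, pd.Series) else marker, dtype=float)
    if np.unique(m).size < 2:
        raise ValueError("marker is constant; no cutoff exists")
    n = len(m)
    lo_n = max(1, int(np.ceil(min_frac * n)))
    values = np.sort(m)
    best_stat, best_cut = -np.inf, None
    for i in range(lo_n - 1, n - lo_n):
        if values[i] == values[i + 1]:
            continue
        cut = 0.5 * (values[i] + values[i + 1])
        stat = _logrank_stat_two_group(t, d, m > cut)
        if stat > best_stat:
            best_stat, best_cut = stat, cut
    if best_cut is None:
        raise ValueError("no admissible cutoff under the group-size constraint")
    return float(best_cut)
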