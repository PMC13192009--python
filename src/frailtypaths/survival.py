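"""Weighted survival estimation: Kaplan–Meier, Cox PH, PH diagnostics, Weibull PH.

Survey design is handled as weighted estimation plus a PSU-clustered
sandwich variance; full Taylor-linearised variance with stratum
finite-population corrections is deliberately out of scope.  The Cox
model supports an attained-age time scale via delayed entry, mirroring
analyses where age rather than time-on-study indexes the risk sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._cox import (
    CoxData,
    breslow_baseline,
    newton_cox,
    schoenfeld_residuals,
    score_residuals,
)

__all__ = [
    "KmCurve",
    "CoxFit",
    "WeibullPHFit",
    "km_weighted",
    "fit_cox",
    "test_proportional_hazards",
    "fit_weibull_ph",
]


@dataclass
class KmCurve:
    """Weighted product-limit curve with Greenwood standard errors."""

    group: object
    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "time": self.times,
             "survival": self.survival, "se": self.se}
        )


@dataclass
class CoxFit:
    """Weighted Cox proportional-hazards fit."""

    params: pd.Series
    cov_model: pd.DataFrame
    cov_robust: pd.DataFrame | None
    ties: str
    time_scale: str
    n: int
    n_events: int
    loglik: float
    n_iter: int
    baseline: dict = field(repr=False, default_factory=dict)
    _strata: list = field(repr=False, default_factory=list)

    @property
    def cov(self) -> pd.DataFrame:
        return self.cov_robust if self.cov_robust is not None else self.cov_model

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov.values))
        z = self.params.values / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": np.exp(self.params),
                "se": se,
                "z": z,
                "p": p,
                "ci_low": self.params - 1.959963984540054 * se,
                "ci_high": self.params + 1.959963984540054 * se,
            }
        )


@dataclass
class WeibullPHFit:
    """Weibull proportional-hazards fit; coefficients are log hazard ratios."""

    params: pd.Series          # covariate log-HRs
    shape: float               # Weibull shape p
    scale: float               # Weibull rate parameter lambda
    cov: pd.DataFrame          # covariance of (log lambda, log p, beta)
    loglik: float
    n_events: int

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov.values))[2:]
        z = self.params.values / se
        return pd.DataFrame(
            {"coef": self.params, "se": se, "z": z,
             "p": 2 * stats.norm.sf(np.abs(z))}
        )


def _check_surv(df, time_col, event_col, weight_col):
    t = df[time_col].to_numpy(float)
    e = df[event_col].to_numpy()
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    w = np.ones(len(df)) if weight_col is None else df[weight_col].to_numpy(float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return t, e.astype(int), w


def km_weighted(df, group_col=None, *, time_col="followup_time",
                event_col="event", weight_col=None) -> list[KmCurve]:
    """Weighted Kaplan–Meier per group.

    The product-limit estimator uses weighted event counts d(t) and
    weighted numbers at risk Y(t); the Greenwood variance uses the same
    weighted counts, so the curve is invariant to rescaling all weights.
    """
    groups = [(None, df)] if group_col is None else list(df.groupby(group_col))
    curves = []
    for g, sub in groups:
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        t, e, w = _check_surv(sub, time_col, event_col, weight_col)
        order = np.argsort(t)
        t, e, w = t[order], e[order], w[order]
        ev_times = np.unique(t[e == 1])
        atrisk = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        s, var_term = [], []
        S, V = 1.0, 0.0
        for tk in ev_times:
            i = np.searchsorted(t, tk, side="left")
            Y = atrisk[i]
            d = w[(t == tk) & (e == 1)].sum()
            S *= 1.0 - d / Y
            if Y > d:
                V += d / (Y * (Y - d))
            s.append(S)
            var_term.append(V)
        s = np.array(s)
        se = s * np.sqrt(np.array(var_term))
        curves.append(KmCurve(group=g, times=ev_times, survival=s, se=se))
    return curves


def fit_cox(df, covariates, *, time_col="followup_time", event_col="event",
            weight_col=None, entry_col=None, strata_col=None, cluster_col=None,
            ties="efron", time_scale="study_time", age_col="age",
            tol=1e-9, max_iter=100, beta0=None) -> CoxFit:
    """Weighted Cox PH regression.

    time_scale="attained_age" treats age at baseline as a delayed-entry
    time so that risk sets are indexed by attained age; otherwise time on
    study is used (entry 0, or ``entry_col`` if supplied).  When
    ``cluster_col`` is given a PSU-clustered sandwich variance is
    reported alongside the model-based inverse information.
    """
    if time_scale not in ("study_time", "attained_age"):
        raise ValueError(f"unknown time_scale {time_scale!r}")
    t, e, w = _check_surv(df, time_col, event_col, weight_col)
    X = df[list(covariates)].to_numpy(float)
    if time_scale == "attained_age":
        entry = df[age_col].to_numpy(float)
        exit_ = entry + t
    else:
        entry = df[entry_col].to_numpy(float) if entry_col else None
        exit_ = t
    strata_labels = (
        df[strata_col].to_numpy() if strata_col is not None
        else np.zeros(len(df), dtype=int)
    )
    strata, keys, row_blocks = [], [], []
    for key in pd.unique(strata_labels):
        m = strata_labels == key
        strata.append(CoxData(X[m], exit_[m], e[m], w[m],
                              entry[m] if entry is not None else None))
        keys.append(key)
        row_blocks.append(np.where(m)[0])
    if sum(d.n_events for d in strata) < 1:
        raise ValueError("no events in data")
    beta, info, ll, n_iter = newton_cox(strata, ties=ties, tol=tol,
                                        max_iter=max_iter, beta0=beta0)
    names = list(covariates)
    cov_model = pd.DataFrame(np.linalg.inv(info), index=names, columns=names)
    cov_robust = None
    if cluster_col is not None:
        U = np.zeros((len(df), len(names)))
        for d, rows in zip(strata, row_blocks):
            U[rows] = score_residuals(beta, d)
        gid = pd.factorize(df[cluster_col].to_numpy())[0]
        Ug = np.zeros((gid.max() + 1, len(names)))
        np.add.at(Ug, gid, U)
        meat = Ug.T @ Ug
        bread = cov_model.values
        cov_robust = pd.DataFrame(bread @ meat @ bread, index=names, columns=names)
    baseline = {}
    for d, key in zip(strata, keys):
        bt, dlam = breslow_baseline(beta, d)
        baseline[key] = pd.DataFrame({"time": bt, "dLambda0": dlam})
    return CoxFit(
        params=pd.Series(beta, index=names), cov_model=cov_model,
        cov_robust=cov_robust, ties=ties, time_scale=time_scale,
        n=len(df), n_events=int(e.sum()), loglik=ll, n_iter=n_iter,
        baseline=baseline, _strata=strata,
    )


def _time_transform(kind, d: CoxData):
    """Transform of event time used by the proportional-hazards test."""
    tt = d.ev_time
    if kind == "identity":
        return tt.astype(float)
    if kind == "rank":
        return stats.rankdata(tt).astype(float)
    if kind == "km":
        # left-continuous weighted KM evaluated at each event time
        g = np.empty(len(tt))
        S = 1.0
        atrisk = np.concatenate([np.cumsum(d.w[::-1])[::-1], [0.0]])
        wv = d.w[d.ev_mask]
        for k, t0 in enumerate(d.uniq_times):
            lo = d.tie_starts[k]
            hi = lo + d.tie_counts[k]
            g[lo:hi] = 1.0 - S
            i = np.searchsorted(d.time, t0, side="left")
            S *= 1.0 - wv[lo:hi].sum() / atrisk[i]
        return g
    raise ValueError(f"unknown transform {kind!r}")


def test_proportional_hazards(fit: CoxFit, *, transform="km") -> pd.DataFrame:
    """Grambsch–Therneau test of proportional hazards from Schoenfeld residuals.

    Scaled Schoenfeld residuals are regressed on a transform of event
    time (default: one minus the Kaplan–Meier survival).  Returns one
    chi-square row per covariate plus a global row.
    """
    names = list(fit.params.index)
    p = len(names)
    beta = fit.params.values
    res_list, g_list = [], []
    d_events = 0
    for d in fit._strata:
        if d.n_events < 2:
            continue
        _, res = schoenfeld_residuals(beta, d)
        res_list.append(res)
        g_list.append(_time_transform(transform, d))
        d_events += d.n_events
    if d_events <= p:
        raise ValueError("fewer events than covariates; PH test undefined")
    R = np.vstack(res_list)
    g = np.concatenate(g_list)
    gc = g - g.mean()
    u = gc @ R
    Iinv = fit.cov_model.values
    v = Iinv @ u
    ssg = float(gc @ gc)
    rows = []
    for j, name in enumerate(names):
        stat = d_events * v[j] ** 2 / (Iinv[j, j] * ssg)
        rows.append((name, stat, 1, stats.chi2.sf(stat, 1)))
    stat_g = d_events / ssg * float(u @ v)
    rows.append(("GLOBAL", stat_g, p, stats.chi2.sf(stat_g, p)))
    return pd.DataFrame(rows, columns=["covariate", "chi2", "df", "p"]).set_index(
        "covariate"
    )


def fit_weibull_ph(df, covariates, *, time_col="followup_time",
                   event_col="event", weight_col=None,
                   cluster_col=None) -> WeibullPHFit:
    """Weighted right-censored Weibull proportional-hazards regression.

    Hazard h(t|x) = p * lam * t^(p-1) * exp(x'beta); the covariate
    coefficients are therefore directly comparable to Cox log-HRs.
    Fitted by BFGS on (log lam, log p, beta) with analytic gradient.
    With ``cluster_col`` the reported covariance is a cluster-robust
    sandwich over per-subject scores; otherwise the inverse observed
    information.
    """
    t, e, w = _check_surv(df, time_col, event_col, weight_col)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive for the Weibull model")
    if e.sum() < 1:
        raise ValueError("no events in data")
    X = df[list(covariates)].to_numpy(float)
    logt = np.log(t)

    def nll_grad(par):
        loglam, logp, beta = par[0], par[1], par[2:]
        lam, shape = np.exp(loglam), np.exp(logp)
        eta = X @ beta
        H = lam * t**shape * np.exp(eta)  # cumulative hazard
        ll = w @ (e * (logp + loglam + (shape - 1) * logt + eta) - H)
        g_loglam = w @ (e - H)
        g_logp = w @ (e * (1 + shape * logt) - H * shape * logt)
        g_beta = X.T @ (w * (e - H))
        return -ll, -np.concatenate([[g_loglam, g_logp], g_beta])

    x0 = np.zeros(2 + X.shape[1])
    x0[0] = np.log(e.sum() / (w @ t))  # exponential rate as starting value
    res = optimize.minimize(nll_grad, x0, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    from statsmodels.tools.numdiff import approx_hess1

    # Newton polish: BFGS can stall near the optimum on flat likelihoods
    par = res.x
    nll, grad = nll_grad(par)
    trace = [float(nll)]
    for _ in range(50):
        if np.linalg.norm(grad) < 1e-7 * (1.0 + abs(nll)):
            break
        H = approx_hess1(par, lambda q: nll_grad(q)[0])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        shrink = 1.0
        for _ in range(30):
            cand = par - shrink * step
            nll_new, grad_new = nll_grad(cand)
            if nll_new <= nll + 1e-12:
                break
            shrink *= 0.5
        else:
            break
        par, nll, grad = cand, nll_new, grad_new
        trace.append(float(nll))
    if np.linalg.norm(grad) > 1e-4 * (1.0 + abs(nll)):
        raise RuntimeError(
            "Weibull PH fit did not converge; negative log-likelihood trace: "
            f"{[round(v, 6) for v in trace]}")
    H = approx_hess1(par, lambda q: nll_grad(q)[0])
    names = ["log_scale", "log_shape"] + list(covariates)
    bread = np.linalg.inv(H)
    if cluster_col is not None:
        loglam, logp, beta = par[0], par[1], par[2:]
        shape = np.exp(logp)
        Hcum = np.exp(loglam) * t**shape * np.exp(X @ beta)
        S = np.column_stack([
            w * (e - Hcum),
            w * (e * (1 + shape * logt) - Hcum * shape * logt),
            X * (w * (e - Hcum))[:, None],
        ])
        gid = pd.factorize(df[cluster_col].to_numpy())[0]
        Sg = np.zeros((gid.max() + 1, S.shape[1]))
        np.add.at(Sg, gid, S)
        cov = pd.DataFrame(bread @ (Sg.T @ Sg) @ bread,
                           index=names, columns=names)
    else:
        cov = pd.DataFrame(bread, index=names, columns=names)
    return WeibullPHFit(
        params=pd.Series(par[2:], index=list(covariates)),
        shape=float(np.exp(par[1])), scale=float(np.exp(par[0])),
        cov=cov, loglik=-res.fun, n_events=int(e.sum()),
    )
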