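"""Vectorised weighted Cox partial-likelihood engine.

Supports case weights, delayed entry (left truncation, used for the
attained-age time scale), Efron/Breslow tie handling, baseline-hazard
stratification and PSU-clustered sandwich variance.  Risk-set sums are
suffix sums of time-sorted arrays and the Hessian is assembled from
diagonal-weighted Gram matrices, so one Newton step costs
O(n log n + n p + n p^2 via BLAS); this is what makes bootstrap
resampling of the decomposition models cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CoxData",
    "cox_loglik_grad_hess",
    "newton_cox",
    "breslow_baseline",
    "schoenfeld_residuals",
    "score_residuals",
]


class CoxData:
    """Pre-sorted view of one baseline-hazard stratum.

    Parameters are plain arrays; ``entry`` may be None for the usual
    time-on-study scale (everyone at risk from 0).
    """

    def __init__(self, X, time, event, weight=None, entry=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n = len(time)
        if weight is None:
            weight = np.ones(n)
        weight = np.asarray(weight, dtype=float)
        if np.any(weight <= 0):
            raise ValueError("weights must be strictly positive")
        if entry is not None:
            entry = np.asarray(entry, dtype=float)
            if np.any(time <= entry):
                raise ValueError("exit time must exceed entry time")
        order = np.argsort(time, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.time = time[order]
        self.event = event[order]
        self.w = weight[order]
        self.entry = entry[order] if entry is not None else None
        self.order = order
        self.n, self.p = self.X.shape
        ev = self.event == 1
        self.ev_mask = ev
        self.ev_time = self.time[ev]
        self.Xev = np.ascontiguousarray(self.X[ev])
        self.wev = self.w[ev]
        # distinct event times and tie-group boundaries (event rows are
        # contiguous per time after the stable sort restricted to events)
        self.uniq_times, self.tie_starts = np.unique(self.ev_time, return_index=True)
        self.tie_counts = np.diff(np.append(self.tie_starts, len(self.ev_time)))
        self.wsum = np.add.reduceat(self.wev, self.tie_starts)
        # gather indices that do not depend on beta
        self.risk_idx = np.searchsorted(self.time, self.uniq_times, side="left")
        if self.entry is not None:
            self.entry_order = np.argsort(self.entry, kind="stable")
            self.entry_sorted = self.entry[self.entry_order]
            self.entry_idx = np.searchsorted(
                self.entry_sorted, self.uniq_times, side="left"
            )
        # at-risk window of each subject over distinct event times
        self.win_hi = np.searchsorted(self.uniq_times, self.time, side="right")
        if self.entry is not None:
            self.win_lo = np.searchsorted(self.uniq_times, self.entry, side="right")
        else:
            self.win_lo = np.zeros(self.n, dtype=int)
        self.n_events = int(ev.sum())
        # expanded (event time k, within-tie index l) rows for Efron
        dk = self.tie_counts
        self.exp_idx = np.repeat(np.arange(len(dk)), dk)
        l = np.arange(len(self.exp_idx)) - np.repeat(self.tie_starts, dk)
        self.exp_frac = l / dk[self.exp_idx]
        self.wbar = self.wsum / dk

    def risk_sums(self, eta):
        """S0 and S1 over the at-risk set at each distinct event time.

        With delayed entry the at-risk sum at t is (sum over exit >= t)
        minus (sum over entry >= t); both are suffix sums of sorted
        arrays, gathered with searchsorted.
        """
        r = self.w * np.exp(eta)
        rX = r[:, None] * self.X
        c0 = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
        c1 = np.concatenate([np.cumsum(rX[::-1], axis=0)[::-1], np.zeros((1, self.p))])
        S0 = c0[self.risk_idx]
        S1 = c1[self.risk_idx]
        if self.entry is not None:
            re = r[self.entry_order]
            rXe = rX[self.entry_order]
            d0 = np.concatenate([np.cumsum(re[::-1])[::-1], [0.0]])
            d1 = np.concatenate(
                [np.cumsum(rXe[::-1], axis=0)[::-1], np.zeros((1, self.p))]
            )
            S0 = S0 - d0[self.entry_idx]
            S1 = S1 - d1[self.entry_idx]
        return r, S0, S1

    def window_sum(self, per_time):
        """For each subject, sum of ``per_time`` over the distinct event
        times falling in the subject's at-risk window (entry, exit]."""
        c = np.concatenate([[0.0], np.cumsum(per_time)])
        return c[self.win_hi] - c[self.win_lo]


def _stratum_llgh(beta, d: CoxData, ties):
    eta = d.X @ beta
    r, S0, S1 = d.risk_sums(eta)
    rev = r[d.ev_mask]
    ll = float(d.wev @ eta[d.ev_mask])
    grad = d.wev @ d.Xev
    if ties == "breslow":
        a = d.wsum / S0
        b = np.zeros_like(a)
        ll -= float(d.wsum @ np.log(S0))
        Z = S1 / S0[:, None]
        wz = d.wsum
        grad -= d.wsum @ Z
    elif ties == "efron":
        s0d = np.add.reduceat(rev, d.tie_starts)
        s1d = np.add.reduceat(rev[:, None] * d.Xev, d.tie_starts, axis=0)
        idx, frac, wb = d.exp_idx, d.exp_frac, d.wbar[d.exp_idx]
        denom = S0[idx] - frac * s0d[idx]
        ll -= float(wb @ np.log(denom))
        Z = (S1[idx] - frac[:, None] * s1d[idx]) / denom[:, None]
        wz = wb
        grad -= wb @ Z
        # per-tie-group accumulation coefficients for the S2 terms
        a = np.zeros(len(d.uniq_times))
        b = np.zeros(len(d.uniq_times))
        np.add.at(a, idx, wb / denom)
        np.add.at(b, idx, wb * frac / denom)
    else:
        raise ValueError(f"unknown ties method {ties!r}")
    # Hessian of -loglik:
    #   sum_k a_k S2(t_k) - sum_k b_k s2d_k - sum wz Z Z'
    # with S2 = sum_{i at risk} r_i x_i x_i' re-expressed per subject.
    A = r * d.window_sum(a)
    H = (d.X * A[:, None]).T @ d.X
    if ties == "efron":
        bev = np.repeat(b, d.tie_counts) * rev
        H -= (d.Xev * bev[:, None]).T @ d.Xev
    H -= (Z * wz[:, None]).T @ Z
    return ll, grad, H


def cox_loglik_grad_hess(beta, strata, ties="efron"):
    """Weighted log partial likelihood, gradient and observed information."""
    p = strata[0].p
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for d in strata:
        if d.n_events == 0:
            continue
        li, gi, hi = _stratum_llgh(beta, d, ties)
        ll += li
        grad += gi
        hess += hi
    return ll, grad, hess


def newton_cox(strata, ties="efron", tol=1e-9, max_iter=100, beta0=None):
    """Newton–Raphson with step halving on the weighted partial likelihood.

    Returns (beta, information matrix, log-likelihood, n_iter).
    """
    p = strata[0].p
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    # gradient tolerance is relative to the number of events so the
    # stopping rule is sample-size invariant
    scale = max(1.0, float(sum(d.n_events for d in strata)))
    ll, grad, hess = cox_loglik_grad_hess(beta, strata, ties)
    for it in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol * scale:
            return beta, hess, ll, it
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "singular information matrix in Cox fit; possible separation "
                "or collinear covariates"
            ) from exc
        if not np.all(np.isfinite(step)) or np.linalg.norm(step) > 50:
            raise RuntimeError(
                "monotone partial likelihood detected (diverging coefficients); "
                f"gradient norm {gnorm:.3g}"
            )
        shrink = 1.0
        if np.max(np.abs(beta + step)) > 15:
            raise RuntimeError(
                "monotone partial likelihood (perfect separation): "
                f"coefficients diverging beyond |beta| = 15 at iteration {it}"
            )
        for _ in range(30):
            cand = beta + shrink * step
            ll_new, grad_new, hess_new = cox_loglik_grad_hess(cand, strata, ties)
            if ll_new >= ll - 1e-12:
                break
            shrink *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    gnorm = float(np.linalg.norm(grad))
    if gnorm >= tol * scale:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations; "
            f"gradient norm {gnorm:.3g}"
        )
    return beta, hess, ll, max_iter


def breslow_baseline(beta, d: CoxData):
    """Breslow step estimate of the cumulative baseline hazard.

    Returns (distinct event times, increments dLambda0)."""
    _, S0, _ = d.risk_sums(d.X @ beta)
    return d.uniq_times, d.wsum / S0


def schoenfeld_residuals(beta, d: CoxData):
    """Weighted Schoenfeld residuals, one row per event (sorted by time).

    Residual for an event at t is w_i (x_i - xbar(t)) with xbar the
    weighted risk-set mean; tied events share xbar.
    """
    _, S0, S1 = d.risk_sums(d.X @ beta)
    xbar = S1 / S0[:, None]
    idx = np.repeat(np.arange(len(d.uniq_times)), d.tie_counts)
    res = d.wev[:, None] * (d.Xev - xbar[idx])
    return d.ev_time, res


def score_residuals(beta, d: CoxData):
    """Per-subject score residuals (Breslow form), in the original row order."""
    r, S0, S1 = d.risk_sums(d.X @ beta)
    xbar = S1 / S0[:, None]
    dlam = d.wsum / S0
    Lam = d.window_sum(dlam)
    cxl = np.vstack([np.zeros(d.p), np.cumsum(xbar * dlam[:, None], axis=0)])
    Psi = cxl[d.win_hi] - cxl[d.win_lo]
    U = -r[:, None] * (d.X * Lam[:, None] - Psi)
    ev = d.ev_mask
    tidx = np.searchsorted(d.uniq_times, d.time[ev])
    U[ev] += d.w[ev, None] * (d.X[ev] - xbar[tidx])
    out = np.empty_like(U)
    out[d.order] = U
    return out
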