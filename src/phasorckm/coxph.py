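"""Weighted Cox proportional-hazards engine.

Implements the weighted partial likelihood with Efron handling of tied event
times (follow-up recorded in months makes ties the norm), Newton-Raphson
estimation, Efron-consistent score residuals (the ingredient of the
design-based sandwich variance), and the weighted Breslow/Efron baseline
cumulative hazard.

Notation per distinct event time t_k with tied death set D_k (d_k deaths,
weight sum s_k), risk set R_k, and phi_j = exp(x_j beta):

    A_k = sum_{R_k} w phi,  a_k = sum_{R_k} w phi x,  M_k = sum_{R_k} w phi x x'
    B_k, b_k, MD_k: the same sums over D_k only.

Efron pseudo-step l = 0..d_k-1 uses the deflated denominator
D_kl = A_k - (l/d_k) B_k, giving

    loglik = sum_k [ sum_{D_k} w eta - (s_k/d_k) sum_l log D_kl ].

Score residuals are the martingale-integral form; summed with case weights
they reproduce the Efron score exactly (zero at the MLE), which keeps the
sandwich variance internally consistent with the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CoxConvergenceError(RuntimeError):
    """Newton iteration failed (separation, no events, or collinear covariates)."""


@dataclass
class CoxFit:
    """Fitted weighted Cox model on centered covariates."""

    beta: np.ndarray
    naive_cov: np.ndarray          # inverse information (the sandwich "bread")
    loglik: float
    score_contribs: np.ndarray     # per-subject weighted score residuals, original row order
    baseline_times: np.ndarray     # distinct event times, ascending
    baseline_cumhaz: np.ndarray    # Efron baseline cumulative hazard at those times
    x_center: np.ndarray           # covariate means subtracted before fitting
    n_events: int
    converged: bool

    def cumhaz_at(self, times) -> np.ndarray:
        """Baseline cumulative hazard step function evaluated at ``times``."""
        idx = np.searchsorted(self.baseline_times, np.asarray(times, float), side="right")
        ch = np.concatenate([[0.0], self.baseline_cumhaz])
        return ch[idx]


def _group_structure(t, e):
    """Start indices of distinct-time groups and of the groups containing events."""
    n = len(t)
    boundaries = np.flatnonzero(np.diff(t)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    has_event = np.logical_or.reduceat(e, starts) if len(starts) else np.array([], bool)
    return starts, ends, np.flatnonzero(has_event)


def _suffix_sums(X, wphi, starts):
    """Risk-set sums sum_{j >= start} of w*phi, w*phi*x, w*phi*x*x'."""
    S0 = np.cumsum(wphi[::-1])[::-1]
    xw = X * wphi[:, None]
    S1 = np.cumsum(xw[::-1], axis=0)[::-1]
    S2 = np.cumsum(np.einsum("ip,iq->ipq", X, xw)[::-1], axis=0)[::-1]
    return S0[starts], S1[starts], S2[starts]


def _loglik_grad_hess(t, e, X, w, beta):
    """Weighted Efron partial likelihood, gradient and information."""
    n, p = X.shape
    eta = X @ beta
    wphi = w * np.exp(eta)

    starts, ends, ev_gi = _group_structure(t, e)
    A_at, a_at, M_at = _suffix_sums(X, wphi, starts)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for gi in ev_gi:
        sl = slice(starts[gi], ends[gi])
        ev = e[sl]
        Xd = X[sl][ev]
        wd = w[sl][ev]
        wphid = wphi[sl][ev]
        d = len(wd)
        s = wd.sum()
        B = wphid.sum()
        b = Xd.T @ wphid
        MD = (Xd * wphid[:, None]).T @ Xd

        f = np.arange(d) / d
        D = A_at[gi] - f * B                      # (d,)
        xbar = (a_at[gi][None, :] - f[:, None] * b[None, :]) / D[:, None]
        ll += float(wd @ eta[sl][ev]) - (s / d) * float(np.log(D).sum())
        grad += Xd.T @ wd - (s / d) * xbar.sum(axis=0)
        inv = 1.0 / D
        info += (s / d) * (
            inv.sum() * M_at[gi] - (f * inv).sum() * MD - xbar.T @ xbar
        )
    return ll, grad, info


def _score_residuals_and_baseline(t, e, X, w, beta):
    """Efron score residuals (per subject, sorted order) and baseline cumhaz."""
    n, p = X.shape
    phi = np.exp(X @ beta)
    wphi = w * phi

    starts, ends, ev_gi = _group_structure(t, e)
    xw = X * wphi[:, None]
    A_all = np.cumsum(wphi[::-1])[::-1]
    a_all = np.cumsum(xw[::-1], axis=0)[::-1]
    A_at, a_at = A_all[starts], a_all[starts]

    # per distinct *event* time: hazard-increment aggregates over Efron steps
    g0 = np.zeros(len(ev_gi)); h0 = np.zeros(len(ev_gi))
    g1 = np.zeros((len(ev_gi), p)); h1 = np.zeros((len(ev_gi), p))
    xbm = np.zeros((len(ev_gi), p))
    for k, gi in enumerate(ev_gi):
        sl = slice(starts[gi], ends[gi])
        ev = e[sl]
        wd = w[sl][ev]
        wphid = wphi[sl][ev]
        Xd = X[sl][ev]
        d = len(wd)
        s = wd.sum()
        B = wphid.sum()
        b = Xd.T @ wphid
        f = np.arange(d) / d
        D = A_at[gi] - f * B
        dlam = (s / d) / D
        xbar = (a_at[gi][None, :] - f[:, None] * b[None, :]) / D[:, None]
        g0[k] = dlam.sum()
        g1[k] = dlam @ xbar
        h0[k] = ((1 - f) * dlam).sum()
        h1[k] = ((1 - f) * dlam) @ xbar
        xbm[k] = xbar.mean(axis=0)
    ev_groups = ev_gi
    C0 = np.concatenate([[0.0], np.cumsum(g0)])
    C1 = np.vstack([np.zeros(p), np.cumsum(g1, axis=0)])
    event_times = t[starts[ev_groups]]

    # map each subject to the number of event times <= its own time
    K = np.searchsorted(event_times, t, side="right")
    # for deaths, the index of their own event time among event times
    own = np.searchsorted(event_times, t, side="left")

    S = np.empty((n, p))
    cens = ~e
    S[cens] = -(phi[cens, None] * (X[cens] * C0[K[cens], None] - C1[K[cens]]))
    idx_d = np.flatnonzero(e)
    ki = own[idx_d]
    S[idx_d] = (
        X[idx_d] - xbm[ki]
        - phi[idx_d, None] * (
            X[idx_d] * (C0[ki, None] + h0[ki, None])
            - (C1[ki] + h1[ki])
        )
    )
    return S * w[:, None], event_times, np.cumsum(g0)


def fit_cox(
    time,
    event,
    X,
    weights=None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxFit:
    """Fit a weighted Cox model (Efron ties) by Newton-Raphson.

    Covariates are centered at their weighted means internally; ``beta`` is
    invariant to centering and the baseline hazard refers to the weighted-mean
    covariate profile.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if not e.any():
        raise CoxConvergenceError("no events observed")

    center = np.average(X, axis=0, weights=w)
    Xc = X - center

    # sort by time ascending (stable: ties keep input order; ordering within a
    # tied group does not affect any sum)
    order = np.argsort(t, kind="stable")
    ts, es, Xs, ws = t[order], e[order], Xc[order], w[order]

    beta = np.zeros(p)
    ll, grad, info = _loglik_grad_hess(ts, es, Xs, ws, beta)
    converged = False
    ll_scale = max(1.0, abs(ll))
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol * ll_scale:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError("singular information matrix") from exc
        if not np.all(np.isfinite(step)) or np.max(np.abs(step)) > 50:
            raise CoxConvergenceError("divergent step; likely separation or no usable events")
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
        # step-halving line search on the partial likelihood; the acceptance
        # slack is relative to |ll| (float noise in large weighted sums)
        factor = 1.0
        accepted = False
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _loglik_grad_hess(ts, es, Xs, ws, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10 * ll_scale:
                accepted = True
                break
            factor /= 2.0
        if not accepted:
            # stuck at float-precision plateau: treat as converged if the
            # gradient is already small relative to the information scale
            if np.max(np.abs(grad)) < 1e-5 * ll_scale:
                converged = True
                break
            raise CoxConvergenceError("partial likelihood could not be increased")
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
    if not np.all(np.isfinite(info)):
        raise CoxConvergenceError("non-finite information matrix")
    naive_cov = np.linalg.pinv(info)

    S_sorted, ev_times, cumhaz = _score_residuals_and_baseline(ts, es, Xs, ws, beta)
    S = np.empty_like(S_sorted)
    S[order] = S_sorted
    return CoxFit(
        beta=beta,
        naive_cov=naive_cov,
        loglik=ll,
        score_contribs=S,
        baseline_times=ev_times,
        baseline_cumhaz=cumhaz,
        x_center=center,
        n_events=int(e.sum()),
        converged=converged,
    )
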