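"""Cox proportional-hazards fitting on the partial likelihood.

A small Newton-Raphson solver for the Cox model with Breslow (default) or
Efron handling of tied event times, plus a fit vectorised across many
single-binary-covariate models, which is what the lncRNA-pair screen needs:
for a binary covariate the risk-set sums reduce to at-risk counts, so
thousands of pair models can be solved simultaneously with cumulative-count
arithmetic instead of one general fit per pair.

The partial log-likelihood under Breslow ties is

    logPL(beta) = sum_events [ eta_i - log S0(t_i) ],
    S0(t) = sum_{j at risk at t} exp(eta_j),   eta = X beta,

with all deaths in a tie group sharing the risk set at the group's time.
Efron replaces S0 within a tie group of d deaths by S0 - (l/d) * sum of the
dying subjects' weights for l = 0..d-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ReopairError


class ConvergenceError(ReopairError):
    """The Newton iteration failed to converge."""


def _sort_survival(time: np.ndarray, event: np.ndarray):
    """Sort ascending by time; return order, tie-group start index per sample."""
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    if time.ndim != 1 or time.shape != event.shape:
        raise ReopairError("time and event must be 1-D arrays of equal length")
    order = np.argsort(time, kind="stable")
    ts = time[order]
    # first index of each tie group = position of the first sample with the same time
    group_start = np.searchsorted(ts, ts, side="left")
    return order, ts, event[order], group_start


def cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Cox partial log-likelihood at ``beta`` (Breslow or Efron ties)."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.atleast_1d(np.asarray(beta, float))
    ll, _, _ = _cox_derivatives(beta, X, time, event, ties, want_derivs=False)
    return ll


def _cox_derivatives(beta, X, time, event, ties, want_derivs=True):
    """Return (loglik, gradient, hessian) of the partial log-likelihood."""
    n, p = X.shape
    order, ts, es, gstart = _sort_survival(time, event)
    Xs = X[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # guard against overflow; logPL shifts cancel below
    w = np.exp(eta)
    # reverse-cumulative risk-set sums, evaluated at tie-group starts
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    if want_derivs:
        wxx = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    ev_idx = np.nonzero(es == 1)[0]
    if ev_idx.size == 0:
        raise ReopairError("no events in survival data")
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # iterate tie groups that contain deaths
    death_groups = {}
    for i in ev_idx:
        death_groups.setdefault(gstart[i], []).append(i)
    for g, members in death_groups.items():
        d = len(members)
        sum_eta = eta[members].sum()
        sum_x = Xs[members].sum(axis=0)
        if ties == "breslow" or d == 1:
            ll += sum_eta - d * np.log(S0[g])
            if want_derivs:
                mu = S1[g] / S0[g]
                grad += sum_x - d * mu
                hess += d * (S2[g] / S0[g] - np.outer(mu, mu))
        elif ties == "efron":
            wd = w[members].sum()
            wxd = (w[members, None] * Xs[members]).sum(axis=0)
            if want_derivs:
                wxxd = (w[members, None, None]
                        * (Xs[members][:, :, None] * Xs[members][:, None, :])).sum(axis=0)
            ll += sum_eta
            for l in range(d):
                f = l / d
                s0 = S0[g] - f * wd
                ll -= np.log(s0)
                if want_derivs:
                    s1 = S1[g] - f * wxd
                    mu = s1 / s0
                    grad_term = mu
                    grad -= grad_term
                    hess += (S2[g] - f * wxxd) / s0 - np.outer(mu, mu)
            if want_derivs:
                grad += sum_x
        else:
            raise ReopairError(f"unknown tie method {ties!r}")
    # undo the eta shift: each event contributes +max, each log S0 term -max -> cancels
    return ll, grad if want_derivs else None, hess if want_derivs else None


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit."""

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    names: Sequence[str]
    ties: str = "breslow"

    @property
    def aic(self) -> float:
        """Akaike information criterion on the partial likelihood."""
        return -2.0 * self.loglik + 2.0 * len(self.beta)

    def summary(self) -> pd.DataFrame:
        z = np.divide(self.beta, self.se, out=np.zeros_like(self.beta),
                      where=self.se > 0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        lo = self.beta - 1.959963984540054 * self.se
        hi = self.beta + 1.959963984540054 * self.se
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": np.exp(self.beta),
                "hr_ci_low": np.exp(lo),
                "hr_ci_high": np.exp(hi),
                "z": z,
                "p": p,
            },
            index=list(self.names),
        )


def cox_fit(
    X,
    time,
    event,
    ties: str = "breslow",
    names: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (n, p) array or DataFrame of covariates
    time, event : survival time and 0/1 event indicator
    ties : ``'breslow'`` (default) or ``'efron'``

    Raises
    ------
    ConvergenceError
        If the iteration diverges or the information matrix is singular.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else names
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    n_events = int(event.sum())
    ll_null, _, _ = _cox_derivatives(np.zeros(p), X, time, event, ties, want_derivs=False)

    beta = np.zeros(p)
    ll, grad, hess = _cox_derivatives(beta, X, time, event, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix in Cox fit")
        # step halving on the partial likelihood
        shrink = 1.0
        for _ in range(30):
            cand = beta + shrink * step
            ll_new, _, _ = _cox_derivatives(cand, X, time, event, ties, want_derivs=False)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            shrink *= 0.5
        else:
            raise ConvergenceError("step halving failed in Cox fit")
        beta = cand
        improved = ll_new - ll
        ll = ll_new
        _, grad, hess = _cox_derivatives(beta, X, time, event, ties)
        if abs(improved) < tol and np.abs(grad).max() < 1e-6:
            converged = True
            break
        if np.abs(beta).max() > 50:
            raise ConvergenceError("coefficients diverged (possible complete separation)")
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular information matrix at the Cox solution")
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxFit(beta, se, cov, float(ll), float(ll_null), n, n_events,
                  converged, names, ties)


def cox_screen_binary(
    Xbin: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    block_size: int = 8192,
) -> pd.DataFrame:
    """Univariate Breslow-Cox fits for many binary covariates at once.

    ``Xbin`` is an (m, n) 0/1 matrix: one row per candidate covariate (e.g.
    one lncRNA pair's within-sample ordering states), columns = samples in
    the same order as ``time``/``event``. Returns a DataFrame with columns
    ``beta``, ``se``, ``hr``, ``z``, ``p``, ``converged`` (one row per
    covariate). Covariates with no variation, or with complete separation,
    come back with ``converged=False`` and ``p=1``.

    Rows are processed in blocks of ``block_size``; the result is identical
    regardless of blocking.
    """
    Xbin = np.asarray(Xbin)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    if event.sum() == 0:
        raise ReopairError("no events in survival data")
    order, ts, es, gstart = _sort_survival(time, event)
    ev_idx = np.nonzero(es == 1)[0]
    risk_idx = gstart[ev_idx]                 # risk-set start index per death
    n = time.size
    at_risk = (n - risk_idx).astype(float)    # total at risk per death

    out = []
    for lo in range(0, Xbin.shape[0], block_size):
        xb = Xbin[lo:lo + block_size].astype(float)
        xs = xb[:, order]
        # n1[k, j]: subjects with covariate 1 at risk at death j, for row k
        csum = np.cumsum(xs[:, ::-1], axis=1)[:, ::-1]
        n1 = csum[:, risk_idx]
        e1 = xs[:, ev_idx].sum(axis=1)        # deaths with covariate 1
        n0 = at_risk[None, :] - n1

        beta = np.zeros(xb.shape[0])
        for _ in range(max_iter):
            eb = np.exp(beta)[:, None]
            s0 = n0 + n1 * eb
            pr = n1 * eb / s0                 # P(covariate=1 | risk set), per death
            U = e1 - pr.sum(axis=1)
            I = (pr * (1.0 - pr)).sum(axis=1)
            step = np.where(I > 0, U / np.maximum(I, 1e-300), 0.0)
            step = np.clip(step, -5.0, 5.0)
            beta = beta + step
            beta = np.clip(beta, -30.0, 30.0)
            if np.abs(U).max() < 1e-9:
                break
        eb = np.exp(beta)[:, None]
        s0 = n0 + n1 * eb
        pr = n1 * eb / s0
        I = (pr * (1.0 - pr)).sum(axis=1)
        U = e1 - pr.sum(axis=1)
        with np.errstate(divide="ignore"):
            se = np.where(I > 0, 1.0 / np.sqrt(np.maximum(I, 1e-300)), np.inf)
        ok = (np.abs(U) < 1e-6) & (np.abs(beta) < 15) & (I > 0)
        z = np.where(ok, beta / se, 0.0)
        p = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        out.append(pd.DataFrame({
            "beta": np.where(ok, beta, np.nan),
            "se": np.where(ok, se, np.nan),
            "hr": np.where(ok, np.exp(beta), np.nan),
            "z": z,
            "p": p,
            "converged": ok,
        }))
    return pd.concat(out, ignore_index=True)
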