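"""Counting-process Cox partial likelihood (Breslow ties) with L1 paths.

The likelihood is the start-stop (Andersen–Gill) partial likelihood: a row
``(s, t, d, x)`` is at risk for every event time ``tau`` with
``s < tau <= t``.  Ties are handled by the Breslow approximation, so the
log partial likelihood is

    ll(beta) = sum_{rows with d=1} eta_i  -  sum_tau d_tau * log S(tau),
    S(tau)   = sum_{i in R(tau)} exp(eta_i),       eta = X beta.

Both the score and the (exact) observed information reduce to dense matrix
products via cumulative-sum tricks over the sorted event times, so every
evaluation is O(n p + T p) and the Hessian O(n p^2 + T p^2).

The lasso solver is FISTA (accelerated proximal gradient) with backtracking
on the objective ``-ll/n_events + lam * sum(pf * |beta|)``, run warm-started
down a geometric lambda path; the unpenalized fit is damped Newton with
step-halving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxData:
    """Pre-processed design for the partial-likelihood evaluations."""

    X: np.ndarray        # (n, p)
    event: np.ndarray    # (n,) 0/1
    lo: np.ndarray       # first covered event-time index per row
    hi: np.ndarray       # one past the last covered event-time index
    d: np.ndarray        # (T,) tie multiplicities per event time
    n_events: int

    @classmethod
    def from_arrays(cls, start, stop, event, X) -> "CoxData":
        start = np.asarray(start, dtype=float)
        stop = np.asarray(stop, dtype=float)
        event = np.asarray(event, dtype=int)
        X = np.ascontiguousarray(X, dtype=float)
        if np.any(stop <= start):
            raise ValueError("every row needs t_start < t_stop")
        n_events = int(event.sum())
        if n_events == 0:
            raise ValueError("no events in the data; Cox fit refused")
        times = np.unique(stop[event == 1])
        lo = np.searchsorted(times, start, side="right")
        hi = np.searchsorted(times, stop, side="right")
        d = np.bincount(
            np.searchsorted(times, stop[event == 1]), minlength=times.size
        ).astype(float)
        return cls(X=X, event=event, lo=lo, hi=hi, d=d, n_events=n_events)

    # -- core quantities ---------------------------------------------------

    def _risk_sums(self, w: np.ndarray) -> np.ndarray:
        """S(tau) for every event time, via a difference array."""
        acc = np.zeros(self.d.size + 1)
        np.add.at(acc, self.lo, w)
        np.add.at(acc, self.hi, -w)
        return np.cumsum(acc)[:-1]

    def loglik(self, beta: np.ndarray) -> float:
        eta = self.X @ beta
        S = self._risk_sums(np.exp(eta))
        return float(eta[self.event == 1].sum() - self.d @ np.log(S))

    def loglik_grad(self, beta: np.ndarray):
        """Return ``(ll, gradient of ll)``."""
        eta = self.X @ beta
        w = np.exp(eta)
        S = self._risk_sums(w)
        ll = float(eta[self.event == 1].sum() - self.d @ np.log(S))
        cumH = np.concatenate([[0.0], np.cumsum(self.d / S)])
        G = cumH[self.hi] - cumH[self.lo]
        resid = self.event - w * G  # martingale residuals
        return ll, self.X.T @ resid

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        """Observed information (negative Hessian of ll), exact Breslow."""
        eta = self.X @ beta
        w = np.exp(eta)
        S = self._risk_sums(w)
        cumH = np.concatenate([[0.0], np.cumsum(self.d / S)])
        G = cumH[self.hi] - cumH[self.lo]
        term1 = self.X.T @ (self.X * (w * G)[:, None])
        # weighted risk-set means per event time
        WX = self.X * w[:, None]
        acc = np.zeros((self.d.size + 1, self.X.shape[1]))
        np.add.at(acc, self.lo, WX)
        np.add.at(acc, self.hi, -WX)
        M = np.cumsum(acc, axis=0)[:-1]
        U = M / S[:, None]
        term2 = (U * self.d[:, None]).T @ U
        return term1 - term2


def newton_fit(
    data: CoxData,
    tol: float = 1e-9,
    max_iter: int = 50,
    ridge: float = 1e-9,
):
    """Unpenalized maximum partial likelihood via damped Newton.

    Returns ``(beta, se, ll)``; raises :class:`ConvergenceError` on failure.
    """
    p = data.X.shape[1]
    beta = np.zeros(p)
    ll, grad = data.loglik_grad(beta)
    for _ in range(max_iter):
        H = data.hessian(beta)
        try:
            step = np.linalg.solve(H + ridge * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = data.loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step-halving failed")
        beta = cand
        ll_prev = ll
        ll, grad = data.loglik_grad(beta)
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)) or abs(ll - ll_prev) < tol * (
            abs(ll_prev) + 1.0
        ):
            break
    else:
        raise ConvergenceError(f"Newton did not converge in {max_iter} iterations")
    H = data.hessian(beta)
    cov = np.linalg.inv(H + ridge * np.eye(p))
    se = np.sqrt(np.diag(cov))
    return beta, se, ll


def _soft_threshold(z: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def lambda_max(data: CoxData, pf: np.ndarray) -> float:
    """Smallest lambda at which every penalized coefficient is zero."""
    _, grad = data.loglik_grad(np.zeros(data.X.shape[1]))
    g = np.abs(grad) / data.n_events
    with np.errstate(divide="ignore"):
        ratio = np.where(pf > 0, g / np.where(pf > 0, pf, 1.0), 0.0)
    return float(ratio.max())


def fista_lasso(
    data: CoxData,
    lam: float,
    pf: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
):
    """Minimize ``-ll/n_ev + lam * sum(pf * |beta|)`` by FISTA."""
    n = data.n_events
    p = data.X.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    y = beta.copy()
    t_mom = 1.0
    L = 1.0

    def smooth(b):
        ll, grad = data.loglik_grad(b)
        return -ll / n, -grad / n

    f_y, g_y = smooth(y)
    obj_prev = np.inf
    for _ in range(max_iter):
        # backtracking line search on the smooth part
        for _ in range(60):
            cand = _soft_threshold(y - g_y / L, lam * pf / L)
            diff = cand - y
            f_cand = -data.loglik(cand) / n
            quad = f_y + g_y @ diff + 0.5 * L * (diff @ diff)
            if f_cand <= quad + 1e-12:
                break
            L *= 2.0
        beta_new = cand
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        y = beta_new + ((t_mom - 1.0) / t_new) * (beta_new - beta)
        beta, t_mom = beta_new, t_new
        obj = f_cand + lam * float(pf @ np.abs(beta))
        if abs(obj_prev - obj) < tol * (abs(obj) + 1e-10):
            break
        obj_prev = obj
        f_y, g_y = smooth(y)
        L = max(L / 2.0, 1e-6)  # allow the step to grow back
    return beta


def lasso_path(
    data: CoxData,
    lambdas: np.ndarray,
    pf: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Warm-started coefficient path; returns (len(lambdas), p)."""
    p = data.X.shape[1]
    out = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for k, lam in enumerate(lambdas):
        beta = fista_lasso(data, float(lam), pf, beta0=beta, tol=tol, max_iter=max_iter)
        out[k] = beta
    return out


def default_lambdas(
    data: CoxData, pf: np.ndarray, n_lambda: int = 25, min_ratio: float = 0.05
) -> np.ndarray:
    lmax = lambda_max(data, pf)
    if lmax <= 0:
        raise ValueError("all-zero gradient at beta=0; nothing to penalize")
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)
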