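"""Discount-model fitting and the model-free impulsivity count.

Two one-reward discount functions are fitted by least squares to the four
tomorrow-anchored indifference points (proportions of the 20-euro reward at
delays of 3, 6, 9 and 12 months):

* hyperbolic: SV(T) = 1 / (1 + k*T), one parameter k >= 0 per month;
* quasi-hyperbolic (beta-delta): SV(0) = 1 and SV(T) = beta * delta**T for
  T > 0, with 0 <= beta, delta <= 1. beta indexes present-bias (smaller beta,
  more extra weight on immediacy); delta indexes patience, with discount rate
  log(1/delta).

Fits use a multi-start grid followed by local refinement, and the two models
are compared by the least-squares AIC, n*ln(SSE/n) + 2p. The model-free
impulsivity index NImp counts sooner choices on the 84 non-catch trials.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .design import FIT_DELAYS

#: search ceiling for the hyperbolic rate (per month)
K_MAX = 10.0
#: floor applied to k before taking ln(k), and to SSE before the AIC log
LNK_FLOOR = 1e-4
SSE_FLOOR = 1e-10


def sv_hyperbolic(k, T):
    """Hyperbolic subjective value 1/(1 + k*T) of a unit reward."""
    k = np.asarray(k, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    if np.any(T < 0):
        raise ValueError("T must be >= 0")
    out = 1.0 / (1.0 + k * T)
    return float(out) if out.ndim == 0 else out


def sv_quasihyperbolic(beta, delta, T):
    """Quasi-hyperbolic subjective value: 1 at T=0, beta*delta**T for T>0."""
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValueError("beta must be in [0, 1]")
    if np.any(delta < 0) or np.any(delta > 1):
        raise ValueError("delta must be in [0, 1]")
    if np.any(T < 0):
        raise ValueError("T must be >= 0")
    out = np.where(T > 0, beta * np.power(delta, T), 1.0)
    return float(out) if out.ndim == 0 else out


def aic_ls(sse: float, n_points: int, n_params: int) -> float:
    """Least-squares AIC: n*ln(SSE/n) + 2p, with SSE floored at 1e-10."""
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    sse = max(float(sse), SSE_FLOOR)
    return n_points * np.log(sse / n_points) + 2 * n_params


def _check_ips(T, ips):
    T = np.asarray(T, dtype=float).reshape(-1)
    ips = np.asarray(ips, dtype=float).reshape(-1)
    if T.shape != ips.shape:
        raise ValueError("T and indifference points must have equal length")
    if np.any(ips < 0) or np.any(ips > 1):
        raise ValueError("indifference points must be proportions in [0, 1]")
    if np.any(T < 0):
        raise ValueError("delays must be >= 0")
    return T, ips


class HyperbolicDiscounter(BaseEstimator, RegressorMixin):
    """Least-squares fit of SV(T) = 1/(1+kT) to indifference points.

    A coarse grid over k in [0, k_max] (zero plus log-spaced points) locates
    the basin; bounded scalar minimization refines it.

    Attributes: ``k_``, ``ln_k_`` (with a 1e-4 floor under the log),
    ``sse_``, ``aic_``, ``n_params_ = 1``.
    """

    n_params_ = 1

    def __init__(self, k_max: float = K_MAX, n_grid: int = 200):
        self.k_max = k_max
        self.n_grid = n_grid

    def fit(self, X, y):
        T, ips = _check_ips(X, y)

        def sse(k):
            return float(np.sum((ips - 1.0 / (1.0 + k * T)) ** 2))

        grid = np.concatenate(
            [[0.0], np.logspace(-5, np.log10(self.k_max), self.n_grid)]
        )
        losses = ((ips[None, :] - 1.0 / (1.0 + grid[:, None] * T[None, :])) ** 2).sum(1)
        best = int(np.argmin(losses))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid.size - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                sse, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            k = float(res.x) if res.fun <= losses[best] else float(grid[best])
        else:
            k = float(grid[best])
        self.k_ = k
        self.ln_k_ = float(np.log(max(k, LNK_FLOOR)))
        self.sse_ = sse(k)
        self.aic_ = aic_ls(self.sse_, T.size, self.n_params_)
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).reshape(-1)
        return 1.0 / (1.0 + self.k_ * T)


class QuasiHyperbolicDiscounter(BaseEstimator, RegressorMixin):
    """Least-squares fit of SV(T) = beta*delta**T (T>0) on [0,1]^2.

    Multi-start: a coarse (beta, delta) grid, then bounded least-squares
    refinement from the best starts.

    Attributes: ``beta_``, ``delta_``, ``sse_``, ``aic_``, ``n_params_ = 2``.
    """

    n_params_ = 2

    def __init__(self, n_grid: int = 41, n_starts: int = 3):
        self.n_grid = n_grid
        self.n_starts = n_starts

    def fit(self, X, y):
        T, ips = _check_ips(X, y)
        if np.any(T == 0):
            raise ValueError("fit uses only T > 0 points (SV(0) is fixed at 1)")

        bg, dg = np.meshgrid(
            np.linspace(0.0, 1.0, self.n_grid), np.linspace(0.0, 1.0, self.n_grid)
        )
        preds = bg.ravel()[:, None] * np.power(dg.ravel()[:, None], T[None, :])
        losses = ((ips[None, :] - preds) ** 2).sum(axis=1)
        order = np.argsort(losses)[: self.n_starts]

        def residuals(params):
            b, d = params
            return ips - b * np.power(d, T)

        best_params = (float(bg.ravel()[order[0]]), float(dg.ravel()[order[0]]))
        best_sse = float(losses[order[0]])
        for idx in order:
            x0 = np.array([bg.ravel()[idx], dg.ravel()[idx]])
            res = optimize.least_squares(
                residuals, x0, bounds=([0.0, 0.0], [1.0, 1.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            sse = float(np.sum(res.fun**2))
            if sse < best_sse:
                best_sse = sse
                best_params = (float(res.x[0]), float(res.x[1]))
        self.beta_, self.delta_ = best_params
        self.sse_ = best_sse
        self.aic_ = aic_ls(self.sse_, T.size, self.n_params_)
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).reshape(-1)
        return np.where(T > 0, self.beta_ * np.power(self.delta_, T), 1.0)

    @property
    def discount_rate_(self) -> float:
        """log(1/delta), the long-run discount rate of the beta-delta model."""
        return float(np.log(1.0 / max(self.delta_, 1e-12)))


def fit_hyperbolic(ips, T=FIT_DELAYS):
    """Thin wrapper: fit the hyperbolic model, return (k, sse)."""
    est = HyperbolicDiscounter().fit(T, ips)
    return est.k_, est.sse_


def fit_quasihyperbolic(ips, T=FIT_DELAYS):
    """Thin wrapper: fit the beta-delta model, return (beta, delta, sse)."""
    est = QuasiHyperbolicDiscounter().fit(T, ips)
    return est.beta_, est.delta_, est.sse_


def count_impulsive(trials: pd.DataFrame) -> int:
    """NImp: sooner choices on the non-catch trials (84 of the 108)."""
    non_catch = trials[~trials["is_catch"]]
    if non_catch["choice"].isna().any():
        raise ValueError("missing choices on non-catch trials")
    return int((non_catch["choice"] == "sooner").sum())


@dataclass
class DiscountFit:
    """Per-participant discounting summary."""

    participant_id: object
    k: float
    ln_k: float
    beta: float
    delta: float
    sse_hyp: float
    sse_qh: float
    aic_hyp: float
    aic_qh: float
    preferred_model: str
    n_imp: int


def fit_participant(pid, ips, trials=None, T=FIT_DELAYS) -> DiscountFit:
    """Fit both models to one participant's 4 tomorrow-anchored IPs."""
    hyp = HyperbolicDiscounter().fit(T, ips)
    qh = QuasiHyperbolicDiscounter().fit(T, ips)
    n_imp = count_impulsive(trials) if trials is not None else -1
    return DiscountFit(
        participant_id=pid,
        k=hyp.k_,
        ln_k=hyp.ln_k_,
        beta=qh.beta_,
        delta=qh.delta_,
        sse_hyp=hyp.sse_,
        sse_qh=qh.sse_,
        aic_hyp=hyp.aic_,
        aic_qh=qh.aic_,
        preferred_model="hyperbolic" if hyp.aic_ <= qh.aic_ else "quasi-hyperbolic",
        n_imp=n_imp,
    )


def fit_cohort(ip_table: pd.DataFrame, trials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fit every participant from an indifference-point table.

    ``ip_table`` is the output of :func:`tempodisc.indifference.indifference_profile`;
    only blocks 1-4 (delays 3-12 months with a "tomorrow" anchor) enter the fit.
    """
    rows = []
    for pid, sub in ip_table.groupby("participant_id", sort=True):
        sub = sub[sub["block"].isin([1, 2, 3, 4])].sort_values("block")
        if len(sub) != 4:
            raise ValueError(f"participant {pid}: need the 4 tomorrow-anchored blocks")
        ptrials = (
            trials[trials["participant_id"] == pid] if trials is not None else None
        )
        fit = fit_participant(pid, sub["ip_proportion"].to_numpy(), ptrials)
        rows.append(asdict(fit))
    return pd.DataFrame(rows)
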