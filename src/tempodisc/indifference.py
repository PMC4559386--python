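"""Indifference-point estimation from binary choices.

The indifference point (IP) of a block is the sooner amount at which the
participant is equally likely to take either option. It is estimated by
maximum-likelihood logistic regression of the choice (sooner=1) on the sooner
amount, IP = -intercept/slope, clipped to [0, 20] euros and also expressed as
a proportion of the fixed 20-euro later reward.

With 18 trials and a 2.50-euro amount grid, deterministic responders are
common and produce perfectly separated data on which unregularized ML does
not converge. Those blocks fall back to the midpoint between the largest
amount at which the later option was always taken and the smallest amount at
which the sooner option was always taken (all-later responders get IP=20,
all-sooner IP=0), flagged ``separated``. Catch trials are kept in the
regression: they anchor both ends of the psychometric curve.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from scipy.special import expit

from .design import LATER_AMOUNT

TRIALS_PER_BLOCK = 18


class IndifferencePointEstimator(BaseEstimator):
    """Logistic psychometric-curve fit with a midpoint fallback.

    Parameters
    ----------
    later_amount : float
        The fixed delayed amount; the IP is clipped to [0, later_amount].

    Attributes
    ----------
    ip_ : float
        Indifference point in euros.
    ip_proportion_ : float
        ``ip_ / later_amount``.
    intercept_, slope_ : float
        Logistic coefficients of P(sooner) = logistic(a + b*amount);
        NaN when the fallback was used.
    separated_ : bool
        True when the midpoint fallback replaced the ML fit.
    """

    def __init__(self, later_amount: float = LATER_AMOUNT):
        self.later_amount = later_amount

    def fit(self, X, y):
        """Fit from sooner amounts ``X`` (1d or (n,1)) and ``y`` (1 = sooner)."""
        amounts = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if amounts.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.isnan(y).any():
            raise ValueError("choices contain missing values")

        self.separated_ = False
        self.intercept_ = np.nan
        self.slope_ = np.nan

        sooner_amts = amounts[y == 1]
        later_amts = amounts[y == 0]
        if sooner_amts.size == 0:
            self._set_ip(self.later_amount, separated=True)
            return self
        if later_amts.size == 0:
            self._set_ip(0.0, separated=True)
            return self
        if later_amts.max() < sooner_amts.min():
            # monotone deterministic responder: perfectly separated
            self._set_ip(self._midpoint(amounts, y), separated=True)
            return self

        exog = sm.add_constant(amounts)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            a, b = res.params
        except Exception:
            converged = False
            a = b = np.nan
        if not converged or not np.isfinite(b) or b <= 0:
            # quasi-separation or a degenerate (non-increasing) curve
            self._set_ip(self._midpoint(amounts, y), separated=True)
            return self
        self.intercept_ = float(a)
        self.slope_ = float(b)
        self._set_ip(float(np.clip(-a / b, 0.0, self.later_amount)), separated=False)
        return self

    def predict_proba_sooner(self, X):
        """P(choose sooner) at the given amounts (ML fit only)."""
        if np.isnan(self.slope_):
            raise ValueError("no logistic fit available (fallback was used)")
        amounts = np.asarray(X, dtype=float).reshape(-1)
        return expit(self.intercept_ + self.slope_ * amounts)

    def _set_ip(self, ip, separated):
        self.ip_ = float(ip)
        self.ip_proportion_ = self.ip_ / self.later_amount
        self.separated_ = bool(separated)

    def _midpoint(self, amounts, y):
        """Midpoint between the always-later and always-sooner regions."""
        lo, hi = 0.0, self.later_amount
        later_always = [
            a for a in np.unique(amounts) if np.all(y[amounts == a] == 0)
        ]
        sooner_always = [
            a for a in np.unique(amounts) if np.all(y[amounts == a] == 1)
        ]
        if later_always:
            lo = max(later_always)
        if sooner_always:
            hi = min(sooner_always)
        return float(np.clip((lo + hi) / 2.0, 0.0, self.later_amount))


def estimate_ip(block_trials: pd.DataFrame) -> dict:
    """Estimate the IP of one block (18 trials with recorded choices)."""
    if len(block_trials) != TRIALS_PER_BLOCK:
        raise ValueError(
            f"expected {TRIALS_PER_BLOCK} trials in a block, got {len(block_trials)}"
        )
    if block_trials["choice"].isna().any():
        raise ValueError("block contains trials without a recorded choice")
    est = IndifferencePointEstimator().fit(
        block_trials["sooner_amount"].to_numpy(),
        (block_trials["choice"] == "sooner").astype(float).to_numpy(),
    )
    return {
        "ip_euros": est.ip_,
        "ip_proportion": est.ip_proportion_,
        "intercept": est.intercept_,
        "slope": est.slope_,
        "separated": est.separated_,
    }


def indifference_profile(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-block IP table (participant x 6 block rows)."""
    rows = []
    for (pid, block), sub in trials.groupby(["participant_id", "block"], sort=True):
        entry = estimate_ip(sub)
        entry.update(participant_id=pid, block=int(block))
        rows.append(entry)
    cols = [
        "participant_id",
        "block",
        "ip_euros",
        "ip_proportion",
        "intercept",
        "slope",
        "separated",
    ]
    return pd.DataFrame(rows)[cols]
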