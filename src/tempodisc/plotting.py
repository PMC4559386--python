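"""Discount-curve plots (indifference points with fitted models)."""

from __future__ import annotations

import numpy as np

from .design import FIT_DELAYS
from .discounting import sv_hyperbolic, sv_quasihyperbolic


def plot_discount_fit(ips, k, beta, delta, ip_se=None, ax=None, title=None):
    """Plot indifference points with the hyperbolic and beta-delta fits.

    ``ips`` are the four proportions at 3, 6, 9 and 12 months; ``ip_se``
    optional standard errors for error bars. Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    T = np.asarray(FIT_DELAYS, dtype=float)
    grid = np.linspace(0.0, T.max(), 200)
    ax.errorbar(T, ips, yerr=ip_se, fmt="ko", capsize=3, label="indifference points")
    ax.plot(grid, sv_hyperbolic(k, grid), color="0.7", label=f"hyperbolic (k={k:.3f})")
    pos = grid[grid > 0]
    ax.plot(
        pos,
        sv_quasihyperbolic(beta, delta, pos),
        "k--",
        label=rf"quasi-hyperbolic ($\beta$={beta:.2f}, $\delta$={delta:.3f})",
    )
    ax.plot([0, pos.min()], [1.0, sv_quasihyperbolic(beta, delta, pos.min())],
            color="0.3")
    ax.set_xlabel("delay (months)")
    ax.set_ylabel("proportion of delayed reward")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax
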