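"""Diagnostic figure: histogram, fitted mixture/null densities, local fdr."""

from __future__ import annotations

import numpy as np

from .estimators import MixtureFit
from .localfdr import local_fdr_curve

__all__ = ["plot_fit"]


def plot_fit(fit: MixtureFit, path=None, title: str | None = None):
    """Two-panel figure: density scale (histogram, f-hat, p0*f0-hat) above
    the local-fdr curve.  Returns the matplotlib Figure; saves if ``path``
    is given."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    hist = fit.hist
    x = hist.midpoints
    grid = np.linspace(x[0], x[-1], 400)
    scale = hist.total * hist.width
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(6, 7), sharex=True,
                                   height_ratios=[2, 1])
    ax0.bar(x, hist.density(), width=hist.width, color="0.85",
            edgecolor="0.6", label="histogram")
    ax0.plot(grid, np.exp(fit.log_mixture(grid)) / scale, "g-",
             label=r"mixture $\hat f$")
    if fit.beta is not None:
        ax0.plot(grid, np.exp(fit.log_null(grid)) / scale, "b--",
                 label=r"null $\hat p_0 \hat f_0$")
    ax0.set_ylabel("density")
    ax0.legend(frameon=False)
    if title:
        ax0.set_title(title)
    if fit.beta is not None:
        ax1.plot(grid, local_fdr_curve(fit, grid), "b-")
    ax1.axhline(1.0, color="0.5", lw=0.8, ls=":")
    ax1.set_ylabel("local fdr")
    ax1.set_xlabel("z")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
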