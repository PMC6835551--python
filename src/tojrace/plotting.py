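"""Minimal data/curve overlay for judgment data and fitted models."""

from __future__ import annotations

import numpy as np

from .models import model_probability
from .synthetic import JudgmentData

__all__ = ["plot_fit"]


def plot_fit(data: JudgmentData, fits=None, ax=None, n_curve: int = 400):
    """Overlay per-SOA probe-first frequencies with fitted model curves.

    ``fits`` is an iterable of :class:`~tojrace.fitting.FitResult`.  Returns
    the matplotlib axes.  The y axis follows the package convention:
    probability of responding "probe first", which falls as SOA grows.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    soas = data.design.soa_array
    ax.plot(soas, data.frequencies, "o", color="0.3", label="data")
    grid = np.linspace(soas.min(), soas.max(), n_curve)
    for fit in fits or []:
        ax.plot(grid, model_probability(fit.model, fit.params, grid),
                label=f"{fit.model} (BIC {fit.bic:.1f})")
    ax.set_xlabel("SOA (ms)  [negative = probe first]")
    ax.set_ylabel('P(respond "probe first")')
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax
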