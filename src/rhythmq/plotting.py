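"""Minimal per-series fit overlay plot (mean +/- SEM with the fitted cosinor)."""

from __future__ import annotations

import numpy as np

from .cosinor import CosinorFit


def plot_series_fit(times_h, values, fit: CosinorFit, ax=None, label: str = ""):
    """Scatter time-point means (+/- SEM) and overlay the fitted 24-h cosinor.

    The dashed sinusoid is drawn only when the fit has a defined amplitude,
    mirroring how rhythmic profiles are presented in daily-profile figures.
    """
    import matplotlib.pyplot as plt

    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    means, sems, uts = [], [], np.unique(t)
    for ut in uts:
        yy = y[t == ut]
        means.append(yy.mean())
        sems.append(yy.std(ddof=1) / np.sqrt(len(yy)) if len(yy) > 1 else 0.0)
    ax.errorbar(uts, means, yerr=sems, fmt="o", capsize=3, label=label or None)
    if fit.amplitude_defined:
        grid = np.linspace(t.min(), t.max(), 200)
        ax.plot(grid, fit.predict(grid), "--",
                label=f"A={fit.amplitude:.2f}, acro={fit.acrophase_h:.1f} h")
    ax.set_xlabel("time (ZT/CT h)")
    ax.set_ylabel("level")
    if label or fit.amplitude_defined:
        ax.legend(frameon=False)
    return ax
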