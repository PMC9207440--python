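"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the cosinor oracle is a
brute-force grid search over the acrophase with a per-phase 2-parameter linear
fit, and the studentized-range oracle is a direct Monte-Carlo simulation of
the range of p standard normals over an independent chi-based scale estimate.
"""

from __future__ import annotations

import numpy as np

OMEGA = np.pi / 12.0


def gridsearch_cosinor(times_h, values, phi_step: float = 1e-3):
    """Nonlinear least squares by exhaustive acrophase grid search.

    For every phi on a grid of ``phi_step`` radians, fit ``y = M + A*cos(
    omega*t - phi)`` linearly in (M, A) and keep the phi with the smallest
    residual sum of squares.  Returns (M, A, phi, rss) with A >= 0.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)

    def fit_at(phis):
        C = np.cos(OMEGA * t[None, :] - np.atleast_1d(phis)[:, None])
        cbar = C.mean(axis=1)
        ybar = y.mean()
        Cc = C - cbar[:, None]
        scc = (Cc**2).sum(axis=1)
        scy = (Cc * (y - ybar)[None, :]).sum(axis=1)
        A = scy / scc
        M = ybar - A * cbar
        rss = ((y - ybar) ** 2).sum() - A * scy
        return M, A, rss

    phis = np.arange(0.0, 2.0 * np.pi, phi_step)
    _, _, rss = fit_at(phis)
    i = int(np.argmin(rss))
    phi = float(phis[i])
    # iterated parabolic refinement of the 1-D profile RSS(phi)
    for step in (phi_step, phi_step / 50, phi_step / 2500):
        _, _, (lo, mid, hi) = fit_at([phi - step, phi, phi + step])
        denom = hi - 2.0 * mid + lo
        if denom > 0:
            phi += 0.5 * step * (lo - hi) / denom
    m, a, r = (float(v[0]) for v in fit_at(phi))
    if a < 0:  # equivalent representation with positive amplitude
        a, phi = -a, phi + np.pi
    return float(m), float(a), float(phi % (2.0 * np.pi)), float(r)


def mc_studentized_range_quantile(
    n_means: int, df: int, alpha: float, n_mc: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo upper-alpha quantile of the studentized range q(p, df)."""
    z = rng.standard_normal((n_mc, n_means))
    r = z.max(axis=1) - z.min(axis=1)
    s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    return float(np.quantile(r / s, 1.0 - alpha))
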