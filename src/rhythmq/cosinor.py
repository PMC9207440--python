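"""Fixed-period (24-h) cosinor fitting by linear least squares.

The model is ``f(t) = M + A * cos(t * pi/12 - phi)``: *M* (mesor) is the
rhythm-adjusted mean, *A* >= 0 the amplitude and *phi* the acrophase (timing of
the fitted peak). With the angular frequency fixed at ``omega = pi/12`` per
hour the model is linear in ``(M, beta_c, beta_s)`` through

    f(t) = M + beta_c * cos(omega t) + beta_s * sin(omega t),

with ``A = hypot(beta_c, beta_s)`` and ``phi = atan2(beta_s, beta_c)``.  The
linear solution is therefore the *global* optimum of the nonlinear problem.
Standard errors come from the residual sum of squares: the parameter
covariance is ``sigma^2 (X'X)^{-1}`` with ``sigma^2 = RSS / (n - 3)``, and the
errors of A and phi follow by first-order (delta-method) propagation.

The quantity ``SE(A)/A`` is the noise/signal ratio of the amplitude; small
values indicate a well-determined oscillation and it is one of the three
rhythm-detection criteria applied downstream (threshold 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OMEGA", "CosinorFit", "fit_cosinor", "noise_signal_ratio"]

#: angular frequency of a 24-h rhythm, radians per hour
OMEGA = np.pi / 12.0

# amplitudes below _AMP_TOL * max(1, |M|) are treated as exactly zero:
# the acrophase (and SE(A)/A) is then undefined.
_AMP_TOL = 1e-12


@dataclass(frozen=True)
class CosinorFit:
    """Result of a 24-h cosinor least-squares fit."""

    mesor: float
    amplitude: float
    acrophase_rad: float
    se_mesor: float
    se_amplitude: float
    se_acrophase_rad: float
    rss: float
    n_obs: int
    r_squared: float
    series_id: str | None = field(default=None, compare=False)

    @property
    def acrophase_h(self) -> float:
        """Acrophase in clock hours (ZT/CT), in [0, 24)."""
        if not np.isfinite(self.acrophase_rad):
            return float("nan")
        return float(np.mod(self.acrophase_rad / OMEGA, 24.0))

    @property
    def se_acrophase_h(self) -> float:
        return float(self.se_acrophase_rad / OMEGA)

    @property
    def amplitude_defined(self) -> bool:
        """False for flat series whose acrophase carries no information."""
        return self.amplitude > _AMP_TOL * max(1.0, abs(self.mesor))

    @property
    def noise_signal(self) -> float:
        """SE(A)/A; NaN when the amplitude is (numerically) zero."""
        if not self.amplitude_defined:
            return float("nan")
        return float(self.se_amplitude / self.amplitude)

    def predict(self, times_h: np.ndarray) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        if not self.amplitude_defined:
            return np.full_like(t, self.mesor)
        return self.mesor + self.amplitude * np.cos(OMEGA * t - self.acrophase_rad)


def _design_matrix(times_h: np.ndarray) -> np.ndarray:
    wt = OMEGA * times_h
    return np.column_stack([np.ones_like(times_h), np.cos(wt), np.sin(wt)])


def fit_cosinor(
    times_h,
    values,
    *,
    series_id: str | None = None,
) -> CosinorFit:
    """Fit ``M + A cos(pi/12 * t - phi)`` to observations by least squares.

    Parameters
    ----------
    times_h
        Sampling times in hours (ZT/CT). Times beyond 24 h are legitimate and
        enter at their phase modulo 24 (e.g. the next-day 27-h sample is
        phase-equivalent to 3 h).
    values
        Measurements (fold change, mg/dl, ...), one per time entry.

    Raises
    ------
    ValueError
        For fewer than 4 observations, or a rank-deficient design (fewer than
        3 distinct sampling phases modulo 24 h).
    """
    t = np.asarray(times_h, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if t.shape != y.shape:
        raise ValueError("times_h and values must have the same length")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("times_h and values must be finite")
    n = t.size
    if n < 4:
        raise ValueError(f"cosinor fit needs >= 4 observations, got {n}")
    phases = np.unique(np.round(np.mod(t, 24.0), 9))
    if phases.size < 3:
        raise ValueError(
            "rank-deficient design: need >= 3 distinct sampling phases mod 24 h, "
            f"got {phases.size}"
        )

    X = _design_matrix(t)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:  # pragma: no cover - guarded by the phase check above
        raise ValueError("rank-deficient cosinor design matrix")
    resid = y - X @ beta
    rss = float(resid @ resid)
    mesor, bc, bs = (float(b) for b in beta)
    amplitude = float(np.hypot(bc, bs))

    sigma2 = rss / (n - 3)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_mesor = float(np.sqrt(cov[0, 0]))

    flat = amplitude <= _AMP_TOL * max(1.0, abs(mesor))
    if flat:
        acro = float("nan")
        se_amp = float(np.sqrt(max(cov[1, 1], cov[2, 2])))
        se_acro = float("nan")
    else:
        acro = float(np.mod(np.arctan2(bs, bc), 2.0 * np.pi))
        # delta method through A = hypot(bc, bs), phi = atan2(bs, bc)
        ga = np.array([0.0, bc / amplitude, bs / amplitude])
        gp = np.array([0.0, -bs / amplitude**2, bc / amplitude**2])
        se_amp = float(np.sqrt(ga @ cov @ ga))
        se_acro = float(np.sqrt(gp @ cov @ gp))

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    return CosinorFit(
        mesor=mesor,
        amplitude=0.0 if flat else amplitude,
        acrophase_rad=acro,
        se_mesor=se_mesor,
        se_amplitude=se_amp,
        se_acrophase_rad=se_acro,
        rss=rss,
        n_obs=n,
        r_squared=r2,
        series_id=series_id,
    )


def noise_signal_ratio(fit: CosinorFit) -> float:
    """Amplitude noise/signal ratio SE(A)/A of a fit.

    NaN (propagated as non-rhythmic downstream) when the amplitude is zero.
    """
    return fit.noise_signal
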