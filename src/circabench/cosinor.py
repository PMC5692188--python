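"""Cosinor regression: least-squares fit of a single cosine component.

The model is ``y = M + A*cos(2*pi*(t - phi)/T)`` at a fixed period ``T``,
linearized as ``y = M + b_c*cos(w t) + b_s*sin(w t)`` so the fit is ordinary
least squares; then ``A = hypot(b_c, b_s)`` (non-negative) and the acrophase
``phi = atan2(b_s, b_c)/w`` normalized into ``[0, T)``.  The fold change is
the fitted peak over the fitted trough, ``(M + A) / (M - A)``, defined only
when the trough is positive.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ValidationError

__all__ = ["Cosinor", "cosinor_fit"]


class Cosinor(BaseEstimator):
    """Least-squares cosinor fit at a fixed period for many series at once.

    Parameters
    ----------
    period_h : float
        Period of the fitted cosine, hours.

    Attributes (after ``fit``)
    --------------------------
    mesor_, amplitude_, phase_h_, r_squared_, fold_change_ : ndarray
        One entry per series.  ``amplitude_`` is non-negative, ``phase_h_``
        lies in ``[0, period_h)``, ``fold_change_`` is NaN when the fitted
        trough is not positive, and ``r_squared_`` is 0 for constant series.
    """

    def __init__(self, period_h: float = 24.0):
        self.period_h = period_h

    def fit(self, X, times_h):
        if self.period_h <= 0:
            raise ValidationError(f"period_h={self.period_h} must be positive")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        t = np.asarray(times_h, dtype=float)
        if X.shape[1] != t.size:
            raise ValidationError(
                f"X has {X.shape[1]} columns but times_h has {t.size} entries"
            )
        if np.unique(np.round(t, 9)).size < 3:
            raise ValidationError("cosinor fit needs at least 3 distinct timepoints")
        w = 2.0 * np.pi / self.period_h
        Z = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
        if np.linalg.matrix_rank(Z) < 3:
            raise ValidationError(
                "degenerate design: sampling times are aliased modulo the "
                f"period ({self.period_h} h); the cosine is not identifiable"
            )
        coef, *_ = np.linalg.lstsq(Z, X.T, rcond=None)
        mesor = coef[0]
        b_c, b_s = coef[1], coef[2]
        amplitude = np.hypot(b_c, b_s)
        phase = (np.arctan2(b_s, b_c) / w) % self.period_h
        fitted = (Z @ coef).T
        ss_res = ((X - fitted) ** 2).sum(axis=1)
        ss_tot = ((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        trough = mesor - amplitude
        with np.errstate(invalid="ignore", divide="ignore"):
            fold = np.where(trough > 0, (mesor + amplitude) / trough, np.nan)
        # a flat fit has no acrophase
        phase = np.where(amplitude > 0, phase, np.nan)

        self.n_features_in_ = X.shape[1]
        self.mesor_ = mesor
        self.amplitude_ = amplitude
        self.phase_h_ = phase
        self.r_squared_ = np.clip(r2, 0.0, 1.0)
        self.fold_change_ = fold
        return self


def cosinor_fit(series, grid, period_h: float):
    """Fit one series; returns ``(mesor, amplitude, phase_h, r_squared, fold_change)``.

    ``grid`` may be a :class:`~circabench.grid.TimeGrid` or a vector of
    per-column times.
    """
    from .grid import TimeGrid

    times = grid.column_times_h if isinstance(grid, TimeGrid) else np.asarray(grid, float)
    est = Cosinor(period_h=period_h).fit(np.atleast_2d(series), times)
    return (
        float(est.mesor_[0]),
        float(est.amplitude_[0]),
        float(est.phase_h_[0]),
        float(est.r_squared_[0]),
        float(est.fold_change_[0]),
    )
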