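"""JTK-style rhythmicity detection with exact nonparametric p-values.

For every alternative on a (period, phase) grid the detector scores the
series against a cosine rank template with the tie-aware Kendall statistic
S and converts it to an exact two-sided tail probability from the
permutation null (:mod:`circabench.nulldist`).  Per series,

* ``p_raw``  = the minimum exact p over all alternatives,
* ``p_adj``  = ``min(1, p_raw * n_alternatives)`` — the Bonferroni
  ("adjusted p") correction for the within-series search,
* ``q_bh``   = Benjamini-Hochberg FDR across series, applied to ``p_adj``.

The phase grid spans the FULL period at ``phase_step_h`` resolution and the
tail is two-sided.  A phase and its half-period shift then yield the same
two-sided p (S changes sign only), so the Bonferroni count deliberately
double-counts this redundancy — the convention of the widely used JTK
implementation, and the source of its characteristic conservatism on null
data.  The winning template's phase, sign-corrected by the sign of S, is
reported as ``best_phase_h`` at phase-grid granularity; amplitude, mesor,
fold change and R^2 are refined by a cosinor fit at the best period.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cosinor import Cosinor
from .dataset import Dataset
from .errors import ValidationError
from .grid import TimeGrid
from .nulldist import exact_null, pair_sign_matrix, reference_template

logger = logging.getLogger(__name__)

__all__ = ["JTKDetector", "jtk_test", "bh_adjust"]

_CHUNK_CELLS = 1 << 26  # cap on n_series * n_cols^2 sign-matrix cells per chunk

RESULT_COLUMNS = (
    "series_id",
    "p_raw",
    "p_adj",
    "q_bh",
    "best_period_h",
    "best_phase_h",
    "mesor",
    "amplitude",
    "fold_change",
    "r_squared",
)


def bh_adjust(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <= 1)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class JTKDetector(BaseEstimator):
    """Exact rank-template rhythmicity test over a (period, phase) grid.

    Parameters
    ----------
    period_set : sequence of float
        Candidate periods in hours.  Default ``(24,)`` — tune this to the
        organism's empirically determined period.
    phase_step_h : float or None
        Phase-grid resolution; ``None`` uses the sampling interval.  Must
        divide every period in ``period_set``.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame
        One row per series: p_raw, p_adj, q_bh, best_period_h, best_phase_h,
        mesor, amplitude, fold_change, r_squared.  Constant series get
        p_adj = 1 and NaN phase.
    n_alternatives_ : int
        Number of (period, phase) templates searched.
    """

    def __init__(self, period_set=(24.0,), phase_step_h: float | None = None):
        self.period_set = period_set
        self.phase_step_h = phase_step_h

    # -- internals ---------------------------------------------------------

    def _alternatives(self, interval_h: float):
        periods = [float(T) for T in np.atleast_1d(np.asarray(self.period_set, float))]
        if not periods or any(T <= 0 for T in periods):
            raise ValidationError(f"period_set must be non-empty positive, got {periods}")
        step = float(self.phase_step_h) if self.phase_step_h is not None else interval_h
        if step <= 0 or not np.isfinite(step):
            raise ValidationError(f"phase_step_h={step} must be positive")
        alts = []
        for T in periods:
            k = T / step
            if abs(k - round(k)) > 1e-9:
                raise ValidationError(
                    f"phase_step_h={step} does not divide period {T}"
                )
            for phase in np.arange(int(round(k))) * step:
                alts.append((T, float(phase)))
        return alts, step

    def fit(self, X, times_h):
        """Run the test on every row of ``X`` sampled at ``times_h``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if isinstance(times_h, TimeGrid):
            grid = times_h
            col_times = grid.column_times_h
            interval = grid.interval_h
        else:
            col_times = np.asarray(times_h, dtype=float)
            diffs = np.diff(np.unique(np.round(col_times, 9)))
            interval = float(diffs.min()) if diffs.size else float("nan")
        if X.shape[1] != col_times.size:
            raise ValidationError(
                f"X has {X.shape[1]} columns but {col_times.size} column times given"
            )
        n_series, n_cols = X.shape
        alts, step = self._alternatives(interval)
        n_alt = len(alts)
        logger.info(
            "JTK-style test: %d series x %d columns; %d (period, phase) "
            "alternatives (full-cycle phase grid, step %g h, two-sided exact "
            "tails, Bonferroni x%d)",
            n_series, n_cols, n_alt, step, n_alt,
        )

        templates = [reference_template(col_times, T, phase) for T, phase in alts]
        nulls = [exact_null(t.tie_signature) for t in templates]
        weights = [pair_sign_matrix(t) for t in templates]

        S = np.empty((n_series, n_alt), dtype=np.int64)
        chunk = max(1, _CHUNK_CELLS // max(1, n_cols * n_cols))
        for lo in range(0, n_series, chunk):
            hi = min(lo + chunk, n_series)
            d = np.sign(X[lo:hi, None, :] - X[lo:hi, :, None]).astype(np.int8)
            for a, w in enumerate(weights):
                s = np.tensordot(d, w, axes=([1, 2], [0, 1]))
                S[lo:hi, a] = s // 2
        P = np.column_stack(
            [nulls[a].sf_abs(S[:, a]) for a in range(n_alt)]
        )

        p_raw = P.min(axis=1)
        # among minimal-p alternatives prefer the largest S (positive template)
        s_masked = np.where(P == p_raw[:, None], S, np.iinfo(np.int64).min)
        best = np.argmax(s_masked, axis=1)
        rows = np.arange(n_series)
        best_period = np.array([alts[a][0] for a in best])
        best_phase = np.array([alts[a][1] for a in best])
        flip = S[rows, best] < 0
        best_phase = np.where(
            flip, (best_phase + best_period / 2.0) % best_period, best_phase
        )
        p_adj = np.minimum(1.0, p_raw * n_alt)
        q_bh = bh_adjust(p_adj)

        constant = np.ptp(X, axis=1) == 0
        best_phase = np.where(constant, np.nan, best_phase)

        # cosinor refinement at each series' best period
        mesor = np.empty(n_series)
        amplitude = np.empty(n_series)
        fold = np.empty(n_series)
        r2 = np.empty(n_series)
        for T in np.unique(best_period):
            sel = best_period == T
            cos = Cosinor(period_h=float(T)).fit(X[sel], col_times)
            mesor[sel] = cos.mesor_
            amplitude[sel] = cos.amplitude_
            fold[sel] = cos.fold_change_
            r2[sel] = cos.r_squared_

        self.n_features_in_ = n_cols
        self.n_alternatives_ = n_alt
        self.alternatives_ = alts
        self.S_ = S
        self.p_raw_ = p_raw
        self.p_adj_ = p_adj
        self.q_bh_ = q_bh
        self.best_period_h_ = best_period
        self.best_phase_h_ = best_phase
        self.results_ = pd.DataFrame(
            {
                "series_id": [f"series_{i:05d}" for i in range(n_series)],
                "p_raw": p_raw,
                "p_adj": p_adj,
                "q_bh": q_bh,
                "best_period_h": best_period,
                "best_phase_h": best_phase,
                "mesor": mesor,
                "amplitude": amplitude,
                "fold_change": fold,
                "r_squared": r2,
            }
        )
        return self

    def fit_dataset(self, dataset: Dataset):
        """Convenience: fit on a :class:`Dataset`, keeping its series ids."""
        self.fit(dataset.values, dataset.grid)
        self.results_["series_id"] = dataset.truth["series_id"].to_numpy()
        return self

    def predict(self, threshold: float = 0.05, which_p: str = "p_adj"):
        """Hit flags at a strict threshold on a fitted p-value column."""
        if which_p not in {"p_raw", "p_adj", "q_bh"}:
            raise ValidationError(f"unknown p-value field {which_p!r}")
        return (self.results_[which_p] < threshold).to_numpy()


def jtk_test(series, grid, period_set=(24.0,), phase_step_h=None) -> pd.DataFrame:
    """Functional wrapper: test one series (1-D) or a matrix of series.

    Returns the detector's results table (one row per series).
    """
    X = np.atleast_2d(np.asarray(series, dtype=float))
    det = JTKDetector(period_set=period_set, phase_step_h=phase_step_h)
    det.fit(X, grid)
    return det.results_
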