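"""Synthetic rhythmic/arrhythmic time-series generation with ground truth.

Each rhythmic series is a cosine,

    y(t) = baseline + A * cos(2*pi*(t - phase) / period) + eps,

with period and amplitude drawn uniformly from user ranges, phase uniform
over the whole cycle, and i.i.d. Gaussian noise ``eps ~ N(0, noise_sd^2)``
per (timepoint, replicate) cell.  Arrhythmic series are baseline plus noise
only.  A single seeded generator stream per dataset is consumed in a fixed
order (truth first, then noise, then outliers), so a config plus seed fully
determines the output bit-for-bit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dataset import Dataset, series_ids
from .errors import ValidationError
from .grid import TimeGrid, build_time_grid

logger = logging.getLogger(__name__)

__all__ = [
    "build_time_grid",
    "sample_ground_truth",
    "synthesize_dataset",
    "inject_outliers",
]


def sample_ground_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-series truth: rhythmic flags and rhythm parameters.

    Exactly ``round(frac_rhythmic * n_series)`` series are flagged rhythmic
    (a seeded random subset; the count is exact, never stochastic).  Rhythmic
    series draw period ~ U[period_min_h, period_max_h], amplitude ~
    U[amp_min, amp_max] (sign included) and phase ~ U[0, period).
    """
    n = config.n_series
    n_rhythmic = int(np.rint(config.frac_rhythmic * n))
    flags = np.zeros(n, dtype=bool)
    if n_rhythmic > 0:
        flags[rng.choice(n, size=n_rhythmic, replace=False)] = True

    period = np.full(n, np.nan)
    phase = np.full(n, np.nan)
    amplitude = np.full(n, np.nan)
    if n_rhythmic > 0:
        period[flags] = rng.uniform(config.period_min_h, config.period_max_h, n_rhythmic)
        amplitude[flags] = rng.uniform(config.amp_min, config.amp_max, n_rhythmic)
        phase[flags] = rng.uniform(0.0, period[flags])

    return pd.DataFrame(
        {
            "series_id": series_ids(n),
            "is_rhythmic": pd.array(flags, dtype="boolean"),
            "true_period_h": period,
            "true_phase_h": phase,
            "true_amplitude": amplitude,
        }
    )


def _cosine_matrix(truth: pd.DataFrame, column_times_h: np.ndarray) -> np.ndarray:
    """Noise-free signal matrix implied by a truth table."""
    n = len(truth)
    signal = np.zeros((n, column_times_h.size))
    mask = truth["is_rhythmic"].fillna(False).to_numpy(dtype=bool)
    if mask.any():
        T = truth.loc[mask, "true_period_h"].to_numpy()[:, None]
        phi = truth.loc[mask, "true_phase_h"].to_numpy()[:, None]
        A = truth.loc[mask, "true_amplitude"].to_numpy()[:, None]
        signal[mask] = A * np.cos(2.0 * np.pi * (column_times_h[None, :] - phi) / T)
    return signal


def synthesize_dataset(config: SimulationConfig) -> Dataset:
    """Generate a full :class:`Dataset` from a :class:`SimulationConfig`."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = build_time_grid(config.duration_h, config.interval_h, config.replicates)
    truth = sample_ground_truth(config, rng)
    values = config.baseline + _cosine_matrix(truth, grid.column_times_h)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    ds = Dataset(
        grid=grid,
        values=values,
        truth=truth,
        provenance=[
            f"synthesize_dataset: duration_h={config.duration_h}, "
            f"interval_h={config.interval_h}, replicates={config.replicates}, "
            f"n_series={config.n_series}, frac_rhythmic={config.frac_rhythmic}, "
            f"noise_sd={config.noise_sd}, seed={config.seed}"
        ],
    )
    if config.outliers_enabled:
        ds = inject_outliers(
            ds,
            config.outlier_rate,
            config.outlier_magnitude,
            rng,
            noise_sd=config.noise_sd,
        )
    return ds


def inject_outliers(
    dataset: Dataset,
    outlier_rate: float,
    outlier_magnitude: float,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> Dataset:
    """Add symmetric spikes of ``outlier_magnitude * noise_sd`` to random cells.

    Each cell is independently hit with probability ``outlier_rate``; the
    spike sign is equiprobable.  The altered-cell count is recorded in the
    provenance.
    """
    if not 0.0 <= outlier_rate <= 1.0:
        raise ValidationError(f"outlier_rate={outlier_rate} not in [0, 1]")
    if outlier_magnitude < 0:
        raise ValidationError(f"outlier_magnitude={outlier_magnitude} must be >= 0")
    shape = dataset.values.shape
    mask = rng.random(shape) < outlier_rate
    signs = np.where(rng.random(shape) < 0.5, -1.0, 1.0)
    values = dataset.values + mask * signs * outlier_magnitude * noise_sd
    n_hit = int(mask.sum())
    logger.info("inject_outliers altered %d of %d cells", n_hit, mask.size)
    return dataset.evolved(
        dataset.grid,
        values,
        f"inject_outliers: rate={outlier_rate}, magnitude={outlier_magnitude}, "
        f"noise_sd={noise_sd}, cells_altered={n_hit}",
    )
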