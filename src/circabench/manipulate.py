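"""Dataset manipulations for design studies — including deliberately bad ones.

``duplicate_concatenate`` tiles a dataset along the time axis to fake a
longer experiment.  This destroys the independence of samples that every
rhythmicity test assumes and is provided purely to *measure* the resulting
false-positive inflation; applying it to real data before testing is
malpractice, and the operation says so at INFO level.  ``downsample`` and
``truncate`` derive sparser and shorter designs from a dense run, as used
when studying sampling-density and duration trade-offs.

All manipulations preserve the ground truth and the number of series; only
the grid and the value matrix change, and every application is recorded in
the dataset provenance.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import Dataset
from .errors import ValidationError
from .grid import TimeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "duplicate_concatenate",
    "downsample",
    "truncate",
    "DuplicateConcatenate",
    "Downsample",
    "Truncate",
]


def duplicate_concatenate(dataset: Dataset, total_copies: int) -> Dataset:
    """Tile the matrix ``total_copies`` times along time (copy c spans
    ``[c*duration, (c+1)*duration)``).  ``total_copies=2`` is the "first
    concatenation"."""
    if int(total_copies) != total_copies or total_copies < 1:
        raise ValidationError(f"total_copies={total_copies} must be a positive integer")
    total_copies = int(total_copies)
    if total_copies == 1:
        return dataset
    grid = dataset.grid
    duration = grid.duration_h
    times = np.concatenate([grid.times_h + c * duration for c in range(total_copies)])
    new_grid = TimeGrid(times_h=times, replicates=grid.replicates)
    values = np.tile(dataset.values, (1, total_copies))
    logger.info(
        "duplicate_concatenate: MALPRACTICE SIMULATION - tiling %g h of data "
        "to %d total copies; samples are no longer independent",
        duration, total_copies,
    )
    return dataset.evolved(
        new_grid,
        values,
        f"duplicate_concatenate: total_copies={total_copies} "
        f"(concatenation level {total_copies - 1})",
    )


def downsample(dataset: Dataset, keep_every: int) -> Dataset:
    """Keep every ``keep_every``-th timepoint (all its replicates)."""
    if int(keep_every) != keep_every or keep_every < 1:
        raise ValidationError(f"keep_every={keep_every} must be a positive integer")
    keep_every = int(keep_every)
    grid = dataset.grid
    if keep_every > grid.n_timepoints:
        raise ValidationError(
            f"keep_every={keep_every} exceeds the {grid.n_timepoints} timepoints"
        )
    if keep_every == 1:
        return dataset
    keep_t = np.arange(0, grid.n_timepoints, keep_every)
    col_mask = np.zeros(grid.n_timepoints, dtype=bool)
    col_mask[keep_t] = True
    col_mask = np.repeat(col_mask, grid.replicates)
    new_grid = TimeGrid(times_h=grid.times_h[keep_t], replicates=grid.replicates)
    return dataset.evolved(
        new_grid,
        dataset.values[:, col_mask],
        f"downsample: keep_every={keep_every} "
        f"(interval {grid.interval_h} h -> {new_grid.interval_h} h)",
    )


def truncate(dataset: Dataset, new_duration_h: float) -> Dataset:
    """Keep columns with time < ``new_duration_h`` (must be a whole number
    of intervals and at most the current duration)."""
    grid = dataset.grid
    if new_duration_h > grid.duration_h + 1e-9:
        raise ValidationError(
            f"new_duration_h={new_duration_h} exceeds the current duration "
            f"{grid.duration_h}"
        )
    ratio = new_duration_h / grid.interval_h
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValidationError(
            f"new_duration_h={new_duration_h} is not a positive multiple of "
            f"the interval {grid.interval_h}"
        )
    keep_t = grid.times_h < new_duration_h - 1e-9
    if keep_t.all():
        return dataset
    col_mask = np.repeat(keep_t, grid.replicates)
    new_grid = TimeGrid(times_h=grid.times_h[keep_t], replicates=grid.replicates)
    return dataset.evolved(
        new_grid,
        dataset.values[:, col_mask],
        f"truncate: new_duration_h={new_duration_h}",
    )


class _DatasetTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer base: fit is a no-op, transform maps Dataset -> Dataset."""

    def fit(self, X: Dataset, y=None):
        return self


class DuplicateConcatenate(_DatasetTransformer):
    def __init__(self, total_copies: int = 2):
        self.total_copies = total_copies

    def transform(self, X: Dataset) -> Dataset:
        return duplicate_concatenate(X, self.total_copies)


class Downsample(_DatasetTransformer):
    def __init__(self, keep_every: int = 2):
        self.keep_every = keep_every

    def transform(self, X: Dataset) -> Dataset:
        return downsample(X, self.keep_every)


class Truncate(_DatasetTransformer):
    def __init__(self, new_duration_h: float = 24.0):
        self.new_duration_h = new_duration_h

    def transform(self, X: Dataset) -> Dataset:
        return truncate(X, self.new_duration_h)
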