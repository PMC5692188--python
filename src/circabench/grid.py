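"""Sampling-time grids for simulated time-course experiments.

A :class:`TimeGrid` describes when samples were taken and how many replicates
exist per timepoint.  Times follow a half-open convention ``[0, duration)``:
a 48 h experiment sampled every 2 h has 24 timepoints, T00 through T46.  This
makes "every other timepoint of 48 h @ 2 h" exactly the 48 h @ 4 h grid, and
"the first half" exactly the 24 h @ 4 h grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_TIME_TOL = 1e-9


def format_time_label(t_h: float, replicate: int) -> str:
    """Column label for a (time, replicate) pair, e.g. ``T04_r1``.

    Integral hours are zero-padded to two digits; fractional hours keep
    their decimal representation.
    """
    if abs(t_h - round(t_h)) < _TIME_TOL:
        stamp = f"{int(round(t_h)):02d}"
    else:
        stamp = f"{t_h:g}"
    return f"T{stamp}_r{replicate}"


@dataclass(frozen=True)
class TimeGrid:
    """Evenly spaced sampling times with a fixed replicate count.

    Parameters
    ----------
    times_h : ndarray
        Strictly increasing, evenly spaced sampling times in hours.
    replicates : int
        Number of replicate columns per timepoint.
    """

    times_h: np.ndarray
    replicates: int = 1
    column_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times_h, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValidationError("times_h must be a non-empty 1-D sequence")
        if self.replicates < 1:
            raise ValidationError(f"replicates must be >= 1, got {self.replicates}")
        diffs = np.diff(times)
        if times.size > 1:
            if np.any(diffs <= 0):
                raise ValidationError("times_h must be strictly increasing")
            if np.any(np.abs(diffs - diffs[0]) > _TIME_TOL * max(1.0, times[-1])):
                raise ValidationError("times_h must be evenly spaced")
        object.__setattr__(self, "times_h", times)
        labels = tuple(
            format_time_label(t, r + 1)
            for t in times
            for r in range(self.replicates)
        )
        object.__setattr__(self, "column_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.times_h.size

    @property
    def n_columns(self) -> int:
        return self.times_h.size * self.replicates

    @property
    def interval_h(self) -> float:
        if self.times_h.size < 2:
            return float("nan")
        return float(self.times_h[1] - self.times_h[0])

    @property
    def duration_h(self) -> float:
        """Half-open duration: last time plus one interval."""
        if self.times_h.size < 2:
            return float(self.times_h[0])
        return float(self.times_h[-1] + self.interval_h)

    @property
    def column_times_h(self) -> np.ndarray:
        """Time of every column, replicates expanded in order."""
        return np.repeat(self.times_h, self.replicates)


def build_time_grid(duration_h: float, interval_h: float, replicates: int = 1) -> TimeGrid:
    """Build the grid ``{0, interval, ..., duration - interval}``.

    ``duration_h`` must be a whole multiple of ``interval_h``.
    """
    if duration_h <= 0 or interval_h <= 0:
        raise ValidationError(
            f"duration_h and interval_h must be positive, got "
            f"duration_h={duration_h}, interval_h={interval_h}"
        )
    ratio = duration_h / interval_h
    n = int(round(ratio))
    if abs(ratio - n) > _TIME_TOL or n < 1:
        raise ValidationError(
            f"duration_h={duration_h} is not an integer multiple of "
            f"interval_h={interval_h}"
        )
    times = np.arange(n) * float(interval_h)
    return TimeGrid(times_h=times, replicates=int(replicates))
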