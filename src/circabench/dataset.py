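"""The in-memory container tying values, sampling grid and ground truth.

Ground truth is a pandas DataFrame with one row per series and columns
``series_id, is_rhythmic, true_period_h, true_phase_h, true_amplitude``.
Arrhythmic series carry NaN ("not applicable") truth parameters, never 0,
so they cannot silently enter a numeric summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import TimeGrid

TRUTH_COLUMNS = (
    "series_id",
    "is_rhythmic",
    "true_period_h",
    "true_phase_h",
    "true_amplitude",
)


def series_ids(n: int) -> pd.Index:
    """Stable zero-padded identifiers series_00000, series_00001, ..."""
    return pd.Index([f"series_{i:05d}" for i in range(n)], name="series_id")


def empty_truth(n: int) -> pd.DataFrame:
    """Truth table for externally supplied data: no ground truth known."""
    return pd.DataFrame(
        {
            "series_id": series_ids(n),
            "is_rhythmic": pd.array([pd.NA] * n, dtype="boolean"),
            "true_period_h": np.nan,
            "true_phase_h": np.nan,
            "true_amplitude": np.nan,
        }
    )


def validate_truth(truth: pd.DataFrame) -> None:
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ValidationError(f"ground-truth table missing columns {missing}")
    if truth["series_id"].duplicated().any():
        raise ValidationError("ground-truth series_id values must be unique")


@dataclass
class Dataset:
    """Value matrix plus its :class:`TimeGrid` and per-series ground truth.

    ``values`` has shape ``(n_series, grid.n_columns)``; row order matches
    the truth table.  ``provenance`` is an append-only history of the
    operations that produced the dataset.
    """

    grid: TimeGrid
    values: np.ndarray
    truth: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape[1] != self.grid.n_columns:
            raise ValidationError(
                f"values has {self.values.shape[1]} columns but the grid "
                f"defines {self.grid.n_columns}"
            )
        validate_truth(self.truth)
        if len(self.truth) != self.values.shape[0]:
            raise ValidationError(
                f"truth has {len(self.truth)} rows but values has "
                f"{self.values.shape[0]} series"
            )

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    def evolved(self, grid: TimeGrid, values: np.ndarray, entry: str) -> "Dataset":
        """New dataset sharing this one's truth, with a provenance entry."""
        return Dataset(
            grid=grid,
            values=values,
            truth=self.truth.copy(),
            provenance=[*self.provenance, entry],
        )

    def to_frame(self) -> pd.DataFrame:
        """Truth columns followed by one value column per (time, replicate)."""
        out = self.truth.reset_index(drop=True).copy()
        vals = pd.DataFrame(self.values, columns=list(self.grid.column_labels))
        return pd.concat([out, vals], axis=1)
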