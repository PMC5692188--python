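"""CSV dialects and run manifests.

Dataset files carry five ground-truth columns (``series_id, is_rhythmic,
true_period, true_phase, true_amplitude``) followed by one value column per
(time, replicate) pair labeled ``T<HH>_r<k>``.  Time labels are absolute
hours, so a duplicated-and-concatenated dataset is visible in the file
(columns continue T48, T50, ...).  Unknown truth fields are written "NA".
Files without the truth columns are accepted as external data with an
empty truth table.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import Dataset, empty_truth, validate_truth
from .errors import ValidationError
from .grid import TimeGrid

_LABEL_RE = re.compile(r"^T(\d+(?:\.\d+)?)_r(\d+)$")

_TRUTH_FILE_COLUMNS = {
    "series_id": "series_id",
    "is_rhythmic": "is_rhythmic",
    "true_period": "true_period_h",
    "true_phase": "true_phase_h",
    "true_amplitude": "true_amplitude",
}


def write_dataset_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the ground-truth CSV dialect (>=10 sig. digits)."""
    frame = dataset.to_frame().rename(
        columns={v: k for k, v in _TRUTH_FILE_COLUMNS.items()}
    )
    rhythm = frame["is_rhythmic"]
    frame["is_rhythmic"] = rhythm.map({True: 1, False: 0}).astype("Int64")
    frame.to_csv(path, index=False, na_rep="NA", float_format="%.12g")


def _parse_labels(labels: list[str]) -> TimeGrid:
    times, reps = [], []
    for j, lab in enumerate(labels):
        m = _LABEL_RE.match(lab)
        if not m:
            raise ValidationError(
                f"malformed column label {lab!r} at value column {j + 1}"
            )
        times.append(float(m.group(1)))
        reps.append(int(m.group(2)))
    times = np.asarray(times)
    reps = np.asarray(reps)
    uniq_times = np.unique(times)
    if np.any(np.diff(uniq_times) <= 0):  # np.unique sorts; guard anyway
        raise ValidationError("column times are not strictly increasing")
    n_rep = int(reps.max())
    expected_times = np.repeat(uniq_times, n_rep)
    expected_reps = np.tile(np.arange(1, n_rep + 1), uniq_times.size)
    if times.size != expected_times.size or np.any(times != expected_times) or np.any(
        reps != expected_reps
    ):
        raise ValidationError(
            "value columns must be ordered by increasing time with replicates "
            "r1..rk per timepoint; found a shuffled or ragged layout"
        )
    return TimeGrid(times_h=uniq_times, replicates=n_rep)


def read_dataset_csv(path: str | Path) -> Dataset:
    """Read a dataset CSV, reconstructing the grid from the column labels."""
    raw = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    cols = list(raw.columns)
    has_truth = cols[: len(_TRUTH_FILE_COLUMNS)] == list(_TRUTH_FILE_COLUMNS)
    value_cols = cols[len(_TRUTH_FILE_COLUMNS):] if has_truth else cols
    if not value_cols:
        raise ValidationError(f"{path}: no value columns found")
    grid = _parse_labels(value_cols)
    values = np.empty((len(raw), len(value_cols)))
    for j, c in enumerate(value_cols):
        col = pd.to_numeric(raw[c], errors="coerce")
        bad = col.isna() & raw[c].notna() if raw[c].dtype == object else col.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric cell at row {i + 2}, column {c!r}"
            )
        values[:, j] = col.to_numpy()
    if has_truth:
        truth = raw[list(_TRUTH_FILE_COLUMNS)].rename(columns=_TRUTH_FILE_COLUMNS)
        truth["is_rhythmic"] = (
            pd.to_numeric(truth["is_rhythmic"], errors="coerce")
            .map({1: True, 0: False})
            .astype("boolean")
        )
        for c in ("true_period_h", "true_phase_h", "true_amplitude"):
            truth[c] = pd.to_numeric(truth[c], errors="coerce")
        validate_truth(truth)
        provenance = [f"read_dataset_csv: {path}"]
    else:
        truth = empty_truth(len(raw))
        provenance = [f"read_dataset_csv: {path} (external, no ground truth)"]
    return Dataset(grid=grid, values=values, truth=truth, provenance=provenance)


def write_results_csv(results: pd.DataFrame, path: str | Path) -> None:
    """Write a detection-results table, NaN rendered as NA."""
    out = results.rename(
        columns={
            "best_period_h": "best_period",
            "best_phase_h": "best_phase",
        }
    )
    out.to_csv(path, index=False, na_rep="NA", float_format="%.12g")


@dataclass
class RunManifest:
    """Everything needed to regenerate an output file bit-identically."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    operations: list[str] = field(default_factory=list)
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")
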