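"""Simulation configuration: every user-settable generator option.

Defaults describe a generic bulk-transcriptomics circadian time course:
a 48 h collection sampled every 2 h without replication, 1000 features of
which half are rhythmic, ~24 h periods, amplitudes of 1-3 expression units
around a mesor of 10, and unit-variance Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

_TIME_TOL = 1e-9


@dataclass
class SimulationConfig:
    """All options of the synthetic-data generator.

    Attributes
    ----------
    duration_h, interval_h : float
        Experiment length and sampling interval, hours.  The duration must
        be a whole multiple of the interval (half-open grid convention).
    n_series, replicates : int
        Number of simulated series (features) and replicates per timepoint.
    frac_rhythmic : float
        Fraction of series carrying a genuine cosine rhythm; the rhythmic
        count is exact (``round(frac_rhythmic * n_series)``), not binomial.
    amp_min, amp_max : float
        Amplitude range (uniform draw).  Negative amplitudes are allowed and
        equivalent to a half-period phase shift; the signed draw is stored.
    period_min_h, period_max_h : float
        Period range in hours (uniform draw).
    baseline : float
        Mesor (midline) common to all series, arbitrary expression units.
    noise_sd : float
        Standard deviation of the i.i.d. Gaussian noise added to every cell.
    outliers_enabled, outlier_rate, outlier_magnitude :
        Optional symmetric additive spikes of ``outlier_magnitude * noise_sd``
        applied independently per cell with probability ``outlier_rate``.
    seed : int
        Seed of the single generator stream used for truth then noise.
    """

    duration_h: float = 48.0
    interval_h: float = 2.0
    n_series: int = 1000
    replicates: int = 1
    frac_rhythmic: float = 0.5
    amp_min: float = 1.0
    amp_max: float = 3.0
    period_min_h: float = 24.0
    period_max_h: float = 24.0
    baseline: float = 10.0
    noise_sd: float = 1.0
    outliers_enabled: bool = False
    outlier_rate: float = 0.01
    outlier_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_h <= 0 or self.interval_h <= 0:
            raise ValidationError(
                f"duration_h={self.duration_h} and interval_h={self.interval_h} "
                "must both be positive"
            )
        ratio = self.duration_h / self.interval_h
        if abs(ratio - round(ratio)) > _TIME_TOL:
            raise ValidationError(
                f"duration_h={self.duration_h} is not an integer multiple of "
                f"interval_h={self.interval_h}"
            )
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise ValidationError(f"frac_rhythmic={self.frac_rhythmic} not in [0, 1]")
        if self.replicates < 1:
            raise ValidationError(f"replicates={self.replicates} must be >= 1")
        if self.n_series < 1:
            raise ValidationError(f"n_series={self.n_series} must be >= 1")
        if self.amp_min > self.amp_max:
            raise ValidationError(
                f"amp_min={self.amp_min} exceeds amp_max={self.amp_max}"
            )
        if not 0 < self.period_min_h <= self.period_max_h:
            raise ValidationError(
                f"need 0 < period_min_h <= period_max_h, got "
                f"({self.period_min_h}, {self.period_max_h})"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd={self.noise_sd} must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValidationError(f"outlier_rate={self.outlier_rate} not in [0, 1]")
        if self.outlier_magnitude < 0:
            raise ValidationError(
                f"outlier_magnitude={self.outlier_magnitude} must be >= 0"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
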