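"""Core containers for genus-level abundance time series.

A :class:`GenusTimeSeriesTable` holds one body site's taxa-by-day abundance
matrix together with taxon labels and integer day indices.  All downstream
stages (prevalence filtering, imputation, normalization, the lagged
regression itself) consume and produce these tables or the derived
:class:`ProcessedSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TableValidationError(ValueError):
    """Raised when an abundance table violates its structural invariants."""


@dataclass
class GenusTimeSeriesTable:
    """Taxa x timepoints abundance matrix for one body site.

    Parameters
    ----------
    site_label : str
        Free-text label, e.g. ``"gut"``.
    taxa : list of str
        Ordered genus names; must be unique.
    days : numpy.ndarray of int
        Strictly increasing day indices, one per column.
    values : numpy.ndarray
        Non-negative abundances, shape ``(len(taxa), len(days))``.
    signed : bool
        False for raw/relative abundance tables (values must be >= 0);
        True for derived tables (standardized or differenced series) where
        negative values are meaningful.
    """

    site_label: str
    taxa: list[str]
    days: np.ndarray
    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise TableValidationError(f"duplicate taxon names: {dupes}")
        if self.days.ndim != 1 or np.any(np.diff(self.days) <= 0):
            raise TableValidationError("day indices must be strictly increasing")
        if self.values.shape != (len(self.taxa), len(self.days)):
            raise TableValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.taxa)} taxa, {len(self.days)} days)"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise TableValidationError(
                f"non-finite value for taxon {self.taxa[bad[0]]!r} "
                f"on day {self.days[bad[1]]}"
            )
        if not self.signed and np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise TableValidationError(
                f"negative abundance for taxon {self.taxa[bad[0]]!r} "
                f"on day {self.days[bad[1]]}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_days(self) -> int:
        return len(self.days)

    def has_gaps(self) -> bool:
        """True when day indices are not consecutive integers."""
        return bool(np.any(np.diff(self.days) != 1))

    def copy_with(self, **kwargs) -> "GenusTimeSeriesTable":
        args = dict(
            site_label=self.site_label,
            taxa=list(self.taxa),
            days=self.days.copy(),
            values=self.values.copy(),
            signed=self.signed,
        )
        args.update(kwargs)
        return GenusTimeSeriesTable(**args)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.days)


@dataclass
class ProcessedSeries:
    """Standardized, first-differenced relative abundances ready for the VAR.

    ``matrix`` has one row per retained taxon and ``T - 1`` columns (one per
    day-to-day transition).  ``provenance`` records the processing steps in
    the order applied, so the transformation history is auditable.
    """

    site_label: str
    taxa: list[str]
    matrix: np.ndarray
    imputation_seed: int | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.taxa):
            raise TableValidationError(
                "processed matrix row count does not match taxa"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise TableValidationError("processed matrix has non-finite values")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]
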