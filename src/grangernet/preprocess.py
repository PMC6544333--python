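"""Raw abundance table -> model-ready matrix.

The pipeline applied to each body site, in order:

1. drop genera detected on fewer than 90% of days (prevalence filter);
2. replace remaining zeros with a uniform draw on ``[1e-5 m, 1e-3 m]``
   where ``m`` is that genus's mean abundance, treating absences of an
   otherwise-prevalent genus as sub-detection-threshold presence;
3. convert each day's column to relative abundances (sum to one);
4. standardize each genus by its own mean and standard deviation, putting
   genera spanning orders of magnitude on a common SD scale;
5. first-difference to remove stochastic and deterministic trends.

Coefficients fitted downstream are therefore in units of "SD change in the
response per SD change in the predictor", on the differenced scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import RunConfig
from .tables import GenusTimeSeriesTable, ProcessedSeries


class PreprocessError(ValueError):
    pass


def filter_prevalent(table: GenusTimeSeriesTable,
                     threshold: float) -> GenusTimeSeriesTable:
    """Keep taxa with nonzero abundance on at least ``threshold`` of days.

    The boundary is inclusive: a taxon present on exactly
    ``threshold * n_days`` days is retained.
    """
    if not (0 < threshold <= 1):
        raise PreprocessError("threshold must be in (0, 1]")
    prevalence = (table.values > 0).mean(axis=1)
    # small epsilon guards against float representation of e.g. 90/100 < 0.9
    keep = prevalence >= threshold - 1e-12
    if not keep.any():
        raise PreprocessError(
            f"no taxa reach prevalence {threshold:.0%} in site "
            f"{table.site_label!r}; lower the threshold"
        )
    taxa = [t for t, k in zip(table.taxa, keep) if k]
    return table.copy_with(taxa=taxa, values=table.values[keep])


def impute_absences(table: GenusTimeSeriesTable, lo: float, hi: float,
                    seed: int) -> GenusTimeSeriesTable:
    """Replace zeros with uniform draws on ``[lo*m, hi*m]``, ``m`` the taxon mean.

    Nonzero entries are untouched.  Draws are independent per zero entry and
    reproducible under ``seed``.
    """
    if not lo < hi:
        raise PreprocessError("require lo < hi")
    means = table.values.mean(axis=1)
    if np.any(means <= 0):
        bad = table.taxa[int(np.argmin(means > 0))]
        raise PreprocessError(
            f"taxon {bad!r} has an all-zero series; mean undefined"
        )
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    zero = values == 0
    for i in range(table.n_taxa):
        n0 = int(zero[i].sum())
        if n0:
            values[i, zero[i]] = rng.uniform(lo * means[i], hi * means[i],
                                             size=n0)
    return table.copy_with(values=values)


def to_relative(table: GenusTimeSeriesTable) -> GenusTimeSeriesTable:
    """Close each day's column to relative abundances summing to one."""
    sums = table.values.sum(axis=0)
    if np.any(sums <= 0):
        day = table.days[int(np.argmin(sums > 0))]
        raise PreprocessError(f"day {day} has zero total abundance")
    return table.copy_with(values=table.values / sums)


def standardize(table: GenusTimeSeriesTable) -> GenusTimeSeriesTable:
    """Center and scale each taxon's series to mean 0, sample SD 1."""
    means = table.values.mean(axis=1, keepdims=True)
    sds = table.values.std(axis=1, ddof=1, keepdims=True)
    if np.any(sds <= 0):
        bad = table.taxa[int(np.argmin(sds[:, 0] > 0))]
        raise PreprocessError(f"taxon {bad!r} has a constant series")
    centered = (table.values - means) / sds
    return table.copy_with(values=centered, signed=True)


def first_difference(table: GenusTimeSeriesTable) -> GenusTimeSeriesTable:
    """Successive differences along time; output has one fewer column."""
    if table.n_days < 2:
        raise PreprocessError("need at least 2 days to difference")
    return table.copy_with(days=table.days[1:],
                           values=np.diff(table.values, axis=1),
                           signed=True)


def preprocess(table: GenusTimeSeriesTable,
               config: RunConfig) -> ProcessedSeries:
    """Full preprocessing chain; records provenance of every step."""
    if table.has_gaps():
        warnings.warn(
            f"site {table.site_label!r} has non-consecutive day indices; "
            "the lag operator treats columns as consecutive observations",
            stacklevel=2,
        )
    seed = config.seed_for("impute")
    provenance = []
    t = filter_prevalent(table, config.prevalence_threshold)
    provenance.append(
        f"filter_prevalent(threshold={config.prevalence_threshold}): "
        f"{table.n_taxa} -> {t.n_taxa} taxa"
    )
    t = impute_absences(t, config.impute_lo, config.impute_hi, seed)
    provenance.append(
        f"impute_absences(lo={config.impute_lo}, hi={config.impute_hi}, "
        f"seed={seed}) on raw counts"
    )
    t = to_relative(t)
    provenance.append("to_relative")
    t = standardize(t)
    provenance.append("standardize(sample sd)")
    t = first_difference(t)
    provenance.append("first_difference")
    return ProcessedSeries(
        site_label=table.site_label,
        taxa=t.taxa,
        matrix=t.values,
        imputation_seed=seed,
        provenance=provenance,
    )
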