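"""Reshuffling null model for the strong-edge network.

Randomly permuting each taxon's processed series over time destroys every
lagged relationship while preserving each series' marginal distribution.
Re-running the full penalized autoregression on the shuffled data and
scoring coefficients against the *actual* data's strong-coefficient
thresholds measures how many "strong" links the pipeline fabricates from
pure noise; ordered taxon pairs that come out strong in both the actual and
the reshuffled run are treated as suspect and removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .edges import (CausalEdge, StrongThresholds, apply_thresholds,
                    extract_edges)
from .tables import ProcessedSeries
from .varlasso import fit_all_responses


@dataclass
class NullReport:
    site_label: str
    n_strong_actual: int
    n_strong_null: int
    n_strong_pairs_actual: int
    n_strong_pairs_null: int
    null_fraction: float | None
    overlapping_pairs: list[tuple[str, str]]
    seed: int
    null_edges: list[CausalEdge] = field(repr=False, default_factory=list)


def reshuffle_table(series: ProcessedSeries, seed: int,
                    mode: str = "per_taxon") -> ProcessedSeries:
    """Permute the processed series over time.

    ``per_taxon`` (default) permutes each taxon's series independently,
    destroying autocorrelation and all cross-lag structure.  ``columns``
    applies one shared permutation of days, preserving same-day
    cross-sectional correlation.
    """
    rng = np.random.default_rng(seed)
    M = series.matrix
    if mode == "per_taxon":
        shuffled = np.vstack([row[rng.permutation(M.shape[1])] for row in M])
    elif mode == "columns":
        shuffled = M[:, rng.permutation(M.shape[1])]
    else:
        raise ValueError(f"unknown reshuffle mode {mode!r}")
    return ProcessedSeries(
        site_label=series.site_label,
        taxa=list(series.taxa),
        matrix=shuffled,
        imputation_seed=series.imputation_seed,
        provenance=series.provenance + [f"reshuffle(mode={mode}, seed={seed})"],
    )


def strong_pairs(edges: list[CausalEdge]) -> set[tuple[str, str]]:
    return {e.pair for e in edges if e.strong}


def null_run(series: ProcessedSeries, config: RunConfig,
             thresholds: StrongThresholds,
             actual_edges: list[CausalEdge],
             seed: int | None = None,
             mode: str = "per_taxon") -> NullReport:
    """Fit the full model on reshuffled data and compare strong sets.

    Strong flags on the null run use the actual-data thresholds, never
    recomputed ones, so both runs answer "how many coefficients exceed the
    real data's strength bar".
    """
    if thresholds is None:
        raise ValueError("need the actual-data strong thresholds")
    if seed is None:
        seed = config.seed_for("reshuffle")
    shuffled = reshuffle_table(series, seed, mode=mode)
    tensor = fit_all_responses(shuffled, config)
    null_edges = apply_thresholds(extract_edges(tensor), thresholds)
    n_actual = sum(e.strong for e in actual_edges)
    n_null = sum(e.strong for e in null_edges)
    pairs_actual = strong_pairs(actual_edges)
    pairs_null = strong_pairs(null_edges)
    return NullReport(
        site_label=series.site_label,
        n_strong_actual=n_actual,
        n_strong_null=n_null,
        n_strong_pairs_actual=len(pairs_actual),
        n_strong_pairs_null=len(pairs_null),
        null_fraction=(n_null / n_actual) if n_actual else None,
        overlapping_pairs=sorted(pairs_actual & pairs_null),
        seed=seed,
        null_edges=null_edges,
    )


def overlap_filter(actual_strong: list[CausalEdge],
                   null_strong: list[CausalEdge]) -> list[CausalEdge]:
    """Drop actual strong edges whose ordered (cause, effect) pair is also
    strong in the null run.  Removal is pair-level: every lag of a shared
    pair goes."""
    null_pairs = strong_pairs(null_strong)
    return [e for e in actual_strong if e.pair not in null_pairs]
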