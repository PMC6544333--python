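"""Correlation network and its contrast with Granger causality.

Pearson correlation on the same processed series used for the causal fit
gives the co-occurrence network a correlation-based analysis would report.
Per timescale, each ordered interspecific pair is cross-classified by its
Pearson status (positive / negative / insignificant) and its Granger status
from the qualitative timescale call, and a chi-square test of independence
on the 3x3 table asks whether the two methods agree more than chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .edges import TimescaleCall
from .tables import ProcessedSeries

CATEGORIES = ("positive", "negative", "insignificant")


@dataclass(frozen=True)
class PairCorrelation:
    taxon_a: str
    taxon_b: str
    r: float
    p_value: float
    significant: bool

    @property
    def sign(self) -> str:
        if not self.significant:
            return "insignificant"
        return "positive" if self.r > 0 else "negative"


@dataclass
class SignContingency:
    site_label: str
    timescale: str
    counts: pd.DataFrame  # rows: Pearson category, cols: Granger category
    chi_square: float | None = None
    dof: int = 4
    p_value: float | None = None


def pearson_network(series: ProcessedSeries,
                    alpha: float = 0.05) -> dict[frozenset,
                                                 PairCorrelation]:
    """Pearson correlation for every unordered taxon pair.

    Two-sided test at ``alpha``, unadjusted for multiplicity (matching the
    per-test false-positive arithmetic of the causal analysis).
    """
    M = series.matrix
    if M.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    sds = M.std(axis=1)
    if np.any(sds == 0):
        bad = series.taxa[int(np.argmin(sds > 0))]
        raise ValueError(f"taxon {bad!r} has a constant series")
    out = {}
    for i, j in combinations(range(series.n_taxa), 2):
        r, p = stats.pearsonr(M[i], M[j])
        a, b = series.taxa[i], series.taxa[j]
        out[frozenset((a, b))] = PairCorrelation(
            taxon_a=a, taxon_b=b, r=float(r), p_value=float(p),
            significant=bool(p < alpha))
    return out


def sign_contingency(pearson: dict[frozenset, PairCorrelation],
                     calls: list[TimescaleCall], timescale: str,
                     taxa: list[str],
                     site_label: str = "") -> SignContingency:
    """3x3 Pearson-vs-Granger sign table over ordered interspecific pairs.

    Pairs whose Granger call in the window is conflicting are excluded;
    pairs with no in-window coefficient count as Granger-insignificant, and
    pairs with a non-significant correlation as Pearson-insignificant.
    """
    if timescale not in ("short", "long"):
        raise ValueError("timescale must be 'short' or 'long'")
    gc_sign = {
        (c.cause, c.effect): (c.short_sign if timescale == "short"
                              else c.long_sign)
        for c in calls
    }
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for cause, effect in permutations(taxa, 2):
        g = gc_sign.get((cause, effect), "none")
        if g == "conflicting":
            continue
        if g == "none":
            g = "insignificant"
        pear = pearson.get(frozenset((cause, effect)))
        p = pear.sign if pear is not None else "insignificant"
        counts.loc[p, g] += 1
    return SignContingency(site_label=site_label, timescale=timescale,
                           counts=counts)


def chi_square_independence(table: SignContingency) -> tuple[float, int,
                                                             float]:
    """Pearson chi-square test of independence on the 3x3 sign table.

    Expected counts come from the margins; cells whose expected count is
    zero (an empty margin) contribute nothing.  Degrees of freedom are fixed
    at 4 for the 3x3 layout.  Warns when any expected count is below 5.
    """
    O = table.counts.to_numpy(dtype=float)
    total = O.sum()
    if total == 0:
        raise ValueError("contingency table has zero grand total")
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    mask = E > 0
    stat = float(((O[mask] - E[mask]) ** 2 / E[mask]).sum())
    if np.any(E[mask] < 5):
        warnings.warn("expected count below 5; chi-square approximation "
                      "may be poor", stacklevel=2)
    dof = 4
    p = float(stats.chi2.sf(stat, dof))
    table.chi_square, table.dof, table.p_value = stat, dof, p
    return stat, dof, p


def causality_vs_correlation_scatter(
        pearson: dict[frozenset, PairCorrelation],
        extremes: dict[tuple[str, str], tuple[float | None, float | None]],
) -> dict:
    """Pair the correlation coefficient with the extreme Granger
    coefficients for every ordered pair significant under both methods.

    Returns the paired records plus the Spearman rank correlation between
    Pearson r and the dominant (largest-magnitude) Granger coefficient.
    """
    records = []
    for (cause, effect), (mx, mn) in sorted(extremes.items()):
        pear = pearson.get(frozenset((cause, effect)))
        if pear is None or not pear.significant or cause == effect:
            continue
        candidates = [v for v in (mx, mn) if v is not None]
        dominant = max(candidates, key=abs)
        records.append({
            "cause": cause, "effect": effect, "pearson_r": pear.r,
            "max_positive_gc": mx, "min_negative_gc": mn,
            "dominant_gc": dominant,
        })
    if len(records) >= 3:
        rho, p = stats.spearmanr([r["pearson_r"] for r in records],
                                 [r["dominant_gc"] for r in records])
        rho, p = float(rho), float(p)
    else:
        rho, p = float("nan"), float("nan")
    return {"records": records, "rank_correlation": rho,
            "rank_correlation_p": p}
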