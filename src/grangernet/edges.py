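"""Causal edges, strong-coefficient selection, and timescale summaries.

A retained (nonzero) tensor entry becomes a :class:`CausalEdge`.  Because
most retained coefficients are small, downstream ecology focuses on the
"strong" subset: within each body site, the top 5th percentile of positive
coefficients and the bottom 5th percentile of negative ones, each sign
thresholded separately.  Lags are further grouped into qualitative
timescales — short (1-5 days) and long (15-20 days) — with ordered pairs
whose in-window coefficients disagree in sign flagged as conflicting and
excluded from qualitative comparisons.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace

import numpy as np

from .varlasso import CoefficientTensor

SignLabel = str  # "positive" | "negative" | "none" | "conflicting"


@dataclass(frozen=True)
class CausalEdge:
    cause: str
    effect: str
    lag: int
    coefficient: float
    strong: bool = False

    def __post_init__(self) -> None:
        if self.coefficient == 0:
            raise ValueError("a causal edge must have a nonzero coefficient")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    @property
    def intraspecific(self) -> bool:
        return self.cause == self.effect

    @property
    def sign(self) -> int:
        return 1 if self.coefficient > 0 else -1

    @property
    def pair(self) -> tuple[str, str]:
        return (self.cause, self.effect)


@dataclass
class StrongThresholds:
    site_label: str
    positive_cut: float | None
    negative_cut: float | None


@dataclass(frozen=True)
class TimescaleCall:
    cause: str
    effect: str
    short_sign: SignLabel
    long_sign: SignLabel

    @property
    def intraspecific(self) -> bool:
        return self.cause == self.effect


def extract_edges(tensor: CoefficientTensor) -> list[CausalEdge]:
    """One edge per nonzero tensor entry, ordered by (effect, cause, lag)."""
    edges = []
    for i, effect in enumerate(tensor.taxa):
        for j, cause in enumerate(tensor.taxa):
            for k in range(tensor.lags):
                b = tensor.B[i, j, k]
                if b != 0:
                    edges.append(CausalEdge(cause=cause, effect=effect,
                                            lag=k + 1, coefficient=float(b)))
    edges.sort(key=lambda e: (e.effect, e.cause, e.lag))
    return edges


def mark_strong(edges: list[CausalEdge], percentile: float = 5.0,
                site_label: str = "") -> tuple[StrongThresholds,
                                               list[CausalEdge]]:
    """Flag the strongest ``percentile``% of each sign's coefficients.

    Positive edges at or above the (100 - percentile)th percentile of the
    positive coefficients, and negative edges at or below the percentile-th
    percentile of the negative ones.  Percentiles use linear interpolation
    between order statistics; ties with the cut are flagged.
    """
    pos = [e.coefficient for e in edges if e.coefficient > 0]
    neg = [e.coefficient for e in edges if e.coefficient < 0]
    pos_cut = float(np.percentile(pos, 100 - percentile)) if pos else None
    neg_cut = float(np.percentile(neg, percentile)) if neg else None
    flagged = []
    for e in edges:
        strong = bool(
            (pos_cut is not None and e.coefficient >= pos_cut)
            if e.coefficient > 0
            else (neg_cut is not None and e.coefficient <= neg_cut)
        )
        flagged.append(replace(e, strong=strong))
    return StrongThresholds(site_label=site_label, positive_cut=pos_cut,
                            negative_cut=neg_cut), flagged


def apply_thresholds(edges: list[CausalEdge],
                     thresholds: StrongThresholds) -> list[CausalEdge]:
    """Flag edges against pre-computed cuts (e.g. the actual-data cuts when
    scoring a reshuffled null run)."""
    out = []
    for e in edges:
        if e.coefficient > 0:
            strong = (thresholds.positive_cut is not None
                      and e.coefficient >= thresholds.positive_cut)
        else:
            strong = (thresholds.negative_cut is not None
                      and e.coefficient <= thresholds.negative_cut)
        out.append(replace(e, strong=strong))
    return out


def _window_sign(signs: set[int]) -> SignLabel:
    if not signs:
        return "none"
    if signs == {1}:
        return "positive"
    if signs == {-1}:
        return "negative"
    return "conflicting"


def classify_timescales(edges: list[CausalEdge],
                        short_range: tuple[int, int] = (1, 5),
                        long_range: tuple[int, int] = (15, 20),
                        ) -> list[TimescaleCall]:
    """Qualitative short/long interaction sign per ordered pair.

    A window's sign is positive or negative when all of the pair's in-window
    coefficients agree, conflicting when they mix, and none when no edge
    falls in the window.  Lags outside both windows are ignored.
    """
    by_pair: dict[tuple[str, str], tuple[set[int], set[int]]] = defaultdict(
        lambda: (set(), set()))
    for e in edges:
        short, long_ = by_pair[e.pair]
        if short_range[0] <= e.lag <= short_range[1]:
            short.add(e.sign)
        if long_range[0] <= e.lag <= long_range[1]:
            long_.add(e.sign)
    calls = [
        TimescaleCall(cause=c, effect=f, short_sign=_window_sign(s),
                      long_sign=_window_sign(l))
        for (c, f), (s, l) in by_pair.items()
    ]
    calls.sort(key=lambda t: (t.effect, t.cause))
    return calls


def timescale_window_summary(edges: list[CausalEdge],
                             short_range: tuple[int, int] = (1, 5),
                             long_range: tuple[int, int] = (15, 20),
                             ) -> dict:
    """Edge counts per qualitative window — short, middle, long — split by
    sign and interaction class.  The middle window is the complement of the
    short and long windows (6-14 days at the defaults)."""
    out = {cls: {w: {"positive": 0, "negative": 0}
                 for w in ("short", "middle", "long")}
           for cls in ("interspecific", "intraspecific")}
    for e in edges:
        if short_range[0] <= e.lag <= short_range[1]:
            window = "short"
        elif long_range[0] <= e.lag <= long_range[1]:
            window = "long"
        else:
            window = "middle"
        cls = "intraspecific" if e.intraspecific else "interspecific"
        out[cls][window]["positive" if e.coefficient > 0 else "negative"] += 1
    return out


def pair_extremes(edges: list[CausalEdge]) -> dict[tuple[str, str],
                                                   tuple[float | None,
                                                         float | None]]:
    """Per ordered pair: (largest positive, most negative) coefficient over
    all lags, or None when that sign is absent."""
    out: dict[tuple[str, str], tuple[float | None, float | None]] = {}
    for e in edges:
        mx, mn = out.get(e.pair, (None, None))
        if e.coefficient > 0:
            mx = e.coefficient if mx is None else max(mx, e.coefficient)
        else:
            mn = e.coefficient if mn is None else min(mn, e.coefficient)
        out[e.pair] = (mx, mn)
    return out


def coefficient_count_summary(edges: list[CausalEdge],
                              scope: str = "all") -> dict:
    """Distribution of per-(predictor, effect) coefficient counts.

    Mirrors a per-pair tally of how many distinct-lag coefficients connect
    each ordered pair, split interspecific/intraspecific, plus the fraction
    of effect taxa with at least one significant predictor of each class.
    """
    pool = _scoped(edges, scope)
    counts: Counter = Counter(e.pair for e in pool)
    inter_hist = Counter(v for (c, f), v in counts.items() if c != f)
    intra_hist = Counter(v for (c, f), v in counts.items() if c == f)
    effects = {e.effect for e in pool}
    with_inter = {e.effect for e in pool if not e.intraspecific}
    with_intra = {e.effect for e in pool if e.intraspecific}
    n_eff = len(effects)
    return {
        "interspecific_histogram": dict(inter_hist),
        "intraspecific_histogram": dict(intra_hist),
        "pair_counts": dict(counts),
        "fraction_with_interspecific": (len(with_inter) / n_eff
                                        if n_eff else float("nan")),
        "fraction_with_intraspecific": (len(with_intra) / n_eff
                                        if n_eff else float("nan")),
    }


def lag_sign_spectrum(edges: list[CausalEdge], L: int,
                      scope: str = "strong") -> dict:
    """Counts of positive/negative coefficients per lag, split inter/intra.

    Returns arrays of length L (index k = lag k+1) for each class and sign,
    plus overall positive/negative totals per class.
    """
    pool = _scoped(edges, scope)
    spec = {
        cls: {"positive": np.zeros(L, dtype=int),
              "negative": np.zeros(L, dtype=int)}
        for cls in ("interspecific", "intraspecific")
    }
    for e in pool:
        cls = "intraspecific" if e.intraspecific else "interspecific"
        sign = "positive" if e.coefficient > 0 else "negative"
        spec[cls][sign][e.lag - 1] += 1
    for cls in spec:
        spec[cls]["total_positive"] = int(spec[cls]["positive"].sum())
        spec[cls]["total_negative"] = int(spec[cls]["negative"].sum())
    return spec


def genus_summary(edges: list[CausalEdge], scope: str = "strong",
                  lag_side: str = "cause") -> dict:
    """Per-genus participation in (by default strong) edges.

    Counts positive/negative interspecific cause- and effect-edges, and the
    mean lag of the genus's interspecific edges and of its intraspecific
    edges.  ``lag_side`` picks which end of an interspecific edge the mean
    lag is attributed to ("cause", the default, or "effect").  A genus
    appears iff it participates in at least one in-scope edge.
    """
    if lag_side not in ("cause", "effect"):
        raise ValueError(f"unknown lag_side {lag_side!r}")
    pool = _scoped(edges, scope)
    out: dict[str, dict] = {}

    def entry(g: str) -> dict:
        return out.setdefault(g, {
            "cause_positive": 0, "cause_negative": 0,
            "effect_positive": 0, "effect_negative": 0,
            "interspecific_lags": [], "intraspecific_lags": [],
        })

    for e in pool:
        if e.intraspecific:
            entry(e.cause)["intraspecific_lags"].append(e.lag)
        else:
            key = "positive" if e.coefficient > 0 else "negative"
            entry(e.cause)[f"cause_{key}"] += 1
            entry(e.effect)[f"effect_{key}"] += 1
            entry(getattr(e, lag_side))["interspecific_lags"].append(e.lag)
    for g, rec in out.items():
        for k in ("interspecific_lags", "intraspecific_lags"):
            lags = rec.pop(k)
            rec[k.replace("_lags", "_mean_lag")] = (
                float(np.mean(lags)) if lags else None)
    return out


def _scoped(edges: list[CausalEdge], scope: str) -> list[CausalEdge]:
    if scope == "all":
        return list(edges)
    if scope == "strong":
        return [e for e in edges if e.strong]
    raise ValueError(f"unknown scope {scope!r}")
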