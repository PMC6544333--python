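"""Cross-body-site conservation of causal interactions.

Two sites are compared on their shared genera only.  An interaction is
quantitatively conserved when both sites carry an edge with the same
(cause, effect, lag) and coefficient sign, and qualitatively conserved when
both carry the same (cause, effect, timescale window, sign) — the looser
criterion that tolerates day-level lag differences.  Intraspecific
(self-)interactions compare by (genus, lag, sign) quantitatively and
(genus, sign) qualitatively.  Conserved fractions use the union of the two
sites' in-scope interactions over shared taxa as denominator (a
Jaccard-style measure), reported separately for interspecific and
intraspecific interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .edges import CausalEdge, TimescaleCall


@dataclass
class ConservationReport:
    site_a: str
    site_b: str
    mode: str  # quantitative | qualitative
    shared_taxa: list[str]
    conserved_interspecific: list[tuple]
    conserved_intraspecific: list[tuple]
    union_interspecific: int
    union_intraspecific: int
    site_counts: dict[str, tuple[int, int]] | None = None
    # per-site (interspecific, intraspecific) in-scope key counts

    def fractions(self, denominator: str = "union"
                  ) -> dict[str, float | None]:
        """Conserved fractions; ``denominator`` is ``union`` (Jaccard-style,
        symmetric) or a site label (that site's own in-scope count)."""
        if denominator == "union":
            denoms = (self.union_interspecific, self.union_intraspecific)
        elif self.site_counts and denominator in self.site_counts:
            denoms = self.site_counts[denominator]
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        return {
            "interspecific": (len(self.conserved_interspecific) / denoms[0]
                              if denoms[0] else None),
            "intraspecific": (len(self.conserved_intraspecific) / denoms[1]
                              if denoms[1] else None),
        }


def shared_taxa(site_taxa: dict[str, list[str]]) -> dict:
    """Set algebra over per-site genus lists.

    Returns the pairwise (and higher-order) intersections plus the
    exclusive Venn-region counts for every combination of sites.
    """
    if len(site_taxa) < 2:
        raise ValueError("need at least 2 sites")
    sets = {s: set(t) for s, t in site_taxa.items()}
    sites = sorted(sets)
    intersections: dict[tuple[str, ...], set[str]] = {}
    for k in range(1, len(sites) + 1):
        for combo in combinations(sites, k):
            inter = set.intersection(*(sets[s] for s in combo))
            intersections[combo] = inter
    venn_counts = {}
    universe = set.union(*sets.values())
    for k in range(1, len(sites) + 1):
        for combo in combinations(sites, k):
            inside = set(combo)
            exclusive = intersections[combo] - set().union(
                *(sets[s] for s in sites if s not in inside), set())
            venn_counts[combo] = len(exclusive)
    return {"intersections": intersections, "venn_counts": venn_counts,
            "union_size": len(universe)}


def _quant_keys(edges: list[CausalEdge], shared: set[str]) -> tuple[set, set]:
    inter, intra = set(), set()
    for e in edges:
        if e.cause in shared and e.effect in shared:
            if e.intraspecific:
                intra.add((e.cause, e.lag, e.sign))
            else:
                inter.add((e.cause, e.effect, e.lag, e.sign))
    return inter, intra


def _qual_keys(calls: list[TimescaleCall],
               shared: set[str]) -> tuple[set, set]:
    inter, intra = set(), set()
    for c in calls:
        if c.cause not in shared or c.effect not in shared:
            continue
        for window, sign in (("short", c.short_sign), ("long", c.long_sign)):
            if sign in ("none", "conflicting"):
                continue
            if c.intraspecific:
                intra.add((c.cause, sign))
            else:
                inter.add((c.cause, c.effect, window, sign))
    return inter, intra


def conserved_edges(site_a: str, site_b: str,
                    edges_a: list[CausalEdge], edges_b: list[CausalEdge],
                    mode: str = "quantitative",
                    calls_a: list[TimescaleCall] | None = None,
                    calls_b: list[TimescaleCall] | None = None,
                    taxa_a: list[str] | None = None,
                    taxa_b: list[str] | None = None) -> ConservationReport:
    """Conservation of interactions between two sites' edge sets.

    ``taxa_a`` / ``taxa_b`` default to the taxa appearing in each edge set;
    pass the sites' full retained-taxa lists for a faithful shared-genus
    restriction.  Qualitative mode requires the timescale calls.
    """
    ta = set(taxa_a) if taxa_a is not None else (
        {e.cause for e in edges_a} | {e.effect for e in edges_a})
    tb = set(taxa_b) if taxa_b is not None else (
        {e.cause for e in edges_b} | {e.effect for e in edges_b})
    shared = ta & tb
    if mode == "quantitative":
        inter_a, intra_a = _quant_keys(edges_a, shared)
        inter_b, intra_b = _quant_keys(edges_b, shared)
    elif mode == "qualitative":
        if calls_a is None or calls_b is None:
            raise ValueError("qualitative mode needs timescale calls")
        inter_a, intra_a = _qual_keys(calls_a, shared)
        inter_b, intra_b = _qual_keys(calls_b, shared)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ConservationReport(
        site_a=site_a, site_b=site_b, mode=mode,
        shared_taxa=sorted(shared),
        conserved_interspecific=sorted(inter_a & inter_b),
        conserved_intraspecific=sorted(intra_a & intra_b),
        union_interspecific=len(inter_a | inter_b),
        union_intraspecific=len(intra_a | intra_b),
        site_counts={site_a: (len(inter_a), len(intra_a)),
                     site_b: (len(inter_b), len(intra_b))},
    )


def conservation_fractions(report: ConservationReport) -> dict:
    return report.fractions()
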