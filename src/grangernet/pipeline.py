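"""End-to-end driver: preprocessing through conservation, per body site.

Stages per site, in order: preprocess -> penalized autoregression ->
edge extraction and strong-coefficient selection -> reshuffling null and
overlap filter -> timescale classification -> Pearson comparison.  When two
or more sites are given, every site pair is additionally compared for
quantitative and qualitative conservation.  All outputs are plain-text TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .config import RunConfig
from .conserve import ConservationReport, conserved_edges
from .correlate import (SignContingency, chi_square_independence,
                        causality_vs_correlation_scatter, pearson_network,
                        sign_contingency)
from .edges import (CausalEdge, StrongThresholds, TimescaleCall,
                    classify_timescales, extract_edges, mark_strong,
                    pair_extremes)
from .nulls import NullReport, null_run, overlap_filter
from .preprocess import preprocess
from .tables import GenusTimeSeriesTable, ProcessedSeries
from .varlasso import CoefficientTensor, fit_all_responses


class StageError(RuntimeError):
    def __init__(self, stage: str, site: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for site {site!r}: {cause}")
        self.stage, self.site = stage, site


@dataclass
class SiteResult:
    site_label: str
    processed: ProcessedSeries
    tensor: CoefficientTensor
    edges: list[CausalEdge]
    thresholds: StrongThresholds
    strong_edges: list[CausalEdge]           # after overlap filtering
    calls: list[TimescaleCall]
    null_report: NullReport
    pearson: dict
    contingencies: dict[str, SignContingency]
    scatter: dict


@dataclass
class PipelineResult:
    config: RunConfig
    sites: dict[str, SiteResult]
    conservation: dict[tuple[str, str, str], ConservationReport]
    log: list[str] = field(default_factory=list)


def _run_stage(stage: str, site: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise StageError(stage, site, exc) from exc


def run_site(table: GenusTimeSeriesTable, config: RunConfig,
             log: list[str] | None = None) -> SiteResult:
    site = table.site_label
    log = log if log is not None else []
    processed = _run_stage("preprocess", site, preprocess, table, config)
    log.append(f"[{site}] preprocess: {processed.n_taxa} taxa, "
               f"{processed.n_timepoints} transitions "
               f"(imputation seed {processed.imputation_seed})")
    tensor = _run_stage("fit", site, fit_all_responses, processed, config)
    log.append(f"[{site}] fit: nonzero fraction "
               f"{tensor.nonzero_fraction():.3f}")
    all_edges = _run_stage("edges", site, extract_edges, tensor)
    thresholds, all_edges = _run_stage(
        "strong", site, mark_strong, all_edges, config.strong_percentile,
        site)
    null_seed = config.seed_for("reshuffle")
    report = _run_stage("null", site, null_run, processed, config,
                        thresholds, all_edges, null_seed)
    strong = [e for e in all_edges if e.strong]
    strong = _run_stage("overlap_filter", site, overlap_filter, strong,
                        report.null_edges)
    log.append(f"[{site}] null(seed {null_seed}): "
               f"{report.n_strong_pairs_null} null strong pairs vs "
               f"{report.n_strong_pairs_actual} actual; "
               f"{len(report.overlapping_pairs)} overlapping removed")
    calls = _run_stage("timescales", site, classify_timescales, strong,
                       config.short_range, config.long_range)
    pearson = _run_stage("correlate", site, pearson_network, processed,
                         config.alpha)
    contingencies = {}
    for window in ("short", "long"):
        ct = sign_contingency(pearson, calls, window, processed.taxa, site)
        chi_square_independence(ct)
        contingencies[window] = ct
    scatter = causality_vs_correlation_scatter(pearson,
                                               pair_extremes(all_edges))
    return SiteResult(site_label=site, processed=processed, tensor=tensor,
                      edges=all_edges, thresholds=thresholds,
                      strong_edges=strong, calls=calls, null_report=report,
                      pearson=pearson, contingencies=contingencies,
                      scatter=scatter)


def run_pipeline(config: RunConfig,
                 tables: dict[str, GenusTimeSeriesTable] | list,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage for every site, then cross-site conservation."""
    if not isinstance(tables, dict):
        tables = {t.site_label: t for t in tables}
    if not tables:
        raise ValueError("need at least one site table")
    log = [f"config: {config}"]
    sites = {label: run_site(t, config, log) for label, t in tables.items()}
    conservation: dict[tuple[str, str, str], ConservationReport] = {}
    labels = sorted(sites)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ra, rb = sites[a], sites[b]
            for mode in ("quantitative", "qualitative"):
                conservation[(a, b, mode)] = conserved_edges(
                    a, b, ra.strong_edges, rb.strong_edges, mode=mode,
                    calls_a=ra.calls, calls_b=rb.calls,
                    taxa_a=ra.processed.taxa, taxa_b=rb.processed.taxa)
    result = PipelineResult(config=config, sites=sites,
                            conservation=conservation, log=log)
    if outdir is not None:
        write_archive(result, outdir)
    return result


def write_archive(result: PipelineResult, outdir: str | Path) -> None:
    """Persist every stage output as TSV/GraphML under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_file(outdir / "config.txt")
    for label, r in result.sites.items():
        d = outdir / label
        d.mkdir(exist_ok=True)
        io.write_processed(r.processed, d / "processed.tsv")
        io.write_tensor(r.tensor, d / "coefficients.tsv")
        io.write_penalty_report(r.tensor, d / "penalties.tsv")
        io.write_edge_list(r.edges, d / "edges.tsv")
        io.write_edge_list(r.strong_edges, d / "strong_edges.tsv")
        io.edges_to_graphml(r.strong_edges, d / "strong_network.graphml")
        _write_calls(r.calls, d / "timescale_calls.tsv")
        _write_null(r.null_report, d / "null_report.tsv")
        for window, ct in r.contingencies.items():
            ct.counts.to_csv(d / f"contingency_{window}.tsv", sep="\t")
    for (a, b, mode), rep in result.conservation.items():
        _write_conservation(rep, outdir / f"conservation_{a}_{b}_{mode}.tsv")
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")


def _write_calls(calls: list[TimescaleCall], path: Path) -> None:
    lines = ["cause\teffect\tshort_sign\tlong_sign"]
    lines += [f"{c.cause}\t{c.effect}\t{c.short_sign}\t{c.long_sign}"
              for c in calls]
    path.write_text("\n".join(lines) + "\n")


def _write_null(report: NullReport, path: Path) -> None:
    lines = [
        f"site\t{report.site_label}",
        f"n_strong_actual\t{report.n_strong_actual}",
        f"n_strong_null\t{report.n_strong_null}",
        f"n_strong_pairs_actual\t{report.n_strong_pairs_actual}",
        f"n_strong_pairs_null\t{report.n_strong_pairs_null}",
        f"null_fraction\t{report.null_fraction}",
        f"seed\t{report.seed}",
        "overlapping_pairs\t" + ";".join(
            f"{c}->{e}" for c, e in report.overlapping_pairs),
    ]
    path.write_text("\n".join(lines) + "\n")


def _write_conservation(rep: ConservationReport, path: Path) -> None:
    fr = rep.fractions()
    lines = [
        f"sites\t{rep.site_a}\t{rep.site_b}",
        f"mode\t{rep.mode}",
        f"shared_taxa\t{';'.join(rep.shared_taxa)}",
        f"conserved_interspecific\t{len(rep.conserved_interspecific)}",
        f"union_interspecific\t{rep.union_interspecific}",
        f"fraction_interspecific\t{fr['interspecific']}",
        f"conserved_intraspecific\t{len(rep.conserved_intraspecific)}",
        f"union_intraspecific\t{rep.union_intraspecific}",
        f"fraction_intraspecific\t{fr['intraspecific']}",
    ]
    path.write_text("\n".join(lines) + "\n")
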