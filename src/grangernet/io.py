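"""Readers and writers for the pipeline's file formats.

Tab-separated text is the canonical interchange format throughout: abundance
tables (first column taxon name, header row of day indices), processed
series (same layout plus a provenance sidecar), long-format coefficient
tensors, edge lists, and GraphML for the strong-edge network.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .edges import CausalEdge
from .tables import GenusTimeSeriesTable, ProcessedSeries, TableValidationError
from .varlasso import CoefficientTensor

EDGE_COLUMNS = ["cause", "effect", "lag", "coefficient", "sign",
                "intraspecific", "strong"]


def read_abundance_table(path: str | Path, format: str = "tsv",
                         site_label: str | None = None
                         ) -> GenusTimeSeriesTable:
    """Read a taxa x days abundance table.

    TSV dialect: first column holds taxon names, the header row holds
    integer day indices.  Row and column order are preserved.
    """
    path = Path(path)
    if format == "biom":
        raise NotImplementedError(
            "BIOM input is not supported in this build; convert to TSV"
        )
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        days = df.columns.astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise TableValidationError(
            f"{path}: header must contain integer day indices "
            f"(got {list(df.columns)[:5]}...)"
        ) from exc
    return GenusTimeSeriesTable(
        site_label=site_label if site_label is not None else path.stem,
        taxa=[str(t) for t in df.index],
        days=days,
        values=df.to_numpy(dtype=float),
    )


def write_table(table: GenusTimeSeriesTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, index=pd.Index(table.taxa, name="taxon"),
                      columns=table.days)
    df.to_csv(path, sep="\t")


def write_processed(series: ProcessedSeries, path: str | Path) -> None:
    """Write the processed matrix as TSV plus a ``.provenance.txt`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(series.matrix,
                      index=pd.Index(series.taxa, name="taxon"),
                      columns=range(1, series.n_timepoints + 1))
    df.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".provenance.txt")
    lines = [f"site\t{series.site_label}",
             f"imputation_seed\t{series.imputation_seed}"]
    lines += [f"step\t{s}" for s in series.provenance]
    sidecar.write_text("\n".join(lines) + "\n")


def read_processed(path: str | Path,
                   site_label: str | None = None) -> ProcessedSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ProcessedSeries(
        site_label=site_label if site_label is not None else path.stem,
        taxa=[str(t) for t in df.index],
        matrix=df.to_numpy(dtype=float),
    )


def write_edge_list(edges: list[CausalEdge], path: str | Path) -> None:
    """Edge list as TSV, deterministically ordered by (effect, cause, lag)."""
    rows = [
        {
            "cause": e.cause, "effect": e.effect, "lag": e.lag,
            "coefficient": repr(float(e.coefficient)), "sign": e.sign,
            "intraspecific": int(e.intraspecific), "strong": int(e.strong),
        }
        for e in sorted(edges, key=lambda e: (e.effect, e.cause, e.lag))
    ]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t",
                                                    index=False)


def read_edge_list(path: str | Path) -> list[CausalEdge]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        CausalEdge(cause=str(r.cause), effect=str(r.effect), lag=int(r.lag),
                   coefficient=float(r.coefficient), strong=bool(r.strong))
        for r in df.itertuples()
    ]


def write_tensor(tensor: CoefficientTensor, path: str | Path) -> None:
    """Long-format TSV of nonzero coefficients (effect, cause, lag, value)."""
    rows = []
    for i, effect in enumerate(tensor.taxa):
        for j, cause in enumerate(tensor.taxa):
            for k in range(tensor.lags):
                b = tensor.B[i, j, k]
                if b != 0:
                    rows.append({"effect": effect, "cause": cause,
                                 "lag": k + 1, "coefficient": repr(float(b))})
    pd.DataFrame(rows, columns=["effect", "cause", "lag", "coefficient"]
                 ).to_csv(path, sep="\t", index=False)


def read_tensor(path: str | Path, taxa: list[str],
                lags: int) -> CoefficientTensor:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    n = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    B = np.zeros((n, n, lags))
    for r in df.itertuples():
        B[idx[str(r.effect)], idx[str(r.cause)], int(r.lag) - 1] = float(
            r.coefficient)
    return CoefficientTensor(taxa=list(taxa), B=B,
                             selected_penalty=np.zeros(n),
                             intercepts=np.zeros(n))


def write_penalty_report(tensor: CoefficientTensor, path: str | Path) -> None:
    rows = []
    for i, taxon in enumerate(tensor.taxa):
        rec = {"response": taxon,
               "selected_penalty": tensor.selected_penalty[i],
               "intercept": tensor.intercepts[i],
               "n_retained": int(np.count_nonzero(tensor.B[i]))}
        ppath = tensor.penalty_paths.get(taxon)
        if ppath is not None:
            rec["min_msfe"] = float(ppath.msfe.min())
            rec["validation_msfe"] = ppath.validation_msfe
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def edges_to_graphml(edges: list[CausalEdge], path: str | Path) -> None:
    """Export a (multi-)edge network with sign and lag attributes."""
    G = nx.MultiDiGraph()
    for e in sorted(edges, key=lambda e: (e.effect, e.cause, e.lag)):
        G.add_edge(e.cause, e.effect, lag=e.lag, coefficient=e.coefficient,
                   sign=e.sign, strong=e.strong,
                   intraspecific=e.intraspecific)
    nx.write_graphml(G, path)
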