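"""Readers and writers for the pipeline's text formats.

Tabular data is TSV (UTF-8, '.' decimal), with sample metadata carried in
'#'-prefixed header rows above the gene table; networks round-trip through
SIF (``geneA pp|pn geneB`` by edge sign), GraphML (full attributes) and a
plain edge-list TSV; synthetic truth objects serialise to JSON with graphs
as edge lists and precision matrices as dense row-major arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    SAMPLE_META_COLUMNS,
    STATUS_CODES,
    ConsensusNetwork,
    CtTable,
    ExpressionMatrix,
    SyntheticTruth,
)

#: SIF interaction labels by edge sign (pp = positive, pn = negative)
SIGN_TO_SIF = {1: "pp", -1: "pn"}
SIF_TO_SIGN = {v: k for k, v in SIGN_TO_SIF.items()}


# ---------------------------------------------------------------------------
# tabular formats

def _write_table(values: pd.DataFrame, samples: pd.DataFrame, path: Path, scale: str | None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if scale is not None:
            fh.write(f"# scale\t{scale}\n")
        for col in SAMPLE_META_COLUMNS:
            row = "\t".join(str(v) for v in samples[col])
            fh.write(f"# {col}\t{row}\n")
        values.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n")


def _read_table(path: Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    meta: dict[str, list[str]] = {}
    header: dict[str, str] = {}
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, *vals = line[1:].strip().split("\t")
            if key in SAMPLE_META_COLUMNS:
                meta[key] = vals
            else:
                header[key] = vals[0] if vals else ""
    values = pd.read_csv(path, sep="\t", skiprows=skip, index_col="gene")
    values.index.name = None
    values.columns.name = None
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta]
    if missing:
        raise ValueError(f"{path} lacks metadata rows: {missing}")
    for key, vals in meta.items():
        if len(vals) != values.shape[1]:
            raise ValueError(
                f"{path}: metadata row {key!r} has {len(vals)} entries "
                f"for {values.shape[1]} sample columns"
            )
    samples = pd.DataFrame(meta, index=pd.Index(values.columns, name="sample"))
    if "replicate" in samples:
        try:
            samples["replicate"] = pd.to_numeric(samples["replicate"])
        except (ValueError, TypeError):
            pass
    return values, samples, header


def write_expression(expr: ExpressionMatrix, path) -> None:
    _write_table(expr.values, expr.samples, Path(path), expr.scale)


def read_expression(path) -> ExpressionMatrix:
    values, samples, header = _read_table(Path(path))
    return ExpressionMatrix(values, samples, scale=header.get("scale", "ratio"))


def _status_path(path: Path) -> Path:
    return path.with_name(path.stem + ".status" + path.suffix)


def write_ct(ct: CtTable, path) -> None:
    """Write Ct values to ``path`` and the status table to a sibling file."""
    path = Path(path)
    _write_table(ct.values, ct.samples, path, scale=None)
    _write_table(ct.status, ct.samples, _status_path(path), scale=None)


def read_ct(path) -> CtTable:
    path = Path(path)
    values, samples, _ = _read_table(path)
    status, _, _ = _read_table(_status_path(path))
    status = status.astype(str)
    bad = set(np.unique(status.values)) - set(STATUS_CODES)
    if bad:
        raise ValueError(f"unknown status codes in {_status_path(path)}: {sorted(bad)}")
    return CtTable(values.astype(float), status, samples)


# ---------------------------------------------------------------------------
# networks

def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, ConsensusNetwork) else net


def write_network(net, path, fmt: str | None = None) -> None:
    """Write a network as SIF, GraphML or an edge-list TSV (by extension)."""
    path = Path(path)
    g = _as_graph(net)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                a, b = sorted((u, v))
                fh.write(f"{a}\t{SIGN_TO_SIF[data.get('sign', 1)]}\t{b}\n")
            for node in sorted(nx.isolates(g)):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        out = nx.Graph()
        out.add_nodes_from(sorted(g.nodes()))
        for u, v, data in sorted(g.edges(data=True)):
            out.add_edge(*sorted((u, v)), **{k: data[k] for k in sorted(data)})
        nx.write_graphml(out, path)
    elif fmt in ("tsv", "txt"):
        table = (net.edge_table() if isinstance(net, ConsensusNetwork)
                 else _edge_table(g))
        table.to_csv(path, sep="\t", index=False, lineterminator="\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def _edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [{"gene_a": min(u, v), "gene_b": max(u, v), **data}
            for u, v, data in g.edges(data=True)]
    return (pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "sign"])
            .sort_values(["gene_a", "gene_b"]).reset_index(drop=True))


def read_network(path, fmt: str | None = None) -> nx.Graph:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "sif":
        g = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) == 3:
                    a, rel, b = parts
                    if rel not in SIF_TO_SIGN:
                        raise ValueError(f"{path}:{ln}: unknown interaction type {rel!r}")
                    g.add_edge(a, b, sign=SIF_TO_SIGN[rel])
                elif parts != [""]:
                    raise ValueError(f"{path}:{ln}: malformed SIF row")
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {fmt!r}")


def write_consensus(net: ConsensusNetwork, out_dir, stem: str) -> list[Path]:
    """Write a consensus network in all three dialects; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in ("sif", "graphml", "tsv"):
        p = out_dir / f"{stem}.{ext}"
        write_network(net, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# synthetic truth and gene lists

def _graph_to_json(g: nx.Graph) -> dict:
    return {"nodes": sorted(g.nodes()),
            "edges": sorted([sorted((u, v)) for u, v in g.edges()])}


def _graph_from_json(d: dict) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(d["nodes"])
    g.add_edges_from(d["edges"])
    return g


def write_truth(truth: SyntheticTruth, path) -> None:
    doc = {
        "stages": truth.stages,
        "gene_ids": truth.gene_ids,
        "planned_losers": truth.planned_losers,
        "planned_gainers": truth.planned_gainers,
        "batch_params": {k: list(v) for k, v in truth.batch_params.items()},
        "seed": truth.seed,
        "conditions": truth.conditions,
        "stage_graphs": {k: _graph_to_json(g) for k, g in truth.stage_graphs.items()},
        "precision_matrices": {k: np.asarray(m).tolist()
                               for k, m in truth.precision_matrices.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_truth(path) -> SyntheticTruth:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return SyntheticTruth(
        stages=doc["stages"],
        stage_graphs={k: _graph_from_json(g) for k, g in doc["stage_graphs"].items()},
        precision_matrices={k: np.asarray(m, dtype=float)
                            for k, m in doc["precision_matrices"].items()},
        gene_ids=doc["gene_ids"],
        planned_losers=doc["planned_losers"],
        planned_gainers=doc["planned_gainers"],
        batch_params={k: tuple(v) for k, v in doc["batch_params"].items()},
        seed=doc["seed"],
        conditions=doc.get("conditions", {}),
    )


def write_gene_list(genes, path) -> None:
    """Newline-delimited gene list (one id per line, enrichment-tool ready)."""
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip()]


def write_provenance(doc: dict, path) -> None:
    """JSON provenance log: parameters, seeds, per-stage summaries."""
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True, default=str),
                          encoding="utf-8")
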