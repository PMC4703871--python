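"""Per-gene connectivity change across stage networks.

Connectivity of a gene is its degree (number of retained edges). Gain or
loss across development is the signed sum of degree differences over every
ordered pair of stages (three pairs for three stages); the per-pair
breakdown is always kept so alternative summaries can be recomputed. Genes
absent from a stage network count as degree 0 — the gene universe is fixed
across stages.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ConnectivityDelta, ConsensusNetwork
from .preprocess import hypergeom_upper


def _graph_of(network) -> nx.Graph:
    return network.graph if isinstance(network, ConsensusNetwork) else network


def degree(network, gene: str) -> int:
    """Number of retained edges incident to ``gene``; 0 when absent."""
    g = _graph_of(network)
    return g.degree(gene) if gene in g else 0


def connectivity_change(stage_networks: dict[str, "nx.Graph | ConsensusNetwork"]) -> list[ConnectivityDelta]:
    """Signed degree change per gene over every ordered pair of stages.

    ``stage_networks`` maps stage label to network, in developmental order
    (insertion order is the stage order). For stages a < b the pair delta is
    degree at b minus degree at a; the total is the sum over pairs.
    """
    stages = list(stage_networks)
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    graphs = {s: _graph_of(n) for s, n in stage_networks.items()}
    universe = sorted(set().union(*(g.nodes() for g in graphs.values())))
    deltas = []
    for gene in universe:
        per_pair = {}
        for a in range(len(stages)):
            for b in range(a + 1, len(stages)):
                sa, sb = stages[a], stages[b]
                per_pair[(sa, sb)] = degree(graphs[sb], gene) - degree(graphs[sa], gene)
        deltas.append(ConnectivityDelta(gene_id=gene, delta=sum(per_pair.values()),
                                        per_pair_deltas=per_pair))
    return deltas


def top_k_with_ties(deltas: list[ConnectivityDelta], k: int = 20,
                    direction: str = "gainers") -> list[str]:
    """Top-k genes by signed delta, keeping every tie with the k-th value.

    Gainers are sorted by descending delta, losers ascending; ties at the
    k-th position are all included, so the list may exceed k. Within equal
    deltas the ordering is lexicographic by gene id.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if direction not in ("gainers", "losers"):
        raise ValueError("direction must be 'gainers' or 'losers'")
    sign = -1 if direction == "gainers" else 1
    ranked = sorted(deltas, key=lambda d: (sign * d.delta, d.gene_id))
    if len(ranked) <= k:
        if len(ranked) < k:
            warnings.warn(f"only {len(ranked)} genes available for top-{k}", stacklevel=2)
        return [d.gene_id for d in ranked]
    cutoff = ranked[k - 1].delta
    return [d.gene_id for d in ranked if sign * d.delta <= sign * cutoff]


def delta_table(deltas: list[ConnectivityDelta]) -> pd.DataFrame:
    """Tabular view: gene, per-pair deltas, total, gain and loss ranks."""
    rows = []
    for d in deltas:
        row = {"gene": d.gene_id}
        row.update({f"{a}->{b}": v for (a, b), v in d.per_pair_deltas.items()})
        row["delta"] = d.delta
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    table["gain_rank"] = table["delta"].rank(ascending=False, method="min").astype(int)
    table["loss_rank"] = table["delta"].rank(ascending=True, method="min").astype(int)
    return table.sort_index()


def perturbation_overlap(
    perturbed,
    reference,
    developmental_losers: list[str],
    developmental_gainers: list[str],
    k: int = 20,
    universe: int | None = None,
    draws: int | None = None,
) -> dict:
    """Connectivity change under perturbation, tested against developmental lists.

    Deltas are degree(perturbed) - degree(reference) per gene on the shared
    gene universe; the top-k (tie-aware) gainer and loser lists are
    intersected with supplied developmental gainer/loser lists and each
    overlap is tested with the upper-tail hypergeometric probability of
    drawing that many shared genes in ``draws`` draws (default: the list
    length) from ``universe`` genes.
    """
    gp, gr = _graph_of(perturbed), _graph_of(reference)
    if set(gp.nodes()) != set(gr.nodes()):
        raise ValueError("perturbed and reference networks must share a gene universe")
    genes = sorted(gp.nodes())
    if universe is None:
        universe = len(genes)
    deltas = [
        ConnectivityDelta(gene_id=g, delta=degree(gp, g) - degree(gr, g),
                          per_pair_deltas={("reference", "perturbed"):
                                           degree(gp, g) - degree(gr, g)})
        for g in genes
    ]
    losing = [d for d in deltas if d.delta < 0]
    gaining = [d for d in deltas if d.delta > 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short candidate lists are expected here
        losers = top_k_with_ties(losing, k, "losers") if losing else []
        gainers = top_k_with_ties(gaining, k, "gainers") if gaining else []

    def _test(top: list[str], dev: list[str]) -> tuple[int, float]:
        if not top or not dev:
            return 0, 1.0
        overlap = len(set(top) & set(dev))
        n_draws = draws if draws is not None else len(top)
        return overlap, hypergeom_upper(overlap, len(dev), n_draws, universe)

    loser_vs_gain = _test(losers, developmental_gainers)
    loser_vs_loss = _test(losers, developmental_losers)
    gainer_vs_gain = _test(gainers, developmental_gainers)
    gainer_vs_loss = _test(gainers, developmental_losers)
    return {
        "deltas": deltas,
        "losers": losers,
        "gainers": gainers,
        "overlap_p": {
            ("losers", "developmental_gainers"): loser_vs_gain,
            ("losers", "developmental_losers"): loser_vs_loss,
            ("gainers", "developmental_gainers"): gainer_vs_gain,
            ("gainers", "developmental_losers"): gainer_vs_loss,
        },
    }
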