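"""Permutation test for gene-set connectivity in an interaction network.

Asks whether a query gene is more connected to its first neighbours within a
given gene set than expected for random gene sets of the same size drawn
from the network. The observed statistic is the degree of the query in the
subnetwork induced by the query plus the gene set; the null distribution
comes from re-drawing the gene set at random (default 1,000 replicates).

Two p-values are reported: the raw exceedance proportion (which can be
exactly 0 when the observed value beats every replicate) and the
bias-adjusted (exceedances + 1) / (replicates + 1), which can never be 0 and
is the recommended summary.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .datatypes import PermutationResult


def first_neighbor_connectivity(db: nx.Graph, query: str, gene_set) -> int:
    """Degree of ``query`` in the subnetwork induced by {query} | gene_set."""
    if query not in db:
        raise ValueError(f"query gene {query!r} absent from the interaction network")
    gene_set = set(gene_set)
    if query in gene_set:
        raise ValueError("query gene must not be part of the gene set")
    missing = gene_set - set(db.nodes())
    if missing:
        raise ValueError(f"gene set members absent from the network: {sorted(missing)}")
    return sum(1 for nb in db.neighbors(query) if nb in gene_set)


def random_set_null(
    db: nx.Graph,
    query: str,
    set_size: int,
    n_reps: int = 1000,
    exclude=(),
    seed: int = 0,
) -> np.ndarray:
    """Null connectivity counts from random gene sets of the given size.

    Sets are drawn without replacement from the network's genes, excluding
    the query and any ``exclude`` list (e.g. the original gene set, to keep
    the null unrelated to it).
    """
    if query not in db:
        raise ValueError(f"query gene {query!r} absent from the interaction network")
    eligible = sorted(set(db.nodes()) - {query} - set(exclude))
    if set_size > len(eligible):
        raise ValueError(
            f"set_size {set_size} exceeds the {len(eligible)} eligible genes"
        )
    rng = np.random.default_rng(seed)
    nb_set = set(db.neighbors(query))
    neighbors = np.array([g in nb_set for g in eligible])
    n = len(eligible)
    null = np.empty(n_reps, dtype=int)
    for i in range(n_reps):
        idx = rng.choice(n, size=set_size, replace=False)
        null[i] = int(neighbors[idx].sum())
    return null


def effective_pvalue(observed: int, null_values) -> tuple[float, float]:
    """Raw and bias-adjusted permutation p-values.

    p_raw = #{null >= observed} / n;  p_adjusted = (#{null >= observed} + 1) / (n + 1).
    """
    null = np.asarray(null_values)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    exceed = int((null >= observed).sum())
    return exceed / null.size, (exceed + 1) / (null.size + 1)


def connectivity_permutation_test(
    db: nx.Graph,
    query: str,
    gene_set,
    n_reps: int = 1000,
    exclude_gene_set: bool = False,
    seed: int = 0,
) -> PermutationResult:
    """Observed first-neighbour connectivity versus the random-set null."""
    gene_set = sorted(set(gene_set))
    observed = first_neighbor_connectivity(db, query, gene_set)
    exclude = gene_set if exclude_gene_set else ()
    null = random_set_null(db, query, len(gene_set), n_reps=n_reps, exclude=exclude, seed=seed)
    p_raw, p_adj = effective_pvalue(observed, null)
    return PermutationResult(
        query_gene=query,
        observed=observed,
        null_values=null,
        p_raw=p_raw,
        p_adjusted=p_adj,
        seed=seed,
    )
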