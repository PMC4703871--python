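"""Ground-truth generators for testing the network pipeline end to end.

The generative model mirrors the assumptions of the downstream machinery: a
Gaussian graphical model on the log2 scale whose precision matrix has support
exactly on a known stage-specific graph. Developmental rewiring deletes edges
preferentially from a planned set of "losers" and adds edges around planned
"gainers", so connectivity-change recovery is directly testable. Expression is
exponentiated to the fold-ratio scale, optionally batch-shifted, and can be
encoded back to Ct cycles with undetermined/flagged entries to exercise the
qPCR preprocessing front end.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    STATUS_FLAGGED,
    STATUS_OK,
    STATUS_UNDETERMINED,
    CtTable,
    ExpressionMatrix,
    SyntheticTruth,
    gene_names,
    sample_meta,
)

DEFAULT_BATCH_PARAMS = {"batch1": (0.0, 1.0), "batch2": (0.25, 1.0)}

# Ct encoding defaults: 20-cycle intercept, one cycle per log2 unit of
# template (perfect efficiency), 35-cycle detection limit.
DEFAULT_CT_INTERCEPT = 20.0
DEFAULT_CT_SLOPE = -1.0
DEFAULT_CT_DETECTION_LIMIT = 35.0


def _scale_free_graph(nodes: list[str], n_edges: int, rng: np.random.Generator) -> nx.Graph:
    """Preferential-attachment tree plus degree-preferential extra edges.

    Gives an exact edge count with a heavy-tailed degree distribution.
    """
    n = len(nodes)
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds the {max_edges} possible edges")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if n_edges == 0:
        return g
    # attachment tree
    order = list(rng.permutation(nodes))
    g.add_edge(order[0], order[1])
    for node in order[2 : min(n, n_edges + 1)]:
        attached = [v for v in order if v in g and g.degree(v) > 0 and v != node]
        probs = np.array([g.degree(v) for v in attached], dtype=float)
        target = attached[rng.choice(len(attached), p=probs / probs.sum())]
        g.add_edge(node, target)
    # extra edges, endpoints drawn proportionally to current degree + 1
    while g.number_of_edges() < n_edges:
        probs = np.array([g.degree(v) + 1.0 for v in nodes])
        u, v = rng.choice(n, size=2, replace=False, p=probs / probs.sum())
        a, b = nodes[u], nodes[v]
        if not g.has_edge(a, b):
            g.add_edge(a, b)
    return g


def _random_graph(nodes: list[str], n_edges: int, rng: np.random.Generator) -> nx.Graph:
    n = len(nodes)
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds the {max_edges} possible edges")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    all_pairs = list(itertools.combinations(range(n), 2))
    chosen = rng.choice(len(all_pairs), size=n_edges, replace=False)
    g.add_edges_from((nodes[all_pairs[i][0]], nodes[all_pairs[i][1]]) for i in chosen)
    return g


def _rewire_once(
    g: nx.Graph,
    n_rewire: int,
    losers: list[str],
    gainers: list[str],
    rng: np.random.Generator,
    force_planned: bool,
) -> nx.Graph:
    """Delete and add exactly n_rewire edges, biased to losers/gainers.

    Deletions avoid gainer-incident edges; additions avoid loser-incident
    pairs and never re-create an edge deleted in the same transition. When
    ``force_planned`` is set (first transition), every loser loses at least
    one edge and every gainer gains at least one, making the planned lists
    strictly monotone across the whole stage sequence.
    """
    new = g.copy()
    gainer_set, loser_set = set(gainers), set(losers)

    deleted: list[tuple[str, str]] = []

    def deletable():
        return [e for e in new.edges() if e[0] not in gainer_set and e[1] not in gainer_set]

    if force_planned:
        for gene in losers:
            cands = [e for e in deletable() if gene in e]
            if not cands:
                raise ValueError(f"planned loser {gene!r} has no deletable edge")
            e = cands[rng.integers(len(cands))]
            new.remove_edge(*e)
            deleted.append(tuple(sorted(e)))
    while len(deleted) < n_rewire:
        cands = deletable()
        if not cands:
            raise ValueError("rewiring infeasible: no deletable edges remain")
        e = cands[rng.integers(len(cands))]
        new.remove_edge(*e)
        deleted.append(tuple(sorted(e)))
    deleted_set = set(deleted)

    nodes = list(new.nodes())

    def addable():
        out = []
        for a, b in itertools.combinations(nodes, 2):
            if a in loser_set or b in loser_set:
                continue
            if new.has_edge(a, b) or tuple(sorted((a, b))) in deleted_set:
                continue
            out.append((a, b))
        return out

    added = 0
    if force_planned:
        for gene in gainers:
            cands = [p for p in addable() if gene in p]
            if not cands:
                raise ValueError(f"planned gainer {gene!r} has no addable edge")
            new.add_edge(*cands[rng.integers(len(cands))])
            added += 1
    while added < n_rewire:
        cands = addable()
        if not cands:
            raise ValueError("rewiring infeasible: graph too dense to add edges")
        new.add_edge(*cands[rng.integers(len(cands))])
        added += 1
    return new


def gen_stage_truth(
    n_genes: int,
    stages: list[str] = ("PND14", "PND21", "PND28"),
    n_rewire: int = 5,
    graph_model: str = "scale-free",
    seed: int = 0,
    n_edges: int | None = None,
    weight_range: tuple[float, float] = (0.2, 0.8),
    batch_params: dict[str, tuple[float, float]] | None = None,
) -> SyntheticTruth:
    """Generate ground-truth stage graphs with planned connectivity turnover.

    Consecutive stages differ by exactly ``n_rewire`` edge deletions plus
    ``n_rewire`` additions. Deletions are taken preferentially from the
    planned losers and additions wired to the planned gainers, so losers have
    strictly fewer edges at the last stage than the first and gainers
    strictly more (both lists are empty when ``n_rewire == 0``).
    """
    stages = list(stages)
    if n_genes < 5:
        raise ValueError("n_genes must be at least 5")
    if len(stages) < 2:
        raise ValueError("need at least 2 stage labels")
    if n_rewire < 0:
        raise ValueError("n_rewire must be non-negative")
    max_edges = n_genes * (n_genes - 1) // 2
    if n_rewire >= max_edges:
        raise ValueError(f"n_rewire={n_rewire} is not below the {max_edges} possible edges")
    if n_edges is None:
        n_edges = int(round(4 * n_genes / 3))

    rng = np.random.default_rng(seed)
    genes = gene_names(n_genes)
    if graph_model == "scale-free":
        base = _scale_free_graph(genes, n_edges, rng)
    elif graph_model == "random":
        base = _random_graph(genes, n_edges, rng)
    else:
        raise ValueError(f"unknown graph_model {graph_model!r}")

    if n_rewire == 0:
        losers: list[str] = []
        gainers: list[str] = []
    else:
        n_planned = max(1, min(n_genes // 6, n_rewire))
        by_degree = sorted(genes, key=lambda g: (-base.degree(g), g))
        losers = by_degree[:n_planned]  # high degree: edges available to lose
        pool = [g for g in by_degree[n_planned:]]
        gainers = sorted(pool[-n_planned:])  # low degree: room to gain

    graphs = {stages[0]: base}
    current = base
    for t, stage in enumerate(stages[1:]):
        current = _rewire_once(current, n_rewire, losers, gainers, rng, force_planned=(t == 0))
        graphs[stage] = current

    if n_rewire > 0:
        first, last = graphs[stages[0]], graphs[stages[-1]]
        for gene in losers:
            if not last.degree(gene) < first.degree(gene):
                raise AssertionError(f"planned loser {gene!r} did not lose edges")
        for gene in gainers:
            if not last.degree(gene) > first.degree(gene):
                raise AssertionError(f"planned gainer {gene!r} did not gain edges")

    precisions = {
        label: precision_from_graph(g, weight_range=weight_range, seed=int(rng.integers(2**31)))
        for label, g in graphs.items()
    }
    return SyntheticTruth(
        stages=stages,
        stage_graphs=graphs,
        precision_matrices=precisions,
        gene_ids=genes,
        planned_losers=sorted(losers),
        planned_gainers=sorted(gainers),
        batch_params=dict(batch_params or DEFAULT_BATCH_PARAMS),
        seed=seed,
    )


def add_reversion_condition(
    truth: SyntheticTruth,
    label: str = "perturbed",
    condition: str = "overexpression",
    seed: int | None = None,
) -> SyntheticTruth:
    """Add a perturbation condition whose graph reverts to the first stage.

    Models an intervention at the final stage that restores the immature
    (first-stage) network configuration: genes that gained edges across
    development lose them again and vice versa.
    """
    if label in truth.stage_graphs:
        raise ValueError(f"label {label!r} already present")
    g = truth.stage_graphs[truth.stages[0]].copy()
    truth.stage_graphs[label] = g
    truth.precision_matrices[label] = precision_from_graph(
        g, seed=truth.seed + 1 if seed is None else seed
    )
    truth.conditions[label] = condition
    return truth


def precision_from_graph(
    graph: nx.Graph,
    weight_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
    standardize: bool = True,
) -> np.ndarray:
    """Symmetric positive-definite precision matrix supported on the graph.

    Edge entries get a random magnitude in ``weight_range`` with random sign;
    the common diagonal is 1 plus the maximum absolute off-diagonal row sum
    (strict diagonal dominance, hence positive definiteness). With
    ``standardize`` the matrix is rescaled to a unit diagonal.
    """
    if any(u == v for u, v in graph.edges()):
        raise ValueError("graph must not contain self-loops")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes())
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    omega = np.zeros((n, n))
    for u, v in sorted(map(tuple, map(sorted, graph.edges()))):
        w = rng.uniform(*weight_range) * rng.choice([-1.0, 1.0])
        omega[index[u], index[v]] = omega[index[v], index[u]] = w
    row_sums = np.abs(omega).sum(axis=1)
    d = 1.0 + row_sums.max()
    np.fill_diagonal(omega, d)
    if standardize:
        omega /= d
    return omega


def simulate_expression(
    truth: SyntheticTruth,
    n_per_stage: int = 12,
    batch_assignment: dict[str, list[str]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Sample fold-ratio expression for every label of the truth object.

    Per label, ``n_per_stage`` samples are drawn from a zero-mean
    multivariate Gaussian with covariance inv(Omega) on the log2 scale, plus
    optional iid noise; each sample's batch shift/scale from
    ``truth.batch_params`` is applied on the log2 scale before exponentiation.
    """
    if n_per_stage < 3:
        raise ValueError("n_per_stage must be at least 3")
    labels = truth.labels
    batch_labels = sorted(truth.batch_params)
    if batch_assignment is not None:
        unknown = set(batch_assignment) - set(labels)
        if unknown:
            raise ValueError(f"unknown stage labels in batch_assignment: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    blocks, meta_frames = [], []
    sample_counter = 0
    for label in labels:
        omega = truth.precision_matrices[label]
        cov = np.linalg.inv(omega)
        log2x = rng.multivariate_normal(np.zeros(len(truth.gene_ids)), cov, size=n_per_stage,
                                        method="cholesky").T
        if noise_sd > 0:
            log2x = log2x + rng.normal(0.0, noise_sd, size=log2x.shape)
        if batch_assignment is not None and label in batch_assignment:
            batches = batch_assignment[label]
            if isinstance(batches, str):
                batches = [batches] * n_per_stage
        else:
            batches = [batch_labels[i % len(batch_labels)] for i in range(n_per_stage)]
        if len(batches) != n_per_stage:
            raise ValueError(f"batch assignment for {label!r} must list one batch per sample")
        unknown_b = set(batches) - set(truth.batch_params)
        if unknown_b:
            raise ValueError(f"unknown batch labels: {sorted(unknown_b)}")
        for j, b in enumerate(batches):
            shift, scale = truth.batch_params[b]
            log2x[:, j] = scale * log2x[:, j] + shift
        ids = [f"S{sample_counter + j + 1:04d}" for j in range(n_per_stage)]
        sample_counter += n_per_stage
        blocks.append(pd.DataFrame(2.0**log2x, index=truth.gene_ids, columns=ids))
        meta_frames.append(
            sample_meta(ids, stage=label, batch=batches,
                        condition=truth.condition_of(label),
                        replicate=list(range(1, n_per_stage + 1)))
        )
    values = pd.concat(blocks, axis=1)
    return ExpressionMatrix(values, pd.concat(meta_frames), scale="ratio")


def encode_ct(
    expr: ExpressionMatrix,
    intercept: float = DEFAULT_CT_INTERCEPT,
    slope: float = DEFAULT_CT_SLOPE,
    detection_limit: float = DEFAULT_CT_DETECTION_LIMIT,
    flag_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CtTable:
    """Encode expression as quantification cycles with quality flags.

    Ct = intercept + slope * log2(expression) + noise, with slope < 0 (more
    template amplifies earlier). Entries beyond the detection limit or with
    non-positive expression become ``undetermined``; a ``flag_rate`` fraction
    of the remaining entries is randomly marked ``flagged``.
    """
    if slope >= 0:
        raise ValueError("slope must be negative (more template -> lower Ct)")
    if not 0 <= flag_rate <= 1:
        raise ValueError("flag_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x = expr.values.to_numpy(dtype=float)
    positive = x > 0
    ct = np.full(x.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ct[positive] = intercept + slope * np.log2(x[positive])
    if noise_sd > 0:
        ct[positive] += rng.normal(0.0, noise_sd, size=int(positive.sum()))
    status = np.full(x.shape, STATUS_OK, dtype=object)
    undet = ~positive | (ct > detection_limit)
    status[undet] = STATUS_UNDETERMINED
    ct[undet] = np.nan
    if flag_rate > 0:
        flagged = (rng.random(x.shape) < flag_rate) & ~undet
        status[flagged] = STATUS_FLAGGED
    return CtTable(
        values=pd.DataFrame(ct, index=expr.values.index, columns=expr.values.columns),
        status=pd.DataFrame(status, index=expr.values.index, columns=expr.values.columns),
        samples=expr.samples.copy(),
    )


def gen_interaction_db(
    n_genes: int,
    model: str = "scale-free",
    mean_degree: float = 4.0,
    seed: int = 0,
    prefix: str = "G",
) -> nx.Graph:
    """Simple undirected interaction network standing in for a literature db."""
    if mean_degree < 0:
        raise ValueError("mean_degree must be non-negative")
    n_edges = int(round(mean_degree * n_genes / 2))
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges:
        raise ValueError("mean_degree implies more edges than possible")
    rng = np.random.default_rng(seed)
    nodes = gene_names(n_genes, prefix=prefix)
    if model == "scale-free":
        return _scale_free_graph(nodes, n_edges, rng)
    if model == "random":
        return _random_graph(nodes, n_edges, rng)
    raise ValueError(f"unknown model {model!r}")
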