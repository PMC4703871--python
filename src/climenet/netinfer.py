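"""Consensus co-expression network inference.

The estimator treats each gene in turn as a controlling variable: for n
genes, n leave-one-gene-out matrices of first-order partial correlations are
formed, and each is inverted approximately with CLIME (constrained
L1-minimisation) over a grid of regularisation values. Per member, the
regularisation level whose thresholded network best approximates a
scale-free degree distribution is kept; edges are filtered at a percentile
of absolute weight; and the consensus retains edges present in at least a
given fraction (default 95%) of the member networks eligible for the pair.

Edge signs follow the precision-to-partial-correlation convention
sign(-Omega_jk): a negative precision entry encodes a positive conditional
association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._lp import LpInfeasibleError, solve_clime_columns
from .datatypes import (
    ConsensusNetwork,
    ExpressionMatrix,
    PartialCorrelationEnsemble,
    PrecisionEstimate,
)

#: entries of Omega-hat below this magnitude are treated as exact zeros
ZERO_TOL = 1e-10


def loo_partial_correlations(expr: ExpressionMatrix) -> PartialCorrelationEnsemble:
    """All leave-one-gene-out first-order partial correlation matrices.

    Member i has entry (j, k) = (r_jk - r_ji r_ki) / sqrt((1 - r_ji^2)(1 - r_ki^2))
    from Pearson correlations of log2 expression: the association of j and k
    after removing the linear effect of the held-out gene i. For n genes, n
    member matrices of dimension (n-1) x (n-1) are produced.
    """
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if expr.n_genes < 3:
        raise ValueError("need at least 3 genes")
    log2 = expr.log2_values()
    if log2.isna().any().any():
        raise ValueError("expression matrix contains missing values; impute first")
    x = log2.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = sorted(log2.index[sd == 0])
        raise ValueError(f"zero-variance gene(s): {bad}")
    r = np.corrcoef(x)
    genes = expr.gene_ids
    n = len(genes)
    members: dict[str, pd.DataFrame] = {}
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        ri = r[keep][:, i]
        if (np.abs(ri) >= 1 - 1e-12).any():
            j = genes[keep[int(np.argmax(np.abs(ri)))]]
            raise ValueError(
                f"gene {j!r} is perfectly correlated with held-out gene {genes[i]!r}; "
                "partial correlation undefined"
            )
        sub = r[np.ix_(keep, keep)]
        denom = np.sqrt(np.outer(1 - ri**2, 1 - ri**2))
        member = (sub - np.outer(ri, ri)) / denom
        member = np.clip(member, -1.0, 1.0)
        np.fill_diagonal(member, 1.0)
        labels = [genes[j] for j in keep]
        members[genes[i]] = pd.DataFrame(member, index=labels, columns=labels)
    return PartialCorrelationEnsemble(members=members, gene_ids=list(genes),
                                      n_samples=expr.n_samples)


def lambda_grid(n_points: int = 20, low: float = 0.01, high: float = 1.0) -> np.ndarray:
    """Equi-spaced regularisation values from ``high`` down to ``low``."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    return np.linspace(high, low, n_points)


def clime_estimate(
    sigma, lam: float, backend: str = "simplex", held_out_gene: str | None = None
) -> PrecisionEstimate:
    """Constrained L1-minimisation estimate of the inverse of ``sigma``.

    Each column b solves min ||w||_1 subject to ||sigma w - e_b||_inf <= lam;
    the column-stacked solution is symmetrised entrywise by keeping the
    smaller-magnitude of the (j, k) and (k, j) entries. The recorded
    feasibility residual is the maximum constraint violation of the
    pre-symmetrisation columns and satisfies residual <= lam + solver
    tolerance.
    """
    if isinstance(sigma, pd.DataFrame):
        labels = list(sigma.index)
        S = sigma.to_numpy(dtype=float)
    else:
        S = np.asarray(sigma, dtype=float)
        labels = [str(i) for i in range(S.shape[0])]
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("sigma must be symmetric")
    raw = solve_clime_columns(S, lam, backend=backend)
    residual = float(np.abs(S @ raw - np.eye(S.shape[0])).max())
    # entrywise min-magnitude symmetrisation
    smaller = np.abs(raw) <= np.abs(raw.T)
    omega = np.where(smaller, raw, raw.T)
    omega[np.abs(omega) < ZERO_TOL] = 0.0
    return PrecisionEstimate(
        omega=pd.DataFrame(omega, index=labels, columns=labels),
        lam=float(lam),
        feasibility_residual=residual,
        held_out_gene=held_out_gene,
    )


def scale_free_fit(network: nx.Graph, log_binning: bool = False) -> float:
    """R^2 of the log10-log10 degree-distribution regression.

    The degree distribution p(k) is computed over observed positive degrees;
    the fit is the squared correlation of log10 p(k) on log10 k. With
    ``log_binning`` the degrees are pooled into powers-of-two bins first
    (density per bin width, geometric bin centres), which stabilises the
    tail on larger networks; it is off by default. With fewer than 3
    distinct positive degrees (or bins) the fit is defined as 0.
    """
    if network.number_of_edges() == 0:
        raise ValueError("edgeless network has no degree distribution")
    degrees = np.array([d for _, d in network.degree() if d > 0])
    if log_binning:
        n_bins = int(np.ceil(np.log2(degrees.max()))) + 1
        edges = 2.0 ** np.arange(n_bins + 1)  # [1,2), [2,4), ...
        counts, _ = np.histogram(degrees, bins=edges)
        widths = np.diff(edges)
        keep = counts > 0
        if keep.sum() < 3:
            return 0.0
        ks = np.sqrt(edges[:-1] * edges[1:])[keep]
        pk = (counts[keep] / counts.sum()) / widths[keep]
    else:
        ks, counts = np.unique(degrees, return_counts=True)
        if len(ks) < 3:
            return 0.0
        pk = counts / counts.sum()
    fit = stats.linregress(np.log10(ks), np.log10(pk))
    return float(fit.rvalue**2)


def threshold_edges(estimate: PrecisionEstimate, percentile: float = 10.0) -> nx.Graph:
    """Filter candidate edges at a percentile of absolute weight.

    Candidate edges are the nonzero off-diagonal entries of Omega-hat; edges
    with |weight| >= the linear-interpolation percentile of the nonzero
    absolute weights are retained. Edge attributes: ``weight`` = |Omega_jk|,
    ``sign`` = sign(-Omega_jk). All genes appear as nodes, including
    isolated ones.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    omega = estimate.omega.to_numpy()
    genes = estimate.gene_ids
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = omega[iu, ju]
    nz = np.abs(vals) > 0
    if not nz.any():
        warnings.warn("no nonzero off-diagonal entries; empty network", stacklevel=2)
        return g
    cutoff = np.percentile(np.abs(vals[nz]), percentile)
    for a, b, w in zip(iu[nz], ju[nz], vals[nz]):
        if abs(w) >= cutoff:
            g.add_edge(genes[a], genes[b], weight=float(abs(w)), sign=int(np.sign(-w)))
    return g


@dataclass
class LambdaSelection:
    """Chosen estimate plus the per-candidate scoring trace."""

    estimate: PrecisionEstimate
    network: nx.Graph
    fit: float
    trace: pd.DataFrame = field(repr=False)


def select_lambda(
    candidates: list[PrecisionEstimate],
    percentile: float = 10.0,
    score_order: str = "filter_then_score",
    log_binning: bool = False,
) -> LambdaSelection:
    """Pick the candidate whose network best approximates scale-free topology.

    Each candidate is thresholded and scored with :func:`scale_free_fit`;
    ties break toward larger lambda (the sparser model). With
    ``score_order="score_then_filter"`` the degree distribution is scored on
    the unthresholded support instead, and the winner is thresholded
    afterwards.
    """
    if not candidates:
        raise ValueError("no candidate estimates")
    if score_order not in ("filter_then_score", "score_then_filter"):
        raise ValueError(f"unknown score_order {score_order!r}")
    rows = []
    best = None  # (fit, estimate, network)
    for est in sorted(candidates, key=lambda e: -e.lam):
        net = threshold_edges(est, percentile)
        if score_order == "filter_then_score":
            scored_net = net
        else:
            scored_net = threshold_edges(est, 0.0)
        if scored_net.number_of_edges() == 0:
            fit = None
        else:
            fit = scale_free_fit(scored_net, log_binning=log_binning)
        rows.append({"lambda": est.lam, "fit": np.nan if fit is None else fit,
                     "n_edges": net.number_of_edges()})
        if fit is not None and (best is None or fit > best[0]):
            best = (fit, est, net)
    trace = pd.DataFrame(rows)
    if best is None:
        raise ValueError("all candidates are edgeless after thresholding")
    return LambdaSelection(estimate=best[1], network=best[2], fit=best[0], trace=trace)


def consensus(
    member_networks: dict[str, nx.Graph], freq_threshold: float = 0.95
) -> ConsensusNetwork:
    """Frequency-based consensus over the leave-one-gene-out member networks.

    For an unordered pair (j, k), the eligible members are those whose node
    set contains both genes (n - 2 of n when every gene is held out once);
    the edge is retained when its occurrence frequency among eligible
    members reaches ``freq_threshold``. The consensus sign is the majority
    sign among occurrences (ties resolved by the largest-magnitude
    occurrence) and the weight is the mean |Omega| over occurrences.
    """
    if not member_networks:
        raise ValueError("need at least one member network")
    if not 0 < freq_threshold <= 1:
        raise ValueError("freq_threshold must be in (0, 1]")
    universe = sorted(set().union(*(g.nodes() for g in member_networks.values())))
    universe_set = set(universe)
    for held_out, g in member_networks.items():
        nodes = set(g.nodes())
        if held_out in nodes:
            raise ValueError(f"member for held-out gene {held_out!r} contains that gene")
        if nodes != universe_set - {held_out}:
            raise ValueError(f"member for {held_out!r} has a conflicting node set")

    node_sets = {h: set(g.nodes()) for h, g in member_networks.items()}
    occurrences: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for g in member_networks.values():
        for u, v, data in g.edges(data=True):
            key = (u, v) if u < v else (v, u)
            occurrences.setdefault(key, []).append((data["sign"], data["weight"]))

    out = nx.Graph()
    out.add_nodes_from(universe)
    for (u, v), occ in sorted(occurrences.items()):
        eligible = sum(1 for nodes in node_sets.values() if u in nodes and v in nodes)
        f = len(occ) / eligible
        if f < freq_threshold:
            continue
        signs = np.array([s for s, _ in occ])
        weights = np.array([w for _, w in occ])
        pos, neg = int((signs > 0).sum()), int((signs < 0).sum())
        if pos > neg:
            sign = 1
        elif neg > pos:
            sign = -1
        else:
            sign = int(signs[int(np.argmax(weights))])
        out.add_edge(u, v, weight=float(weights.mean()), sign=sign, frequency=float(f),
                     occurrences=len(occ), eligible=int(eligible))
    return ConsensusNetwork(graph=out, threshold=freq_threshold)


@dataclass
class NetworkInferenceResult:
    network: ConsensusNetwork
    member_networks: dict[str, nx.Graph]
    diagnostics: pd.DataFrame  # held-out gene, chosen lambda, fit, edge count


def shrink_to_pd(sigma: pd.DataFrame, floor: float = 1e-3) -> tuple[pd.DataFrame, float]:
    """Minimal shrinkage toward the identity to enforce positive definiteness.

    Sample partial-correlation matrices are singular whenever samples are
    fewer than genes, which empties the CLIME constraint set at small
    lambda. When the smallest eigenvalue is below ``floor`` the matrix is
    replaced by (sigma + r I) / (1 + r) with the smallest r that lifts the
    eigenvalue to the floor — the unit diagonal is preserved and the
    perturbation vanishes for well-conditioned input. Returns the (possibly
    unchanged) matrix and r.
    """
    eigmin = float(np.linalg.eigvalsh(sigma.to_numpy()).min())
    if eigmin >= floor:
        return sigma, 0.0
    r = (floor - eigmin) / (1.0 - floor)
    shrunk = (sigma + r * np.eye(sigma.shape[0])) / (1.0 + r)
    return pd.DataFrame(shrunk, index=sigma.index, columns=sigma.columns), r


def infer_network(
    expr: ExpressionMatrix,
    lambda_points: int = 20,
    lambda_min: float = 0.01,
    lambda_max: float = 1.0,
    edge_percentile: float = 10.0,
    consensus_freq: float = 0.95,
    score_order: str = "filter_then_score",
    backend: str = "simplex",
    shrinkage_floor: float | None = 1e-3,
    log_binning: bool = False,
) -> NetworkInferenceResult:
    """Full consensus-network inference for one condition / time point.

    Composes the leave-one-gene-out ensemble, per-member CLIME estimation
    across the lambda grid, scale-free lambda selection, percentile edge
    filtering and frequency consensus. Deterministic given input and
    settings. Singular member matrices are shrunk minimally toward the
    identity (see :func:`shrink_to_pd`); ``shrinkage_floor=None`` disables
    this and lets infeasible grid points drop out of selection instead.
    """
    ensemble = loo_partial_correlations(expr)
    grid = lambda_grid(lambda_points, lambda_min, lambda_max)
    member_networks: dict[str, nx.Graph] = {}
    diag_rows = []
    for held_out in ensemble.gene_ids:
        sigma = ensemble.members[held_out]
        shrink_r = 0.0
        if shrinkage_floor is not None:
            sigma, shrink_r = shrink_to_pd(sigma, shrinkage_floor)
        # Rank-deficient member matrices (fewer samples than genes) make the
        # constraint set empty below some lambda; those grid points admit no
        # estimate and are excluded from selection.
        candidates = []
        n_infeasible = 0
        for lam in grid:
            try:
                candidates.append(
                    clime_estimate(sigma, lam, backend=backend, held_out_gene=held_out)
                )
            except LpInfeasibleError:
                n_infeasible += 1
        if not candidates:
            raise ValueError(
                f"no feasible lambda for held-out gene {held_out!r}; "
                "the member matrix is too ill-conditioned"
            )
        try:
            sel = select_lambda(candidates, percentile=edge_percentile,
                                score_order=score_order, log_binning=log_binning)
        except ValueError as exc:
            raise ValueError(f"lambda selection failed for held-out gene {held_out!r}") from exc
        member_networks[held_out] = sel.network
        diag_rows.append({
            "held_out_gene": held_out,
            "lambda": sel.estimate.lam,
            "fit": sel.fit,
            "n_edges": sel.network.number_of_edges(),
            "feasibility_residual": sel.estimate.feasibility_residual,
            "n_infeasible_lambdas": n_infeasible,
            "shrinkage": shrink_r,
        })
    net = consensus(member_networks, freq_threshold=consensus_freq)
    return NetworkInferenceResult(
        network=net,
        member_networks=member_networks,
        diagnostics=pd.DataFrame(diag_rows),
    )
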