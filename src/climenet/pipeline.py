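"""End-to-end orchestration: simulate -> preprocess -> infer -> compare.

``run_pipeline`` executes the full workflow on synthetic data from a single
config: generate ground truth and Ct-encoded expression, run the qPCR
preprocessing chain per condition, infer one consensus network per
developmental stage plus the perturbation condition, rank connectivity
gainers/losers, test the perturbation lists against the developmental ones,
and write every artifact (networks in three dialects, delta tables, gene
lists, provenance JSON) to an output directory.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from . import connectivity as conn
from . import io as cio
from . import netinfer, preprocess, synthdata
from .config import RunConfig
from .datatypes import ExpressionMatrix, SyntheticTruth


def _derive_seed(seed: int, offset: int) -> int:
    return int(np.random.default_rng([seed, offset]).integers(2**31))


def simulate_dataset(config: RunConfig) -> tuple[SyntheticTruth, ExpressionMatrix]:
    """Ground truth plus simulated fold-ratio expression for every label."""
    truth = synthdata.gen_stage_truth(
        config.n_genes,
        stages=config.stages,
        n_rewire=config.n_rewire,
        graph_model=config.graph_model,
        seed=_derive_seed(config.seed, 1),
    )
    if config.with_perturbation:
        synthdata.add_reversion_condition(truth, seed=_derive_seed(config.seed, 2))
    expr = synthdata.simulate_expression(
        truth,
        n_per_stage=config.n_per_stage,
        noise_sd=config.noise_sd,
        seed=_derive_seed(config.seed, 3),
    )
    return truth, expr


def preprocess_condition(expr: ExpressionMatrix, config: RunConfig) -> ExpressionMatrix:
    """Outlier flagging, imputation and batch correction for one label."""
    mask = preprocess.flag_outliers(expr, mad_multiplier=config.mad_multiplier)
    k = min(config.impute_k, expr.n_genes - 1)
    cleaned = preprocess.knn_impute(expr, mask, k=k)
    if config.batch_correction and cleaned.samples["batch"].nunique() > 1:
        cleaned = preprocess.batch_correct(cleaned)
    return cleaned


def infer_stage_networks(expr: ExpressionMatrix, config: RunConfig) -> dict[str, netinfer.NetworkInferenceResult]:
    """One consensus network per stage/condition label in the expression data."""
    results = {}
    for label in expr.samples["stage"].unique():
        sub = expr.subset_samples((expr.samples["stage"] == label).to_numpy())
        cleaned = preprocess_condition(sub, config)
        results[label] = netinfer.infer_network(
            cleaned,
            lambda_points=config.lambda_points,
            lambda_min=config.lambda_min,
            lambda_max=config.lambda_max,
            edge_percentile=config.edge_percentile,
            consensus_freq=config.consensus_freq,
            score_order=config.score_order,
            backend=config.lp_backend,
            log_binning=config.log_binning,
        )
    return results


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages and write the artifact directory.

    Returns a summary dict (also written as provenance JSON).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth, expr_true = simulate_dataset(config)
    cio.write_truth(truth, out_dir / "truth.json")

    ct = synthdata.encode_ct(
        expr_true,
        intercept=config.ct_intercept,
        slope=config.ct_slope,
        detection_limit=config.ct_detection_limit,
        flag_rate=config.flag_rate,
        seed=_derive_seed(config.seed, 4),
    )
    cio.write_ct(ct, out_dir / "ct_table.tsv")

    filtered, dropped = preprocess.filter_probes(ct, config.max_bad_fraction)
    reference_gene = config.reference_gene or filtered.gene_ids[-1]
    calibrator_stage = config.calibrator_stage or config.stages[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # bad reference entries are handled by exclusion
        expr = preprocess.delta_delta_ct(filtered, reference_gene,
                                         {"stage": calibrator_stage})
    cio.write_expression(expr, out_dir / "expression.tsv")

    results = infer_stage_networks(expr, config)
    for label, res in results.items():
        cio.write_consensus(res.network, out_dir / "networks", f"network_{label}")
        res.diagnostics.to_csv(out_dir / "networks" / f"diagnostics_{label}.tsv",
                               sep="\t", index=False, lineterminator="\n")

    stage_labels = [s for s in config.stages if s in results]
    stage_nets = {s: results[s].network for s in stage_labels}
    deltas = conn.connectivity_change(stage_nets)
    conn.delta_table(deltas).to_csv(out_dir / "connectivity_deltas.tsv", sep="\t",
                                    lineterminator="\n")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # panels smaller than k are fine in demos
        dev_losers = conn.top_k_with_ties(deltas, config.top_k, "losers")
        dev_gainers = conn.top_k_with_ties(deltas, config.top_k, "gainers")
    cio.write_gene_list(dev_losers, out_dir / "developmental_losers.txt")
    cio.write_gene_list(dev_gainers, out_dir / "developmental_gainers.txt")

    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "dropped_probes": dropped,
        "reference_gene": reference_gene,
        "stages": {
            label: {
                "n_edges": res.network.n_edges,
                "lambdas": res.diagnostics["lambda"].tolist(),
            }
            for label, res in results.items()
        },
        "developmental_losers": dev_losers,
        "developmental_gainers": dev_gainers,
    }

    perturbed_labels = [lbl for lbl in results if lbl not in config.stages]
    if perturbed_labels and stage_labels:
        lbl = perturbed_labels[0]
        overlap = conn.perturbation_overlap(
            results[lbl].network, results[stage_labels[-1]].network,
            developmental_losers=dev_losers, developmental_gainers=dev_gainers,
            k=config.top_k, universe=len(expr.gene_ids),
        )
        cio.write_gene_list(overlap["losers"], out_dir / "perturbation_losers.txt")
        cio.write_gene_list(overlap["gainers"], out_dir / "perturbation_gainers.txt")
        summary["perturbation"] = {
            "label": lbl,
            "losers": overlap["losers"],
            "gainers": overlap["gainers"],
            "overlap_p": {f"{a}|{b}": {"overlap": o, "p": p}
                          for (a, b), (o, p) in overlap["overlap_p"].items()},
        }

    cio.write_provenance(summary, out_dir / "provenance.json")
    return summary
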