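"""From raw Ct tables to clean relative-expression matrices.

Implements the qPCR front end of the pipeline: probe filtering on
undetermined/flagged replicate fractions, delta-delta-Ct relative
quantification, robust outlier flagging, k-nearest-neighbour imputation,
empirical-Bayes batch correction, standard-curve quantification, and the
descriptive helpers (reference-relative transform, kernel density, skewness,
hypergeometric overlap, arcsine transform) used to characterise expression
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    STATUS_OK,
    CtTable,
    ExpressionMatrix,
    StandardCurve,
)


def _resolve_selector(samples: pd.DataFrame, selector) -> np.ndarray:
    """Turn a sample selector into a boolean mask over the metadata rows.

    Accepts a dict of metadata equality constraints ({"stage": "PND14"}), a
    list of sample ids, a boolean sequence, or a callable on the metadata.
    """
    if callable(selector):
        mask = np.asarray(selector(samples), dtype=bool)
    elif isinstance(selector, dict):
        mask = np.ones(len(samples), dtype=bool)
        for key, val in selector.items():
            mask &= (samples[key] == val).to_numpy()
    else:
        sel = list(selector)
        if sel and all(isinstance(s, (bool, np.bool_)) for s in sel):
            mask = np.asarray(sel, dtype=bool)
        else:
            mask = samples.index.isin(sel)
    if mask.shape != (len(samples),):
        raise ValueError("selector mask length does not match sample count")
    if not mask.any():
        raise ValueError("sample selector matched no samples")
    return mask


def filter_probes(ct: CtTable, max_bad_fraction: float = 0.5) -> tuple[CtTable, list[str]]:
    """Drop genes whose undetermined-or-flagged fraction reaches the cutoff.

    A gene is excluded when its fraction of bad replicates is greater than or
    equal to ``max_bad_fraction`` (default: half the replicates). Returns the
    filtered table and the list of dropped genes.
    """
    if not 0 < max_bad_fraction <= 1:
        raise ValueError("max_bad_fraction must be in (0, 1]")
    if ct.n_genes == 0 or ct.values.shape[1] == 0:
        raise ValueError("empty Ct table")
    bad = ct.bad_fraction()
    dropped = sorted(bad.index[bad >= max_bad_fraction])
    keep = bad.index[bad < max_bad_fraction]
    if len(keep) == 0:
        warnings.warn("all genes excluded by the probe filter", stacklevel=2)
    filtered = CtTable(ct.values.loc[keep].copy(), ct.status.loc[keep].copy(), ct.samples.copy())
    return filtered, dropped


def delta_delta_ct(ct: CtTable, reference_gene: str, calibrator_group) -> ExpressionMatrix:
    """Delta-delta-Ct relative quantification.

    Per sample, dCt = Ct(gene) - Ct(reference gene); relative expression is
    2^-(dCt - mean dCt over the calibrator group), so the calibrator group's
    geometric mean is 1 for every gene. Samples whose reference-gene entry is
    not ``ok`` are excluded with a warning; bad target entries become NaN for
    downstream imputation.
    """
    if reference_gene not in ct.values.index:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    ref_ok = (ct.status.loc[reference_gene] == STATUS_OK).to_numpy()
    if not ref_ok.all():
        excluded = list(ct.values.columns[~ref_ok])
        warnings.warn(
            f"excluding {len(excluded)} sample(s) with bad reference-gene entries: {excluded}",
            stacklevel=2,
        )
    cols = ct.values.columns[ref_ok]
    samples = ct.samples.loc[cols]
    values = ct.values[cols].where(ct.status[cols] == STATUS_OK)
    targets = values.drop(index=reference_gene)
    d_ct = targets.sub(values.loc[reference_gene], axis=1)
    cal_mask = _resolve_selector(samples, calibrator_group)
    cal_mean = d_ct.loc[:, cal_mask].mean(axis=1)
    if cal_mean.isna().any():
        bad = sorted(cal_mean.index[cal_mean.isna()])
        raise ValueError(f"calibrator group has no usable entries for genes: {bad}")
    dd_ct = d_ct.sub(cal_mean, axis=0)
    return ExpressionMatrix(2.0 ** (-dd_ct), samples.copy(), scale="ratio")


def flag_outliers(expr: ExpressionMatrix, mad_multiplier: float = 3.0) -> pd.DataFrame:
    """Flag entries deviating from the gene median by > multiplier * MAD.

    Works on log2 values with the raw (unscaled) median absolute deviation; a
    gene with zero MAD flags nothing. Existing NaNs are never flagged.
    Returns a boolean mask aligned with ``expr.values``.
    """
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples per gene to flag outliers")
    log2 = expr.log2_values()
    med = log2.median(axis=1)
    mad = (log2.sub(med, axis=0)).abs().median(axis=1)
    with np.errstate(invalid="ignore"):
        mask = log2.sub(med, axis=0).abs().gt(mad_multiplier * mad, axis=0)
    mask[log2.isna()] = False
    mask.loc[mad == 0] = False
    return mask


def knn_impute(expr: ExpressionMatrix, mask: pd.DataFrame | None = None, k: int = 10) -> ExpressionMatrix:
    """Impute masked/missing entries from the k nearest gene profiles.

    Distances are Euclidean over co-observed log2 entries between gene
    profiles; a masked entry is replaced by the mean of that sample's values
    over the k nearest genes. Observed entries are never altered.
    """
    from sklearn.impute import KNNImputer

    if k >= expr.n_genes:
        raise ValueError("k must be smaller than the number of genes")
    log2 = expr.log2_values()
    if mask is not None:
        log2 = log2.mask(mask)
    fully_missing = log2.isna().all(axis=1)
    if fully_missing.any():
        raise ValueError(
            f"gene(s) fully missing, cannot impute: {sorted(log2.index[fully_missing])}"
        )
    if not log2.isna().any().any():
        return expr.with_values(expr.values.copy())
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputed = pd.DataFrame(imputer.fit_transform(log2), index=log2.index, columns=log2.columns)
    # never touch observed entries (guard against library-side rescaling)
    imputed[~log2.isna()] = log2
    if expr.scale == "ratio":
        return expr.with_values(2.0**imputed, scale="ratio")
    return expr.with_values(imputed, scale="log2")


def _design_matrix(samples: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    parts = [np.ones((len(samples), 1))]
    for cov in covariates:
        levels = pd.unique(samples[cov])
        if len(levels) > 1:
            dummies = pd.get_dummies(samples[cov], drop_first=True).to_numpy(dtype=float)
            parts.append(dummies)
    return np.hstack(parts)


def batch_correct(
    expr: ExpressionMatrix,
    covariates: list[str] = ("stage", "condition"),
    preserve_grand_mean: bool = True,
    eb_iter_tol: float = 1e-8,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standardises each gene against a model retaining the biological
    covariates (developmental stage and condition by default), estimates
    per-batch location/scale effects, shrinks them toward cross-gene priors
    (normal prior for locations, inverse-gamma for scales, moment-matched),
    removes them, and restores the standardisation. With
    ``preserve_grand_mean`` each gene is re-centred to its pre-correction
    mean afterwards, a location-only touch-up making the per-gene grand mean
    exactly invariant.
    """
    samples = expr.samples
    batches = samples["batch"].astype(str)
    batch_levels = sorted(pd.unique(batches))
    if len(batch_levels) == 1:
        return expr.with_values(expr.values.copy())
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs at least 2 samples")

    covariates = [c for c in covariates if c in samples.columns]
    batch_dummies = pd.get_dummies(batches).loc[:, batch_levels].to_numpy(dtype=float)
    covar_design = _design_matrix(samples, covariates)[:, 1:]  # drop intercept
    # drop covariate columns that are linear combinations of earlier ones
    # (e.g. a condition determined by stage), keeping the design full rank
    kept: list[np.ndarray] = []
    base = np.ones((len(samples), 1))
    for col in covar_design.T:
        trial = np.hstack([base] + [c[:, None] for c in kept] + [col[:, None]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(col)
    covar_design = (np.column_stack(kept) if kept
                    else np.empty((len(samples), 0)))
    design = np.hstack([batch_dummies, covar_design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("batch is confounded with a biological covariate; effect unidentifiable")

    log2 = expr.log2_values()
    X = log2.to_numpy(dtype=float)  # genes x samples
    n_genes, n_samples = X.shape
    n_batch = len(batch_levels)
    batch_sizes = np.array([counts[b] for b in batch_levels], dtype=float)

    beta = np.linalg.solve(design.T @ design, design.T @ X.T)  # coeffs x genes
    grand_mean = (batch_sizes / n_samples) @ beta[:n_batch]  # per gene
    resid = X.T - design @ beta
    var_pooled = (resid**2).mean(axis=0)  # per gene
    if (var_pooled <= 0).any():
        raise ValueError("zero residual variance; batch model degenerate")

    stand_mean = grand_mean[None, :] + covar_design @ beta[n_batch:]
    Z = (X.T - stand_mean) / np.sqrt(var_pooled)[None, :]  # samples x genes

    Z_adj = Z.copy()
    for bi, b in enumerate(batch_levels):
        rows = (batches == b).to_numpy()
        n_b = rows.sum()
        gamma_hat = Z[rows].mean(axis=0)
        delta_hat = Z[rows].var(axis=0, ddof=1)
        # moment-matched hyperpriors (normal on gamma, inverse gamma on delta)
        gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        for _ in range(200):
            g_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (n_b * tau2 + delta_star)
            sum2 = ((Z[rows] - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior) / (n_b / 2 + a_prior - 1)
            change = max(np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max())
            gamma_star, delta_star = g_new, d_new
            if change < eb_iter_tol:
                break
        Z_adj[rows] = (Z[rows] - gamma_star[None, :]) / np.sqrt(delta_star)[None, :]

    X_adj = (Z_adj * np.sqrt(var_pooled)[None, :] + stand_mean).T
    if preserve_grand_mean:
        X_adj += (X.mean(axis=1) - X_adj.mean(axis=1))[:, None]
    corrected = pd.DataFrame(X_adj, index=log2.index, columns=log2.columns)
    if expr.scale == "ratio":
        return expr.with_values(2.0**corrected, scale="ratio")
    return expr.with_values(corrected, scale="log2")


def fit_standard_curve(dilution_points) -> StandardCurve:
    """Least-squares Ct-vs-log10(dilution) line from a serial dilution.

    ``dilution_points`` is a sequence of (dilution fraction, Ct); replicate
    Cts at the same dilution are averaged before fitting. The slope must be
    negative (template dilution delays amplification).
    """
    pts = pd.DataFrame(list(dilution_points), columns=["dilution", "ct"])
    if (pts["dilution"] <= 0).any():
        raise ValueError("dilution fractions must be positive")
    means = pts.groupby("dilution", sort=True)["ct"].mean()
    if len(means) < 3:
        raise ValueError("need at least 3 distinct dilution points")
    logd = np.log10(means.index.to_numpy(dtype=float))
    if logd.max() - logd.min() < 1.0:
        raise ValueError("dilution series must span at least one log10 unit")
    fit = stats.linregress(logd, means.to_numpy())
    if fit.slope >= 0:
        raise ValueError("standard curve slope must be negative (inverted curve)")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        dilution_points=[(float(d), float(c)) for d, c in means.items()],
    )


def standard_curve_quantify(curve_cts, sample_cts) -> tuple[StandardCurve, np.ndarray]:
    """Fit a relative standard curve and quantify sample Ct values against it."""
    curve = fit_standard_curve(curve_cts)
    return curve, curve.quantify(sample_cts)


def normalize_quantities(target, reference) -> np.ndarray:
    """Housekeeping normalisation: target / reference quantity, elementwise."""
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if (reference <= 0).any():
        raise ValueError("reference quantities must be positive")
    return target / reference


def relative_to_reference(
    expr: ExpressionMatrix, reference_group, mean_type: str = "arithmetic"
) -> pd.DataFrame:
    """Per-gene log2 ratios to the mean of a reference sample group.

    ``mean_type`` selects the arithmetic (default) or geometric mean of the
    reference samples on the ratio scale. Genes with a non-positive reference
    mean are dropped with a warning.
    """
    if mean_type not in ("arithmetic", "geometric"):
        raise ValueError("mean_type must be 'arithmetic' or 'geometric'")
    mask = _resolve_selector(expr.samples, reference_group)
    ratios = expr.values if expr.scale == "ratio" else 2.0**expr.values
    ref = ratios.loc[:, mask]
    if mean_type == "arithmetic":
        ref_mean = ref.mean(axis=1)
    else:
        ref_mean = 2.0 ** np.log2(ref).mean(axis=1)
    bad = ref_mean <= 0
    if bad.any():
        warnings.warn(f"dropping genes with non-positive reference mean: "
                      f"{sorted(ref_mean.index[bad])}", stacklevel=2)
    keep = ref_mean.index[~bad]
    return np.log2(ratios.loc[keep].div(ref_mean.loc[keep], axis=0))


def skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness g1 * sqrt(n(n-1))/(n-2).

    Returns NaN for a zero-variance sample (skewness undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        return float("nan")
    return float(stats.skew(x, bias=False))


@dataclass
class KdeResult:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float  # kernel standard deviation actually used


def kde_density(values, grid) -> KdeResult:
    """Gaussian kernel density with Silverman's-rule bandwidth on a grid."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: zero bandwidth")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.asarray(grid, dtype=float)
    return KdeResult(grid=grid, density=kde(grid), bandwidth=float(np.sqrt(kde.covariance[0, 0])))


def hypergeom_upper(overlap: int, set1: int, set2: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts the overlap when ``set2`` items are drawn without replacement
    from a universe containing ``set1`` marked items.
    """
    if min(overlap, set1, set2, universe) < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(set1, set2) or max(set1, set2) > universe:
        raise ValueError("inconsistent counts for hypergeometric test")
    return float(stats.hypergeom.sf(overlap - 1, universe, set1, set2))


def arcsine_transform(proportions) -> np.ndarray:
    """Variance-stabilising arcsin(sqrt(p)) transform of proportions, radians."""
    p = np.asarray(proportions, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))
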