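# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `climenet`, and what the synthetic-data tests do and do
not establish about behaviour on real data.

## Scope of the pipeline

The package covers the computational chain from raw qPCR quantification
cycles to consensus co-expression networks and their comparison:

1. Ct-table preprocessing (probe filtering, delta-delta-Ct, outlier
   flagging, k-NN imputation, batch correction);
2. consensus network inference per developmental stage or condition;
3. per-gene connectivity turnover across stages and under perturbation;
4. permutation testing of gene-set connectivity in an interaction network;
5. a synthetic-data generator providing ground truth for all of the above.

Descriptive helpers (reference-relative log2 ratios, kernel density,
adjusted skewness, hypergeometric overlap, arcsine transform,
standard-curve quantification) support the usual summaries around such an
analysis. Functional-enrichment calls on the resulting gene lists and
interaction-database retrieval are out of scope: the package produces
the plain-text gene lists and consumes user-supplied networks.

## Preprocessing

**Probe filter.** A gene is dropped when the fraction of its replicates
flagged `undetermined` or `flagged` is ≥ `max_bad_fraction` (default 0.5).
The rule is ≥, so exactly half bad is excluded. The filter is idempotent.

**Delta-delta-Ct.** Per sample, ΔCt = Ct(gene) − Ct(reference gene);
relative expression is 2^−(ΔCt − mean ΔCt over the calibrator group), so
the calibrator group's *geometric* mean is exactly 1 per gene. The
calibrator is a sample selector (default in the demo: the earliest
developmental stage); whether the original assays calibrated against a
single sample or a group mean is generally ambiguous in practice, and the
group mean is the stabler choice. Samples whose reference-gene entry is
not `ok` are excluded with a warning; bad target entries become NaN and
flow into imputation.

**Outliers.** There is no canonical definition of an expression outlier on
these panels; the package uses a robust, parameter-light rule: flag
entries more than `mad_multiplier` (default 3) raw median-absolute
-deviations from the gene's median on the log2 scale. A gene with zero MAD
flags nothing (degenerate rule, protects near-constant genes).

**Imputation.** Gene-wise k-nearest-neighbour imputation (default k = 10,
the convention for this approach): a missing entry is the mean of that
sample's values over the k genes whose profiles are nearest in Euclidean
distance on co-observed log2 entries. Implemented via
scikit-learn's `KNNImputer` on the genes-as-rows matrix; observed entries
are never altered (enforced, not assumed).

**Batch correction.** Parametric empirical-Bayes location/scale
adjustment per gene and batch: standardise each gene against a design
retaining stage and condition, estimate per-batch effects, shrink them
toward cross-gene moment-matched priors (normal for locations,
inverse-gamma for scales), remove, restore. A batch confounded 1:1 with a
biological covariate makes the design rank-deficient and raises. The
implementation matches the Bioconductor reference (`sva::ComBat`,
parametric variant) to ~1e-8 on shared inputs; a cross-check against it
runs in the test suite via Rscript. One deliberate addition:
`preserve_grand_mean` (default on) re-centres each gene to its
pre-correction mean afterwards. Canonical ComBat preserves per-gene means
only approximately; the re-centring is a location-only touch-up that makes
the invariant exact without affecting any variance or covariance
structure. The nonparametric ComBat variant is out of scope.

## Network inference

**Ensemble.** For n genes, n leave-one-gene-out matrices of first-order
partial correlations r_jk·i are formed from Pearson correlations of log2
expression. Each member conditions every pairwise association on one
held-out gene; the inverse of such a matrix carries the conditional
(graphical-model) structure of the remaining genes. Zero-variance genes
and perfectly collinear pairs are hard errors naming the offending gene.

**CLIME.** Each member Σ̂ is approximately inverted by constrained L1
minimisation: column b solves min ‖ω‖₁ s.t. ‖Σ̂ω − e_b‖∞ ≤ λ, a linear
program after positive/negative variable splitting. The default backend
is a numba-compiled tableau dual simplex specialised to this problem
(costs are all +1, so the all-slack basis is dual feasible; Bland's rule
guarantees finite termination on degenerate instances; constraint
tolerance 1e-8). scipy's HiGHS is available as `backend="highs"` and
serves as the independent oracle in tests — the two agree on per-column
L1 objectives to ~1e-15 on random instances. The final matrix is
symmetrised entrywise by keeping the smaller-magnitude of (Ω̂_jk, Ω̂_kj);
the recorded `feasibility_residual` is measured on the pre-symmetrisation
columns, where the bound residual ≤ λ + tolerance is guaranteed
(symmetrisation can break the columnwise constraint, so the bound is not
restated for the symmetrised matrix).

**Rank-deficient members.** With fewer samples than genes — the normal
regime for qPCR panels — member matrices are singular and the CLIME
constraint set is empty below a matrix-dependent λ. Two safeguards:
`clime_estimate` raises a specific infeasibility error, and
`infer_network` first applies minimal shrinkage toward the identity,
(Σ̂ + rI)/(1 + r) with the smallest r lifting the minimum eigenvalue to
`shrinkage_floor` (default 1e-3). The unit diagonal is preserved, the
perturbation vanishes for well-conditioned input, and the per-member r is
reported in the diagnostics. Reference implementations of CLIME likewise
perturb the diagonal by default. Setting `shrinkage_floor=None` instead
drops infeasible grid points from selection.

**λ selection.** Twenty equi-spaced λ values from 1 down to 0.01 are
estimated per member. Each candidate is thresholded, its degree
distribution p(k) over observed positive degrees is fit by least squares
in log10–log10 coordinates, and the candidate maximising R² wins; fewer
than 3 distinct positive degrees defines the fit as 0, and ties break
toward larger λ (parsimony). Whether filtering precedes scoring is
genuinely ambiguous in this family of procedures; the default is
filter-then-score, with `score_order="score_then_filter"` available.
Log-binned scoring is offered as an option but off by default.

**Edge filter and consensus.** Candidate edges are nonzero off-diagonal
entries; the cut is the linear-interpolation 10th percentile of the
nonzero absolute weights pooled over the whole matrix (per-column pooling
is a conceivable alternative; whole-matrix is the implemented reading),
with the retain rule ≥. Edge sign is sign(−Ω̂_jk), the standard
precision-to-partial-correlation convention. The consensus counts, for
each unordered pair, the members containing the edge against the members
*eligible* for the pair — a pair appears in n − 2 of the n leave-one-out
members — and retains edges with frequency ≥ 0.95. Consensus sign is the
majority sign among occurrences (ties: the largest-|weight| occurrence);
the weight is the mean |Ω̂| over occurrences.

**What the consensus does and does not filter.** Because all members
derive from one dataset, sampling-noise correlations recur in nearly every
member and can pass the 95% rule; the ensemble protects against artifacts
tied to a single controlling gene, not against sampling noise. On data
simulated from an edgeless truth the consensus is sparse but not empty
(~10% of possible pairs at 20 genes, n = 500). Interpreting consensus
edges on real data should account for this noise floor; the tests assert
the true property (null networks stay far sparser than structured ones)
rather than emptiness.

## Connectivity turnover

Connectivity is plain degree in the retained network. Gain/loss across
stages is the signed sum of degree differences over *every ordered pair*
of stages (three pairs for three stages); the per-pair breakdown is always
reported so alternative summaries can be recomputed. Genes absent from a
stage network count degree 0 — the panel's gene universe is fixed. Top-k
lists (default k = 20) include every gene tying the k-th value, with
lexicographic gene id as the deterministic secondary key. The
perturbation analysis differences the perturbed network against a
reference network and tests the tie-aware top lists against supplied
developmental gainer/loser lists by upper-tail hypergeometric probability.

## Permutation test

The observed statistic is the query gene's degree in the subnetwork
induced by {query} ∪ gene set. The null re-draws the gene set uniformly
without replacement from the network's genes (excluding the query and,
optionally, the original set) n_reps times (default 1,000). Two p-values
are reported: the raw exceedance proportion r/n, which can be exactly 0
when the observed value beats every replicate, and the bias-adjusted
(r + 1)/(n + 1), which cannot; the adjusted value is the recommended
summary. The null mean and SD accompany the observed value. Calibration:
with observed sets drawn from the null itself, adjusted p-values are
uniform up to the discreteness of the count statistic — on sparse
networks the statistic has few attainable values and *any* uniformity
check fails by construction, so the calibration test uses a dense network
where the statistic spreads over many values.

## Synthetic data

The generator realises exactly the assumptions the estimator makes, which
is what makes recovery testable: per stage, a precision matrix Ω with
support equal to a known graph (edge magnitudes uniform in [0.2, 0.8],
random sign, positive definiteness by strict diagonal dominance with the
common diagonal 1 + max absolute row sum, rescaled to unit diagonal);
log2 expression drawn from N(0, Ω⁻¹); per-batch additive shift and
multiplicative scale applied on the log2 scale (defaults: two instrument
batches, second batch +0.25 log2 units); exponentiation to fold-ratios;
optional Ct encoding Ct = 20 − log2(expression) + noise with a 35-cycle
detection limit and a configurable random flag rate (encoding defaults
are arbitrary but fixed). Stage graphs rewire by exactly `n_rewire`
deletions plus additions per transition, deletions biased into a planned
loser set and additions into a planned gainer set so that the planned
lists change strictly and connectivity recovery has a known answer; a
perturbation condition can be added whose graph reverts to the first
stage. Scale-free graphs are built as a preferential-attachment tree plus
degree-preferential extra edges (exact edge count); `n_edges` defaults to
4n/3. With `n_rewire=0` the stage graphs are identical and the planned
lists are empty.

What the generator does *not* emulate: amplification-efficiency
differences between probes beyond the linear standard-curve model,
non-Gaussian expression (the model is a Gaussian copula on the log
scale), count-like noise at the detection limit, correlated batch-by-gene
interactions, or real developmental timing. Passing recovery tests shows
the estimator works when its model holds; it does not certify performance
under model misspecification.

## Problem sizes and demonstration choices

The recovery benchmarks run at 30 genes / ~40 edges / 500 samples per
condition, where member matrices are well-conditioned; there the pipeline
recovers roughly a third to a half of planted edges at ~0.3–0.5 F1,
far above degree-matched random baselines (~0.1). The demo workflow
(`RunConfig` defaults, `climenet run`) uses 150 samples per condition:
at panel-realistic sizes (≈12 samples per stage) the 95% consensus is
near-empty on 30 genes, and 150 is the smallest round size at which the
demo networks are non-trivial end to end, Ct encoding and batch
correction included. The generator's own `simulate_expression` default
(12 per stage) reflects panel-scale studies. At demo scale the
perturbation-overlap p-values are typically non-significant: detecting
rewiring from differences of sparse consensus estimates has little power
at these sizes, and the connectivity machinery's recovery properties are
therefore demonstrated on ground-truth graphs in the test suite.

## Numerical conventions and edge cases

- λ grid descends from `lambda_max` to `lambda_min` inclusive; at λ = 1
  the all-zero matrix is the L1-minimal feasible solution for any
  correlation input, at λ ≥ small the identity case Σ = I yields
  (1 − λ)·I exactly.
- Percentiles use numpy's linear interpolation; retain rules are ≥
  everywhere (probe filter, edge filter, consensus frequency).
- Entries of Ω̂ below 1e-10 in magnitude are treated as exact zeros.
- Adjusted Fisher–Pearson skewness g1·√(n(n−1))/(n−2); zero-variance
  samples return NaN.
- Kernel density uses Silverman's-rule bandwidth; the realised kernel SD
  is returned alongside the curve. Constant samples raise (zero
  bandwidth).
- All generators and the pipeline are bit-reproducible under a fixed
  seed; derived seeds are spawned deterministically from the run seed.
- TSV is the canonical tabular dialect (tab-separated, '.' decimal,
  UTF-8, '#'-prefixed metadata rows); networks round-trip through SIF
  (`pp`/`pn` interaction labels by sign), GraphML (full attributes) and
  edge-list TSV.

## Known limitations

- The consensus noise floor described above: consensus frequency is not a
  false-discovery control.
- Scale-free R² on unbinned degrees is a coarse model-selection signal on
  small panels (often < 3 distinct degrees, where the fit is defined 0).
- The dual simplex solves tens of thousands of small LPs per run;
  wall-clock grows roughly with genes³ × λ-grid, so panels much beyond
  ~150 genes become slow on one core.
- The permutation test conditions on the supplied interaction network;
  its p-values say nothing about the quality or completeness of that
  network.
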