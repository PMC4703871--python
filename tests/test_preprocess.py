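"""qPCR preprocessing: probe filtering, delta-delta-Ct, outliers, imputation,
batch correction, standard curves and the descriptive statistics helpers."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_ct, make_expression

from climenet import preprocess, synthdata
from climenet.datatypes import (
    STATUS_FLAGGED,
    STATUS_OK,
    STATUS_UNDETERMINED,
    ExpressionMatrix,
    sample_meta,
)


class TestFilterProbes:
    def test_half_bad_replicates_is_excluded(self):
        status = np.full((2, 6), STATUS_OK, dtype=object)
        status[0, :3] = STATUS_UNDETERMINED  # exactly 50% bad -> excluded
        ct = make_ct(np.full((2, 6), 25.0), status)
        filtered, dropped = preprocess.filter_probes(ct)
        assert dropped == ["G001"]
        assert filtered.gene_ids == ["G002"]

    def test_all_ok_gene_retained(self):
        ct = make_ct(np.full((3, 4), 25.0))
        filtered, dropped = preprocess.filter_probes(ct)
        assert dropped == [] and filtered.n_genes == 3

    def test_retained_set_matches_counting_oracle(self, rng):
        n_genes, n_reps = 10, 8
        values = rng.uniform(15, 30, (n_genes, n_reps))
        status = np.full((n_genes, n_reps), STATUS_OK, dtype=object)
        bad_counts = rng.integers(0, n_reps + 1, n_genes)
        for i, k in enumerate(bad_counts):
            cols = rng.choice(n_reps, k, replace=False)
            for c in cols:
                status[i, c] = STATUS_FLAGGED if c % 2 else STATUS_UNDETERMINED
        ct = make_ct(values, status)
        filtered, dropped = preprocess.filter_probes(ct, 0.5)
        expected_keep = [f"G{i+1:03d}" for i in range(n_genes)
                        if bad_counts[i] / n_reps < 0.5]
        assert filtered.gene_ids == expected_keep
        assert len(dropped) == n_genes - len(expected_keep)

    def test_idempotent(self):
        status = np.full((4, 6), STATUS_OK, dtype=object)
        status[2, :4] = STATUS_UNDETERMINED
        ct = make_ct(np.full((4, 6), 25.0), status)
        once, _ = preprocess.filter_probes(ct)
        twice, dropped2 = preprocess.filter_probes(once)
        assert dropped2 == []
        assert once.values.equals(twice.values)

    def test_empty_table_raises_and_all_dropped_warns(self):
        ct = make_ct(np.full((2, 4), 25.0))
        empty = type(ct)(ct.values.iloc[:0], ct.status.iloc[:0], ct.samples)
        with pytest.raises(ValueError, match="empty"):
            preprocess.filter_probes(empty)
        allbad = make_ct(np.full((2, 4), 25.0),
                         np.full((2, 4), STATUS_UNDETERMINED, dtype=object))
        with pytest.warns(UserWarning, match="all genes"):
            filtered, dropped = preprocess.filter_probes(allbad)
        assert filtered.n_genes == 0 and len(dropped) == 2


class TestDeltaDeltaCt:
    def test_gene_tracking_reference_is_flat_at_one(self):
        values = np.vstack([np.arange(20.0, 26.0), np.arange(20.0, 26.0)])
        ct = make_ct(values)
        expr = preprocess.delta_delta_ct(ct, "G002", {"stage": "S1"})
        assert np.allclose(expr.values.loc["G001"], 1.0)

    def test_one_cycle_less_is_twofold(self):
        # target one cycle below reference in sample 2, equal in calibrator
        values = np.array([[24.0, 23.0], [24.0, 24.0]])
        ct = make_ct(values)
        expr = preprocess.delta_delta_ct(ct, "G002", ["S001"])
        assert expr.values.loc["G001", "S002"] == pytest.approx(2.0)

    def test_matches_hand_computed_oracle(self, rng):
        values = rng.uniform(18, 30, (4, 6))
        ct = make_ct(values)
        cal = ["S001", "S002"]
        expr = preprocess.delta_delta_ct(ct, "G004", cal)
        for gi, gene in enumerate(["G001", "G002", "G003"]):
            d_ct = values[gi] - values[3]
            dd_ct = d_ct - d_ct[:2].mean()
            np.testing.assert_allclose(expr.values.loc[gene], 2.0 ** (-dd_ct),
                                       rtol=0, atol=1e-12)

    def test_calibrator_geometric_mean_is_one(self, rng):
        values = rng.uniform(18, 30, (5, 8))
        ct = make_ct(values)
        expr = preprocess.delta_delta_ct(ct, "G005", {"stage": "S1"})
        geo = np.exp(np.log(expr.values).mean(axis=1))
        np.testing.assert_allclose(geo, 1.0, atol=1e-12)

    def test_bad_reference_entry_excludes_sample(self):
        values = np.full((3, 4), 24.0)
        status = np.full((3, 4), STATUS_OK, dtype=object)
        status[2, 1] = STATUS_UNDETERMINED
        ct = make_ct(values, status)
        with pytest.warns(UserWarning, match="excluding 1 sample"):
            expr = preprocess.delta_delta_ct(ct, "G003", ["S001"])
        assert list(expr.values.columns) == ["S001", "S003", "S004"]


class TestOutliersAndImputation:
    def test_constant_gene_flags_nothing(self):
        expr = make_expression(np.ones((2, 6)))
        mask = preprocess.flag_outliers(expr)
        assert not mask.values.any()

    def test_hundredfold_spike_is_flagged(self, rng):
        base = rng.uniform(0.9, 1.1, (1, 10))
        base[0, 4] = 100.0
        expr = make_expression(base)
        mask = preprocess.flag_outliers(expr, 3)
        assert mask.iloc[0, 4]
        assert mask.values.sum() == 1

    def test_infinite_multiplier_flags_nothing(self, rng):
        expr = make_expression(rng.uniform(0.5, 2.0, (4, 8)))
        assert not preprocess.flag_outliers(expr, np.inf).values.any()

    def test_impute_without_missing_is_identity(self, rng):
        expr = make_expression(rng.uniform(0.5, 2.0, (6, 5)))
        out = preprocess.knn_impute(expr, k=2)
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_imputed_value_matches_brute_force_neighbour_oracle(self, rng):
        values = rng.uniform(-2, 2, (6, 5))
        expr = make_expression(values, scale="log2")
        mask = pd.DataFrame(False, index=expr.values.index, columns=expr.values.columns)
        mask.iloc[0, 2] = True
        out = preprocess.knn_impute(expr, mask, k=2)
        # brute force: rank genes 1..5 by Euclidean distance to gene 0 over
        # the columns where gene 0 is observed
        obs_cols = [0, 1, 3, 4]
        dists = [np.linalg.norm(values[g, obs_cols] - values[0, obs_cols])
                 for g in range(1, 6)]
        nearest = np.argsort(dists, kind="stable")[:2] + 1
        expected = values[nearest, 2].mean()
        assert out.values.iloc[0, 2] == pytest.approx(expected, abs=1e-10)

    def test_observed_entries_never_altered(self, rng):
        values = rng.uniform(0.5, 2.0, (8, 6))
        expr = make_expression(values)
        mask = pd.DataFrame(False, index=expr.values.index, columns=expr.values.columns)
        mask.iloc[1, 1] = True
        mask.iloc[4, 3] = True
        out = preprocess.knn_impute(expr, mask, k=3)
        untouched = ~mask.values
        np.testing.assert_allclose(out.values.values[untouched],
                                   expr.values.values[untouched], rtol=1e-12)

    def test_fully_missing_gene_raises(self, rng):
        expr = make_expression(rng.uniform(0.5, 2.0, (5, 4)))
        mask = pd.DataFrame(False, index=expr.values.index, columns=expr.values.columns)
        mask.iloc[2, :] = True
        with pytest.raises(ValueError, match="fully missing"):
            preprocess.knn_impute(expr, mask, k=2)


def _two_batch_expression(rng, n_genes=20, n_per_batch=15, shift=1.0):
    """Two batches per stage with an injected additive log2 shift."""
    n = 2 * n_per_batch
    x = rng.normal(0.0, 1.0, (n_genes, n))
    stage = ["A"] * n_per_batch + ["B"] * n_per_batch
    # batches interleave stages so batch is not confounded with stage
    batch = (["b1", "b2"] * n_per_batch)[:n]
    x[:, np.array(batch) == "b2"] += shift
    cols = [f"S{i:03d}" for i in range(n)]
    frame = pd.DataFrame(x, index=[f"G{i:03d}" for i in range(n_genes)], columns=cols)
    return ExpressionMatrix(frame, sample_meta(cols, stage, batch), scale="log2")


class TestBatchCorrect:
    def test_single_batch_is_identity(self, rng):
        expr = make_expression(rng.uniform(0.5, 2.0, (5, 8)))
        out = preprocess.batch_correct(expr)
        np.testing.assert_allclose(out.values, expr.values, atol=1e-8)

    def test_additive_shift_removed(self, rng):
        expr = _two_batch_expression(rng, shift=1.5)
        out = preprocess.batch_correct(expr)
        vals = out.values.to_numpy()
        b2 = (expr.samples["batch"] == "b2").to_numpy()
        for g in range(vals.shape[0]):
            d = vals[g, b2].mean() - vals[g, ~b2].mean()
            se = np.sqrt(vals[g, b2].var(ddof=1) / b2.sum()
                         + vals[g, ~b2].var(ddof=1) / (~b2).sum())
            assert abs(d) < 3 * se

    def test_per_gene_grand_mean_preserved(self, rng):
        expr = _two_batch_expression(rng)
        out = preprocess.batch_correct(expr)
        np.testing.assert_allclose(out.values.mean(axis=1), expr.values.mean(axis=1),
                                   atol=1e-6)

    def test_batch_f_statistic_reduced_for_every_gene(self, rng):
        expr = _two_batch_expression(rng, shift=2.0)
        out = preprocess.batch_correct(expr)
        b2 = (expr.samples["batch"] == "b2").to_numpy()

        def fstat(vals):
            return stats.f_oneway(vals[b2], vals[~b2]).statistic

        for g in range(expr.n_genes):
            assert fstat(out.values.to_numpy()[g]) < fstat(expr.values.to_numpy()[g])

    def test_condition_determined_by_stage_is_tolerated(self, rng):
        # 'condition' is an exact function of 'stage' (the perturbation arm):
        # the redundant covariate column must be pruned, not reported as
        # batch confounding
        expr = _two_batch_expression(rng, shift=1.0)
        cond = ["control" if s == "A" else "overexpression"
                for s in expr.samples["stage"]]
        samples = expr.samples.copy()
        samples["condition"] = cond
        expr = ExpressionMatrix(expr.values, samples, scale="log2")
        out = preprocess.batch_correct(expr)
        b2 = (expr.samples["batch"] == "b2").to_numpy()
        gaps = out.values.to_numpy()[:, b2].mean(axis=1) - \
            out.values.to_numpy()[:, ~b2].mean(axis=1)
        raw_gaps = expr.values.to_numpy()[:, b2].mean(axis=1) - \
            expr.values.to_numpy()[:, ~b2].mean(axis=1)
        # the injected 1.0-unit shift is largely removed (EB shrinkage leaves
        # per-gene residuals at this sample size)
        assert np.abs(gaps).mean() < 0.3 * np.abs(raw_gaps).mean()

    def test_confounded_batch_raises(self, rng):
        n = 12
        x = rng.normal(0, 1, (5, n))
        stage = ["A"] * 6 + ["B"] * 6
        batch = ["b1"] * 6 + ["b2"] * 6  # 1:1 with stage
        cols = [f"S{i}" for i in range(n)]
        expr = ExpressionMatrix(pd.DataFrame(x, columns=cols),
                                sample_meta(cols, stage, batch), scale="log2")
        with pytest.raises(ValueError, match="confounded"):
            preprocess.batch_correct(expr)

    def test_matches_r_sva_combat_oracle(self, rng, tmp_path):
        """Independent cross-check against the Bioconductor reference."""
        if subprocess.run(["Rscript", "-e", "library(sva)"],
                          capture_output=True).returncode != 0:
            pytest.skip("R sva not available")
        expr = _two_batch_expression(rng, n_genes=12, n_per_batch=10)
        xp = tmp_path / "x.tsv"
        mp = tmp_path / "meta.tsv"
        op = tmp_path / "out.tsv"
        expr.values.to_csv(xp, sep="\t")
        expr.samples[["stage", "batch"]].to_csv(mp, sep="\t", index=False)
        script = tmp_path / "combat.R"
        script.write_text(
            "suppressMessages(library(sva))\n"
            "args <- commandArgs(trailingOnly=TRUE)\n"
            "x <- as.matrix(read.table(args[1], sep='\\t', header=TRUE, row.names=1))\n"
            "meta <- read.table(args[2], sep='\\t', header=TRUE)\n"
            "mod <- model.matrix(~stage, data=meta)\n"
            "out <- ComBat(dat=x, batch=meta$batch, mod=mod, par.prior=TRUE)\n"
            "write.table(out, args[3], sep='\\t', quote=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script), str(xp), str(mp), str(op)],
                       check=True, capture_output=True)
        r_out = pd.read_csv(op, sep="\t", index_col=0)
        ours = preprocess.batch_correct(expr, preserve_grand_mean=False)
        assert np.abs(ours.values.to_numpy() - r_out.to_numpy()).max() < 1e-5


class TestStandardCurve:
    def test_perfect_efficiency_series_recovers_dilutions(self):
        dilutions = np.array([0.5, 0.1, 0.02, 0.004, 0.002])
        slope, intercept = -3.32, 24.0
        cts = intercept + slope * np.log10(dilutions)
        curve, quantities = preprocess.standard_curve_quantify(
            list(zip(dilutions, cts)), cts
        )
        np.testing.assert_allclose(quantities, dilutions, rtol=1e-9)
        assert curve.slope == pytest.approx(slope)

    def test_noiseless_r_squared_is_one(self):
        dilutions = np.array([0.5, 0.05, 0.005])
        cts = 22.0 - 3.1 * np.log10(dilutions)  # positive slope? no: minus
        curve = preprocess.fit_standard_curve(list(zip(dilutions, 22.0 + -3.1 * np.log10(dilutions))))
        assert curve.r_squared == pytest.approx(1.0)

    def test_duplicate_ct_at_one_dilution_uses_mean(self):
        dilutions = [0.5, 0.5, 0.05, 0.005]
        cts = [20.0, 21.0, 24.0, 27.4]
        curve = preprocess.fit_standard_curve(list(zip(dilutions, cts)))
        ref = preprocess.fit_standard_curve([(0.5, 20.5), (0.05, 24.0), (0.005, 27.4)])
        assert curve.slope == pytest.approx(ref.slope)
        assert curve.intercept == pytest.approx(ref.intercept)

    def test_inverted_curve_rejected(self):
        dilutions = [0.5, 0.05, 0.005]
        cts = [27.0, 24.0, 20.0]  # Ct increasing with template: inverted
        with pytest.raises(ValueError, match="slope"):
            preprocess.fit_standard_curve(list(zip(dilutions, cts)))

    def test_narrow_series_rejected(self):
        with pytest.raises(ValueError, match="log10"):
            preprocess.fit_standard_curve([(0.5, 20.0), (0.4, 20.3), (0.3, 20.7)])


class TestDescriptiveHelpers:
    def test_reference_samples_have_zero_mean_log_ratio(self, rng):
        expr = make_expression(rng.uniform(0.5, 2.0, (5, 9)),
                               stage=["LJ"] * 3 + ["EJ"] * 6)
        ratios = preprocess.relative_to_reference(expr, {"stage": "LJ"})
        ref_cols = ratios.columns[:3]
        np.testing.assert_allclose((2.0 ** ratios[ref_cols]).mean(axis=1), 1.0,
                                   atol=1e-12)

    def test_doubled_gene_reports_plus_one(self):
        values = np.array([[1.0, 1.0, 2.0]])
        expr = make_expression(values, stage=["ref", "ref", "test"])
        ratios = preprocess.relative_to_reference(expr, {"stage": "ref"})
        assert ratios.iloc[0, 2] == pytest.approx(1.0)

    def test_matches_hand_division_oracle(self, rng):
        values = rng.uniform(0.5, 2.0, (4, 6))
        expr = make_expression(values, stage=["r", "r", "r", "t", "t", "t"])
        ratios = preprocess.relative_to_reference(expr, {"stage": "r"})
        expected = np.log2(values / values[:, :3].mean(axis=1, keepdims=True))
        np.testing.assert_allclose(ratios.to_numpy(), expected, atol=1e-12)

    def test_geometric_mean_option(self, rng):
        values = rng.uniform(0.5, 2.0, (3, 4))
        expr = make_expression(values, stage=["r", "r", "t", "t"])
        ratios = preprocess.relative_to_reference(expr, {"stage": "r"}, "geometric")
        geo = 2.0 ** (np.log2(values[:, :2]).mean(axis=1, keepdims=True))
        np.testing.assert_allclose(ratios.to_numpy(), np.log2(values / geo), atol=1e-12)

    def test_skewness_symmetric_sample_is_zero(self):
        assert preprocess.skewness([-2, -1, 0, 1, 2]) == pytest.approx(0.0)

    def test_skewness_matches_moment_formula(self):
        x = np.array([0.0, 0.0, 0.0, 1.0])
        n = len(x)
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        g1 = m3 / m2**1.5
        expected = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        assert preprocess.skewness(x) == pytest.approx(expected, rel=1e-12)

    def test_skewness_antisymmetry_and_degenerate(self, rng):
        x = rng.normal(0, 1, 50)
        assert preprocess.skewness(-x) == pytest.approx(-preprocess.skewness(x))
        assert np.isnan(preprocess.skewness([1.0, 1.0, 1.0]))

    def test_kde_integrates_to_one_with_mode_near_zero(self, rng):
        x = rng.normal(0, 1, 2000)
        grid = np.linspace(-6, 6, 2001)
        res = preprocess.kde_density(x, grid)
        assert np.trapezoid(res.density, grid) == pytest.approx(1.0, abs=1e-3)
        assert abs(grid[np.argmax(res.density)]) < 0.3
        assert (res.density >= 0).all()

    def test_kde_two_point_sample_matches_analytic_kernel_sum(self):
        x = np.array([-1.0, 1.0])
        grid = np.linspace(-4, 4, 101)
        res = preprocess.kde_density(x, grid)
        h = res.bandwidth
        expected = 0.5 * (stats.norm.pdf(grid, -1, h) + stats.norm.pdf(grid, 1, h))
        np.testing.assert_allclose(res.density, expected, atol=1e-12)

    def test_kde_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            preprocess.kde_density([2.0, 2.0, 2.0], np.linspace(0, 4, 10))

    def test_hypergeom_trivial_cases(self):
        assert preprocess.hypergeom_upper(0, 10, 20, 100) == pytest.approx(1.0)
        assert preprocess.hypergeom_upper(10, 10, 10, 10) == pytest.approx(1.0)

    def test_hypergeom_matches_exhaustive_tail_sum(self):
        from math import comb

        overlap, s1, s2, universe = 5, 10, 20, 100
        tail = sum(comb(s1, k) * comb(universe - s1, s2 - k) for k in range(overlap, s1 + 1))
        expected = tail / comb(universe, s2)
        assert preprocess.hypergeom_upper(overlap, s1, s2, universe) == pytest.approx(
            expected, abs=1e-12
        )

    def test_hypergeom_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            preprocess.hypergeom_upper(11, 10, 20, 100)
        with pytest.raises(ValueError):
            preprocess.hypergeom_upper(1, 10, 200, 100)

    def test_arcsine_closed_forms(self):
        out = preprocess.arcsine_transform([0.0, 0.5, 1.0])
        np.testing.assert_allclose(out, [0.0, np.pi / 4, np.pi / 2], atol=1e-15)
        with pytest.raises(ValueError):
            preprocess.arcsine_transform([1.2])


class TestRoundTripWithEncoder:
    def test_zero_noise_round_trip_recovers_fold_ratios(self):
        """encode_ct -> delta_delta_ct at slope -1, zero noise is exact."""
        truth = synthdata.gen_stage_truth(8, n_rewire=1, seed=21)
        expr = synthdata.simulate_expression(truth, 6, seed=22)
        ct = synthdata.encode_ct(expr, intercept=20.0, slope=-1.0,
                                 detection_limit=np.inf, flag_rate=0.0, seed=0)
        ref = expr.gene_ids[-1]
        cal = {"stage": truth.stages[0]}
        decoded = preprocess.delta_delta_ct(ct, ref, cal)
        x = expr.values
        rel = x.drop(index=ref).div(x.loc[ref], axis=1)
        cal_mask = (expr.samples["stage"] == truth.stages[0]).to_numpy()
        geo = np.exp(np.log(rel.loc[:, cal_mask]).mean(axis=1))
        expected = rel.div(geo, axis=0)
        np.testing.assert_allclose(decoded.values.to_numpy(), expected.to_numpy(),
                                   rtol=1e-10)
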