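import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socexp import (
    ExpressionMatrix,
    attractor_field,
    between_state_sampling,
    cm_approximation,
    correlation_series,
    detect_focal_point,
    group_by_key,
    minimal_ensemble_scan,
    scaled_correlation,
)


class TestScaledCorrelation:
    def test_identical_vectors_give_one(self):
        v = np.array([1.0, 2.0, 3.5, 0.2])
        assert scaled_correlation(v, v, "none") == pytest.approx(1.0)
        assert scaled_correlation(v, v, "cm_group") == pytest.approx(1.0)
        assert scaled_correlation(v, v, "cm_whole", r1=1.0, rk=1.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_cm_group_equals_product_moment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, rng.integers(3, 80)))
        assert scaled_correlation(a, b, "cm_group") == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_independent_groups_fluctuate_around_zero(self, synth):
        grouping, _ = group_by_key(synth.fluct, synth.matrix, "nrmsf_desc", 440)
        j = synth.matrix.index_of_time(10)
        x1 = synth.matrix.subset(grouping.members(1)).values[:, j]
        vals = []
        for g in range(5, 45, 5):
            xg = synth.matrix.subset(grouping.members(g)).values[:, j]
            vals.append(scaled_correlation(x1, xg, "cm_group"))
        assert np.abs(np.mean(vals)) < 0.1

    def test_zero_denominator_nan(self):
        assert np.isnan(scaled_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "cm_group"))

    def test_cm_whole_requires_references(self):
        with pytest.raises(ValueError):
            scaled_correlation([1.0, 2.0], [3.0, 4.0], "cm_whole")


class TestCorrelationSeries:
    def test_time_invariant_matrix(self):
        vals = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        m = ExpressionMatrix(["a", "b", "c"], [0, 10, 15, 20], vals, "natural_log")
        s = correlation_series(m, None, "P(t0;tj)")
        assert np.allclose(s.values, 1.0)
        sc = correlation_series(m, None, "P(tj;tj+1-tj)")
        assert np.all(np.isnan(sc.values))

    def test_initial_value_is_one(self, synth_small):
        s = correlation_series(synth_small.matrix, None, "P(t0;tj)")
        assert s.values[0] == pytest.approx(1.0)
        assert np.nanmax(np.abs(s.values)) <= 1.0 + 1e-12

    def test_memoryless_changes_forget_initial_step(self, synth):
        genes = synth.truth.genes
        hes = genes.index[(genes.state == "sub") & (genes.component == "HES")].tolist()
        s = correlation_series(synth.matrix, hes, "P(t1-t0;tj+1-tj)")
        assert np.abs(s.values[2:]).max() < 0.1
        assert s.values[0] == pytest.approx(1.0)

    def test_gene_permutation_invariance(self, synth_small):
        ids = list(synth_small.matrix.gene_ids)
        rng = np.random.default_rng(0)
        perm = [ids[i] for i in rng.permutation(len(ids))]
        s1 = correlation_series(synth_small.matrix, ids, "P(tj;tj+1)")
        s2 = correlation_series(synth_small.matrix, perm, "P(tj;tj+1)")
        assert np.allclose(s1.values, s2.values, atol=1e-12)

    def test_unknown_series_rejected(self, synth_small):
        with pytest.raises(ValueError, match="unknown series"):
            correlation_series(synth_small.matrix, None, "bogus")


class TestCMApproximation:
    def test_two_gene_toy_matches_hand_norms(self):
        vals = np.array([[1.0, 2.0, 1.5], [3.0, 2.5, 3.5]])
        m = ExpressionMatrix(["a", "b"], [0, 10, 15], vals, "natural_log")
        cm = cm_approximation(m, None)
        x = vals
        dev0 = x[:, 0] - x[:, 0].mean()
        n0 = np.sqrt((dev0**2).sum())
        d0 = x[:, 1] - x[:, 0]
        nd0 = np.sqrt(((d0 - d0.mean()) ** 2).sum())
        assert cm.norms[0] == pytest.approx(n0)
        assert cm.lambda_j[0] == pytest.approx(n0 / nd0)
        assert cm.gamma_j[0] == pytest.approx(cm.norms[1] / cm.norms[0])

    def test_exact_series_is_pearson_oracle(self, synth):
        sub = synth.partition.genes("sub")
        cm = cm_approximation(synth.matrix, sub)
        x = synth.matrix.subset(sub).values
        j = 4
        expected = np.corrcoef(x[:, j], x[:, j + 1] - x[:, j])[0, 1]
        assert cm.exact[j] == pytest.approx(expected, abs=1e-12)

    def test_approximation_tracks_exact_series(self, synth):
        cm = cm_approximation(synth.matrix, synth.partition.genes("sub"))
        assert np.corrcoef(cm.exact, cm.approx)[0, 1] > 0.9
        assert cm.alpha > 0

    def test_eq3_identity_on_coherent_ensemble(self, synth):
        """gamma_j P(t0;t_{j+1}) - P(t0;t_j) ~ alpha (<x(t_j)> - <x(t_{j+1})>)."""
        sub = synth.partition.genes("sub")
        cm = cm_approximation(synth.matrix, sub)
        p0 = correlation_series(synth.matrix, sub, "P(t0;tj)").values
        lhs = cm.gamma_j * p0[1:] - p0[:-1]
        rhs = cm.alpha * (cm.cm[:-1] - cm.cm[1:])
        assert np.corrcoef(lhs, rhs)[0, 1] > 0.99
        assert np.abs(lhs - rhs).max() < 0.05

    def test_zero_norm_errors(self):
        vals = np.ones((3, 3))
        m = ExpressionMatrix(["a", "b", "c"], [0, 10, 15], vals, "natural_log")
        with pytest.raises(ValueError, match="zero deviation norm"):
            cm_approximation(m, None)

    def test_distance_shrinks_with_oscillation_amplitude(self):
        from socexp import SyntheticConfig, generate_expression, compute_rmsf, partition_states

        rel = []
        for amp in (0.2, 0.9):
            cfg = SyntheticConfig(n_genes=4000, seed=9)
            cfg.osc_var_fraction = {"super": 0.7, "near": 0.05, "sub": amp}
            m, _ = generate_expression(cfg)
            part = partition_states(compute_rmsf(m))
            cm = cm_approximation(m, part.genes("sub"))
            rel.append(cm.fit_distance / np.linalg.norm(cm.exact))
        assert rel[1] < rel[0]


class TestFocalPoint:
    def test_found_on_default_synthetic(self, synth):
        grouping, traj = group_by_key(synth.fluct, synth.matrix, "nrmsf_desc", 440)
        fp = detect_focal_point(synth.matrix, grouping, traj, [0, 10, 15, 20])
        assert fp.found
        assert traj.cm_nrmsf.min() <= fp.nrmsf_fp <= traj.cm_nrmsf.max()
        assert fp.curves.shape == (4, grouping.k)

    def test_time_invariant_matrix_has_no_fp(self):
        rng = np.random.default_rng(0)
        col = rng.normal(2.0, 1.0, 400)
        vals = np.tile(col[:, None], (1, 4))
        m = ExpressionMatrix([f"g{i}" for i in range(400)], [0, 10, 15, 20], vals, "natural_log")
        from socexp import compute_rmsf

        fl = compute_rmsf(m)
        grouping, traj = group_by_key(fl, m, "nrmsf_desc", 40)
        fp = detect_focal_point(m, grouping, traj, [0, 10, 15])
        assert not fp.found

    def test_needs_three_times(self, synth_small):
        grouping, traj = group_by_key(synth_small.fluct, synth_small.matrix, "nrmsf_desc", 200)
        with pytest.raises(ValueError):
            detect_focal_point(synth_small.matrix, grouping, traj, [0, 10])


class TestEnsembleScan:
    def test_full_size_sd_exactly_zero(self, synth_small):
        sub = synth_small.partition.genes("sub")
        scan = minimal_ensemble_scan(synth_small.matrix, sub, [20, len(sub)], repeats=20, seed=3)
        # sampling the whole set: every repeat is the same ensemble
        assert np.all(scan.delta_sd[-1] == 0.0)
        assert np.all(scan.d0_sd[-1] < 1e-12)

    def test_sd_decreases_with_ensemble_size(self, synth):
        sub = synth.partition.genes("sub")
        scan = minimal_ensemble_scan(synth.matrix, sub, [10, 50, 400], repeats=100, seed=3)
        pooled = scan.delta_sd[:, 1:4].mean(axis=1)
        assert pooled[0] > pooled[1] > pooled[2]
        assert scan.scaling["delta_P"]["exponent"] > 0

    def test_oversized_request_errors(self, synth_small):
        with pytest.raises(ValueError):
            minimal_ensemble_scan(synth_small.matrix, ["g000001", "g000002"], [5], repeats=2, seed=0)


class TestBetweenStateSampling:
    def test_identical_states_give_plus_one(self, synth_small):
        part = synth_small.partition
        same = part.states.copy()
        from socexp.criticality import CriticalPartition

        p = CriticalPartition(same)
        out = between_state_sampling(synth_small.matrix, p, "sub", "sub", m=len(part.genes("sub")), repeats=3, seed=0)
        assert out["cm_change_corr_mean"] == pytest.approx(1.0)

    def test_antiphase_states_strongly_negative(self, synth):
        out = between_state_sampling(synth.matrix, synth.partition, "super", "sub", m=100, repeats=50, seed=2)
        assert out["cm_change_corr_mean"] < -0.9

    def test_convergence_distance_shrinks(self, synth):
        out = between_state_sampling(
            synth.matrix, synth.partition, "super", "sub", m=50, repeats=30, seed=2, convergence_sizes=[10, 200]
        )
        conv = out["convergence"]
        assert conv.distance.iloc[1] < conv.distance.iloc[0]


class TestAttractorField:
    def test_same_column_perfect_correlation(self, synth_small):
        af = attractor_field(synth_small.matrix, 10, 10)
        assert af.r == 1.0
        assert np.allclose(af.dx, 0.0)

    def test_profile_invariance_high_r(self, synth):
        af = attractor_field(synth.matrix, 10, 15)
        assert af.r >= 0.95
        xs, ys = af.standardized()
        resid = ys - af.r * xs
        assert np.abs(resid.mean()) < 1e-8

    def test_dy_none_at_last_time(self, synth_small):
        times = synth_small.matrix.times
        af = attractor_field(synth_small.matrix, times[-2], times[-1])
        assert af.dy is None
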