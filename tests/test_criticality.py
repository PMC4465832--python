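import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socexp import (
    ExpressionMatrix,
    fit_power_law,
    modality_scan,
    modality_sequence,
    partition_states,
    regulatory_density,
    sandpile_cp,
    sarle_b,
)
from socexp.criticality import fit_power_law_deab
from socexp.fluctuation import compute_rmsf, FluctuationTable
import pandas as pd


def sarle_moment_oracle(x):
    """Direct-moment Sarle b: population skewness/kurtosis + finite-sample term."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    m3 = ((x - mu) ** 3).mean()
    m4 = ((x - mu) ** 4).mean()
    g1 = m3 / m2**1.5
    g2 = m4 / m2**2 - 3.0
    return (g1**2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


class TestSarleB:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_moment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(5, 200))
        rep = sarle_b(x)
        assert rep.b == pytest.approx(sarle_moment_oracle(x), abs=1e-12)

    def test_gaussian_limit_one_third(self):
        x = np.random.default_rng(1).normal(size=200_000)
        assert sarle_b(x).b == pytest.approx(1 / 3, abs=0.01)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            sarle_b([2.0, 2.0, 2.0, 2.0])

    def test_small_sample_errors(self):
        with pytest.raises(ValueError, match="n >= 4"):
            sarle_b([1.0, 2.0, 3.0])

    @pytest.mark.parametrize(
        "b,expected",
        [(0.70, "bimodal"), (0.49, "flattened"), (0.45, "flattened"), (0.43, "unimodal"), (5 / 9, "flattened")],
    )
    def test_modality_classes(self, b, expected):
        from socexp.criticality import BIMODAL_THRESHOLD, FLATTENED_BAND

        if b > BIMODAL_THRESHOLD:
            cls = "bimodal"
        elif FLATTENED_BAND[0] <= b <= FLATTENED_BAND[1]:
            cls = "flattened"
        else:
            cls = "unimodal"
        assert cls == expected


def _tent_matrix(n=3000, seed=0, monotone=False):
    """Matrix whose change-grouped profile is a tent (apex at zero change)."""
    rng = np.random.default_rng(seed)
    d = np.sort(rng.uniform(-0.5, 0.5, n))
    y0 = d if monotone else 5.0 - 8.0 * np.abs(d) + rng.normal(0, 0.01, n)
    x = np.column_stack([y0, y0 + d, y0 + d])
    return ExpressionMatrix([f"g{i}" for i in range(n)], [0, 10, 15], x, "natural_log")


class TestSandpileCP:
    def test_planted_tent_apex_at_zero_change(self):
        prof = sandpile_cp(_tent_matrix(), 0, 10, n=100)
        assert prof.transition_detected
        assert abs(prof.cp.cm_change) < 0.05
        assert prof.singularity_score > 1.0

    def test_monotone_profile_no_transition(self):
        prof = sandpile_cp(_tent_matrix(monotone=True), 0, 10, n=100)
        assert not prof.transition_detected
        assert prof.singularity_score == 0.0

    def test_synthetic_default_detects_cp_each_pair(self, synth):
        for pair in ((10, 15), (15, 20), (20, 30)):
            prof = sandpile_cp(synth.matrix, *pair, n=440, fluct=synth.fluct)
            assert prof.significant(0.5)
            assert abs(prof.cp.cm_change) < 0.05

    def test_group_size_floor(self, synth_small):
        with pytest.raises(ValueError, match="n >= 50"):
            sandpile_cp(synth_small.matrix, 10, 15, n=10)


class TestRegulatoryDensity:
    def _matrix_from_xy(self, x, y):
        # y = ln eps(t0); x = change to t1
        vals = np.column_stack([y, y + x, y + x])
        return ExpressionMatrix([f"g{i}" for i in range(len(x))], [0, 10, 15], vals, "natural_log")

    def test_single_gaussian_one_mode(self):
        rng = np.random.default_rng(2)
        m = self._matrix_from_xy(rng.normal(0, 0.3, 4000), rng.normal(2, 0.3, 4000))
        dens = regulatory_density(m, m.gene_ids, 0, 10)
        assert len(dens.modes) == 1
        assert dens.density.sum() == pytest.approx(1.0)

    def test_two_separated_y_components_label_hes_les(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.normal(1.0, 0.2, 3000), rng.normal(4.0, 0.2, 3000)])
        x = rng.normal(0, 0.2, 6000)
        m = self._matrix_from_xy(x, y)
        dens = regulatory_density(m, m.gene_ids, 0, 10)
        assert dens.hes is not None and dens.les is not None
        assert dens.hes["y"] > dens.les["y"]

    def test_identical_points_single_bin(self):
        m = self._matrix_from_xy(np.zeros(60), np.full(60, 2.0))
        dens = regulatory_density(m, m.gene_ids, 0, 10)
        assert dens.density.max() == pytest.approx(1.0)
        assert (dens.density > 0).sum() == 1


class TestModality:
    def test_high_variance_window_unimodal(self, synth):
        rep = modality_scan(synth.matrix, synth.fluct, 10, (0.10, 0.14))
        assert rep.modality == "unimodal"

    def test_low_variance_window_bimodal(self, synth):
        rep = modality_scan(synth.matrix, synth.fluct, 10, (0.03, 0.06))
        assert rep.modality == "bimodal"
        assert rep.b > 5 / 9

    def test_empty_window_errors(self, synth):
        with pytest.raises(ValueError, match="selects no genes"):
            modality_scan(synth.matrix, synth.fluct, 10, (1.5, 1.6))

    def test_sequence_runs_unimodal_to_bimodal(self, synth):
        seq = modality_sequence(synth.matrix, synth.fluct, 10, start=0.14, stop=0.02, width=0.02, step=0.01)
        classes = seq.modality.tolist()
        assert classes[0] == "unimodal"
        assert classes[-1] == "bimodal"
        last_uni = max(i for i, c in enumerate(classes) if c == "unimodal")
        first_bi = min(i for i, c in enumerate(classes) if c == "bimodal")
        assert last_uni < first_bi


class TestPartition:
    def _fluct(self, nrmsf, ids=None):
        ids = ids or [f"g{i}" for i in range(len(nrmsf))]
        table = pd.DataFrame({"rmsf": nrmsf, "nrmsf": nrmsf, "mean_expr": 0.0}, index=pd.Index(ids, name="gene_id"))
        return FluctuationTable(table, 1.0)

    def test_three_way_labels(self):
        part = partition_states(self._fluct([0.05, 0.10, 0.20]))
        assert part.states.tolist() == ["sub", "near", "super"]

    def test_boundary_goes_to_lower_state(self):
        part = partition_states(self._fluct([0.08, 0.16]))
        assert part.states.tolist() == ["sub", "near"]

    def test_counts_sum_and_order_invariance(self, synth):
        part = synth.partition
        assert sum(part.counts.values()) == synth.matrix.n_genes
        shuffled = synth.fluct.table.sample(frac=1.0, random_state=0)
        part2 = partition_states(FluctuationTable(shuffled, synth.fluct.max_rmsf))
        assert part2.counts == part.counts

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            partition_states(self._fluct([0.1, 0.2]), thresholds=(0.5, 0.2))


class TestPowerLaw:
    def test_exact_points_recovered(self):
        eps = np.array([2.0, 5.0, 20.0, 100.0])
        nrmsf = 1.0 - 2.0 * eps**-0.5
        fit = fit_power_law(eps, nrmsf)
        assert fit.alpha == pytest.approx(2.0, abs=1e-10)
        assert fit.beta == pytest.approx(0.5, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_scale_consistency(self):
        rng = np.random.default_rng(5)
        eps = np.exp(rng.uniform(0.5, 4.0, 30))
        nrmsf = np.clip(1.0 - 1.3 * eps**-0.2 * np.exp(rng.normal(0, 0.05, 30)), 0.001, 0.999)
        f1 = fit_power_law(eps, nrmsf)
        c = 3.7
        f2 = fit_power_law(c * eps, nrmsf)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-12)
        assert f2.alpha == pytest.approx(f1.alpha * c**f1.beta, rel=1e-10)

    def test_nonpositive_eps_errors(self):
        with pytest.raises(ValueError, match="nonpositive"):
            fit_power_law([1.0, -2.0, 3.0], [0.1, 0.2, 0.3])

    def test_deab_coordinates_round_trip(self):
        eps = np.array([2.0, 5.0, 20.0])
        nrmsf = 1.0 - 1.5 * eps**-0.3
        pts = np.column_stack([np.log(eps), np.log(1 - nrmsf)])
        fit = fit_power_law_deab(pts)
        assert fit.beta == pytest.approx(0.3, abs=1e-10)
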