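import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from replinoise import (
    DistanceError,
    DistanceSummary,
    bray_curtis,
    intra_inter_distances,
    kde,
    overlap_coefficient,
    pairwise_bray_curtis,
)
from conftest import make_design, random_table


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((10, 0, 5), (10, 0, 5), 0.0),
            ((10, 0), (0, 7), 1.0),
            ((2, 2), (2, 0), 2.0 / 6.0),
        ],
    )
    def test_closed_form_values(self, x, y, expected):
        assert bray_curtis(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_undefined_for_two_empty_vectors(self):
        with pytest.raises(DistanceError, match="all-zero"):
            bray_curtis(np.zeros(3), np.zeros(3))
        with pytest.raises(DistanceError, match="non-negative"):
            bray_curtis(np.array([1.0, -1.0]), np.array([1.0, 1.0]))

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_scipy_and_is_symmetric(self, data):
        n = data.draw(st.integers(2, 20))
        vec = st.lists(st.floats(0, 100, allow_nan=False), min_size=n, max_size=n)
        x = np.array(data.draw(vec))
        y = np.array(data.draw(vec))
        if x.sum() + y.sum() == 0:
            return
        d = bray_curtis(x, y)
        assert d == pytest.approx(bray_curtis(y, x))
        assert 0.0 <= d <= 1.0
        if x.sum() > 0 and y.sum() > 0:
            assert d == pytest.approx(scipy_braycurtis(x, y), abs=1e-12)

    def test_invariant_to_joint_rescaling(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(10), rng.random(10)
        assert bray_curtis(7.5 * x, 7.5 * y) == pytest.approx(bray_curtis(x, y))

    def test_pairwise_matches_elementwise(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 50, size=(6, 9)).astype(float) + 0.1
        dm = pairwise_bray_curtis(m)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert dm[i, j] == pytest.approx(bray_curtis(m[i], m[j]))
        assert np.allclose(np.diag(dm), 0)


class TestKde:
    def test_density_integrates_to_one_and_is_nonnegative(self):
        rng = np.random.default_rng(2)
        grid, dens = kde(rng.random(200))
        assert (dens >= 0).all()
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_all_equal_values_peak_at_value(self):
        grid, dens = kde(np.full(10, 0.5))
        assert grid[np.argmax(dens)] == pytest.approx(0.5, abs=0.01)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_sample_has_modes_near_both_clusters(self):
        vals = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        # Silverman's rule over-smooths a two-point-mass sample; fix the
        # bandwidth so the two construction modes are resolvable
        grid, dens = kde(vals, bandwidth=0.02)
        lo_mode = grid[np.argmax(dens[grid < 0.5])]
        hi_mode = grid[grid >= 0.5][np.argmax(dens[grid >= 0.5])]
        assert lo_mode == pytest.approx(0.1, abs=0.05)
        assert hi_mode == pytest.approx(0.9, abs=0.05)

    def test_uniform_sample_is_flat_in_the_interior(self):
        # Monte-Carlo oracle: density of U[0,1] is 1 everywhere
        rng = np.random.default_rng(3)
        grid, dens = kde(rng.random(10_000))
        interior = (grid >= 0.1) & (grid <= 0.9)
        assert np.abs(dens[interior] - 1.0).max() < 0.1

    def test_too_few_values_rejected(self):
        with pytest.raises(DistanceError):
            kde(np.array([0.4]))
        with pytest.raises(DistanceError):
            kde(np.array([0.4, 1.7]))


class TestOverlap:
    def test_identical_curves_overlap_one(self):
        rng = np.random.default_rng(4)
        a = kde(rng.random(100))
        assert overlap_coefficient(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_curves_overlap_near_zero(self):
        a = kde(np.random.default_rng(5).normal(0.05, 0.005, 100).clip(0, 1))
        b = kde(np.random.default_rng(6).normal(0.95, 0.005, 100).clip(0, 1))
        assert overlap_coefficient(a, b) < 0.05

    def test_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(7)
        a, b = kde(rng.random(60)), kde(rng.random(80))
        assert overlap_coefficient(a, b) == pytest.approx(overlap_coefficient(b, a))

    def test_mismatched_grids_rejected(self):
        a = kde(np.random.default_rng(8).random(50))
        b = kde(np.random.default_rng(9).random(50), grid_size=100)
        with pytest.raises(DistanceError, match="grid"):
            overlap_coefficient(a, b)


class TestIntraInterPartition:
    def test_identical_rows_give_all_zero_distances(self, tiny_design):
        from replinoise import CountTable

        counts = np.tile([50, 30, 20], (4, 1))
        t = CountTable(tiny_design.sample_ids, ["o1", "o2", "o3"], counts)
        s = intra_inter_distances(t, tiny_design, stratum="kit")
        assert sorted(s.intra_values) == [0.0, 0.0]
        assert sorted(s.inter_values) == [0.0] * 4

    def test_disjoint_kits_give_unit_inter_distances(self, tiny_design):
        from replinoise import CountTable

        counts = np.array([[100, 0], [100, 0], [0, 100], [0, 100]])
        t = CountTable(tiny_design.sample_ids, ["o1", "o2"], counts)
        s = intra_inter_distances(t, tiny_design, stratum="kit")
        assert sorted(s.intra_values) == [0.0, 0.0]
        assert sorted(s.inter_values) == [1.0] * 4

    def test_provenance_pairs_respect_strata(self):
        rng = np.random.default_rng(11)
        design = make_design(n_groups=3, n_reps=2)
        t = random_table(rng, design)
        s = intra_inter_distances(t, design, stratum="kit")
        for _, row in s.intra.iterrows():
            assert row["group_a"] == row["group_b"]
        for _, row in s.inter.iterrows():
            assert row["group_a"] != row["group_b"]

    def test_matches_double_loop_oracle(self):
        """Partition equals an independent brute-force pairing on 12 samples."""
        rng = np.random.default_rng(12)
        design = make_design(n_groups=3, n_reps=4)
        t = random_table(rng, design, n_otus=10)
        s = intra_inter_distances(t, design, stratum="kit")

        rel = t.counts / t.counts.sum(axis=1, keepdims=True)
        kit = {sid: design.loc(sid)["kit_id"] for sid in t.sample_ids}
        intra_oracle, inter_oracle = [], []
        for i in range(t.n_samples):
            for j in range(i + 1, t.n_samples):
                d = scipy_braycurtis(rel[i], rel[j])
                a, b = t.sample_ids[i], t.sample_ids[j]
                (intra_oracle if kit[a] == kit[b] else inter_oracle).append(d)
        assert np.allclose(np.sort(s.intra_values), np.sort(intra_oracle), atol=1e-12)
        assert np.allclose(np.sort(s.inter_values), np.sort(inter_oracle), atol=1e-12)

    def test_no_replicates_anywhere_is_an_error(self):
        rng = np.random.default_rng(13)
        design = make_design(n_groups=4, n_reps=1)
        t = random_table(rng, design)
        with pytest.raises(DistanceError, match="replicates"):
            intra_inter_distances(t, design, stratum="kit")

    def test_zero_total_sample_rejected_by_distance_ops(self, tiny_design):
        from replinoise import CountTable

        counts = np.array([[10, 0], [8, 2], [0, 0], [5, 5]])
        t = CountTable(tiny_design.sample_ids, ["o1", "o2"], counts)
        with pytest.raises(DistanceError, match="zero-total"):
            intra_inter_distances(t, tiny_design, stratum="kit")

    def test_rarefaction_mode_is_seeded_and_depth_bound(self, tiny_table, tiny_design):
        a = intra_inter_distances(tiny_table, tiny_design, normalize="rarefy", rarefy_depth=50, seed=1)
        b = intra_inter_distances(tiny_table, tiny_design, normalize="rarefy", rarefy_depth=50, seed=1)
        assert np.array_equal(a.intra_values, b.intra_values)

    def test_summary_invariants(self):
        rng = np.random.default_rng(14)
        design = make_design(n_groups=2, n_reps=3)
        t = random_table(rng, design)
        s = intra_inter_distances(t, design, stratum="kit")
        assert ((s.intra["distance"] >= 0) & (s.intra["distance"] <= 1)).all()
        grid, dens = s.kde_intra
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)
        assert 0.0 <= s.overlap <= 1.0

    def test_identical_intra_and_inter_sets_overlap_one(self):
        vals = np.random.default_rng(15).random(40)
        s = DistanceSummary.from_values(vals, vals)
        assert s.overlap == pytest.approx(1.0, abs=1e-9)
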