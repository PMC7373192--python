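import numpy as np
import pandas as pd
import pytest

from replinoise import (
    CountTable,
    DesignError,
    DistanceError,
    SimConfig,
    concordance_score,
    identify_contaminants,
    mean_of_replicate_medians,
    remove_contaminants,
    simulate_controls,
)
from conftest import make_design


def table_from_rel(design, rel_rows, depth=1000, otus=None):
    counts = np.rint(np.asarray(rel_rows, dtype=float) * depth).astype(int)
    otus = otus or [f"Otu{i}" for i in range(counts.shape[1])]
    return CountTable(design.sample_ids, otus, counts)


class TestMeanOfReplicateMedians:
    def test_single_replicate_spurious_otu_is_zeroed(self):
        design = make_design(n_groups=1, n_reps=3)
        t = table_from_rel(design, [[1.0, 0.0], [1.0, 0.0], [0.4, 0.6]])
        prof = mean_of_replicate_medians(t, design)
        by = prof.profile.set_index("otu_id")["mean"]
        assert by["Otu0"] == pytest.approx(1.0)
        assert by["Otu1"] == 0.0

    def test_median_of_three_replicates(self):
        design = make_design(n_groups=1, n_reps=3)
        t = table_from_rel(design, [[0.2, 0.8], [0.4, 0.6], [0.6, 0.4]])
        prof = mean_of_replicate_medians(t, design)
        by = prof.profile.set_index("otu_id")["mean"]
        assert by["Otu0"] == pytest.approx(0.4)
        assert by["Otu1"] == pytest.approx(0.6)

    def test_mean_across_specimens(self):
        design = make_design(n_groups=2, n_reps=2)
        t = table_from_rel(
            design, [[0.4, 0.6], [0.4, 0.6], [0.8, 0.2], [0.8, 0.2]]
        )
        prof = mean_of_replicate_medians(t, design)
        by = prof.profile.set_index("otu_id")["mean"]
        assert by["Otu0"] == pytest.approx(0.6)
        assert by["Otu1"] == pytest.approx(0.4)
        assert prof.n_specimens == 2

    def test_minority_otu_suppression_property(self):
        """An OTU absent from a strict majority of every specimen's
        replicates has consensus abundance exactly 0 (with the midpoint
        median convention for even replicate counts, presence in exactly
        r/2 replicates is NOT suppressed, so the bound is floor((r-1)/2))."""
        rng = np.random.default_rng(21)
        for trial in range(20):
            n_reps = int(rng.integers(3, 6))
            n_spec = int(rng.integers(1, 4))
            design = make_design(n_groups=n_spec, n_reps=n_reps)
            counts = rng.integers(1, 100, size=(len(design), 6))
            minority = (n_reps - 1) // 2  # largest presence with a zero median
            counts[:, 0] = 0
            for s in range(n_spec):
                rows = rng.choice(n_reps, size=minority, replace=False)
                counts[s * n_reps + rows, 0] = rng.integers(1, 100, size=rows.size)
            t = CountTable(design.sample_ids, [f"Otu{i}" for i in range(6)], counts)
            prof = mean_of_replicate_medians(t, design)
            assert prof.profile.set_index("otu_id")["mean"]["Otu0"] == 0.0

    def test_invariant_to_replicate_and_specimen_order(self):
        rng = np.random.default_rng(22)
        design = make_design(n_groups=3, n_reps=3)
        counts = rng.integers(0, 50, size=(9, 5)) + 1
        t = CountTable(design.sample_ids, [f"Otu{i}" for i in range(5)], counts)
        prof = mean_of_replicate_medians(t, design)

        perm = rng.permutation(9)
        t2 = CountTable([t.sample_ids[i] for i in perm], t.otu_ids, counts[perm])
        prof2 = mean_of_replicate_medians(t2, design.subset(t2.sample_ids))
        pd.testing.assert_frame_equal(prof.profile, prof2.profile)

    def test_single_replicate_specimen_excluded_with_warning(self):
        design = make_design(n_groups=2, n_reps=1)
        t = table_from_rel(design, [[0.5, 0.5], [0.9, 0.1]])
        with pytest.raises(DesignError):
            mean_of_replicate_medians(t, design)  # nothing left after exclusion
        with pytest.raises(DesignError):
            mean_of_replicate_medians(t, design, on_single_replicate="error")


class TestIdentifyContaminants:
    def test_ubiquitous_abundant_otu_flagged(self):
        design = make_design(n_groups=3, n_reps=3, control_groups=("G1", "G2", "G3"))
        rng = np.random.default_rng(23)
        counts = rng.integers(10, 40, size=(9, 5))
        counts[:, 0] = 300  # ~30% everywhere
        t = CountTable(design.sample_ids, [f"Otu{i}" for i in range(5)], counts)
        report = identify_contaminants(t, design)
        assert "Otu0" in report.flagged_otus

    def test_one_shot_otu_not_flagged(self):
        design = make_design(n_groups=2, n_reps=3, control_groups=("G1", "G2"))
        counts = np.full((6, 4), 50)
        counts[:, 0] = 0
        counts[0, 0] = 500  # one replicate of one kit only
        t = CountTable(design.sample_ids, [f"Otu{i}" for i in range(4)], counts)
        report = identify_contaminants(t, design)
        assert "Otu0" not in report.flagged_otus

    def test_non_control_table_rejected(self, tiny_table, tiny_design):
        with pytest.raises(DesignError, match="control"):
            identify_contaminants(tiny_table, tiny_design)

    def test_planted_contaminant_recovered_with_few_false_positives(self):
        """Simulator oracle: one contaminated kit against noise-only kits."""
        false_positives = 0
        recovered = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimConfig(
                seed=seed, input_copies=0.0, contamination_copies=1e6, noise_scale=1e3,
                n_contaminant_otus=3,
            )
            table, design = simulate_controls(cfg, n_kits=3, contaminated_kits=(0,))
            report = identify_contaminants(table, design)
            planted = {o for o in cfg.contaminant_otus(0)
                       if table.counts[:, table.otu_ids.index(o)].sum() > 0}
            # the planted kit's major contaminant OTUs are recovered
            major = {o for o in planted
                     if table.counts[:3, table.otu_ids.index(o)].mean() / cfg.read_depth > 0.2}
            recovered += major <= set(report.flagged_otus)
            false_positives += len(set(report.flagged_otus) - planted)
        assert recovered == n_seeds
        assert false_positives / n_seeds <= 1.0

    def test_clean_noiseless_controls_flag_nothing(self):
        # no contamination and no noise reads: nothing can be flagged
        design = make_design(n_groups=2, n_reps=3, control_groups=("G1", "G2"))
        rng = np.random.default_rng(24)
        counts = rng.multinomial(1000, [0.5, 0.3, 0.2], size=6)
        t = CountTable(design.sample_ids, ["a", "b", "c"], counts)
        report = identify_contaminants(t, design, min_abund=1.01)  # impossible bar
        assert report.flagged_otus == []


class TestRemoveContaminants:
    def test_retention_accounting(self):
        design = make_design(n_groups=1, n_reps=2)
        t = CountTable(design.sample_ids, ["keep", "bad"], np.array([[90, 10], [45, 5]]))
        cleaned, report = remove_contaminants(t, ["bad"])
        assert cleaned.otu_ids == ["keep"]
        assert np.allclose(report.retention["fraction_retained"], 0.9)
        assert report.mean_retention == pytest.approx(0.9)

    def test_empty_flag_set_retains_everything(self, tiny_table):
        cleaned, report = remove_contaminants(tiny_table, [])
        assert np.array_equal(cleaned.counts, tiny_table.counts)
        assert (report.retention["fraction_retained"] == 1.0).all()

    def test_emptied_sample_reported_not_dropped(self):
        design = make_design(n_groups=1, n_reps=2)
        t = CountTable(design.sample_ids, ["only", "other"], np.array([[10, 0], [5, 5]]))
        cleaned, report = remove_contaminants(t, ["only"])
        assert report.emptied_samples == ["G1_r1"]
        assert cleaned.n_samples == 2

    def test_unknown_otu_rejected(self, tiny_table):
        with pytest.raises(KeyError):
            remove_contaminants(tiny_table, ["ghost"])


class TestConcordanceScore:
    def test_identical_replicates_score_one(self):
        design = make_design(n_groups=1, n_reps=3)
        t = CountTable(design.sample_ids, ["a", "b"], np.tile([70, 30], (3, 1)))
        assert concordance_score(t, design, "G1") == 1.0

    def test_disjoint_replicates_score_zero(self):
        design = make_design(n_groups=1, n_reps=2)
        t = CountTable(design.sample_ids, ["a", "b"], np.array([[100, 0], [0, 100]]))
        assert concordance_score(t, design, "G1") == 0.0

    def test_partial_overlap_arithmetic(self):
        # shared OTU carries 180 of 200 reads -> 0.9
        design = make_design(n_groups=1, n_reps=2)
        t = CountTable(
            design.sample_ids, ["A", "B", "C"], np.array([[90, 10, 0], [90, 0, 10]])
        )
        assert concordance_score(t, design, "G1") == pytest.approx(0.9)

    def test_fewer_than_two_replicates_rejected(self):
        design = make_design(n_groups=1, n_reps=1)
        t = CountTable(design.sample_ids, ["a"], np.array([[10]]))
        with pytest.raises(DistanceError, match=">= 2"):
            concordance_score(t, design, "G1")
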