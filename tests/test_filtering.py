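import numpy as np
import pandas as pd
import pytest

from m2seq import (BulkPairDataset, MultiPopulationSet, VariantKey,
                   run_filter_pipeline, step2_high_index_filter,
                   step3_low_index_filter)
from m2seq.filtering import report_from_frame
from m2seq.indices import compute_indices
from tests.conftest import make_dataset


def statuses_by_pos(frame):
    return dict(zip(frame["pos"], frame["status"]))


class TestStep1:
    def test_shared_key_removed_everywhere_singletons_kept(self, toy_populations):
        mps = MultiPopulationSet(toy_populations)
        frames, _ = run_filter_pipeline(mps)
        for pid in ("Mut01", "Mut02", "Mut03"):
            assert statuses_by_pos(frames[pid])[100] == "STEP1_REMOVED"
        assert statuses_by_pos(frames["Mut02"])[700] == "PASS"
        assert statuses_by_pos(frames["Mut03"])[800] == "PASS"

    def test_occurrence_index_counts_populations(self, toy_populations):
        mps = MultiPopulationSet(toy_populations)
        idx = mps.occurrence_index
        assert idx[VariantKey("Chr01", 100, "C", "T")] == {"Mut01", "Mut02", "Mut03"}
        assert idx[VariantKey("Chr02", 700, "C", "T")] == {"Mut02"}
        assert all(1 <= len(v) <= 3 for v in idx.values())

    def test_single_population_is_a_noop(self, toy_populations):
        mps = MultiPopulationSet(toy_populations[:1])
        frames, _ = run_filter_pipeline(mps)
        assert (frames["Mut01"]["status"] != "STEP1_REMOVED").all()

    def test_symmetric_under_population_permutation(self, toy_populations):
        f_fwd, _ = run_filter_pipeline(MultiPopulationSet(toy_populations))
        f_rev, _ = run_filter_pipeline(MultiPopulationSet(toy_populations[::-1]))
        for pid in f_fwd:
            pd.testing.assert_series_equal(f_fwd[pid]["status"], f_rev[pid]["status"])


class TestSteps23:
    def test_high_index_needs_both_bulks(self):
        ds = make_dataset(
            "p",
            [
                ("Chr01", 1, "C", "T", 1, 9, 2, 8),    # 0.9 / 0.8 -> removed
                ("Chr01", 2, "C", "T", 1, 9, 5, 5),    # 0.9 / 0.5 -> retained
                ("Chr01", 3, "C", "T", 3, 7, 3, 7),    # exactly 0.7 both -> retained (strict >)
            ],
        )
        frame = step2_high_index_filter(compute_indices(ds))
        assert frame["status"].tolist() == ["STEP2_REMOVED", "PASS", "PASS"]

    def test_low_index_and_mutant_zero_rules(self):
        ds = make_dataset(
            "p",
            [
                ("Chr01", 1, "C", "T", 8, 2, 15, 5),   # 0.2 / 0.25 -> removed
                ("Chr01", 2, "C", "T", 15, 0, 8, 8),   # mutant-zero -> removed
                ("Chr01", 3, "C", "T", 9, 1, 4, 6),    # 0.1 / 0.6 -> retained (repulsion marker)
            ],
        )
        frame = step3_low_index_filter(compute_indices(ds))
        assert frame["status"].tolist() == ["STEP3_REMOVED", "STEP3_REMOVED", "PASS"]


class TestPipeline:
    def test_toy_partition_one_variant_per_status(self, toy_populations):
        frames, reports = run_filter_pipeline(MultiPopulationSet(toy_populations))
        r = next(rep for rep in reports if rep.population_id == "Mut01")
        assert (r.n_input, r.n_depth_fail, r.n_step1, r.n_step2, r.n_step3, r.n_retained) == (
            6, 1, 1, 1, 2, 1
        )
        assert statuses_by_pos(frames["Mut01"])[600] == "PASS"

    def test_report_partitions_input(self, small_sim):
        datasets, _ = small_sim
        _, reports = run_filter_pipeline(MultiPopulationSet(datasets))
        for r in reports:
            assert (
                r.n_depth_fail + r.n_step1 + r.n_step2 + r.n_step3 + r.n_retained
                == r.n_input
            )

    def test_report_must_partition(self):
        frame = compute_indices(
            make_dataset("p", [("Chr01", 1, "C", "T", 5, 5, 5, 5)])
        )
        frame.loc[0, "status"] = "PASS"
        bad = frame.copy()
        bad["status"] = "NOT_A_STATUS"
        with pytest.raises(ValueError):
            report_from_frame("p", bad)

    def test_idempotent_on_its_own_pass_output(self, toy_populations):
        frames, _ = run_filter_pipeline(MultiPopulationSet(toy_populations))
        survivors = []
        for pop in toy_populations:
            frame = frames[pop.population_id]
            keep = frame[frame["status"] == "PASS"]
            survivors.append(
                BulkPairDataset(pop.population_id, keep.drop(columns=[
                    "snp_index_mut", "snp_index_wt", "dsi", "adsi", "status"]))
            )
        frames2, _ = run_filter_pipeline(MultiPopulationSet(survivors))
        for pid in frames2:
            assert (frames2[pid]["status"] == "PASS").all()

    def test_all_background_dataset_retains_nothing(self):
        shared = [("Chr01", p, "C", "T", 1, 20, 1, 20) for p in range(100, 400, 100)]
        pops = [make_dataset(f"Mut{i}", shared) for i in (1, 2)]
        frames, reports = run_filter_pipeline(MultiPopulationSet(pops))
        assert all(r.n_retained == 0 for r in reports)


class TestAgainstSimulatedTruth:
    def test_step1_recovers_planted_shared_background(self, small_sim):
        """With disjoint per-population EMS sets, the step-1 removal set is
        exactly the planted shared background present in each population."""
        datasets, truths = small_sim
        frames, _ = run_filter_pipeline(MultiPopulationSet(datasets))
        for ds, truth in zip(datasets, truths):
            frame = frames[ds.population_id]
            removed = set(
                zip(*(frame.loc[frame["status"] == "STEP1_REMOVED", c]
                      for c in ("chrom", "pos")))
            )
            planted = truth.truth[truth.truth["origin"] == "background_shared"]
            planted_keys = set(zip(planted["chrom"], planted["pos"]))
            assert removed == planted_keys

    def test_retained_density_tracks_planted_ems_rate(self, small_config, small_sim):
        datasets, truths = small_sim
        frames, _ = run_filter_pipeline(MultiPopulationSet(datasets))
        genome_mb = small_config.genome_mb
        for ds, truth in zip(datasets, truths):
            retained = (frames[ds.population_id]["status"] == "PASS").sum()
            planted = len(truth.truth[truth.truth["origin"] == "ems_cell0"])
            # retention removes some true EMS sites (repulsion near-zeros) but
            # should stay within the planted density
            assert 0.5 * planted <= retained <= planted
            assert retained / genome_mb <= small_config.ems_rate_per_mb * 1.1
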