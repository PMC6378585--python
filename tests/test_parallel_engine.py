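"""Interleaved planning, worker isolation, order-preserving merge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parastorm.errors import MergeError, PlanError, RunError
from parastorm.io_formats import LocalizationTable, read_table
from parastorm.localize import localize_frames
from parastorm.parallel_engine import (
    WorkerConfig,
    contiguous_block_counts,
    export_manifests,
    merge_tables,
    plan_interleave,
    run_parallel,
    run_worker_from_manifest,
)


class TestPlanInterleave:
    def test_four_workers_thirteen_frames(self):
        plan = plan_interleave(13, 4)
        assert plan.frames_for(1) == [1, 5, 9, 13]
        assert plan.frames_for(2) == [2, 6, 10]
        assert plan.frames_for(3) == [3, 7, 11]
        assert plan.frames_for(4) == [4, 8, 12]

    def test_single_worker_gets_everything(self):
        assert plan_interleave(5, 1).frames_for(1) == [1, 2, 3, 4, 5]

    def test_more_workers_than_frames_is_plan_error(self):
        with pytest.raises(PlanError):
            plan_interleave(3, 4)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(n=st.integers(1, 500), w=st.integers(1, 32))
    def test_assignments_partition_and_balance(self, n, w):
        if w > n:
            w = n
        plan = plan_interleave(n, w)
        chunks = plan.assignments
        flat = [f for c in chunks for f in c]
        assert sorted(flat) == list(range(1, n + 1))
        sizes = [len(c) for c in chunks]
        assert max(sizes) - min(sizes) <= 1


def _table_with_frames(frames, id_start=1):
    records = []
    for i, f in enumerate(frames):
        records.append({"id": float(id_start + i), "frame": float(f),
                        "x_nm": 100.0 * f, "y_nm": 50.0 * f,
                        "sigma_nm": 130.0, "intensity_photons": 1000.0,
                        "offset_photons": 10.0, "bkgstd_photons": 3.0,
                        "uncertainty_xy_nm": 9.5})
    return LocalizationTable.from_records(records, dim=2)


class TestMergeTables:
    def test_merged_frames_non_decreasing(self):
        plan = plan_interleave(13, 4)
        tables = [_table_with_frames(plan.frames_for(w)) for w in (1, 2, 3, 4)]
        merged = merge_tables(tables)
        frames = merged.df["frame"].to_numpy()
        assert np.all(np.diff(frames) >= 0)
        assert sorted(frames) == list(range(1, 14))

    def test_single_table_only_ids_reassigned(self):
        t = _table_with_frames([3, 1, 2], id_start=10)
        merged = merge_tables([t])
        assert list(merged.df["id"]) == [1.0, 2.0, 3.0]
        assert list(merged.df["frame"]) == [1.0, 2.0, 3.0]

    def test_merge_of_parity_split_restores_table(self):
        full = _table_with_frames([1, 2, 3, 4, 5, 6, 7, 8])
        odd = LocalizationTable(full.df[full.df["frame"] % 2 == 1], 2)
        even = LocalizationTable(full.df[full.df["frame"] % 2 == 0], 2)
        merged = merge_tables([odd, even])
        for col in ("frame", "x_nm", "y_nm"):
            np.testing.assert_array_equal(merged.df[col], full.df[col])

    def test_overlapping_frames_is_merge_error(self):
        with pytest.raises(MergeError):
            merge_tables([_table_with_frames([1, 2]),
                          _table_with_frames([2, 3])])


class TestRunParallel:
    def test_merged_csv_independent_of_worker_count(self, medium_handle,
                                                    tmp_path):
        blobs = {}
        for w in (1, 2, 4):
            plan = plan_interleave(medium_handle.n_frames, w)
            report = run_parallel(medium_handle, plan,
                                  WorkerConfig(engine="phasor"),
                                  tmp_path / f"w{w}", processes=(w == 2))
            blobs[w] = report.merged_table_path.read_bytes()
            assert sum(report.worker_counts) == len(report.merged_table)
        assert blobs[1] == blobs[2] == blobs[4]

    def test_stride_one_equals_merged_strided_tables(self, medium_handle):
        whole = localize_frames(medium_handle, 1, 1, engine="phasor")
        parts = [localize_frames(medium_handle, w, 4, engine="phasor")
                 for w in (1, 2, 3, 4)]
        merged = merge_tables(parts)
        for col in whole.df.columns:
            np.testing.assert_array_equal(merged.df[col].to_numpy(),
                                          whole.df[col].to_numpy())

    def test_worker_scratch_layout(self, medium_handle, tmp_path):
        plan = plan_interleave(medium_handle.n_frames, 2)
        run_parallel(medium_handle, plan, WorkerConfig(engine="phasor"),
                     tmp_path / "scratch", processes=False)
        for w in (1, 2):
            wdir = tmp_path / "scratch" / f"worker_{w}"
            assert (wdir / f"part_{w}.csv").exists()
            assert (wdir / f"config_{w}.txt").exists()
            assert (wdir / f"log_{w}.txt").exists()

    def test_worker_failure_names_worker_and_frames(self, medium_handle,
                                                    tmp_path):
        import dataclasses
        broken = dataclasses.replace(medium_handle,
                                     path=str(tmp_path / "missing.tif"))
        plan = plan_interleave(60, 4)
        with pytest.raises(RunError, match=r"worker 1 .*frames 1\.\.57"):
            run_parallel(broken, plan, WorkerConfig(engine="phasor"),
                         tmp_path / "fail", processes=False)


class TestManifests:
    def test_manifest_worker_reproduces_pool_worker(self, medium_handle,
                                                    tmp_path):
        plan = plan_interleave(medium_handle.n_frames, 3)
        config = WorkerConfig(engine="phasor")
        manifests = export_manifests(medium_handle.path, plan, config,
                                     tmp_path / "man")
        assert len(manifests) == 3
        part = run_worker_from_manifest(manifests[1])
        direct = localize_frames(medium_handle, 2, 3, engine="phasor")
        back = read_table(part)
        np.testing.assert_allclose(back.df["x_nm"], direct.df["x_nm"],
                                   rtol=1e-5)
        assert list(back.df["frame"]) == list(direct.df["frame"])


def test_contiguous_block_counts_sum_matches():
    t = _table_with_frames([1, 1, 2, 5, 6, 9, 10, 10])
    counts = contiguous_block_counts(t, n_frames=10, n_workers=2)
    assert sum(counts) == len(t)
    assert counts == [4, 4]
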