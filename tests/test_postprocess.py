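"""Filter chain semantics, drift estimation, consecutive-frame merging."""

import numpy as np
import pytest

from parastorm.errors import ConfigError, DriftError
from parastorm.io_formats import LocalizationTable
from parastorm.postprocess import (
    DriftTrajectory,
    PostprocessConfig,
    apply_drift_correction,
    apply_filter_chain,
    estimate_drift,
    merge_consecutive,
)


def table_from(fields: dict, dim=2, n=None):
    n = n if n is not None else len(next(iter(fields.values())))
    base = {
        "id": np.arange(1, n + 1, dtype=float),
        "frame": np.ones(n),
        "x_nm": np.zeros(n), "y_nm": np.zeros(n),
        "sigma_nm": np.full(n, 130.0),
        "intensity_photons": np.full(n, 1000.0),
        "offset_photons": np.full(n, 10.0),
        "bkgstd_photons": np.full(n, 3.0),
        "uncertainty_xy_nm": np.full(n, 9.5),
    }
    if dim == 3:
        base.update({"z_nm": np.zeros(n), "sigma1_nm": np.full(n, 130.0),
                     "sigma2_nm": np.full(n, 130.0),
                     "uncertainty_z_nm": np.full(n, 50.0)})
    base.update({k: np.asarray(v, dtype=float) for k, v in fields.items()})
    import pandas as pd
    return LocalizationTable(pd.DataFrame(base), dim)


class TestFilters:
    def test_minphot_keeps_exactly_one_photon(self):
        t = table_from({"intensity_photons": [0.2, 1.0, 3.5]})
        out = apply_filter_chain(t, PostprocessConfig(steps=("minphot",)))
        assert list(out.df["intensity_photons"]) == [1.0, 3.5]

    def test_zunc_keeps_exactly_500nm(self):
        t = table_from({"uncertainty_z_nm": [100.0, 500.0, 501.0]}, dim=3)
        out = apply_filter_chain(t, PostprocessConfig(steps=("zunc",)))
        assert list(out.df["uncertainty_z_nm"]) == [100.0, 500.0]

    def test_zunc_ignored_for_2d(self):
        t = table_from({"intensity_photons": [5.0, 5.0]})
        out = apply_filter_chain(t, PostprocessConfig(steps=("zunc",)))
        assert len(out) == 2

    def test_sigma_intercentile_on_1_to_20(self):
        t = table_from({"sigma_nm": np.arange(1.0, 21.0)})
        out = apply_filter_chain(t, PostprocessConfig(steps=("sigma",)))
        # P10 = 2.9, P75 = 15.25 under linear interpolation: keep 3..15
        assert len(out) == 13
        assert list(out.df["sigma_nm"]) == list(np.arange(3.0, 16.0))

    def test_filters_only_remove_never_alter(self):
        rng = np.random.default_rng(0)
        t = table_from({"intensity_photons": rng.uniform(0, 10, 50),
                        "sigma_nm": rng.uniform(50, 400, 50)})
        out = apply_filter_chain(t, PostprocessConfig(steps=("minphot",
                                                             "sigma")))
        surviving = out.df["id"].to_numpy()
        orig = t.df.set_index("id").loc[surviving]
        for col in ("x_nm", "sigma_nm", "intensity_photons"):
            np.testing.assert_array_equal(out.df[col].to_numpy(),
                                          orig[col].to_numpy())

    def test_provenance_counts_per_step(self):
        t = table_from({"intensity_photons": [0.5, 2.0, 2.0]})
        out = apply_filter_chain(t, PostprocessConfig(steps=("minphot",)))
        assert any("kept 2/3" in line for line in out.provenance)

    def test_unknown_token_is_config_error(self):
        with pytest.raises(ConfigError, match="despeckle"):
            PostprocessConfig(steps=("minphot", "despeckle"))

    def test_token_string_round_trip(self):
        cfg = PostprocessConfig.from_tokens("minphot,sigma,drift")
        assert cfg.steps == ("minphot", "sigma", "drift")
        assert cfg.token_string == "minphot,sigma,drift"


def clustered_table(rng, n_frames, shift_second_half=(0.0, 0.0)):
    """Localizations on a fixed random structure, optionally half-shifted."""
    n_pts = 60
    sx = rng.uniform(500, 5900, n_pts)
    sy = rng.uniform(500, 5900, n_pts)
    records = []
    rid = 1
    for f in range(1, n_frames + 1):
        idx = rng.integers(0, n_pts, 12)
        dx, dy = (shift_second_half if f > n_frames // 2 else (0.0, 0.0))
        for i in idx:
            records.append({"id": float(rid), "frame": float(f),
                            "x_nm": sx[i] + dx + rng.normal(0, 10),
                            "y_nm": sy[i] + dy + rng.normal(0, 10),
                            "sigma_nm": 130.0, "intensity_photons": 1000.0,
                            "offset_photons": 10.0, "bkgstd_photons": 3.0,
                            "uncertainty_xy_nm": 9.5})
            rid += 1
    return LocalizationTable.from_records(records, dim=2)


class TestDrift:
    def test_drift_free_table_is_flat(self):
        t = clustered_table(np.random.default_rng(1), 100)
        traj = estimate_drift(t, n_bins=4, magnification=5,
                              pixel_size_nm=100.0)
        assert np.abs(traj.displacements_nm).max() < 20.0  # 1 super-pixel

    def test_constructed_100nm_shift_recovered(self):
        t = clustered_table(np.random.default_rng(2), 100,
                            shift_second_half=(100.0, 0.0))
        traj = estimate_drift(t, n_bins=2, magnification=5,
                              pixel_size_nm=100.0)
        # bin-2 displacement relative to bin 1 = difference of the per-frame
        # trajectory between the two bin centres
        step = traj.displacements_nm[74] - traj.displacements_nm[24]
        assert abs(step[0] - 100.0) < 5.0
        assert abs(step[1]) < 5.0

    def test_thin_bin_is_drift_error(self):
        t = clustered_table(np.random.default_rng(3), 10)
        with pytest.raises(DriftError):
            estimate_drift(t, n_bins=11, magnification=5)

    def test_drift_plot_written(self, tmp_path):
        t = clustered_table(np.random.default_rng(4), 60)
        plot = tmp_path / "drift.png"
        estimate_drift(t, n_bins=3, magnification=5, plot_path=plot)
        assert plot.exists() and plot.stat().st_size > 0


class TestApplyDriftCorrection:
    def test_zero_trajectory_leaves_table_unchanged(self):
        t = table_from({"x_nm": [100.0], "y_nm": [200.0]})
        traj = DriftTrajectory(np.zeros((5, 2)))
        out = apply_drift_correction(t, traj)
        assert out.df["x_nm"][0] == 100.0 and out.df["y_nm"][0] == 200.0

    def test_sign_convention(self):
        t = table_from({"x_nm": [100.0], "y_nm": [200.0], "frame": [3.0]})
        disp = np.zeros((5, 2))
        disp[2] = [5.0, -5.0]
        out = apply_drift_correction(t, DriftTrajectory(disp))
        assert out.df["x_nm"][0] == 95.0
        assert out.df["y_nm"][0] == 205.0

    def test_apply_then_reestimate_is_flat(self):
        rng = np.random.default_rng(5)
        t = clustered_table(rng, 100, shift_second_half=(120.0, -60.0))
        traj = estimate_drift(t, n_bins=2, magnification=5)
        corrected = apply_drift_correction(t, traj)
        residual = estimate_drift(corrected, n_bins=2, magnification=5)
        assert np.abs(residual.displacements_nm).max() < 15.0


class TestMergeConsecutive:
    def test_two_consecutive_records_merge_with_photon_weights(self):
        t = table_from({"frame": [3.0, 4.0],
                        "x_nm": [1000.0, 1010.0], "y_nm": [500.0, 500.0],
                        "intensity_photons": [500.0, 600.0]})
        out = merge_consecutive(t, radius_nm=50.0, max_gap_frames=0)
        assert len(out) == 1
        rec = out.df.iloc[0]
        assert rec["frame"] == 3.0
        assert rec["intensity_photons"] == 1100.0
        assert rec["x_nm"] == pytest.approx(
            (1000.0 * 500 + 1010.0 * 600) / 1100.0)

    def test_same_frame_records_never_merge(self):
        t = table_from({"frame": [3.0, 3.0],
                        "x_nm": [1000.0, 1000.0], "y_nm": [0.0, 0.0]})
        out = merge_consecutive(t, radius_nm=50.0, max_gap_frames=0)
        assert len(out) == 2

    def test_distant_records_never_merge(self):
        t = table_from({"frame": [3.0, 4.0],
                        "x_nm": [1000.0, 1200.0], "y_nm": [0.0, 0.0]})
        out = merge_consecutive(t, radius_nm=50.0, max_gap_frames=0)
        assert len(out) == 2

    def test_gap_tolerance(self):
        t = table_from({"frame": [1.0, 3.0], "x_nm": [0.0, 0.0],
                        "y_nm": [0.0, 0.0]})
        assert len(merge_consecutive(t, 50.0, max_gap_frames=0)) == 2
        assert len(merge_consecutive(t, 50.0, max_gap_frames=1)) == 1

    def test_run_of_three_becomes_one_record(self):
        t = table_from({"frame": [5.0, 6.0, 7.0],
                        "x_nm": [0.0, 10.0, -10.0], "y_nm": [0.0, 0.0, 0.0]})
        out = merge_consecutive(t, radius_nm=50.0, max_gap_frames=0)
        assert len(out) == 1
        assert out.df.iloc[0]["intensity_photons"] == 3000.0

    def test_every_input_lands_in_exactly_one_output(self):
        rng = np.random.default_rng(6)
        n = 100
        t = table_from({"frame": np.sort(rng.integers(1, 30, n)).astype(float),
                        "x_nm": rng.uniform(0, 4000, n),
                        "y_nm": rng.uniform(0, 4000, n)})
        out = merge_consecutive(t, radius_nm=80.0, max_gap_frames=0)
        assert out.df["intensity_photons"].sum() == pytest.approx(
            t.df["intensity_photons"].sum())
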