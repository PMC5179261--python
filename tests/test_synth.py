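"""Synthetic scene generator: determinism, ground-truth consistency,
and pipeline recovery of rendered tubules."""

from dataclasses import replace

import numpy as np
import pytest

from tubulequant.synth import (
    SceneParams,
    TubulePlacementError,
    cohort_preset,
    generate_cohort,
    generate_scene,
    scene_preset,
    stable_seed,
    tubule_recovery,
)


class TestGenerateScene:
    def test_same_seed_bit_identical(self, small_scene_params):
        img1, truth1 = generate_scene(small_scene_params)
        img2, truth2 = generate_scene(small_scene_params)
        np.testing.assert_array_equal(img1.marker_channel, img2.marker_channel)
        np.testing.assert_array_equal(img1.cell_channel, img2.cell_channel)
        assert truth1.tubule_arc_lengths_um == truth2.tubule_arc_lengths_um

    def test_different_seed_differs(self, small_scene_params):
        img1, _ = generate_scene(small_scene_params)
        img2, _ = generate_scene(replace(small_scene_params, seed=43))
        assert not np.array_equal(img1.marker_channel, img2.marker_channel)

    def test_empty_scene_marker_is_zero(self):
        params = SceneParams(
            image_size=(128, 128),
            cell_radius_px=40,
            n_puncta=0,
            n_tubules=0,
            noise_sd=0,
            noise_model="gaussian",
            background_gradient=0,
            mtoc=False,
        )
        img, truth = generate_scene(params)
        assert not img.marker_channel.any()
        assert truth.tubules == ()

    def test_arc_lengths_within_requested_range(self):
        params = SceneParams(
            image_size=(512, 512),
            cell_radius_px=200,
            n_tubules=8,
            tubule_length_um_range=(3.0, 6.0),
            seed=1,
        )
        _, truth = generate_scene(params)
        assert len(truth.tubules) == 8
        for t in truth.tubules:
            assert 3.0 - 1e-6 <= t.arc_length_um <= 6.0 + 1e-6

    def test_arc_length_matches_polyline_recomputation(self, small_scene_params):
        _, truth = generate_scene(small_scene_params)
        for t in truth.tubules:
            recomputed = (
                float(np.linalg.norm(np.diff(t.points, axis=0), axis=1).sum())
                * small_scene_params.pixel_size_um
            )
            assert abs(recomputed - t.arc_length_um) < 0.01

    def test_centrelines_inside_cell_mask(self, small_scene_params):
        _, truth = generate_scene(small_scene_params)
        for t in truth.tubules:
            ipts = np.rint(t.points).astype(int)
            assert truth.cell_mask[ipts[:, 0], ipts[:, 1]].all()

    def test_placement_failure_raises(self):
        params = SceneParams(
            image_size=(64, 64),
            cell_radius_px=8,
            n_tubules=1,
            tubule_length_um_range=(10.0, 10.0),  # 100 px walk in an 8 px cell
            seed=0,
        )
        with pytest.raises(TubulePlacementError):
            generate_scene(params)

    def test_puncta_avoid_tubules_flag(self):
        from scipy.spatial import cKDTree

        params = SceneParams(
            image_size=(512, 512),
            cell_radius_px=200,
            n_tubules=5,
            n_puncta=60,
            puncta_avoid_tubules=True,
            avoid_margin_px=4.0,
            seed=2,
        )
        _, truth = generate_scene(params)
        tree = cKDTree(np.vstack([t.points for t in truth.tubules]))
        dists, _ = tree.query(np.array(truth.puncta_centres))
        assert (dists >= 4.0).all()

    def test_noiseless_unblurred_tubule_recovered_within_15pct(self):
        """With the PSF and noise off, the measured skeleton length of a
        rendered tubule stays within +-15% of its ground-truth arc length."""
        from tubulequant.pipeline import PipelineConfig, analyze_image

        params = SceneParams(
            image_size=(512, 512),
            cell_radius_px=200,
            n_puncta=0,
            n_tubules=3,
            tubule_length_um_range=(4.0, 8.0),
            psf_sigma_px=0.0,
            noise_sd=0.0,
            noise_model="gaussian",
            background_gradient=0.0,
            seed=6,
        )
        img, truth = generate_scene(params)
        analysis = analyze_image(img, PipelineConfig())
        lengths = sorted(analysis.result.tubule_lengths_px)
        gt = sorted(t.arc_length_um / params.pixel_size_um for t in truth.tubules)
        assert len(lengths) == len(gt)
        for measured, true in zip(lengths, gt):
            assert abs(measured - true) / true <= 0.15


class TestGenerateCohort:
    def test_counts_and_determinism(self, tmp_path):
        control = scene_preset(
            "control-like", image_size=(128, 128), cell_radius_px=40, n_puncta=10
        )
        treated = scene_preset(
            "depleted-like",
            image_size=(128, 128),
            cell_radius_px=40,
            n_puncta=10,
            tubule_length_um_range=(2.0, 4.0),
        )
        m1 = generate_cohort(control, treated, 2, 3, base_seed=5, out_dir=tmp_path / "a")
        m2 = generate_cohort(control, treated, 2, 3, base_seed=5, out_dir=tmp_path / "b")
        assert len(m1) == 12  # 2 conditions x 3 repeats x 2 images
        assert m1.drop(columns="path").equals(m2.drop(columns="path"))
        assert len(list((tmp_path / "a" / "images").glob("*.tif"))) == 12
        f1 = sorted((tmp_path / "a" / "images").glob("*.tif"))[0]
        f2 = sorted((tmp_path / "b" / "images").glob("*.tif"))[0]
        assert f1.read_bytes() == f2.read_bytes()

    def test_condition_length_separation_in_ground_truth(self, tmp_path):
        control = SceneParams(
            image_size=(128, 128), cell_radius_px=40, n_puncta=5,
            n_tubules=2, tubule_length_um_range=(0.5, 1.5),
        )
        treated = replace(control, tubule_length_um_range=(3.0, 6.0))
        generate_cohort(control, treated, 3, 2, base_seed=9, out_dir=tmp_path)
        import pandas as pd

        truth = pd.read_csv(tmp_path / "truth" / "tubules.csv")
        truth["condition"] = truth["image_id"].str.split("_").str[0]
        means = truth.groupby("condition")["arc_length_um"].mean()
        assert means["treated"] > means["control"] + 1.0

    def test_seed_is_insertion_order_independent(self):
        assert stable_seed(1, "control", 0, 3) == stable_seed(1, "control", 0, 3)
        assert stable_seed(1, "control", 0, 3) != stable_seed(1, "treated", 0, 3)
        assert 0 <= stable_seed(99, "x", 5, 5) < 2**31


class TestPresets:
    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            scene_preset("nope")
        with pytest.raises(KeyError):
            cohort_preset("nope")

    def test_fig3_like_pairs_control_and_depleted(self):
        control, treated = cohort_preset("fig3-like")
        assert control.n_tubules < treated.n_tubules
        assert control.tubule_length_um_range[1] <= treated.tubule_length_um_range[1]
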