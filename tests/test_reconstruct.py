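"""Projection matching, weighted back-projection, FSC and resolution."""

import numpy as np
import pytest

import helifil as hf
from helifil import _project
from helifil.helix_search import HelicalParams, helical_self_correlation
from helifil.reconstruct import (OrientationAssignment, FSCCurve,
                                 assign_orientations, back_project,
                                 reconstruct_filament, compute_fsc,
                                 resolution_at_threshold)

from helpers import WORK_BOX, WORK_PIXEL, masked_volume_correlation


def _two_blob_phantom(box=32):
    c = (box - 1) / 2
    zz, yy, xx = np.mgrid[0:box, 0:box, 0:box]
    vol = np.exp(-(((zz - c - 4) ** 2 + (yy - c) ** 2 + (xx - c - 5) ** 2) / 18.0))
    vol += 0.7 * np.exp(-(((zz - c + 5) ** 2 + (yy - c - 3) ** 2 + (xx - c + 2) ** 2) / 10.0))
    return hf.VolumeGrid(voxels=vol.astype(np.float32), voxel_size=2.0)


class TestAssignOrientations:
    def test_known_angles_recovered_within_library_step(self):
        phantom = _two_blob_phantom()
        rng = np.random.default_rng(0)
        true_angles = [(rng.uniform(0, 360), rng.uniform(80, 100)) for _ in range(20)]
        imgs = [_project.project_volume(phantom.voxels.astype(float), p, t, 0.0)
                for p, t in true_angles]
        out = assign_orientations(imgs, phantom, angular_step=4.0,
                                  azimuth_range=(0.0, 360.0), tilt_range=(78.0, 102.0),
                                  max_shift_px=2)
        errs = []
        for (p_true, t_true), (p, t, _) in zip(true_angles, out.angles):
            d_true = np.array([np.sin(np.radians(t_true)) * np.cos(np.radians(p_true)),
                               np.sin(np.radians(t_true)) * np.sin(np.radians(p_true)),
                               np.cos(np.radians(t_true))])
            d_est = np.array([np.sin(np.radians(t)) * np.cos(np.radians(p)),
                              np.sin(np.radians(t)) * np.sin(np.radians(p)),
                              np.cos(np.radians(t))])
            errs.append(np.degrees(np.arccos(np.clip(d_true @ d_est, -1, 1))))
        within = np.mean(np.array(errs) <= 4.0)
        assert within >= 0.95

    def test_reference_projection_matches_itself(self):
        phantom = _two_blob_phantom()
        img = _project.project_volume(phantom.voxels.astype(float), 40.0, 90.0, 0.0)
        out = assign_orientations([img], phantom, angular_step=4.0,
                                  azimuth_range=(0.0, 360.0), tilt_range=(82.0, 98.0),
                                  max_shift_px=2)
        assert out.scores[0] > 0.999
        assert out.angles[0][0] == pytest.approx(40.0, abs=1e-6)

    def test_median_error_never_rises_with_finer_library(self):
        phantom = _two_blob_phantom()
        rng = np.random.default_rng(1)
        true_angles = [(rng.uniform(0, 360), 90.0) for _ in range(12)]
        imgs = [_project.project_volume(phantom.voxels.astype(float), p, t, 0.0)
                for p, t in true_angles]
        medians = []
        for step in (8.0, 4.0, 2.0):
            out = assign_orientations(imgs, phantom, angular_step=step,
                                      azimuth_range=(0.0, 360.0),
                                      tilt_range=(90.0, 90.0), max_shift_px=2)
            errs = [min(abs(p - pt) % 360, 360 - abs(p - pt) % 360)
                    for (pt, _), (p, _, _) in zip(true_angles, out.angles)]
            medians.append(np.median(errs))
        assert medians[1] <= medians[0] + 1e-9
        assert medians[2] <= medians[1] + 1e-9


class TestBackProject:
    def test_phantom_recovered_from_60_views(self):
        phantom = _two_blob_phantom()
        n = 60
        phis = np.linspace(0, 360, n, endpoint=False)
        imgs = [_project.project_volume(phantom.voxels.astype(float), p, 90.0, 0.0)
                for p in phis]
        ors = OrientationAssignment(
            angles=np.column_stack([phis, np.full(n, 90.0), np.zeros(n)]),
            shifts=np.zeros((n, 2)), scores=np.ones(n))
        rec = back_project(imgs, ors, voxel_size=2.0)
        corr = masked_volume_correlation(rec.voxels.astype(float),
                                         phantom.voxels.astype(float), 12, 12)
        assert corr >= 0.95

    def test_more_noisy_views_never_hurt(self):
        phantom = _two_blob_phantom()
        rng = np.random.default_rng(2)
        corrs = {}
        for n in (50, 100):
            phis = np.linspace(0, 360, n, endpoint=False)
            imgs = []
            for p in phis:
                img = _project.project_volume(phantom.voxels.astype(float), p, 90.0, 0.0)
                imgs.append(img + rng.normal(0, img.std(), img.shape))
            ors = OrientationAssignment(
                angles=np.column_stack([phis, np.full(n, 90.0), np.zeros(n)]),
                shifts=np.zeros((n, 2)), scores=np.ones(n))
            rec = back_project(imgs, ors, voxel_size=2.0)
            corrs[n] = masked_volume_correlation(rec.voxels.astype(float),
                                                 phantom.voxels.astype(float), 12, 12)
        assert corrs[100] >= corrs[50] - 0.01

    def test_too_few_or_collinear_views_rejected(self):
        imgs = [np.zeros((32, 32))] * 2
        ors = OrientationAssignment(angles=np.zeros((2, 3)), shifts=np.zeros((2, 2)),
                                    scores=np.zeros(2))
        with pytest.raises(ValueError, match=">= 3"):
            back_project(imgs, ors)
        imgs = [np.zeros((32, 32))] * 4
        ors = OrientationAssignment(angles=np.tile([45.0, 90.0, 0.0], (4, 1)),
                                    shifts=np.zeros((4, 2)), scores=np.zeros(4))
        with pytest.raises(ValueError, match="collinear"):
            back_project(imgs, ors)


class TestComputeFsc:
    def test_identical_volumes_give_unity(self):
        rng = np.random.default_rng(3)
        vol = hf.VolumeGrid(voxels=rng.normal(size=(32,) * 3).astype(np.float32),
                            voxel_size=2.0)
        curve = compute_fsc(vol, vol)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-6)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(4)
        a = hf.VolumeGrid(voxels=rng.normal(size=(64,) * 3).astype(np.float32),
                          voxel_size=2.0)
        b = hf.VolumeGrid(voxels=rng.normal(size=(64,) * 3).astype(np.float32),
                          voxel_size=2.0)
        curve = compute_fsc(a, b)
        assert np.all(np.abs(curve.fsc[3:]) < 0.2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        vol = hf.VolumeGrid(voxels=rng.normal(size=(32,) * 3).astype(np.float32),
                            voxel_size=2.0)
        scaled = hf.VolumeGrid(voxels=(2.7 * vol.voxels).astype(np.float32),
                               voxel_size=2.0)
        curve = compute_fsc(vol, scaled)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-5)

    def test_grid_mismatch_rejected(self):
        a = hf.VolumeGrid(voxels=np.zeros((32,) * 3, np.float32), voxel_size=2.0)
        b = hf.VolumeGrid(voxels=np.zeros((16,) * 3, np.float32), voxel_size=2.0)
        with pytest.raises(ValueError, match="mismatch"):
            compute_fsc(a, b)


class TestResolutionAtThreshold:
    def test_constructed_step_curve(self):
        freqs = np.linspace(0.0, 0.25, 32)
        fsc = np.where(freqs <= 1.0 / 20.0, 1.0, 0.0)
        curve = FSCCurve(frequencies=freqs, fsc=fsc)
        res = resolution_at_threshold(curve, 0.5, voxel_size=2.0)
        assert res == pytest.approx(20.0, abs=2.0)   # one shell width

    def test_never_crossing_returns_nyquist_with_flag(self):
        freqs = np.linspace(0.0, 0.25, 32)
        curve = FSCCurve(frequencies=freqs, fsc=np.ones(32))
        res = resolution_at_threshold(curve, 0.5, voxel_size=2.0)
        assert res == pytest.approx(4.0)
        assert curve.no_crossing

    def test_threshold_out_of_range_rejected(self):
        curve = FSCCurve(frequencies=np.array([0.0, 0.1]), fsc=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="threshold"):
            resolution_at_threshold(curve, 1.5)

    def test_half_set_resolution_improves_with_image_count(self):
        phantom = _two_blob_phantom()
        rng = np.random.default_rng(6)
        res = []
        for n in (20, 60):
            phis = np.linspace(0, 360, n, endpoint=False)
            imgs = []
            for p in phis:
                img = _project.project_volume(phantom.voxels.astype(float), p, 90.0, 0.0)
                imgs.append(img + rng.normal(0, 2.0 * img.std(), img.shape))
            halves = []
            for half in (imgs[0::2], imgs[1::2]):
                hphis = phis[0::2] if half is imgs[0::2] else phis[1::2]
                ors = OrientationAssignment(
                    angles=np.column_stack([hphis, np.full(len(half), 90.0),
                                            np.zeros(len(half))]),
                    shifts=np.zeros((len(half), 2)), scores=np.ones(len(half)))
                halves.append(back_project(half, ors, voxel_size=2.0))
            curve = compute_fsc(*halves)
            res.append(resolution_at_threshold(curve, 0.5, voxel_size=2.0))
        assert res[1] <= res[0] + 1e-9


class TestReconstructFilament:
    @pytest.fixture(scope="class")
    def noisy_segments(self, extended_volume):
        rng = np.random.default_rng(9)
        vox = extended_volume.voxels.astype(float)
        imgs = []
        for _ in range(60):
            img = _project.project_volume(vox, rng.uniform(0, 360), 90.0, 0.0)
            imgs.append(img + rng.normal(0, np.sqrt(img.var() / 0.2), img.shape))
        return imgs

    def test_phantom_recovery_and_self_consistency(self, extended_volume,
                                                   noisy_segments):
        hp = HelicalParams(pitch=110.0, twist=40.5)
        vol = reconstruct_filament(noisy_segments, hp, WORK_PIXEL)
        corr = masked_volume_correlation(vol.voxels.astype(float),
                                         extended_volume.voxels.astype(float), 16, 19)
        assert corr >= 0.9
        assert helical_self_correlation(vol, hp) >= 0.99

    def test_measured_diameter_matches_generator(self, extended_volume,
                                                 noisy_segments):
        hp = HelicalParams(pitch=110.0, twist=40.5)
        vol = reconstruct_filament(noisy_segments, hp, WORK_PIXEL)
        outer, _ = hf.measure_diameters(hf.radial_density_profile(vol), 1.0)
        ref_outer, _ = hf.measure_diameters(
            hf.radial_density_profile(extended_volume), 1.0)
        assert outer == pytest.approx(ref_outer, abs=2 * WORK_PIXEL + 1.0)

    def test_half_set_fsc_starts_at_unity_and_trends_down(self, noisy_segments):
        hp = HelicalParams(pitch=110.0, twist=40.5)
        half1 = reconstruct_filament(noisy_segments[0::2], hp, WORK_PIXEL,
                                     align_rounds=1)
        half2 = reconstruct_filament(noisy_segments[1::2], hp, WORK_PIXEL,
                                     align_rounds=1)
        curve = compute_fsc(half1, half2)
        assert curve.fsc[0] == pytest.approx(1.0, abs=1e-3)
        smooth = np.convolve(curve.fsc, np.ones(3) / 3, mode="valid")
        assert smooth[-1] < smooth[0]
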