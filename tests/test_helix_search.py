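"""Helical symmetrisation, reprojection, matching error and the grid search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helifil as hf
from helifil import _project
from helifil.helix_search import (HelicalParams, SearchGrid, symmetrize,
                                  reproject_model, match_error, grid_search,
                                  refine_minimum, search_helical_params,
                                  estimate_filament_radius,
                                  ParametricReferenceBuilder,
                                  helical_self_correlation)
from helifil.synthfil import ImagingParams

from helpers import WORK_BOX, WORK_PIXEL


class TestHelicalParams:
    @given(pitch=st.floats(1.0, 500.0), twist=st.floats(0.1, 359.9))
    @settings(max_examples=50, deadline=None)
    def test_rise_consistent_with_pitch_and_twist(self, pitch, twist):
        hp = HelicalParams(pitch=pitch, twist=twist)
        assert hp.rise == pytest.approx(pitch * twist / 360.0, abs=1e-9)

    @pytest.mark.parametrize("pitch,twist", [(-1.0, 40.0), (0.0, 40.0),
                                             (100.0, 0.0), (100.0, 360.0)])
    def test_invalid_parameters_rejected(self, pitch, twist):
        with pytest.raises(ValueError):
            HelicalParams(pitch=pitch, twist=twist)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="steps"):
            SearchGrid((80, 130), 0.0, (35, 48), 2.0)
        with pytest.raises(ValueError, match="ranges"):
            SearchGrid((130, 80), 3.2, (35, 48), 2.0)


HP_EXT = HelicalParams(pitch=110.0, twist=40.5)


@pytest.fixture(scope="module")
def smooth_volume():
    """Well-sampled helical model (blob sigma = 2 voxels): contract checks
    on the symmetry operators are not confounded by interpolation of
    voxel-scale detail."""
    from helifil.synthfil import GaussianBlob, DnaThread, HelicalModel
    model = HelicalModel(pitch=110.0, twist=40.5, filament_radius=46.0,
                         protomer=(GaussianBlob((0.0, 0.0, 0.0), 8.0, 1.0),),
                         axial_dna=DnaThread(4.5), n_turns=3.0)
    return hf.build_helical_volume(model, WORK_BOX, WORK_PIXEL)


class TestSymmetrize:
    def test_cylinder_unchanged(self):
        box = WORK_BOX
        c = (box - 1) / 2
        zz, yy, xx = np.mgrid[0:box, 0:box, 0:box]
        r = np.hypot(yy - c, xx - c)
        cyl = np.exp(-((r - 10) ** 2) / 20).astype(np.float32)
        vol = hf.VolumeGrid(voxels=cyl, voxel_size=WORK_PIXEL)
        out = symmetrize(vol, HP_EXT, 0.6)
        rel_rms = np.sqrt(((out.voxels - cyl) ** 2).mean()) / cyl.std()
        assert rel_rms < 1e-2

    def test_idempotent(self, smooth_volume):
        once = symmetrize(smooth_volume, HP_EXT, 0.6)
        twice = symmetrize(once, HP_EXT, 0.6)
        a = once.voxels.ravel() - once.voxels.mean()
        b = twice.voxels.ravel() - twice.voxels.mean()
        assert a @ b / (np.linalg.norm(a) * np.linalg.norm(b)) >= 0.999

    def test_output_invariant_under_own_operator(self):
        # band-limited random input; invariance read over the central region
        # that symmetrisation actually averages (edge voxels with no trusted
        # source keep their input values by contract)
        from scipy import ndimage
        rng = np.random.default_rng(0)
        noise = ndimage.gaussian_filter(rng.normal(size=(WORK_BOX,) * 3), 1.5)
        vol = hf.VolumeGrid(voxels=noise.astype(np.float32), voxel_size=WORK_PIXEL)
        out = symmetrize(vol, HP_EXT, 0.6)
        box = WORK_BOX
        c = (box - 1) / 2
        zz, yy, xx = np.mgrid[0:box, 0:box, 0:box]
        central = ((np.hypot(yy - c, xx - c) <= 0.42 * box)
                   & (np.abs(zz - c) <= 0.35 * box))
        moved = _project.screw_resample(out.voxels.astype(float), HP_EXT.twist,
                                        HP_EXT.rise / WORK_PIXEL)
        good = np.isfinite(moved) & central
        a = out.voxels[good] - out.voxels[good].mean()
        b = moved[good] - moved[good].mean()
        assert a @ b / (np.linalg.norm(a) * np.linalg.norm(b)) >= 0.995

    def test_generator_self_consistency(self, extended_volume):
        out = symmetrize(extended_volume, HP_EXT, 0.6)
        a = out.voxels.ravel() - out.voxels.mean()
        b = extended_volume.voxels.ravel() - extended_volume.voxels.mean()
        assert a @ b / (np.linalg.norm(a) * np.linalg.norm(b)) >= 0.99

    def test_subvoxel_rise_rejected(self):
        vol = hf.VolumeGrid(voxels=np.zeros((32,) * 3, np.float32), voxel_size=4.0)
        with pytest.raises(ValueError, match="undersampled"):
            symmetrize(vol, HelicalParams(pitch=20.0, twist=40.0), 0.6)


class TestReprojectModel:
    def test_symmetric_volume_periodic_in_azimuth(self, smooth_volume):
        # advancing the azimuth by one twist equals an axial shift by one
        # rise (the screw symmetry); compare away from the box edges
        sym = symmetrize(smooth_volume, HP_EXT, 0.6)
        a = _project.project_volume(sym.voxels.astype(float), 10.0, 90.0, 0.0)
        b = _project.project_volume(sym.voxels.astype(float), 10.0 + HP_EXT.twist,
                                    90.0, 0.0)
        b = _project.shift_image(b, -HP_EXT.rise / WORK_PIXEL, 0.0)
        rows = slice(10, WORK_BOX - 10)
        assert _project.ncc(a[rows], b[rows]) >= 0.999

    def test_single_azimuth(self, extended_volume):
        assert len(reproject_model(extended_volume, HP_EXT, 1)) == 1

    def test_matches_render_projection_path(self, extended_volume):
        projs = reproject_model(extended_volume, HP_EXT, 3)
        imaging = ImagingParams(box_size=WORK_BOX, pixel_size=WORK_PIXEL)
        for i, proj in enumerate(projs):
            direct = hf.render_projection(extended_volume,
                                          (i * HP_EXT.twist / 3, 90.0, 0.0), imaging)
            np.testing.assert_allclose(proj, direct, atol=1e-8)


class TestMatchError:
    def test_exact_reprojection_scores_zero(self, extended_volume):
        projs = reproject_model(extended_volume, HP_EXT, 4)
        err = match_error(projs[2], projs, WORK_PIXEL, HP_EXT.pitch, rot_range=0)
        assert err < 1e-6

    def test_shifted_copy_recovered(self, extended_volume):
        projs = reproject_model(extended_volume, HP_EXT, 2)
        shifted = np.roll(projs[0], 3, axis=0)   # axial shift by 3 px
        err = match_error(shifted, projs, WORK_PIXEL, HP_EXT.pitch, rot_range=0)
        assert err < 1e-3

    def test_wrong_pitch_scores_worse(self, extended_volume):
        builder = ParametricReferenceBuilder(radius=54.0)
        img = reproject_model(extended_volume, HP_EXT, 1)[0]
        errs = {}
        for pitch in (110.0, 113.2):
            hp = HelicalParams(pitch=pitch, twist=40.5)
            ref = builder([img], hp, WORK_PIXEL)
            projs = reproject_model(ref, hp, 8)
            errs[pitch] = match_error(img, projs, WORK_PIXEL, pitch)
        assert errs[110.0] < errs[113.2]

    def test_box_mismatch_rejected(self):
        with pytest.raises(ValueError, match="box"):
            match_error(np.zeros((32, 32)), [np.zeros((64, 64))], 4.0, 100.0)


class TestGridSearch:
    @pytest.fixture(scope="class")
    def noiseless_avgs(self, extended_volume):
        rng = np.random.default_rng(1)
        vox = extended_volume.voxels.astype(float)
        return [_project.project_volume(vox, rng.uniform(0, 360), 90.0, 0.0)
                for _ in range(8)]

    def test_noiseless_data_minimum_at_generating_node(self, noiseless_avgs):
        grid = SearchGrid((103.6, 116.4), 3.2, (36.5, 44.5), 2.0)
        surface = grid_search(noiseless_avgs, grid, WORK_PIXEL,
                              n_azimuths=8, rot_range=0)
        pitch, twist, _ = surface.global_minimum()
        assert (pitch, twist) == (110.0, 40.5)

    def test_surface_dimensions_match_grid(self, noiseless_avgs):
        grid = SearchGrid((106.8, 113.2), 3.2, (38.5, 42.5), 2.0)
        surface = grid_search(noiseless_avgs, grid, WORK_PIXEL,
                              n_azimuths=8, rot_range=0)
        assert surface.error.shape == (len(grid.pitches), len(grid.twists))
        assert np.isfinite(surface.error).all()

    def test_deterministic_bit_identical_surfaces(self, noiseless_avgs):
        grid = SearchGrid((108.0, 112.0), 2.0, (39.5, 41.5), 1.0)
        a = grid_search(noiseless_avgs, grid, WORK_PIXEL, n_azimuths=8, rot_range=0)
        b = grid_search(noiseless_avgs, grid, WORK_PIXEL, n_azimuths=8, rot_range=0)
        np.testing.assert_array_equal(a.error, b.error)

    def test_refine_recovers_within_one_fine_step(self, noiseless_avgs):
        fine = SearchGrid((108.4, 112.4), 0.5, (39.0, 43.0), 0.5)
        refined = refine_minimum(noiseless_avgs, HelicalParams(110.4, 41.0),
                                 fine, WORK_PIXEL, n_azimuths=8, rot_range=0)
        assert refined.params.pitch == pytest.approx(110.0, abs=0.5)
        assert refined.params.twist == pytest.approx(40.5, abs=0.5)

    def test_boundary_minimum_flagged(self, noiseless_avgs):
        # fine window deliberately off to one side of the true optimum
        fine = SearchGrid((111.5, 114.0), 0.5, (41.5, 43.5), 0.5)
        with pytest.warns(UserWarning, match="boundary"):
            refined = refine_minimum(noiseless_avgs, HelicalParams(112.0, 42.0),
                                     fine, WORK_PIXEL, n_azimuths=8, rot_range=0)
        assert refined.at_boundary

    def test_empty_class_average_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            grid_search([], SearchGrid((100, 110), 5, (40, 42), 1), WORK_PIXEL)


class TestFilamentRadiusEstimate:
    def test_extended_and_compressed_radii_ordered(self, study_mixture):
        stack, meta = study_mixture
        from helifil.preprocess import preprocess_stack
        filtered = preprocess_stack(stack)
        ext = [img.astype(float) for img, s in zip(filtered.images, meta.state)
               if s == "extended"][:50]
        comp = [img.astype(float) for img, s in zip(filtered.images, meta.state)
                if s == "compressed"][:50]
        r_ext = estimate_filament_radius(ext, WORK_PIXEL)
        r_comp = estimate_filament_radius(comp, WORK_PIXEL)
        assert r_comp > r_ext
        assert r_ext == pytest.approx(54.0, abs=8.0)
        assert r_comp == pytest.approx(65.0, abs=8.0)


def test_reca_like_twist_recovery_gives_six_ish_protomers():
    """Scaled-down RecA-like search: recovered twist ~59 deg puts the
    protomer count per turn between 6 and 6.2."""
    from helifil.preprocess import preprocess_stack
    from helifil.msa import eigen_decompose, classify, class_average
    from helpers import make_config

    cfg = make_config(21, n_segments=200, states=[{"name": "reca", "fraction": 1.0}])
    stack, _ = hf.generate_dataset(cfg)
    stack = preprocess_stack(stack)
    eig = eigen_decompose(stack, 10)
    cls = classify(stack, eig, n_classes=13, seed=5)
    avgs = [ca.image for ca in class_average(stack, cls)]
    grid = SearchGrid((72.0, 92.0), 3.2, (50.0, 68.0), 3.0)
    refined, _ = search_helical_params(avgs, WORK_PIXEL, coarse=grid,
                                       n_azimuths=8, rot_step=10.0)
    ppt = 360.0 / refined.params.twist
    assert 6.0 < ppt < 6.2
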