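"""Fiducial tilt-series alignment: per-stage oracles on simulated data and
the deterministic end-to-end chain."""

import numpy as np
import pytest

from stakit.fixtures import SimulationRecipe, simulate_tilt_series
from stakit.tilt_alignment import (
    AlignmentParams,
    AlignmentResult,
    Marker3DModel,
    MarkerObservation,
    MarkerTrail,
    ProjectionModel,
    TiltSeries,
    align_tilt_series,
    build_data_template,
    center_trails,
    detect_candidates,
    estimate_initial_model,
    extract_patch,
    index_trails,
    project_points,
    prune_by_rmsd,
    refine_marker_centers,
    reindex_by_reprojection,
    reintegrate_missing,
    residual_norms,
    rotational_symmetry_filter,
    shift_gauge_residuals,
    solve_projection_model,
    synthetic_bead_template,
    triangulate_markers,
    write_imod_alignment,
    xf_matrix,
)

# ---------------------------------------------------------------- helpers


def dummy_series(n_img=41, tilts=(-60, 60)):
    # 1x1 images put the center at (0, 0): observation coordinates built
    # straight from the projection equation need no frame conversion
    angles = np.linspace(tilts[0], tilts[1], n_img)
    return TiltSeries(np.zeros((n_img, 1, 1)), angles)


def exact_trails(model, beads, noise=0.0, outlier_frac=0.0, seed=0,
                 drop=None):
    """Trails built directly from the projection equation (no images)."""
    rng = np.random.default_rng(seed)
    proj = project_points(model, beads)
    trails = []
    for j in range(len(beads)):
        obs = []
        for i in range(model.n_images):
            if drop and (i, j) in drop:
                continue
            p = proj[i, j].copy()
            if noise:
                p += rng.normal(0, noise, 2)
            if outlier_frac and rng.random() < outlier_frac:
                p = rng.uniform(-256, 256, 2)
            obs.append(MarkerObservation(i, p, 1.0))
        trails.append(MarkerTrail(observations=obs, marker_id=j))
    return trails


@pytest.fixture(scope="module")
def geometry():
    rng = np.random.default_rng(17)
    n_img, n_beads = 41, 15
    tilts = np.linspace(-60, 60, n_img)
    beads = np.column_stack([
        rng.uniform(-150, 150, n_beads),
        rng.uniform(-150, 150, n_beads),
        rng.uniform(-60, 60, n_beads),
    ])
    beads -= beads.mean(axis=0)
    model = ProjectionModel(85.0, rng.uniform(-20, 20, (n_img, 2)), tilts)
    return model, beads


# ---------------------------------------------------------------- detection


class TestBeadTemplate:
    def test_radius_3_disc_pixel_count(self):
        t = synthetic_bead_template(3)
        assert t.shape == (13, 13)
        assert int((t < 0).sum()) == 29  # discrete disc of radius 3

    def test_radius_1_plus_shape(self):
        t = synthetic_bead_template(1)
        assert t.shape == (5, 5)
        assert int((t < 0).sum()) == 5

    def test_fourfold_symmetric(self):
        t = synthetic_bead_template(4)
        assert np.array_equal(t, np.rot90(t))

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            synthetic_bead_template(0)


class TestDetection:
    def test_planted_bead_found_within_one_pixel(self):
        img = np.zeros((128, 128))
        from stakit.fixtures import _render_bead

        _render_bead(img, np.array([70.0, 50.0]), 4.0)
        obs = detect_candidates(img, synthetic_bead_template(4), n_peaks=3)
        assert np.linalg.norm(obs[0].position_2d - [70, 50]) < 1.0

    def test_two_beads_top_two_peaks(self):
        img = np.zeros((128, 128))
        from stakit.fixtures import _render_bead

        _render_bead(img, np.array([30.0, 30.0]), 4.0)
        _render_bead(img, np.array([70.0, 30.0]), 4.0)
        obs = detect_candidates(img, synthetic_bead_template(4), n_peaks=2)
        got = sorted(round(o.position_2d[0]) for o in obs)
        assert got == [30, 70]

    def test_flat_image_yields_nothing(self):
        assert detect_candidates(np.zeros((64, 64)),
                                 synthetic_bead_template(3), 5) == []

    def test_noise_scores_below_planted_scores(self, rng):
        from stakit.fixtures import _render_bead

        noise = rng.normal(0, 0.5, (128, 128))
        planted = noise.copy()
        _render_bead(planted, np.array([64.0, 64.0]), 4.0)
        t = synthetic_bead_template(4)
        s_noise = max(o.cc_score for o in detect_candidates(noise, t, 5))
        s_plant = max(o.cc_score for o in detect_candidates(planted, t, 5))
        assert s_plant > s_noise

    def test_template_must_be_smaller(self):
        with pytest.raises(ValueError):
            detect_candidates(np.zeros((8, 8)), synthetic_bead_template(4), 1)


class TestDataTemplate:
    def test_identical_beads_average_to_single_bead_patch(self, clean_sim):
        series, model, markers = clean_sim
        t = synthetic_bead_template(series.fiducial_radius_px)
        cands = []
        for i in range(series.n_images):
            cands.extend(detect_candidates(series.images[i], t, 10,
                                           image_index=i))
        side = 4 * series.fiducial_radius_px + 1
        data_t = build_data_template(series, cands, template_side=side)
        single = extract_patch(series.images[cands[0].image_index],
                               cands[0].position_2d, side)
        # same bead shape up to subpixel sampling differences
        corr = np.corrcoef(data_t.ravel(), single.ravel())[0, 1]
        assert corr > 0.98

    def test_single_candidate_returns_that_subimage(self, clean_sim):
        series, _, _ = clean_sim
        t = synthetic_bead_template(series.fiducial_radius_px)
        obs = detect_candidates(series.images[0], t, 1, image_index=0)
        side = 4 * series.fiducial_radius_px + 1
        data_t = build_data_template(series, obs[:1], template_side=side)
        assert np.array_equal(
            data_t, extract_patch(series.images[0], obs[0].position_2d, side)
        )

    def test_averaging_reduces_background_noise(self, rng):
        sigma = 0.5
        k = 100
        patches = rng.normal(0, sigma, (k, 17, 17))
        series = TiltSeries(patches, np.zeros(k))
        cands = [
            MarkerObservation(i, np.array([8.0, 8.0]), 1.0) for i in range(k)
        ]
        avg = build_data_template(series, cands, template_side=17,
                                  n_subimages=k)
        assert avg.std() < 2 * sigma / np.sqrt(k)


class TestSymmetryFilter:
    def test_bead_retained_straight_edge_discarded(self):
        from stakit.fixtures import _render_bead

        bead = np.zeros((17, 17))
        _render_bead(bead, np.array([8.0, 8.0]), 4.0)
        edge = np.zeros((17, 17))
        edge[:, :8] = -1.0
        obs = [MarkerObservation(0, np.array([8.0, 8.0]), 1.0)] * 2
        kept = rotational_symmetry_filter(obs, [bead, edge], threshold=0.5)
        assert len(kept) == 1

    def test_threshold_minus_one_retains_all(self, rng):
        subs = [rng.normal(0, 1, (9, 9)) for _ in range(5)]
        obs = [MarkerObservation(0, np.array([4.0, 4.0]), 1.0)] * 5
        assert len(rotational_symmetry_filter(obs, subs, threshold=-1.0)) == 5


# ---------------------------------------------------------------- trails


def separated_series(n_img=21, size=256):
    """Noise-free series whose bead projections never overlap."""
    from stakit.fixtures import _render_bead

    tilts = np.linspace(-60, 60, n_img)
    rng = np.random.default_rng(2)
    model = ProjectionModel(40.0, rng.uniform(-5, 5, (n_img, 2)), tilts)
    # z = 0 keeps projected separations >= 35 px at every tilt
    beads = np.array([
        [x, y, 0.0]
        for x, y in [(-70, -70), (0, -70), (70, -70), (-70, 0),
                     (70, 0), (-70, 70), (0, 70), (70, 70)]
    ], dtype=float)
    beads -= beads.mean(axis=0)
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    proj = project_points(model, beads) + center
    images = np.zeros((n_img, size, size))
    for i in range(n_img):
        for j in range(len(beads)):
            _render_bead(images[i], proj[i, j], 4.0)
    series = TiltSeries(images, tilts, pixel_size=10.0, fiducial_diameter=8.0)
    return series, model, beads


class TestIndexTrails:
    def test_noiseless_series_full_trails(self):
        series, model, beads = separated_series()
        t = synthetic_bead_template(series.fiducial_radius_px)
        obs = []
        for i in range(series.n_images):
            obs.extend(detect_candidates(series.images[i], t, 12,
                                         image_index=i))
        trails = index_trails(series, obs)
        full = [tr for tr in trails if len(tr) == series.n_images]
        assert len(full) == len(beads)

    def test_single_image_no_trails(self, clean_sim):
        series, _, _ = clean_sim
        t = synthetic_bead_template(series.fiducial_radius_px)
        obs = detect_candidates(series.images[0], t, 12, image_index=0)
        assert index_trails(series, obs) == []


# ---------------------------------------------------------------- solving


class TestTriangulate:
    def test_noiseless_recovery(self, geometry):
        model, beads = geometry
        trails = exact_trails(model, beads)
        mk = triangulate_markers(trails, model)
        err = max(
            np.linalg.norm(mk.coordinates[j] - beads[j])
            for j in range(len(beads))
        )
        assert err < 1e-6

    def test_marker_at_origin_zero_shift_projects_to_center(self):
        model = ProjectionModel(0.0, np.zeros((5, 2)),
                                np.linspace(-60, 60, 5))
        proj = project_points(model, np.zeros((1, 3)))
        assert np.abs(proj).max() < 1e-12

    def test_noisy_recovery_scales_like_sigma_over_sqrt_n(self, geometry):
        model, beads = geometry
        sigma = 1.0
        trails = exact_trails(model, beads, noise=sigma, seed=4)
        mk = triangulate_markers(trails, model)
        err = np.array([mk.coordinates[j] - beads[j] for j in range(len(beads))])
        per_coord = err.std(axis=0)
        # z is less constrained by a +/-60 degree range; allow 4x
        assert np.all(per_coord < 4 * sigma / np.sqrt(41))
        assert np.all(per_coord[:2] < 2 * sigma / np.sqrt(41))

    def test_single_view_marker_skipped(self):
        model = ProjectionModel(10.0, np.zeros((3, 2)), [-30.0, 0.0, 30.0])
        lone = MarkerTrail(
            observations=[MarkerObservation(1, np.array([5.0, 5.0]), 1.0)],
            marker_id=0,
        )
        assert len(triangulate_markers([lone], model)) == 0


class TestSolveProjectionModel:
    def test_noiseless_exact_recovery(self, geometry):
        model, beads = geometry
        trails = exact_trails(model, beads)
        series = dummy_series()
        init, mk0 = estimate_initial_model(trails, series)
        est, mk = solve_projection_model(trails, mk0, series, initial=init)
        assert abs(est.tilt_axis_angle - model.tilt_axis_angle) < 0.01
        assert np.abs(est.shifts - model.shifts).max() < 0.01

    def test_axis_markers_zero_residual(self):
        tilts = np.linspace(-60, 60, 11)
        model = ProjectionModel(0.0, np.zeros((11, 2)), tilts)
        beads = np.column_stack([np.zeros(4), np.linspace(-50, 50, 4),
                                 np.zeros(4)])
        trails = exact_trails(model, beads)
        assert np.abs(project_points(model, beads)[:, :, 0]).max() < 1e-12
        mk = triangulate_markers(trails, model)
        res = residual_norms(trails, model, mk)
        assert max(r.max() for r in res.values()) < 1e-9

    def test_robust_beats_plain_lsq_with_outliers(self, geometry):
        model, beads = geometry
        series = dummy_series()
        trails = exact_trails(model, beads, noise=0.5, outlier_frac=0.10,
                              seed=11)
        init, mk0 = estimate_initial_model(trails, series)
        est_rob, _ = solve_projection_model(trails, mk0, series, robust=True,
                                            initial=init)
        est_lsq, _ = solve_projection_model(trails, mk0, series, robust=False,
                                            initial=init)
        err_rob = abs(est_rob.tilt_axis_angle - model.tilt_axis_angle)
        err_lsq = abs(est_lsq.tilt_axis_angle - model.tilt_axis_angle)
        assert err_rob < 0.1
        assert err_lsq > err_rob

    def test_insufficient_markers_rejected(self, geometry):
        model, beads = geometry
        trails = exact_trails(model, beads)[:2]
        with pytest.raises(ValueError, match=">= 3"):
            solve_projection_model(trails, triangulate_markers(trails, model),
                                   dummy_series())

    def test_tilt_angles_never_modified(self, geometry):
        model, beads = geometry
        series = dummy_series()
        trails = exact_trails(model, beads, noise=0.3, seed=2)
        init, mk0 = estimate_initial_model(trails, series)
        est, _ = solve_projection_model(trails, mk0, series, initial=init)
        assert np.array_equal(est.tilt_angles, series.nominal_tilt_angles)


class TestReindex:
    def test_withheld_assignments_recovered(self, geometry):
        model, beads = geometry
        rng = np.random.default_rng(3)
        full = exact_trails(model, beads)
        observations = [o for t in full for o in t.observations]
        # withhold 20%: rebuild trails missing those observations
        keep_mask = rng.random(len(observations)) > 0.2
        index_of = {id(o): k for k, o in enumerate(observations)}
        series = dummy_series()
        kept_trails = []
        for t in full:
            obs = [o for o in t.observations if keep_mask[index_of[id(o)]]]
            if len(obs) >= 2:
                kept_trails.append(MarkerTrail(observations=obs,
                                               marker_id=t.marker_id))
        init, mk0 = estimate_initial_model(kept_trails, series)
        est, mk = solve_projection_model(kept_trails, mk0, series,
                                         initial=init)
        trails, est, mk = reindex_by_reprojection(
            est, mk, observations, series, distance_threshold_px=5.0
        )
        assert sum(len(t) for t in trails) == len(observations)

    def test_zero_threshold_adds_nothing(self, geometry):
        model, beads = geometry
        trails = exact_trails(model, beads)
        observations = [o for t in trails for o in t.observations]
        mk = triangulate_markers(trails, model)
        out, _, _ = reindex_by_reprojection(
            model, mk, observations, dummy_series(), distance_threshold_px=0.0
        )
        assert sum(len(t) for t in out) == 0

    def test_close_markers_one_observation_each(self):
        tilts = np.linspace(-60, 60, 11)
        model = ProjectionModel(0.0, np.zeros((11, 2)), tilts)
        beads = np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        proj = project_points(model, beads)
        obs = [MarkerObservation(i, proj[i, 0] + [0.0, 0.4], 1.0)
               for i in range(11)]
        mk = Marker3DModel(coordinates={0: beads[0], 1: beads[1]})
        trails, _, _ = reindex_by_reprojection(
            model, mk, obs, dummy_series(11), distance_threshold_px=3.0,
            max_rounds=1,
        )
        # each observation is assigned once, to the nearer marker only
        total = sum(len(t) for t in trails)
        assert total == len(obs)


class TestReintegrate:
    def test_deleted_image_fully_recovered(self, geometry):
        model, beads = geometry
        full = exact_trails(model, beads)
        observations = [o for t in full for o in t.observations]
        drop_img = 20
        partial = []
        for t in full:
            obs = [o for o in t.observations if o.image_index != drop_img]
            partial.append(MarkerTrail(observations=obs,
                                       marker_id=t.marker_id))
        mk = triangulate_markers(partial, model)
        out = reintegrate_missing(model, mk, dummy_series(), observations,
                                  partial, search_radius_px=5.0)
        count = sum(
            1 for t in out for o in t.observations
            if o.image_index == drop_img
        )
        assert count == len(beads)

    def test_never_decreases_observation_count(self, geometry):
        model, beads = geometry
        trails = exact_trails(model, beads, noise=0.5, seed=8)
        observations = [o for t in trails for o in t.observations]
        mk = triangulate_markers(trails, model)
        before = sum(len(t) for t in trails)
        out = reintegrate_missing(model, mk, dummy_series(), observations,
                                  trails, search_radius_px=5.0)
        assert sum(len(t) for t in out) >= before


class TestRefineCenters:
    def test_truncated_positions_recovered(self, clean_sim):
        series, model, markers = clean_sim
        proj = project_points(model, markers.as_array()) + series.center
        trails = []
        for j in range(len(markers)):
            obs = [
                MarkerObservation(i, np.floor(proj[i, j]), 1.0)
                for i in range(series.n_images)
            ]
            trails.append(MarkerTrail(observations=obs, marker_id=j))
        refined = refine_marker_centers(series, trails)
        errs = np.concatenate([
            np.linalg.norm(t.positions - proj[:, j], axis=1)
            for j, t in enumerate(refined)
        ])
        assert np.median(errs) < 0.1

    def test_single_observation_marker_unchanged(self, clean_sim):
        series, _, _ = clean_sim
        lone = MarkerTrail(
            observations=[MarkerObservation(0, np.array([100.0, 100.0]), 1.0)],
            marker_id=0,
        )
        out = refine_marker_centers(series, [lone])
        assert np.array_equal(out[0].positions, [[100.0, 100.0]])

    def test_refinement_does_not_worsen_model_fit(self, clean_sim):
        series, model, markers = clean_sim
        proj = project_points(model, markers.as_array()) + series.center
        rng = np.random.default_rng(0)
        trails = []
        for j in range(len(markers)):
            obs = [
                MarkerObservation(i, proj[i, j] + rng.uniform(-0.4, 0.4, 2),
                                  1.0)
                for i in range(series.n_images)
            ]
            trails.append(MarkerTrail(observations=obs, marker_id=j))

        def mean_residual(trs):
            res = residual_norms(center_trails(trs, series.center), model,
                                 markers)
            return np.mean(np.concatenate(list(res.values())))

        before = mean_residual(trails)
        after = mean_residual(refine_marker_centers(series, trails))
        assert after <= before


class TestPrune:
    def make_result(self, geometry, bad_marker=None):
        model, beads = geometry
        series = dummy_series()
        trails = exact_trails(model, beads, noise=0.2, seed=6)
        if bad_marker is not None:
            for o in trails[bad_marker].observations:
                o.position_2d = o.position_2d + np.array([10.0, 0.0]) * np.sign(
                    np.sin(o.image_index)
                )
        mk = triangulate_markers(trails, model)
        est, mk = solve_projection_model(trails, mk, series, initial=model,
                                         robust=False)
        res = residual_norms(trails, est, mk)
        return AlignmentResult(est, mk, res), trails, series

    def test_systematic_error_marker_pruned(self, geometry):
        result, trails, series = self.make_result(geometry, bad_marker=4)
        out = prune_by_rmsd(result, 3.0, trails, series)
        assert out.pruned_marker_ids == [4]
        assert out.global_rmsd <= result.global_rmsd

    def test_infinite_threshold_prunes_nothing(self, geometry):
        result, trails, series = self.make_result(geometry)
        out = prune_by_rmsd(result, np.inf, trails, series)
        assert out.pruned_marker_ids == []

    def test_pruning_below_three_markers_rejected(self, geometry):
        result, trails, series = self.make_result(geometry)
        with pytest.raises(ValueError, match="at least 3"):
            prune_by_rmsd(result, 1e-12, trails, series)


# ---------------------------------------------------------------- output


class TestImodOutput:
    def test_identity_model_identity_xf(self, tmp_path):
        model = ProjectionModel(0.0, np.zeros((3, 2)), [-3.0, 0.0, 3.0])
        result = AlignmentResult(model, Marker3DModel(), {})
        write_imod_alignment(result, tmp_path / "a.xf", tmp_path / "a.tlt")
        rows = np.loadtxt(tmp_path / "a.xf")
        assert rows.shape == (3, 6)
        assert np.allclose(rows, [[1, 0, 0, 1, 0, 0]] * 3)

    def test_90_degree_axis_rotation_part(self):
        a, t = xf_matrix(90.0, np.zeros(2))
        assert np.allclose(a, [[0, 1], [-1, 0]], atol=1e-12)

    def test_tlt_bit_preserves_nominal_angles(self, tmp_path):
        angles = np.array([-60.0, -31.7, 0.123456789, 60.0])
        model = ProjectionModel(10.0, np.zeros((4, 2)), angles)
        result = AlignmentResult(model, Marker3DModel(), {})
        write_imod_alignment(result, tmp_path / "b.xf", tmp_path / "b.tlt")
        back = np.array([
            float(line)
            for line in (tmp_path / "b.tlt").read_text().splitlines()
        ])
        assert np.array_equal(back, angles)

    def test_xf_grammar_six_floats_per_line(self, tmp_path):
        model = ProjectionModel(33.0, np.arange(10).reshape(5, 2),
                                np.linspace(-6, 6, 5))
        result = AlignmentResult(model, Marker3DModel(), {})
        write_imod_alignment(result, tmp_path / "c.xf", tmp_path / "c.tlt")
        for line in (tmp_path / "c.xf").read_text().splitlines():
            assert len(line.split()) == 6


# ---------------------------------------------------------------- end-to-end


class TestEndToEnd:
    def test_small_series_parameter_recovery(self, small_sim):
        series, truth_model, truth_markers = small_sim
        result = align_tilt_series(series)
        est = result.projection_model
        psi_err = abs(
            (est.tilt_axis_angle - truth_model.tilt_axis_angle + 90) % 180
            - 90
        )
        assert psi_err < 0.5
        shift_err = shift_gauge_residuals(est, truth_model)
        assert np.median(shift_err) < 0.5
        assert np.array_equal(est.tilt_angles, series.nominal_tilt_angles)

    def test_determinism(self, small_sim):
        series, _, _ = small_sim
        a = align_tilt_series(series)
        b = align_tilt_series(series)
        assert a.projection_model.tilt_axis_angle == b.projection_model.tilt_axis_angle
        assert np.array_equal(a.projection_model.shifts,
                              b.projection_model.shifts)
        assert a.pruned_marker_ids == b.pruned_marker_ids

    def test_three_bead_minimum_completes(self):
        recipe = SimulationRecipe(
            n_tilts=21, image_size=256, n_beads=3, shift_amplitude=5.0,
            snr=4.0, rng_seed=21,
        )
        series, truth_model, _ = simulate_tilt_series(recipe)
        result = align_tilt_series(series)
        psi_err = abs(
            (result.projection_model.tilt_axis_angle
             - truth_model.tilt_axis_angle + 90) % 180 - 90
        )
        assert psi_err < 1.0

    def test_stage_errors_name_stage(self):
        series = TiltSeries(np.zeros((5, 64, 64)), np.linspace(-6, 6, 5))
        with pytest.raises(RuntimeError, match="stage"):
            align_tilt_series(series)
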