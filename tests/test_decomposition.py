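import numpy as np
import pytest

from fluorotrack.decomposition import (
    DecompositionState,
    SolverConfig,
    estimate_position,
    initialize_references,
    objective,
    residual,
    track_sequence,
    update_background_reference,
    update_tumor_reference,
)
from fluorotrack.image_model import (
    Displacement,
    IntensityImage,
    Region,
    binarize,
    center_of_mass,
    shift_image,
)
from fluorotrack.matching import MatchConfig
from fluorotrack.phantom import (
    MotionSpec,
    PhantomConfig,
    TumorSpec,
    BackgroundSpec,
    render_sequence,
    rough_outline,
)


def single_pixel_outline(shape, row, col):
    m = np.zeros(shape, dtype=bool)
    m[row, col] = True
    return Region(m)


class TestInitialization:
    def test_constant_inside_outline_and_complementary_background(self):
        frame = IntensityImage(np.full((4, 4), 5.0))
        state = initialize_references(frame, single_pixel_outline((4, 4), 1, 2), I0=1.0)
        assert state.tumor_ref.values[1, 2] == 1.0
        assert state.tumor_ref.values.sum() == 1.0
        assert state.bg_ref.values[1, 2] == 4.0
        assert np.all(np.delete(state.bg_ref.values.ravel(), 1 * 4 + 2) == 5.0)
        assert state.d_tumor.as_tuple() == (0, 0)
        assert state.d_bg.as_tuple() == (0, 0)

    def test_zero_intensity_init_warns(self):
        frame = IntensityImage(np.ones((3, 3)))
        with pytest.warns(UserWarning):
            initialize_references(frame, single_pixel_outline((3, 3), 1, 1), I0=0.0)

    def test_whole_frame_outline(self):
        frame = IntensityImage(np.full((3, 3), 7.0))
        state = initialize_references(frame, Region(np.ones((3, 3), dtype=bool)), I0=2.0)
        assert np.all(state.bg_ref.values == 5.0)

    def test_empty_outline_errors(self):
        frame = IntensityImage(np.ones((3, 3)))
        with pytest.raises(ValueError):
            initialize_references(frame, Region(np.zeros((3, 3), dtype=bool)))


class TestResidualAndObjective:
    def test_consistent_state_has_zero_residual(self):
        frame = IntensityImage(np.random.default_rng(0).random((6, 6)))
        state = initialize_references(frame, single_pixel_outline((6, 6), 3, 3))
        e = residual(frame, state)
        assert np.allclose(e.values, 0.0)
        assert objective(e) == 0.0

    def test_hand_computed_residual(self):
        frame = IntensityImage(np.full((2, 2), 5.0))
        state = DecompositionState(
            tumor_ref=IntensityImage(np.full((2, 2), 1.0)),
            bg_ref=IntensityImage(np.full((2, 2), 3.0)),
        )
        e = residual(frame, state)
        assert np.all(e.values == -1.0)
        assert objective(e) == pytest.approx(2.0)  # 1/2 * 4 * 1


class TestTumorReferenceUpdate:
    def test_zero_residual_is_stationary(self):
        state = DecompositionState(
            tumor_ref=IntensityImage(np.full((3, 3), 0.5)),
            bg_ref=IntensityImage(np.zeros((3, 3))),
        )
        before = state.tumor_ref.values.copy()
        e = IntensityImage(np.zeros((3, 3)))
        update_tumor_reference(state, e, SolverConfig(eta=0.5))
        assert np.array_equal(state.tumor_ref.values, before)

    def test_unshifted_update_is_minus_eta_times_residual(self):
        state = DecompositionState(
            tumor_ref=IntensityImage(np.full((3, 3), 2.0)),
            bg_ref=IntensityImage(np.zeros((3, 3))),
        )
        e_vals = np.zeros((3, 3))
        e_vals[1, 1] = 2.0
        update_tumor_reference(state, IntensityImage(e_vals), SolverConfig(eta=0.5))
        assert state.tumor_ref.values[1, 1] == pytest.approx(1.0)
        assert state.tumor_ref.values[0, 0] == pytest.approx(2.0)

    @pytest.mark.parametrize("d", [(0, 0), (1, 0), (2, -1)])
    def test_gradient_matches_finite_differences(self, d):
        """The analytic update direction equals the central finite-difference
        gradient of J with respect to each tumor-reference pixel."""
        rng = np.random.default_rng(42)
        m = n = 8
        frame = IntensityImage(rng.random((m, n)))
        bg = IntensityImage(rng.random((m, n)))
        ref = IntensityImage(rng.random((m, n)) + 0.5)
        state = DecompositionState(
            tumor_ref=ref.copy(), bg_ref=bg, d_tumor=Displacement(*d)
        )

        def J_of(ref_vals):
            s = DecompositionState(
                tumor_ref=IntensityImage(ref_vals),
                bg_ref=bg,
                d_tumor=Displacement(*d),
            )
            return objective(residual(frame, s))

        e = residual(frame, state)
        eta = 1.0
        cfg = SolverConfig(
            eta=eta, clamp_nonnegative=False, support_dilation_px=-1
        )
        before = state.tumor_ref.values.copy()
        update_tumor_reference(state, e, cfg)
        analytic_grad = (before - state.tumor_ref.values) / eta

        h = 1e-6
        fd = np.zeros_like(before)
        for i in range(m):
            for j in range(n):
                up, dn = before.copy(), before.copy()
                up[i, j] += h
                dn[i, j] -= h
                fd[i, j] = (J_of(up) - J_of(dn)) / (2 * h)
        assert np.allclose(analytic_grad, fd, atol=1e-6)

    def test_nonnegativity_clamp(self):
        state = DecompositionState(
            tumor_ref=IntensityImage(np.full((3, 3), 0.1)),
            bg_ref=IntensityImage(np.zeros((3, 3))),
        )
        e = IntensityImage(np.full((3, 3), 10.0))
        update_tumor_reference(state, e, SolverConfig(eta=1.0))
        assert np.all(state.tumor_ref.values == 0.0)


class TestBackgroundReferenceUpdate:
    def test_static_background_rewrite(self):
        rng = np.random.default_rng(1)
        frame = IntensityImage(rng.random((5, 5)))
        state = initialize_references(frame, single_pixel_outline((5, 5), 2, 2))
        state.tumor_ref.values[2, 2] = 0.4
        update_background_reference(state, frame)
        assert np.allclose(
            state.bg_ref.values, frame.values - state.tumor_ref.values
        )

    def test_recomposition_exact_after_update(self):
        rng = np.random.default_rng(2)
        frame = IntensityImage(rng.random((8, 10)))
        state = initialize_references(frame, single_pixel_outline((8, 10), 4, 5))
        state.d_tumor = Displacement(2, 1)
        state.d_bg = Displacement(1, 0)
        update_background_reference(state, frame)
        ta = shift_image(state.tumor_ref, state.d_tumor)
        tb = shift_image(state.bg_ref, state.d_bg)
        joint = ta.valid & tb.valid & frame.valid
        assert np.allclose(
            (ta.values + tb.values)[joint], frame.values[joint], atol=1e-12
        )

    def test_out_of_frame_reference_pixels_keep_values(self):
        frame = IntensityImage(np.full((4, 6), 2.0))
        state = initialize_references(frame, single_pixel_outline((4, 6), 2, 3))
        state.d_bg = Displacement(3, 0)
        old = state.bg_ref.values.copy()
        update_background_reference(state, frame)
        # reference columns with no corresponding in-frame location: the last 3
        assert np.array_equal(state.bg_ref.values[:, 3:], old[:, 3:])


class TestEstimatePosition:
    def test_reference_frame_is_zero(self):
        frame = IntensityImage(np.full((10, 10), 1.0))
        outline = np.zeros((10, 10), dtype=bool)
        outline[4:7, 4:7] = True
        state = initialize_references(frame, Region(outline))
        (u, v), (umm, vmm) = estimate_position(state, SolverConfig(), 0.26)
        assert (u, v) == (0.0, 0.0)

    def test_rigid_shift_read_out_in_px_and_mm(self):
        frame = IntensityImage(np.full((20, 20), 1.0), spacing_mm=0.26)
        outline = np.zeros((20, 20), dtype=bool)
        outline[8:11, 8:11] = True
        state = initialize_references(frame, Region(outline))
        state.d_tumor = Displacement(3, 4)
        (u, v), (umm, vmm) = estimate_position(state, SolverConfig(), 0.26)
        assert (u, v) == (3.0, 4.0)
        assert np.hypot(umm, vmm) == pytest.approx(5 * 0.26)


def quick_phantom(seed=3, n=40, noise=0.0, **kw):
    cfg = PhantomConfig(
        frame_shape=(120, 160),
        n_frames=n,
        tumor=TumorSpec(radii_px=(10, 7), peak=1.8, profile="disk"),
        background=BackgroundSpec(
            base=0.5, gradient=0.3, band_contrast=2.2, vessel_contrast=0.12,
            texture_contrast=0.06,
        ),
        motion=MotionSpec(p2p_mm=(1.5, 6.0), period_s=2.5),
        noise_sd=noise,
        seed=seed,
        **kw,
    )
    return render_sequence(cfg)


class TestTrackSequence:
    def test_truth_initialized_run_is_a_fixed_point(self):
        """With references initialized to the true components the decomposition
        reproduces the rendered integer trajectory exactly (e_p = 0)."""
        frames, truth = quick_phantom()
        from fluorotrack.decomposition import _frame_step

        state = DecompositionState(
            tumor_ref=truth.tumor.copy(), bg_ref=truth.background.copy()
        )
        state.ref_centroid = center_of_mass(binarize(truth.tumor, 0.5))
        cfg, mcfg = SolverConfig(), MatchConfig(search_radius=10)
        for t, frame in enumerate(frames):
            _frame_step(frame, state, cfg, mcfg)
            (u, v), _ = estimate_position(state, cfg)
            assert (u, v) == tuple(truth.trace_int_px[t])

    def test_objective_non_increasing_within_inner_loop(self):
        frames, truth = quick_phantom(n=20)
        outline = rough_outline(truth, 3)
        res = track_sequence(
            frames, outline, SolverConfig(eta=0.1, n_inner=3),
            MatchConfig(search_radius=10),
        )
        for js in res.objective_trace:
            assert all(b <= a + 1e-9 for a, b in zip(js, js[1:]))

    def test_default_inner_iteration_count_is_two(self):
        assert SolverConfig().n_inner == 2
        frames, truth = quick_phantom(n=3)
        res = track_sequence(frames, rough_outline(truth, 3), None,
                             MatchConfig(search_radius=6))
        assert all(len(js) == 2 for js in res.objective_trace)

    def test_partial_result_on_lost_target(self):
        frames, truth = quick_phantom(n=8)
        outline = rough_outline(truth, 3)
        # make later frames unmatched: blank them entirely
        for f in frames[4:]:
            f.valid[:] = False
        res = track_sequence(frames, outline, None, MatchConfig(search_radius=6))
        assert res.failure is not None
        assert res.failure[0] == 5
        assert res.n_frames == 4

    def test_single_frame_sequence(self):
        frames, truth = quick_phantom(n=1)
        res = track_sequence(frames, rough_outline(truth, 3), None,
                             MatchConfig(search_radius=4))
        assert res.n_frames == 1
        assert res.u_px[0] == 0.0 and res.v_px[0] == 0.0
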