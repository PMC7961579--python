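import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osmech import (
    CellGroundTruth,
    Morphology,
    compute_morphology,
    detect_contour,
    fit_ellipse,
    render_frames,
    simulate_trace,
    trace_axes,
)
from osmech.protocols import StretchProtocol
from osmech.tracking import AxisTrace, phase_marks_from_protocol


def _ellipse_frame(size=100, a=30.0, b=20.0, angle_deg=30.0, level=1.0):
    from skimage.draw import ellipse

    img = np.zeros((size, size), dtype=float)
    rr, cc = ellipse(size / 2, size / 2, a, b, rotation=np.radians(angle_deg))
    img[rr, cc] = level
    return img


def _trace(protocol, L, S, orient, brightness=None):
    n = protocol.n_frames
    time = np.arange(n) / protocol.frame_rate
    return AxisTrace(
        cell_id="t",
        time=time,
        long_um=np.asarray(L, dtype=float),
        short_um=np.asarray(S, dtype=float),
        orientation_deg=np.asarray(orient, dtype=float),
        brightness=np.ones(n) if brightness is None else brightness,
        phase_marks=phase_marks_from_protocol(protocol, time),
        protocol=protocol,
    )


class TestDetectContour:
    def test_contour_covers_true_mask(self):
        from skimage.measure import grid_points_in_poly

        img = _ellipse_frame() + np.random.default_rng(0).normal(0, 0.02, (100, 100))
        contour = detect_contour(img)
        assert contour is not None
        rec = grid_points_in_poly(img.shape, contour)
        true = _ellipse_frame() > 0.5
        assert (rec & true).sum() / true.sum() >= 0.98

    def test_blank_noise_frame_fails(self):
        img = np.random.default_rng(1).normal(0, 0.01, (64, 64))
        assert detect_contour(img) is None

    def test_largest_of_two_objects_selected(self):
        img = np.zeros((100, 100))
        img[10:20, 10:20] = 1.0  # 100 px
        img[50:90, 50:90] = 1.0  # 1600 px
        contour = detect_contour(img)
        assert contour[:, 0].mean() > 40  # centred on the big object

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            detect_contour(np.empty((0, 0)))


class TestFitEllipse:
    def test_recovers_rendered_ellipse(self):
        # 30 px and 20 px semi-axes at 0.2 um/px -> L = 12 um, S = 8 um
        contour = detect_contour(_ellipse_frame(a=30, b=20, angle_deg=30))
        L, S, ang = fit_ellipse(contour, pixel_scale=0.2)
        assert L == pytest.approx(12.0, rel=0.02)
        assert S == pytest.approx(8.0, rel=0.02)
        # rendered rotation of the row-axis maps to 90 + 30 in image angles
        assert min(abs(ang - 120.0), abs(ang - 60.0)) < 2.0

    def test_circle_axes_equal(self):
        contour = detect_contour(_ellipse_frame(a=25, b=25))
        L, S, ang = fit_ellipse(contour, pixel_scale=0.2)
        assert L == pytest.approx(S, rel=0.01)
        assert np.isfinite(ang)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.array([[0, 0], [1, 1], [2, 2], [3, 3.5]]), 0.2)

    def test_collinear_contour_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError):
            fit_ellipse(pts, 0.2)


@pytest.fixture(scope="module")
def short_protocol():
    return StretchProtocol(
        laser_power=800.0, step_stress=0.76, pre_stretch_duration=1.0,
        stretch_duration=3.0, relax_duration=2.0, frame_rate=10.0,
    )


class TestTraceAxes:
    def test_round_trip_recovers_axes(self, short_protocol):
        truth = CellGroundTruth(
            cell_id="rt", class_label="PBMC", elastic_modulus=20.0, viscosity=20.0,
            activity=0.0, radius=5.0, initial_ellipticity=1.1, brightness=1.0,
            rotation_rate=3.0, poisson_ratio=0.45,
        )
        tr = simulate_trace(truth, short_protocol, axis_noise_sd=0.0, seed=0)
        stack = render_frames(tr, image_size=120, pixel_scale=0.2,
                              background_noise_sd=0.01, seed=1)
        rec = trace_axes(stack, short_protocol, 0.2, cell_id="rt")
        assert rec.valid
        assert len(rec) == len(tr)
        assert np.max(np.abs(rec.long_um - tr.long_um) / tr.long_um) < 0.02
        assert np.max(np.abs(rec.short_um - tr.short_um) / tr.short_um) < 0.02

    def test_all_blank_stack_invalid(self, short_protocol):
        stack = np.zeros((short_protocol.n_frames, 64, 64))
        rec = trace_axes(stack, short_protocol, 0.2)
        assert not rec.valid

    def test_stack_length_mismatch_rejected(self, short_protocol):
        with pytest.raises(ValueError):
            trace_axes(np.zeros((5, 64, 64)), short_protocol, 0.2)

    def test_isolated_failures_interpolated(self, short_protocol):
        truth = CellGroundTruth(
            cell_id="gap", class_label="PBMC", elastic_modulus=20.0, viscosity=20.0,
            activity=0.0, radius=5.0, initial_ellipticity=1.0, brightness=1.0,
            rotation_rate=0.0, poisson_ratio=0.45,
        )
        tr = simulate_trace(truth, short_protocol, axis_noise_sd=0.0, seed=0)
        stack = render_frames(tr, image_size=120, pixel_scale=0.2,
                              background_noise_sd=0.0, seed=1)
        stack[10] = 0.0  # one dropped frame
        rec = trace_axes(stack, short_protocol, 0.2)
        assert rec.valid
        assert np.isfinite(rec.long_um).all()
        assert rec.long_um[10] == pytest.approx(10.0, rel=0.02)


class TestMorphology:
    def test_circle_identity(self, short_protocol):
        n = short_protocol.n_frames
        tr = _trace(short_protocol, np.full(n, 10.0), np.full(n, 10.0), np.zeros(n))
        m = compute_morphology(tr)
        assert m.area == pytest.approx(25 * np.pi, rel=1e-12)
        assert m.effective_radius == pytest.approx(5.0, rel=1e-12)
        assert m.initial_ellipticity == pytest.approx(1.0)
        assert m.rotation_degree == 0.0

    def test_rotation_sums_absolute_steps(self, short_protocol):
        n = short_protocol.n_frames
        orient = np.zeros(n)
        i0, _ = phase_marks_from_protocol(
            short_protocol, np.arange(n) / short_protocol.frame_rate
        )
        orient[i0 + 1] = 10.0
        orient[i0 + 2 :] = 5.0
        tr = _trace(short_protocol, np.full(n, 10.0), np.full(n, 10.0), orient)
        assert compute_morphology(tr).rotation_degree == pytest.approx(15.0)

    def test_rotation_unwraps_at_180(self, short_protocol):
        n = short_protocol.n_frames
        orient = np.full(n, 179.0)
        i0, _ = phase_marks_from_protocol(
            short_protocol, np.arange(n) / short_protocol.frame_rate
        )
        orient[i0 + 1 :] = 1.0  # a 2-degree step across the wrap, not 178
        tr = _trace(short_protocol, np.full(n, 10.0), np.full(n, 10.0), orient)
        assert compute_morphology(tr).rotation_degree == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=25)
    @given(offset=st.floats(0.0, 180.0))
    def test_rotation_invariant_under_global_offset(self, short_protocol, offset):
        n = short_protocol.n_frames
        rng = np.random.default_rng(7)
        orient = np.cumsum(rng.normal(0, 3, n)) % 180.0
        tr1 = _trace(short_protocol, np.full(n, 10.0), np.full(n, 10.0), orient)
        tr2 = _trace(short_protocol, np.full(n, 10.0), np.full(n, 10.0), (orient + offset) % 180.0)
        assert compute_morphology(tr1).rotation_degree == pytest.approx(
            compute_morphology(tr2).rotation_degree, abs=1e-9
        )


class TestAxisTraceValidation:
    def test_long_must_dominate_short(self, short_protocol):
        n = short_protocol.n_frames
        with pytest.raises(ValueError):
            _trace(short_protocol, np.full(n, 8.0), np.full(n, 10.0), np.zeros(n))

    def test_time_strictly_increasing(self, short_protocol):
        n = short_protocol.n_frames
        tr_kwargs = dict(
            cell_id="bad",
            time=np.zeros(n),
            long_um=np.full(n, 10.0),
            short_um=np.full(n, 9.0),
            orientation_deg=np.zeros(n),
            brightness=np.ones(n),
            phase_marks=(1, 2),
            protocol=short_protocol,
        )
        with pytest.raises(ValueError):
            AxisTrace(**tr_kwargs)
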