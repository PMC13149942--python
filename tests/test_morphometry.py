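import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from spikescan import (
    PhantomSpec,
    estimate_axis,
    fit_quadrangle,
    generate_phantom,
    outline_features,
    width_profile,
)
from spikescan.errors import GeometryError, ValidationError
from spikescan.morphometry import (
    OUTLINE_FEATURE_NAMES,
    QUAD_FEATURE_NAMES,
    QuadrangleFeatures,
)
from spikescan.phantom import LABEL_BODY


def disk_mask(radius=200, pad=10):
    size = 2 * (radius + pad)
    mask = np.zeros((size, size), dtype=np.uint8)
    rr, cc = draw_disk((size // 2, size // 2), radius + 0.5)
    mask[rr, cc] = LABEL_BODY
    return mask


class TestEstimateAxis:
    def test_vertical_phantom_axis(self, kite_phantom, kite_spec):
        axis = estimate_axis(kite_phantom.truth_mask)
        angle = math.degrees(math.atan2(axis.unit_axis[1], -axis.unit_axis[0]))
        assert abs(angle) <= 1.0
        assert axis.length_px * kite_spec.mm_per_px == pytest.approx(
            kite_spec.body_length_mm, rel=0.02
        )

    def test_base_is_lower_than_tip(self, kite_phantom):
        axis = estimate_axis(kite_phantom.truth_mask)
        assert axis.base_point_px[0] > axis.tip_point_px[0]

    def test_rotated_phantom_axis(self):
        ph = generate_phantom(
            PhantomSpec(awn_count=0, noise_sd=0.0, rotation_deg=10.0, seed=2)
        )
        axis = estimate_axis(ph.truth_mask)
        angle = math.degrees(math.atan2(axis.unit_axis[1], -axis.unit_axis[0]))
        assert angle == pytest.approx(10.0, abs=1.0)

    def test_single_pixel_body_is_degenerate(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[5, 5] = LABEL_BODY
        with pytest.raises(GeometryError):
            estimate_axis(mask)

    def test_empty_body_is_degenerate(self):
        with pytest.raises(GeometryError):
            estimate_axis(np.zeros((10, 10), dtype=np.uint8))


class TestOutlineFeatures:
    def test_disk_limits(self):
        feats = outline_features(disk_mask(), 0.1)
        assert 0.95 <= feats.c_Ci <= 1.02
        assert 0.95 <= feats.c_Ro <= 1.02
        assert 0.95 <= feats.c_So <= 1.02
        assert 0.98 <= feats.c_Ru <= 1.05

    def test_kite_area_and_convexity(self, kite_phantom, kite_spec, cal02):
        feats = outline_features(kite_phantom.truth_mask, cal02)
        assert feats.c_S == pytest.approx(kite_spec.kite_area_mm2, rel=0.02)
        assert feats.c_So >= 0.98

    def test_zero_awn_pixels_zero_awn_area(self, kite_phantom, cal02):
        assert outline_features(kite_phantom.truth_mask, cal02).c_Sa == 0.0

    def test_awn_area_matches_truth_mask(self, awned_phantom):
        feats = outline_features(awned_phantom.truth_mask, 0.2)
        assert feats.c_Sa == pytest.approx(awned_phantom.awn_area_mm2, rel=1e-12)

    def test_descriptor_bounds(self, awned_phantom):
        eps = 0.05
        f = outline_features(awned_phantom.truth_mask, 0.2)
        assert 0 < f.c_Ci <= 1 + eps
        assert 0 < f.c_Ro <= 1 + eps
        assert 0 < f.c_So <= 1 + 1e-9
        assert f.c_Ru >= 1 - eps

    def test_convex_polygon_oracle(self):
        """Pixel-count area and traced perimeter vs exact polygon values."""
        ang = np.linspace(0, 2 * np.pi, 7)[:-1] + 0.3
        r = 200 + 150 * np.sin(ang)
        c = 200 + 150 * np.cos(ang)
        mask = np.zeros((400, 400), dtype=np.uint8)
        rr, cc = draw_polygon(r, c, mask.shape)
        mask[rr, cc] = LABEL_BODY
        exact_area = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
        pts = np.stack([r, c], axis=1)
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        exact_perim = np.hypot(d[:, 0], d[:, 1]).sum()
        feats = outline_features(mask, 1.0)
        assert feats.c_S == pytest.approx(exact_area, rel=0.01)
        assert feats.c_P == pytest.approx(exact_perim, rel=0.01)

    def test_scale_covariance(self, kite_phantom):
        axis = estimate_axis(kite_phantom.truth_mask)
        f1 = outline_features(kite_phantom.truth_mask, 0.2, axis=axis)
        f2 = outline_features(kite_phantom.truth_mask, 0.4, axis=axis)
        assert f2.c_L == pytest.approx(2 * f1.c_L)
        assert f2.c_P == pytest.approx(2 * f1.c_P)
        assert f2.c_S == pytest.approx(4 * f1.c_S)
        for name in ("c_Ci", "c_Ro", "c_So", "c_Ru"):
            assert getattr(f2, name) == pytest.approx(getattr(f1, name))

    def test_rotation_invariance(self):
        base = outline_features(
            generate_phantom(PhantomSpec(awn_count=0, seed=5)).truth_mask, 0.2
        )
        rot = outline_features(
            generate_phantom(
                PhantomSpec(awn_count=0, rotation_deg=15.0, seed=5)
            ).truth_mask,
            0.2,
        )
        for name in OUTLINE_FEATURE_NAMES[:-1]:  # c_Sa is zero in both
            a, b = getattr(base, name), getattr(rot, name)
            assert b == pytest.approx(a, rel=0.03)

    def test_feature_count_is_eight(self, kite_phantom, cal02):
        feats = outline_features(kite_phantom.truth_mask, cal02)
        assert len(feats.as_dict()) == 8
        assert tuple(feats.as_dict()) == OUTLINE_FEATURE_NAMES


class TestWidthProfile:
    def test_symmetric_phantom_profile(self, kite_phantom, kite_spec, cal02):
        axis = estimate_axis(kite_phantom.truth_mask)
        prof = width_profile(kite_phantom.truth_mask, axis, cal02)
        inner = prof[2:-2]  # end bins are sparse by construction
        asym = np.abs(inner[:, 1] - inner[:, 2]).max()
        assert asym <= 2 * kite_spec.mm_per_px

    def test_peak_position_matches_spec(self, kite_phantom, kite_spec, cal02):
        axis = estimate_axis(kite_phantom.truth_mask)
        prof = width_profile(kite_phantom.truth_mask, axis, cal02)
        widths = prof[:, 1] + prof[:, 2]
        t_star = prof[np.argmax(widths), 0]
        assert t_star == pytest.approx(kite_spec.width_position_rel, abs=0.05)

    def test_too_few_bins_rejected(self, kite_phantom, cal02):
        axis = estimate_axis(kite_phantom.truth_mask)
        with pytest.raises(ValidationError):
            width_profile(kite_phantom.truth_mask, axis, cal02, n_bins=4)


class TestFitQuadrangle:
    def test_recovers_kite_parameters(self, kite_phantom, kite_spec, cal02):
        axis = estimate_axis(kite_phantom.truth_mask)
        q = fit_quadrangle(kite_phantom.truth_mask, axis, cal02)
        assert q.q_L == pytest.approx(kite_spec.body_length_mm, rel=0.02)
        assert q.q_W == pytest.approx(kite_spec.body_max_width_mm, rel=0.02)
        assert q.q_pW == pytest.approx(kite_spec.width_position_rel, abs=0.05)

    def test_identities_machine_precision(self, kite_phantom, cal02):
        axis = estimate_axis(kite_phantom.truth_mask)
        q = fit_quadrangle(kite_phantom.truth_mask, axis, cal02)
        assert q.q_P == pytest.approx(2 * (q.q_a + q.q_b), abs=1e-12)
        assert q.q_A == pytest.approx(q.q_L * q.q_W / 2, abs=1e-12)
        assert q.q_alpha + q.q_beta + 2 * q.q_gamma == pytest.approx(360.0, abs=1e-9)
        assert q.q_a == pytest.approx(
            math.hypot(q.q_pW * q.q_L, q.q_W / 2), abs=1e-12
        )
        assert 0 < q.q_r < 1

    def test_degenerate_strip_limits(self):
        q = QuadrangleFeatures.from_axis_width(100.0, 1e-9, 0.4)
        assert q.q_r == pytest.approx(0.0, abs=1e-10)
        assert q.q_alpha == pytest.approx(0.0, abs=1e-6)
        assert q.q_beta == pytest.approx(0.0, abs=1e-6)
        assert q.q_gamma == pytest.approx(180.0, abs=1e-6)

    def test_eleven_parameters(self, kite_phantom, cal02):
        axis = estimate_axis(kite_phantom.truth_mask)
        q = fit_quadrangle(kite_phantom.truth_mask, axis, cal02)
        assert len(q.as_dict()) == 11
        assert tuple(q.as_dict()) == QUAD_FEATURE_NAMES

    def test_scale_covariance(self, kite_phantom):
        axis = estimate_axis(kite_phantom.truth_mask)
        q1 = fit_quadrangle(kite_phantom.truth_mask, axis, 0.2)
        q2 = fit_quadrangle(kite_phantom.truth_mask, axis, 0.4)
        assert q2.q_L == pytest.approx(2 * q1.q_L)
        assert q2.q_W == pytest.approx(2 * q1.q_W)
        assert q2.q_A == pytest.approx(4 * q1.q_A)
        assert q2.q_pW == pytest.approx(q1.q_pW)
        assert q2.q_r == pytest.approx(q1.q_r)
        assert q2.q_alpha == pytest.approx(q1.q_alpha)

    @settings(max_examples=50, deadline=None)
    @given(
        q_l=st.floats(10.0, 300.0),
        q_w=st.floats(0.5, 100.0),
        q_pw=st.floats(0.02, 0.98),
    )
    def test_identities_hold_for_any_kite(self, q_l, q_w, q_pw):
        q = QuadrangleFeatures.from_axis_width(q_l, q_w, q_pw)
        assert q.q_P == pytest.approx(2 * (q.q_a + q.q_b), rel=1e-12)
        assert q.q_A == pytest.approx(q_l * q_w / 2, rel=1e-12)
        assert q.q_alpha + q.q_beta + 2 * q.q_gamma == pytest.approx(360.0, abs=1e-9)
        assert q.q_b == pytest.approx(
            math.hypot((1 - q_pw) * q_l, q_w / 2), rel=1e-12
        )

    def test_nineteen_morphological_features_total(self, kite_phantom, cal02):
        axis = estimate_axis(kite_phantom.truth_mask)
        q = fit_quadrangle(kite_phantom.truth_mask, axis, cal02)
        o = outline_features(kite_phantom.truth_mask, cal02, axis=axis)
        assert len({**q.as_dict(), **o.as_dict()}) == 19
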