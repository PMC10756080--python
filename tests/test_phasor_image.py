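"""Phasor-space segmentation, denoising, histograms and pseudocolour maps."""

import numpy as np
import pytest

from hsiphasor import (
    CircleCursor,
    HSIStack,
    PhaseWedgeCursor,
    PolygonCursor,
    median_filter_phasor,
    phase_modulation,
    phasor_histogram,
    phasor_of_roi,
    phasor_transform,
    pseudocolor_phase,
    select_by_cursor,
)
from hsiphasor.synthetic import (
    PhantomConfig,
    make_tissue_phantom,
    mixture_spectrum,
)

from conftest import uniform_field


def two_material_field(phase_a=60.0, phase_b=120.0, shape=(10, 10)):
    """Half the pixels at phase_a, half at phase_b, modulation 0.8."""
    field = uniform_field(0.0, 0.0, shape)
    half = shape[0] // 2
    for sl, ph in (((slice(None, half),), phase_a), ((slice(half, None),), phase_b)):
        rad = np.radians(ph)
        field.G[sl] = 0.8 * np.cos(rad)
        field.S[sl] = 0.8 * np.sin(rad)
    labels = np.zeros(shape, dtype=int)
    labels[half:] = 1
    return field, labels


class TestMedianFilter:
    def test_constant_field_unchanged(self):
        fld = uniform_field(0.3, 0.4, (7, 7))
        out = median_filter_phasor(fld, kernel=3)
        np.testing.assert_array_equal(out.G, fld.G)
        np.testing.assert_array_equal(out.S, fld.S)

    def test_single_outlier_replaced(self):
        fld = uniform_field(0.5, 0.2, (5, 5))
        fld.G[2, 2], fld.S[2, 2] = -0.9, -0.1
        out = median_filter_phasor(fld, kernel=3)
        assert out.G[2, 2] == pytest.approx(0.5)
        assert out.S[2, 2] == pytest.approx(0.2)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_filter_phasor(uniform_field(0, 0.5), kernel=4)

    def test_intensity_and_mask_untouched(self, rng):
        fld = uniform_field(0.1, 0.1, (6, 6))
        fld.valid_mask[0, 0] = False
        out = median_filter_phasor(fld, kernel=3)
        np.testing.assert_array_equal(out.valid_mask, fld.valid_mask)
        np.testing.assert_array_equal(out.total_intensity, fld.total_intensity)

    def test_noise_reduction_on_phantom(self):
        """Filtering tightens the phasor cluster of a homogeneous material."""
        config = PhantomConfig(size=(64, 64), seed=5, n_nests=1)
        phantom = make_tissue_phantom(config)
        fld = phasor_transform(phantom.stack, intensity_threshold=100.0)
        filt = median_filter_phasor(fld, kernel=3)
        dermis = (phantom.labels == 1) & fld.valid_mask
        for plane_raw, plane_f in ((fld.G, filt.G), (fld.S, filt.S)):
            assert plane_f[dermis].std() < plane_raw[dermis].std()


class TestPhasorHistogram:
    def test_identical_phasors_fill_one_bin(self):
        fld = uniform_field(0.25, 0.25, (8, 8))
        hist = phasor_histogram(fld, bins=64)
        assert hist.counts.sum() == 64
        assert (hist.counts > 0).sum() == 1

    def test_empty_mask_gives_zero_histogram(self):
        fld = uniform_field(0.2, 0.2)
        fld.valid_mask[:] = False
        assert phasor_histogram(fld).counts.sum() == 0

    def test_two_material_phantom_modes(self):
        """Histogram modes sit within one bin width of the true component phasors."""
        fld, _ = two_material_field(shape=(40, 40))
        hist = phasor_histogram(fld, bins=50)
        width = hist.g_edges[1] - hist.g_edges[0]
        peaks = np.argwhere(hist.counts >= 0.4 * hist.counts.max())
        centers = [
            (hist.g_edges[i] + width / 2, hist.s_edges[j] + width / 2)
            for i, j in peaks
        ]
        for ph in (60.0, 120.0):
            true = (0.8 * np.cos(np.radians(ph)), 0.8 * np.sin(np.radians(ph)))
            best = min(np.hypot(c[0] - true[0], c[1] - true[1]) for c in centers)
            assert best <= width


class TestPseudocolor:
    def test_midpoint_phase_uniform_color(self):
        rad = np.radians(112.5)
        fld = uniform_field(0.5 * np.cos(rad), 0.5 * np.sin(rad))
        rgb = pseudocolor_phase(fld, phase_range=(45.0, 180.0))
        assert np.ptp(rgb.reshape(-1, 3), axis=0).max() < 1e-12

    def test_endpoints_clamped(self):
        lo = uniform_field(np.cos(np.radians(45)), np.sin(np.radians(45)))
        below = uniform_field(np.cos(np.radians(10)), np.sin(np.radians(10)))
        np.testing.assert_allclose(
            pseudocolor_phase(lo, (45.0, 180.0)), pseudocolor_phase(below, (45.0, 180.0))
        )

    def test_invalid_pixels_black(self):
        fld = uniform_field(0.0, 0.6)
        fld.valid_mask[0, :] = False
        rgb = pseudocolor_phase(fld)
        assert np.all(rgb[0] == 0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pseudocolor_phase(uniform_field(0, 0.5), phase_range=(90.0, 90.0))

    def test_lesion_renders_at_high_phase_end(self):
        """On a noiseless phantom the red-shifted lesion maps to the violet end."""
        from hsiphasor.synthetic import MELANOMA_LESION_MIXTURE

        config = PhantomConfig(
            size=(64, 64),
            seed=2,
            poisson_noise=False,
            region_mixtures={
                "dermis": {"collagen_I": 1.0},
                "epidermis": {"nadh": 1.0},
                "lesion": dict(MELANOMA_LESION_MIXTURE),
            },
        )
        phantom = make_tissue_phantom(config)
        fld = phasor_transform(phantom.stack, intensity_threshold=100.0)
        pm = phase_modulation(fld)
        lesion = phantom.lesion_mask() & pm.valid_mask
        dermis = (phantom.labels == 1) & pm.valid_mask
        # phase separation implies palette separation
        frac_lesion = np.median(pm.phase[lesion])
        frac_dermis = np.median(pm.phase[dermis])
        assert frac_lesion > frac_dermis
        # ground-truth label agreement of a wedge cursor around the lesion phase
        wedge = PhaseWedgeCursor(
            phase_lo=(frac_lesion + frac_dermis) / 2, phase_hi=359.0
        )
        mask = select_by_cursor(fld, wedge).mask
        truth = phantom.lesion_mask()
        valid = fld.valid_mask
        agreement = (mask[valid] == truth[valid]).mean()
        assert agreement >= 0.99


class TestCursors:
    def test_huge_circle_selects_all_valid(self):
        fld = uniform_field(0.1, 0.2)
        fld.valid_mask[1, 1] = False
        roi = select_by_cursor(fld, CircleCursor((0.0, 0.0), 2.0))
        np.testing.assert_array_equal(roi.mask, fld.valid_mask)

    def test_disjoint_circle_selects_none(self):
        fld = uniform_field(0.5, 0.5)
        roi = select_by_cursor(fld, CircleCursor((-0.8, -0.8), 0.05))
        assert not roi.mask.any()

    def test_circle_boundary_inclusive(self):
        fld = uniform_field(0.5, 0.0)
        roi = select_by_cursor(fld, CircleCursor((0.3, 0.0), 0.2))
        assert roi.mask.all()

    def test_wedge_selects_exactly_one_material(self):
        fld, labels = two_material_field()
        roi = select_by_cursor(fld, PhaseWedgeCursor(90.0, 180.0))
        np.testing.assert_array_equal(roi.mask, labels == 1)

    def test_polygon_cursor_contains(self):
        fld = uniform_field(0.2, 0.2)
        tri = PolygonCursor([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
        assert select_by_cursor(fld, tri).mask.all()

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            PolygonCursor([(0, 0), (1, 1), (1, 0), (0, 1)])

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CircleCursor((0, 0), 0.0)
        with pytest.raises(ValueError):
            PhaseWedgeCursor(180.0, 90.0)

    def test_cursor_json_round_trip(self):
        from hsiphasor.phasor_image import Cursor

        for c in (
            CircleCursor((0.1, 0.2), 0.3),
            PolygonCursor([(0, 0), (1, 0), (0, 1)]),
            PhaseWedgeCursor(45.0, 180.0, 0.1, 0.9),
        ):
            back = Cursor.from_dict(c.to_dict())
            assert back.to_dict() == c.to_dict()


class TestReciprocity:
    def test_roi_restriction(self):
        fld = uniform_field(0.3, 0.3, (4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        sub = phasor_of_roi(fld, mask)
        assert sub.valid_mask.sum() == 1
        full = phasor_of_roi(fld, np.ones((4, 4), dtype=bool))
        np.testing.assert_array_equal(full.valid_mask, fld.valid_mask)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            phasor_of_roi(uniform_field(0, 0.5, (4, 4)), np.ones((3, 3), dtype=bool))

    def test_reciprocity_closure_exact(self, rng):
        """Every phasor surviving cursor -> mask -> secondary phasor obeys the cursor."""
        shape = (30, 30)
        G = rng.uniform(-0.7, 0.7, shape)
        S = rng.uniform(-0.7, 0.7, shape)
        from hsiphasor import PhasorField

        fld = PhasorField(G, S, np.ones(shape), np.ones(shape, dtype=bool))
        cursor = CircleCursor((0.2, 0.1), 0.3)
        sub = phasor_of_roi(fld, select_by_cursor(fld, cursor))
        pts = sub.valid_points()
        assert np.all(cursor.contains(pts[:, 0], pts[:, 1]))
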