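"""Cortical profile extraction and intensity-ratio quantifications."""
import numpy as np
import pytest

from blastopol.benchmarks import make_arc_disc
from blastopol.errors import (
    EmptyProfileError,
    IncompleteTraceError,
    InvalidInputError,
    InvalidMeasurementError,
    UndefinedRatioError,
)
from blastopol.profiles import (
    NuclearMeasurement,
    cdx2_doublet_ratio,
    cortical_enrichment,
    cytoplasm_control_mean,
    ep_lp_intensity_ratio,
    extract_contact_free_profile,
    nuclear_cytoplasmic_ratio,
    smooth_profile,
)
from conftest import two_discs


class TestExtraction:
    def test_isolated_disc_spans_full_perimeter(self):
        img, labels = make_arc_disc(radius_px=30, enrichment=1.0)
        prof = extract_contact_free_profile(img, labels, 1, 1.0)
        assert prof.closed
        assert prof.span_deg > 350.0
        # arc length tracks the analytic circumference
        assert prof.total_length_um == pytest.approx(2 * np.pi * 30, rel=0.05)

    def test_calibration_scales_arc_length(self):
        img, labels = make_arc_disc(radius_px=30, enrichment=1.0)
        p1 = extract_contact_free_profile(img, labels, 1, 1.0)
        p2 = extract_contact_free_profile(img, labels, 1, 0.5)
        assert p2.total_length_um == pytest.approx(0.5 * p1.total_length_um)

    def test_tangent_discs_exclude_contact(self):
        a, b = two_discs(25, 48)
        labels = a.astype(np.uint16) + 2 * b.astype(np.uint16)
        img = np.ones_like(labels, float)
        prof = extract_contact_free_profile(img, labels, 1, 1.0, band_px=2)
        assert not prof.closed
        assert prof.span_deg < 360.0

    def test_enclosed_cell_raises(self):
        yy, xx = np.mgrid[0:61, 0:61]
        d = np.hypot(yy - 30, xx - 30)
        labels = np.zeros((61, 61), np.uint16)
        labels[d <= 20] = 2          # surrounding ring cell
        labels[d <= 10] = 1          # fully enclosed cell
        with pytest.raises(EmptyProfileError):
            extract_contact_free_profile(np.ones_like(d), labels, 1, 1.0)

    def test_rendered_arc_enrichment_recovered(self):
        """Half-arc at 2x baseline: in-arc vs out-of-arc mean ratio within 5%."""
        img, labels = make_arc_disc(radius_px=40, arc_fraction=0.5, enrichment=2.0)
        prof = extract_contact_free_profile(img, labels, 1, 1.0)
        top = np.abs(prof.angle_deg) < 85.0
        bottom = np.abs(prof.angle_deg) > 95.0
        ratio = prof.intensity[top].mean() / prof.intensity[bottom].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestRatios:
    @pytest.mark.parametrize(
        "icortex,icyto,expected", [(2.0, 1.0, 1.0), (1.0, 1.0, 0.0), (0.5, 1.0, -0.5)]
    )
    def test_cortical_enrichment_formula(self, icortex, icyto, expected):
        assert cortical_enrichment(icortex, icyto) == pytest.approx(expected)

    def test_cortical_enrichment_rejects_nonpositive_cytoplasm(self):
        with pytest.raises(InvalidMeasurementError):
            cortical_enrichment(1.0, 0.0)

    @pytest.mark.parametrize("nuc,cyto,expected", [(4.0, 2.0, 2.0), (3.0, 3.0, 1.0)])
    def test_nuclear_cytoplasmic_ratio(self, nuc, cyto, expected):
        m = NuclearMeasurement(int_nucleus=nuc, int_cytoplasm=cyto)
        assert nuclear_cytoplasmic_ratio(m) == pytest.approx(expected)

    def test_nuclear_ratio_rejects_zero_cytoplasm(self):
        with pytest.raises(InvalidMeasurementError):
            nuclear_cytoplasmic_ratio(NuclearMeasurement(1.0, 0.0))

    def test_ep_lp_ratio_identity_and_construction(self):
        sig = np.array([2.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        dapi = np.ones(8)
        ep = np.array([1, 1, 0, 0, 0, 0, 0, 0], bool)
        assert ep_lp_intensity_ratio(sig, dapi, ep) == pytest.approx(2.0)
        assert ep_lp_intensity_ratio(np.ones(8), dapi, ep) == pytest.approx(1.0)
        # DAPI normalization: doubling one cell's stain halves its weight
        assert ep_lp_intensity_ratio(sig, 2 * dapi, ep) == pytest.approx(2.0)

    def test_ep_lp_ratio_requires_both_classes(self):
        with pytest.raises(UndefinedRatioError):
            ep_lp_intensity_ratio(np.ones(8), np.ones(8), np.ones(8, bool))

    def test_ep_lp_ratio_permutation_null_is_unbiased(self):
        """Random labels on exchangeable cells: resampled mean ratio ~ 1."""
        rng = np.random.default_rng(0)
        sig = rng.normal(10.0, 1.0, 8)
        dapi = rng.normal(5.0, 0.5, 8)
        ratios = []
        for _ in range(5000):
            ep = np.zeros(8, bool)
            ep[rng.choice(8, 2, replace=False)] = True
            ratios.append(ep_lp_intensity_ratio(sig, dapi, ep))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)

    def test_gain_invariance_of_all_ratios(self):
        rng = np.random.default_rng(1)
        sig, dapi = rng.uniform(1, 5, 8), rng.uniform(1, 5, 8)
        ep = np.array([1, 0, 0, 0, 1, 0, 0, 0], bool)
        for c in (0.5, 3.0, 17.0):
            assert cortical_enrichment(c * 2.0, c * 1.0) == pytest.approx(1.0)
            assert nuclear_cytoplasmic_ratio(
                NuclearMeasurement(c * 4.0, c * 2.0)
            ) == pytest.approx(2.0)
            assert ep_lp_intensity_ratio(c * sig, dapi, ep) == pytest.approx(
                c * ep_lp_intensity_ratio(sig, dapi, ep) / c
            )


class TestSmoothing:
    def _profile(self, y):
        from blastopol.profiles import CorticalProfile

        n = len(y)
        x = np.linspace(0, 10, n)
        return CorticalProfile(
            cell_id=1, t=0, z=0, arc_um=x,
            angle_deg=np.linspace(-180, 180, n, endpoint=False),
            intensity=np.asarray(y, float), total_length_um=10.0,
            points=np.zeros((n, 2)), pixel_size_um=1.0,
        )

    def test_constant_profile_unchanged(self):
        p = self._profile(np.full(50, 7.0))
        assert np.allclose(smooth_profile(p).intensity, 7.0)

    def test_quadratic_reproduced_and_idempotent(self):
        x = np.linspace(0, 10, 60)
        y = 3.0 + 2.0 * x - 0.5 * x**2
        p = self._profile(y)
        s1 = smooth_profile(p)
        assert np.allclose(s1.intensity, y, atol=1e-8)
        s2 = smooth_profile(s1)
        assert np.allclose(s2.intensity, s1.intensity, atol=1e-8)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 200)
        s = smooth_profile(self._profile(y))
        assert s.intensity.var() < y.var()

    def test_arc_positions_unchanged(self):
        p = self._profile(np.arange(30, dtype=float))
        assert np.array_equal(smooth_profile(p).arc_um, p.arc_um)

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            smooth_profile(self._profile(np.ones(2)))
        with pytest.raises(InvalidInputError):
            smooth_profile(self._profile(np.ones(10)), window=11)


class TestDoubletRatio:
    def test_identity_and_background_cancellation(self):
        tr = np.vstack([np.linspace(1, 2, 10), np.linspace(1, 2, 10)])
        bg = np.full(10, 0.5)
        r, trace = cdx2_doublet_ratio(tr, bg, division_frame=10)
        assert r == pytest.approx(1.0)
        r2, _ = cdx2_doublet_ratio(tr, 2 * bg, division_frame=10)
        assert r2 == pytest.approx(r)

    def test_ep_ordering(self):
        tr = np.vstack([np.full(5, 1.0), np.full(5, 1.18)])
        r, _ = cdx2_doublet_ratio(tr, np.ones(5), division_frame=5, ep_index=1)
        assert r == pytest.approx(1.18)

    def test_missing_division_frame(self):
        tr = np.ones((2, 5))
        with pytest.raises(IncompleteTraceError):
            cdx2_doublet_ratio(tr, np.ones(5), division_frame=9)


def test_cytoplasm_control_region_avoids_cortex_and_nucleus():
    img, labels = make_arc_disc(radius_px=30, enrichment=3.0, cytoplasm=100.0)
    nucleus = np.zeros_like(labels, bool)
    nucleus[28:36, 28:36] = True
    img[nucleus] = 999.0
    # margin must clear the 2-px cortical band plus discretization
    mean = cytoplasm_control_mean(img, labels == 1, nucleus, pixel_size_um=1.0,
                                  margin_um=3.5)
    assert mean == pytest.approx(100.0)
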