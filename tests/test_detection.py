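"""Three-criterion apical-domain detection and domain morphometrics."""
import numpy as np
import pytest

from blastopol import DetectionConfig
from blastopol.benchmarks import make_arc_disc
from blastopol.detection import (
    ApicalDomainCall,
    CandidateArc,
    apical_nucleus_distance,
    apply_domain_criteria,
    arc_overlap_deg,
    domain_size_degrees,
    find_candidate_domain,
)
from blastopol.errors import ConfigurationError, MissingInputError, NoCandidateError
from blastopol.profiles import extract_contact_free_profile


def brute_force_candidate(profile, config):
    """Independent dumb search: every contiguous window (with wrap for
    closed profiles), length fraction in bounds, maximize window-mean /
    rest-mean, ties to longer arc then smaller start angle."""
    n = len(profile)
    arc = profile.arc_um
    inten = profile.intensity
    ang = profile.angle_deg
    total = profile.total_length_um
    tot_sum = inten.sum()
    if profile.closed:
        closure = total - (arc[-1] - arc[0])
        arc = np.concatenate([arc, arc[-1] + closure + (arc[1:] - arc[0])])
        inten2 = np.concatenate([inten, inten[1:]])
        ang2 = np.concatenate([ang, ang[1:] + 360.0])
        max_start = n
    else:
        inten2, ang2, max_start = inten, ang, n
    best = None
    for s in range(max_start):
        for k in range(2, n):
            if s + k > len(inten2):
                break
            length = arc[s + k - 1] - arc[s]
            frac = length / total
            if not (config.length_fraction_min <= frac <= config.length_fraction_max):
                continue
            wsum = inten2[s:s + k].sum()
            rest = (tot_sum - wsum) / (n - k)
            ratio = wsum / k / rest if rest > 0 else np.inf
            key = (ratio, length, -ang2[s])
            if best is None or key > best:
                best = key
    return best


def _random_profiles(n_profiles=12, seed=0):
    rng = np.random.default_rng(seed)
    for i in range(n_profiles):
        frac = rng.uniform(0.2, 0.9)
        enr = rng.uniform(1.2, 3.0)
        img, labels = make_arc_disc(radius_px=int(rng.integers(18, 35)),
                                    arc_fraction=frac, enrichment=enr)
        img = img + rng.normal(0, 30.0, img.shape)
        yield extract_contact_free_profile(img, labels, 1, 1.0)


class TestCandidateSearch:
    def test_agrees_with_brute_force(self):
        cfg = DetectionConfig()
        for prof in _random_profiles():
            cand = find_candidate_domain(prof, cfg)
            oracle = brute_force_candidate(prof, cfg)
            assert cand.intensity_ratio == pytest.approx(oracle[0], rel=1e-9)
            assert cand.length_um == pytest.approx(oracle[1], rel=1e-9)

    def test_bright_half_arc_recovered(self):
        img, labels = make_arc_disc(radius_px=40, arc_fraction=0.5, enrichment=2.0)
        prof = extract_contact_free_profile(img, labels, 1, 1.0)
        cand = find_candidate_domain(prof, DetectionConfig())
        overlap = arc_overlap_deg(
            (cand.start_angle_deg, cand.end_angle_deg), (-90.0, 90.0)
        )
        assert overlap >= 0.9 * 180.0
        assert cand.intensity_ratio > 1.8

    def test_uniform_profile_ratio_near_one(self):
        img, labels = make_arc_disc(radius_px=30, enrichment=1.0)
        prof = extract_contact_free_profile(img, labels, 1, 1.0)
        cand = find_candidate_domain(prof, DetectionConfig())
        assert cand.intensity_ratio == pytest.approx(1.0, abs=0.02)

    def test_oversized_bright_arc_capped_at_length_bound(self):
        img, labels = make_arc_disc(radius_px=40, arc_fraction=0.95, enrichment=2.0)
        prof = extract_contact_free_profile(img, labels, 1, 1.0)
        cand = find_candidate_domain(prof, DetectionConfig())
        assert cand.length_fraction <= 0.80 + 1e-9

    def test_too_short_profile_raises(self):
        from blastopol.profiles import CorticalProfile

        prof = CorticalProfile(
            cell_id=1, t=0, z=0, arc_um=np.array([0.0]),
            angle_deg=np.array([0.0]), intensity=np.array([1.0]),
            total_length_um=1.0, points=np.zeros((1, 2)), pixel_size_um=1.0,
        )
        with pytest.raises(NoCandidateError):
            find_candidate_domain(prof, DetectionConfig())


def _cand(ratio, fraction=0.5, start=-45.0, end=45.0, z=0):
    return CandidateArc(
        start_angle_deg=start, end_angle_deg=end, length_um=fraction * 100,
        length_fraction=fraction, mean_intensity=ratio, intensity_ratio=ratio,
        z=z, start_index=0, n_samples=10,
    )


class TestCriteria:
    def test_all_criteria_met(self):
        cands = [_cand(2.0, 0.5, z=z) for z in range(2)]
        call = apply_domain_criteria(cands, DetectionConfig(), z_step_um=2.0)
        assert call.polarized
        assert call.z_extent_um == pytest.approx(4.0)

    def test_ratio_exactly_threshold_fails_strict_inequality(self):
        cands = [_cand(1.5, 0.5, z=z) for z in range(3)]
        call = apply_domain_criteria(cands, DetectionConfig(), z_step_um=2.0)
        assert not call.polarized

    def test_length_fraction_above_bound_fails(self):
        cands = [_cand(2.0, 0.85, z=z) for z in range(3)]
        call = apply_domain_criteria(cands, DetectionConfig(), z_step_um=2.0)
        assert not call.polarized

    def test_inclusive_length_bounds(self):
        for frac in (0.33, 0.80):
            cands = [_cand(2.0, frac, z=z) for z in range(2)]
            assert apply_domain_criteria(cands, DetectionConfig(), 2.0).polarized

    def test_depth_requires_overlapping_contiguous_run(self):
        # two passing slices with disjoint arcs: no 3 um slab
        cands = [_cand(2.0, 0.4, -90, -10, z=0), _cand(2.0, 0.4, 30, 110, z=1)]
        assert not apply_domain_criteria(cands, DetectionConfig(), 2.0).polarized
        # thick slices: a single slice satisfies the slab rule
        assert apply_domain_criteria(
            [_cand(2.0, 0.5, z=0)], DetectionConfig(), z_step_um=4.0
        ).polarized

    def test_gap_in_z_breaks_run(self):
        cands = [_cand(2.0, 0.5, z=0), None, _cand(2.0, 0.5, z=2)]
        assert not apply_domain_criteria(cands, DetectionConfig(), 2.0).polarized

    def test_missing_calibration_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_domain_criteria([_cand(2.0)], DetectionConfig(), z_step_um=0.0)


class TestDomainSize:
    def test_closure_and_semicircle(self):
        assert domain_size_degrees((10.0, 10.0)) == 360.0
        assert domain_size_degrees((-90.0, 90.0)) == 180.0
        assert domain_size_degrees((170.0, -170.0)) == pytest.approx(20.0)

    @pytest.mark.parametrize("frac", [0.35, 0.5, 0.7])
    def test_rendered_fraction_recovered(self, frac):
        img, labels = make_arc_disc(radius_px=40, arc_fraction=frac)
        prof = extract_contact_free_profile(img, labels, 1, 1.0)
        cand = find_candidate_domain(prof, DetectionConfig())
        size = domain_size_degrees((cand.start_angle_deg, cand.end_angle_deg))
        sample_deg = 360.0 / len(prof)
        assert abs(size - frac * 360.0) <= sample_deg + 1e-9


class TestInvariances:
    def test_gain_invariance(self):
        img, labels = make_arc_disc(radius_px=35, arc_fraction=0.5, enrichment=2.0)
        p1 = extract_contact_free_profile(img, labels, 1, 1.0)
        p2 = extract_contact_free_profile(img * 7.5, labels, 1, 1.0)
        c1 = find_candidate_domain(p1)
        c2 = find_candidate_domain(p2)
        assert c1.intensity_ratio == pytest.approx(c2.intensity_ratio)
        assert c1.start_angle_deg == c2.start_angle_deg

    def test_rotation_invariance_90_degrees(self):
        img, labels = make_arc_disc(radius_px=35, arc_fraction=0.45, enrichment=2.0)
        c1 = find_candidate_domain(extract_contact_free_profile(img, labels, 1, 1.0))
        c2 = find_candidate_domain(
            extract_contact_free_profile(np.rot90(img).copy(), np.rot90(labels).copy(), 1, 1.0)
        )
        assert c1.intensity_ratio == pytest.approx(c2.intensity_ratio, rel=1e-6)
        assert domain_size_degrees(
            (c1.start_angle_deg, c1.end_angle_deg)
        ) == pytest.approx(
            domain_size_degrees((c2.start_angle_deg, c2.end_angle_deg)), abs=1e-6
        )

    def test_enrichment_monotonicity(self):
        """Raising the rendered enrichment never turns a call off."""
        was_polarized = False
        for enr in (1.2, 1.6, 2.0, 3.0, 5.0):
            img, labels = make_arc_disc(radius_px=35, arc_fraction=0.5, enrichment=enr)
            prof = extract_contact_free_profile(img, labels, 1, 1.0)
            cand = find_candidate_domain(prof)
            call = apply_domain_criteria([cand, _cand(cand.intensity_ratio,
                                                      cand.length_fraction,
                                                      cand.start_angle_deg,
                                                      cand.end_angle_deg, z=1)],
                                         DetectionConfig(), 2.0)
            if was_polarized:
                assert call.polarized
            was_polarized = was_polarized or call.polarized
        assert was_polarized


class TestNucleusDistance:
    def _cell_with_nucleus(self, offset_px, radius=30, nucleus_r=8):
        size = 2 * radius + 9
        c = size // 2
        yy, xx = np.mgrid[0:size, 0:size]
        cell = np.hypot(yy - c, xx - c) <= radius
        # nucleus displaced toward +x (angle 0)
        nx = c + offset_px
        nucleus = np.hypot(yy - c, xx - nx) <= nucleus_r
        return cell, nucleus

    def test_tangent_nucleus_zero_distance(self):
        cell, nucleus = self._cell_with_nucleus(offset_px=22)  # 22+8=30: touching
        d = apical_nucleus_distance(cell, nucleus, (-30.0, 30.0), 1.0)
        assert d <= 1.5

    def test_known_offset_recovered(self):
        # nucleus edge 5 px from the cortex at the domain midpoint
        cell, nucleus = self._cell_with_nucleus(offset_px=17)
        d = apical_nucleus_distance(cell, nucleus, (-30.0, 30.0), 1.0)
        assert d == pytest.approx(5.0, abs=1.0)
        # calibration-aware
        d2 = apical_nucleus_distance(cell, nucleus, (-30.0, 30.0), 0.5)
        assert d2 == pytest.approx(2.5, abs=0.5)

    def test_apical_nuclei_closer_than_basal(self):
        """Cohort ordering: apically placed nuclei have smaller distances."""
        apical, basal = [], []
        for off in (18, 19, 20):
            cell, nuc = self._cell_with_nucleus(offset_px=off)
            apical.append(apical_nucleus_distance(cell, nuc, (-30.0, 30.0), 1.0))
        for off in (0, 2, 4):
            cell, nuc = self._cell_with_nucleus(offset_px=off)
            basal.append(apical_nucleus_distance(cell, nuc, (-30.0, 30.0), 1.0))
        assert np.mean(apical) < np.mean(basal)

    def test_empty_nucleus_rejected(self):
        cell, _ = self._cell_with_nucleus(10)
        with pytest.raises(MissingInputError):
            apical_nucleus_distance(cell, np.zeros_like(cell), (-30.0, 30.0), 1.0)
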