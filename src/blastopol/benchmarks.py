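"""Self-contained validation studies on synthetic data.

Each function regenerates its inputs from a seed, runs the package's own
measurement path, and returns summary numbers.  They back both the test
suite and the reproduction script, so the same code path produces every
reported figure of merit.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .config import DetectionConfig, SimulationConfig
from .detection import domain_size_degrees, find_candidate_domain
from .geometry import aspect_ratio_3d, circle_contact_angle, interblastomere_angle
from .io import ImageStack
from .pipeline import analyze_movie
from .profiles import extract_contact_free_profile
from .stats import binomial_independence_test, fisher_exact, two_proportion_ztest
from .synthetic import generate_lineage_table, render_embryo_movie
from .timing import embryo_ep_status

__all__ = [
    "onset_recovery_study",
    "ep_calibration_study",
    "ztest_type1_study",
    "fisher_enumeration_pvalue",
    "fisher_agreement_study",
    "geometry_oracle_study",
    "make_arc_disc",
]


def onset_recovery_study(
    n_embryos: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    **config_overrides,
) -> dict:
    """Detect polarization onsets on rendered movies and score them
    against ground truth.

    Returns the fraction of cells whose detected onset frame equals the
    true onset frame exactly, the fraction within one frame, and the
    number of cells scored.
    """
    cfg = SimulationConfig(noise_sd=noise_sd, seed=seed, **config_overrides)
    det = DetectionConfig()
    root = np.random.SeedSequence(seed)
    exact = within1 = total = 0
    for child in root.spawn(n_embryos):
        rng = np.random.default_rng(child)
        movie = render_embryo_movie(cfg, rng)
        stack = ImageStack(
            data=movie.data,
            labels=movie.labels,
            nuclei=movie.nuclei,
            pixel_size_um=movie.pixel_size_um,
            z_step_um=movie.z_step_um,
            frame_interval_min=movie.frame_interval_min,
        )
        cleav = dict(zip(movie.truth["cell"], movie.truth["cleavage_min"]))
        _, classes = analyze_movie(stack, detection=det, cleavage_min=cleav)
        merged = classes.merge(movie.truth, on="cell", suffixes=("_det", "_true"))
        err = (merged["onset_min_det"] - merged["onset_frame_min"]).abs()
        err /= movie.frame_interval_min
        total += len(merged)
        exact += int((err == 0).sum())
        within1 += int((err <= 1).sum())
    return {
        "fraction_exact": exact / total,
        "fraction_within_1_frame": within1 / total,
        "n_cells": total,
    }


def ep_calibration_study(
    n_embryos: int = 5000,
    ep_probability: float = 0.2,
    seed: int = 0,
) -> dict:
    """EP-embryo frequency and cell-autonomy fit over many simulated embryos.

    With independent per-cell EP events the expected EP-embryo fraction is
    ``1 - (1 - p)^8``; the study reports the observed fraction, its
    distance in binomial standard deviations, and the Monte-Carlo binomial
    goodness-of-fit p-value of the per-embryo EP counts.
    """
    cfg = SimulationConfig(
        n_embryos=n_embryos, ep_probability=ep_probability, seed=seed
    )
    rng = np.random.default_rng(seed)
    table = generate_lineage_table(cfg, rng)
    flags, counts = [], []
    for _, grp in table.groupby("embryo")["mother_class"]:
        flag, k = embryo_ep_status(grp)
        flags.append(flag)
        counts.append(k)
    frac = float(np.mean(flags))
    expected = 1.0 - (1.0 - ep_probability) ** cfg.cells_per_embryo
    sd = np.sqrt(expected * (1.0 - expected) / n_embryos)
    fit = binomial_independence_test(
        counts, cfg.cells_per_embryo, rng=np.random.default_rng(seed + 1)
    )
    return {
        "ep_embryo_fraction": frac,
        "expected_fraction": expected,
        "binomial_sd": float(sd),
        "deviation_sds": float(abs(frac - expected) / sd),
        "independence_p_value": fit.p_value,
    }


def ztest_type1_study(
    n_reps: int = 10000,
    p_null: float = 0.3,
    n_per_arm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the pooled two-proportion z-test."""
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n_per_arm, p_null, n_reps)
    x2 = rng.binomial(n_per_arm, p_null, n_reps)
    _, p = two_proportion_ztest(x1, n_per_arm, x2, n_per_arm)
    return {"rejection_rate": float(np.mean(p < alpha)), "n_reps": n_reps}


def fisher_enumeration_pvalue(table) -> float:
    """Independent two-tailed Fisher p by explicit fixed-margin enumeration.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed one (with a
    relative tolerance for float ties).
    """
    (a, b), (c, d) = np.asarray(table, int)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    from scipy.special import gammaln

    def log_comb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logp = log_comb(r1, ks) + log_comb(n - r1, c1 - ks) - log_comb(n, c1)
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    obs = pmf[a - lo]
    return float(pmf[pmf <= obs * (1.0 + 1e-7)].sum())


def fisher_agreement_study(
    max_total: int = 30,
    n_random: int = 300,
    random_max_total: int = 60,
    seed: int = 0,
) -> dict:
    """Max |p difference| between the Fisher test and brute enumeration.

    Exhaustive over every 2x2 table with grand total up to ``max_total``,
    plus random tables up to ``random_max_total``.
    """
    worst = 0.0
    n_checked = 0
    for total in range(1, max_total + 1):
        for r1 in range(total + 1):
            for c1 in range(total + 1):
                lo, hi = max(0, r1 + c1 - total), min(r1, c1)
                for a in range(lo, hi + 1):
                    t = [[a, r1 - a], [c1 - a, total - r1 - c1 + a]]
                    worst = max(worst, abs(fisher_exact(t) - fisher_enumeration_pvalue(t)))
                    n_checked += 1
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        t = rng.integers(0, random_max_total // 4 + 1, size=(2, 2))
        if t.sum() == 0 or t.sum() > random_max_total:
            continue
        worst = max(worst, abs(fisher_exact(t) - fisher_enumeration_pvalue(t)))
        n_checked += 1
    return {"max_abs_p_difference": worst, "n_tables": n_checked}


def make_arc_disc(
    radius_px: int = 40,
    arc_fraction: float = 0.5,
    enrichment: float = 2.0,
    cortex: float = 600.0,
    cytoplasm: float = 200.0,
    size: int | None = None,
):
    """Isolated disc cell with a bright cortical arc of known angular fraction.

    Returns ``(image, labels)`` for detector oracles: the arc covers
    ``arc_fraction`` of the full circle, centered at angle 0, at
    ``enrichment`` x the cortical baseline.
    """
    size = size or (2 * radius_px + 9)
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - c, xx - c)
    ang = np.degrees(np.arctan2(yy - c, xx - c))
    img = np.zeros((size, size))
    img[dist <= radius_px] = cytoplasm
    ring = (dist <= radius_px) & (dist > radius_px - 2.0)
    img[ring] = cortex
    half = arc_fraction * 180.0
    img[ring & (np.abs(ang) <= half)] = cortex * enrichment
    labels = (dist <= radius_px).astype(np.uint16)
    return img, labels


def geometry_oracle_study(seed: int = 0) -> dict:
    """Geometry measurements against analytic shapes.

    Sphere and 2:1 prolate ellipsoid aspect ratios from voxel moments; the
    contact angle of two partitioned discs against the circle-circle closed
    form; and the measured apical-domain size on a rendered arc of known
    fraction.
    """
    out = {}
    # voxelized sphere, isotropic spacing
    zz, yy, xx = np.mgrid[-20:21, -20:21, -20:21]
    sphere = zz**2 + yy**2 + xx**2 <= 18**2
    out["sphere_aspect_ratio"] = aspect_ratio_3d(sphere, (1.0, 1.0, 1.0)).aspect_ratio
    # 2:1 prolate ellipsoid (long axis along x)
    zz, yy, xx = np.mgrid[-14:15, -14:15, -26:27]
    ell = (zz / 12.0) ** 2 + (yy / 12.0) ** 2 + (xx / 24.0) ** 2 <= 1.0
    out["ellipsoid_aspect_ratio"] = aspect_ratio_3d(ell, (1.0, 1.0, 1.0)).aspect_ratio

    # two equal discs, centers 1.4 r apart, nearest-center partition
    r, dfrac = 60.0, 1.4
    d = dfrac * r
    size = int(2 * r + d) + 10
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size / 2.0
    x1, x2 = size / 2.0 - d / 2.0, size / 2.0 + d / 2.0
    d1 = np.hypot(yy - cy, xx - x1)
    d2 = np.hypot(yy - cy, xx - x2)
    mask1 = (d1 <= r) & (d1 <= d2)
    mask2 = (d2 <= r) & (d2 < d1)
    measured = interblastomere_angle(mask1, mask2, 1.0)
    expected = circle_contact_angle(d, r)
    out["contact_angle_measured_deg"] = measured
    out["contact_angle_expected_deg"] = expected
    out["contact_angle_error_deg"] = abs(measured - expected)

    # rendered arc of known fraction on an isolated disc
    frac = 0.5
    img, labels = make_arc_disc(radius_px=40, arc_fraction=frac)
    prof = extract_contact_free_profile(img, labels, 1, 1.0)
    cand = find_candidate_domain(prof, DetectionConfig())
    size_deg = domain_size_degrees((cand.start_angle_deg, cand.end_angle_deg))
    sample_deg = 360.0 / len(prof)
    out["domain_size_measured_deg"] = size_deg
    out["domain_size_expected_deg"] = frac * 360.0
    out["domain_size_error_samples"] = abs(size_deg - frac * 360.0) / sample_deg
    return out
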