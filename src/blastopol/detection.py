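"""Three-criterion apical-domain detection and domain-derived morphometrics.

A blastomere is called polarized at one frame when a contiguous cortical
arc satisfies, somewhere in z, all of:

1. **length** - the arc covers between 33% and 80% (inclusive) of the
   cell's contact-free cortex;
2. **intensity** - the arc's mean intensity is strictly more than 1.5x the
   mean intensity of the remaining contact-free cortex;
3. **depth** - arcs passing (1) and (2), with at least 50% mutual angular
   overlap between consecutive slices, occur on a contiguous z-run spanning
   at least 3 um.

Candidate arcs are found by exhaustive search over all contiguous windows
within the length bounds, maximizing mean intensity (ties: longer arc,
then smaller start angle).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import DetectionConfig
from .errors import (
    ConfigurationError,
    InvalidInputError,
    MissingInputError,
    NoCandidateError,
)
from .profiles import CorticalProfile

__all__ = [
    "CandidateArc",
    "ApicalDomainCall",
    "find_candidate_domain",
    "apply_domain_criteria",
    "domain_size_degrees",
    "apical_nucleus_distance",
    "arc_overlap_deg",
]


@dataclass
class CandidateArc:
    """Best-scoring cortical window of one profile."""

    start_angle_deg: float
    end_angle_deg: float
    length_um: float
    length_fraction: float
    mean_intensity: float
    intensity_ratio: float   # window mean / mean of remaining contact-free samples
    z: int
    start_index: int
    n_samples: int

    @property
    def span_deg(self) -> float:
        return (self.end_angle_deg - self.start_angle_deg) % 360.0 or 360.0


@dataclass
class ApicalDomainCall:
    """Outcome of the three-criterion test for one cell at one frame."""

    cell_id: int
    frame: int
    polarized: bool
    start_angle_deg: float = np.nan
    end_angle_deg: float = np.nan
    length_fraction: float = np.nan
    intensity_ratio: float = np.nan
    z_extent_um: float = 0.0
    domain_size_deg: float = np.nan
    best_z: int = -1
    apical_nucleus_distance_um: float = np.nan


def _segments(profile: CorticalProfile, gap_factor: float = 2.5):
    """Split sample indices into contiguous boundary segments.

    Contact exclusion leaves spatial gaps between consecutive (angle-sorted)
    samples; a step larger than ``gap_factor`` x the median step opens a new
    segment.  A closed profile is returned as a single segment flagged
    circular.
    """
    n = len(profile)
    if n < 2:
        return [np.arange(n)], False
    steps = np.diff(profile.arc_um)
    med = np.median(steps)
    breaks = np.flatnonzero(steps > gap_factor * max(med, profile.pixel_size_um))
    if len(breaks) == 0:
        return [np.arange(n)], profile.closed
    segs = np.split(np.arange(n), breaks + 1)
    return segs, False


def find_candidate_domain(
    profile: CorticalProfile,
    config: DetectionConfig | None = None,
) -> CandidateArc:
    """Exhaustive best-window search over one contact-free profile.

    Over all contiguous arcs whose length fraction (of the contact-free
    total) lies within the configured bounds, returns the arc maximizing
    the intensity ratio -- the window mean over the mean of the remaining
    contact-free samples, the same statistic the intensity criterion
    thresholds.  Making the search the arg-max of its own test statistic
    keeps the selected arc from collapsing onto a noisy sub-window of the
    true domain (every sub-window ties on mean intensity, but only the
    full domain maximizes the ratio).  Ties are broken by longer arc,
    then by smaller start angle.

    Raises :class:`NoCandidateError` when no window fits the length bounds.
    """
    config = config or DetectionConfig()
    n = len(profile)
    if n == 0:
        raise InvalidInputError("empty profile")
    total = profile.total_length_um
    total_sum = float(profile.intensity.sum())
    segs, circular = _segments(profile)

    best = None  # (ratio, length, -start_angle) lexicographic max
    for seg in segs:
        idx = seg
        arc = profile.arc_um[idx]
        inten = profile.intensity[idx]
        ang = profile.angle_deg[idx]
        m = len(idx)
        if circular and m > 1:
            # allow wrap-around windows: extend by one lap
            closure = total - (arc[-1] - arc[0])
            arc = np.concatenate([arc, arc[-1] + closure + (arc[1:] - arc[0])])
            inten = np.concatenate([inten, inten[1:]])
            ang = np.concatenate([ang, ang[1:] + 360.0])
            idx = np.concatenate([idx, idx[1:]])
        csum = np.concatenate([[0.0], np.cumsum(inten)])
        for k in range(2, min(m + 1, n)):  # rest of profile stays non-empty
            starts = np.arange(0, len(inten) - k + 1)
            if circular:
                starts = starts[starts < m]
            if len(starts) == 0:
                continue
            lengths = arc[starts + k - 1] - arc[starts]
            frac = lengths / total
            ok = (frac >= config.length_fraction_min) & (frac <= config.length_fraction_max)
            if not ok.any():
                continue
            win_sum = csum[starts + k] - csum[starts]
            means = win_sum / k
            rest_mean = (total_sum - win_sum) / (n - k)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(rest_mean > 0, means / rest_mean, np.inf)
            ratios = np.where(ok, ratios, -np.inf)
            j = int(np.argmax(ratios))
            key = (ratios[j], lengths[j], -ang[starts[j]])
            if best is None or key > best[0]:
                best = (key, starts[j], k, ang, means[j])

    if best is None:
        raise NoCandidateError(
            "no contiguous window within the configured length-fraction bounds"
        )
    key, s, k, ang, mean_in = best
    ratio = float(key[0])
    length = float(key[1])
    return CandidateArc(
        start_angle_deg=float((ang[s] + 180.0) % 360.0 - 180.0),
        end_angle_deg=float((ang[s + k - 1] + 180.0) % 360.0 - 180.0),
        length_um=float(length),
        length_fraction=float(length / total),
        mean_intensity=float(mean_in),
        intensity_ratio=ratio,
        z=profile.z,
        start_index=int(s),
        n_samples=int(k),
    )


def arc_overlap_deg(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Angular overlap (degrees) of two circular arcs given as (start, end)."""
    def unroll(arc):
        s, e = arc
        span = (e - s) % 360.0
        return s % 360.0, span

    s1, w1 = unroll(a)
    s2, w2 = unroll(b)
    # candidate shifts of arc 2 relative to arc 1
    best = 0.0
    for shift in (-360.0, 0.0, 360.0):
        lo = max(s1, s2 + shift)
        hi = min(s1 + w1, s2 + shift + w2)
        best = max(best, hi - lo)
    return best


def apply_domain_criteria(
    candidates: list[CandidateArc | None],
    config: DetectionConfig,
    z_step_um: float,
    *,
    cell_id: int = 0,
    frame: int = 0,
) -> ApicalDomainCall:
    """Combine per-slice candidate arcs into a polarized/unpolarized call.

    ``candidates`` is ordered by z (one entry per slice; ``None`` where the
    cell has no usable profile).  The z-extent of a run of ``k`` passing
    slices is counted as the slab thickness ``k * z_step_um``, so a single
    slice with a z-step of at least ``depth_min_um`` can satisfy depth.
    """
    if z_step_um is None or z_step_um <= 0:
        raise ConfigurationError("z_step_um calibration required")
    passing = []
    for i, cand in enumerate(candidates):
        ok = (
            cand is not None
            and config.length_fraction_min <= cand.length_fraction <= config.length_fraction_max
            and cand.intensity_ratio > config.intensity_ratio_threshold
        )
        passing.append(cand if ok else None)

    # contiguous runs of passing slices with mutual angular overlap >= threshold
    best_run: list[int] = []
    run: list[int] = []
    for i, cand in enumerate(passing):
        if cand is None:
            run = []
            continue
        if run:
            prev = passing[run[-1]]
            ov = arc_overlap_deg(
                (prev.start_angle_deg, prev.end_angle_deg),
                (cand.start_angle_deg, cand.end_angle_deg),
            )
            mutual = min(
                ov / prev.span_deg if prev.span_deg else 0.0,
                ov / cand.span_deg if cand.span_deg else 0.0,
            )
            if mutual < config.z_overlap_min:
                run = []
        run = run + [i]
        if len(run) > len(best_run):
            best_run = run

    z_extent = len(best_run) * z_step_um
    if best_run and z_extent >= config.depth_min_um:
        best = max(best_run, key=lambda i: passing[i].intensity_ratio)
        cand = passing[best]
        return ApicalDomainCall(
            cell_id=cell_id,
            frame=frame,
            polarized=True,
            start_angle_deg=cand.start_angle_deg,
            end_angle_deg=cand.end_angle_deg,
            length_fraction=cand.length_fraction,
            intensity_ratio=cand.intensity_ratio,
            z_extent_um=z_extent,
            domain_size_deg=domain_size_degrees((cand.start_angle_deg, cand.end_angle_deg)),
            best_z=cand.z,
        )
    # report the strongest single-slice candidate for diagnostics
    avail = [c for c in candidates if c is not None]
    top = max(avail, key=lambda c: c.intensity_ratio) if avail else None
    return ApicalDomainCall(
        cell_id=cell_id,
        frame=frame,
        polarized=False,
        start_angle_deg=top.start_angle_deg if top else np.nan,
        end_angle_deg=top.end_angle_deg if top else np.nan,
        length_fraction=top.length_fraction if top else np.nan,
        intensity_ratio=top.intensity_ratio if top else np.nan,
        z_extent_um=z_extent,
        best_z=top.z if top else -1,
    )


def domain_size_degrees(arc: tuple[float, float]) -> float:
    """Angle subtended by a domain arc (start, end in degrees) at the centroid."""
    start, end = arc
    size = (end - start) % 360.0
    return 360.0 if size == 0.0 else float(size)


def apical_nucleus_distance(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    domain_arc: tuple[float, float],
    pixel_size_um: float,
    *,
    embryo_center: tuple[float, float] | None = None,
) -> float:
    """Distance (um) from the nucleus to the cortex at the domain midpoint.

    The cortex point at the angular midpoint of the domain arc is located on
    the cell boundary; the returned value is the distance from that point to
    the nearest nucleus boundary point.  Measured on the plane where the
    nucleus is largest (caller selects the plane).
    """
    if not np.asarray(nucleus_mask).any():
        raise MissingInputError("nucleus mask is empty")
    if not np.asarray(cell_mask).any():
        raise MissingInputError("cell mask is empty")
    cm = np.asarray(cell_mask, bool)
    nm = np.asarray(nucleus_mask, bool)
    boundary = cm & ~ndimage.binary_erosion(cm, border_value=0)
    br, bc = np.nonzero(boundary)
    cy, cx = ndimage.center_of_mass(cm)
    if embryo_center is None:
        axis_ang = 0.0
    else:
        ey, ex = embryo_center
        axis_ang = np.degrees(np.arctan2(cy - ey, cx - ex))
    mid = (domain_arc[0] + domain_size_degrees(domain_arc) / 2.0) % 360.0
    ang = (np.degrees(np.arctan2(br - cy, bc - cx)) - axis_ang) % 360.0
    diff = np.abs((ang - mid + 180.0) % 360.0 - 180.0)
    i = int(np.argmin(diff))
    apex = np.array([br[i], bc[i]], float)

    nb = nm & ~ndimage.binary_erosion(nm, border_value=0)
    nr, nc = np.nonzero(nb)
    d = np.sqrt((nr - apex[0]) ** 2 + (nc - apex[1]) ** 2)
    return float(d.min() * pixel_size_um)
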