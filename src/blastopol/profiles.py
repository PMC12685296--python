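"""Contact-free cortical intensity profiles and intensity-ratio measurements.

The central object is :class:`CorticalProfile`: intensities sampled along a
cell's boundary at one (t, z), restricted to the portion of the cortex that
does not touch a neighboring cell.  Samples are ordered by angular position
about the cell centroid, measured from the embryo-center -> cell-centroid
axis so that the outward-facing cortex is centered at 0 degrees.

All ratio quantifications used downstream live here:

* cortical enrichment  (Icortex - Icytoplasm) / Icytoplasm
* nuclear : cytoplasmic ratio  INTnucleus / INTcytoplasm
* embryo-level EP : LP nuclear intensity ratio (DNA-stain normalized)
* doublet reporter ratio at the end of the 8-cell stage
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import (
    EmptyProfileError,
    IncompleteTraceError,
    InvalidInputError,
    InvalidMeasurementError,
    MissingInputError,
    UndefinedRatioError,
)

__all__ = [
    "CorticalProfile",
    "NuclearMeasurement",
    "extract_contact_free_profile",
    "cortical_enrichment",
    "smooth_profile",
    "nuclear_cytoplasmic_ratio",
    "ep_lp_intensity_ratio",
    "cdx2_doublet_ratio",
    "cytoplasm_control_mean",
]


@dataclass
class CorticalProfile:
    """Ordered contact-free cortical samples of one cell at one (t, z)."""

    cell_id: int
    t: int
    z: int
    arc_um: np.ndarray        # strictly increasing cumulative arc position
    angle_deg: np.ndarray     # ascending, in (-180, 180], about cell centroid
    intensity: np.ndarray
    total_length_um: float    # contact-free cortex length
    points: np.ndarray        # (n, 2) pixel coordinates (row, col) of samples
    pixel_size_um: float
    closed: bool = False      # True when the profile spans the full perimeter
    icytoplasm: float | None = None

    def __len__(self) -> int:
        return len(self.intensity)

    @property
    def span_deg(self) -> float:
        """Angular extent covered by the samples (360 when closed)."""
        if self.closed:
            return 360.0
        return float(self.angle_deg[-1] - self.angle_deg[0])


@dataclass
class NuclearMeasurement:
    """Mean nuclear vs equal-area cytoplasmic intensity of one cell."""

    int_nucleus: float
    int_cytoplasm: float
    dapi_nucleus: float | None = None


def _wrap_deg(a):
    """Wrap angles into (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    # 8-connected outer rim of the mask (erosion with the cross element)
    return mask & ~ndimage.binary_erosion(mask, border_value=0)


def extract_contact_free_profile(
    image: np.ndarray,
    labels: np.ndarray,
    cell_id: int,
    pixel_size_um: float,
    *,
    band_px: int = 2,
    embryo_center: tuple[float, float] | None = None,
    t: int = 0,
    z: int = 0,
    icytoplasm: float | None = None,
) -> CorticalProfile:
    """Sample intensity along the contact-free boundary of one labeled cell.

    Boundary pixels within ``band_px`` (Chebyshev) of any other labeled cell
    are excluded as contact cortex.  One sample is taken per boundary pixel;
    arc position is the cumulative Euclidean step length in micrometres.

    Raises
    ------
    MissingInputError
        if ``cell_id`` is absent from ``labels``.
    EmptyProfileError
        if the cell is fully enclosed by neighbors.
    """
    mask = labels == cell_id
    if not mask.any():
        raise MissingInputError(f"cell {cell_id} not present in label mask")

    # work on a crop for speed
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    pad = band_px + 2
    r0 = max(0, rows[0] - pad)
    r1 = min(mask.shape[0], rows[-1] + pad + 1)
    c0 = max(0, cols[0] - pad)
    c1 = min(mask.shape[1], cols[-1] + pad + 1)
    m = mask[r0:r1, c0:c1]
    lab = labels[r0:r1, c0:c1]
    img = np.asarray(image)[r0:r1, c0:c1]

    boundary = _boundary_mask(m)
    neighbors = (lab > 0) & ~m
    if band_px > 0 and neighbors.any():
        excl = ndimage.binary_dilation(
            neighbors, structure=np.ones((3, 3), bool), iterations=band_px
        )
        free = boundary & ~excl
    else:
        excl = None
        free = boundary
    if not free.any():
        raise EmptyProfileError(f"cell {cell_id} has no contact-free boundary")

    pr, pc = np.nonzero(free)
    cy, cx = ndimage.center_of_mass(m)
    if embryo_center is None:
        ey, ex = ndimage.center_of_mass(labels > 0)
    else:
        ey, ex = embryo_center
    # outward axis: embryo center -> cell centroid (global coordinates)
    ay, ax = (cy + r0) - ey, (cx + c0) - ex
    if ay == 0 and ax == 0:
        ay, ax = 0.0, 1.0
    axis_ang = np.degrees(np.arctan2(ay, ax))

    ang = _wrap_deg(np.degrees(np.arctan2(pr - cy, pc - cx)) - axis_ang)
    order = np.argsort(ang, kind="stable")
    pr, pc, ang = pr[order], pc[order], ang[order]

    pts = np.column_stack([pr, pc]).astype(float)
    steps = np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1)) * pixel_size_um
    arc = np.concatenate([[0.0], np.cumsum(steps)])

    closed = not (boundary & ~free).any() if excl is None else not (boundary & excl).any()
    total = float(arc[-1])
    if closed and len(pts) > 1:
        # include the closure step of the full perimeter
        total += float(np.sqrt(np.sum((pts[-1] - pts[0]) ** 2))) * pixel_size_um
    if total <= 0:
        raise EmptyProfileError(f"cell {cell_id}: degenerate boundary")

    inten = img[pr, pc].astype(float)
    pts[:, 0] += r0
    pts[:, 1] += c0
    return CorticalProfile(
        cell_id=cell_id,
        t=t,
        z=z,
        arc_um=arc,
        angle_deg=ang,
        intensity=inten,
        total_length_um=total,
        points=pts,
        pixel_size_um=pixel_size_um,
        closed=bool(closed),
        icytoplasm=icytoplasm,
    )


def cortical_enrichment(icortex: float, icytoplasm: float) -> float:
    """Cortical signal excess over cytoplasm: (Icortex - Icyto) / Icyto."""
    if icytoplasm <= 0:
        raise InvalidMeasurementError("Icytoplasm must be positive")
    return (icortex - icytoplasm) / icytoplasm


def cytoplasm_control_mean(
    image: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    *,
    pixel_size_um: float = 1.0,
    margin_um: float = 2.0,
) -> float:
    """Mean intensity of a standard cytoplasmic control region.

    The region is the cell interior eroded ``margin_um`` away from the
    cortex and, when a nucleus mask is given, at least the same margin away
    from the nucleus.
    """
    m_px = margin_um / pixel_size_um
    region = ndimage.distance_transform_edt(cell_mask) > m_px
    if nucleus_mask is not None and nucleus_mask.any():
        region &= ndimage.distance_transform_edt(~np.asarray(nucleus_mask, bool)) > m_px
    if not region.any():
        raise MissingInputError("cytoplasmic control region is empty after erosion")
    return float(np.asarray(image)[region].mean())


def smooth_profile(profile: CorticalProfile, window: int = 20, polyorder: int = 2) -> CorticalProfile:
    """Local polynomial (Savitzky-Golay style) smoothing of the intensity.

    For each sample the nearest ``window`` samples (by index; windows shrink
    symmetrically only at the profile ends) are fit with a polynomial of
    ``polyorder`` over arc position and evaluated at the sample.  Arc
    positions and angles are unchanged; constants and exact quadratics are
    reproduced to numerical precision.
    """
    n = len(profile)
    if n < 3:
        raise InvalidInputError("smoothing needs at least 3 samples")
    if window > n:
        raise InvalidInputError(f"window ({window}) exceeds sample count ({n})")
    if window < polyorder + 1:
        raise InvalidInputError("window must be at least polyorder + 1")
    x = profile.arc_um
    y = profile.intensity
    out = np.empty(n)
    half = window // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        xs = x[lo:hi] - x[i]
        deg = min(polyorder, hi - lo - 1)
        coef = np.polynomial.polynomial.polyfit(xs, y[lo:hi], deg)
        out[i] = coef[0]
    return replace(profile, intensity=out)


def nuclear_cytoplasmic_ratio(measurement: NuclearMeasurement) -> float:
    """INTnucleus / INTcytoplasm on the plane where the nucleus is largest."""
    if measurement.int_cytoplasm <= 0:
        raise InvalidMeasurementError("cytoplasmic mean must be positive")
    return measurement.int_nucleus / measurement.int_cytoplasm


def ep_lp_intensity_ratio(
    nuclear_means,
    dapi_means,
    ep_flags,
) -> float:
    """Embryo-level mean(EP) / mean(LP) of DNA-stain-normalized nuclear signal.

    Each cell's signal is first divided by its DNA-stain (DAPI) nuclear
    mean; the normalized values are averaged within the early-polarizing
    and late-polarizing groups and the ratio of group means returned.
    """
    sig = np.asarray(nuclear_means, float)
    dapi = np.asarray(dapi_means, float)
    ep = np.asarray(ep_flags, bool)
    if sig.shape != dapi.shape or sig.shape != ep.shape:
        raise InvalidInputError("per-cell arrays must have identical shape")
    if np.any(dapi <= 0):
        raise InvalidMeasurementError("DAPI means must be positive")
    if not ep.any() or ep.all():
        raise UndefinedRatioError("embryo must contain both EP and LP cells")
    norm = sig / dapi
    return float(norm[ep].mean() / norm[~ep].mean())


def cdx2_doublet_ratio(
    nuclear_traces,
    background_trace,
    division_frame: int,
    ep_index: int | None = None,
):
    """Reporter intensity ratio between the two cells of an 8-cell-stage doublet.

    Each nucleus's per-frame mean is normalized by the cytoplasmic
    background; the reported scalar is cell_1 / cell_2 at the last frame
    before the first 8->16 division.  When one cell is early polarizing its
    index is passed as ``ep_index`` and the ratio is ordered EP / LP;
    otherwise the given (left / right) order is kept.

    Returns ``(ratio_at_final_frame, ratio_trace)``.
    """
    traces = np.asarray(nuclear_traces, float)
    bg = np.asarray(background_trace, float)
    if traces.ndim != 2 or traces.shape[0] != 2:
        raise InvalidInputError("nuclear_traces must have shape (2, n_frames)")
    if bg.ndim == 1:
        bg = np.stack([bg, bg])
    if bg.shape != traces.shape:
        raise InvalidInputError("background trace shape mismatch")
    n = traces.shape[1]
    if not (1 <= division_frame <= n):
        raise IncompleteTraceError(
            f"division frame {division_frame} outside trace of length {n}"
        )
    if np.any(bg <= 0):
        raise InvalidMeasurementError("background must be positive")
    a, b = (1, 0) if ep_index == 1 else (0, 1)
    norm = traces / bg
    ratio_trace = norm[a] / norm[b]
    return float(ratio_trace[division_frame - 1]), ratio_trace
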