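"""Inter-blastomere contact angles, 2-D division geometry, 3-D aspect ratios.

The inter-blastomere angle (IEA) is measured at the two endpoints of the
shared contact interface: the local tangent of each cell's contact-free
boundary is estimated by a low-order polynomial fit over a short arc, the
two tangents are oriented away from the junction along their own surfaces,
and the angle between them (averaged over the two endpoints) is the IEA.
Flattened cells whose outer surfaces form a straight line through the
junction give 180 degrees; a point contact between two discs gives ~0.

An embryo counts as compacted when every measured IEA is at least 120
degrees.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    InsufficientDepthError,
    InvalidShapeError,
    MissingInputError,
    NotAdjacentError,
)

__all__ = [
    "ShapeMetrics2D",
    "AspectRatio3D",
    "interblastomere_angle",
    "compaction_state",
    "apex_geometry_2d",
    "aspect_ratio_3d",
    "normalize_aspect_ratios",
    "circle_contact_angle",
]


@dataclass
class ShapeMetrics2D:
    """Wedge geometry of a blastomere in the embryo mid-plane."""

    apex_angle_deg: float
    side_length_um: float   # mean lateral edge length (basal corner -> apical edge)
    full_length_um: float   # mean converging-line length (basal corner -> apex)
    length_ratio: float     # side : full


@dataclass
class AspectRatio3D:
    """Principal-axis lengths of a 3-D cell mask."""

    long_axis_um: float
    short_axis_um: float
    aspect_ratio: float
    normalized: float | None = None


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    b = mask & ~ndimage.binary_erosion(mask, border_value=0)
    r, c = np.nonzero(b)
    return np.column_stack([r, c]).astype(float)


def _free_contour(mask: np.ndarray, other: np.ndarray, gap_px: float) -> np.ndarray:
    """Sub-pixel outline of ``mask`` away from ``other`` (contact-free)."""
    from skimage import measure as _skm

    contours = _skm.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise InvalidShapeError("mask has no contour")
    cont = max(contours, key=len)
    dist = ndimage.distance_transform_edt(~np.asarray(other, bool))
    iv = np.clip(cont.astype(int), 0, np.array(other.shape) - 1)
    free = dist[iv[:, 0], iv[:, 1]] > gap_px
    return cont[free]


def _fit_circle(points: np.ndarray):
    """Least-squares (Kasa) circle through a 2-D point cloud."""
    if len(points) < 3:
        raise InvalidShapeError("need at least 3 points for a circle fit")
    x, y = points[:, 1], points[:, 0]
    design = np.column_stack([x, y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(design, x**2 + y**2, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if not np.isfinite(r2) or r2 <= 0:
        raise InvalidShapeError("degenerate circle fit")
    return np.array([cy, cx]), float(np.sqrt(r2))


def interblastomere_angle(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    pixel_size_um: float = 1.0,
    *,
    exclude: np.ndarray | None = None,
    gap_px: float = 1.5,
    local_arc_um: float | None = None,
) -> float:
    """Exterior contact angle (degrees) between two adjacent blastomeres.

    The contact-free outline of each cell is fit with a circle (uniform
    cortical tension keeps the free surface of a blastomere at constant
    curvature, so the free cortex is a circular arc to good approximation);
    the angle between the two fitted arcs at their junction follows
    analytically from the center distance ``d`` and radii:
    ``IEA = 180 - arccos((r1^2 + r2^2 - d^2) / (2 r1 r2))``.
    This gives ~0 for a point contact (d = 2r) and 180 for fully flattened
    cells.  ``exclude`` marks additional cells whose vicinity is removed
    from the free outlines (triple junctions); ``local_arc_um`` optionally
    restricts each fit to outline points within that distance of the
    contact, for strongly non-circular cells.

    Raises :class:`NotAdjacentError` when the masks share no interface.
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if not a.any() or not b.any():
        raise MissingInputError("empty mask")
    grow = np.ones((3, 3), bool)
    contact = (a & ndimage.binary_dilation(b, grow)) | (b & ndimage.binary_dilation(a, grow))
    if not contact.any():
        raise NotAdjacentError("masks share no contact interface")

    ex = np.zeros_like(a) if exclude is None else np.asarray(exclude, bool)
    free_a = _free_contour(a, b | ex, gap_px)
    free_b = _free_contour(b, a | ex, gap_px)
    if local_arc_um is not None:
        iface = np.column_stack(np.nonzero(contact)).astype(float)
        r_px = local_arc_um / pixel_size_um

        def near(pts):
            d = np.min(
                np.linalg.norm(pts[:, None, :] - iface[None, :, :], axis=2), axis=1
            )
            return pts[d <= r_px]

        free_a, free_b = near(free_a), near(free_b)
    c1, r1 = _fit_circle(free_a)
    c2, r2 = _fit_circle(free_b)
    d = float(np.linalg.norm(c1 - c2))
    arg = np.clip((r1**2 + r2**2 - d**2) / (2.0 * r1 * r2), -1.0, 1.0)
    return float(180.0 - np.degrees(np.arccos(arg)))


def circle_contact_angle(distance: float, radius: float) -> float:
    """Closed-form IEA of two equal intersecting circles (oracle geometry).

    For centers ``distance`` apart and common ``radius``, the exterior angle
    between the two circular surfaces at an intersection point is
    ``2 * arccos(d / 2r)`` degrees: 0 at point contact (d = 2r), 180 at
    full overlap (d = 0).
    """
    x = np.clip(distance / (2.0 * radius), -1.0, 1.0)
    return float(np.degrees(2.0 * np.arccos(x)))


def compaction_state(angles) -> bool:
    """True when every measured inter-blastomere angle is >= 120 degrees."""
    arr = np.asarray(list(angles), float)
    if arr.size == 0:
        raise MissingInputError("no inter-blastomere angles to assess")
    return bool(np.all(arr >= 120.0))


def apex_geometry_2d(
    cell_mask: np.ndarray,
    domain_arc: tuple[float, float],
    pixel_size_um: float = 1.0,
    *,
    embryo_center: tuple[float, float] | None = None,
    min_area_px: int = 20,
) -> ShapeMetrics2D:
    """Apex angle and side:full length ratio of a mid-plane cell outline.

    The apex is the boundary point at the angular midpoint of the apical
    domain arc (or of the contact-free arc when no domain exists).  Basal
    corners are the boundary points of largest lateral excursion from the
    apical axis on either side; converging lines join them to the apex, and
    the lateral sides join them to the domain-arc endpoints.
    """
    cm = np.asarray(cell_mask, bool)
    if cm.sum() < min_area_px:
        raise InvalidShapeError(f"mask area below {min_area_px} px")
    pts = _boundary_points(cm)
    cy, cx = ndimage.center_of_mass(cm)
    if embryo_center is None:
        axis_ang = 0.0
    else:
        axis_ang = np.degrees(np.arctan2(cy - embryo_center[0], cx - embryo_center[1]))
    ang = (np.degrees(np.arctan2(pts[:, 0] - cy, pts[:, 1] - cx)) - axis_ang) % 360.0

    span = (domain_arc[1] - domain_arc[0]) % 360.0 or 360.0
    mid = (domain_arc[0] + span / 2.0) % 360.0

    def at_angle(target):
        diff = np.abs((ang - target + 180.0) % 360.0 - 180.0)
        return pts[int(np.argmin(diff))]

    apex = at_angle(mid)
    d1 = at_angle(domain_arc[0] % 360.0)
    d2 = at_angle(domain_arc[1] % 360.0)

    u = apex - np.array([cy, cx])
    nu = np.linalg.norm(u)
    if nu == 0:
        raise InvalidShapeError("apex coincides with centroid")
    u = u / nu

    def cross2(a, b):
        return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

    rel = pts - np.array([cy, cx])
    lateral = cross2(u, rel)
    dist_apex = np.linalg.norm(pts - apex, axis=1)
    # the basal edge is the boundary band at minimal apical projection;
    # its endpoints are the lateral extremes within that band
    proj = rel @ u
    band = proj <= proj.min() + 0.15 * (proj.max() - proj.min())
    if not band.any():
        band = np.ones(len(pts), bool)

    def corner(side_sign):
        s = np.where(band, lateral * side_sign, -np.inf)
        m = s.max()
        cand = np.flatnonzero(s >= m - 0.5)  # half-pixel tie band
        return pts[cand[int(np.argmax(dist_apex[cand]))]]

    b1 = corner(+1.0)
    b2 = corner(-1.0)
    v1 = b1 - apex
    v2 = b2 - apex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise InvalidShapeError("degenerate converging lines")
    apex_angle = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))

    # pair each basal corner with the domain endpoint on its own side
    if cross2(u, d1 - np.array([cy, cx])) >= 0:
        e1, e2 = d1, d2
    else:
        e1, e2 = d2, d1
    side1 = np.linalg.norm(b1 - e1)
    side2 = np.linalg.norm(b2 - e2)
    side = 0.5 * (side1 + side2) * pixel_size_um
    full = 0.5 * (n1 + n2) * pixel_size_um
    return ShapeMetrics2D(
        apex_angle_deg=float(apex_angle),
        side_length_um=float(side),
        full_length_um=float(full),
        length_ratio=float(side / full),
    )


def aspect_ratio_3d(
    mask_zyx: np.ndarray,
    spacing_um: tuple[float, float, float],
    *,
    min_voxels: int = 30,
) -> AspectRatio3D:
    """Principal-axis aspect ratio of a 3-D cell mask from spatial moments.

    Axis half-lengths are ``sqrt(5 * lambda)`` for the eigenvalues of the
    anisotropy-corrected voxel covariance (exact for a solid ellipsoid);
    the aspect ratio is longest / shortest axis.
    """
    m = np.asarray(mask_zyx, bool)
    if m.ndim != 3:
        raise InvalidShapeError("mask must be 3-D (z, y, x)")
    if m.sum() < min_voxels:
        raise InvalidShapeError(f"mask below {min_voxels} voxels")
    zs = np.unique(np.nonzero(m)[0])
    if len(zs) < 2:
        raise InsufficientDepthError("mask spans fewer than 2 z-slices")
    coords = np.column_stack(np.nonzero(m)).astype(float) * np.asarray(spacing_um)
    cov = np.cov(coords.T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    evals = np.clip(evals, 1e-12, None)
    axes = 2.0 * np.sqrt(5.0 * evals)
    return AspectRatio3D(
        long_axis_um=float(axes[-1]),
        short_axis_um=float(axes[0]),
        aspect_ratio=float(axes[-1] / axes[0]),
    )


def normalize_aspect_ratios(ratios) -> np.ndarray:
    """Embryo-normalize aspect ratios so that their mean is exactly 1."""
    arr = np.asarray(list(ratios), float)
    if arr.size == 0:
        raise MissingInputError("no aspect ratios to normalize")
    return arr / arr.mean()
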