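"""Seeded synthetic 8-cell embryo movies and lineage tables.

The generator provides ground truth for every downstream stage:

* :func:`generate_lineage_table` draws, per blastomere, an independent
  early-polarization (EP) flag, an onset time (uniform within an hour of
  cleavage for EP cells; truncated normal after compaction for LP cells),
  a division-symmetry outcome conditional on EP status, and daughter
  polarity / trophectoderm fates conditional on symmetry and polarity.

* :func:`render_embryo_movie` renders a calibrated T x Z x Y x X intensity
  stack with companion per-cell label and nucleus masks.  Cells are discs
  on a ring in a mid-plane-centric geometry (spheres in z), deformed at
  contacts by a nearest-center partition; the inter-blastomere angle
  follows the configured compaction ramp (the center distance of two equal
  circles meeting at angle theta is ``2 r cos(theta / 2)``).  From each
  cell's true onset, a contiguous cortical arc covering the configured
  fraction of the contact-free cortex carries ``domain_enrichment`` times
  the cortical baseline across the configured z-depth, centered on the
  outward-facing axis.  Noise is additive Gaussian, clipped at zero.

All randomness flows from one explicitly passed seeded generator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SimulationConfig
from .errors import ConfigurationError

__all__ = [
    "EmbryoMovie",
    "generate_lineage_table",
    "render_embryo_movie",
    "draw_polarization_timing",
]


@dataclass
class EmbryoMovie:
    """Rendered synthetic movie plus per-cell ground truth."""

    data: np.ndarray        # (t, z, y, x) uint16 intensities
    labels: np.ndarray      # (t, z, y, x) uint16 cell ids (0 = background)
    nuclei: np.ndarray      # (t, z, y, x) uint16 nucleus ids
    truth: pd.DataFrame     # one row per cell
    pixel_size_um: float
    z_step_um: float
    frame_interval_min: float
    embryo_center_px: tuple[float, float]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.frame_interval_min


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def draw_polarization_timing(config: SimulationConfig, rng, n_cells: int):
    """Draw (cleavage, EP flag, absolute onset) for ``n_cells`` blastomeres.

    EP onsets are uniform in ``[0, ep_onset_window_min]`` after the cell's
    own cleavage; LP onsets are normal (mean/sd from the config) truncated
    to the interval between the 120-degree compaction time and two frames
    before the movie ends, so every simulated onset is observable.
    """
    rng = _as_rng(rng)
    cleavage = rng.uniform(0.0, config.cleavage_jitter_min, n_cells)
    ep = rng.random(n_cells) < config.ep_probability
    onset = np.empty(n_cells)
    onset[ep] = cleavage[ep] + rng.uniform(0.0, config.ep_onset_window_min, int(ep.sum()))
    lo = config.compaction_120_min
    hi = max(lo + 1.0, config.movie_minutes - 2.0 * config.frame_interval_min)
    n_lp = int((~ep).sum())
    if n_lp:
        a = (lo - config.lp_onset_mean_min) / max(config.lp_onset_sd_min, 1e-9)
        b = (hi - config.lp_onset_mean_min) / max(config.lp_onset_sd_min, 1e-9)
        onset[~ep] = sps.truncnorm.rvs(
            a, b, loc=config.lp_onset_mean_min, scale=config.lp_onset_sd_min,
            size=n_lp, random_state=rng,
        )
    return cleavage, ep, onset


def generate_lineage_table(
    config: SimulationConfig,
    rng=None,
    *,
    ep_flags: np.ndarray | None = None,
) -> pd.DataFrame:
    """One lineage record per 8-cell blastomere, with ground truth columns.

    EP flags are drawn independently per cell with ``ep_probability``
    (or taken from ``ep_flags`` to stay consistent with a rendered movie);
    division symmetry is conditional on EP status; a symmetric division
    yields two polar daughters, an asymmetric one yields exactly one; TE
    fate is drawn conditional on daughter polarity.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    n = config.n_embryos * config.cells_per_embryo
    embryo = np.repeat(np.arange(config.n_embryos), config.cells_per_embryo)
    cell = np.tile(np.arange(1, config.cells_per_embryo + 1), config.n_embryos)

    cleavage, ep, onset = draw_polarization_timing(config, rng, n)
    if ep_flags is not None:
        ep = np.asarray(ep_flags, bool)
        if ep.shape != (n,):
            raise ConfigurationError("ep_flags must have one entry per cell")

    p_sym = np.where(ep, config.p_sym_given_ep, config.p_sym_given_lp)
    symmetric = rng.random(n) < p_sym
    # asymmetric: exactly one polar daughter, position chosen at random
    first_polar = rng.random(n) < 0.5
    d1_polar = symmetric | first_polar
    d2_polar = symmetric | ~first_polar

    def fates(polar):
        p = np.where(polar, config.p_te_given_polar, config.p_te_given_apolar)
        te = rng.random(n) < p
        return te

    d1_te = fates(d1_polar)
    d2_te = fates(d2_polar)
    return pd.DataFrame(
        {
            "embryo": embryo,
            "cell": cell,
            "ep": ep,
            "mother_class": np.where(ep, "EP", "LP"),
            "cleavage_min": cleavage,
            "onset_min": onset,
            "onset_rel_min": onset - cleavage,
            "division": np.where(symmetric, "symmetric", "asymmetric"),
            "daughter1_polar": d1_polar,
            "daughter2_polar": d2_polar,
            "daughter1_position": np.where(d1_te, "outer", "inner"),
            "daughter2_position": np.where(d2_te, "outer", "inner"),
            "daughter1_marker": d1_te,
            "daughter2_marker": d2_te,
            "daughter1_fate": np.where(d1_te, "TE", "ICM"),
            "daughter2_fate": np.where(d2_te, "TE", "ICM"),
        }
    )


def _ring_layout(config: SimulationConfig, t_min: float):
    """Cell centers (um, relative to embryo center) and the target angle."""
    n = config.cells_per_embryo
    theta = config.angle_at(t_min)
    r = config.cell_radius_um
    d = 2.0 * r * np.cos(np.radians(theta / 2.0))
    ring = d / (2.0 * np.sin(np.pi / n)) if n > 1 else 0.0
    phis = 2.0 * np.pi * np.arange(n) / n
    centers = np.column_stack([ring * np.sin(phis), ring * np.cos(phis)])  # (y, x)
    return centers, theta, phis


def render_embryo_movie(
    config: SimulationConfig,
    rng=None,
    *,
    embryo_id: int = 0,
) -> EmbryoMovie:
    """Render one synthetic embryo movie with ground-truth onset times."""
    if config.domain_depth_um < config.z_step_um:
        raise ConfigurationError("domain_depth_um must be at least z_step_um")
    rng = _as_rng(config.seed if rng is None else rng)
    n = config.cells_per_embryo
    ps = config.pixel_size_um
    r_um = config.cell_radius_um

    cleavage, ep, onset = draw_polarization_timing(config, rng, n)
    times = config.frame_times()
    onset_frame = np.searchsorted(times, onset, side="left")

    # field of view sized for the loosest (pre-compaction) ring
    centers0, _, _ = _ring_layout(config, 0.0)
    extent = np.abs(centers0).max() + r_um + 4.0
    half_px = int(np.ceil(extent / ps))
    size = 2 * half_px + 1
    c0 = half_px  # embryo center pixel (y and x)

    yy, xx = np.mgrid[0:size, 0:size]
    T, Z = config.n_frames, config.n_z
    data = np.zeros((T, Z, size, size), np.uint16)
    labels = np.zeros((T, Z, size, size), np.uint16)
    nuclei = np.zeros((T, Z, size, size), np.uint16)

    z_mid = (Z - 1) / 2.0
    w_px = max(1.0, config.cortex_width_um / ps)
    rn_um = config.nucleus_radius_um
    apex_um = np.where(ep, config.ep_nucleus_apex_um, config.lp_nucleus_apex_um)

    for t in range(T):
        centers_um, theta, phis = _ring_layout(config, times[t])
        cy = c0 + centers_um[:, 0] / ps
        cx = c0 + centers_um[:, 1] / ps
        out_y = np.sin(phis)
        out_x = np.cos(phis)
        contact_free_deg = max(360.0 - 2.0 * theta, 10.0)
        half_domain = 0.5 * config.domain_arc_fraction * contact_free_deg

        dist = np.sqrt(
            (yy[None] - cy[:, None, None]) ** 2 + (xx[None] - cx[:, None, None]) ** 2
        )  # (n, Y, X) in px
        ang_rel = np.degrees(
            np.arctan2(yy[None] - cy[:, None, None], xx[None] - cx[:, None, None])
            - np.arctan2(out_y, out_x)[:, None, None]
        )
        ang_rel = (ang_rel + 180.0) % 360.0 - 180.0

        for zi in range(Z):
            dz = (zi - z_mid) * config.z_step_um
            rz2 = r_um**2 - dz**2
            if rz2 <= 0:
                continue
            rz_px = np.sqrt(rz2) / ps
            inside = dist <= rz_px
            rel = dist - rz_px
            rel_masked = np.where(inside, rel, np.inf)
            owner = np.argmin(rel_masked, axis=0)
            any_inside = inside.any(axis=0)
            lab = np.where(any_inside, owner + 1, 0).astype(np.uint16)
            labels[t, zi] = lab

            img = np.full((size, size), config.background_intensity)
            cyto = inside & (dist <= rz_px - w_px)
            img[cyto.any(axis=0)] = config.cytoplasm_intensity

            # nuclei (spheres at the mid-plane, offset along the outward axis)
            if abs(dz) < rn_um:
                rnz_px = np.sqrt(rn_um**2 - dz**2) / ps
                off = (r_um - apex_um - rn_um) / ps
                ny = cy + out_y * off
                nx = cx + out_x * off
                nd = np.sqrt(
                    (yy[None] - ny[:, None, None]) ** 2
                    + (xx[None] - nx[:, None, None]) ** 2
                )
                nmask = nd <= rnz_px
                img[nmask.any(axis=0)] = config.nucleus_intensity
                nuc_owner = np.argmin(np.where(nmask, nd, np.inf), axis=0)
                nuclei[t, zi] = np.where(nmask.any(axis=0), nuc_owner + 1, 0).astype(
                    np.uint16
                )

            ring = inside & (dist > rz_px - w_px)
            img[ring.any(axis=0)] = config.cortex_intensity

            in_depth = abs(dz) <= config.domain_depth_um / 2.0
            if in_depth:
                polarized = times[t] >= onset
                dom = (
                    ring
                    & (np.abs(ang_rel) <= half_domain)
                    & polarized[:, None, None]
                )
                img[dom.any(axis=0)] = config.cortex_intensity * config.domain_enrichment

            if config.noise_sd > 0:
                img = img + rng.normal(0.0, config.noise_sd, img.shape)
            data[t, zi] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(
        {
            "embryo": embryo_id,
            "cell": np.arange(1, n + 1),
            "ep": ep,
            "cleavage_min": cleavage,
            "onset_min": onset,
            "onset_frame": onset_frame,
            "onset_frame_min": times[np.clip(onset_frame, 0, T - 1)],
            "nucleus_apex_um": apex_um,
            "domain_arc_fraction": config.domain_arc_fraction,
        }
    )
    return EmbryoMovie(
        data=data,
        labels=labels,
        nuclei=nuclei,
        truth=truth,
        pixel_size_um=ps,
        z_step_um=config.z_step_um,
        frame_interval_min=config.frame_interval_min,
        embryo_center_px=(float(c0), float(c0)),
    )
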