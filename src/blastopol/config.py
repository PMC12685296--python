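"""Configuration objects for simulation, detection and pipeline runs.

All configs are plain dataclasses validated on construction and round-trip
to/from YAML.  Units are embedded in field names where they are not obvious
(``*_um`` micrometres, ``*_min`` minutes, rates in degrees/minute).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "DetectionConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic 8-cell embryo generator.

    The defaults describe the experimental regime the analysis targets:
    time-lapse frames every 20 minutes through the 8-cell stage, early
    polarization onsets uniform within one hour of cleavage, late onsets
    after the embryo has compacted past 120 degrees, an apical domain
    covering half of the contact-free cortex at twice the cortical baseline
    intensity over a 6 um z-extent, and division-symmetry / trophectoderm
    probabilities conditioned on polarization timing.
    """

    # cohort
    n_embryos: int = 1
    cells_per_embryo: int = 8
    seed: int = 0

    # acquisition
    frame_interval_min: float = 20.0
    n_frames: int = 21
    z_step_um: float = 2.0
    n_z: int = 5
    pixel_size_um: float = 0.75

    # polarization timing
    ep_probability: float = 0.2
    ep_onset_window_min: float = 60.0
    lp_onset_mean_min: float = 340.0
    lp_onset_sd_min: float = 40.0
    cleavage_jitter_min: float = 20.0

    # apical domain rendering
    domain_arc_fraction: float = 0.5
    domain_enrichment: float = 2.0
    domain_depth_um: float = 6.0

    # compaction ramp: inter-blastomere angle 60 -> 180 deg
    compaction_start_min: float = 120.0
    compaction_rate_deg_min: float = 0.3
    max_angle_deg: float = 178.0

    # cell geometry
    cell_radius_um: float = 15.0
    nucleus_radius_um: float = 4.0
    ep_nucleus_apex_um: float = 1.0
    lp_nucleus_apex_um: float = 5.0
    cortex_width_um: float = 1.5

    # intensities (arbitrary units, rendered into uint16)
    background_intensity: float = 40.0
    cytoplasm_intensity: float = 200.0
    cortex_intensity: float = 600.0
    nucleus_intensity: float = 300.0
    noise_sd: float = 30.0

    # lineage outcome probabilities
    p_sym_given_ep: float = 0.717
    p_sym_given_lp: float = 0.387
    p_te_given_polar: float = 0.95
    p_te_given_apolar: float = 0.08

    def __post_init__(self) -> None:
        for name in (
            "ep_probability",
            "p_sym_given_ep",
            "p_sym_given_lp",
            "p_te_given_polar",
            "p_te_given_apolar",
        ):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")
        _check(self.frame_interval_min > 0, "frame_interval_min must be > 0")
        _check(0.0 < self.domain_arc_fraction < 1.0,
               "domain_arc_fraction must be in (0, 1)")
        _check(self.n_frames >= 1 and self.n_z >= 1, "need >= 1 frame and z-slice")
        _check(self.ep_onset_window_min >= 0, "ep_onset_window_min must be >= 0")
        _check(self.lp_onset_mean_min >= 0 and self.lp_onset_sd_min >= 0,
               "LP onset parameters must be non-negative")
        _check(self.cells_per_embryo >= 1, "cells_per_embryo must be >= 1")
        _check(self.pixel_size_um > 0 and self.z_step_um > 0,
               "calibration must be positive")
        _check(self.cell_radius_um > self.nucleus_radius_um > 0,
               "cell radius must exceed nucleus radius")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")

    @property
    def movie_minutes(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_min

    def frame_times(self):
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval_min

    def angle_at(self, t_min: float) -> float:
        """Target inter-blastomere angle (degrees) of the compaction ramp."""
        ang = 60.0 + self.compaction_rate_deg_min * max(0.0, t_min - self.compaction_start_min)
        return float(min(ang, self.max_angle_deg))

    @property
    def compaction_120_min(self) -> float:
        """Time at which the ramp crosses the 120-degree compaction threshold."""
        return self.compaction_start_min + 60.0 / self.compaction_rate_deg_min


@dataclass
class DetectionConfig:
    """Thresholds of the three-criterion apical-domain definition.

    A cortical arc is an apical domain when (a) its length is between
    ``length_fraction_min`` and ``length_fraction_max`` of the contact-free
    cortex, (b) its mean intensity is strictly more than
    ``intensity_ratio_threshold`` times the mean of the remaining
    contact-free cortex, and (c) it is visible across at least
    ``depth_min_um`` of z-depth.  ``persistence_frames`` consecutive
    positive frames are required before a temporal onset is accepted.
    """

    length_fraction_min: float = 0.33
    length_fraction_max: float = 0.80
    intensity_ratio_threshold: float = 1.5
    depth_min_um: float = 3.0
    persistence_frames: int = 2
    z_overlap_min: float = 0.5  # mutual angular overlap between consecutive slices

    def __post_init__(self) -> None:
        _check(0.0 < self.length_fraction_min < self.length_fraction_max < 1.0,
               "need 0 < length_fraction_min < length_fraction_max < 1")
        _check(self.intensity_ratio_threshold > 1.0,
               "intensity_ratio_threshold must exceed 1")
        _check(self.depth_min_um > 0, "depth_min_um must be > 0")
        _check(self.persistence_frames >= 1, "persistence_frames must be >= 1")
        _check(0.0 < self.z_overlap_min <= 1.0, "z_overlap_min must be in (0, 1]")


@dataclass
class RunConfig:
    """Paths, calibration and options for a full pipeline run."""

    output_dir: str = "blastopol_out"
    image_path: str | None = None
    labels_path: str | None = None
    nuclei_path: str | None = None
    events_path: str | None = None  # per-cell cleavage / lineage CSV
    pixel_size_um: float = 1.0
    z_step_um: float = 2.0
    frame_interval_min: float = 20.0
    contact_band_px: int = 2
    timing_mode: str = "live"  # or "fixed"
    seed: int = 0
    verbosity: int = 1
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        _check(self.timing_mode in ("live", "fixed"),
               f"timing_mode must be 'live' or 'fixed', got {self.timing_mode!r}")
        _check(self.contact_band_px >= 0, "contact_band_px must be >= 0")


_SECTION_TYPES = {"detection": DetectionConfig, "simulation": SimulationConfig}


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def save_config(cfg, path: str | Path) -> None:
    """Serialize any config dataclass to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=True)


def load_config(path: str | Path, kind=SimulationConfig):
    """Load a config dataclass of type ``kind`` from YAML.

    Unknown keys raise :class:`ConfigurationError` rather than being
    silently dropped.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(data, kind)


def _from_dict(data: dict, kind):
    names = {f.name for f in dataclasses.fields(kind)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown config keys for {kind.__name__}: {sorted(unknown)}")
    if kind is RunConfig:
        for sec, typ in _SECTION_TYPES.items():
            if sec in data and isinstance(data[sec], dict):
                data = dict(data)
                data[sec] = typ(**data[sec])
    return kind(**data)


_PATH_KEYS = {"output_dir", "image_path", "labels_path", "nuclei_path", "events_path"}


def config_hash(cfg) -> str:
    """Stable short hash of a config's scientific parameters.

    Filesystem locations are excluded so that identical analyses written to
    different directories hash identically.
    """
    d = {k: v for k, v in _to_dict(cfg).items() if k not in _PATH_KEYS}
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
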