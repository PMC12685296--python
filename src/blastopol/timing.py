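"""Early/late polarization classification and onset-time summaries.

A blastomere is **early polarizing (EP)** when it forms its apical domain
(1) within the first hour after the reference cleavage event and (2) before
the inter-blastomere angle between it and its neighbors reaches 120
degrees.  A polarized cell failing either condition is **late polarizing
(LP)**; a cell with no accepted onset is **unpolarized**.

Two timing modes mirror the two experimental designs:

* ``live``  - the reference event is the cell's *own* third-cleavage
  completion (time-lapse movies);
* ``fixed`` - the reference is the *last* third cleavage in the embryo
  (snapshot of a fixed embryo).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IncompleteTrackError, InvalidInputError, UnresolvableClassError

__all__ = [
    "BlastomereTrack",
    "polarization_onset",
    "classify_polarity",
    "embryo_ep_status",
    "onset_histogram",
    "EP_WINDOW_MIN",
    "COMPACTION_ANGLE_DEG",
]

EP_WINDOW_MIN = 60.0
COMPACTION_ANGLE_DEG = 120.0


@dataclass
class BlastomereTrack:
    """Per-frame observations of one 8-cell-stage blastomere."""

    embryo_id: int
    cell_id: int
    cleavage_min: float                 # completion of its third cleavage
    times_min: np.ndarray               # frame times (absolute minutes)
    polarized: np.ndarray               # per-frame apical-domain calls (bool)
    min_neighbor_angle_deg: np.ndarray | None = None  # per-frame min IEA (NaN ok)
    end_min: float | None = None        # 8->16 division time, if observed
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, float)
        self.polarized = np.asarray(self.polarized, bool)
        if self.times_min.shape != self.polarized.shape:
            raise InvalidInputError("times and calls must align")
        if self.min_neighbor_angle_deg is not None:
            self.min_neighbor_angle_deg = np.asarray(self.min_neighbor_angle_deg, float)
            if self.min_neighbor_angle_deg.shape != self.times_min.shape:
                raise InvalidInputError("angle series must align with frames")


def polarization_onset(track: BlastomereTrack, persistence: int = 2) -> float | None:
    """First frame time at which the domain call turns and stays positive.

    A run of at least ``persistence`` consecutive positive frames is
    required; the onset is the time of the first frame of that run.
    Returns ``None`` when no such run occurs before the track ends (or
    before the 8->16 division when ``end_min`` is set).
    """
    sel = track.times_min >= track.cleavage_min
    if track.end_min is not None:
        sel &= track.times_min <= track.end_min
    if not sel.any():
        raise IncompleteTrackError(
            f"cell {track.cell_id}: no frames at the 8-cell stage"
        )
    times = track.times_min[sel]
    calls = track.polarized[sel]
    n = len(calls)
    for i in range(n - persistence + 1):
        if calls[i:i + persistence].all():
            return float(times[i])
    return None


def classify_polarity(
    track: BlastomereTrack,
    mode: str = "live",
    *,
    embryo_last_cleavage_min: float | None = None,
    persistence: int = 2,
    window_min: float = EP_WINDOW_MIN,
    angle_threshold_deg: float = COMPACTION_ANGLE_DEG,
) -> str:
    """Classify one blastomere as ``'EP'``, ``'LP'`` or ``'unpolarized'``."""
    if mode not in ("live", "fixed"):
        raise InvalidInputError(f"unknown timing mode {mode!r}")
    onset = polarization_onset(track, persistence=persistence)
    if onset is None:
        return "unpolarized"
    if mode == "live":
        reference = track.cleavage_min
    else:
        if embryo_last_cleavage_min is None:
            raise InvalidInputError("fixed mode requires embryo_last_cleavage_min")
        reference = embryo_last_cleavage_min
    within_window = (onset - reference) <= window_min
    if track.min_neighbor_angle_deg is None:
        raise UnresolvableClassError("no inter-blastomere angle series")
    idx = int(np.argmin(np.abs(track.times_min - onset)))
    iea = track.min_neighbor_angle_deg[idx]
    if np.isnan(iea):
        raise UnresolvableClassError(
            f"cell {track.cell_id}: inter-blastomere angle missing at onset"
        )
    pre_compaction = iea < angle_threshold_deg
    return "EP" if (within_window and pre_compaction) else "LP"


def embryo_ep_status(classes) -> tuple[bool, int]:
    """(has at least one EP cell, EP count) for one embryo's classes."""
    classes = list(classes)
    n_ep = sum(c == "EP" for c in classes)
    return n_ep >= 1, n_ep


def onset_histogram(onsets_min, bin_width_min: float = 20.0):
    """Histogram of cleavage-relative onset times with local-maxima peaks.

    Returns ``(counts, bin_edges, peak_times)`` where peaks are centers of
    bins that are strict-or-plateau local maxima of the counts.  No formal
    bimodality test is applied.
    """
    arr = np.asarray(list(onsets_min), float)
    if arr.size == 0:
        raise InvalidInputError("no onset times")
    hi = max(arr.max(), bin_width_min)
    edges = np.arange(0.0, hi + bin_width_min, bin_width_min)
    if edges[-1] < hi + 1e-9:
        edges = np.append(edges, edges[-1] + bin_width_min)
    counts, edges = np.histogram(arr, bins=edges)
    padded = np.concatenate([[0], counts, [0]])
    peaks = []
    i = 1
    while i <= len(counts):
        if padded[i] > padded[i - 1]:
            j = i
            while j < len(counts) and padded[j + 1] == padded[j]:
                j += 1
            if padded[j] > padded[j + 1]:
                peaks.append(0.5 * (i - 1 + j - 1))  # plateau center (bin index)
            i = j + 1
        else:
            i += 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_times = [
        float(np.interp(p, np.arange(len(centers)), centers)) for p in peaks
    ]
    return counts, edges, peak_times
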