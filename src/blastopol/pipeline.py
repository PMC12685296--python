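"""End-to-end orchestration: profiles -> detection -> timing -> statistics.

:func:`analyze_movie` runs the imaging half on one calibrated stack with
label masks and returns per-frame domain calls plus the per-cell
classification table.  :func:`analysis_report` turns a lineage table (from
the generator or from user annotation) into the contingency statistics.
:func:`run_pipeline` wires both behind a :class:`~blastopol.config.RunConfig`.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DetectionConfig, RunConfig, config_hash, save_config
from .detection import ApicalDomainCall, apply_domain_criteria, find_candidate_domain
from .errors import (
    BlastopolError,
    EmptyProfileError,
    MissingInputError,
    NoCandidateError,
    NotAdjacentError,
)
from .geometry import interblastomere_angle
from .io import ImageStack, read_stack, read_table, write_stack, write_table
from .profiles import extract_contact_free_profile
from .stats import binomial_independence_test, proportion_table, two_proportion_ztest
from .synthetic import generate_lineage_table, render_embryo_movie
from .timing import BlastomereTrack, classify_polarity, embryo_ep_status, polarization_onset

log = logging.getLogger("blastopol")

__all__ = ["analyze_movie", "analysis_report", "run_pipeline", "min_neighbor_angles"]


def _frame_calls(
    stack: ImageStack,
    cell_id: int,
    t: int,
    det: DetectionConfig,
    band_px: int,
    embryo_center,
    min_area_px: int,
) -> ApicalDomainCall:
    cands = []
    for z in range(stack.data.shape[1]):
        lab = stack.labels[t, z]
        if int((lab == cell_id).sum()) < min_area_px:
            cands.append(None)
            continue
        try:
            prof = extract_contact_free_profile(
                stack.data[t, z],
                lab,
                cell_id,
                stack.pixel_size_um,
                band_px=band_px,
                embryo_center=embryo_center,
                t=t,
                z=z,
            )
            cands.append(find_candidate_domain(prof, det))
        except (EmptyProfileError, NoCandidateError, MissingInputError):
            cands.append(None)
    return apply_domain_criteria(
        cands, det, stack.z_step_um, cell_id=cell_id, frame=t
    )


def min_neighbor_angles(
    labels_2d: np.ndarray,
    cell_id: int,
    pixel_size_um: float,
    **iea_kwargs,
) -> float:
    """Minimum inter-blastomere angle between one cell and its neighbors."""
    mask = labels_2d == cell_id
    others = [i for i in np.unique(labels_2d) if i not in (0, cell_id)]
    angles = []
    for o in others:
        other = labels_2d == o
        rest = (labels_2d > 0) & ~mask & ~other
        try:
            angles.append(
                interblastomere_angle(
                    mask, other, pixel_size_um, exclude=rest, **iea_kwargs
                )
            )
        except NotAdjacentError:
            continue
    return float(min(angles)) if angles else np.nan


def analyze_movie(
    stack: ImageStack,
    *,
    detection: DetectionConfig | None = None,
    cleavage_min: dict | pd.Series | None = None,
    band_px: int = 2,
    mode: str = "live",
    min_area_px: int = 30,
    embryo_id: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect apical domains and classify polarity timing for every cell.

    Returns ``(calls, classes)``: per-cell-per-frame domain calls, and the
    per-cell classification table (onset, minimum neighbor IEA at onset,
    EP/LP/unpolarized class, censoring flag).
    """
    if stack.labels is None:
        raise MissingInputError("stack has no label masks")
    det = detection or DetectionConfig()
    T, Z = stack.data.shape[:2]
    z_mid = Z // 2
    times = np.arange(T) * stack.frame_interval_min
    cell_ids = sorted(int(c) for c in np.unique(stack.labels) if c != 0)

    call_rows = []
    calls_by_cell: dict[int, list[ApicalDomainCall]] = {}
    for t in range(T):
        ec = _center_of(stack.labels[t, z_mid])
        for cid in cell_ids:
            call = _frame_calls(stack, cid, t, det, band_px, ec, min_area_px)
            calls_by_cell.setdefault(cid, []).append(call)
            call_rows.append(
                {
                    "embryo": embryo_id,
                    "cell": cid,
                    "frame": t,
                    "t_min": times[t],
                    "polarized": call.polarized,
                    "intensity_ratio": call.intensity_ratio,
                    "length_fraction": call.length_fraction,
                    "z_extent_um": call.z_extent_um,
                    "domain_size_deg": call.domain_size_deg,
                    "start_angle_deg": call.start_angle_deg,
                    "end_angle_deg": call.end_angle_deg,
                }
            )
    calls = pd.DataFrame(call_rows)

    cls_rows = []
    cleav = cleavage_min or {}
    last_cleavage = max(cleav.values()) if len(cleav) else 0.0
    for cid in cell_ids:
        seq = calls_by_cell[cid]
        pol = np.array([c.polarized for c in seq])
        track = BlastomereTrack(
            embryo_id=embryo_id,
            cell_id=cid,
            cleavage_min=float(cleav.get(cid, 0.0)),
            times_min=times,
            polarized=pol,
            min_neighbor_angle_deg=np.full(T, np.nan),
        )
        onset = polarization_onset(track, persistence=det.persistence_frames)
        iea = np.nan
        if onset is not None:
            fi = int(np.argmin(np.abs(times - onset)))
            iea = min_neighbor_angles(
                stack.labels[fi, z_mid], cid, stack.pixel_size_um
            )
            track.min_neighbor_angle_deg[fi] = iea
            klass = classify_polarity(
                track,
                mode,
                embryo_last_cleavage_min=last_cleavage,
                persistence=det.persistence_frames,
            )
        else:
            klass = "unpolarized"
        cls_rows.append(
            {
                "embryo": embryo_id,
                "cell": cid,
                "cleavage_min": float(cleav.get(cid, 0.0)),
                "onset_min": np.nan if onset is None else onset,
                "min_iea_at_onset_deg": iea,
                "class": klass,
                "censored": onset is None,
            }
        )
    return calls, pd.DataFrame(cls_rows)


def _center_of(labels_2d: np.ndarray):
    ys, xs = np.nonzero(labels_2d > 0)
    if len(ys) == 0:
        return None
    return float(ys.mean()), float(xs.mean())


def analysis_report(lineage: pd.DataFrame, classes: pd.DataFrame | None = None) -> dict:
    """Contingency statistics of a lineage table, as a JSON-ready dict.

    Reproduces the published comparisons: symmetric-division frequency and
    TE contribution by polarity timing (Fisher exact tests), polar-daughter
    frequencies, EP-embryo frequency, and the binomial goodness-of-fit of
    per-embryo EP counts to an independent (cell-autonomous) model.
    """
    out: dict = {}
    df = lineage.copy()
    n_anomalous = int((~df["daughter1_polar"] & ~df["daughter2_polar"]).sum())
    ok = df["daughter1_polar"] | df["daughter2_polar"]
    out["anomalous_divisions_excluded"] = n_anomalous
    d2 = df[ok]

    sym = proportion_table(
        d2.assign(symmetric=d2["division"] == "symmetric"),
        "mother_class",
        "symmetric",
    )
    out["symmetric_division"] = _table_dict(sym)

    daughters = pd.DataFrame(
        {
            "mother_class": np.repeat(df["mother_class"].to_numpy(), 2),
            "polar": np.ravel(df[["daughter1_polar", "daughter2_polar"]].to_numpy()),
            "fate": np.ravel(df[["daughter1_fate", "daughter2_fate"]].to_numpy()),
        }
    )
    out["te_contribution"] = _table_dict(
        proportion_table(daughters.assign(te=daughters["fate"] == "TE"), "mother_class", "te")
    )
    out["polar_daughters"] = _table_dict(
        proportion_table(daughters, "mother_class", "polar")
    )

    per_embryo = df.groupby("embryo")["ep"].sum().astype(int)
    flags = [embryo_ep_status(g)[0] for _, g in df.groupby("embryo")["mother_class"]]
    out["ep_embryo_frequency_pct"] = 100.0 * float(np.mean(flags)) if len(flags) else np.nan
    if len(per_embryo) >= 10:
        n_cells = int(df.groupby("embryo").size().max())
        fit = binomial_independence_test(per_embryo.to_numpy(), n_cells, rng=0)
        out["binomial_independence"] = {
            "p_hat": fit.p_hat,
            "statistic": fit.statistic,
            "p_value": fit.p_value,
            "note": fit.note,
        }
    if classes is not None:
        out["class_counts"] = classes["class"].value_counts().to_dict()
    return out


def _table_dict(res) -> dict:
    return {
        "groups": list(res.group_labels),
        "table": res.table.tolist(),
        "proportions_pct": [round(p, 1) for p in res.proportions_pct],
        "test": res.test_name,
        "p_value": res.p_value,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline described by a run configuration.

    Without image paths the synthetic generator supplies the movie and the
    lineage table (seeded from the run config).  Per-stage CSVs, the JSON
    report, the echoed config and a log are written to ``output_dir``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    logging.basicConfig(level=logging.INFO if cfg.verbosity else logging.WARNING)
    log.info("run config hash=%s seed=%s", chash, cfg.seed)
    save_config(cfg, out / "run_config.yaml")

    stage = "inputs"
    try:
        if cfg.image_path is None:
            stage = "simulate"
            sim = cfg.simulation
            rng = np.random.default_rng(cfg.seed)
            movie = render_embryo_movie(sim, rng)
            lineage = generate_lineage_table(
                sim, rng, ep_flags=movie.truth["ep"].to_numpy()
            )
            lineage["cleavage_min"] = movie.truth["cleavage_min"].to_numpy()
            lineage["onset_min"] = movie.truth["onset_min"].to_numpy()
            stack = ImageStack(
                data=movie.data,
                labels=movie.labels,
                nuclei=movie.nuclei,
                pixel_size_um=movie.pixel_size_um,
                z_step_um=movie.z_step_um,
                frame_interval_min=movie.frame_interval_min,
            )
            write_stack(out / "movie.tif", movie.data)
            write_stack(out / "labels.tif", movie.labels)
            write_stack(out / "nuclei.tif", movie.nuclei)
            write_table(movie.truth, out / "ground_truth.csv", config_hash=chash, seed=cfg.seed)
            cleav = dict(zip(movie.truth["cell"], movie.truth["cleavage_min"]))
        else:
            for p, name in ((cfg.image_path, "images"), (cfg.labels_path, "label masks")):
                if p is None or not Path(p).exists():
                    raise MissingInputError(f"pre-flight: {name} not found at {p}")
            stack = read_stack(
                cfg.image_path,
                pixel_size_um=cfg.pixel_size_um,
                z_step_um=cfg.z_step_um,
                frame_interval_min=cfg.frame_interval_min,
            )
            stack.labels = read_stack(
                cfg.labels_path,
                pixel_size_um=cfg.pixel_size_um,
                z_step_um=cfg.z_step_um,
                frame_interval_min=cfg.frame_interval_min,
            ).data
            lineage = read_table(cfg.events_path) if cfg.events_path else None
            cleav = None
            if lineage is not None and "cleavage_min" in lineage:
                cleav = dict(zip(lineage["cell"], lineage["cleavage_min"]))

        stage = "detect+classify"
        calls, classes = analyze_movie(
            stack,
            detection=cfg.detection,
            cleavage_min=cleav,
            band_px=cfg.contact_band_px,
            mode=cfg.timing_mode,
        )
        write_table(calls, out / "domain_calls.csv", config_hash=chash, seed=cfg.seed)
        write_table(classes, out / "classification.csv", config_hash=chash, seed=cfg.seed)

        stage = "statistics"
        report = {"config_hash": chash, "seed": cfg.seed}
        if lineage is not None and "division" in getattr(lineage, "columns", []):
            report.update(analysis_report(lineage, classes))
        report["classes"] = classes["class"].value_counts().to_dict()
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        return report
    except BlastopolError as err:
        raise BlastopolError(f"pipeline stage '{stage}' failed: {err}") from err


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)
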