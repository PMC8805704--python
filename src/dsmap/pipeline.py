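"""End-to-end pipelines and run configuration.

Two entry points bind the stages together:

* :func:`run_ds_pipeline` — raw stimulation movie + trial schedule →
  ΔF/F → pixel-wise DS map → ROI proposal → per-cell tuning statistics →
  clustered, labelled map with summary tables;
* :func:`run_wave_pipeline` — raw wave movie → baseline-subtracted,
  smoothed movie → segmented wave events → propagation vectors, bias and
  frequency.

Every output table carries ``# key=value`` header lines with the
configuration hash and seed, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, mapstats, preprocess, tuning, waves
from .core import Movie, StimulusSchedule, config_hash, write_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the study constants.

    (8 directions × 3 repeats, 1000 permutations, 95th-percentile
    significance, k ∈ 2–8 clusters, 1000 µm central/peripheral split,
    α = 0.01.)
    """

    # paths
    movie_path: str = ""
    schedule_path: str = ""
    output_dir: str = "dsmap_out"
    # session registration
    fov_offset_um: tuple[float, float] = (300.0, 300.0)
    quadrant: str = "ventronasal"
    fov_id: int = 0
    # preprocessing
    guard_frames: int = 0
    # detection
    neighbor_radius: int = 1
    median_kernel: int = 3
    vs_threshold: float = 0.5
    min_area_px: int = 9
    max_area_px: int = 500
    # tuning statistics
    n_perm: int = 1000
    significance_percentile: float = 95.0
    peak_prominence: float = 0.1
    timing_tol: float = 0.25
    bad_corr_threshold: float = 0.2
    # clustering / map
    k_min: int = 2
    k_max: int = 8
    n_init: int = 50
    alpha: float = 0.01
    # wave analysis
    wave_window_s: float = 30.0
    wave_sigma: tuple[float, float, float] = (2.0, 2.0, 2.0)
    wave_threshold: float | None = None
    wave_threshold_k: float = 5.0
    wave_min_area_px: int = 100
    wave_min_frames: int = 3
    wave_grid_px: int = 16
    # randomness
    rng_seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        d = self.as_dict()
        for key in ("movie_path", "schedule_path", "output_dir"):
            d.pop(key, None)  # run location is not an analysis parameter
        return config_hash(d)

    def header(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.rng_seed}

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fov_offset_um", "wave_sigma"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# DS-map pipeline
# ---------------------------------------------------------------------------

def analyze_rois(
    dff: Movie,
    rois: detect.RoiSet,
    schedule: StimulusSchedule,
    config: RunConfig,
) -> pd.DataFrame:
    """Tuning statistics for every ROI → per-cell table."""
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    for roi in rois:
        cell = tuning.extract_peaks(dff, roi.mask, schedule)
        cell.roi_id = roi.id
        result = tuning.analyze_cell(
            cell,
            schedule,
            n_perm=config.n_perm,
            rng_seed=rng,
            peak_prominence=config.peak_prominence,
            timing_tol=config.timing_tol,
            bad_corr_threshold=config.bad_corr_threshold,
        )
        rows.append(
            {
                "roi_id": roi.id,
                "x_um": roi.centroid_um[0],
                "y_um": roi.centroid_um[1],
                "pref_deg": result.pref_direction,
                "vs_norm": result.vs_norm,
                "vs_raw": result.vs_raw,
                "dsi": result.dsi,
                "percentile": result.dsi_percentile,
                "significant": result.dsi_percentile > config.significance_percentile,
                "cell_class": result.cell_class,
                "quadrant": config.quadrant,
                "fov_id": config.fov_id,
                "marker_type": None,
                "cluster_label": "unassigned",
            }
        )
    cols = mapstats.CELL_TABLE_COLUMNS + ["quadrant", "fov_id", "marker_type", "cluster_label"]
    return pd.DataFrame(rows, columns=cols)


def run_ds_pipeline(
    config: RunConfig,
    movie: Movie | None = None,
    schedule: StimulusSchedule | None = None,
) -> dict:
    """Preprocess → detect → quantify → map.  Returns the output bundle.

    ``movie``/``schedule`` may be passed in memory; otherwise they are
    loaded from the configured paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header()
    notes: list[str] = []

    if movie is None:
        movie = Movie.load_tiff(config.movie_path)
    if schedule is None:
        schedule = StimulusSchedule.from_tsv(config.schedule_path)
    schedule.validate_blocks()

    dff, baseline = preprocess.preprocess(movie, schedule, guard_frames=config.guard_frames)
    meanimg = movie.data.mean(axis=0, dtype=np.float64)

    ds_map = detect.pixelwise_ds_map(dff, schedule, neighbor_radius=config.neighbor_radius)
    filtered = detect.enrich_ds_regions(ds_map, kernel=config.median_kernel)
    rois = detect.propose_rois(
        filtered,
        meanimg,
        vs_threshold=config.vs_threshold,
        min_area_px=config.min_area_px,
        max_area_px=config.max_area_px,
        fov_offset_um=config.fov_offset_um,
        pixel_size_um=movie.pixel_size_um,
    )
    if len(rois) == 0:
        notes.append("no ROIs passed the detection thresholds")

    cells = analyze_rois(dff, rois, schedule, config)

    cluster_json: dict = {"strata": {}}
    summary_table = pd.DataFrame()
    sig = cells[cells["significant"].astype(bool)] if len(cells) else cells
    if len(sig) >= 2:
        cells = mapstats.cluster_and_label_strata(
            cells,
            k_range=range(config.k_min, config.k_max + 1),
            rng_seed=config.rng_seed,
            n_init=config.n_init,
        )
        summary_table = mapstats.map_statistics(cells)
        for key, grp in mapstats.stratify(cells).items():
            s = grp[grp["significant"].astype(bool)]
            if len(s) < 2:
                continue
            model = mapstats.cluster_directions(
                s["pref_deg"].to_numpy(),
                k_range=range(config.k_min, config.k_max + 1),
                rng_seed=config.rng_seed,
                n_init=config.n_init,
            )
            cluster_json["strata"]["/".join(key)] = {
                "k": model.k,
                "mean_sv": model.mean_sv,
                "centroid_angles_deg": model.centroid_angles.tolist(),
                "candidates": {str(k): v for k, v in model.candidates.items()},
            }
    else:
        notes.append("fewer than 2 significant cells; clustering skipped")

    write_table(out / "cells.tsv", cells, header)
    if len(summary_table):
        write_table(out / "map_summary.tsv", summary_table, header)
    write_table(out / "rois.tsv", rois.to_frame(), header)
    with open(out / "cluster_model.json", "w") as fh:
        json.dump({**header, **cluster_json, "notes": notes}, fh, indent=2, sort_keys=True)
    _plot_ds_map(cells, out / "ds_map.png")

    return {
        "cells": cells,
        "rois": rois,
        "summary": summary_table,
        "cluster_model": cluster_json,
        "baseline": baseline,
        "notes": notes,
        "output_dir": str(out),
    }


def _plot_ds_map(cells: pd.DataFrame, path) -> None:
    """Vector map: one arrow per significant cell (angle = preferred
    direction, length = tuning strength)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sig = cells[cells["significant"].astype(bool)] if len(cells) else cells
    if len(sig):
        th = np.deg2rad(sig["pref_deg"].to_numpy())
        r = sig["vs_norm"].to_numpy()
        ax.quiver(
            sig["x_um"], sig["y_um"], r * np.cos(th), r * np.sin(th),
            angles="xy", scale_units="xy", scale=0.01, width=0.004,
        )
    ax.set_xlabel("x (µm from optic nerve)")
    ax.set_ylabel("y (µm from optic nerve)")
    ax.set_aspect("equal")
    ax.set_title(f"DS map: {len(sig)} significant cells")
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)


# ---------------------------------------------------------------------------
# wave pipeline
# ---------------------------------------------------------------------------

def run_wave_pipeline(config: RunConfig, movie: Movie | None = None) -> dict:
    """Wave dF → smoothing → segmentation → vectors → bias/frequency."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header()

    if movie is None:
        movie = Movie.load_tiff(config.movie_path)

    events, table, summary = waves.analyze_wave_movie(
        movie,
        window_s=config.wave_window_s,
        sigma=config.wave_sigma,
        threshold=config.wave_threshold,
        threshold_k=config.wave_threshold_k,
        min_area_px=config.wave_min_area_px,
        min_frames=config.wave_min_frames,
        grid_px=config.wave_grid_px,
    )
    write_table(out / "waves.tsv", table, header)

    vec_rows = []
    for e in events:
        if e.vector_field is None:
            continue
        gy, gx, _ = e.vector_field.shape
        for iy in range(gy):
            for ix in range(gx):
                vx, vy = e.vector_field[iy, ix]
                if np.isfinite(vx):
                    vec_rows.append(
                        {
                            "wave_id": e.id,
                            "region_x_um": e.region_centers[iy, ix, 0],
                            "region_y_um": e.region_centers[iy, ix, 1],
                            "vx": vx,
                            "vy": vy,
                        }
                    )
    write_table(out / "wave_vectors.tsv", pd.DataFrame(vec_rows), header)
    with open(out / "wave_summary.json", "w") as fh:
        json.dump({**header, **summary}, fh, indent=2, sort_keys=True)
    return {"events": events, "table": table, "summary": summary, "output_dir": str(out)}
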