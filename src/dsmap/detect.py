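"""Semi-automatic detection of direction-selective somata.

Every pixel of the ΔF/F movie is treated as a miniature ROI: its trace is
averaged with its square neighborhood, a peak response per trial is
extracted, peaks are averaged per stimulus direction, and the vector sum
and DSI are computed — exactly the statistics used for whole-cell
quantification.  A 2-D median filter then suppresses single-pixel
speckle and enriches contiguous cell-like regions of coherent preferred
direction, and candidate ROIs are proposed as connected suprathreshold
components (optionally intersected with bright soma-like regions of the
mean image).  The ROI-proposal step replaces the manual drawing of oval
ROIs over the mathematically-determined DS regions; its thresholds are
explicit configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

from .core import Movie, StimulusSchedule, ang_diff_deg, wrap_deg

logger = logging.getLogger(__name__)


@dataclass
class PixelDSMap:
    """Per-pixel tuning maps; ``pref_direction`` is NaN where undefined."""

    pref_direction: np.ndarray   # degrees
    vs_norm: np.ndarray          # normalized resultant, [0, 1] for R ≥ 0
    vs_raw: np.ndarray           # raw resultant length
    dsi: np.ndarray              # [−1, 1]


@dataclass
class Roi:
    id: int
    mask: np.ndarray             # boolean, FOV-shaped
    centroid_px: tuple[float, float]   # (row, col)
    centroid_um: tuple[float, float]   # (x, y) relative to the optic nerve


@dataclass
class RoiSet:
    rois: list[Roi]

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def label_image(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=np.int32)
        for roi in self.rois:
            out[roi.mask] = roi.id + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": [r.id for r in self.rois],
                "centroid_x_um": [r.centroid_um[0] for r in self.rois],
                "centroid_y_um": [r.centroid_um[1] for r in self.rois],
                "area_px": [int(r.mask.sum()) for r in self.rois],
            }
        )


# ---------------------------------------------------------------------------
# pixel-wise tuning maps
# ---------------------------------------------------------------------------

def pixelwise_ds_map(
    dff: Movie, schedule: StimulusSchedule, neighbor_radius: int = 1
) -> PixelDSMap:
    """Vector sum and DSI at every pixel of a ΔF/F movie.

    ``neighbor_radius`` sets the square smoothing neighborhood
    (radius 1 ⇒ 3×3 mean; 0 ⇒ no smoothing).
    """
    if dff.kind != "dff":
        raise ValueError("pixelwise_ds_map expects a ΔF/F movie")
    schedule.validate_blocks()
    data = dff.data
    if neighbor_radius > 0:
        size = 2 * neighbor_radius + 1
        data = ndimage.uniform_filter(
            data.astype(np.float64), size=(1, size, size), mode="nearest"
        )
    else:
        data = data.astype(np.float64)

    dirs = schedule.directions
    ny, nx = dff.shape_yx
    sums = np.zeros((len(dirs), ny, nx))
    counts = np.zeros(len(dirs))
    dir_index = {d: i for i, d in enumerate(dirs)}
    for _, trial in schedule.trials.iterrows():
        s, e = int(trial["start_frame"]), int(trial["end_frame"])
        i = dir_index[trial["direction_deg"]]
        sums[i] += data[s : e + 1].max(axis=0)
        counts[i] += 1
    means = sums / counts[:, None, None]

    z = np.tensordot(np.exp(1j * np.deg2rad(dirs)), means, axes=1)
    vs_raw = np.abs(z)
    total = means.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vs_norm = np.where(np.abs(total) > 0, vs_raw / np.where(total == 0, 1, total), 0.0)
    pref = wrap_deg(np.rad2deg(np.angle(z)))
    pref[vs_raw < 1e-12] = np.nan

    dist_p = np.abs(ang_diff_deg(dirs[:, None, None], pref[None]))
    dist_n = np.abs(ang_diff_deg(dirs[:, None, None], pref[None] + 180.0))
    ip = np.nanargmin(np.where(np.isnan(dist_p), np.inf, dist_p), axis=0)
    inull = np.nanargmin(np.where(np.isnan(dist_n), np.inf, dist_n), axis=0)
    rp = np.take_along_axis(means, ip[None], axis=0)[0]
    rn = np.take_along_axis(means, inull[None], axis=0)[0]
    denom = rp + rn
    with np.errstate(divide="ignore", invalid="ignore"):
        dsi = np.where(denom > 0, (rp - rn) / np.where(denom == 0, 1, denom), 0.0)
    dsi = np.clip(dsi, -1.0, 1.0)
    dsi[np.isnan(pref)] = 0.0
    return PixelDSMap(pref_direction=pref, vs_norm=vs_norm, vs_raw=vs_raw, dsi=dsi)


def enrich_ds_regions(ds_map: PixelDSMap, kernel: int = 3) -> PixelDSMap:
    """2-D median filter of the tuning maps (kernel 1 ⇒ identity).

    Preferred direction is median-filtered circularly: the unit-vector
    components are medianed separately and the angle re-derived, avoiding
    0/360° wrap artifacts.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer ≥ 1")
    if kernel == 1:
        return PixelDSMap(
            ds_map.pref_direction.copy(),
            ds_map.vs_norm.copy(),
            ds_map.vs_raw.copy(),
            ds_map.dsi.copy(),
        )
    med = lambda a: ndimage.median_filter(a, size=kernel, mode="nearest")
    th = np.deg2rad(ds_map.pref_direction)
    cx = np.where(np.isnan(th), 0.0, np.cos(th))
    sx = np.where(np.isnan(th), 0.0, np.sin(th))
    mcx, msx = med(cx), med(sx)
    pref = wrap_deg(np.rad2deg(np.arctan2(msx, mcx)))
    pref[np.hypot(mcx, msx) < 1e-12] = np.nan
    return PixelDSMap(
        pref_direction=pref,
        vs_norm=med(ds_map.vs_norm),
        vs_raw=med(ds_map.vs_raw),
        dsi=med(ds_map.dsi),
    )


# ---------------------------------------------------------------------------
# ROI proposal
# ---------------------------------------------------------------------------

def propose_rois(
    filtered: PixelDSMap,
    meanimg: np.ndarray | None = None,
    vs_threshold: float = 0.5,
    min_area_px: int = 9,
    max_area_px: int = 500,
    bright_k: float = 3.0,
    fov_offset_um: tuple[float, float] = (0.0, 0.0),
    pixel_size_um: float = 1.0,
) -> RoiSet:
    """Connected components of high normalized vector sum → candidate ROIs.

    If a mean image is supplied, candidate pixels must also be bright:
    above median + ``bright_k`` robust standard deviations (MAD-based).
    Components outside [min_area_px, max_area_px] are dropped.  ROIs are
    ordered deterministically by centroid (row, then column).
    """
    if vs_threshold <= 0 or min_area_px <= 0:
        raise ValueError("thresholds must be positive")
    mask = filtered.vs_norm >= vs_threshold
    if meanimg is not None:
        m = np.asarray(meanimg, dtype=float)
        mad = np.median(np.abs(m - np.median(m)))
        bright = m > np.median(m) + bright_k * 1.4826 * mad
        mask &= bright
    labels = cc_label(mask, connectivity=2)
    props = regionprops(labels)
    keep = [p for p in props if min_area_px <= p.area <= max_area_px]
    keep.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    rois = []
    for i, p in enumerate(keep):
        roi_mask = labels == p.label
        row, col = p.centroid
        rois.append(
            Roi(
                id=i,
                mask=roi_mask,
                centroid_px=(float(row), float(col)),
                centroid_um=(
                    fov_offset_um[0] + float(col) * pixel_size_um,
                    fov_offset_um[1] + float(row) * pixel_size_um,
                ),
            )
        )
    logger.info("proposed %d ROIs (vs ≥ %.2f, area %d–%d px)",
                len(rois), vs_threshold, min_area_px, max_area_px)
    return RoiSet(rois)
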