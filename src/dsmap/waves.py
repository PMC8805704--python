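"""Retinal-wave propagation analysis.

Raw wave movies are baseline-subtracted with a moving average that
excludes wave frames (two passes: a provisional robust threshold flags
active frames, then the baseline is recomputed over quiet frames only),
smoothed with a 3-D Gaussian (σ = 2 px in x, y and 2 frames in t), and
segmented into wave events as 3-D-connected suprathreshold components.

For each event the FOV is tiled into square regions and a propagation
vector computed per region from the activation-time map (first
suprathreshold frame per pixel): a plane fit to activation time gives its
spatial gradient, and the propagation vector points along +∇t — the
direction in which the wavefront arrives later — normalized to unit
length.  The event's mean direction is the circular mean of its region
vectors and its directionality the resultant length of those unit
vectors (1 = all regions agree, 0 = no net direction).  A wave whose mean
vector has a positive x component propagates temporally; negative x,
nasally; the nasal/temporal proportions over classifiable waves quantify
the propagation bias, and event count over recording time gives the wave
frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Movie, circ_mean_deg, resultant_length, wrap_deg

logger = logging.getLogger(__name__)


@dataclass
class WaveEvent:
    """One segmented wave and its region-wise propagation vectors."""

    id: int
    start_frame: int
    end_frame: int
    footprint: np.ndarray = field(repr=False)          # boolean (y, x)
    n_pixels: int = 0
    vector_field: np.ndarray | None = field(default=None, repr=False)  # (gy, gx, 2) unit vectors, NaN invalid
    region_centers: np.ndarray | None = field(default=None, repr=False)
    mean_direction: float = float("nan")               # degrees
    mean_vector: np.ndarray | None = None              # (x, y), unit length
    directionality: float = float("nan")               # [0, 1]

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


# ---------------------------------------------------------------------------
# baseline subtraction
# ---------------------------------------------------------------------------

def _robust_excess(x: np.ndarray, k: float) -> np.ndarray:
    """True where x exceeds its median by k robust SDs (MAD-based, with a
    small floor so noiseless plateaus are still caught)."""
    med = np.median(x)
    dev = x - med
    if np.abs(dev).max() == 0:
        return np.zeros(len(x), dtype=bool)
    sd = max(1.4826 * np.median(np.abs(dev)), 0.01 * np.abs(dev).max())
    return dev > k * sd


def _flag_active_frames(F: np.ndarray, win: int, k: float) -> np.ndarray:
    """Wave-frame flags: frame means that stand out either from the local
    moving average (sharp events) or from the global median (long plateaus)."""
    fm = F.mean(axis=(1, 2))
    local = fm - ndimage.uniform_filter1d(fm, size=win, mode="nearest")
    return _robust_excess(local, k) | _robust_excess(fm, k)


def wave_dff(movie: Movie, window_s: float = 30.0, flag_k: float = 3.0) -> Movie:
    """dF = F − moving-average baseline, with wave frames excluded.

    Pass 1 estimates a provisional moving-average baseline over all
    frames and flags active (wave) frames by a robust threshold on the
    spatial-mean residual; pass 2 recomputes the per-pixel moving average
    over quiet frames only.  Windows containing no quiet frame fall back
    to the pixel's overall quiet-frame mean, with a warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if movie.kind != "raw":
        raise ValueError("wave_dff expects a raw movie")
    # keep float32 inputs in float32: wave movies are large and dF is
    # thresholded, not differenced at fine precision
    work_dtype = np.float32 if movie.data.dtype == np.float32 else np.float64
    F = movie.data.astype(work_dtype)
    win = max(3, int(round(window_s * movie.frame_rate_hz)))

    active = _flag_active_frames(F, win, flag_k)
    quiet = (~active).astype(work_dtype)
    if not quiet.any():
        raise ValueError("every frame was flagged as a wave; cannot form a baseline")

    num = ndimage.uniform_filter1d(F * quiet[:, None, None], size=win, axis=0, mode="nearest")
    den = ndimage.uniform_filter1d(quiet, size=win, mode="nearest")
    empty = den <= 1.0 / (2 * win)  # window holds no quiet frame
    if empty.any():
        logger.warning(
            "%d frame window(s) had no quiet frames; widened to the full recording",
            int(empty.sum()),
        )
    global_base = F[~active].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = num / den[:, None, None]
    base[empty] = global_base
    dF = F - base
    return Movie(dF, movie.frame_rate_hz, movie.pixel_size_um, kind="dff")


def smooth_3d(dF: Movie, sigma: tuple[float, float, float] = (2.0, 2.0, 2.0)) -> Movie:
    """Separable 3-D Gaussian over (t, y, x); σ in frames / px."""
    sm = ndimage.gaussian_filter(dF.data, sigma=sigma, mode="nearest")
    return Movie(sm, dF.frame_rate_hz, dF.pixel_size_um, kind=dF.kind)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def auto_threshold(smoothed: Movie, k: float = 5.0) -> float:
    """Robust suprathreshold level: median + k·MAD-based SD of all voxels."""
    x = smoothed.data
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med + k * 1.4826 * mad


def segment_waves(
    smoothed: Movie,
    threshold: float,
    min_area_px: int = 100,
    min_frames: int = 3,
) -> list[WaveEvent]:
    """Wave events as 3-D-connected suprathreshold components.

    Components smaller than ``min_area_px`` (spatial footprint) or
    shorter than ``min_frames`` are discarded.  Events are returned in
    order of start frame.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = smoothed.data >= threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    events = []
    if n:
        objects = ndimage.find_objects(labels)
        for lab, sl in enumerate(objects, start=1):
            comp = labels[sl] == lab
            footprint = np.zeros(smoothed.shape_yx, dtype=bool)
            footprint[sl[1], sl[2]] = comp.any(axis=0)
            t0, t1 = sl[0].start, sl[0].stop - 1
            if footprint.sum() < min_area_px or (t1 - t0 + 1) < min_frames:
                continue
            events.append(
                WaveEvent(
                    id=len(events),
                    start_frame=int(t0),
                    end_frame=int(t1),
                    footprint=footprint,
                    n_pixels=int(footprint.sum()),
                )
            )
    events.sort(key=lambda e: (e.start_frame, e.id))
    for i, e in enumerate(events):
        e.id = i
    logger.info("segmented %d wave event(s) at threshold %.3g", len(events), threshold)
    return events


# ---------------------------------------------------------------------------
# propagation vectors
# ---------------------------------------------------------------------------

def _activation_time_map(event: WaveEvent, smoothed: Movie, threshold: float) -> np.ndarray:
    """First suprathreshold time (s) per footprint pixel; NaN elsewhere."""
    sub = smoothed.data[event.start_frame : event.end_frame + 1]
    above = sub >= threshold
    any_above = above.any(axis=0)
    first = above.argmax(axis=0).astype(float)
    first[~any_above] = np.nan
    first[~event.footprint] = np.nan
    return (first + event.start_frame) / smoothed.frame_rate_hz


def wave_vectors(
    event: WaveEvent,
    smoothed: Movie,
    threshold: float,
    grid_px: int = 16,
    min_valid_frac: float = 0.5,
) -> WaveEvent:
    """Per-region propagation vectors from the activation-time gradient.

    The FOV is tiled into ``grid_px``-square regions.  In each region with
    enough activated pixels, a plane ``t(x, y)`` is least-squares fitted
    to the activation times; the unit propagation vector points along the
    fitted ∇t (the wavefront reaches larger t later, so +∇t is the travel
    direction).  The event's mean direction, mean unit vector and
    directionality (resultant length of region unit vectors) are filled
    in on the returned event.  Single-frame events have no temporal
    gradient and are flagged with NaN vectors.
    """
    if event.n_frames < 2:
        logger.warning("wave %d spans a single frame; vectors undefined", event.id)
        event.vector_field = None
        event.mean_direction = float("nan")
        event.directionality = float("nan")
        return event
    tmap = _activation_time_map(event, smoothed, threshold)
    ny, nx = tmap.shape
    gy, gx = ny // grid_px, nx // grid_px
    vec = np.full((gy, gx, 2), np.nan)
    centers = np.zeros((gy, gx, 2))
    pix = smoothed.pixel_size_um
    # centred region coordinates, µm; symmetric so an x-flip negates dt/dx exactly
    coords = (np.arange(grid_px) - (grid_px - 1) / 2.0) * pix
    CX, CY = np.meshgrid(coords, coords)
    for iy in range(gy):
        for ix in range(gx):
            block = tmap[iy * grid_px : (iy + 1) * grid_px, ix * grid_px : (ix + 1) * grid_px]
            centers[iy, ix] = ((ix + 0.5) * grid_px * pix, (iy + 0.5) * grid_px * pix)
            valid = np.isfinite(block)
            if valid.mean() < min_valid_frac:
                continue
            t = block[valid]
            A = np.column_stack([CX[valid], CY[valid], np.ones(t.size)])
            (gx_t, gy_t, _), *_ = np.linalg.lstsq(A, t, rcond=None)
            norm = float(np.hypot(gx_t, gy_t))
            if norm < 1e-12:
                continue
            vec[iy, ix] = (gx_t / norm, gy_t / norm)

    event.vector_field = vec
    event.region_centers = centers
    flat = vec.reshape(-1, 2)
    ok = np.isfinite(flat).all(axis=1)
    if not ok.any():
        event.mean_direction = float("nan")
        event.directionality = float("nan")
        event.mean_vector = None
        return event
    angles = wrap_deg(np.rad2deg(np.arctan2(flat[ok, 1], flat[ok, 0])))
    event.mean_direction = circ_mean_deg(angles)
    event.directionality = resultant_length(angles)
    resultant = flat[ok].mean(axis=0)
    n = np.linalg.norm(resultant)
    event.mean_vector = resultant / n if n > 0 else None
    return event


# ---------------------------------------------------------------------------
# propagation bias and frequency
# ---------------------------------------------------------------------------

def classify_wave(event: WaveEvent) -> str:
    """``temporal`` (+x mean vector), ``nasal`` (−x) or ``unclassified``."""
    if event.mean_vector is None or not np.isfinite(event.mean_vector).all():
        return "unclassified"
    x = event.mean_vector[0]
    if x > 0:
        return "temporal"
    if x < 0:
        return "nasal"
    return "unclassified"


def _majority_class(event: WaveEvent) -> str:
    """Nasal/temporal call by majority of region-vector x signs (reported alongside)."""
    if event.vector_field is None:
        return "unclassified"
    flat = event.vector_field.reshape(-1, 2)
    ok = np.isfinite(flat).all(axis=1)
    xs = flat[ok, 0]
    n_t, n_n = int((xs > 0).sum()), int((xs < 0).sum())
    if n_t > n_n:
        return "temporal"
    if n_n > n_t:
        return "nasal"
    return "unclassified"


def propagation_bias(events: list[WaveEvent]) -> dict:
    """Nasal/temporal proportions over classifiable waves.

    Returns mean-vector-based proportions (primary) and the majority-of-
    region-vectors proportions alongside.
    """
    classes = [classify_wave(e) for e in events]
    n_nasal = classes.count("nasal")
    n_temporal = classes.count("temporal")
    n_cls = n_nasal + n_temporal
    if n_cls == 0:
        raise ValueError("no wave has a defined mean propagation vector")
    maj = [_majority_class(e) for e in events]
    maj_n, maj_t = maj.count("nasal"), maj.count("temporal")
    maj_cls = maj_n + maj_t
    return {
        "prop_nasal": n_nasal / n_cls,
        "prop_temporal": n_temporal / n_cls,
        "n_classified": n_cls,
        "n_unclassified": len(events) - n_cls,
        "prop_nasal_majority": maj_n / maj_cls if maj_cls else float("nan"),
        "prop_temporal_majority": maj_t / maj_cls if maj_cls else float("nan"),
    }


def wave_frequency(events: list[WaveEvent], duration_s: float) -> float:
    """Waves per minute over the recording."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(events) / (duration_s / 60.0)


def waves_table(events: list[WaveEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wave_id": [e.id for e in events],
            "start_frame": [e.start_frame for e in events],
            "end_frame": [e.end_frame for e in events],
            "n_pixels": [e.n_pixels for e in events],
            "mean_direction_deg": [e.mean_direction for e in events],
            "directionality": [e.directionality for e in events],
            "class": [classify_wave(e) for e in events],
        }
    )


def analyze_wave_movie(
    movie: Movie,
    window_s: float = 30.0,
    sigma: tuple[float, float, float] = (2.0, 2.0, 2.0),
    threshold: float | None = None,
    threshold_k: float = 5.0,
    min_area_px: int = 100,
    min_frames: int = 3,
    grid_px: int = 16,
) -> tuple[list[WaveEvent], pd.DataFrame, dict]:
    """Full wave pipeline: dF → smooth → segment → vectors → bias/frequency."""
    dF = wave_dff(movie, window_s=window_s)
    sm = smooth_3d(dF, sigma=sigma)
    thr = threshold if threshold is not None else auto_threshold(sm, k=threshold_k)
    events = segment_waves(sm, thr, min_area_px=min_area_px, min_frames=min_frames)
    for e in events:
        wave_vectors(e, sm, thr, grid_px=grid_px)
    table = waves_table(events)
    summary = {
        "n_waves": len(events),
        "frequency_per_min": wave_frequency(events, movie.duration_s),
        "threshold": thr,
    }
    if events:
        try:
            summary.update(propagation_bias(events))
        except ValueError:
            pass
    return events, table, summary
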