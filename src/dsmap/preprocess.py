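"""Raw fluorescence → ΔF/F₀.

The baseline image F₀ is the per-pixel temporal mean over frames that lie
outside every stimulus-trial window (so evoked transients never
contaminate the baseline), optionally padded by a guard band; ΔF/F₀ is
then (F − F₀)/F₀ frame by frame.  Motion correction is exposed only as a
pass-through hook: synthetic inputs are drift-free and registration of
real data is expected to happen upstream.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable

import numpy as np

from .core import Movie, StimulusSchedule

logger = logging.getLogger(__name__)


def motion_correct(movie: Movie, method: Callable[[Movie], Movie] | None = None) -> Movie:
    """Optional registration hook; identity by default."""
    if method is None:
        return movie
    return method(movie)


def compute_baseline(
    movie: Movie, schedule: StimulusSchedule | None, guard_frames: int = 0
) -> np.ndarray:
    """Per-pixel baseline F₀: temporal mean of non-stimulus frames.

    Frames inside any [start_frame, end_frame] trial window (± an optional
    guard band) are excluded.  With no schedule, the mean runs over the
    whole movie.  Raises if no baseline frames remain.
    """
    if movie.kind != "raw":
        raise ValueError("compute_baseline expects a raw movie")
    n = movie.n_frames
    if schedule is not None and len(schedule) > 0:
        if schedule.trials["start_frame"].min() < 0 or schedule.trials["end_frame"].max() >= n:
            raise ValueError("schedule trial windows fall outside the movie")
        keep = ~schedule.stimulus_frame_mask(n, guard_frames)
    else:
        keep = np.ones(n, dtype=bool)
    if not keep.any():
        raise ValueError("no non-stimulus frames remain to estimate the baseline")
    baseline = movie.data[keep].mean(axis=0, dtype=np.float64)
    logger.info(
        "baseline from %d/%d frames (guard=%d frames)", int(keep.sum()), n, guard_frames
    )
    return baseline


def compute_dff(movie: Movie, baseline: np.ndarray) -> Movie:
    """ΔF/F₀ = (F − F₀)/F₀, per pixel per frame.

    Pixels with non-positive baseline cannot be normalized; they are set
    to 0 throughout and reported with a warning rather than propagating
    NaN/inf.
    """
    if movie.kind != "raw":
        raise ValueError("compute_dff expects a raw movie")
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != movie.shape_yx:
        raise ValueError("baseline shape does not match the movie's spatial shape")
    bad = baseline <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} pixel(s) have non-positive baseline; "
            "their ΔF/F is masked to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(bad, 1.0, baseline)
    dff = (movie.data.astype(np.float64) - safe) / safe
    dff[:, bad] = 0.0
    return Movie(dff, movie.frame_rate_hz, movie.pixel_size_um, kind="dff")


def preprocess(
    movie: Movie,
    schedule: StimulusSchedule | None,
    guard_frames: int = 0,
    registration: Callable[[Movie], Movie] | None = None,
) -> tuple[Movie, np.ndarray]:
    """Full preprocessing chain: (optional) registration → baseline → ΔF/F."""
    movie = motion_correct(movie, registration)
    baseline = compute_baseline(movie, schedule, guard_frames)
    return compute_dff(movie, baseline), baseline
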