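"""Shared containers and circular-geometry helpers.

Coordinate and angle conventions used throughout the package
------------------------------------------------------------
Positions are measured in micrometres relative to the optic nerve head.
The array column index is the +x axis and the row index is the +y axis.
Directions (of bar motion or wave propagation) are measured
counter-clockwise in retinal coordinates:

    0° = temporal, 90° = dorsal, 180° = nasal, 270° = ventral

so a wave whose mean propagation vector has a positive x component is
travelling temporally and one with a negative x component nasally.  The
nasal/temporal anchoring follows the field's standard convention; placing
dorsal at 90° (rather than 270°) is this package's documented choice and is
applied consistently everywhere.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("dsmap")

#: canonical cluster directions, degrees (see module docstring)
CANONICAL_ANGLES = {
    "temporal": 0.0,
    "dorsal": 90.0,
    "nasal": 180.0,
    "ventral": 270.0,
}

#: eccentricity split between central and peripheral fields of view, µm
ECCENTRICITY_SPLIT_UM = 1000.0


# ---------------------------------------------------------------------------
# circular helpers
# ---------------------------------------------------------------------------

def wrap_deg(angle):
    """Wrap angle(s) into [0, 360)."""
    return np.mod(angle, 360.0)


def ang_diff_deg(a, b):
    """Signed circular difference a − b in (−180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def unit_vectors(angles_deg):
    """(N, 2) array of unit vectors (cos θ, sin θ) for angles in degrees."""
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return np.column_stack([np.cos(th), np.sin(th)])


def circ_mean_deg(angles_deg, weights=None):
    """Weighted circular mean of angles in degrees, in [0, 360).

    Returns NaN when the resultant vanishes (no defined mean direction).
    """
    v = unit_vectors(angles_deg)
    if weights is not None:
        v = v * np.asarray(weights, dtype=float)[:, None]
    r = v.sum(axis=0)
    if np.hypot(*r) < 1e-12:
        return float("nan")
    return float(wrap_deg(np.rad2deg(np.arctan2(r[1], r[0]))))


def resultant_length(angles_deg, weights=None):
    """Mean resultant length R ∈ [0, 1] of unit vectors at the given angles."""
    v = unit_vectors(angles_deg)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        v = v * w[:, None]
        denom = w.sum()
    else:
        denom = len(v)
    if denom == 0:
        return 0.0
    r = v.sum(axis=0) / denom
    return float(np.hypot(*r))


# ---------------------------------------------------------------------------
# Movie
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    """A fluorescence time series: ``data[t, y, x]``.

    ``kind`` is ``"raw"`` for fluorescence in arbitrary units and ``"dff"``
    for baseline-normalized ΔF/F₀.
    """

    data: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    kind: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be 3-D (t, y, x); got {self.data.ndim}-D")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.kind not in ("raw", "dff"):
            raise ValueError(f"kind must be 'raw' or 'dff', got {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def save_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            np.asarray(self.data, dtype=np.float32),
            metadata={
                "frame_rate_hz": self.frame_rate_hz,
                "pixel_size_um": self.pixel_size_um,
                "kind": self.kind,
            },
        )

    @classmethod
    def load_tiff(cls, path, frame_rate_hz=None, pixel_size_um=None, kind=None) -> "Movie":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return cls(
            data=data,
            frame_rate_hz=float(frame_rate_hz or meta.get("frame_rate_hz", 1.0)),
            pixel_size_um=float(pixel_size_um or meta.get("pixel_size_um", 1.0)),
            kind=kind or meta.get("kind", "raw"),
        )


# ---------------------------------------------------------------------------
# StimulusSchedule
# ---------------------------------------------------------------------------

SCHEDULE_COLUMNS = [
    "trial",
    "block",
    "direction_deg",
    "width_um",
    "length_um",
    "speed_um_s",
    "start_frame",
    "end_frame",
]


@dataclass
class StimulusSchedule:
    """Ordered drifting-bar trials; one row per trial.

    Mirrors the per-trial metadata text file written by the stimulus
    software: bar direction, geometry, speed, and the start/end frame of
    each trial window.
    """

    trials: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SCHEDULE_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"schedule missing columns: {missing}")
        self.trials = self.trials.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def directions(self) -> np.ndarray:
        """Sorted unique stimulus directions, degrees."""
        return np.sort(self.trials["direction_deg"].unique())

    @property
    def n_blocks(self) -> int:
        return int(self.trials["block"].nunique())

    def validate_blocks(self) -> None:
        """Every block must contain each direction exactly once."""
        dirs = set(self.directions)
        for b, grp in self.trials.groupby("block"):
            got = list(grp["direction_deg"])
            if len(got) != len(dirs) or set(got) != dirs:
                raise ValueError(
                    f"block {b} is incomplete: has directions {sorted(got)}, "
                    f"expected one each of {sorted(dirs)}"
                )

    def stimulus_frame_mask(self, n_frames: int, guard_frames: int = 0) -> np.ndarray:
        """Boolean mask over frames, True inside any trial window (± guard)."""
        mask = np.zeros(n_frames, dtype=bool)
        for s, e in zip(self.trials["start_frame"], self.trials["end_frame"]):
            lo = max(0, int(s) - guard_frames)
            hi = min(n_frames, int(e) + 1 + guard_frames)
            mask[lo:hi] = True
        return mask

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.trials[SCHEDULE_COLUMNS].to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StimulusSchedule":
        try:
            df = pd.read_csv(path, sep="\t", comment="#")
        except Exception as exc:  # surface the offending file, keep the cause
            raise ValueError(f"could not parse schedule file {path}: {exc}") from exc
        missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"schedule file {path} lacks required columns {missing} "
                f"(header line 1 must name them)"
            )
        bad = df["direction_deg"].isna() | df["start_frame"].isna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbers
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(f"schedule file {path}: invalid trial at line {line}")
        return cls(df)


# ---------------------------------------------------------------------------
# provenance headers
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping (for output headers)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=_default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(path, df: pd.DataFrame, header: dict | None = None) -> None:
    """Write a TSV with ``# key=value`` provenance header lines."""
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
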