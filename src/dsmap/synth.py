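"""Ground-truthed synthetic imaging data.

Emulates the two kinds of recording the analysis consumes:

* drifting-bar visual-stimulation sessions — a field of view (FOV) of
  tuned ON and ON-OFF cells plus untuned cells, imaged while a bright bar
  sweeps the FOV in 8 directions (45° apart), 3 block-shuffled repeats,
  bar 500 µm wide × 1000 µm long moving at 250 µm/s with 10 s between
  trials;

* spontaneous retinal-wave sessions — an 850 µm FOV imaged at 128×128 px
  while planar wavefronts cross it, each propagating nasally with a
  configurable probability and temporally otherwise.

Every generated movie comes with a machine-readable ground-truth table so
each downstream stage can be scored against what was injected.

The calcium response model is deliberately simple: a transient rises
instantaneously at the frame following the bar edge crossing the soma and
decays exponentially with the indicator time constant; transients add
linearly and are truncated at the recorded trial window so inter-trial
frames are exactly at baseline.  Peak amplitude follows a von-Mises-shaped
tuning curve  A·exp(κ·(cos(θ−θ_pref)−1))  so that κ=0 yields an untuned
cell and large κ a sharply tuned one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

from .core import (
    CANONICAL_ANGLES,
    Movie,
    SCHEDULE_COLUMNS,
    StimulusSchedule,
    ang_diff_deg,
    wrap_deg,
)

CELL_CLASSES = ("ON", "ONOFF", "NONDS")
CLUSTER_LABELS = ("nasal", "temporal", "dorsal", "ventral", "none")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of a simulated visual-stimulation session.

    Defaults reproduce the recording and stimulus constants of the study
    conditions: 256×256 px FOV at 2.96 Hz, 8 bar directions × 3 repeats,
    bar 500×1000 µm at 250 µm/s, 10 s inter-trial interval.  The FOV side
    in µm (512 µm ⇒ 2 µm/px) and the indicator decay constant are this
    package's choices, documented in the methods note.
    """

    fov_size_px: int = 256
    fov_size_um: float = 512.0
    frame_rate_hz: float = 2.96
    n_directions: int = 8
    n_repeats: int = 3
    bar_width_um: float = 500.0
    bar_length_um: float = 1000.0
    bar_speed_um_s: float = 250.0
    intertrial_s: float = 10.0
    noise_sd: float = 0.05
    indicator_decay_s: float = 0.8
    rng_seed: int = 0
    # session geometry / bookkeeping
    fov_offset_um: tuple[float, float] = (300.0, 300.0)
    quadrant: str = "ventronasal"
    baseline_f: float = 100.0
    cell_radius_um: float = 8.0
    lead_in_s: float = 10.0
    decay_tail_s: float | None = None  # None ⇒ 5 × indicator_decay_s
    dtype: str = "float32"

    def __post_init__(self):
        if self.n_directions < 1 or self.n_repeats < 1:
            raise ValueError("n_directions and n_repeats must be ≥ 1")
        if self.bar_speed_um_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("bar_speed_um_s and frame_rate_hz must be positive")
        if self.decay_tail_s is None:
            self.decay_tail_s = 5.0 * self.indicator_decay_s
        if self.decay_tail_s >= self.intertrial_s:
            raise ValueError("decay_tail_s must be shorter than intertrial_s")

    @property
    def pixel_size_um(self) -> float:
        return self.fov_size_um / self.fov_size_px

    @property
    def directions(self) -> np.ndarray:
        return np.arange(self.n_directions) * (360.0 / self.n_directions)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class WaveSimConfig:
    """Parameters of a simulated retinal-wave session.

    Defaults follow the wave-imaging configuration (850 µm FOV, 128×128 px
    at 5.92 Hz, ≥50 waves per FOV).  ``nasal_bias`` is the probability that
    a wave propagates nasally (180°) rather than temporally (0°); each
    sampled axis direction gets Gaussian angular jitter.
    """

    fov_size_px: int = 128
    fov_size_um: float = 850.0
    frame_rate_hz: float = 5.92
    n_waves: int = 50
    nasal_bias: float = 0.5
    wave_speed_um_s: float = 200.0
    wavefront_width_um: float = 200.0
    rng_seed: int = 0
    jitter_deg: float = 15.0
    gap_s: float = 4.0
    amplitude_dff: float = 1.0
    baseline_f: float = 100.0
    noise_sd: float = 0.02
    lead_in_s: float = 2.0
    dtype: str = "float32"

    def __post_init__(self):
        if self.n_waves < 1:
            raise ValueError("n_waves must be ≥ 1")
        if not 0.0 <= self.nasal_bias <= 1.0:
            raise ValueError("nasal_bias must lie in [0, 1]")

    @property
    def pixel_size_um(self) -> float:
        return self.fov_size_um / self.fov_size_px

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruthCell:
    """One simulated cell and everything the pipeline should recover."""

    position: tuple[float, float]      # (x, y) µm relative to the optic nerve
    preferred_direction: float         # degrees in [0, 360)
    tuning_kappa: float                # von-Mises concentration; 0 ⇒ untuned
    response_amplitude: float          # peak ΔF/F at the preferred direction
    cell_class: str                    # ON | ONOFF | NONDS
    cluster_label: str                 # nasal | temporal | dorsal | ventral | none
    marker: bool = False               # GFP+ stand-in

    def __post_init__(self):
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        if self.cluster_label not in CLUSTER_LABELS:
            raise ValueError(f"unknown cluster_label {self.cluster_label!r}")
        if self.cell_class == "NONDS" and self.tuning_kappa != 0:
            raise ValueError("NONDS cells must have tuning_kappa 0")
        self.preferred_direction = float(wrap_deg(self.preferred_direction))

    @property
    def distance_um(self) -> float:
        return float(np.hypot(*self.position))


def cells_to_frame(cells: list[GroundTruthCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell": np.arange(len(cells)),
            "x_um": [c.position[0] for c in cells],
            "y_um": [c.position[1] for c in cells],
            "pref_deg": [c.preferred_direction for c in cells],
            "kappa": [c.tuning_kappa for c in cells],
            "amplitude": [c.response_amplitude for c in cells],
            "cell_class": [c.cell_class for c in cells],
            "cluster_label": [c.cluster_label for c in cells],
            "marker": [c.marker for c in cells],
        }
    )


# ---------------------------------------------------------------------------
# tuning model
# ---------------------------------------------------------------------------

def tuning_amplitude(trial_direction_deg, pref_deg, kappa, amplitude):
    """Von-Mises-shaped peak ΔF/F: A·exp(κ(cos Δ − 1)); equals A at Δ=0."""
    delta = np.deg2rad(ang_diff_deg(trial_direction_deg, pref_deg))
    return amplitude * np.exp(kappa * (np.cos(delta) - 1.0))


def block_shuffled_directions(n_directions: int, n_repeats: int, rng: np.random.Generator):
    """Trial direction sequence: each block is a permutation of all directions."""
    dirs = np.arange(n_directions) * (360.0 / n_directions)
    out = np.concatenate([rng.permutation(dirs) for _ in range(n_repeats)])
    blocks = np.repeat(np.arange(n_repeats), n_directions)
    return out, blocks


def simulate_cell_peaks(
    pref_deg: float,
    kappa: float,
    amplitude: float,
    noise_sd: float,
    rng: np.random.Generator,
    n_directions: int = 8,
    n_repeats: int = 3,
    window_frames: int = 12,
    decay_frames: float = 2.4,
) -> pd.DataFrame:
    """Per-trial peak ΔF/F of one cell under the block-shuffled protocol.

    Bypasses movie rendering but reproduces what peak extraction measures:
    each trial's peak is the maximum over a ``window_frames``-long response
    window of (transient with exponential decay) + Gaussian noise of sd
    ``noise_sd``.  Taking the window maximum matters — it makes peaks
    positively biased and non-negative in practice, exactly like peaks
    read off real ΔF/F traces, which keeps the DSI's null bin away from
    zero-crossing artifacts.  Used for permutation-test calibration at
    scale.  ``window_frames=1`` degenerates to a single additive draw.
    """
    directions, blocks = block_shuffled_directions(n_directions, n_repeats, rng)
    mean_amp = tuning_amplitude(directions, pref_deg, kappa, amplitude)
    kernel = np.exp(-np.arange(window_frames) / decay_frames)
    traces = mean_amp[:, None] * kernel[None, :] + rng.normal(
        0.0, noise_sd, size=(len(directions), window_frames)
    )
    peaks = traces.max(axis=1)
    return pd.DataFrame(
        {
            "trial": np.arange(len(directions)),
            "block": blocks,
            "direction_deg": directions,
            "peak": peaks,
        }
    )


# ---------------------------------------------------------------------------
# cell-map generation
# ---------------------------------------------------------------------------

_DEFAULT_PROPORTIONS = {
    "nasal": 0.225,
    "temporal": 0.225,
    "dorsal": 0.225,
    "ventral": 0.225,
    "none": 0.1,
}


def _counts_from_proportions(n_cells: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of n_cells across cluster labels."""
    labels = list(proportions)
    raw = np.array([proportions[l] for l in labels], dtype=float) * n_cells
    counts = np.floor(raw).astype(int)
    rem = n_cells - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return dict(zip(labels, counts))


def make_cell_map(
    config: SimConfig,
    n_cells: int,
    proportions: dict | None = None,
    map_gradient: dict | float = 0.0,
    *,
    tuning_kappa: float = 4.0,
    jitter_deg: float = 10.0,
    jitter_bound_deg: float | None = None,
    marker_fraction: float = 0.1,
    p_onoff: float = 0.5,
    amp_range: tuple[float, float] = (0.8, 1.2),
    positions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[GroundTruthCell]:
    """Place ``n_cells`` ground-truth cells in the FOV, retina-map style.

    Each cluster-labelled cell's preferred direction is its cluster's
    canonical angle plus ``gradient × distance-from-optic-nerve`` (deg/mm)
    plus Gaussian jitter truncated at ``jitter_bound_deg`` (default 3σ).
    Cells labelled ``"none"`` are untuned (κ=0).  Somata are packed without
    ROI overlap; a FOV too small for ``n_cells`` raises ``ValueError``.

    ``positions``: optional (n_cells, 2) array of optic-nerve-relative
    (x, y) µm coordinates to use instead of random placement.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be ≥ 0")
    if n_cells == 0:
        return []
    proportions = dict(proportions or _DEFAULT_PROPORTIONS)
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {total}")
    unknown = set(proportions) - set(CLUSTER_LABELS)
    if unknown:
        raise ValueError(f"unknown cluster labels in proportions: {unknown}")
    if not isinstance(map_gradient, dict):
        map_gradient = {l: float(map_gradient) for l in CLUSTER_LABELS}
    if jitter_bound_deg is None:
        jitter_bound_deg = 3.0 * jitter_deg
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)

    # soma placement: rejection sampling with a minimum separation
    off_x, off_y = config.fov_offset_um
    margin = config.cell_radius_um + config.pixel_size_um
    min_sep = 2.0 * config.cell_radius_um + 2.0 * config.pixel_size_um
    if positions is not None:
        pos = np.asarray(positions, dtype=float)
        if pos.shape != (n_cells, 2):
            raise ValueError("positions must have shape (n_cells, 2)")
    else:
        lo = margin
        hi = config.fov_size_um - margin
        if hi <= lo:
            raise ValueError("FOV too small for the configured cell radius")
        placed: list[np.ndarray] = []
        tries = 0
        max_tries = 2000 * n_cells
        while len(placed) < n_cells:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"could not pack {n_cells} non-overlapping cells of radius "
                    f"{config.cell_radius_um} µm into a {config.fov_size_um} µm FOV"
                )
            cand = rng.uniform(lo, hi, size=2)
            if all(np.hypot(*(cand - p)) >= min_sep for p in placed):
                placed.append(cand)
        pos = np.array(placed) + np.array([off_x, off_y])

    counts = _counts_from_proportions(n_cells, proportions)
    labels = np.concatenate([[l] * c for l, c in counts.items()])
    rng.shuffle(labels)

    cells = []
    for i in range(n_cells):
        label = labels[i]
        dist_mm = np.hypot(*pos[i]) / 1000.0
        if label == "none":
            pref = rng.uniform(0.0, 360.0)
            kappa = 0.0
            cls = "NONDS"
            marker = False
        else:
            jitter = np.clip(
                rng.normal(0.0, jitter_deg), -jitter_bound_deg, jitter_bound_deg
            )
            pref = CANONICAL_ANGLES[label] + map_gradient.get(label, 0.0) * dist_mm + jitter
            kappa = tuning_kappa
            cls = "ONOFF" if rng.random() < p_onoff else "ON"
            marker = label in ("ventral", "nasal") and rng.random() < marker_fraction
        cells.append(
            GroundTruthCell(
                position=(float(pos[i, 0]), float(pos[i, 1])),
                preferred_direction=pref,
                tuning_kappa=kappa,
                response_amplitude=float(rng.uniform(*amp_range)),
                cell_class=cls,
                cluster_label=label,
                marker=marker,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# stimulus-session rendering
# ---------------------------------------------------------------------------

def _motion_span_um(direction_deg: float, fov_um: float) -> tuple[float, float]:
    """Min/max projection of the FOV square onto the motion direction."""
    th = np.deg2rad(direction_deg)
    corners = np.array([[0, 0], [fov_um, 0], [0, fov_um], [fov_um, fov_um]])
    s = corners @ np.array([np.cos(th), np.sin(th)])
    return float(s.min()), float(s.max())


def build_schedule(config: SimConfig, rng: np.random.Generator | None = None) -> StimulusSchedule:
    """Block-shuffled trial schedule with frame-accurate trial windows.

    The recorded ``end_frame`` extends past the stimulus sweep by a short
    decay tail so that the trial window contains the full calcium
    transient; the 10 s inter-trial gap is measured from the sweep end.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    directions, blocks = block_shuffled_directions(config.n_directions, config.n_repeats, rng)
    rate = config.frame_rate_hz
    tail_frames = int(np.ceil(config.decay_tail_s * rate))
    rows = []
    t = config.lead_in_s
    for i, (d, b) in enumerate(zip(directions, blocks)):
        s_min, s_max = _motion_span_um(d, config.fov_size_um)
        active_s = (s_max - s_min + config.bar_width_um) / config.bar_speed_um_s
        start_frame = int(np.ceil(t * rate))
        stim_end_frame = int(np.ceil((t + active_s) * rate))
        rows.append(
            {
                "trial": i,
                "block": int(b),
                "direction_deg": float(d),
                "width_um": config.bar_width_um,
                "length_um": config.bar_length_um,
                "speed_um_s": config.bar_speed_um_s,
                "start_frame": start_frame,
                "end_frame": stim_end_frame + tail_frames,
                "t_start_s": t,  # extra column: exact sweep start time
            }
        )
        t += active_s + config.intertrial_s
    df = pd.DataFrame(rows)
    return StimulusSchedule(df[SCHEDULE_COLUMNS + ["t_start_s"]])


def cell_roi_pixels(cell: GroundTruthCell, config: SimConfig):
    """(rows, cols) pixel indices of a cell's soma disk in the FOV."""
    x_loc = cell.position[0] - config.fov_offset_um[0]
    y_loc = cell.position[1] - config.fov_offset_um[1]
    r = max(1.0, config.cell_radius_um / config.pixel_size_um)
    return _draw_disk(
        (y_loc / config.pixel_size_um, x_loc / config.pixel_size_um),
        r,
        shape=(config.fov_size_px, config.fov_size_px),
    )


def render_stimulus_movie(
    cells: list[GroundTruthCell], config: SimConfig
) -> tuple[Movie, StimulusSchedule, pd.DataFrame]:
    """Render a raw-fluorescence movie of a drifting-bar session.

    Each ON (and NONDS) cell emits one transient per trial when the bar's
    leading edge crosses its soma; each ON-OFF cell emits a second
    transient when the trailing edge crosses, bar_width/speed later (2 s at
    the default geometry).  Transient peak amplitude follows the cell's
    tuning curve evaluated at the trial direction.  Pixel noise is
    Gaussian with sd ``noise_sd`` (in ΔF/F units).  Returns the raw movie,
    the schedule, and the ground-truth cell table.
    """
    rng = np.random.default_rng(config.rng_seed)
    schedule = build_schedule(config, rng)
    rate = config.frame_rate_hz
    tau_frames = config.indicator_decay_s * rate
    n_frames = int(np.ceil(schedule.trials["end_frame"].max() + config.lead_in_s * rate)) + 1

    fov = config.fov_size_px
    dff = np.zeros((n_frames, fov, fov), dtype=np.float64)
    rois = [cell_roi_pixels(c, config) for c in cells]

    for cell, (rr, cc) in zip(cells, rois):
        if len(rr) == 0:
            continue
        x_loc = cell.position[0] - config.fov_offset_um[0]
        y_loc = cell.position[1] - config.fov_offset_um[1]
        for _, trial in schedule.trials.iterrows():
            d = trial["direction_deg"]
            th = np.deg2rad(d)
            s_cell = x_loc * np.cos(th) + y_loc * np.sin(th)
            s_min, _ = _motion_span_um(d, config.fov_size_um)
            t_on = trial["t_start_s"] + (s_cell - s_min) / config.bar_speed_um_s
            amp = tuning_amplitude(
                d, cell.preferred_direction, cell.tuning_kappa, cell.response_amplitude
            )
            onsets = [t_on]
            if cell.cell_class == "ONOFF":
                onsets.append(t_on + config.bar_width_um / config.bar_speed_um_s)
            end = int(trial["end_frame"])
            for t0 in onsets:
                f0 = int(np.ceil(t0 * rate))
                if f0 > end:
                    continue
                k = np.arange(f0, end + 1)
                dff[k[0] : k[-1] + 1, rr, cc] += (
                    amp * np.exp(-(k - f0) / tau_frames)
                )[:, None]

    dtype = np.dtype(config.dtype)
    f0 = config.baseline_f
    movie_data = (f0 * (1.0 + dff)).astype(dtype)
    if config.noise_sd > 0:
        movie_data = movie_data + rng.normal(
            0.0, config.noise_sd * f0, size=movie_data.shape
        ).astype(dtype)
    movie = Movie(movie_data, rate, config.pixel_size_um, kind="raw")
    return movie, schedule, cells_to_frame(cells)


# ---------------------------------------------------------------------------
# wave-session rendering
# ---------------------------------------------------------------------------

def render_wave_movie(config: WaveSimConfig) -> tuple[Movie, pd.DataFrame]:
    """Render a raw movie of sequential planar retinal waves.

    Each wave propagates nasally (180°) with probability ``nasal_bias``
    and temporally (0°) otherwise, with Gaussian angular jitter; the
    wavefront is a Gaussian band of FWHM ``wavefront_width_um`` sweeping
    the FOV at ``wave_speed_um_s``.  Waves never overlap in time.  Returns
    the movie and a ground-truth table (direction, nasal/temporal label,
    frame span).
    """
    rng = np.random.default_rng(config.rng_seed)
    rate = config.frame_rate_hz
    fov = config.fov_size_px
    pix = config.pixel_size_um
    sigma = config.wavefront_width_um / 2.355  # FWHM → σ

    xx = np.arange(fov) * pix
    X, Y = np.meshgrid(xx, xx)  # X: column (x), Y: row (y)

    # sample all waves up front so the timeline is known before allocation
    rows = []
    t = config.lead_in_s
    for i in range(config.n_waves):
        is_nasal = bool(rng.random() < config.nasal_bias)
        base = 180.0 if is_nasal else 0.0
        jitter = np.clip(rng.normal(0.0, config.jitter_deg), -60.0, 60.0)
        d = wrap_deg(base + jitter)
        th = np.deg2rad(d)
        s = X * np.cos(th) + Y * np.sin(th)
        span = s.max() - s.min()
        dur = (span + 6.0 * sigma) / config.wave_speed_um_s
        rows.append(
            {
                "wave": i,
                "direction_deg": float(d),
                "label": "nasal" if is_nasal else "temporal",
                "t0": t,
                "dur": dur,
                "s_min": float(s.min()),
            }
        )
        t += dur + config.gap_s
    n_frames = int(np.ceil((t + config.gap_s) * rate))

    dtype = np.dtype(config.dtype)
    dff = np.zeros((n_frames, fov, fov), dtype=dtype)
    for row in rows:
        th = np.deg2rad(row["direction_deg"])
        s = X * np.cos(th) + Y * np.sin(th)
        f0 = int(np.ceil(row["t0"] * rate))
        f1 = int(np.floor((row["t0"] + row["dur"]) * rate))
        row["start_frame"], row["end_frame"] = f0, f1
        tt = np.arange(f0, f1 + 1) / rate - row["t0"]
        front = row["s_min"] - 3.0 * sigma + config.wave_speed_um_s * tt
        dff[f0 : f1 + 1] += (
            config.amplitude_dff
            * np.exp(-((s[None, :, :] - front[:, None, None]) ** 2) / (2.0 * sigma**2))
        ).astype(dtype)

    b = config.baseline_f
    data = (b * (1.0 + dff)).astype(dtype)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd * b, size=data.shape).astype(dtype)
    movie = Movie(data, rate, pix, kind="raw")
    truth = pd.DataFrame(rows)[
        ["wave", "direction_deg", "label", "start_frame", "end_frame"]
    ]
    return movie, truth


def render_radial_wave_movie(config: WaveSimConfig) -> Movie:
    """One radially expanding wave from the FOV centre (directionality ≈ 0 case)."""
    rate = config.frame_rate_hz
    fov = config.fov_size_px
    pix = config.pixel_size_um
    sigma = config.wavefront_width_um / 2.355
    xx = np.arange(fov) * pix
    X, Y = np.meshgrid(xx, xx)
    c = (fov - 1) * pix / 2.0
    R = np.hypot(X - c, Y - c)
    dur = (R.max() + 3.0 * sigma) / config.wave_speed_um_s
    n_frames = int(np.ceil((config.lead_in_s + dur + config.gap_s) * rate))
    dff = np.zeros((n_frames, fov, fov), dtype=np.float64)
    f0 = int(np.ceil(config.lead_in_s * rate))
    f1 = int(np.floor((config.lead_in_s + dur) * rate))
    tt = np.arange(f0, f1 + 1) / rate - config.lead_in_s
    radius = config.wave_speed_um_s * tt
    dff[f0 : f1 + 1] = config.amplitude_dff * np.exp(
        -((R[None, :, :] - radius[:, None, None]) ** 2) / (2.0 * sigma**2)
    )
    data = (config.baseline_f * (1.0 + dff)).astype(np.dtype(config.dtype))
    return Movie(data, rate, pix, kind="raw")
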