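import numpy as np
import pytest

from dsmap.synth import (
    GroundTruthCell,
    SimConfig,
    make_cell_map,
    render_stimulus_movie,
)


def small_config(**kw):
    """Reduced-scale session config for unit tests (128 px / 256 µm FOV)."""
    defaults = dict(
        fov_size_px=128,
        fov_size_um=256.0,
        intertrial_s=6.0,
        rng_seed=1,
        noise_sd=0.05,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_session():
    """A 12-cell noisy session shared by detection/pipeline tests."""
    cfg = small_config()
    cells = make_cell_map(cfg, 12, rng=np.random.default_rng(7))
    movie, schedule, truth = render_stimulus_movie(cells, cfg)
    return cfg, cells, movie, schedule, truth


def render_one_cell(cell_class="ON", pref=180.0, kappa=4.0, amplitude=1.0, **cfg_kw):
    """Noiseless single-cell session in float64, for exact-recovery tests."""
    cfg = small_config(noise_sd=0.0, dtype="float64", **cfg_kw)
    cell = GroundTruthCell(
        position=(
            cfg.fov_offset_um[0] + cfg.fov_size_um / 2,
            cfg.fov_offset_um[1] + cfg.fov_size_um / 2,
        ),
        preferred_direction=pref,
        tuning_kappa=kappa,
        response_amplitude=amplitude,
        cell_class=cell_class,
        cluster_label="none" if cell_class == "NONDS" else "nasal",
    )
    movie, schedule, truth = render_stimulus_movie([cell], cfg)
    return cfg, cell, movie, schedule


@pytest.fixture(scope="session")
def onoff_session():
    return render_one_cell("ONOFF", pref=90.0)


@pytest.fixture(scope="session")
def on_session():
    return render_one_cell("ON", pref=180.0)
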