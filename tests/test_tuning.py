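"""Vector sum, DSI, permutation significance and ON/ON-OFF classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dsmap.core import ang_diff_deg, wrap_deg
from dsmap.preprocess import preprocess
from dsmap.synth import (
    cell_roi_pixels,
    make_cell_map,
    render_stimulus_movie,
    simulate_cell_peaks,
    tuning_amplitude,
)
from dsmap.tuning import (
    CellResponse,
    classify_on_onoff,
    dsi,
    extract_peaks,
    permutation_test,
    vector_sum,
)
from .conftest import render_one_cell, small_config

DIRS8 = np.arange(8) * 45.0


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_vector_sum(responses, directions):
    """Literal term-by-term polar summation."""
    x = y = total = 0.0
    for r, d in zip(responses, directions):
        x += r * np.cos(np.deg2rad(d))
        y += r * np.sin(np.deg2rad(d))
        total += r
    raw = np.hypot(x, y)
    return wrap_deg(np.rad2deg(np.arctan2(y, x))), raw / total, raw


def oracle_dsi(responses, directions, pref):
    """Explicit bin enumeration for pref/null lookup."""
    best_p, best_n, dp, dn = None, None, 1e9, 1e9
    for i, d in enumerate(directions):
        a = abs(ang_diff_deg(d, pref))
        if a < dp - 1e-12:
            dp, best_p = a, i
        a = abs(ang_diff_deg(d, pref + 180.0))
        if a < dn - 1e-12:
            dn, best_n = a, i
    p, n = responses[best_p], responses[best_n]
    return (p - n) / (p + n) if (p + n) > 0 else 0.0


def test_vector_sum_matches_bruteforce_oracle():
    r = [2.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0]
    got = vector_sum(r, DIRS8)
    pref, norm, raw = oracle_vector_sum(r, DIRS8)
    assert got.pref_deg == pytest.approx(pref, abs=1e-12)
    assert got.vs_norm == pytest.approx(norm, abs=1e-12)
    assert got.vs_raw == pytest.approx(raw, abs=1e-12)


def test_vector_sum_symmetry_gives_zero():
    got = vector_sum(np.ones(8), DIRS8)
    assert got.vs_raw == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(got.pref_deg)


def test_vector_sum_single_direction_is_unit_normalized():
    r = np.zeros(8)
    r[2] = 1.0  # 90°
    got = vector_sum(r, DIRS8)
    assert got.pref_deg == pytest.approx(90.0)
    assert got.vs_norm == pytest.approx(1.0)


@pytest.mark.parametrize(
    "pref_r, null_r, expected", [(1.0, 0.0, 1.0), (1.0, 1.0, 0.0), (3.0, 1.0, 0.5)]
)
def test_dsi_analytic_cases(pref_r, null_r, expected):
    r = np.full(8, null_r)
    r[0] = pref_r
    r[4] = null_r
    assert dsi(r, DIRS8, 0.0) == pytest.approx(expected)


def test_dsi_zero_when_both_bins_zero():
    r = np.zeros(8)
    r[2] = r[6] = 0.0
    assert dsi(r, DIRS8, 90.0) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_dsi_pipeline_equals_explicit_bin_oracle(seed):
    rng = np.random.default_rng(seed)
    r = rng.uniform(0, 2, size=8)
    vs = vector_sum(r, DIRS8)
    assert dsi(r, DIRS8, vs.pref_deg) == pytest.approx(
        oracle_dsi(r, DIRS8, vs.pref_deg), abs=1e-12
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
def test_dsi_and_preferred_direction_scale_invariant(scale, seed):
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.1, 2, size=8)
    vs1, vs2 = vector_sum(r, DIRS8), vector_sum(r * scale, DIRS8)
    assert vs2.pref_deg == pytest.approx(vs1.pref_deg, abs=1e-9)
    assert vs2.vs_norm == pytest.approx(vs1.vs_norm, rel=1e-9)
    assert dsi(r * scale, DIRS8, vs2.pref_deg) == pytest.approx(
        dsi(r, DIRS8, vs1.pref_deg), rel=1e-9
    )


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def _cell_from_peaks(peaks_df):
    return CellResponse.from_trials(peaks_df)


def test_extract_peaks_flat_and_boxcar():
    from dsmap.core import Movie, StimulusSchedule

    data = np.zeros((60, 4, 4))
    data[11:13] = 0.5  # boxcar inside trial 1's window only
    movie = Movie(data, 2.0, 2.0, kind="dff")
    rows = []
    for i in range(8):
        rows.append(
            {
                "trial": i, "block": 0, "direction_deg": i * 45.0,
                "width_um": 500.0, "length_um": 1000.0, "speed_um_s": 250.0,
                "start_frame": i * 7, "end_frame": i * 7 + 5,
            }
        )
    sched = StimulusSchedule(pd.DataFrame(rows))
    cell = extract_peaks(movie, np.ones((4, 4), dtype=bool), sched)
    expected = np.zeros(8)
    expected[1] = 0.5  # frames 11–12 fall in trial 1's window [7, 12]
    assert np.allclose(cell.peaks, expected)


def test_extract_peaks_matches_generator_tuning(onoff_session):
    """Noiseless ON-OFF per-direction mean peaks are proportional to the
    generator tuning curve (the offset transient rides on the onset decay,
    so the proportionality constant is slightly above 1)."""
    cfg, cell, movie, schedule = onoff_session
    dff, _ = preprocess(movie, schedule)
    rr, cc = cell_roi_pixels(cell, cfg)
    mask = np.zeros(movie.shape_yx, dtype=bool)
    mask[rr, cc] = True
    resp = extract_peaks(dff, mask, schedule)
    dirs, means = resp.per_direction_mean_peak()
    expected = tuning_amplitude(
        dirs, cell.preferred_direction, cell.tuning_kappa, cell.response_amplitude
    )
    ratio = means / expected
    assert ratio.min() > 0.99
    assert ratio.max() / ratio.min() == pytest.approx(1.0, abs=0.03)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_permutation_degenerate_constant_responses():
    trials = pd.DataFrame(
        {
            "trial": range(24),
            "block": np.repeat(np.arange(3), 8),
            "direction_deg": np.tile(DIRS8, 3),
            "peak": 1.0,
        }
    )
    res = permutation_test(_cell_from_peaks(trials), rng_seed=0)
    assert res.dsi_percentile == 0.0
    assert not res.significant


def test_permutation_sharply_tuned_cell_is_significant():
    rng = np.random.default_rng(3)
    peaks = simulate_cell_peaks(90.0, 4.0, 1.0, 0.0, rng)
    res = permutation_test(_cell_from_peaks(peaks), rng_seed=0)
    assert res.significant
    assert res.dsi_percentile > 95.0


def test_permutation_reproducible_and_stable_across_seeds():
    rng = np.random.default_rng(5)
    peaks = simulate_cell_peaks(0.0, 4.0, 1.0, 0.05, rng)
    cell = _cell_from_peaks(peaks)
    a = permutation_test(cell, rng_seed=11)
    b = permutation_test(cell, rng_seed=11)
    assert a.dsi_percentile == b.dsi_percentile
    pcts = [permutation_test(cell, rng_seed=s).dsi_percentile for s in range(6)]
    assert max(pcts) - min(pcts) < 3.0


def test_permutation_incomplete_block_raises_with_block_name():
    trials = pd.DataFrame(
        {
            "trial": range(15),
            "block": np.repeat([0, 1], [8, 7]),
            "direction_deg": np.concatenate([DIRS8, DIRS8[:7]]),
            "peak": 1.0,
        }
    )
    with pytest.raises(ValueError, match="block 1"):
        permutation_test(_cell_from_peaks(trials))


# ---------------------------------------------------------------------------
# ON / ON-OFF classification
# ---------------------------------------------------------------------------

def _classify_session(session):
    cfg, cell, movie, schedule = session
    dff, _ = preprocess(movie, schedule)
    rr, cc = cell_roi_pixels(cell, cfg)
    mask = np.zeros(movie.shape_yx, dtype=bool)
    mask[rr, cc] = True
    resp = extract_peaks(dff, mask, schedule)
    return classify_on_onoff(resp, schedule)


def test_classify_noiseless_onoff(onoff_session):
    assert _classify_session(onoff_session) == "ONOFF"


def test_classify_noiseless_on(on_session):
    assert _classify_session(on_session) == "ON"


def test_classify_inconsistent_cell_is_bad():
    rng = np.random.default_rng(0)
    traces = [rng.normal(0, 1.0, 30) for _ in range(24)]
    cell = CellResponse(
        roi_id=0,
        trial_directions=np.tile(DIRS8, 3),
        trial_blocks=np.repeat(np.arange(3), 8),
        peaks=np.array([t.max() for t in traces]),
        trial_traces=traces,
        frame_rate_hz=2.96,
    )
    from dsmap.core import StimulusSchedule

    rows = [
        {
            "trial": i, "block": i // 8, "direction_deg": DIRS8[i % 8],
            "width_um": 500.0, "length_um": 1000.0, "speed_um_s": 250.0,
            "start_frame": i * 30, "end_frame": i * 30 + 29,
        }
        for i in range(24)
    ]
    sched = StimulusSchedule(pd.DataFrame(rows))
    assert classify_on_onoff(cell, sched) == "BAD"


def test_classification_agrees_with_ground_truth_under_noise():
    """Labelled population at noise_sd 0.05: ≥95% ON/ON-OFF agreement."""
    cfg = small_config(rng_seed=21)
    cells = make_cell_map(
        cfg, 10,
        proportions={"nasal": 0.25, "temporal": 0.25, "dorsal": 0.25, "ventral": 0.25},
        rng=np.random.default_rng(21),
    )
    movie, schedule, truth = render_stimulus_movie(cells, cfg)
    dff, _ = preprocess(movie, schedule)
    hits = 0
    for cell in cells:
        rr, cc = cell_roi_pixels(cell, cfg)
        mask = np.zeros(movie.shape_yx, dtype=bool)
        mask[rr, cc] = True
        resp = extract_peaks(dff, mask, schedule)
        hits += classify_on_onoff(resp, schedule) == cell.cell_class
    assert hits >= 0.95 * len(cells)
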