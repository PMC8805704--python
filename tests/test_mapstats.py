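"""Clustering, marker-anchored labels, stratification and map statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from dsmap.core import ang_diff_deg, unit_vectors, wrap_deg
from dsmap.mapstats import (
    circular_variance_deg,
    cluster_directions,
    compare_groups,
    direction_gradient,
    label_clusters,
    map_statistics,
    stratify,
)


def four_cluster_angles(n_per=25, sigma=5.0, seed=0):
    rng = np.random.default_rng(seed)
    out, truth = [], []
    for i, base in enumerate([0.0, 90.0, 180.0, 270.0]):
        out.append(wrap_deg(base + rng.normal(0, sigma, n_per)))
        truth.append(np.full(n_per, i))
    return np.concatenate(out), np.concatenate(truth)


def test_four_tight_groups_select_k4_with_accurate_centroids():
    angles, _ = four_cluster_angles(sigma=5.0)
    model = cluster_directions(angles, rng_seed=0)
    assert model.k == 4
    for want in [0.0, 90.0, 180.0, 270.0]:
        nearest = np.min(np.abs(ang_diff_deg(model.centroid_angles, want)))
        assert nearest < 3.0


def test_identical_points_are_degenerate_with_zero_sv():
    model = cluster_directions(np.full(10, 42.0))
    assert model.degenerate
    assert model.mean_sv == 0.0
    assert np.all(model.assignments == model.assignments[0])


def test_silhouette_matches_bruteforce_pairwise_oracle():
    """SV(i) = (b−a)/max(a,b) with chord distances, computed literally."""
    angles = np.array([0.0, 5.0, 10.0, 180.0, 185.0, 190.0])
    model = cluster_directions(angles, k_range=[2], rng_seed=0)
    X = unit_vectors(angles)
    labels = model.assignments
    for i in range(len(X)):
        same = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        other = [j for j in range(len(X)) if labels[j] != labels[i]]
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = np.mean([np.linalg.norm(X[i] - X[j]) for j in other])
        sv = (b - a) / max(a, b)
        assert model.silhouette_values[i] == pytest.approx(sv, abs=1e-12)


def test_clustering_stable_across_seeds_on_separated_map():
    angles, _ = four_cluster_angles(sigma=8.0, seed=3)
    a = cluster_directions(angles, rng_seed=0)
    b = cluster_directions(angles, rng_seed=12345)
    from sklearn.metrics import adjusted_rand_score

    assert a.k == b.k == 4
    assert adjusted_rand_score(a.assignments, b.assignments) >= 0.99


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def _model_and_markers(marker_frac=0.2, seed=1):
    angles, truth = four_cluster_angles(sigma=10.0, seed=seed)
    model = cluster_directions(angles, rng_seed=0)
    rng = np.random.default_rng(seed)
    marker = np.array([None] * len(angles), dtype=object)
    canonical = {0: None, 1: None, 2: "nasal", 3: "ventral"}
    for i, t in enumerate(truth):
        if canonical[t] and rng.random() < marker_frac:
            marker[i] = canonical[t]
    return angles, truth, model, marker


def test_marker_anchored_labels_are_fully_correct():
    angles, truth, model, marker = _model_and_markers()
    labels, fallback = label_clusters(model, marker)
    assert not fallback
    want = {0: "temporal", 1: "dorsal", 2: "nasal", 3: "ventral"}
    for c in range(model.k):
        members = truth[model.assignments == c]
        majority = np.bincount(members).argmax()
        assert labels[c] == want[majority]


def test_ventral_markers_alone_anchor_all_four_labels():
    angles, truth, model, marker = _model_and_markers()
    marker = np.array([m if m == "ventral" else None for m in marker], dtype=object)
    labels, fallback = label_clusters(model, marker)
    assert not fallback
    assert sorted(labels.values()) == ["dorsal", "nasal", "temporal", "ventral"]
    c_v = next(c for c, l in labels.items() if l == "ventral")
    assert abs(ang_diff_deg(model.centroid_angles[c_v], 270.0)) < 15.0


def test_no_markers_falls_back_to_canonical_angles():
    angles, truth, model, _ = _model_and_markers()
    labels, fallback = label_clusters(model, None)
    assert fallback
    assert sorted(labels.values()) == ["dorsal", "nasal", "temporal", "ventral"]


def test_ambiguous_marker_majority_raises():
    angles = np.array([0.0, 1.0, 180.0, 181.0])
    model = cluster_directions(angles, k_range=[2], rng_seed=0)
    marker = np.array(["ventral", None, "ventral", None], dtype=object)
    with pytest.raises(ValueError, match="ambiguous"):
        label_clusters(model, marker)


def test_rotation_permutes_labels_but_keeps_memberships():
    angles, truth, model, marker = _model_and_markers()
    rot = wrap_deg(angles + 90.0)
    model_r = cluster_directions(rot, rng_seed=0)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(model.assignments, model_r.assignments) == 1.0


# ---------------------------------------------------------------------------
# stratification & summaries
# ---------------------------------------------------------------------------

def _cell_table(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "roi_id": range(n),
            "x_um": rng.uniform(100, 1500, n),
            "y_um": rng.uniform(100, 1500, n),
            "pref_deg": rng.uniform(0, 360, n),
            "vs_norm": rng.uniform(0.3, 1.0, n),
            "vs_raw": rng.uniform(0.3, 3.0, n),
            "dsi": rng.uniform(0, 1, n),
            "percentile": 100.0,
            "significant": True,
            "cell_class": rng.choice(["ON", "ONOFF"], n),
            "quadrant": rng.choice(["ventronasal", "ventrotemporal"], n),
            "fov_id": 0,
            "cluster_label": rng.choice(["nasal", "dorsal"], n),
        }
    )


def test_eccentricity_boundary_at_1000um():
    df = _cell_table(4)
    df.loc[0, ["x_um", "y_um"]] = (999.0, 0.0)
    df.loc[1, ["x_um", "y_um"]] = (1000.0, 0.0)
    df["quadrant"] = "ventronasal"
    strata = stratify(df)
    central = strata[("ventronasal", "central")]
    peripheral = strata[("ventronasal", "peripheral")]
    assert 0 in central.index and 1 in peripheral.index


def test_strata_partition_the_population():
    df = _cell_table(50, seed=2)
    strata = stratify(df)
    assert sum(len(g) for g in strata.values()) == len(df)
    idx = np.concatenate([g.index.to_numpy() for g in strata.values()])
    assert len(np.unique(idx)) == len(df)


def test_single_cluster_proportion_is_one():
    df = _cell_table(10)
    df["cluster_label"] = "ventral"
    df["cell_class"] = "ON"
    table = map_statistics(df)
    assert table["proportion"].tolist() == [1.0]


def test_proportions_sum_to_one_per_group():
    table = map_statistics(_cell_table(60, seed=5))
    sums = table.groupby(["condition", "cell_class"])["proportion"].sum()
    assert np.allclose(sums, 1.0)


def test_circular_variance_matches_von_mises_closed_form():
    kappa = 2.0
    rng = np.random.default_rng(8)
    sample = np.rad2deg(stats.vonmises.rvs(kappa, size=40000, random_state=rng))
    expected = 1.0 - special.i1(kappa) / special.i0(kappa)
    assert circular_variance_deg(sample) == pytest.approx(expected, abs=0.01)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def _fov_cells(dirs_by_fov, dists_mm):
    rows = []
    for fov, (d, dist) in enumerate(zip(dirs_by_fov, dists_mm)):
        for ang in np.atleast_1d(d):
            rows.append(
                {"fov_id": fov, "pref_deg": ang, "x_um": dist * 1000.0, "y_um": 0.0}
            )
    return pd.DataFrame(rows)


def test_two_point_gradient_slope():
    fit = direction_gradient(_fov_cells([90.0, 95.0], [0.0, 1.0]))
    assert fit.slope_deg_per_mm == pytest.approx(5.0, abs=1e-9)


def test_constant_direction_gives_zero_slope():
    fit = direction_gradient(_fov_cells([120.0, 120.0, 120.0], [0.2, 0.8, 1.4]))
    assert fit.slope_deg_per_mm == pytest.approx(0.0, abs=1e-9)


def test_single_distance_raises():
    with pytest.raises(ValueError, match="same distance"):
        direction_gradient(_fov_cells([90.0, 95.0], [1.0, 1.0]))


def test_gradient_parameter_recovery_with_jitter():
    rng = np.random.default_rng(9)
    dists = np.linspace(0.2, 1.8, 6)
    dirs = [270.0 + 5.0 * d + rng.normal(0, 2.0, 15) for d in dists]
    fit = direction_gradient(_fov_cells(dirs, dists))
    assert fit.ci_low <= 5.0 <= fit.ci_high
    assert fit.slope_deg_per_mm == pytest.approx(5.0, abs=2.0)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def test_identical_groups_not_significant():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, 30)
    res = compare_groups({"a": base, "b": base.copy(), "c": base.copy()})
    assert res.anova_f == pytest.approx(0.0, abs=1e-9)
    assert not res.pairwise["significant"].any()


def test_clearly_separated_groups_significant_at_alpha_001():
    rng = np.random.default_rng(2)
    res = compare_groups(
        {"a": rng.normal(0, 0.1, 30), "b": rng.normal(1, 0.1, 30)}, alpha=0.01
    )
    assert res.anova_p < 0.01
    assert res.pairwise["significant"].all()


def test_degenerate_variance_reported_not_raised():
    res = compare_groups({"a": np.ones(5), "b": np.ones(5)})
    assert res.degenerate
    assert not res.pairwise["significant"].any()


def test_tukey_kramer_equal_n_matches_tukey_hsd():
    rng = np.random.default_rng(3)
    groups = {k: rng.normal(m, 1.0, 20) for k, m in zip("abc", [0.0, 0.5, 1.2])}
    res = compare_groups(groups, alpha=0.05)
    ref = stats.tukey_hsd(*groups.values())
    pairs = list(itertools.combinations(range(3), 2))
    for (i, j), p_adj in zip(pairs, res.pairwise["p_adj"]):
        assert p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-6)
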