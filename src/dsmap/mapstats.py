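"""Population-level structure of the direction-selectivity map.

Significantly tuned cells (ON and ON-OFF pooled) are clustered by
preferred direction: each direction becomes a unit vector
(cos θ, sin θ), K-means is run for k = 2…8, cluster fitness is scored by
the mean silhouette value SV(i) = (b(i) − a(i)) / max(a(i), b(i)) with
Euclidean (chord) distance between unit vectors — monotone in angular
distance — and the k with the highest mean SV wins (ties go to the
smaller k).  Clusters are then anchored to retinal axes using
genetically-labelled marker cells: the cluster holding the majority of
ventral-marker cells is the ventral cluster, the cluster immediately
clockwise of it (or holding the nasal markers) is nasal, and dorsal /
temporal are their 180° rotations.  Because preferred directions drift
with retinal location, all of this runs separately per stratum:
ventronasal vs ventrotemporal quadrant × central (<1000 µm from the
optic nerve) vs peripheral (≥1000 µm).

Per-cluster summary statistics (cell proportions, DSI, vector-sum
magnitude, circular variance of angles) and per-FOV direction-gradient
regressions quantify the map; group comparisons use one-way ANOVA with
Tukey-Kramer post-hoc tests (unequal-n safe) at α = 0.01.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import (
    CANONICAL_ANGLES,
    ECCENTRICITY_SPLIT_UM,
    ang_diff_deg,
    circ_mean_deg,
    unit_vectors,
    wrap_deg,
)

logger = logging.getLogger(__name__)

CELL_TABLE_COLUMNS = [
    "roi_id", "x_um", "y_um", "pref_deg", "vs_norm", "vs_raw", "dsi",
    "percentile", "significant", "cell_class",
]


@dataclass
class DSCell:
    """A classified direction-selective cell with retinal position."""

    roi_id: int
    x_um: float
    y_um: float
    pref_deg: float
    vs_norm: float
    vs_raw: float
    dsi: float
    percentile: float
    significant: bool
    cell_class: str
    quadrant: str = "ventronasal"
    fov_id: int = 0
    marker_type: str | None = None     # None | "ventral" | "nasal"
    cluster_label: str = "unassigned"

    @property
    def distance_um(self) -> float:
        return float(np.hypot(self.x_um, self.y_um))

    @property
    def eccentricity_class(self) -> str:
        return "central" if self.distance_um < ECCENTRICITY_SPLIT_UM else "peripheral"


def cells_to_table(cells: list[DSCell]) -> pd.DataFrame:
    df = pd.DataFrame([vars(c) for c in cells])
    df["distance_um"] = np.hypot(df["x_um"], df["y_um"])
    df["eccentricity_class"] = np.where(
        df["distance_um"] < ECCENTRICITY_SPLIT_UM, "central", "peripheral"
    )
    return df


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    k: int
    centroid_angles: np.ndarray          # degrees, one per cluster
    centroids: np.ndarray                # unit vectors, (k, 2)
    assignments: np.ndarray              # cluster index per cell
    silhouette_values: np.ndarray        # per cell
    mean_sv: float
    degenerate: bool = False
    candidates: dict = field(default_factory=dict, repr=False)  # k → mean SV


def cluster_directions(
    pref_deg: np.ndarray,
    k_range=range(2, 9),
    rng_seed: int = 0,
    n_init: int = 50,
) -> ClusterModel:
    """Silhouette-selected K-means of preferred directions on the unit circle.

    Directions are embedded as unit vectors; for each candidate k the mean
    silhouette value (chord distance) is computed and the best k returned
    (ties favour the smaller k; k larger than the number of points is
    skipped with a warning).  Identical inputs are a degenerate case:
    clustering is meaningless, so a flagged model with k = 2, all points
    in one cluster and SV 0 by convention is returned.
    """
    pref_deg = np.asarray(pref_deg, dtype=float)
    if len(pref_deg) < 2:
        raise ValueError("need at least 2 cells to cluster")
    X = unit_vectors(pref_deg)

    if np.allclose(X, X[0], atol=1e-12):
        logger.warning("all preferred directions identical; silhouette undefined")
        return ClusterModel(
            k=2,
            centroid_angles=np.array([wrap_deg(pref_deg[0])] * 2),
            centroids=np.tile(X[0], (2, 1)),
            assignments=np.zeros(len(X), dtype=int),
            silhouette_values=np.zeros(len(X)),
            mean_sv=0.0,
            degenerate=True,
        )

    best = None
    candidates = {}
    for k in k_range:
        if k > len(X):
            logger.warning("skipping k=%d: only %d points", k, len(X))
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed).fit(X)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            continue
        sv = silhouette_samples(X, labels)
        mean_sv = float(sv.mean())
        candidates[k] = mean_sv
        if best is None or mean_sv > best.mean_sv:  # ties keep the smaller k
            cen = km.cluster_centers_
            norms = np.linalg.norm(cen, axis=1, keepdims=True)
            cen_unit = cen / np.where(norms == 0, 1, norms)
            best = ClusterModel(
                k=k,
                centroid_angles=wrap_deg(
                    np.rad2deg(np.arctan2(cen_unit[:, 1], cen_unit[:, 0]))
                ),
                centroids=cen_unit,
                assignments=labels,
                silhouette_values=sv,
                mean_sv=mean_sv,
            )
    if best is None:
        raise ValueError("no candidate k could be evaluated")
    best.candidates = candidates
    return best


# ---------------------------------------------------------------------------
# marker-anchored labeling
# ---------------------------------------------------------------------------

def _majority_cluster(assignments: np.ndarray, member: np.ndarray, what: str) -> int:
    counts = np.bincount(assignments[member], minlength=assignments.max() + 1)
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    if len(winners) > 1:
        raise ValueError(
            f"{what}-marker majority is ambiguous between clusters {list(winners)}; "
            "manual labeling required"
        )
    return int(winners[0])


def _nearest_cluster(model: ClusterModel, angle_deg: float) -> int:
    return int(np.argmin(np.abs(ang_diff_deg(model.centroid_angles, angle_deg))))


def label_clusters(
    model: ClusterModel,
    marker_type: np.ndarray | None = None,
) -> tuple[dict[int, str], bool]:
    """Assign nasal/temporal/dorsal/ventral identities to clusters.

    ``marker_type`` is a per-cell array (aligned with the clustering
    input) holding ``"ventral"`` or ``"nasal"`` for genetically-labelled
    cells and None/"" otherwise.  The ventral cluster is the one holding
    the ventral-marker majority; the nasal cluster holds the nasal-marker
    majority (or, lacking nasal markers, is the cluster immediately
    clockwise of ventral); dorsal and temporal are the 180° rotations.
    With no markers at all, clusters fall back to nearest-canonical-angle
    labels and the returned flag is True.  Marker-majority ties raise.
    """
    labels: dict[int, str] = {c: "unassigned" for c in range(model.k)}
    marker = (
        np.asarray(marker_type, dtype=object)
        if marker_type is not None
        else np.array([None] * len(model.assignments), dtype=object)
    )
    has_v = np.array([m == "ventral" for m in marker])
    has_n = np.array([m == "nasal" for m in marker])

    if not has_v.any() and not has_n.any():
        logger.warning("no marker cells; falling back to nearest-canonical labeling")
        for c in range(model.k):
            name = min(
                CANONICAL_ANGLES,
                key=lambda nm: abs(ang_diff_deg(model.centroid_angles[c], CANONICAL_ANGLES[nm])),
            )
            labels[c] = name if name not in labels.values() else "unassigned"
        return labels, True

    if has_v.any():
        c_v = _majority_cluster(model.assignments, has_v, "ventral")
        labels[c_v] = "ventral"
        c_d = _nearest_cluster(model, model.centroid_angles[c_v] + 180.0)
        if labels[c_d] == "unassigned":
            labels[c_d] = "dorsal"
    if has_n.any():
        c_n = _majority_cluster(model.assignments, has_n, "nasal")
        if labels[c_n] == "unassigned":
            labels[c_n] = "nasal"
    elif has_v.any():
        # immediately clockwise of ventral (angles decrease going clockwise)
        c_v = next(c for c, l in labels.items() if l == "ventral")
        c_n = _nearest_cluster(model, model.centroid_angles[c_v] - 90.0)
        if labels[c_n] == "unassigned":
            labels[c_n] = "nasal"
    c_n = next((c for c, l in labels.items() if l == "nasal"), None)
    if c_n is not None:
        c_t = _nearest_cluster(model, model.centroid_angles[c_n] + 180.0)
        if labels[c_t] == "unassigned":
            labels[c_t] = "temporal"
    # a lone nasal marker population also anchors ventral via the 90° rule
    if c_n is not None and "ventral" not in labels.values():
        c_v = _nearest_cluster(model, model.centroid_angles[c_n] + 90.0)
        if labels[c_v] == "unassigned":
            labels[c_v] = "ventral"
            c_d = _nearest_cluster(model, model.centroid_angles[c_v] + 180.0)
            if labels[c_d] == "unassigned":
                labels[c_d] = "dorsal"
    return labels, False


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify(cells: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    """Partition cells into (quadrant × central/peripheral) strata."""
    cells = cells.copy()
    if "eccentricity_class" not in cells:
        dist = np.hypot(cells["x_um"], cells["y_um"])
        cells["eccentricity_class"] = np.where(
            dist < ECCENTRICITY_SPLIT_UM, "central", "peripheral"
        )
    out = {}
    for key, grp in cells.groupby(["quadrant", "eccentricity_class"], sort=True):
        if len(grp) == 0:
            logger.warning("empty stratum %s skipped", key)
            continue
        out[tuple(key)] = grp
    return out


def cluster_and_label_strata(
    cells: pd.DataFrame, k_range=range(2, 9), rng_seed: int = 0, n_init: int = 50
) -> pd.DataFrame:
    """Run clustering + marker labeling per stratum; returns the labelled table."""
    cells = cells.copy()
    cells["cluster_label"] = "unassigned"
    for key, grp in stratify(cells).items():
        sig = grp[grp["significant"].astype(bool)]
        if len(sig) < 2:
            logger.warning("stratum %s has <2 significant cells; skipped", key)
            continue
        model = cluster_directions(
            sig["pref_deg"].to_numpy(), k_range=k_range, rng_seed=rng_seed, n_init=n_init
        )
        marker = sig["marker_type"].to_numpy() if "marker_type" in sig else None
        labels, _ = label_clusters(model, marker)
        assigned = [labels[a] for a in model.assignments]
        cells.loc[sig.index, "cluster_label"] = assigned
    return cells


# ---------------------------------------------------------------------------
# quantitative map statistics
# ---------------------------------------------------------------------------

def circular_variance_deg(angles_deg) -> float:
    """1 − mean resultant length, for angles in degrees (∈ [0, 1])."""
    return float(stats.circvar(np.asarray(angles_deg, dtype=float), high=360.0, low=0.0))


def map_statistics(cells: pd.DataFrame, condition_col: str | None = None) -> pd.DataFrame:
    """Per (condition ×) cluster × cell-class summary of the DS map.

    Proportions are normalized across cluster labels within each
    (condition, cell-class) group, so they sum to 1 per group.
    """
    if len(cells) == 0:
        raise ValueError("no cells to summarize")
    df = cells.copy()
    if condition_col is None:
        df["_condition"] = "all"
        condition_col = "_condition"
    rows = []
    for (cond, cls), grp in df.groupby([condition_col, "cell_class"], sort=True):
        labelled = grp[grp["cluster_label"] != "unassigned"]
        total = len(labelled)
        for lab, sub in labelled.groupby("cluster_label", sort=True):
            rows.append(
                {
                    "condition": cond,
                    "cell_class": cls,
                    "cluster_label": lab,
                    "n": len(sub),
                    "proportion": len(sub) / total if total else np.nan,
                    "dsi_mean": sub["dsi"].mean(),
                    "dsi_median": sub["dsi"].median(),
                    "vs_mean": sub["vs_norm"].mean(),
                    "angular_variance": circular_variance_deg(sub["pref_deg"]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GradientFit:
    slope_deg_per_mm: float
    ci_low: float
    ci_high: float
    intercept_deg: float
    n_fov: int
    per_fov: pd.DataFrame = field(repr=False)


def direction_gradient(cells: pd.DataFrame, fov_col: str = "fov_id") -> GradientFit:
    """Per-FOV regression of mean preferred direction on optic-nerve distance.

    Each FOV contributes one point: the circular mean preferred direction
    of the cluster's cells, unwrapped around the across-FOV circular mean,
    against the FOV's mean distance from the optic nerve (mm).  Returns
    the least-squares slope in deg/mm with its 95% CI.
    """
    pts = []
    for fov, grp in cells.groupby(fov_col, sort=True):
        mean_dir = circ_mean_deg(grp["pref_deg"].to_numpy())
        dist_mm = float(np.hypot(grp["x_um"], grp["y_um"]).mean()) / 1000.0
        pts.append({"fov": fov, "mean_dir_deg": mean_dir, "distance_mm": dist_mm})
    per_fov = pd.DataFrame(pts).dropna()
    if len(per_fov) < 2:
        raise ValueError("need ≥2 FOVs to fit a gradient")
    x = per_fov["distance_mm"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("all FOVs are at the same distance; gradient undefined")
    ref = circ_mean_deg(per_fov["mean_dir_deg"].to_numpy())
    y = np.asarray(ang_diff_deg(per_fov["mean_dir_deg"], ref), dtype=float)
    res = stats.linregress(x, y)
    dof = len(x) - 2
    if dof > 0 and np.isfinite(res.stderr):
        t = stats.t.ppf(0.975, dof)
        ci = (res.slope - t * res.stderr, res.slope + t * res.stderr)
    else:
        ci = (-np.inf, np.inf)
    return GradientFit(
        slope_deg_per_mm=float(res.slope),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        intercept_deg=float(wrap_deg(res.intercept + ref)),
        n_fov=len(per_fov),
        per_fov=per_fov,
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame
    alpha: float
    degenerate: bool = False


def compare_groups(samples: dict[str, np.ndarray], alpha: float = 0.01) -> GroupComparison:
    """One-way ANOVA + Tukey-Kramer pairwise post-hoc comparisons.

    The Tukey-Kramer form corrects the studentized-range test for unequal
    group sizes (and reduces to Tukey's HSD when sizes are equal).
    Degenerate (zero-variance) inputs are reported, not raised.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(samples[n], dtype=float) for n in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 samples")

    pooled = np.concatenate(arrays)
    degenerate = np.ptp(pooled) == 0
    if degenerate:
        pairs = list(itertools.combinations(names, 2))
        pairwise = pd.DataFrame(
            {
                "group1": [p[0] for p in pairs],
                "group2": [p[1] for p in pairs],
                "meandiff": 0.0,
                "p_adj": 1.0,
                "significant": False,
            }
        )
        return GroupComparison(np.nan, np.nan, pairwise, alpha, degenerate=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)

    endog = pooled
    groups = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
    res = pairwise_tukeyhsd(endog, groups, alpha=alpha)
    uniq = list(res.groupsunique)
    pairs = list(itertools.combinations(uniq, 2))
    pairwise = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "significant": res.reject,
        }
    )
    return GroupComparison(float(f), float(p), pairwise, alpha)
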