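"""Spatial statistics of localized release events.

Localized events are grouped into release sites by agglomerative
(average-linkage) clustering with a 100 nm site-diameter criterion,
interpreted as "every event within 100 nm of its cluster centroid" and
enforced by a post-hoc refinement pass. Boutons whose cluster centroids
are >= 700 nm apart contain two active zones and are excluded from the
spatial analyses. Release areas are convex hulls (um^2) of the event
positions, per mode; the reshuffle statistic permutes the mode labels over
the observed positions (keeping both the position set and the per-mode
counts) and normalizes each mode's observed hull area by its mean shuffled
area — values > 1 mean the real events of that mode are more dispersed
than label-exchangeable chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError

CLUSTER_DIAMETER_NM = 100.0
DUAL_AZ_DISTANCE_NM = 700.0
MIN_EVENTS_SPATIAL = 5
DEFAULT_N_SHUFFLES = 1000


@dataclass
class ClusterSet:
    """Partition of events into release sites."""

    assignments: np.ndarray  # event -> cluster id (0-based)
    centroids: np.ndarray  # (k, 2) nm
    positions: np.ndarray  # (n, 2) nm
    modes: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def counts_by_mode(self) -> pd.DataFrame:
        if self.modes is None:
            raise ValueError("modes not provided")
        df = pd.DataFrame({"cluster": self.assignments, "mode": self.modes})
        out = (
            df.pivot_table(index="cluster", columns="mode", aggfunc="size", fill_value=0)
            .reindex(range(self.n_clusters), fill_value=0)
        )
        out["n_events"] = out.sum(axis=1)
        return out


def _refine(positions: np.ndarray, labels: np.ndarray, radius: float) -> np.ndarray:
    """Reassign events violating the centroid-distance rule; events that fit
    no existing centroid become singletons. Converges in a few passes."""
    labels = labels.copy()
    for _ in range(20):
        ids = np.unique(labels)
        centroids = np.array([positions[labels == i].mean(axis=0) for i in ids])
        moved = False
        for j, p in enumerate(positions):
            d = np.hypot(*(centroids - p).T)
            best = int(np.argmin(d))
            if d[best] <= radius:
                tgt = ids[best]
            else:
                tgt = labels.max() + 1  # new singleton
            if tgt != labels[j]:
                labels[j] = tgt
                moved = True
        if not moved:
            break
    # relabel contiguously in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def cluster_sites(
    positions: np.ndarray,
    modes: np.ndarray | None = None,
    diameter: float = CLUSTER_DIAMETER_NM,
) -> ClusterSet:
    """Average-linkage clustering cut at the site diameter, then refined so
    every event lies within ``diameter`` of its cluster centroid."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = positions.shape[0]
    if n == 0:
        raise ValueError("no events to cluster")
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        Z = linkage(positions, method="average")
        labels = fcluster(Z, t=diameter, criterion="distance") - 1
        labels = _refine(positions, labels, diameter)
    ids = np.unique(labels)
    centroids = np.array([positions[labels == i].mean(axis=0) for i in ids])
    return ClusterSet(
        assignments=labels,
        centroids=centroids,
        positions=positions,
        modes=None if modes is None else np.asarray(modes),
    )


def detect_dual_active_zone(
    clusters: ClusterSet, min_distance: float = DUAL_AZ_DISTANCE_NM
) -> bool:
    """True if any pair of cluster centroids is >= 700 nm apart (two active
    zones; such boutons are excluded from spatial analyses)."""
    c = clusters.centroids
    for i in range(len(c)):
        d = np.hypot(*(c[i + 1 :] - c[i]).T)
        if d.size and np.any(d >= min_distance):
            return True
    return False


def cluster_composition(clusters: ClusterSet) -> dict:
    """Mixed-cluster fraction and synchronous fraction versus cluster size.

    Considers clusters with >= 2 events. Returns per-size tables and an
    OLS line (with 95% CI on the slope) of the synchronous fraction
    against cluster size.
    """
    counts = clusters.counts_by_mode()
    sync = counts.get("synchronous", pd.Series(0, index=counts.index))
    asyn = counts.get("asynchronous", pd.Series(0, index=counts.index))
    multi = counts[counts["n_events"] >= 2]
    if multi.empty:
        return {"per_size": pd.DataFrame(), "mixed_fraction": np.nan, "regression": None}
    mixed = (sync[multi.index] > 0) & (asyn[multi.index] > 0)
    per_size = pd.DataFrame(
        {
            "n_events": multi["n_events"],
            "mixed": mixed,
            "sync_fraction": sync[multi.index] / multi["n_events"],
        }
    )
    by_size = per_size.groupby("n_events").agg(
        mixed_fraction=("mixed", "mean"),
        sync_fraction=("sync_fraction", "mean"),
        n_clusters=("mixed", "size"),
    )
    regression = None
    sizes = per_size["n_events"].to_numpy(dtype=float)
    if np.unique(sizes).size > 1:
        import statsmodels.api as sm

        X = sm.add_constant(sizes)
        model = sm.OLS(per_size["sync_fraction"].to_numpy(), X).fit()
        ci = model.conf_int(alpha=0.05)
        regression = {
            "slope": float(model.params[1]),
            "intercept": float(model.params[0]),
            "slope_ci95": (float(ci[1][0]), float(ci[1][1])),
        }
    return {
        "per_size": by_size,
        "mixed_fraction": float(mixed.mean()),
        "regression": regression,
    }


@dataclass
class ReleaseArea:
    """Convex-hull release areas (um^2) for all/synchronous/asynchronous."""

    S_all: float
    S_sync: float
    S_async: float
    n_sync: int
    n_async: int
    degenerate: bool = False
    normalized_sync: float | None = None
    normalized_async: float | None = None


def hull_area_um2(points_nm: np.ndarray) -> tuple[float, bool]:
    """Convex hull area in um^2; < 3 points or collinear sets give (0, True)."""
    pts = np.asarray(points_nm, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        return 0.0, True
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0, True
    return float(hull.volume) * 1e-6, False  # nm^2 -> um^2


def convex_hull_areas(
    positions: np.ndarray, modes: np.ndarray, min_events: int = MIN_EVENTS_SPATIAL
) -> ReleaseArea:
    """Per-mode convex hull areas. Requires >= 5 included events and both
    modes present (active zones roughly parallel to the imaging plane)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    modes = np.asarray(modes)
    if positions.shape[0] < min_events:
        raise ValueError(f"need >= {min_events} events, got {positions.shape[0]}")
    sync = positions[modes == "synchronous"]
    asyn = positions[modes == "asynchronous"]
    if len(sync) == 0 or len(asyn) == 0:
        raise ValueError("both synchronous and asynchronous events are required")
    S_all, d_all = hull_area_um2(positions)
    S_sync, d_s = hull_area_um2(sync)
    S_async, d_a = hull_area_um2(asyn)
    return ReleaseArea(
        S_all=S_all,
        S_sync=S_sync,
        S_async=S_async,
        n_sync=len(sync),
        n_async=len(asyn),
        degenerate=d_all or d_s or d_a,
    )


def reshuffle_normalized_area(
    positions: np.ndarray,
    modes: np.ndarray,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | None = None,
    permutations: np.ndarray | None = None,
) -> ReleaseArea:
    """Label-permutation normalization of per-mode hull areas.

    Every shuffle permutes the mode labels across the observed positions
    (counts preserved); both modes are normalized against the SAME shuffle
    set, making the two normalized areas a paired statistic. Boutons where
    more than half of the shuffles give degenerate hulls are rejected.
    Explicit ``permutations`` (an (n_shuffles, n_events) index array) may be
    supplied instead of random ones, e.g. for self-checks.
    """
    area = convex_hull_areas(positions, modes)
    rng = np.random.default_rng(seed)
    modes = np.asarray(modes)
    if permutations is not None:
        permutations = np.asarray(permutations, dtype=int)
        n_shuffles = permutations.shape[0]
    sync_areas, async_areas = [], []
    n_degenerate = 0
    for i in range(n_shuffles):
        if permutations is not None:
            perm = modes[permutations[i]]
        else:
            perm = rng.permutation(modes)
        s, ds = hull_area_um2(positions[perm == "synchronous"])
        a, da = hull_area_um2(positions[perm == "asynchronous"])
        if ds or da:
            n_degenerate += 1
        sync_areas.append(s)
        async_areas.append(a)
    if n_degenerate > n_shuffles / 2:
        raise ValueError("bouton excluded: degenerate hulls in most shuffles")
    mean_s, mean_a = float(np.mean(sync_areas)), float(np.mean(async_areas))
    area.normalized_sync = area.S_sync / mean_s if mean_s > 0 else np.nan
    area.normalized_async = area.S_async / mean_a if mean_a > 0 else np.nan
    return area
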