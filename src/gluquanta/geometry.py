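"""Presynaptic bouton and active-zone geometries.

The bouton is a truncated sphere of radius R_bout = 0.5 um
([x^2 + y^2 + z^2 <= 0.25][z <= 0.42], distances in um) with a single
circular active zone (AZ) on the truncated face, area 0.03-0.15 um^2.
VGCCs sit in circular clusters of radius 30 nm, 16 channels per cluster
(7 P/Q, 8 N, 1 R), overall density ~500 um^-2 in every case. Nine canonical
cluster layouts are provided (cases i-ix), varying the cluster count (1-5)
and whether clusters sit centrally (i, ii, iv, v, vii, ix) or peripherally
(iii, vi, viii); the AZ area scales with the cluster count to hold the
density. The layouts reconstruct the published layout classes from their
description; exact cluster coordinates are this package's convention.

Readily releasable vesicles are distributed at an average density of
100 um^-2 (RRP size clamped to 3-15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_BOUT_UM = 0.5
Z_TRUNCATION_UM = 0.42
CLUSTER_RADIUS_UM = 0.030
CHANNELS_PER_CLUSTER = 16
CHANNEL_COMPOSITION = {"P/Q": 7, "N": 8, "R": 1}
TARGET_CHANNEL_DENSITY = 500.0  # um^-2
RRP_DENSITY = 100.0  # vesicles um^-2
RRP_RANGE = (3, 15)
AZ_AREA_RANGE = (0.03, 0.15)

# case id -> (number of clusters, layout class)
CASE_LAYOUTS: dict[str, tuple[int, str]] = {
    "i": (1, "central"),
    "ii": (2, "central"),
    "iii": (2, "peripheral"),
    "iv": (3, "central"),
    "v": (4, "central"),
    "vi": (4, "peripheral"),
    "vii": (5, "central"),
    "viii": (5, "peripheral"),
    "ix": (5, "central_tight"),
}


@dataclass(frozen=True)
class BoutonGeometry:
    """Truncated-sphere bouton with mesh spacing for the Ca2+ solver."""

    r_bout: float = R_BOUT_UM
    z_cut: float = Z_TRUNCATION_UM
    mesh_um: float = 0.040

    def inside(self, x, y, z) -> np.ndarray:
        return (x**2 + y**2 + z**2 <= self.r_bout**2) & (z <= self.z_cut)

    @property
    def az_plane_z(self) -> float:
        return self.z_cut

    @property
    def az_max_radius(self) -> float:
        return float(np.sqrt(self.r_bout**2 - self.z_cut**2))


@dataclass(frozen=True)
class AZGeometry:
    """Active-zone layout: VGCC cluster centres and RRP site capacity."""

    case_id: str
    az_area: float  # um^2
    cluster_centers: np.ndarray  # (k, 2) um, in the AZ plane
    cluster_radius: float = CLUSTER_RADIUS_UM
    channels_per_cluster: int = CHANNELS_PER_CLUSTER

    @property
    def az_radius(self) -> float:
        return float(np.sqrt(self.az_area / np.pi))

    @property
    def n_clusters(self) -> int:
        return self.cluster_centers.shape[0]

    @property
    def channel_density(self) -> float:
        return self.n_clusters * self.channels_per_cluster / self.az_area

    @property
    def rrp_size(self) -> int:
        return int(np.clip(round(self.az_area * RRP_DENSITY), *RRP_RANGE))


def _ring(n: int, radius: float, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2 * np.pi * np.arange(n) / max(n, 1)
    return radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def build_geometry(
    case_id: str,
    az_area: float | None = None,
    mesh_um: float = 0.040,
) -> tuple[BoutonGeometry, AZGeometry]:
    """Construct the bouton and one of the nine AZ layout cases.

    If ``az_area`` is omitted it is set to ``n_clusters * 16 / 500`` so the
    overall channel density is ~500 um^-2 (capped to the 0.03-0.15 um^2
    ultrastructural range). Central layouts place one cluster at the centre
    and the rest on a ring at 0.45 AZ radii (0.3 for the tight variant);
    peripheral layouts place all clusters on a ring at 0.75 AZ radii.
    """
    if case_id not in CASE_LAYOUTS:
        raise ValueError(f"case_id must be one of {sorted(CASE_LAYOUTS)}, got {case_id!r}")
    n_clusters, layout = CASE_LAYOUTS[case_id]
    if az_area is None:
        az_area = float(
            np.clip(
                n_clusters * CHANNELS_PER_CLUSTER / TARGET_CHANNEL_DENSITY,
                *AZ_AREA_RANGE,
            )
        )
    if not AZ_AREA_RANGE[0] <= az_area <= AZ_AREA_RANGE[1]:
        raise ValueError(f"az_area {az_area} outside {AZ_AREA_RANGE} um^2")
    bouton = BoutonGeometry(mesh_um=mesh_um)
    az_radius = float(np.sqrt(az_area / np.pi))
    if az_radius > bouton.az_max_radius + 1e-12:
        raise ValueError("active zone does not fit on the truncated face")
    if layout == "central":
        if n_clusters == 1:
            centers = np.zeros((1, 2))
        else:
            centers = np.vstack([np.zeros((1, 2)), _ring(n_clusters - 1, 0.45 * az_radius)])
    elif layout == "central_tight":
        centers = np.vstack([np.zeros((1, 2)), _ring(n_clusters - 1, 0.30 * az_radius)])
    else:  # peripheral
        centers = _ring(n_clusters, 0.75 * az_radius)
    if np.any(np.hypot(centers[:, 0], centers[:, 1]) + CLUSTER_RADIUS_UM > az_radius + 1e-9):
        raise ValueError(f"case {case_id}: clusters do not fit inside the AZ")
    az = AZGeometry(case_id=case_id, az_area=az_area, cluster_centers=centers)
    density = az.channel_density
    if abs(density - TARGET_CHANNEL_DENSITY) > 0.2 * TARGET_CHANNEL_DENSITY:
        raise ValueError(
            f"case {case_id}: channel density {density:.0f} um^-2 deviates "
            f"more than 20% from {TARGET_CHANNEL_DENSITY:.0f}"
        )
    return bouton, az


def place_rrp_sites(
    az: AZGeometry, rng: np.random.Generator, n_sites: int | None = None
) -> np.ndarray:
    """Uniform random RRP site positions inside the AZ disc (um, AZ plane)."""
    n = az.rrp_size if n_sites is None else n_sites
    r = az.az_radius * np.sqrt(rng.random(n))
    ang = rng.uniform(0, 2 * np.pi, n)
    return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)


@dataclass
class PvMap:
    """Release-probability map over AZ positions.

    p_s varies with position (nanodomain coupling); p_a is uniform; the
    overall per-AP vesicular release probability is
    p_v = p_s + (1 - p_s) p_a and the synchronous fraction at a position
    is p_s / (p_s + (1 - p_s) p_a).
    """

    positions: np.ndarray  # (n, 2) um in the AZ plane
    p_s: np.ndarray
    p_a: float

    def __post_init__(self) -> None:
        self.p_s = np.asarray(self.p_s, dtype=float)
        if np.any((self.p_s < 0) | (self.p_s > 1)) or not 0 <= self.p_a <= 1:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def p_v(self) -> np.ndarray:
        return self.p_s + (1.0 - self.p_s) * self.p_a

    @property
    def sync_fraction(self) -> np.ndarray:
        pv = self.p_v
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(pv > 0, self.p_s / pv, 0.0)

    def interp_p_s(self, points: np.ndarray) -> np.ndarray:
        """Nearest-position lookup of p_s for arbitrary AZ points."""
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        d2 = ((points[:, None, :] - self.positions[None, :, :]) ** 2).sum(axis=2)
        return self.p_s[np.argmin(d2, axis=1)]


def build_pv_map(positions: np.ndarray, p_s: np.ndarray, p_a: float) -> PvMap:
    return PvMap(positions=np.asarray(positions, float), p_s=p_s, p_a=p_a)
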