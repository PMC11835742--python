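"""Parcellation geometry: region centroids, Euclidean distances, network labels.

Coordinates are millimetres in a right-handed MNI-like frame.  All spatial
kernels downstream (the local-order kernel ``exp(-lam * d)`` and the
exponential distance rule of the anatomical coupling) consume the pairwise
Euclidean distance matrix stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

#: Canonical resting-state network names (control, default-mode,
#: temporal-parietal, visual, somatomotor, attentional, salience, limbic).
RSN_NAMES: tuple[str, ...] = ("CON", "DMN", "TP", "VIS", "SOM", "ATT", "SAL", "LIM")


@dataclass(frozen=True)
class ParcelGeometry:
    """Region centroids plus derived pairwise distances and RSN labels.

    Parameters
    ----------
    coords
        ``(N, 3)`` array of centroid positions in mm.
    dist
        ``(N, N)`` symmetric, hollow matrix of Euclidean distances in mm.
    rsn_labels
        Length-``N`` array of network names drawn from :data:`RSN_NAMES`.
    """

    coords: np.ndarray
    dist: np.ndarray
    rsn_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        dist = np.asarray(self.dist, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        n = coords.shape[0]
        if dist.shape != (n, n):
            raise ValueError(f"dist must be ({n}, {n}), got {dist.shape}")
        if not np.allclose(dist, dist.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diagonal(dist)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        expected = squareform(pdist(coords))
        if np.abs(dist - expected).max() > 1e-9:
            raise ValueError("dist is inconsistent with coords (not Euclidean)")
        labels = self.rsn_labels
        if labels is None:
            labels = np.array(["CON"] * n, dtype=object)
        labels = np.asarray(labels, dtype=object)
        if labels.shape != (n,):
            raise ValueError(f"rsn_labels must have length {n}")
        unknown = set(labels) - set(RSN_NAMES)
        if unknown:
            raise ValueError(f"unknown RSN labels: {sorted(unknown)}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "dist", dist)
        object.__setattr__(self, "rsn_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_coords(cls, coords: np.ndarray, rsn_labels=None) -> "ParcelGeometry":
        """Build a geometry from centroid coordinates alone."""
        coords = np.asarray(coords, dtype=float)
        return cls(coords=coords, dist=squareform(pdist(coords)), rsn_labels=rsn_labels)

    def permuted(self, order: np.ndarray) -> "ParcelGeometry":
        """Return the geometry with regions reordered by ``order``."""
        order = np.asarray(order)
        return ParcelGeometry(
            coords=self.coords[order],
            dist=self.dist[np.ix_(order, order)],
            rsn_labels=self.rsn_labels[order],
        )


def generate_geometry(
    n_regions: int,
    seed: int,
    *,
    semi_axes: tuple[float, float, float] = (70.0, 85.0, 60.0),
    min_spacing: float = 3.0,
    n_networks: int = 8,
    max_attempts_per_point: int = 500,
) -> ParcelGeometry:
    """Sample brain-like synthetic parcel centroids inside an ellipsoid.

    Points are dart-thrown uniformly inside an ellipsoid of roughly cortical
    extent (default 140 x 170 x 120 mm) with a hard minimum spacing, then
    partitioned into spatially contiguous clusters by k-means; clusters stand
    in for resting-state networks.

    Parameters
    ----------
    n_regions
        Number of parcels (>= 10).
    seed
        Seed controlling point placement and network labelling; the output is
        fully deterministic per seed.
    min_spacing
        Minimum allowed inter-centroid distance in mm.

    Raises
    ------
    ValueError
        If ``n_regions`` is too small, or too many points are requested to
        satisfy the spacing constraint inside the ellipsoid.
    """
    if n_regions < 10:
        raise ValueError("n_regions must be >= 10")
    rng = np.random.default_rng(seed)
    axes = np.asarray(semi_axes, dtype=float)

    pts: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_point * n_regions
    while len(pts) < n_regions:
        if attempts >= budget:
            raise ValueError(
                f"could not place {n_regions} points with spacing >= "
                f"{min_spacing} mm inside the ellipsoid ({len(pts)} placed)"
            )
        attempts += 1
        # uniform in the unit ball, scaled to the ellipsoid
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        r = rng.random() ** (1.0 / 3.0)
        p = axes * v * r
        if pts and np.min(np.linalg.norm(np.asarray(pts) - p, axis=1)) < min_spacing:
            continue
        pts.append(p)
    coords = np.asarray(pts)

    from sklearn.cluster import KMeans

    k = min(n_networks, len(RSN_NAMES), n_regions)
    km = KMeans(n_clusters=k, n_init=4, random_state=int(rng.integers(2**31)))
    cluster = km.fit_predict(coords)
    labels = np.asarray([RSN_NAMES[c] for c in cluster], dtype=object)
    return ParcelGeometry(coords=coords, dist=squareform(pdist(coords)), rsn_labels=labels)
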