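"""Geographic distances, distance-decay turnover and PCNM eigenfunctions.

The distance-decay model is log10(similarity) = (-2 z) * log10(distance) + b,
so the community turnover rate z is minus half the log-log slope.  Spatial
predictors for ordination come from principal coordinates of neighbour
matrices (PCNM): eigen-decomposition of a truncated Euclidean distance
matrix between sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree

from microeuk.io import DistanceMatrix

EARTH_RADIUS_M = 6_371_000.0


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude out of range")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude out of range")


def geo_distance_matrix(latitudes, longitudes, labels=None) -> DistanceMatrix:
    """Great-circle (haversine) pairwise distances in meters."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    _check_coords(lat, lon)
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    if labels is None:
        labels = [f"site{i}" for i in range(len(lat))]
    return DistanceMatrix(list(labels), d, kind="geographic_m")


def to_cartesian(latitudes, longitudes) -> tuple[np.ndarray, np.ndarray]:
    """Local tangent-plane projection about the centroid, in meters.

    x = R * dlon * cos(lat0), y = R * dlat (angles in radians); valid when
    the site spread is small relative to the Earth radius.
    """
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    _check_coords(lat, lon)
    lat0 = lat.mean()
    lon0 = lon.mean()
    x = EARTH_RADIUS_M * np.radians(lon - lon0) * math.cos(math.radians(lat0))
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


@dataclass
class DecayFit:
    """Log-log distance-decay regression; z = -slope / 2."""

    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    n_pairs: int
    n_excluded: int

    @property
    def z(self) -> float:
        return -self.slope / 2.0


def distance_decay(
    similarity: DistanceMatrix,
    distance_m: DistanceMatrix,
    min_distance_m: float = 1.0,
) -> DecayFit:
    """OLS of log10(similarity) on log10(distance); turnover z = -slope/2.

    Pairs at geographic distance <= ``min_distance_m`` (e.g. same site,
    different depth) or with zero similarity are excluded, their count
    reported in ``n_excluded``.
    """
    if similarity.labels != distance_m.labels:
        raise ValueError("label mismatch between similarity and distance matrices")
    if not similarity.is_similarity:
        raise ValueError("first argument must be a similarity matrix")
    s = similarity.condensed()
    d = distance_m.condensed()
    usable = (d > min_distance_m) & (s > 0)
    n_excluded = int((~usable).sum())
    s, d = s[usable], d[usable]
    if len(s) < 3:
        raise ValueError("fewer than 3 usable pairs for decay regression")
    res = stats.linregress(np.log10(d), np.log10(s))
    n = len(s)
    r2 = res.rvalue**2
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return DecayFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        adj_r2=float(adj),
        p_value=float(res.pvalue),
        n_pairs=n,
        n_excluded=n_excluded,
    )


@dataclass
class PCNMBasis:
    """Positive-eigenvalue spatial eigenfunctions of a truncated distance matrix."""

    eigenvalues: np.ndarray  # descending
    eigenvectors: pd.DataFrame  # sites x axes, orthonormal columns
    truncation_threshold: float

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _mst_longest_edge(d: np.ndarray) -> float:
    mst = minimum_spanning_tree(d).toarray()
    return float(mst.max())


def pcnm(
    distance_m: DistanceMatrix,
    truncation: float | None = None,
    eig_tol: float = 1e-10,
) -> PCNMBasis:
    """Principal coordinates of neighbour matrices.

    Distances above the truncation threshold (default: the longest edge of
    the minimum spanning tree, which keeps the site graph connected) are
    replaced by four times the threshold; the resulting matrix is Gower
    double-centered (-0.5 D² centered) and eigen-decomposed.  Axes with
    eigenvalue > ``eig_tol`` are returned in descending eigenvalue order,
    orthonormal, with the sign convention that each axis' largest-magnitude
    element is positive.
    """
    d = distance_m.values.copy()
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCNM needs at least 3 sites")
    off = d[np.triu_indices(n, k=1)]
    if np.all(off == 0):
        raise ValueError("all sites coincident")
    t = float(truncation) if truncation is not None else _mst_longest_edge(d)
    trunc = d.copy()
    trunc[d > t] = 4 * t
    np.fill_diagonal(trunc, 0.0)

    a = -0.5 * trunc**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    g = (g + g.T) / 2
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > eig_tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1
    axes = pd.DataFrame(
        eigvec,
        index=pd.Index(distance_m.labels, name="sample_id"),
        columns=[f"PCNM{i + 1}" for i in range(eigvec.shape[1])],
    )
    return PCNMBasis(eigenvalues=eigval, eigenvectors=axes, truncation_threshold=t)
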