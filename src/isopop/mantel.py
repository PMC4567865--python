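"""Mantel correlation between distance matrices (isolation by distance).

The genetic input is a population-level pairwise Phi_PT matrix; the
geographic input is a matrix of great-circle distances in km (haversine,
mean Earth radius 6371 km) or planar Euclidean km for synthetic grid
coordinates.  The Mantel statistic is the Pearson correlation of the
upper-triangle entries, and significance comes from simultaneous
row/column permutations of the second matrix.  The alternative is
one-tailed (positive association), matching the directional
isolation-by-distance hypothesis; for small n the full permutation
distribution can be enumerated exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amova import DistanceMatrix

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str = "permutation"  # or "exact"


def geographic_distances(coords: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distances (km) between populations.

    ``coords`` must be indexed by population label with columns
    ``lat``/``lon`` in decimal degrees.
    """
    lat = np.asarray(coords["lat"], dtype=float)
    lon = np.asarray(coords["lon"], dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range (|lat| <= 90, |lon| <= 180)")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(coords.index), d)


def planar_distances(coords: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances for planar km coordinates (columns x_km, y_km)."""
    xy = np.asarray(coords[["x_km", "y_km"]], dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(list(coords.index), d)


def _upper(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / math.sqrt((x @ x) * (y @ y)))


def mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool | None = None,
) -> MantelResult:
    """One-tailed Mantel test for positive association between A and B.

    Both matrices must carry the same labels in the same order and
    ``n >= 4``.  With ``exact=True`` (or ``exact=None`` and ``n <= 6``)
    all ``n!`` simultaneous permutations of B are enumerated and the
    p-value is the exact proportion with ``r_perm >= r_obs``; otherwise
    ``n_perm`` random permutations are drawn and the ``(b+1)/(m+1)``
    estimator is used.
    """
    if A.labels != B.labels:
        raise ValueError("distance matrices must share labels and ordering")
    n = A.n
    if n < 4:
        raise ValueError("Mantel test requires at least 4 labels")
    a = _upper(A.values)
    b = _upper(B.values)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("degenerate distance matrix")
    r_obs = _pearson(a, b)
    if exact is None:
        exact = n <= 6
    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        hits = total = 0
        Bv = B.values
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            r_perm = _pearson(a, _upper(Bv[np.ix_(p, p)]))
            hits += r_perm >= r_obs - 1e-12
            total += 1
        return MantelResult(r=r_obs, p=hits / total, n_perm=total, method="exact")
    rng = np.random.default_rng(seed)
    hits = 0
    Bv = B.values
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _pearson(a, _upper(Bv[np.ix_(p, p)])) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm)
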