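"""Hierarchical analysis of molecular variance (AMOVA) on binary genotypes.

AMOVA decomposes the total sum of squared pairwise distances among
individuals into hierarchical strata (regions / populations /
individuals), converts the mean squares into variance components using
unequal-sample-size coefficients, and expresses differentiation as
Phi statistics:

* ``Phi_PT`` -- variance among populations relative to the total,
* ``Phi_RT`` -- variance among regions relative to the total,
* ``Phi_PR`` -- variance among populations within regions.

The distance metric for band-presence data is the squared Euclidean
distance between 0/1 band vectors, i.e. the number of differing loci.
Significance is assessed by permutation: individuals are permuted among
populations (within regions for ``Phi_PR``), whole populations are
permuted among regions for ``Phi_RT``; p-values use the ``(b+1)/(m+1)``
estimator so they are never exactly zero.

Negative variance-component estimates are retained in
``AMOVAResult.components`` for diagnostics but truncated to zero when
percentages and Phi statistics are formed (the convention of the classic
AMOVA software).  ``components_from_summary`` applies the same algebra
starting from published df/SS tables instead of raw distances, which
makes tabled AMOVA results reproducible without the underlying genotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .aflp import AFLPMatrix

ONE_LEVEL_STRATA = ("Among populations", "Within populations")
TWO_LEVEL_STRATA = (
    "Among regions",
    "Among populations within regions",
    "Within populations",
)


class NoMolecularVarianceError(ValueError):
    """Raised when the total molecular variance is zero."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled rows/columns."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, labels: Sequence[str], values: np.ndarray) -> None:
        labels = tuple(str(l) for l in labels)
        v = np.asarray(values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        v = np.maximum(v, 0.0)
        v.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(str(l)) for l in labels]
        return DistanceMatrix([self.labels[i] for i in idx], self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class Stratum:
    name: str
    df: int
    ss: float

    @property
    def ms(self) -> float:
        return self.ss / self.df


@dataclass(frozen=True)
class AMOVAResult:
    """Strata, variance components, Phi statistics and permutation p-values."""

    strata: tuple[Stratum, ...]
    components: dict[str, float]            # raw estimates (may be negative)
    components_truncated: dict[str, float]  # used for percentages and Phi
    percentages: dict[str, float]
    phi: dict[str, float]
    perm_p: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            rows.append(
                {
                    "stratum": s.name,
                    "df": s.df,
                    "SS": s.ss,
                    "MS": s.ms,
                    "sigma2": self.components[s.name],
                    "percent": self.percentages[s.name],
                }
            )
        return pd.DataFrame(rows).set_index("stratum")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def binary_squared_distance(matrix: AFLPMatrix) -> DistanceMatrix:
    """Individual-level squared Euclidean distance on 0/1 band vectors.

    For binary data this equals the count of loci at which two individuals
    differ.
    """
    d = squareform(pdist(matrix.genotypes.astype(float), metric="sqeuclidean"))
    return DistanceMatrix(matrix.sample_ids, d)


# ---------------------------------------------------------------------------
# Sums of squares
# ---------------------------------------------------------------------------


def _group_indices(labels: Sequence[str]) -> tuple[tuple[str, ...], list[np.ndarray]]:
    order = tuple(dict.fromkeys(labels))
    arr = np.asarray(labels, dtype=object)
    return order, [np.flatnonzero(arr == g) for g in order]


def _ss_groups(d: np.ndarray, groups: list[np.ndarray]) -> float:
    """Sum over groups of (sum of pairwise distances within group) / group size."""
    total = 0.0
    for idx in groups:
        total += d[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return total


# ---------------------------------------------------------------------------
# One-level AMOVA
# ---------------------------------------------------------------------------


def _one_level_components(
    ms_among: float, ms_within: float, sizes: Sequence[int]
) -> tuple[float, float, float]:
    """Return (sigma_among_raw, sigma_within, n0)."""
    sizes = np.asarray(sizes, dtype=float)
    N = sizes.sum()
    k = len(sizes)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    return sigma_among, sigma_within, n0


def _phi_one_level(d: np.ndarray, groups: list[np.ndarray], ss_total: float) -> float:
    sizes = [len(g) for g in groups]
    N = sum(sizes)
    k = len(groups)
    ss_within = _ss_groups(d, groups)
    ss_among = ss_total - ss_within
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (N - k)
    sa, sw, _ = _one_level_components(ms_among, ms_within, sizes)
    sa = max(sa, 0.0)
    return sa / (sa + sw) if (sa + sw) > 0 else 0.0


def amova_one_level(
    d: DistanceMatrix,
    pops: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> AMOVAResult:
    """One-level AMOVA: among vs within populations, with a permutation test.

    ``pops`` gives the population label of every individual, aligned with
    ``d.labels``.  ``n_perm = 0`` skips the permutation test.
    """
    dv = d.values
    N = d.n
    if len(pops) != N:
        raise ValueError("pops must have one label per individual")
    order, groups = _group_indices(pops)
    k = len(order)
    if k < 2:
        raise ValueError("at least two populations are required")
    for g, idx in zip(order, groups):
        if len(idx) < 2:
            raise ValueError(f"population {g!r} has fewer than 2 members")
    ss_total = dv.sum() / (2.0 * N)
    if ss_total <= 0:
        raise NoMolecularVarianceError("no molecular variance")
    ss_within = _ss_groups(dv, groups)
    ss_among = ss_total - ss_within
    strata = (
        Stratum(ONE_LEVEL_STRATA[0], k - 1, ss_among),
        Stratum(ONE_LEVEL_STRATA[1], N - k, ss_within),
    )
    sizes = [len(g) for g in groups]
    sa, sw, _ = _one_level_components(strata[0].ms, strata[1].ms, sizes)
    components = {ONE_LEVEL_STRATA[0]: sa, ONE_LEVEL_STRATA[1]: sw}
    trunc = {k_: max(v, 0.0) for k_, v in components.items()}
    total = sum(trunc.values())
    percentages = {k_: 100.0 * v / total for k_, v in trunc.items()}
    phi = {"Phi_PT": trunc[ONE_LEVEL_STRATA[0]] / total}
    perm_p: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        obs = phi["Phi_PT"]
        sizes_cum = np.cumsum([0] + sizes)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            perm_groups = [perm[sizes_cum[i] : sizes_cum[i + 1]] for i in range(k)]
            if _phi_one_level(dv, perm_groups, ss_total) >= obs - 1e-12:
                hits += 1
        perm_p["Phi_PT"] = (hits + 1) / (n_perm + 1)
    return AMOVAResult(strata, components, trunc, percentages, phi, perm_p, n_perm)


# ---------------------------------------------------------------------------
# Two-level (nested) AMOVA
# ---------------------------------------------------------------------------


def _two_level_coefficients(
    sizes_by_region: Mapping[str, Sequence[int]],
) -> tuple[float, float, float]:
    """Unequal-sample-size coefficients (n, n', n'') for a nested design."""
    all_sizes = [s for v in sizes_by_region.values() for s in v]
    N = float(sum(all_sizes))
    P = len(all_sizes)
    G = len(sizes_by_region)
    s_g = sum(sum(s**2 for s in v) / sum(v) for v in sizes_by_region.values())
    sn2_N = sum(s**2 for s in all_sizes) / N
    n = (N - s_g) / (P - G)
    n_prime = (s_g - sn2_N) / (G - 1)
    n_dblprime = (N - sum(sum(v) ** 2 for v in sizes_by_region.values()) / N) / (G - 1)
    return n, n_prime, n_dblprime


def _two_level_components(
    ms: tuple[float, float, float], sizes_by_region: Mapping[str, Sequence[int]]
) -> tuple[float, float, float]:
    """Raw (sigma_regions, sigma_pops, sigma_within) from the three MS."""
    n, n_prime, n_dblprime = _two_level_coefficients(sizes_by_region)
    ms_a, ms_b, ms_w = ms
    sigma_c = ms_w
    sigma_b = (ms_b - sigma_c) / n
    sigma_a = (ms_a - sigma_c - n_prime * sigma_b) / n_dblprime
    return sigma_a, sigma_b, sigma_c


def _phi_from_two_level(sa: float, sb: float, sc: float) -> dict[str, float]:
    sa, sb = max(sa, 0.0), max(sb, 0.0)
    total = sa + sb + sc
    return {
        "Phi_RT": sa / total if total > 0 else 0.0,
        "Phi_PR": sb / (sb + sc) if (sb + sc) > 0 else 0.0,
        "Phi_PT": (sa + sb) / total if total > 0 else 0.0,
    }


def amova_two_level(
    d: DistanceMatrix,
    pops: Sequence[str],
    regions: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> AMOVAResult:
    """Nested AMOVA: among regions / among populations within regions / within.

    ``pops`` and ``regions`` give per-individual labels aligned with
    ``d.labels``; every population must be nested within a single region.
    """
    dv = d.values
    N = d.n
    if len(pops) != N or len(regions) != N:
        raise ValueError("pops and regions must each have one label per individual")
    pop_order, pop_groups = _group_indices(pops)
    region_of: dict[str, str] = {}
    for p, r in zip(pops, regions):
        if region_of.setdefault(p, r) != r:
            raise ValueError(f"population {p!r} spans multiple regions")
    region_order = tuple(dict.fromkeys(regions))
    G, P = len(region_order), len(pop_order)
    if G < 2:
        raise ValueError("at least two regions are required")
    pops_in_region = {r: [p for p in pop_order if region_of[p] == r] for r in region_order}
    for r, ps in pops_in_region.items():
        if len(ps) < 2:
            raise ValueError(f"region {r!r} has fewer than 2 populations")

    ss_total = dv.sum() / (2.0 * N)
    if ss_total <= 0:
        raise NoMolecularVarianceError("no molecular variance")
    _, region_groups = _group_indices(regions)
    ss_within_pops = _ss_groups(dv, pop_groups)
    ss_within_regions = _ss_groups(dv, region_groups)
    ss_ap = ss_within_regions - ss_within_pops
    ss_ar = ss_total - ss_within_regions
    strata = (
        Stratum(TWO_LEVEL_STRATA[0], G - 1, ss_ar),
        Stratum(TWO_LEVEL_STRATA[1], P - G, ss_ap),
        Stratum(TWO_LEVEL_STRATA[2], N - P, ss_within_pops),
    )
    pop_sizes = {p: len(g) for p, g in zip(pop_order, pop_groups)}
    sizes_by_region = {r: [pop_sizes[p] for p in ps] for r, ps in pops_in_region.items()}
    sa, sb, sc = _two_level_components(
        (strata[0].ms, strata[1].ms, strata[2].ms), sizes_by_region
    )
    components = dict(zip(TWO_LEVEL_STRATA, (sa, sb, sc)))
    trunc = {k: max(v, 0.0) for k, v in components.items()}
    total = sum(trunc.values())
    percentages = {k: 100.0 * v / total for k, v in trunc.items()}
    phi = _phi_from_two_level(sa, sb, sc)

    perm_p: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perm_p["Phi_PT"] = _perm_p_individuals(
            dv, pops, regions, phi["Phi_PT"], "Phi_PT", n_perm, rng
        )
        perm_p["Phi_PR"] = _perm_p_individuals(
            dv, pops, regions, phi["Phi_PR"], "Phi_PR", n_perm, rng
        )
        perm_p["Phi_RT"] = _perm_p_populations(
            dv, pop_order, pop_groups, pops_in_region, phi["Phi_RT"], n_perm, rng
        )
    return AMOVAResult(strata, components, trunc, percentages, phi, perm_p, n_perm)


def _two_level_phi_for_assignment(
    dv: np.ndarray, pop_groups: list[np.ndarray], region_of_pop: Sequence[str]
) -> dict[str, float]:
    """Recompute two-level Phi for an arbitrary assignment of individuals."""
    N = dv.shape[0]
    G_labels = tuple(dict.fromkeys(region_of_pop))
    region_groups = [
        np.concatenate([g for g, r in zip(pop_groups, region_of_pop) if r == reg])
        for reg in G_labels
    ]
    P, G = len(pop_groups), len(G_labels)
    ss_total = dv.sum() / (2.0 * N)
    ss_wp = _ss_groups(dv, pop_groups)
    ss_wr = _ss_groups(dv, region_groups)
    ms = (
        (ss_total - ss_wr) / (G - 1),
        (ss_wr - ss_wp) / (P - G),
        ss_wp / (N - P),
    )
    sizes_by_region = {
        reg: [len(g) for g, r in zip(pop_groups, region_of_pop) if r == reg]
        for reg in G_labels
    }
    sa, sb, sc = _two_level_components(ms, sizes_by_region)
    return _phi_from_two_level(sa, sb, sc)


def _perm_p_individuals(
    dv: np.ndarray,
    pops: Sequence[str],
    regions: Sequence[str],
    obs: float,
    which: str,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permute individuals among populations (within regions for Phi_PR)."""
    pop_order, pop_groups = _group_indices(pops)
    region_of_pop = [regions[g[0]] for g in pop_groups]
    sizes = [len(g) for g in pop_groups]
    within_regions = which == "Phi_PR"
    region_order = tuple(dict.fromkeys(regions))
    regions_arr = np.asarray(regions, dtype=object)
    pop_slots_by_region = {
        reg: [i for i, r in enumerate(region_of_pop) if r == reg] for reg in region_order
    }
    hits = 0
    for _ in range(n_perm):
        new_groups: list[np.ndarray] = [np.empty(0, dtype=int)] * len(pop_groups)
        if within_regions:
            for reg in region_order:
                idx = rng.permutation(np.flatnonzero(regions_arr == reg))
                start = 0
                for slot in pop_slots_by_region[reg]:
                    new_groups[slot] = idx[start : start + sizes[slot]]
                    start += sizes[slot]
        else:
            perm = rng.permutation(dv.shape[0])
            start = 0
            for slot, s in enumerate(sizes):
                new_groups[slot] = perm[start : start + s]
                start += s
        phi = _two_level_phi_for_assignment(dv, new_groups, region_of_pop)[which]
        if phi >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _perm_p_populations(
    dv: np.ndarray,
    pop_order: Sequence[str],
    pop_groups: list[np.ndarray],
    pops_in_region: Mapping[str, Sequence[str]],
    obs: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permute whole populations among regions (for Phi_RT)."""
    counts = {r: len(ps) for r, ps in pops_in_region.items()}
    region_order = list(pops_in_region)
    hits = 0
    P = len(pop_order)
    for _ in range(n_perm):
        shuffled = rng.permutation(P)
        region_of_pop, start = [None] * P, 0
        for r in region_order:
            for j in shuffled[start : start + counts[r]]:
                region_of_pop[j] = r
            start += counts[r]
        phi = _two_level_phi_for_assignment(dv, pop_groups, region_of_pop)["Phi_RT"]
        if phi >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Reconstruction from published summaries
# ---------------------------------------------------------------------------


def components_from_summary(
    strata: Sequence[tuple[int, float]],
    group_sizes: Sequence[int] | Mapping[str, Sequence[int]],
) -> AMOVAResult:
    """Recover variance components and Phi from published (df, SS) rows.

    ``strata`` is ordered from the top stratum downwards: two rows for a
    one-level analysis (among populations, within populations), three rows
    for a nested analysis (among regions, among populations within
    regions, within populations).  ``group_sizes`` is the per-population
    sample-size list (one-level) or a mapping region -> per-population
    sizes (nested).
    """
    strata = [(int(df), float(ss)) for df, ss in strata]
    if len(strata) == 2:
        if isinstance(group_sizes, Mapping):
            sizes = [s for v in group_sizes.values() for s in v]
        else:
            sizes = list(group_sizes)
        N, k = sum(sizes), len(sizes)
        if strata[0][0] != k - 1 or strata[1][0] != N - k:
            raise ValueError(
                f"df ({strata[0][0]}, {strata[1][0]}) inconsistent with "
                f"{k} populations of total size {N}"
            )
        st = (
            Stratum(ONE_LEVEL_STRATA[0], strata[0][0], strata[0][1]),
            Stratum(ONE_LEVEL_STRATA[1], strata[1][0], strata[1][1]),
        )
        sa, sw, _ = _one_level_components(st[0].ms, st[1].ms, sizes)
        components = dict(zip(ONE_LEVEL_STRATA, (sa, sw)))
        trunc = {k_: max(v, 0.0) for k_, v in components.items()}
        total = sum(trunc.values())
        percentages = {k_: 100.0 * v / total for k_, v in trunc.items()}
        phi = {"Phi_PT": trunc[ONE_LEVEL_STRATA[0]] / total}
        return AMOVAResult(st, components, trunc, percentages, phi)
    if len(strata) == 3:
        if not isinstance(group_sizes, Mapping):
            raise ValueError("nested summaries need sizes as a mapping region -> sizes")
        all_sizes = [s for v in group_sizes.values() for s in v]
        N, P, G = sum(all_sizes), len(all_sizes), len(group_sizes)
        expected = (G - 1, P - G, N - P)
        if tuple(df for df, _ in strata) != expected:
            raise ValueError(
                f"df {tuple(df for df, _ in strata)} inconsistent with the "
                f"nested sizes (expected {expected})"
            )
        st = tuple(
            Stratum(name, df, ss)
            for name, (df, ss) in zip(TWO_LEVEL_STRATA, strata)
        )
        sa, sb, sc = _two_level_components((st[0].ms, st[1].ms, st[2].ms), group_sizes)
        components = dict(zip(TWO_LEVEL_STRATA, (sa, sb, sc)))
        trunc = {k_: max(v, 0.0) for k_, v in components.items()}
        total = sum(trunc.values())
        percentages = {k_: 100.0 * v / total for k_, v in trunc.items()}
        phi = _phi_from_two_level(sa, sb, sc)
        return AMOVAResult(st, components, trunc, percentages, phi)
    raise ValueError("strata must contain two or three (df, SS) rows")


# ---------------------------------------------------------------------------
# Pairwise differentiation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwisePhiResult:
    """Population-level pairwise Phi_PT matrix with raw values and p-values."""

    matrix: DistanceMatrix               # truncated at 0
    raw: pd.DataFrame                    # untruncated estimates
    perm_p: pd.DataFrame | None = None


def pairwise_phi_pt(
    matrix: AFLPMatrix, n_perm: int = 0, seed: int | None = None
) -> PairwisePhiResult:
    """Pairwise Phi_PT between all population pairs.

    Each pair is analysed with a one-level AMOVA restricted to that pair.
    Negative estimates are kept in ``raw`` but truncated to zero in the
    returned matrix (which then satisfies the distance-matrix contract).
    """
    pops = matrix.population_labels
    if len(pops) < 2:
        raise ValueError("at least two populations are required")
    d = binary_squared_distance(matrix)
    rng = np.random.default_rng(seed)
    k = len(pops)
    phi_raw = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    pops_arr = np.asarray(matrix.populations, dtype=object)
    for i, j in itertools.combinations(range(k), 2):
        idx = np.flatnonzero((pops_arr == pops[i]) | (pops_arr == pops[j]))
        sub = DistanceMatrix(
            [matrix.sample_ids[t] for t in idx], d.values[np.ix_(idx, idx)]
        )
        sub_pops = [matrix.populations[t] for t in idx]
        try:
            res = amova_one_level(
                sub, sub_pops, n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)) if n_perm else None,
            )
        except NoMolecularVarianceError:
            # genetically uniform pair: no variance, hence no differentiation
            phi_raw[i, j] = phi_raw[j, i] = 0.0
            if n_perm:
                pvals[i, j] = pvals[j, i] = 1.0
            continue
        phi_raw[i, j] = phi_raw[j, i] = res.components[ONE_LEVEL_STRATA[0]] / (
            res.components[ONE_LEVEL_STRATA[0]] + res.components[ONE_LEVEL_STRATA[1]]
        )
        if n_perm:
            pvals[i, j] = pvals[j, i] = res.perm_p["Phi_PT"]
    truncated = np.maximum(phi_raw, 0.0)
    np.fill_diagonal(truncated, 0.0)
    return PairwisePhiResult(
        matrix=DistanceMatrix(pops, truncated),
        raw=pd.DataFrame(phi_raw, index=pops, columns=pops),
        perm_p=pd.DataFrame(pvals, index=pops, columns=pops) if n_perm else None,
    )
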