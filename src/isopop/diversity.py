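"""Within-population diversity statistics for dominant markers.

For band-presence data the allele frequencies behind each locus are not
directly observable: a band is shown by both the dominant homozygote and
the heterozygote.  Two estimators are provided:

``sqrt_hwe``
    Assume Hardy-Weinberg proportions; the frequency of the recessive
    (band-absent) allele is ``q = sqrt(1 - band_freq)`` and ``p = 1 - q``.
    This is the convention of the classic dominant-marker software and the
    package default.
``band_as_allele``
    Treat the band itself as an allele, ``p = band_freq``.  Useful as a
    sensitivity check; both estimators agree at fixed loci.

From the per-locus ``(p, q)`` the module computes Nei's gene diversity
``He = 1 - p^2 - q^2``, Shannon's information index
``I = -(p ln p + q ln q)`` (with ``0 ln 0 = 0``) and the percentage of
polymorphic loci, each averaged over all loci of the matrix.  No
rare-allele cutoff is applied for polymorphism: a locus counts as
polymorphic within a population whenever its band frequency is strictly
between 0 and 1.

Note on the Shannon sign: the index is reported in its standard
non-negative form ``-sum p ln p``; summaries that print it without the
minus sign would be negative-valued, which is inconsistent with tabled
diversity values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aflp import AFLPMatrix

ESTIMATORS = ("sqrt_hwe", "band_as_allele")


@dataclass(frozen=True)
class DiversityResult:
    """Per-population diversity summary."""

    population: str
    percent_polymorphic: float
    nei_He: float
    shannon_I: float
    n_individuals: int


def band_frequency(matrix: AFLPMatrix, population: str) -> np.ndarray:
    """Per-locus fraction of individuals of ``population`` carrying the band."""
    rows = matrix.rows_for(population)
    return matrix.genotypes[rows].mean(axis=0)


def allele_frequencies_dominant(
    band_freq: np.ndarray | float, estimator: str = "sqrt_hwe"
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the (band, null) allele frequencies ``(p, q)``, ``p + q = 1``."""
    f = np.asarray(band_freq, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("band frequencies must lie in [0, 1]")
    if estimator == "sqrt_hwe":
        q = np.sqrt(1.0 - f)
        p = 1.0 - q
    elif estimator == "band_as_allele":
        p = f
        q = 1.0 - f
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    return p, q


def _per_locus_pq(matrix: AFLPMatrix, population: str, estimator: str):
    return allele_frequencies_dominant(band_frequency(matrix, population), estimator)


def nei_gene_diversity(
    matrix: AFLPMatrix, population: str, estimator: str = "sqrt_hwe"
) -> float:
    """Nei's gene diversity ``He = 1 - sum p_i^2`` averaged over loci."""
    p, q = _per_locus_pq(matrix, population, estimator)
    return float(np.mean(1.0 - p**2 - q**2))


def shannon_index(
    matrix: AFLPMatrix, population: str, estimator: str = "sqrt_hwe"
) -> float:
    """Shannon's information index ``-sum p_i ln p_i`` averaged over loci."""
    p, q = _per_locus_pq(matrix, population, estimator)

    def plogp(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = x[nz] * np.log(x[nz])
        return out

    return float(np.mean(-(plogp(p) + plogp(q))))


def percent_polymorphic(matrix: AFLPMatrix, population: str) -> float:
    """Percentage of loci with band frequency strictly between 0 and 1."""
    f = band_frequency(matrix, population)
    return 100.0 * float(np.mean((f > 0) & (f < 1)))


def population_diversity(
    matrix: AFLPMatrix, population: str, estimator: str = "sqrt_hwe"
) -> DiversityResult:
    return DiversityResult(
        population=population,
        percent_polymorphic=percent_polymorphic(matrix, population),
        nei_He=nei_gene_diversity(matrix, population, estimator),
        shannon_I=shannon_index(matrix, population, estimator),
        n_individuals=len(matrix.rows_for(population)),
    )


def diversity_table(matrix: AFLPMatrix, estimator: str = "sqrt_hwe") -> pd.DataFrame:
    """Per-population diversity table (He, I, %PL) for the whole matrix."""
    rows = []
    for pop in matrix.population_labels:
        res = population_diversity(matrix, pop, estimator)
        rows.append(
            {
                "population": pop,
                "region": matrix.region_of[pop],
                "n": res.n_individuals,
                "He": res.nei_He,
                "I": res.shannon_I,
                "PL": res.percent_polymorphic,
            }
        )
    return pd.DataFrame(rows).set_index("population")
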