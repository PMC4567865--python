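"""Data model and I/O for binary dominant-marker (AFLP) genotype matrices.

AFLP scoring produces, per individual, a vector of band presence/absence
calls (1 = fragment of a given length present).  The central container is
:class:`AFLPMatrix`: a strictly binary individuals x loci matrix together
with the population label of every individual and the region label of
every population.  Missing genotype codes are rejected -- samples with
unclear banding patterns are expected to have been re-run or dropped
before import.

Two flat-file dialects are supported:

* ``tsv`` (canonical): one header row ``sample<TAB>population<TAB>region``
  followed by the locus ids; one row per individual with 0/1 entries.
* ``genalex``: a GenAlEx-style export with two leading metadata rows
  (counts row, then title/population-names row) before the header row
  ``sample<TAB>population<TAB>locus ids...``; region labels may be given
  in an optional third column named ``region``, otherwise every
  population is assigned to a single region ``"ALL"``.

A replicate-based genotyping error rate (discordant calls per replicated
pair-locus) is provided for reproducibility checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class AFLPFormatError(ValueError):
    """Raised when a genotype file cannot be parsed into a valid matrix."""


@dataclass(frozen=True)
class AFLPMatrix:
    """Binary individuals x loci genotype matrix with sample metadata.

    Parameters
    ----------
    genotypes:
        Array of shape ``(n_samples, n_loci)`` with entries in {0, 1};
        1 means the band (dominant phenotype) is present.
    sample_ids:
        Unique identifier per row.
    populations:
        Population label per row (same length as ``sample_ids``).
    region_of:
        Mapping from population label to region label.
    locus_ids:
        Column labels; column order defines locus identity.
    """

    genotypes: np.ndarray
    sample_ids: tuple[str, ...]
    populations: tuple[str, ...]
    region_of: Mapping[str, str]
    locus_ids: tuple[str, ...]

    def __init__(
        self,
        genotypes: np.ndarray,
        sample_ids: Sequence[str],
        populations: Sequence[str],
        region_of: Mapping[str, str],
        locus_ids: Sequence[str],
    ) -> None:
        g = np.asarray(genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("genotype entries must be exactly 0 or 1")
        g = g.astype(np.int8)
        g.setflags(write=False)
        sample_ids = tuple(str(s) for s in sample_ids)
        populations = tuple(str(p) for p in populations)
        locus_ids = tuple(str(l) for l in locus_ids)
        if len(sample_ids) != g.shape[0]:
            raise ValueError("row count does not match number of sample ids")
        if len(locus_ids) != g.shape[1]:
            raise ValueError("column count does not match number of locus ids")
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample id(s): {dupes}")
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("duplicate locus ids")
        if len(populations) != len(sample_ids):
            raise ValueError("populations must have one label per sample")
        region_of = dict(region_of)
        missing = sorted(set(populations) - set(region_of))
        if missing:
            raise ValueError(f"populations with no region label: {missing}")
        # hierarchical sampling-design invariants
        for pop in set(populations):
            if populations.count(pop) < 2:
                raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        pops_per_region: dict[str, set[str]] = {}
        for pop in set(populations):
            pops_per_region.setdefault(region_of[pop], set()).add(pop)
        for region, pops in pops_per_region.items():
            if len(pops) < 2:
                raise ValueError(f"region {region!r} has fewer than 2 populations")
        object.__setattr__(self, "genotypes", g)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "populations", populations)
        object.__setattr__(self, "region_of", region_of)
        object.__setattr__(self, "locus_ids", locus_ids)

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def population_labels(self) -> tuple[str, ...]:
        """Distinct population labels in order of first appearance."""
        return tuple(dict.fromkeys(self.populations))

    @property
    def region_labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.region_of[p] for p in self.population_labels))

    def regions_per_sample(self) -> tuple[str, ...]:
        return tuple(self.region_of[p] for p in self.populations)

    def rows_for(self, population: str) -> np.ndarray:
        """Row indices of the individuals of one population."""
        if population not in self.populations:
            raise KeyError(f"unknown population: {population!r}")
        return np.flatnonzero(np.asarray(self.populations, dtype=object) == population)

    def population_of(self, sample_id: str) -> str:
        try:
            idx = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None
        return self.populations[idx]


@dataclass(frozen=True)
class ReplicatePairs:
    """Original/replicate sample-id pairs used for a reproducibility check."""

    pairs: tuple[tuple[str, str], ...]

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        pairs = tuple((str(a), str(b)) for a, b in pairs)
        seen: set[str] = set()
        for a, b in pairs:
            for s in (a, b):
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one pair")
                seen.add(s)
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = ("sample", "population", "region")


def _parse_cell(value: str, row_label: str, locus: str) -> int:
    v = value.strip()
    if v == "0":
        return 0
    if v == "1":
        return 1
    raise AFLPFormatError(
        f"non-binary genotype value {value!r} at (sample {row_label}, locus {locus})"
    )


def read_aflp_matrix(path: str | Path, dialect: str = "tsv") -> AFLPMatrix:
    """Read a genotype flat file into a validated :class:`AFLPMatrix`.

    Row order of the file is preserved.  ``dialect`` is ``"tsv"``
    (canonical) or ``"genalex"`` (two metadata rows before the header).
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if dialect == "tsv":
        header_idx = 0
    elif dialect == "genalex":
        if len(lines) < 3:
            raise AFLPFormatError("GenAlEx file needs two metadata rows plus a header")
        header_idx = 2
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    header = lines[header_idx].split("\t")
    if dialect == "tsv":
        if tuple(h.strip().lower() for h in header[:3]) != _CANONICAL_COLUMNS:
            raise AFLPFormatError(
                "canonical layout requires leading columns sample, population, region"
            )
        n_meta = 3
        has_region = True
    else:
        lowered = [h.strip().lower() for h in header]
        if len(lowered) < 3 or lowered[1] not in ("pop", "population"):
            raise AFLPFormatError("GenAlEx header must be: sample, pop, [region,] loci")
        has_region = len(lowered) > 2 and lowered[2] == "region"
        n_meta = 3 if has_region else 2
    locus_ids = [h.strip() for h in header[n_meta:]]
    if not locus_ids:
        raise AFLPFormatError("no locus columns found")

    sample_ids: list[str] = []
    populations: list[str] = []
    region_of: dict[str, str] = {}
    rows: list[list[int]] = []
    for ln in lines[header_idx + 1 :]:
        parts = ln.split("\t")
        if len(parts) != n_meta + len(locus_ids):
            raise AFLPFormatError(
                f"row for sample {parts[0]!r} has {len(parts) - n_meta} genotype "
                f"columns, expected {len(locus_ids)}"
            )
        sid, pop = parts[0].strip(), parts[1].strip()
        region = parts[2].strip() if has_region else "ALL"
        if pop in region_of and region_of[pop] != region:
            raise AFLPFormatError(
                f"population {pop!r} assigned to two regions "
                f"({region_of[pop]!r} and {region!r})"
            )
        region_of[pop] = region
        sample_ids.append(sid)
        populations.append(pop)
        rows.append([_parse_cell(v, sid, loc) for v, loc in zip(parts[n_meta:], locus_ids)])
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise AFLPFormatError(f"duplicate sample id(s): {dupes}")
    return AFLPMatrix(np.array(rows, dtype=np.int8), sample_ids, populations, region_of, locus_ids)


def write_aflp_matrix(matrix: AFLPMatrix, path: str | Path) -> None:
    """Write the canonical tab-separated layout (bit-exact round trip)."""
    path = Path(path)
    out = ["\t".join(_CANONICAL_COLUMNS + matrix.locus_ids)]
    regions = matrix.regions_per_sample()
    for i, sid in enumerate(matrix.sample_ids):
        row = matrix.genotypes[i]
        out.append(
            "\t".join(
                [sid, matrix.populations[i], regions[i]] + [str(int(v)) for v in row]
            )
        )
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Reproducibility
# ---------------------------------------------------------------------------


def genotyping_error_rate(matrix: AFLPMatrix, pairs: ReplicatePairs) -> float:
    """Replicate-based genotyping error rate.

    The number of discordant locus calls summed over all original/replicate
    pairs, divided by (number of pairs x number of loci).  This is the
    per pair-locus normalisation; loci that could not be scored do not
    occur because the matrix is strictly binary.
    """
    if len(pairs) == 0:
        raise ValueError("at least one replicate pair is required")
    index = {s: i for i, s in enumerate(matrix.sample_ids)}
    mismatches = 0
    for a, b in pairs.pairs:
        for s in (a, b):
            if s not in index:
                raise KeyError(f"replicate sample {s!r} not present in the matrix")
        mismatches += int(np.sum(matrix.genotypes[index[a]] != matrix.genotypes[index[b]]))
    return mismatches / (len(pairs) * matrix.n_loci)
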