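"""Synthetic data with the statistical structure the analyses assume.

Every pipeline input can be generated from a :class:`SimulationConfig`:

* a binary dominant-marker matrix from a hierarchical island model --
  ancestral band-allele frequencies per locus, a Balding-Nichols beta
  drift step to each region and a second step to each population,
  optionally accumulated stepwise along a line of populations to induce
  isolation by distance in one region -- with individuals drawn as
  dominant phenotypes (band present) of a Hardy-Weinberg diploid locus;
* a per-population trait table with region-specific effect sizes
  (Student-t or gamma families);
* dish-level germination counts from the same beta-binomial cell model
  the germination module fits.

The differentiation parameters ``f_within`` / ``f_between`` are *target*
Phi values: the beta drift is applied on the band-frequency scale, where
a Balding-Nichols step with parameter F yields an expected among-group
variance fraction of exactly F at every locus regardless of the
ancestral frequency.  (Applying the step on the allele scale and coding
dominance afterwards inflates band-level differentiation at low-frequency
loci, so the parameter would no longer mean what it says.)  The derived
band-allele frequency of a population is ``1 - sqrt(1 - band_freq)``,
keeping the dominant-marker estimator's generative assumption explicit.

Default scale mirrors a two-region comparative survey: 2 regions x 10
populations x 15 individuals x 308 loci, within-region differentiation
0.29 / 0.37, a between-region component of 0.14, isolation by distance
in the second (more isolated) region, and germination cells of 8 dishes
x 10 seeds with probabilities near one half.  All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .aflp import AFLPMatrix
from .germination import DEFAULT_TREATMENTS, GerminationDataset


@dataclass(frozen=True)
class TraitEffect:
    """Per-region location/scale for one simulated trait."""

    family: str                    # "student_t" or "gamma"
    mean: tuple[float, ...]        # one entry per region
    sd: tuple[float, ...]
    df: float = 10.0               # t tail weight
    lower: float | None = None     # truncation bound (resampled)
    integer: bool = False


def _default_trait_effects() -> dict[str, TraitEffect]:
    # magnitudes mirror the two-region survey the generator emulates
    return {
        "HA": TraitEffect("gamma", (34_610.0, 3_283.0), (34_000.0, 3_200.0)),
        "NI": TraitEffect("student_t", (23.0, 29.0), (7.0, 18.0), lower=5, integer=True),
        "CS": TraitEffect("student_t", (1_055.0, 1_435.0), (620.0, 560.0), lower=50),
        "CD": TraitEffect("student_t", (139.0, 1_599.0), (70.0, 460.0), lower=10),
        "NF": TraitEffect("student_t", (8.6, 20.8), (11.0, 18.0), lower=0),
        "NC": TraitEffect("student_t", (3.1, 3.7), (5.3, 4.7), lower=0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for all synthetic generators."""

    n_regions: int = 2
    pops_per_region: int = 10
    inds_per_pop: int = 15
    n_loci: int = 308
    f_within: tuple[float, ...] = (0.29, 0.37)
    f_between: float = 0.14
    ibd_region: int | None = 1          # index of the spatially ordered region
    region_names: tuple[str, ...] = ("R1", "R2")
    trait_effects: Mapping[str, TraitEffect] = field(
        default_factory=_default_trait_effects
    )
    germination_modes: tuple[tuple[float, ...], ...] = (
        (0.62, 0.55),
        (0.38, 0.31),
        (0.58, 0.51),
        (0.55, 0.48),
    )  # treatments x regions
    germination_concentration: float = 20.0
    dishes_per_cell: int = 8
    seeds_per_dish: int = 10
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.f_within) != self.n_regions:
            raise ValueError("f_within needs one value per region")
        if len(self.region_names) != self.n_regions:
            raise ValueError("region_names needs one name per region")
        for f in (*self.f_within, self.f_between):
            if not 0 <= f < 1:
                raise ValueError("differentiation parameters must lie in [0, 1)")
        if min(self.n_regions, self.pops_per_region, self.inds_per_pop, self.n_loci) < 1:
            raise ValueError("counts must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _bn_step(freq: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols beta drift: Beta(f(1-F)/F, (1-f)(1-F)/F), mean f."""
    if F <= 0:
        return freq.copy()
    f = np.clip(freq, 1e-4, 1 - 1e-4)
    c = (1 - F) / F
    return rng.beta(f * c, (1 - f) * c)


def simulate_aflp(
    config: SimulationConfig, seed: int | None = None
) -> tuple[AFLPMatrix, pd.DataFrame]:
    """Simulate a band-presence matrix and population coordinates (km grid).

    Returns the genotype matrix and a coordinate table indexed by
    population with columns ``region``, ``x_km``, ``y_km``.  Populations
    of the isolation-by-distance region sit on a line and drift
    accumulates stepwise along it; other regions drift in a single step
    and scatter within a 100 km box.  Regions are offset by 300 km.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = config.n_loci
    p_anc = rng.uniform(0.05, 0.95, L)     # ancestral band-allele frequency
    b_anc = 1 - (1 - p_anc) ** 2           # ancestral band frequency

    sample_ids, populations, rows = [], [], []
    region_of: dict[str, str] = {}
    coord_rows = []
    for r in range(config.n_regions):
        region = config.region_names[r]
        b_region = _bn_step(b_anc, config.f_between, rng)
        is_ibd = config.ibd_region is not None and r == config.ibd_region
        if is_ibd:
            # stepwise drift along a chain; per-step F calibrated so the
            # average pairwise differentiation matches f_within
            k = config.pops_per_region
            mean_steps = (k + 1) / 3  # mean |i-j| over pairs on a line
            f_step = 1 - (1 - config.f_within[r]) ** (1 / mean_steps)
            b_prev = b_region
            pop_freqs = []
            for _ in range(k):
                b_prev = _bn_step(b_prev, f_step, rng)
                pop_freqs.append(b_prev)
        else:
            pop_freqs = [
                _bn_step(b_region, config.f_within[r], rng)
                for _ in range(config.pops_per_region)
            ]
        for k_pop, b_pop in enumerate(pop_freqs):
            pop = f"{region}_P{k_pop + 1:02d}"
            region_of[pop] = region
            if is_ibd:
                x, y = 300.0 * r + 15.0 * k_pop, 0.0
            else:
                x = 300.0 * r + 100.0 * rng.random()
                y = 100.0 * rng.random()
            coord_rows.append({"population": pop, "region": region, "x_km": x, "y_km": y})
            draws = (
                rng.random((config.inds_per_pop, L)) < b_pop[None, :]
            ).astype(np.int8)
            for i in range(config.inds_per_pop):
                sample_ids.append(f"{pop}_I{i + 1:02d}")
                populations.append(pop)
            rows.append(draws)
    matrix = AFLPMatrix(
        np.vstack(rows),
        sample_ids,
        populations,
        region_of,
        [f"L{j + 1:03d}" for j in range(L)],
    )
    coords = pd.DataFrame(coord_rows).set_index("population")
    return matrix, coords


def simulate_population_table(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-population trait table with region-specific effects.

    Traits are drawn from the configured family (Student-t location/scale
    or gamma by moment matching); values below a trait's truncation bound
    are resampled at the bound's fold.  PD is derived as NI/HA.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for r in range(config.n_regions):
        region = config.region_names[r]
        for k in range(config.pops_per_region):
            row: dict[str, object] = {
                "population": f"{region}_P{k + 1:02d}",
                "region": region,
            }
            for name, eff in config.trait_effects.items():
                m, s = eff.mean[r], eff.sd[r]
                if eff.family == "gamma":
                    shape = (m / s) ** 2
                    v = rng.gamma(shape, m / shape)
                elif eff.family == "student_t":
                    v = m + s * rng.standard_t(eff.df)
                else:
                    raise ValueError(f"unknown trait family: {eff.family!r}")
                if eff.lower is not None and v < eff.lower:
                    v = eff.lower + abs(v - eff.lower) % max(m, 1.0)
                if eff.integer:
                    v = float(round(v))
                row[name] = v
            rows.append(row)
    df = pd.DataFrame(rows).set_index("population")
    if {"NI", "HA"} <= set(df.columns):
        df["PD"] = df["NI"] / df["HA"]
    return df


def simulate_germination(
    config: SimulationConfig, seed: int | None = None
) -> GerminationDataset:
    """Dish-level germination counts from the beta-binomial cell model.

    Dish probabilities follow a Beta with the configured cell mode and
    shared concentration; counts are Binomial(seeds_per_dish, pi).
    Cell modes are clipped away from {0, 1} by 1e-6.
    """
    if config.germination_concentration <= 2:
        raise ValueError("concentration must exceed 2")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    modes = np.asarray(config.germination_modes, dtype=float)
    if modes.shape != (len(config.treatments), config.n_regions):
        raise ValueError("germination_modes must be treatments x regions")
    modes = np.clip(modes, 1e-6, 1 - 1e-6)
    kappa = config.germination_concentration
    records = []
    for tj, treatment in enumerate(config.treatments):
        for r in range(config.n_regions):
            omega = modes[tj, r]
            a = omega * (kappa - 2) + 1
            b = (1 - omega) * (kappa - 2) + 1
            for dsh in range(config.dishes_per_cell):
                pi = rng.beta(a, b)
                y = rng.binomial(config.seeds_per_dish, pi)
                records.append(
                    {
                        "dish_id": f"{treatment}|{config.region_names[r]}|D{dsh + 1}",
                        "treatment": treatment,
                        "region": config.region_names[r],
                        "germinated": int(y),
                        "sown": config.seeds_per_dish,
                    }
                )
    return GerminationDataset(pd.DataFrame(records))
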