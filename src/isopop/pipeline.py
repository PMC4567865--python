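"""End-to-end orchestration of the comparative-isolation analyses.

``run_pipeline`` reads real inputs (genotype flat file, trait CSV,
germination CSV, coordinates CSV) or simulates them, runs every stage --
per-population diversity, hierarchical AMOVA, pairwise differentiation
and Mantel tests per region, Bayesian two-group trait comparisons,
the germination model with marginal contrasts, and the Spearman screen
-- and writes report tables plus a machine-readable summary.  A manifest
records the seed, package and library versions, the full configuration
and the SHA-256 of every output, so two runs with the same seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .aflp import AFLPMatrix, read_aflp_matrix
from .amova import amova_one_level, amova_two_level, binary_squared_distance, pairwise_phi_pt
from .bayes import TwoGroupModelSpec, fit_two_group, summarize_comparison
from .correlation import TRAIT_COLUMNS, correlation_screen, derive_traits, region_fruit_set
from .diversity import diversity_table
from .germination import (
    GerminationDataset,
    fit_germination,
    letter_groups,
    marginal_contrasts,
    plot_germination,
)
from .mantel import geographic_distances, mantel_test, planar_distances
from .simulate import (
    SimulationConfig,
    simulate_aflp,
    simulate_germination,
    simulate_population_table,
)

log = logging.getLogger("isopop.pipeline")

#: trait -> (likelihood, transform) for the region comparisons
DEFAULT_COMPARISONS: tuple[tuple[str, str, str], ...] = (
    ("HA", "gamma", "none"),
    ("NI", "student_t", "none"),
    ("PD", "student_t", "sqrt"),
    ("CS", "student_t", "none"),
    ("CD", "student_t", "none"),
    ("NF", "student_t", "none"),
    ("NC", "student_t", "sqrt"),
)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and input provenance."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs (paths) or a simulation config, plus analysis settings."""

    out_dir: str | Path = "isopop-results"
    inputs: Mapping[str, str] | None = None      # genotypes/traits/germination/coords
    simulation: SimulationConfig | None = None
    n_perm: int = 999
    compare: tuple[tuple[str, str, str], ...] = DEFAULT_COMPARISONS
    mcmc_chains: int = 4
    mcmc_draws: int = 20_000
    mcmc_warmup: int = 1_000
    germination_draws: int = 20_000
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("exactly one of inputs / simulation must be given")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None and not isinstance(sim, SimulationConfig):
            sim = SimulationConfig(**sim)
        compare = raw.pop("compare", None)
        kwargs: dict[str, Any] = dict(raw)
        if sim is not None:
            kwargs["simulation"] = sim
        if compare is not None:
            kwargs["compare"] = tuple(tuple(c) for c in compare)
        return cls(**kwargs)


@dataclass
class PipelineReport:
    """Paths of the written outputs plus the in-memory results."""

    out_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    results: dict[str, Any] = field(default_factory=dict)
    manifest: dict[str, Any] = field(default_factory=dict)


def _stage(name: str, provenance: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # propagate with stage context
                raise PipelineStageError(
                    f"stage {name!r} failed on {provenance}: {exc}"
                ) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return decorate


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.round(4).to_csv(path)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every applicable analysis stage and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out_dir=out_dir)
    rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(rng.integers(2**31 - 1))  # noqa: E731

    # ---- inputs -------------------------------------------------------
    matrix: AFLPMatrix | None = None
    coords: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    germ: GerminationDataset | None = None
    planar = False
    if config.simulation is not None:
        sim = config.simulation
        matrix, coords = simulate_aflp(sim, seed=stage_seed())
        traits = simulate_population_table(sim, seed=stage_seed())
        germ = simulate_germination(sim, seed=stage_seed())
        planar = True
        provenance = "simulated inputs"
    else:
        provenance = "file inputs"
        inp = dict(config.inputs or {})
        if "genotypes" in inp:
            matrix = read_aflp_matrix(inp["genotypes"], dialect=inp.get("dialect", "tsv"))
        if "traits" in inp:
            traits = pd.read_csv(inp["traits"], index_col=0)
        if "germination" in inp:
            germ = GerminationDataset(pd.read_csv(inp["germination"]))
        if "coords" in inp:
            coords = pd.read_csv(inp["coords"], index_col=0)
            planar = "x_km" in coords.columns

    # ---- genetic stages ----------------------------------------------
    if matrix is not None:
        div = _stage("diversity", provenance)(diversity_table)(matrix)
        _write_csv(out_dir / "diversity.csv", div)
        report.outputs["diversity"] = out_dir / "diversity.csv"
        report.results["diversity"] = div
        if traits is not None:
            joined = traits.join(div[["He", "I", "PL"]], how="left")
            traits = joined

        @_stage("amova", provenance)
        def _amova():
            d = binary_squared_distance(matrix)
            pops = list(matrix.populations)
            regions = list(matrix.regions_per_sample())
            blocks = {}
            blocks["all_populations"] = amova_one_level(
                d, pops, n_perm=config.n_perm, seed=stage_seed()
            )
            if len(set(regions)) >= 2:
                blocks["three_level"] = amova_two_level(
                    d, pops, regions, n_perm=config.n_perm, seed=stage_seed()
                )
                for region in dict.fromkeys(regions):
                    idx = [i for i, r in enumerate(regions) if r == region]
                    sub = d.submatrix([matrix.sample_ids[i] for i in idx])
                    blocks[f"region:{region}"] = amova_one_level(
                        sub, [pops[i] for i in idx], n_perm=config.n_perm,
                        seed=stage_seed(),
                    )
            return blocks

        blocks = _amova()
        rows = []
        for name, res in blocks.items():
            for s in res.strata:
                rows.append(
                    {
                        "analysis": name,
                        "stratum": s.name,
                        "df": s.df,
                        "SS": s.ss,
                        "MS": s.ms,
                        "percent": res.percentages[s.name],
                    }
                )
            for phi_name, value in res.phi.items():
                rows.append(
                    {
                        "analysis": name,
                        "stratum": phi_name,
                        "df": "",
                        "SS": "",
                        "MS": value,
                        "percent": res.perm_p.get(phi_name, ""),
                    }
                )
        amova_df = pd.DataFrame(rows).set_index(["analysis", "stratum"])
        _write_csv(out_dir / "amova.csv", amova_df)
        report.outputs["amova"] = out_dir / "amova.csv"
        report.results["amova"] = blocks

        # ---- Mantel per region ---------------------------------------
        if coords is not None:
            @_stage("mantel", provenance)
            def _mantel():
                out = {}
                for region in matrix.region_labels:
                    pops_r = [
                        p for p in matrix.population_labels
                        if matrix.region_of[p] == region
                    ]
                    if len(pops_r) < 4:
                        continue
                    idx = [
                        i for i, p in enumerate(matrix.populations) if p in pops_r
                    ]
                    sub_ids = [matrix.sample_ids[i] for i in idx]
                    sub = AFLPMatrix(
                        matrix.genotypes[idx],
                        sub_ids,
                        [matrix.populations[i] for i in idx],
                        {p: region for p in pops_r},
                        matrix.locus_ids,
                    ) if len(pops_r) >= 2 else None
                    phi = pairwise_phi_pt(sub).matrix
                    cr = coords.loc[list(phi.labels)]
                    geo = planar_distances(cr) if planar else geographic_distances(cr)
                    res = mantel_test(
                        phi, geo, n_perm=config.n_perm, seed=stage_seed(), exact=False
                    )
                    out[region] = {"r": res.r, "p": res.p, "n_perm": res.n_perm}
                return out

            mantel_res = _mantel()
            _write_json(out_dir / "mantel.json", mantel_res)
            report.outputs["mantel"] = out_dir / "mantel.json"
            report.results["mantel"] = mantel_res

    # ---- trait stages -------------------------------------------------
    if traits is not None:
        traits = _stage("derive_traits", provenance)(derive_traits)(traits)
        regions = list(dict.fromkeys(traits["region"]))

        @_stage("compare", provenance)
        def _compare():
            out = {}
            if len(regions) != 2:
                return out
            a = traits[traits["region"] == regions[0]]
            b = traits[traits["region"] == regions[1]]
            for trait, likelihood, transform in config.compare:
                if trait not in traits.columns:
                    continue
                va = a[trait].dropna().to_numpy()
                vb = b[trait].dropna().to_numpy()
                if len(va) < 3 or len(vb) < 3:
                    continue
                spec = TwoGroupModelSpec(
                    likelihood=likelihood,
                    transform=transform,
                    chains=config.mcmc_chains,
                    draws=config.mcmc_draws,
                    warmup=config.mcmc_warmup,
                )
                draws = fit_two_group(va, vb, spec, seed=stage_seed())
                summ = summarize_comparison(draws)
                entry = {
                    "groups": [regions[0], regions[1]],
                    "likelihood": likelihood,
                    "transform": transform,
                    "mean_diff": summ.mean_diff,
                    "hdi": [summ.hdi_low, summ.hdi_high],
                    "credible": summ.credible,
                    "effect_size": summ.effect_size,
                    "warnings": draws.warnings,
                }
                if transform == "sqrt":
                    back = summarize_comparison(draws, difference="diff_original")
                    entry["back_transformed"] = {
                        "mean_diff": back.mean_diff,
                        "hdi": [back.hdi_low, back.hdi_high],
                        "credible": back.credible,
                    }
                out[trait] = entry
            return out

        comparisons = _compare()
        _write_json(out_dir / "comparisons.json", comparisons)
        report.outputs["comparisons"] = out_dir / "comparisons.json"
        report.results["comparisons"] = comparisons

        @_stage("correlation", provenance)
        def _correlate():
            available = [v for v in TRAIT_COLUMNS if v in traits.columns]
            usable = [
                v for v in available
                if traits[v].notna().sum() >= 4 and traits[v].nunique() > 1
            ]
            screens = {"all": correlation_screen(traits, usable, subset="all")}
            for region in regions:
                sub = traits[traits["region"] == region]
                usable_r = [
                    v for v in usable
                    if sub[v].notna().sum() >= 4 and sub[v].nunique() > 1
                ]
                screens[region] = correlation_screen(traits, usable_r, subset=region)
            return screens

        screens = _correlate()
        for name, cm in screens.items():
            safe = name.replace("/", "_")
            _write_csv(out_dir / f"correlations_{safe}.csv", cm.stars())
            report.outputs[f"correlations_{safe}"] = out_dir / f"correlations_{safe}.csv"
        report.results["correlations"] = screens
        report.results["region_fruit_set"] = region_fruit_set(traits).to_dict()
        report.results["region_means"] = (
            traits.groupby("region").mean(numeric_only=True).to_dict()
        )

    # ---- germination --------------------------------------------------
    if germ is not None:
        @_stage("germination", provenance)
        def _germ():
            post = fit_germination(
                germ,
                seed=stage_seed(),
                chains=config.mcmc_chains,
                draws=config.germination_draws,
                warmup=config.mcmc_warmup,
            )
            tc = marginal_contrasts(post, "treatment")
            rc = marginal_contrasts(post, "region")
            letters = letter_groups(tc)
            cell_summary = {}
            for tj, t in enumerate(post.treatments):
                for rj, r in enumerate(post.regions):
                    draws = post.cell_theta[:, :, tj, rj].reshape(-1)
                    cell_summary[f"{t}|{r}"] = {
                        "median": float(np.median(draws)),
                        "mean": float(draws.mean()),
                    }
            payload = {
                "cells": cell_summary,
                "treatment_contrasts": [
                    {
                        "pair": list(c.pair),
                        "median": c.median,
                        "hdi": [c.hdi_low, c.hdi_high],
                        "credible": c.credible,
                    }
                    for c in tc
                ],
                "region_contrasts": [
                    {
                        "pair": list(c.pair),
                        "median": c.median,
                        "hdi": [c.hdi_low, c.hdi_high],
                        "credible": c.credible,
                    }
                    for c in rc
                ],
                "letters": letters,
                "warnings": post.warnings,
            }
            return post, payload

        post, payload = _germ()
        _write_json(out_dir / "germination.json", payload)
        report.outputs["germination"] = out_dir / "germination.json"
        report.results["germination"] = payload
        if config.make_plots:
            plot_germination(post, out_dir / "germination.png")
            report.outputs["germination_plot"] = out_dir / "germination.png"

    # ---- manifest -----------------------------------------------------
    manifest = {
        "seed": config.seed,
        "versions": {
            "isopop": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        # out_dir is omitted so equal-seed runs yield byte-identical manifests
        "config": json.loads(
            json.dumps(
                {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"},
                default=_json_default,
                sort_keys=True,
            )
        ),
        "outputs": {
            name: {
                "path": str(path.name),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for name, path in sorted(report.outputs.items())
        },
    }
    _write_json(out_dir / "manifest.json", manifest)
    report.outputs["manifest"] = out_dir / "manifest.json"
    report.manifest = manifest
    return report
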