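"""Spearman rank-correlation screen across population-level variables.

The screen relates population-structure variables (habitat area HA in
m^2, number of individuals NI, population density PD in cushions per
m^2, cushion size CS in cm^2, cushion density CD in shoots per m^2),
reproductive traits (flowers NF, capsules NC, fruit set FS) and genetic
variation (He, I, %PL), for all populations together or per region.

Ties receive mid-ranks and the two-sided p-value uses the t
approximation with n - 2 degrees of freedom (scipy's convention); an
exact permutation p-value is available for small samples.  No
multiple-testing correction is applied anywhere in the screen -- the
coefficients are reported raw, with significance stars at 0.05 / 0.01,
and should be read accordingly.

Derived traits: PD = NI / HA, per-population fruit set FS = NC / NF
(undefined when no flowers were produced).  A regional fruit set can be
defined two ways -- the ratio of regional means (mean NC / mean NF) or
the mean of per-population ratios; both are provided because they differ
whenever flower production varies among populations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_COLUMNS = ("HA", "NI", "PD", "CS", "CD", "NF", "NC", "He", "I", "PL")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Spearman results for an ordered variable list."""

    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """Coefficient strings with significance stars (0.05 *, 0.01 **)."""

        def fmt(r, p):
            if np.isnan(r):
                return ""
            star = "**" if p < 0.01 else "*" if p < 0.05 else ""
            return f"{r:.3f}{star}"

        out = self.rho.copy().astype(object)
        for a in self.variables:
            for b in self.variables:
                out.loc[a, b] = fmt(self.rho.loc[a, b], self.p.loc[a, b])
        return out


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns PD (= NI/HA) and FS (= NC/NF) to a trait table.

    ``HA`` must be strictly positive; FS is left missing for populations
    that produced no flowers.  When a PD column is already present, it is
    cross-checked against NI/HA and a mismatch raises a warning (not an
    error), since printed tables carry rounded densities.
    """
    df = table.copy()
    if (df["HA"] <= 0).any():
        bad = df.index[df["HA"] <= 0].tolist()
        raise ValueError(f"habitat area must be positive (violated by {bad})")
    derived_pd = df["NI"] / df["HA"]
    if "PD" in df.columns:
        rel = np.abs(df["PD"] - derived_pd) / derived_pd
        if (rel > 0.5).any():
            import warnings

            warnings.warn(
                "PD column is inconsistent with NI/HA for some populations",
                stacklevel=2,
            )
    df["PD"] = derived_pd
    if {"NF", "NC"} <= set(df.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            fs = df["NC"] / df["NF"]
        df["FS"] = fs.where(df["NF"] > 0)
    return df


def region_fruit_set(table: pd.DataFrame, definition: str = "ratio_of_means") -> pd.Series:
    """Regional fruit set, per region.

    ``ratio_of_means``: (regional mean NC) / (regional mean NF) -- the
    definition consistent with tabled regional summaries.
    ``mean_of_ratios``: mean of the per-population NC/NF values.
    """
    grouped = table.groupby("region")
    if definition == "ratio_of_means":
        return grouped["NC"].mean() / grouped["NF"].mean()
    if definition == "mean_of_ratios":
        tab = derive_traits(table) if "FS" not in table.columns else table
        return tab.groupby("region")["FS"].mean()
    raise ValueError(f"unknown definition: {definition!r}")


def spearman(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> SpearmanResult:
    """Spearman rank correlation with mid-rank ties.

    Pairs with a missing value in either variable are dropped.  The
    default p-value is the two-sided t approximation; ``exact=True``
    enumerates all permutations (n <= 10) and returns the exact two-sided
    permutation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("Spearman correlation requires at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero rank variance: constant variable")
    rho, p = stats.spearmanr(x, y)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p is limited to n <= 10")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a @ b) / math.sqrt((a @ a) * (b @ b))

        obs = abs(corr(rx, ry))
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            hits += abs(corr(rx, ry[list(perm)])) >= obs - 1e-12
            total += 1
        p = hits / total
    return SpearmanResult(rho=float(rho), p=float(p), n=int(n))


def correlation_screen(
    table: pd.DataFrame,
    variables: Sequence[str] = TRAIT_COLUMNS,
    subset: str = "all",
) -> CorrelationMatrix | dict[str, CorrelationMatrix]:
    """Spearman screen over all variable pairs.

    ``subset="all"`` uses the whole table; ``subset="by-region"`` returns
    one matrix per region; a region label restricts to that region.
    """
    variables = tuple(variables)
    unknown = [v for v in variables if v not in table.columns]
    if unknown:
        raise KeyError(f"unknown variable(s): {unknown}")
    if subset == "by-region":
        return {
            str(region): _screen(sub, variables)
            for region, sub in table.groupby("region")
        }
    if subset != "all":
        sub = table[table["region"] == subset]
        if sub.empty:
            raise KeyError(f"unknown region: {subset!r}")
        return _screen(sub, variables)
    return _screen(table, variables)


def _screen(table: pd.DataFrame, variables: tuple[str, ...]) -> CorrelationMatrix:
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    n = pd.DataFrame(
        np.full((k, k), len(table)), index=variables, columns=variables, dtype=int
    )
    for a, b in itertools.combinations(variables, 2):
        res = spearman(table[a], table[b])
        rho.loc[a, b] = rho.loc[b, a] = res.rho
        p.loc[a, b] = p.loc[b, a] = res.p
        n.loc[a, b] = n.loc[b, a] = res.n
    return CorrelationMatrix(variables=variables, rho=rho, p=p, n=n)
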