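"""Hierarchical Bayesian two-way model of dish-level germination counts.

Seeds are germinated in petri dishes (replicates) nested in cells of a
treatment x region design.  The model is a Bayesian analogue of a two-way
logistic ANOVA with overdispersion:

* dish count ~ Binomial(sown, pi_dish),
* pi_dish ~ Beta with mode omega_cell and shared concentration kappa
  (``a = omega (kappa - 2) + 1``, ``b = (1 - omega)(kappa - 2) + 1``),
* logit(omega_cell) = grand mean + treatment + region + interaction
  deflections, each deflection family shrunk by its own scale
  hyperparameter (vague gamma priors on the precisions and on kappa - 2,
  vague normal on the grand mean).

The mode/concentration parameterisation keeps the concentration shared
between cells.  Dish probabilities and the deflection-scale precisions
have conjugate full conditionals and are Gibbs-sampled; the remaining
scalars use adaptive random-walk Metropolis steps.  Deflections are
sampled unconstrained and recentred to sum-to-zero form in every retained
draw.  Marginal treatment/region contrasts are formed draw-wise on the
probability scale and judged credible when their 95% HDI excludes zero;
a compact letter display summarises the pairwise pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import betaln, expit

from .bayes import hdi

DEFAULT_TREATMENTS = ("14HD-light", "22HD-light", "22/14-light", "22/14-dark")


@dataclass(frozen=True)
class GerminationDataset:
    """Dish-level germination counts in a treatment x region design."""

    records: pd.DataFrame

    def __init__(self, records: pd.DataFrame) -> None:
        required = {"dish_id", "treatment", "region", "germinated", "sown"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = records.copy().reset_index(drop=True)
        if df["dish_id"].duplicated().any():
            raise ValueError("duplicate dish ids")
        if (df["germinated"] < 0).any() or (df["germinated"] > df["sown"]).any():
            raise ValueError("need 0 <= germinated <= sown for every dish")
        if (df["sown"] <= 0).any():
            raise ValueError("sown must be positive")
        object.__setattr__(self, "records", df)

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.records["treatment"]))

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.records["region"]))

    def cell_counts(self) -> pd.DataFrame:
        return self.records.groupby(["treatment", "region"]).size().unstack()


@dataclass
class GerminationPosterior:
    """Posterior draws for the two-way germination model."""

    treatments: tuple[str, ...]
    regions: tuple[str, ...]
    cell_theta: np.ndarray            # (chains, draws, T, R) cell modes omega
    grand_mean: np.ndarray            # (chains, draws), logit scale
    treatment_deflections: np.ndarray  # (chains, draws, T), sum to zero
    region_deflections: np.ndarray     # (chains, draws, R), sum to zero
    interaction_deflections: np.ndarray  # (chains, draws, T, R)
    scales: dict[str, np.ndarray]     # deflection-scale draws per family
    concentration: np.ndarray         # (chains, draws), kappa > 2
    ess: dict[str, float]
    rhat: dict[str, float]
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Contrast:
    """Draw-wise difference between two marginal germination probabilities."""

    pair: tuple[str, str]
    draws: np.ndarray
    hdi_low: float
    hdi_high: float
    credible: bool
    median: float


def fit_germination(
    data: GerminationDataset,
    seed: int | None = None,
    chains: int = 4,
    draws: int = 20_000,
    warmup: int = 1_000,
) -> GerminationPosterior:
    """Sample the hierarchical two-way beta-logistic model.

    Dish probabilities and deflection-scale precisions are Gibbs updates;
    the grand mean, deflections and log(kappa - 2) use adaptive
    random-walk Metropolis steps tuned during warmup.  Boundary data
    (all-zero / all-full dishes) fit but trigger a diagnostics warning.
    """
    df = data.records
    treatments, regions = data.treatments, data.regions
    T, R = len(treatments), len(regions)
    if T < 2 or R < 2:
        raise ValueError("need at least 2 treatments and 2 regions")
    cells = data.cell_counts()
    if cells.isna().any().any() or (cells < 2).any().any():
        raise ValueError("every treatment x region cell needs at least 2 dishes")

    y = df["germinated"].to_numpy(float)
    n = df["sown"].to_numpy(float)
    t_idx = np.array([treatments.index(t) for t in df["treatment"]])
    r_idx = np.array([regions.index(r) for r in df["region"]])
    cell_idx = t_idx * R + r_idx
    D, K = len(df), T * R
    C = chains
    rng = np.random.default_rng(seed)

    boundary = bool((y == 0).all() or (y == n).all())

    # --- state ---------------------------------------------------------
    emp = np.clip((y.sum() + 1) / (n.sum() + 2), 1e-3, 1 - 1e-3)
    beta0 = np.log(emp / (1 - emp)) + 0.2 * rng.standard_normal(C)
    at = 0.1 * rng.standard_normal((C, T))
    ar = 0.1 * rng.standard_normal((C, R))
    aint = 0.1 * rng.standard_normal((C, T, R))
    tau = {"treatment": np.ones(C), "region": np.ones(C), "interaction": np.ones(C)}
    z = np.log(18.0) * np.ones(C) + 0.1 * rng.standard_normal(C)  # kappa = 2 + e^z

    a_tau, b_tau = 0.01, 0.01        # vague gamma priors on precisions
    a_k, b_k = 0.01, 0.01            # vague gamma prior on kappa - 2
    beta0_sd = 5.0                   # vague normal prior on the grand mean

    def eta_grid(beta0_, at_, ar_, aint_):
        return beta0_[:, None, None] + at_[:, :, None] + ar_[:, None, :] + aint_

    def current_loglik(beta0_, at_, ar_, aint_, kappa_):
        # dish probabilities are marginalised analytically: with
        # pi ~ Beta(mode omega, concentration kappa), dish counts are
        # beta-binomial, so the likelihood is exact without sampling pi
        om = expit(eta_grid(beta0_, at_, ar_, aint_)).reshape(C, K)
        a = om * (kappa_[:, None] - 2) + 1
        b = (1 - om) * (kappa_[:, None] - 2) + 1
        ad, bd = a[:, cell_idx], b[:, cell_idx]
        return (
            betaln(y[None, :] + ad, (n - y)[None, :] + bd) - betaln(ad, bd)
        ).sum(axis=1)

    n_scalar = 1 + T + R + T * R + 1
    log_step = np.full((C, n_scalar), np.log(0.3))

    keep = {
        "eta": np.empty((C, draws, T, R)),
        "kappa": np.empty((C, draws)),
        "sigma_t": np.empty((C, draws)),
        "sigma_r": np.empty((C, draws)),
        "sigma_i": np.empty((C, draws)),
    }

    for it in range(warmup + draws):
        adapting = it < warmup
        gamma = (it + 1) ** -0.6 if adapting else 0.0
        kappa = 2 + np.exp(z)
        lp_like = current_loglik(beta0, at, ar, aint, kappa)

        # Metropolis: grand mean, deflections, kappa
        upd = 0

        def mh_step(value_getter, value_setter, proposal_setter, prior_fn, upd_i):
            nonlocal lp_like
            cur_prior = prior_fn(value_getter())
            prop_state = proposal_setter(np.exp(log_step[:, upd_i]) * rng.standard_normal(C))
            lp_prop = current_loglik(*prop_state[:4], prop_state[4])
            dlp = (lp_prop + prior_fn(prop_state[5])) - (lp_like + cur_prior)
            accept = np.log(rng.random(C)) < dlp
            value_setter(accept, prop_state[5])
            lp_like = np.where(accept, lp_prop, lp_like)
            if adapting:
                log_step[:, upd_i] += gamma * (np.exp(np.minimum(0.0, dlp)) - 0.44)

        # beta0
        def set_beta0(accept, new):
            beta0[accept] = new[accept]

        mh_step(
            lambda: beta0,
            set_beta0,
            lambda eps: (beta0 + eps, at, ar, aint, kappa, beta0 + eps),
            lambda v: -0.5 * v**2 / beta0_sd**2,
            upd,
        )
        upd += 1
        # treatment deflections
        for j in range(T):
            def set_at(accept, new, j=j):
                at[accept, j] = new[accept]

            def prop_at(eps, j=j):
                new = at.copy()
                new[:, j] += eps
                return (beta0, new, ar, aint, kappa, new[:, j])

            mh_step(lambda j=j: at[:, j], set_at, prop_at,
                    lambda v: -0.5 * tau["treatment"] * v**2, upd)
            upd += 1
        # region deflections
        for j in range(R):
            def set_ar(accept, new, j=j):
                ar[accept, j] = new[accept]

            def prop_ar(eps, j=j):
                new = ar.copy()
                new[:, j] += eps
                return (beta0, at, new, aint, kappa, new[:, j])

            mh_step(lambda j=j: ar[:, j], set_ar, prop_ar,
                    lambda v: -0.5 * tau["region"] * v**2, upd)
            upd += 1
        # interaction deflections
        for tj, rj in itertools.product(range(T), range(R)):
            def set_ai(accept, new, tj=tj, rj=rj):
                aint[accept, tj, rj] = new[accept]

            def prop_ai(eps, tj=tj, rj=rj):
                new = aint.copy()
                new[:, tj, rj] += eps
                return (beta0, at, ar, new, kappa, new[:, tj, rj])

            mh_step(lambda tj=tj, rj=rj: aint[:, tj, rj], set_ai, prop_ai,
                    lambda v: -0.5 * tau["interaction"] * v**2, upd)
            upd += 1
        # kappa via z = log(kappa - 2)
        def set_z(accept, new):
            z[accept] = new[accept]

        mh_step(
            lambda: z,
            set_z,
            lambda eps: (beta0, at, ar, aint, 2 + np.exp(z + eps), z + eps),
            lambda v: a_k * v - b_k * np.exp(v),
            upd,
        )

        # Gibbs: deflection-scale precisions
        tau["treatment"] = rng.gamma(a_tau + T / 2, 1 / (b_tau + (at**2).sum(1) / 2))
        tau["region"] = rng.gamma(a_tau + R / 2, 1 / (b_tau + (ar**2).sum(1) / 2))
        tau["interaction"] = rng.gamma(
            a_tau + T * R / 2, 1 / (b_tau + (aint**2).sum((1, 2)) / 2)
        )

        if not adapting:
            s = it - warmup
            keep["eta"][:, s] = eta_grid(beta0, at, ar, aint)
            keep["kappa"][:, s] = 2 + np.exp(z)
            keep["sigma_t"][:, s] = 1 / np.sqrt(tau["treatment"])
            keep["sigma_r"][:, s] = 1 / np.sqrt(tau["region"])
            keep["sigma_i"][:, s] = 1 / np.sqrt(tau["interaction"])

    # recentre deflections to sum-to-zero form, per retained draw
    eta = keep["eta"]
    m = eta.mean(axis=(2, 3))
    bt = eta.mean(axis=3) - m[..., None]
    br = eta.mean(axis=2) - m[..., None]
    bint = eta - m[..., None, None] - bt[..., :, None] - br[..., None, :]
    theta = expit(eta)

    ess: dict[str, float] = {}
    rhat: dict[str, float] = {}
    for tj, rj in itertools.product(range(T), range(R)):
        name = f"theta[{treatments[tj]},{regions[rj]}]"
        ess[name] = float(az.ess(theta[:, :, tj, rj]))
        rhat[name] = float(az.rhat(theta[:, :, tj, rj]))
    ess["kappa"] = float(az.ess(keep["kappa"]))
    rhat["kappa"] = float(az.rhat(keep["kappa"]))
    warnings: list[str] = []
    if boundary:
        warnings.append("boundary data: all dishes at 0 or all at full germination")
    low = [k for k, v in ess.items() if v < 10_000]
    if low:
        warnings.append(f"effective sample size below 10k for: {', '.join(sorted(low))}")
    bad = [k for k, v in rhat.items() if v > 1.01]
    if bad:
        warnings.append(f"split R-hat above 1.01 for: {', '.join(sorted(bad))}")

    return GerminationPosterior(
        treatments=treatments,
        regions=regions,
        cell_theta=theta,
        grand_mean=m,
        treatment_deflections=bt,
        region_deflections=br,
        interaction_deflections=bint,
        scales={
            "treatment": keep["sigma_t"],
            "region": keep["sigma_r"],
            "interaction": keep["sigma_i"],
        },
        concentration=keep["kappa"],
        ess=ess,
        rhat=rhat,
        warnings=warnings,
    )


def marginal_contrasts(
    post: GerminationPosterior, factor: str, hdi_mass: float = 0.95
) -> list[Contrast]:
    """Pairwise contrasts of marginal germination probabilities.

    The marginal probability of a level averages the cell probabilities
    over the levels of the other factor (balanced average).
    """
    if factor == "treatment":
        levels = post.treatments
        marg = post.cell_theta.mean(axis=3)  # (C, S, T)
    elif factor == "region":
        levels = post.regions
        marg = post.cell_theta.mean(axis=2)  # (C, S, R)
    else:
        raise ValueError(f"unknown factor: {factor!r} (use 'treatment' or 'region')")
    out = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        diff = (marg[:, :, i] - marg[:, :, j]).reshape(-1)
        low, high = hdi(diff, hdi_mass)
        out.append(
            Contrast(
                pair=(levels[i], levels[j]),
                draws=diff,
                hdi_low=low,
                hdi_high=high,
                credible=bool(low > 0 or high < 0),
                median=float(np.median(diff)),
            )
        )
    return out


def letter_groups(contrasts: Sequence[Contrast]) -> dict[str, str]:
    """Compact letter display from pairwise credibility flags.

    Levels sharing a letter have no credible pairwise difference
    (insert-and-absorb algorithm).  All pairwise contrasts of the factor
    must be present.
    """
    levels: list[str] = []
    for c in contrasts:
        for lev in c.pair:
            if lev not in levels:
                levels.append(lev)
    expected = {frozenset(p) for p in itertools.combinations(levels, 2)}
    got = {frozenset(c.pair) for c in contrasts}
    if expected - got:
        raise ValueError("all pairwise contrasts of the factor are required")
    groups: list[set[str]] = [set(levels)]
    for c in contrasts:
        if not c.credible:
            continue
        a, b = c.pair
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb groups contained in others
        groups = [
            g
            for g in new_groups
            if g and not any(g < h for h in new_groups)
        ]
        # drop duplicates
        uniq: list[set[str]] = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    groups.sort(key=lambda g: min(levels.index(l) for l in g))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {lev: "" for lev in levels}
    for letter, g in zip(letters, groups):
        for lev in g:
            out[lev] += letter
    return {lev: "".join(sorted(s)) for lev, s in out.items()}


def plot_germination(
    post: GerminationPosterior, path, hdi_mass: float = 0.95
) -> None:
    """Bar chart of cell germination probabilities with HDI whiskers.

    Bars are grouped by treatment, one bar per region; lowercase letters
    above the groups mark credible treatment differences.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    T, R = len(post.treatments), len(post.regions)
    letters = letter_groups(marginal_contrasts(post, "treatment", hdi_mass))
    fig, ax = plt.subplots(figsize=(1.8 * T + 1, 4))
    width = 0.8 / R
    for rj, region in enumerate(post.regions):
        xs, means, lo, hi = [], [], [], []
        for tj in range(T):
            draws = post.cell_theta[:, :, tj, rj].reshape(-1)
            l, h = hdi(draws, hdi_mass)
            xs.append(tj + (rj - (R - 1) / 2) * width)
            means.append(np.median(draws))
            lo.append(np.median(draws) - l)
            hi.append(h - np.median(draws))
        ax.bar(xs, means, width=width * 0.9, label=region,
               yerr=[lo, hi], capsize=3,
               color="white" if rj == 0 else "0.6", edgecolor="black")
    for tj, treat in enumerate(post.treatments):
        top = max(
            hdi(post.cell_theta[:, :, tj, rj].reshape(-1), hdi_mass)[1]
            for rj in range(R)
        )
        ax.text(tj, top + 0.04, letters[treat], ha="center")
    ax.set_xticks(range(T))
    ax.set_xticklabels(post.treatments, rotation=20)
    ax.set_ylabel("germination probability")
    ax.set_ylim(0, 1)
    ax.legend(title="region")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
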