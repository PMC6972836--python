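"""Synthetic community generation and the HPD-width study-design tool.

The generator mirrors the model's own generative story: site effects
alpha_i ~ N(mu_alpha, sigma_alpha^2), species effects beta_j ~ N(mu_beta,
sigma_beta^2), latent factors and loadings elementwise standard normal (with
the identifiability constraints applied to the loadings), and responses drawn
from the chosen observation family at the implied mean.  Optionally the
species pool is augmented with *rare* species whose effects are centred far
below zero (default N(-4, 0.5^2)), producing the sparse, mostly-absent
columns typical of real community tables.

`hpd_width_design` is the study-design tool: for a factorial grid of (n, p)
it repeatedly simulates communities, fits the latent factor model, and
reports the mean 95% HPD width of the latent factors — the expected
ordination precision of a study with that shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .model_core import CommunityMatrix, LatentState, ModelSpec, PriorSpec
from .posterior import align_rotation, mean_hpd_width
from .samplers import MCMCSettings, fit, identify_rotation

__all__ = [
    "RareSpec",
    "SimulationDesign",
    "generate_community",
    "degrade_to_presence",
    "occurrence_summaries",
    "estimate_population_params",
    "hpd_width_design",
]


@dataclass
class RareSpec:
    """Rare-species augmentation: p_rare extra species with low effects."""

    p_rare: int
    mu: float = -4.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.p_rare < 0 or self.sigma < 0:
            raise ValueError("p_rare and sigma must be non-negative")


@dataclass
class SimulationDesign:
    """Generative-model settings for one simulation scenario."""

    family: str = "binary"  # binary | poisson | negbin | ordinal
    n: int = 20
    p: int = 20
    mu_alpha: float = 0.0
    sigma_alpha: float = 1.0
    mu_beta: float = 0.0
    sigma_beta: float = 1.0
    q: int = 2
    rare: Optional[RareSpec] = None
    reps: int = 50
    seed: int = 0
    K: Optional[int] = None  # ordinal classes
    cutoffs: Optional[np.ndarray] = None  # ordinal; default equiprobable
    omega: float = 1.0  # negbin generation only

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1 or self.reps < 1:
            raise ValueError("n, p and reps must be at least 1")
        if min(self.sigma_alpha, self.sigma_beta) < 0:
            raise ValueError("effect SDs must be non-negative")
        if self.family not in ("binary", "poisson", "negbin", "ordinal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "ordinal":
            if self.K is None or self.K < 2:
                raise ValueError("ordinal designs require K >= 2")
            if self.cutoffs is None:
                self.cutoffs = ndtri(np.arange(1, self.K) / self.K)
            self.cutoffs = np.asarray(self.cutoffs, dtype=float)

    @property
    def p_total(self) -> int:
        return self.p + (self.rare.p_rare if self.rare else 0)


def _rng_for(design: SimulationDesign, replicate: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, replicate)
    return np.random.default_rng(np.random.SeedSequence((design.seed, replicate)))




def generate_community(design: SimulationDesign, replicate: int = 0):
    """Simulate one (CommunityMatrix, true LatentState) pair.

    Deterministic given (design.seed, replicate); distinct replicates use
    independent streams.
    """
    rng = _rng_for(design, replicate)
    n, q = design.n, design.q
    p_tot = design.p_total
    alpha = rng.normal(design.mu_alpha, design.sigma_alpha, size=n)
    beta = rng.normal(design.mu_beta, design.sigma_beta, size=design.p)
    if design.rare and design.rare.p_rare:
        beta_rare = rng.normal(design.rare.mu, design.rare.sigma, size=design.rare.p_rare)
        beta = np.concatenate([beta, beta_rare])
    # latent factors and loadings elementwise standard normal; the stored
    # truth is the rotation-identified representative (zero upper triangle,
    # positive diagonal), matching what a fit reports
    Z, Theta = identify_rotation(
        rng.standard_normal((n, q)), rng.standard_normal((p_tot, q))
    )
    eta = alpha[:, None] + beta[None, :] + Z @ Theta.T
    if design.family == "binary":
        y = (eta + rng.standard_normal((n, p_tot)) > 0).astype(np.int64)
        Y = CommunityMatrix(y, family="binary")
    elif design.family == "poisson":
        mu = np.exp(np.clip(eta, None, 20.0))
        Y = CommunityMatrix(rng.poisson(mu), family="count")
    elif design.family == "negbin":
        mu = np.exp(np.clip(eta, None, 20.0))
        r = 1.0 / design.omega
        lam = rng.gamma(shape=r, scale=mu / r)  # gamma-Poisson mixture
        Y = CommunityMatrix(rng.poisson(lam), family="count")
    else:  # ordinal
        zs = eta + rng.standard_normal((n, p_tot))
        y = 1 + np.searchsorted(design.cutoffs, zs.ravel()).reshape(n, p_tot)
        Y = CommunityMatrix(y, family="ordinal", n_levels=design.K)
    state = LatentState(
        alpha=alpha, beta=beta, Z=Z, Theta=Theta,
        omega=design.omega if design.family == "negbin" else None,
        cutoffs=design.cutoffs if design.family == "ordinal" else None,
    )
    return Y, state


def degrade_to_presence(Y: CommunityMatrix) -> CommunityMatrix:
    """Map counts to presence/absence (1 iff count > 0), preserving labels."""
    if Y.family != "count":
        raise ValueError("degrade_to_presence expects a count matrix")
    return CommunityMatrix(
        (Y.values > 0).astype(np.int64), family="binary",
        site_labels=list(Y.site_labels), species_labels=list(Y.species_labels),
    )


def occurrence_summaries(design: SimulationDesign, mc_draws: int = 100_000, seed: Optional[int] = None):
    """Monte Carlo occurrence analytics for the (rare) species of a design.

    Simulates ``mc_draws`` independent species, each observed at ``design.n``
    sites under the probit generative model, and returns the marginal
    probability a species is present at a site and the probability it is
    absent from every site, with standard errors.  When the design carries a
    rare-species spec the rare effect distribution is used; otherwise the
    common one.
    """
    if design.family != "binary":
        raise ValueError("occurrence summaries are defined for the binary family")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n, q = design.n, design.q
    if design.rare is not None:
        mu_b, sd_b = design.rare.mu, design.rare.sigma
    else:
        mu_b, sd_b = design.mu_beta, design.sigma_beta
    S = int(mc_draws)
    present_frac = np.empty(S)
    # batch over species to bound memory
    batch = max(1, min(S, 20_000_000 // max(n * (q + 2), 1)))
    zero_count = 0
    idx = 0
    while idx < S:
        b = min(batch, S - idx)
        beta = rng.normal(mu_b, sd_b, size=(b, 1))
        theta = rng.standard_normal((b, q))
        alpha = rng.normal(design.mu_alpha, design.sigma_alpha, size=(b, n))
        Z = rng.standard_normal((b, n, q))
        eta = alpha + beta + np.einsum("bnq,bq->bn", Z, theta)
        pres = eta + rng.standard_normal((b, n)) > 0
        present_frac[idx: idx + b] = pres.mean(axis=1)
        zero_count += int((~pres.any(axis=1)).sum())
        idx += b
    occ = float(present_frac.mean())
    occ_se = float(present_frac.std(ddof=1) / np.sqrt(S))
    zero = zero_count / S
    zero_se = float(np.sqrt(zero * (1 - zero) / S))
    return {
        "occurrence_prob": occ, "occurrence_se": occ_se,
        "zero_fraction": float(zero), "zero_fraction_se": zero_se,
        "n_sites": n, "mc_draws": S,
    }


def estimate_population_params(chains) -> tuple:
    """Plug-in population parameters from a fitted model.

    Posterior means of each site effect alpha_i and species effect beta_j are
    reduced to their across-unit mean and sample SD (n-1 denominator) — the
    (mu_alpha, sd_alpha, mu_beta, sd_beta) a design simulation would reuse.
    """
    a = chains.draws["alpha"].mean(axis=0)
    b = chains.draws["beta"].mean(axis=0)
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(a.mean()), sd(a), float(b.mean()), sd(b)


def _fit_spec_for(design: SimulationDesign, fit_family: Optional[str], priors: PriorSpec) -> ModelSpec:
    fam = fit_family or design.family
    return ModelSpec(family=fam, q=design.q, priors=priors, n_levels=design.K)


def hpd_width_design(
    design: SimulationDesign,
    settings: MCMCSettings,
    level: float = 0.95,
    n_values: Optional[Sequence[int]] = None,
    p_values: Optional[Sequence[int]] = None,
    fit_family: Optional[str] = None,
    priors: Optional[PriorSpec] = None,
    as_presence: bool = False,
    align: bool = True,
) -> pd.DataFrame:
    """Expected mean HPD width of the latent factors per (n, p) design cell.

    For every cell of the factorial grid (defaults to the design's own n and
    p) and every replicate: simulate a community, fit the latent factor model
    (``fit_family`` overrides the generating family, e.g. negbin fits to
    Poisson counts; ``as_presence`` degrades generated counts to binary
    first), Procrustes-align the draws (``align=False`` keeps the raw
    identified marginals), and record the mean 95% HPD width.  Returns one
    row per cell with
    the across-replicate mean and SD; replicate failures are recorded, not
    fatal.
    """
    if priors is None:
        priors = PriorSpec()
    n_values = list(n_values) if n_values is not None else [design.n]
    p_values = list(p_values) if p_values is not None else [design.p]
    rows = []
    for n_i in n_values:
        for p_j in p_values:
            cell = replace(design, n=n_i, p=p_j)
            widths = []
            failures = 0
            for rep in range(design.reps):
                try:
                    Y, _ = generate_community(cell, rep)
                    if as_presence:
                        Y = degrade_to_presence(Y)
                    spec = _fit_spec_for(
                        cell, "binary" if as_presence else fit_family, priors
                    )
                    rep_seed = int(
                        np.random.SeedSequence(
                            (design.seed, n_i, p_j, rep)
                        ).generate_state(1)[0] % (2**31)
                    )
                    ch = fit(Y, spec, replace(settings, seed=rep_seed))
                    if align:
                        ch = align_rotation(ch)
                    widths.append(mean_hpd_width(ch, level).mean_width)
                except Exception:
                    failures += 1
            widths = np.asarray(widths)
            rows.append(
                {
                    "n": n_i, "p": p_j,
                    "family": "binary" if as_presence else (fit_family or design.family),
                    "mean_width": float(widths.mean()) if widths.size else np.nan,
                    "sd_width": float(widths.std(ddof=1)) if widths.size > 1 else np.nan,
                    "reps": int(widths.size),
                    "failures": failures,
                }
            )
    return pd.DataFrame(rows)
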