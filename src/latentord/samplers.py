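"""MCMC samplers for the latent factor ordination model.

Two sampling strategies, chosen by observation family:

* binary / ordinal: exact Gibbs via normal data augmentation.  Each cell gets
  a latent z*_ij ~ N(eta_ij, 1) truncated to the region its observed class
  implies; given z* every remaining block (site effects, species effects,
  latent factors, loadings) has a closed-form Gaussian full conditional, and
  ordinal cutoffs are drawn from order-constrained standard-normal
  conditionals.

* poisson / negbin: the conditionals are non-conjugate, so each block is
  updated by random-walk Metropolis within Gibbs.  Proposal scales adapt per
  element (Robbins-Monro, targets 0.44 for scalars and 0.234 for q-vectors)
  during burn-in only, so the post-burn-in chain is a fixed Markov kernel.

Both samplers run in the rotation-unconstrained parameterization, where the
loadings' full conditionals are plain Gaussians and the orientation of the
latent space mixes through single-block updates; each *retained* draw is then
mapped to the identified representation (zero upper triangle, positive
diagonal — see `identify_rotation`), so the chains returned to the user
satisfy the identifiability constraints exactly.  Likelihood-invariant
generalized-Gibbs moves (`_ridge_moves`) accelerate the soft directions the
data cannot pin down.

All draws are generated from a single `numpy.random.Generator` seeded from
`MCMCSettings.seed`; identical inputs give bit-identical chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import gammaln, log_ndtr, ndtri, ndtri_exp

from .model_core import (
    CommunityMatrix,
    LatentState,
    ModelSpec,
    log_likelihood,
)
from .posterior import PosteriorChains

__all__ = ["MCMCSettings", "fit", "truncated_normal", "update_probit_augmentation"]

_TINY = 1e-300


@dataclass
class MCMCSettings:
    """Chain length, thinning, seeding and proposal-adaptation controls."""

    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    proposal_scale: float = 0.3  # initial random-walk scale (count families)
    adapt: bool = True
    target_accept_scalar: float = 0.44
    target_accept_block: float = 0.234

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.thin <= 0:
            raise ValueError("n_iter and thin must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if not (0 < self.target_accept_scalar < 1 and 0 < self.target_accept_block < 1):
            raise ValueError("target acceptance rates must lie in (0,1)")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def truncated_normal(mean, sd, lower, upper, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(mean, sd^2) truncated to (lower, upper), elementwise.

    Inverse-CDF sampling carried out in log-CDF space (``log_ndtr`` /
    ``ndtri_exp``), with the interval reflected so the inversion always runs
    on the numerically favourable side; this stays exact arbitrarily deep in
    the tails, which the probit Gibbs sweep relies on.
    """
    mean = np.asarray(mean, dtype=float)
    shape = np.broadcast_shapes(mean.shape, np.shape(lower), np.shape(upper), np.shape(sd))
    a = np.broadcast_to((np.asarray(lower, float) - mean) / sd, shape)
    b = np.broadcast_to((np.asarray(upper, float) - mean) / sd, shape)
    with np.errstate(invalid="ignore"):
        flip = (a + b) > 0  # work in the lower tail after reflection
    flip = np.where(np.isnan(a + b), np.isinf(a) & (a > 0), flip)
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    log_hi = log_ndtr(hi)
    log_lo = log_ndtr(lo)
    # ratio Phi(lo)/Phi(hi) in [0,1); 0 when lo = -inf
    d = np.exp(np.clip(log_lo - log_hi, None, 0.0))
    u = np.clip(rng.random(shape), 1e-16, 1.0 - 1e-16)
    x = ndtri_exp(log_hi + np.log(d + u * (1.0 - d) + _TINY))
    x = np.where(flip, -x, x)
    return mean + sd * np.clip(x, np.broadcast_to(a, shape), np.broadcast_to(b, shape))


def _bounds_binary(y: np.ndarray):
    lower = np.where(y == 1, 0.0, -np.inf)
    upper = np.where(y == 1, np.inf, 0.0)
    return lower, upper


def _bounds_ordinal(y: np.ndarray, cutoffs: np.ndarray):
    ext = np.concatenate([[-np.inf], cutoffs, [np.inf]])
    return ext[y - 1], ext[y]


def update_probit_augmentation(
    Y: CommunityMatrix, state: LatentState, rng: np.random.Generator
) -> np.ndarray:
    """Redraw the augmented latents z*_ij ~ N(eta_ij, 1) truncated by y_ij."""
    eta = state.alpha[:, None] + state.beta[None, :] + state.Z @ state.Theta.T
    if Y.family == "binary":
        lower, upper = _bounds_binary(Y.values)
    elif Y.family == "ordinal":
        if state.cutoffs is None:
            raise ValueError("ordinal augmentation requires cutoffs")
        lower, upper = _bounds_ordinal(Y.values, state.cutoffs)
    else:
        raise ValueError("probit augmentation applies to binary/ordinal data only")
    return truncated_normal(eta, 1.0, lower, upper, rng)


def _init_state(Y: CommunityMatrix, spec: ModelSpec) -> LatentState:
    n, p, q = Y.n, Y.p, spec.q
    Theta = np.zeros((p, q))
    for k in range(min(q, p)):
        Theta[k, k] = 1.0
    cutoffs = None
    if spec.family == "ordinal":
        K = spec.n_levels
        freqs = np.array([(Y.values <= m).mean() for m in range(1, K)])
        freqs = np.clip(freqs, 1e-3, 1 - 1e-3)
        cutoffs = np.asarray(ndtri(freqs), dtype=float)
        # enforce strict ordering when classes are empty
        for l in range(1, K - 1):
            if cutoffs[l] <= cutoffs[l - 1]:
                cutoffs[l] = cutoffs[l - 1] + 1e-3
    omega = 1.0 if spec.family == "negbin" else None
    return LatentState(
        alpha=np.zeros(n), beta=np.zeros(p), Z=np.zeros((n, q)), Theta=Theta,
        omega=omega, cutoffs=cutoffs,
    )


def fit(Y: CommunityMatrix, spec: ModelSpec, settings: MCMCSettings) -> PosteriorChains:
    """Run the family-appropriate sampler and return retained draws."""
    if not spec.compatible_with(Y):
        raise ValueError(f"model family {spec.family!r} cannot fit data family {Y.family!r}")
    if spec.family == "ordinal" and spec.n_levels < int(Y.values.max()):
        raise ValueError("data contain classes above the model's n_levels")
    state = _init_state(Y, spec)
    ll0 = log_likelihood(Y, state, spec)
    if not np.isfinite(ll0):
        raise ValueError(f"non-finite log-likelihood at initialization (ll={ll0})")
    if spec.family in ("binary", "ordinal"):
        return _fit_probit(Y, spec, settings, state)
    return _fit_count(Y, spec, settings, state)


def identify_rotation(Z: np.ndarray, Theta: np.ndarray):
    """Rotate a (Z, Theta) configuration to the identified representation.

    The likelihood depends on (Z, Theta) only through Z @ Theta.T, which is
    invariant under any orthogonal map Q applied to both; the isotropic
    priors are invariant too.  The identified representative has the leading
    q x q block of Theta lower triangular with positive diagonal (for q = 2:
    theta_11 > 0, theta_12 = 0, theta_22 > 0), obtained by Gram-Schmidt on
    the first q loading rows.  Every function of the identified draws is a
    rotation-invariant functional of the configuration.
    """
    q = Theta.shape[1]
    head = Theta[:q, :q]
    Qm, Rm = np.linalg.qr(head.T)
    sign = np.sign(np.diag(Rm))
    sign[sign == 0] = 1.0
    Qm = Qm * sign[None, :]
    Zr = Z @ Qm
    Tr = Theta @ Qm
    for k in range(min(q, Tr.shape[0])):
        Tr[k, k + 1:] = 0.0  # exact structural zeros
    return Zr, Tr


def _ridge_moves(alpha, beta, Z, Theta, pri, rng, inv_Vt, scale_step=0.15):
    """Generalized-Gibbs moves along the likelihood-invariant ridges.

    The linear predictor is unchanged by (a) shifting every latent factor by
    delta while subtracting Theta@delta from the species effects, (b) adding
    a constant to all site effects and subtracting it from all species
    effects, and (c) scaling a latent dimension while inversely scaling its
    loadings.  The data cannot inform these directions, so plain one-block
    Gibbs random-walks them slowly; here (a) and (b) are drawn exactly from
    their Gaussian conditionals under the priors (translation-group
    generalized Gibbs) and (c) is a Metropolis step on the log scale with the
    multiplicative-group Jacobian.  All three leave the posterior invariant.
    """
    n, q = Z.shape
    p = Theta.shape[0]
    # (a) Z translation absorbed by the species effects
    P = n * np.eye(q) + Theta.T @ Theta / pri.v_beta
    b = -Z.sum(axis=0) + Theta.T @ (beta - pri.mu_beta) / pri.v_beta
    cf = cho_factor(P, lower=True)
    mean = cho_solve(cf, b)
    delta = mean + solve_triangular(cf[0], np.eye(q), lower=True).T @ rng.standard_normal(q)
    Z = Z + delta
    beta = beta - Theta @ delta
    # (b) level trade between site and species effects
    prec = n / pri.v_alpha + p / pri.v_beta
    lin = -(alpha - pri.mu_alpha).sum() / pri.v_alpha + (beta - pri.mu_beta).sum() / pri.v_beta
    c = lin / prec + rng.standard_normal() / np.sqrt(prec)
    alpha = alpha + c
    beta = beta - c
    # (c) per-dimension scale trade between factors and loadings
    for k in range(q):
        s = np.exp(scale_step * rng.standard_normal())
        sz = float(Z[:, k] @ Z[:, k])
        Tn = Theta.copy()
        Tn[:, k] /= s
        dq = float(
            np.einsum("jk,kl,jl->", Tn, inv_Vt, Tn)
            - np.einsum("jk,kl,jl->", Theta, inv_Vt, Theta)
        )
        log_acc = -0.5 * (s**2 - 1.0) * sz - 0.5 * dq + (n - p) * np.log(s)
        if np.log(rng.random()) < log_acc:
            Z[:, k] *= s
            Theta = Tn
    return alpha, beta, Z, Theta


# ---------------------------------------------------------------------------
# probit / ordinal Gibbs


def _fit_probit(Y, spec, settings, state) -> PosteriorChains:
    rng = np.random.default_rng(settings.seed)
    n, p, q = Y.n, Y.p, spec.q
    y = Y.values
    pri = spec.priors
    Vt = pri.v_theta_matrix(q)
    inv_Vt = np.linalg.inv(Vt)
    alpha, beta, Z, Theta = state.alpha, state.beta, state.Z, state.Theta
    cutoffs = state.cutoffs
    ordinal = spec.family == "ordinal"
    K = spec.n_levels if ordinal else None
    if Y.family == "binary":
        lower, upper = _bounds_binary(y)
    class_masks = None
    if ordinal:
        class_masks = [y == m for m in range(1, K + 1)]

    prec_a = p + 1.0 / pri.v_alpha
    prec_b = n + 1.0 / pri.v_beta
    sd_a = 1.0 / np.sqrt(prec_a)
    sd_b = 1.0 / np.sqrt(prec_b)

    m_ret = settings.n_retained
    out = {
        "alpha": np.empty((m_ret, n)),
        "beta": np.empty((m_ret, p)),
        "Z": np.empty((m_ret, n, q)),
        "Theta": np.empty((m_ret, p, q)),
    }
    if ordinal:
        out["cutoffs"] = np.empty((m_ret, K - 1))

    # prior precision blocks for the constrained loading rows

    ridx = 0
    for t in range(settings.n_iter):
        ZT = Z @ Theta.T
        eta = alpha[:, None] + beta[None, :] + ZT
        if ordinal:
            lower, upper = _bounds_ordinal(y, cutoffs)
        zstar = truncated_normal(eta, 1.0, lower, upper, rng)

        # site effects
        resid = (zstar - beta[None, :] - ZT).sum(axis=1)
        alpha = (pri.mu_alpha / pri.v_alpha + resid) / prec_a + sd_a * rng.standard_normal(n)
        # species effects
        resid = (zstar - alpha[:, None] - ZT).sum(axis=0)
        beta = (pri.mu_beta / pri.v_beta + resid) / prec_b + sd_b * rng.standard_normal(p)

        R = zstar - alpha[:, None] - beta[None, :]

        # latent factors: shared precision I + Theta'Theta
        P = np.eye(q) + Theta.T @ Theta
        cf = cho_factor(P, lower=True)
        M = cho_solve(cf, Theta.T @ R.T).T
        Ainv = solve_triangular(cf[0], np.eye(q), lower=True)
        Z = M + rng.standard_normal((n, q)) @ Ainv

        # loadings: all rows share the Gaussian full conditional in the
        # rotation-unconstrained parameterization (identification is applied
        # to the retained draws, not inside the kernel)
        P2 = inv_Vt + Z.T @ Z
        cf2 = cho_factor(P2, lower=True)
        M2 = cho_solve(cf2, Z.T @ R).T
        A2 = solve_triangular(cf2[0], np.eye(q), lower=True)
        Theta = M2 + rng.standard_normal((p, q)) @ A2

        alpha, beta, Z, Theta = _ridge_moves(alpha, beta, Z, Theta, pri, rng, inv_Vt)

        # ordinal cutoffs, sequential scan preserving the ordering
        if ordinal:
            for l in range(K - 1):
                lo = cutoffs[l - 1] if l > 0 else -np.inf
                hi = cutoffs[l + 1] if l < K - 2 else np.inf
                below = zstar[class_masks[l]]
                above = zstar[class_masks[l + 1]]
                if below.size:
                    lo = max(lo, below.max())
                if above.size:
                    hi = min(hi, above.min())
                cutoffs[l] = truncated_normal(np.asarray(0.0), 1.0, lo, hi, rng).item()

        if t >= settings.burn_in and (t - settings.burn_in) % settings.thin == settings.thin - 1:
            Zr, Tr = identify_rotation(Z, Theta)
            out["alpha"][ridx] = alpha
            out["beta"][ridx] = beta
            out["Z"][ridx] = Zr
            out["Theta"][ridx] = Tr
            if ordinal:
                out["cutoffs"][ridx] = cutoffs
            ridx += 1

    out = {k: v[:ridx] for k, v in out.items()}
    return PosteriorChains(
        draws=out, family=spec.family,
        dims={"n": n, "p": p, "q": q, "K": K or 0},
        settings=settings, seed=settings.seed,
    )


# ---------------------------------------------------------------------------
# count families: adaptive random-walk Metropolis within Gibbs


def _cell_loglik_count(y, eta, omega, lgy1, family):
    if family == "poisson":
        return y * eta - np.exp(eta) - lgy1
    r = 1.0 / omega
    mu = np.exp(eta)
    return (
        gammaln(y + r) - gammaln(r) - lgy1
        + r * (np.log(r) - np.log(r + mu))
        + y * (eta - np.log(r + mu))
    )


def _fit_count(Y, spec, settings, state) -> PosteriorChains:
    rng = np.random.default_rng(settings.seed)
    n, p, q = Y.n, Y.p, spec.q
    y = Y.values.astype(float)
    lgy1 = gammaln(y + 1.0)
    pri = spec.priors
    Vt = pri.v_theta_matrix(q)
    inv_Vt = np.linalg.inv(Vt)
    negbin = spec.family == "negbin"
    alpha, beta, Z, Theta = state.alpha, state.beta, state.Z, state.Theta
    omega = state.omega if negbin else None

    ls_a = np.full(n, np.log(settings.proposal_scale))
    ls_b = np.full(p, np.log(settings.proposal_scale))
    ls_z = np.full(n, np.log(settings.proposal_scale))
    ls_t = np.full(p, np.log(settings.proposal_scale))
    ls_w = np.log(settings.proposal_scale)

    eta = alpha[:, None] + beta[None, :] + Z @ Theta.T
    ll = _cell_loglik_count(y, eta, omega, lgy1, spec.family)
    acc_count = {"alpha": 0.0, "beta": 0.0, "Z": 0.0, "Theta": 0.0, "omega": 0.0}
    post_iters = 0

    m_ret = settings.n_retained
    out = {
        "alpha": np.empty((m_ret, n)),
        "beta": np.empty((m_ret, p)),
        "Z": np.empty((m_ret, n, q)),
        "Theta": np.empty((m_ret, p, q)),
    }
    if negbin:
        out["omega"] = np.empty(m_ret)

    def hc_logpdf(w):
        return -np.log1p((w / pri.omega_prior_scale) ** 2)

    ridx = 0
    for t in range(settings.n_iter):
        adapting = settings.adapt and t < settings.burn_in
        gam = 1.0 / (1.0 + t) ** 0.6 if adapting else 0.0

        # --- site effects (independent scalar MH, vectorized over i)
        d = np.exp(ls_a) * rng.standard_normal(n)
        eta_new = eta + d[:, None]
        ll_new = _cell_loglik_count(y, eta_new, omega, lgy1, spec.family)
        an, ao = alpha + d, alpha
        dlp = (
            ll_new.sum(axis=1) - ll.sum(axis=1)
            - 0.5 * ((an - pri.mu_alpha) ** 2 - (ao - pri.mu_alpha) ** 2) / pri.v_alpha
        )
        acc = np.log(rng.random(n)) < dlp
        alpha = np.where(acc, an, ao)
        eta = np.where(acc[:, None], eta_new, eta)
        ll = np.where(acc[:, None], ll_new, ll)
        if adapting:
            ls_a += gam * (acc - settings.target_accept_scalar)
        acc_a = acc.mean()

        # --- species effects
        d = np.exp(ls_b) * rng.standard_normal(p)
        eta_new = eta + d[None, :]
        ll_new = _cell_loglik_count(y, eta_new, omega, lgy1, spec.family)
        bn, bo = beta + d, beta
        dlp = (
            ll_new.sum(axis=0) - ll.sum(axis=0)
            - 0.5 * ((bn - pri.mu_beta) ** 2 - (bo - pri.mu_beta) ** 2) / pri.v_beta
        )
        acc = np.log(rng.random(p)) < dlp
        beta = np.where(acc, bn, bo)
        eta = np.where(acc[None, :], eta_new, eta)
        ll = np.where(acc[None, :], ll_new, ll)
        if adapting:
            ls_b += gam * (acc - settings.target_accept_scalar)
        acc_b = acc.mean()

        # --- latent factor rows
        dZ = np.exp(ls_z)[:, None] * rng.standard_normal((n, q))
        Zn = Z + dZ
        eta_new = eta + dZ @ Theta.T
        ll_new = _cell_loglik_count(y, eta_new, omega, lgy1, spec.family)
        dlp = (
            ll_new.sum(axis=1) - ll.sum(axis=1)
            - 0.5 * ((Zn**2).sum(axis=1) - (Z**2).sum(axis=1))
        )
        acc = np.log(rng.random(n)) < dlp
        Z = np.where(acc[:, None], Zn, Z)
        eta = np.where(acc[:, None], eta_new, eta)
        ll = np.where(acc[:, None], ll_new, ll)
        if adapting:
            ls_z += gam * (acc - settings.target_accept_block)
        acc_z = acc.mean()

        # --- loading rows (columns of eta), rotation-unconstrained
        dT = np.exp(ls_t)[:, None] * rng.standard_normal((p, q))
        Tn = Theta + dT
        eta_new = eta + Z @ dT.T
        ll_new = _cell_loglik_count(y, eta_new, omega, lgy1, spec.family)
        quad = np.einsum("jk,kl,jl->j", Tn, inv_Vt, Tn)
        quad_old = np.einsum("jk,kl,jl->j", Theta, inv_Vt, Theta)
        dlp = ll_new.sum(axis=0) - ll.sum(axis=0) - 0.5 * (quad - quad_old)
        acc = np.log(rng.random(p)) < dlp
        Theta = np.where(acc[:, None], Tn, Theta)
        eta = np.where(acc[None, :], eta_new, eta)
        ll = np.where(acc[None, :], ll_new, ll)
        if adapting:
            ls_t += gam * (acc - settings.target_accept_block)
        acc_t = acc.mean()

        alpha, beta, Z, Theta = _ridge_moves(alpha, beta, Z, Theta, pri, rng, inv_Vt)
        if t % 500 == 499:  # the ridge moves keep eta invariant; refresh drift
            eta = alpha[:, None] + beta[None, :] + Z @ Theta.T
            ll = _cell_loglik_count(y, eta, omega, lgy1, spec.family)

        # --- overdispersion, log-scale random walk
        acc_w = 0.0
        if negbin:
            wn = omega * np.exp(np.exp(ls_w) * rng.standard_normal())
            ll_new = _cell_loglik_count(y, eta, wn, lgy1, "negbin")
            dlp = (
                ll_new.sum() - ll.sum()
                + hc_logpdf(wn) - hc_logpdf(omega)
                + np.log(wn) - np.log(omega)
            )
            if np.log(rng.random()) < dlp:
                omega = wn
                ll = ll_new
                acc_w = 1.0
            if adapting:
                ls_w += gam * (acc_w - settings.target_accept_scalar)

        if t >= settings.burn_in:
            post_iters += 1
            acc_count["alpha"] += acc_a
            acc_count["beta"] += acc_b
            acc_count["Z"] += acc_z
            acc_count["Theta"] += acc_t
            acc_count["omega"] += acc_w
            if (t - settings.burn_in) % settings.thin == settings.thin - 1:
                Zr, Tr = identify_rotation(Z, Theta)
                out["alpha"][ridx] = alpha
                out["beta"][ridx] = beta
                out["Z"][ridx] = Zr
                out["Theta"][ridx] = Tr
                if negbin:
                    out["omega"][ridx] = omega
                ridx += 1

    out = {k: v[:ridx] for k, v in out.items()}
    rates = {k: v / max(post_iters, 1) for k, v in acc_count.items()}
    for name in ("alpha", "beta", "Z", "Theta") + (("omega",) if negbin else ()):
        r = rates[name]
        if not (0.1 <= r <= 0.7):
            warnings.warn(
                f"acceptance rate for block {name} is {r:.2f}, outside [0.1, 0.7]",
                RuntimeWarning,
            )
    return PosteriorChains(
        draws=out, family=spec.family,
        dims={"n": n, "p": p, "q": q, "K": 0},
        settings=settings, seed=settings.seed, accept_rates=rates,
    )
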