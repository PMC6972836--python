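"""Core model types and likelihood machinery for latent factor ordination.

The model places every site i and species j on a shared linear predictor

    g(mu_ij) = alpha_i + beta_j + z_i' theta_j

where ``alpha_i`` is a site effect, ``beta_j`` a species effect, ``z_i`` a
q-dimensional latent factor (the ordination coordinates of site i) and
``theta_j`` the factor loadings of species j.  Four observation families are
supported: probit presence/absence, Poisson counts, negative binomial counts
with quadratic overdispersion (Var = mu + omega*mu^2), and cumulative-probit
ordinal cover classes.

For identifiability the loading matrix is constrained to have zeros above the
diagonal and strictly positive diagonal entries (for q = 2: theta_11 > 0,
theta_12 = 0, theta_22 > 0); latent factors carry a standard normal prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, log_ndtr, ndtr

__all__ = [
    "FAMILIES",
    "CommunityMatrix",
    "PriorSpec",
    "LatentState",
    "ModelSpec",
    "linear_predictor",
    "mean_response",
    "nb_variance",
    "log_likelihood",
    "loglik_matrix",
    "dic",
]

#: observation families of the data matrix
DATA_FAMILIES = ("binary", "count", "ordinal")
#: observation families of the model (count data may be fit as poisson or negbin)
FAMILIES = ("binary", "poisson", "negbin", "ordinal")

_MODEL_TO_DATA = {
    "binary": "binary",
    "poisson": "count",
    "negbin": "count",
    "ordinal": "ordinal",
}


@dataclass
class CommunityMatrix:
    """A validated n x p site-by-species response matrix.

    Rows are sample units (sites), columns are species.  ``family`` declares
    how entries are to be read: presence/absence indicators, non-negative
    integer counts, or ordinal classes 1..K (``n_levels`` = K).
    """

    values: np.ndarray
    family: str
    n_levels: Optional[int] = None
    site_labels: Optional[Sequence[str]] = None
    species_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("community matrix must be two-dimensional")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 sites and 2 species, got {n} x {p}")
        if self.family not in DATA_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {DATA_FAMILIES}")
        vals = self.values
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("community matrix entries must be numeric")
        if np.any(~np.isfinite(vals.astype(float))):
            raise ValueError("community matrix contains missing or non-finite entries")
        if np.any(vals != np.floor(vals)):
            bad = np.argwhere(vals != np.floor(vals))[0]
            raise ValueError(f"non-integer entry at row {bad[0]}, column {bad[1]}")
        self.values = vals.astype(np.int64)
        if self.family == "binary":
            if np.any((self.values != 0) & (self.values != 1)):
                bad = np.argwhere((self.values != 0) & (self.values != 1))[0]
                raise ValueError(f"binary entry not in {{0,1}} at row {bad[0]}, column {bad[1]}")
        elif self.family == "count":
            if np.any(self.values < 0):
                bad = np.argwhere(self.values < 0)[0]
                raise ValueError(f"negative count at row {bad[0]}, column {bad[1]}")
        else:  # ordinal
            if self.n_levels is None or self.n_levels < 2:
                raise ValueError("ordinal data require n_levels K >= 2")
            if np.any((self.values < 1) | (self.values > self.n_levels)):
                bad = np.argwhere((self.values < 1) | (self.values > self.n_levels))[0]
                raise ValueError(
                    f"ordinal entry outside 1..{self.n_levels} at row {bad[0]}, column {bad[1]}"
                )
        if self.site_labels is None:
            self.site_labels = [str(i + 1) for i in range(n)]
        if self.species_labels is None:
            self.species_labels = [f"sp{j + 1}" for j in range(p)]
        if len(self.site_labels) != n or len(self.species_labels) != p:
            raise ValueError("label lengths do not match matrix dimensions")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    alpha_i ~ N(mu_alpha, v_alpha), beta_j ~ N(mu_beta, v_beta),
    theta_j ~ N(0, v_theta) subject to the loading constraints,
    z_i ~ N(0, I), omega ~ half-Cauchy(scale=omega_prior_scale),
    cutoffs ~ standard normal subject to ordering.

    The default half-Cauchy scale is sqrt(20), i.e. squared scale 20.
    """

    mu_alpha: float = 0.0
    v_alpha: float = 1.0
    mu_beta: float = 0.0
    v_beta: float = 1.0
    v_theta: Optional[np.ndarray] = None  # q x q; identity when None
    omega_prior_scale: float = float(np.sqrt(20.0))

    def __post_init__(self) -> None:
        if self.v_alpha <= 0 or self.v_beta <= 0:
            raise ValueError("prior variances must be strictly positive")
        if self.omega_prior_scale <= 0:
            raise ValueError("omega prior scale must be strictly positive")
        if self.v_theta is not None:
            V = np.asarray(self.v_theta, dtype=float)
            if V.ndim != 2 or V.shape[0] != V.shape[1]:
                raise ValueError("v_theta must be a square matrix")
            if not np.allclose(V, V.T):
                raise ValueError("v_theta must be symmetric")
            if np.any(np.linalg.eigvalsh(V) <= 0):
                raise ValueError("v_theta must be positive definite")
            self.v_theta = V

    def v_theta_matrix(self, q: int) -> np.ndarray:
        if self.v_theta is None:
            return np.eye(q)
        if self.v_theta.shape[0] != q:
            raise ValueError(f"v_theta is {self.v_theta.shape[0]}x{self.v_theta.shape[0]}, model has q={q}")
        return self.v_theta


@dataclass
class LatentState:
    """One full parameter configuration of the latent factor model."""

    alpha: np.ndarray  # (n,)
    beta: np.ndarray  # (p,)
    Z: np.ndarray  # (n, q)
    Theta: np.ndarray  # (p, q)
    omega: Optional[float] = None  # negbin overdispersion
    cutoffs: Optional[np.ndarray] = None  # (K-1,), strictly increasing
    z_star: Optional[np.ndarray] = None  # (n, p) augmented latents

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.Theta = np.atleast_2d(np.asarray(self.Theta, dtype=float))
        if self.Z.shape[0] != self.alpha.shape[0]:
            raise ValueError("Z rows must match alpha length")
        if self.Theta.shape[0] != self.beta.shape[0]:
            raise ValueError("Theta rows must match beta length")
        if self.Z.shape[1] != self.Theta.shape[1]:
            raise ValueError("Z and Theta must share the latent dimension q")
        if self.omega is not None and self.omega <= 0:
            raise ValueError("omega must be strictly positive")
        if self.cutoffs is not None:
            self.cutoffs = np.asarray(self.cutoffs, dtype=float)
            if np.any(np.diff(self.cutoffs) <= 0):
                raise ValueError("cutoffs must be strictly increasing")

    @property
    def n(self) -> int:
        return self.alpha.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def check_loading_constraints(self, atol: float = 0.0) -> bool:
        """True iff Theta has zero upper triangle and positive diagonal."""
        q = self.q
        for k in range(min(q, self.Theta.shape[0])):
            if self.Theta[k, k] <= 0:
                return False
            if np.any(np.abs(self.Theta[k, k + 1:]) > atol):
                return False
        return True


@dataclass
class ModelSpec:
    """Observation family, latent dimension, and priors.

    The link is implied by the family: probit for binary/ordinal, log for the
    count families.
    """

    family: str
    q: int = 2
    priors: PriorSpec = field(default_factory=PriorSpec)
    n_levels: Optional[int] = None  # K, ordinal only

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        if self.q < 1:
            raise ValueError("latent dimension q must be >= 1")
        if self.family == "ordinal" and (self.n_levels is None or self.n_levels < 2):
            raise ValueError("ordinal model requires n_levels K >= 2")

    @property
    def link(self) -> str:
        return "log" if self.family in ("poisson", "negbin") else "probit"

    def compatible_with(self, Y: CommunityMatrix) -> bool:
        return _MODEL_TO_DATA[self.family] == Y.family


def eta_matrix(state: LatentState) -> np.ndarray:
    """The n x p matrix of linear predictors alpha_i + beta_j + z_i' theta_j."""
    return state.alpha[:, None] + state.beta[None, :] + state.Z @ state.Theta.T


def linear_predictor(state: LatentState, i: int, j: int) -> float:
    """Linear predictor eta_ij for a single site/species cell (0-based)."""
    if not (0 <= i < state.n):
        raise IndexError(f"site index {i} out of range 0..{state.n - 1}")
    if not (0 <= j < state.p):
        raise IndexError(f"species index {j} out of range 0..{state.p - 1}")
    return float(state.alpha[i] + state.beta[j] + state.Z[i] @ state.Theta[j])


def mean_response(eta, spec: ModelSpec, cutoffs: Optional[np.ndarray] = None):
    """Map linear predictor(s) to the family's mean (or class probabilities).

    binary -> Phi(eta); poisson/negbin -> exp(eta); ordinal -> a vector of K
    class probabilities from successive differences of Phi(c_l - eta)
    (appended axis of length K when eta is an array).
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    if spec.family == "binary":
        return ndtr(eta)
    if spec.family in ("poisson", "negbin"):
        return np.exp(eta)
    # ordinal
    if cutoffs is None:
        raise ValueError("ordinal mean_response requires cutoffs")
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    cdf = ndtr(cutoffs - eta[..., None])  # (..., K-1)
    ones = np.ones(eta.shape + (1,))
    zeros = np.zeros(eta.shape + (1,))
    full = np.concatenate([zeros, cdf, ones], axis=-1)
    return np.diff(full, axis=-1)


def nb_variance(mu, omega) -> np.ndarray:
    """Negative binomial variance mu + omega * mu^2 (Poisson limit at omega=0)."""
    mu = np.asarray(mu, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(mu < 0) or np.any(omega < 0):
        raise ValueError("mu and omega must be non-negative")
    return mu + omega * mu**2


def _binary_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # log Phi(eta) if y=1 else log Phi(-eta); log_ndtr is tail-safe
    return np.where(y == 1, log_ndtr(eta), log_ndtr(-eta))


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def _negbin_loglik(y: np.ndarray, eta: np.ndarray, omega: float) -> np.ndarray:
    # mean/overdispersion parameterization: r = 1/omega, Var = mu + omega mu^2
    r = 1.0 / omega
    mu = np.exp(eta)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * (np.log(r) - np.log(r + mu))
        + y * (eta - np.log(r + mu))
    )


def _ordinal_loglik(y: np.ndarray, eta: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    cuts = np.concatenate([[-np.inf], cutoffs, [np.inf]])
    lower = cuts[y - 1] - eta
    upper = cuts[y] - eta
    prob = ndtr(upper) - ndtr(lower)
    with np.errstate(divide="ignore"):
        return np.log(prob)


def loglik_matrix(Y: CommunityMatrix, state: LatentState, spec: ModelSpec) -> np.ndarray:
    """Per-cell log-likelihood matrix under the model family."""
    if not spec.compatible_with(Y):
        raise ValueError(f"model family {spec.family!r} cannot fit data family {Y.family!r}")
    if state.n != Y.n or state.p != Y.p:
        raise ValueError("state dimensions do not match the data matrix")
    eta = eta_matrix(state)
    y = Y.values
    if spec.family == "binary":
        return _binary_loglik(y, eta)
    if spec.family == "poisson":
        return _poisson_loglik(y, eta)
    if spec.family == "negbin":
        if state.omega is None:
            raise ValueError("negbin likelihood requires state.omega")
        return _negbin_loglik(y, eta, state.omega)
    if state.cutoffs is None:
        raise ValueError("ordinal likelihood requires state.cutoffs")
    return _ordinal_loglik(y, eta, state.cutoffs)


def log_likelihood(Y: CommunityMatrix, state: LatentState, spec: ModelSpec) -> float:
    """Total log-likelihood summed over all cells."""
    return float(loglik_matrix(Y, state, spec).sum())


def loglik_from_eta(
    Y: CommunityMatrix,
    eta: np.ndarray,
    spec: ModelSpec,
    omega: Optional[float] = None,
    cutoffs: Optional[np.ndarray] = None,
) -> float:
    """Total log-likelihood at a given matrix of linear predictors."""
    y = Y.values
    if spec.family == "binary":
        return float(_binary_loglik(y, eta).sum())
    if spec.family == "poisson":
        return float(_poisson_loglik(y, eta).sum())
    if spec.family == "negbin":
        return float(_negbin_loglik(y, eta, omega).sum())
    return float(_ordinal_loglik(y, eta, cutoffs).sum())


def dic(chains, Y: CommunityMatrix, spec: ModelSpec) -> float:
    """Deviance information criterion: DIC = Dbar + pD = 2*Dbar - D(hat).

    Dbar is the posterior mean deviance (-2 log L averaged over retained
    draws).  The plug-in deviance D(hat) is focused on the cell-level linear
    predictors eta_ij (posterior mean eta, plus mean overdispersion/cutoffs
    where applicable) rather than on the individual latent blocks: the
    low-rank product Z @ Theta.T does not commute with elementwise averaging,
    so plugging in averaged blocks would evaluate the deviance at a point the
    posterior never visits.  Used to compare the Poisson and negative
    binomial fits of count data.
    """
    draws = chains.draws
    m = draws["alpha"].shape[0]
    if m == 0:
        raise ValueError("empty chains")
    devs = np.empty(m)
    eta_sum = 0.0
    for t in range(m):
        st = LatentState(
            alpha=draws["alpha"][t],
            beta=draws["beta"][t],
            Z=draws["Z"][t],
            Theta=draws["Theta"][t],
            omega=float(draws["omega"][t]) if "omega" in draws else None,
            cutoffs=draws["cutoffs"][t] if "cutoffs" in draws else None,
        )
        devs[t] = -2.0 * log_likelihood(Y, st, spec)
        eta_sum = eta_sum + eta_matrix(st)
    dbar = float(devs.mean())
    mean_cutoffs = None
    if "cutoffs" in draws:
        mean_cutoffs = np.sort(draws["cutoffs"].mean(axis=0))
    dhat = -2.0 * loglik_from_eta(
        Y,
        eta_sum / m,
        spec,
        omega=float(draws["omega"].mean()) if "omega" in draws else None,
        cutoffs=mean_cutoffs,
    )
    return 2.0 * dbar - dhat
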