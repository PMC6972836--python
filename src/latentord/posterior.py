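"""Posterior summaries: HPD intervals/regions, anchoring, diagnostics.

The headline uncertainty summary is the mean 95% highest-posterior-density
(HPD) interval width of the latent factors, averaged over every site and
every latent dimension.  Because an unconstrained ordination is only defined
up to translation, chains can also be *anchored*: every draw is shifted so a
chosen reference site sits exactly at the origin, turning positions into
distances from that site.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

__all__ = [
    "PosteriorChains",
    "HPDSummary",
    "hpd_interval",
    "mean_hpd_width",
    "anchor",
    "align_rotation",
    "hpd_region_2d",
    "diagnostics",
]

MIN_SAMPLES = 100


@dataclass
class PosteriorChains:
    """Retained MCMC draws of all model parameters plus sampler metadata.

    ``draws`` maps parameter names to arrays whose leading axis indexes the
    retained iteration: alpha (m,n), beta (m,p), Z (m,n,q), Theta (m,p,q),
    and, where the family requires them, omega (m,) and cutoffs (m,K-1).
    """

    draws: Dict[str, np.ndarray]
    family: str
    dims: Dict[str, int]
    settings: object = None
    seed: Optional[int] = None
    accept_rates: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {k: v.shape[0] for k, v in self.draws.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"parameter arrays disagree on retained draws: {lengths}")

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Serialize to a self-describing .npz container (round-trip exact)."""
        meta = {
            "family": self.family,
            "dims": self.dims,
            "seed": self.seed,
            "accept_rates": self.accept_rates,
            "settings": _settings_to_dict(self.settings),
            "params": sorted(self.draws),
        }
        arrays = {f"draw_{k}": v for k, v in self.draws.items()}
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "PosteriorChains":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            draws = {k: z[f"draw_{k}"] for k in meta["params"]}
        settings = None
        if meta["settings"] is not None:
            from .samplers import MCMCSettings

            settings = MCMCSettings(**meta["settings"])
        return cls(
            draws=draws, family=meta["family"], dims=meta["dims"],
            settings=settings, seed=meta["seed"],
            accept_rates=meta.get("accept_rates", {}),
        )


def _settings_to_dict(settings):
    if settings is None:
        return None
    from dataclasses import asdict, is_dataclass

    return asdict(settings) if is_dataclass(settings) else dict(settings)


@dataclass
class HPDSummary:
    """Per-site, per-dimension HPD intervals for the latent factors."""

    intervals: np.ndarray  # (n, q, 2)
    widths: np.ndarray  # (n, q)
    mean_width: float
    level: float = 0.95

    def to_frame(self):
        import pandas as pd

        n, q, _ = self.intervals.shape
        rows = [
            {
                "site": i, "dimension": k + 1,
                "lower": self.intervals[i, k, 0],
                "upper": self.intervals[i, k, 1],
                "width": self.widths[i, k],
            }
            for i in range(n)
            for k in range(q)
        ]
        return pd.DataFrame(rows)


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple:
    """Minimal-width interval containing ceil(level*m) of the sorted samples.

    Chen-Shao sorted-window construction; among equal-width windows the one
    with the smallest lower endpoint is returned.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    m = x.size
    if m < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {m}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0,1)")
    k = int(np.ceil(level * m))
    widths = x[k - 1:] - x[: m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def mean_hpd_width(chains: PosteriorChains, level: float = 0.95) -> HPDSummary:
    """HPD intervals of every latent-factor coordinate z_ik and their widths.

    ``mean_width`` is the arithmetic mean of all n*q interval widths — the
    scalar uncertainty summary used throughout for comparing designs.
    """
    Z = chains.draws["Z"]  # (m, n, q)
    m, n, q = Z.shape
    intervals = np.empty((n, q, 2))
    for i in range(n):
        for k in range(q):
            intervals[i, k] = hpd_interval(Z[:, i, k], level)
    widths = intervals[..., 1] - intervals[..., 0]
    return HPDSummary(
        intervals=intervals, widths=widths,
        mean_width=float(widths.mean()), level=level,
    )


def align_rotation(chains: PosteriorChains, iterations: int = 2) -> PosteriorChains:
    """Procrustes-align every retained draw's configuration by rotation.

    Each draw's latent factor matrix is rotated (orthogonal Procrustes) to
    best match the across-draw mean configuration, iterating the reference a
    few times; loadings are rotated consistently.  This removes the common
    rotational wobble of the whole ordination from the draws, so subsequent
    HPD widths measure *shape-relative* uncertainty — the precision of sites'
    positions relative to one another, which is what an ordination is read
    for.  Note the aligned loadings no longer satisfy the identification
    zero/sign pattern draw by draw.
    """
    from scipy.linalg import orthogonal_procrustes

    Z = chains.draws["Z"].copy()
    Theta = chains.draws["Theta"].copy()
    m = Z.shape[0]
    ref = Z.mean(axis=0)
    for _ in range(iterations):
        for t in range(m):
            R, _ = orthogonal_procrustes(Z[t], ref)
            Z[t] = Z[t] @ R
            Theta[t] = Theta[t] @ R
        ref = Z.mean(axis=0)
    draws = dict(chains.draws)
    draws["Z"] = Z
    draws["Theta"] = Theta
    return replace(chains, draws=draws)


def anchor(chains: PosteriorChains, anchor_site: int) -> PosteriorChains:
    """Re-express latent factors as offsets from one reference site.

    Every draw of every site is shifted by that draw's position of
    ``anchor_site``, whose own draws become exactly the origin.  This removes
    common translations of the whole ordination from the uncertainty.
    """
    Z = chains.draws["Z"]
    n = Z.shape[1]
    if not (0 <= anchor_site < n):
        raise IndexError(f"anchor site {anchor_site} out of range 0..{n - 1}")
    Za = Z - Z[:, anchor_site: anchor_site + 1, :]
    draws = dict(chains.draws)
    draws["Z"] = Za
    return replace(chains, draws=draws)


def hpd_region_2d(draws: np.ndarray, level: float = 0.95, method: str = "kde"):
    """Closed 2-D HPD region for a cloud of posterior draws.

    method='normal_ellipse': mean/covariance ellipse at the chi^2_2(level)
    radius (area pi*r2*sqrt(det C)).  method='kde': highest-density contour
    of a Gaussian KDE (Scott bandwidth) enclosing a ``level`` fraction of the
    draws, extracted as polygon(s).

    Returns a dict with the region parameters, its area, and the fraction of
    draws it actually encloses.
    """
    pts = np.asarray(draws, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("draws must be an m x 2 array")
    m = pts.shape[0]
    if m < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} draws, got {m}")
    cov = np.cov(pts.T)
    if np.linalg.matrix_rank(cov) < 2:
        warnings.warn("rank-deficient draws; falling back to an interval product", RuntimeWarning)
        i0 = hpd_interval(pts[:, 0], level) if pts[:, 0].std() > 0 else (pts[0, 0], pts[0, 0])
        i1 = hpd_interval(pts[:, 1], level) if pts[:, 1].std() > 0 else (pts[0, 1], pts[0, 1])
        inside = (
            (pts[:, 0] >= i0[0]) & (pts[:, 0] <= i0[1])
            & (pts[:, 1] >= i1[0]) & (pts[:, 1] <= i1[1])
        )
        return {
            "method": "box", "box": (i0, i1),
            "area": (i0[1] - i0[0]) * (i1[1] - i1[0]),
            "fraction": float(inside.mean()), "level": level,
        }
    if method == "normal_ellipse":
        from scipy.stats import chi2

        mean = pts.mean(axis=0)
        r2 = chi2.ppf(level, df=2)
        dev = pts - mean
        md2 = np.einsum("ij,jk,ik->i", dev, np.linalg.inv(cov), dev)
        return {
            "method": "normal_ellipse", "mean": mean, "cov": cov, "radius2": r2,
            "area": float(np.pi * r2 * np.sqrt(np.linalg.det(cov))),
            "fraction": float((md2 <= r2).mean()), "level": level,
        }
    if method != "kde":
        raise ValueError("method must be 'kde' or 'normal_ellipse'")
    from scipy.stats import gaussian_kde
    from skimage import measure

    kde = gaussian_kde(pts.T)  # Scott bandwidth by default
    dens_at = kde(pts.T)
    thresh = float(np.quantile(dens_at, 1.0 - level))
    pad = 4.0 * np.sqrt(np.diag(cov))
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    ngrid = 128
    gx = np.linspace(lo[0], hi[0], ngrid)
    gy = np.linspace(lo[1], hi[1], ngrid)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(ngrid, ngrid)
    contours = measure.find_contours(dens, thresh)
    polys = []
    area = 0.0
    for c in contours:
        xs = np.interp(c[:, 0], np.arange(ngrid), gx)
        ys = np.interp(c[:, 1], np.arange(ngrid), gy)
        poly = np.column_stack([xs, ys])
        polys.append(poly)
        area += abs(_shoelace(poly))
    return {
        "method": "kde", "polygons": polys, "threshold": thresh, "area": float(area),
        "fraction": float((dens_at >= thresh).mean()), "level": level,
    }


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def diagnostics(chains: PosteriorChains) -> dict:
    """Split-Rhat and effective sample size per parameter (via ArviZ).

    The single chain is split in half; Rhat > 1.1 triggers a warning naming
    the worst parameter.
    """
    import arviz as az

    out = {}
    worst = (None, -np.inf)
    for name, arr in chains.draws.items():
        m = arr.shape[0]
        half = m // 2
        if half < 2:
            raise ValueError("need at least 4 retained draws for split diagnostics")
        split = np.stack([arr[:half], arr[half: 2 * half]])  # (2, half, ...)
        ds = az.convert_to_dataset(split)
        rhat = np.asarray(az.rhat(ds).to_array()).squeeze(0)
        ess = np.asarray(az.ess(ds).to_array()).squeeze(0)
        out[name] = {"rhat": rhat, "ess": ess}
        if np.max(rhat) > worst[1]:
            worst = (name, float(np.max(rhat)))
    if worst[1] > 1.1:
        warnings.warn(
            f"split-Rhat {worst[1]:.3f} for parameter {worst[0]!r} exceeds 1.1; "
            "chains may not have converged", RuntimeWarning,
        )
    return out
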