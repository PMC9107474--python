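"""Matérn correlation, spatial covariance construction and variogram curves.

The spatial linear mixed model used throughout this package decomposes the
response at location :math:`s` into fixed effects, a correlated Gaussian
random field :math:`u(s)` and an iid nugget :math:`e`:

.. math:: y(s) = x(s)^T \\beta + u(s) + e

with :math:`\\mathrm{cov}[u(s_i), u(s_j)] = \\sigma^2 \\rho(h_{ij})` and
:math:`\\mathrm{var}[e] = \\tau^2`.  The correlation function is the Matérn
family in the :math:`(h/\\phi)^\\kappa K_\\kappa(h/\\phi)` parameterisation,
so the distance parameter ``phi`` is on the same km scale as geoR's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "MaternParams",
    "matern_correlation",
    "pairwise_distances",
    "build_correlation",
    "build_covariance",
    "variogram",
    "chol_with_jitter",
]


@dataclass(frozen=True)
class MaternParams:
    """Random-effects parameters of the spatial LMM.

    tau2
        Nugget variance (response units squared): iid fine-scale variation
        plus measurement error; the discontinuity at the variogram origin.
    sigma2
        Partial sill: variance of the spatially correlated random effect.
    phi
        Matérn distance parameter in km.
    kappa
        Matérn smoothness; 0.5 is the exponential model.
    """

    tau2: float
    sigma2: float
    phi: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.sigma2 < 0:
            raise ValueError("variances tau2 and sigma2 must be non-negative")
        if self.phi <= 0:
            raise ValueError("distance parameter phi must be positive")
        if self.kappa <= 0:
            raise ValueError("smoothness kappa must be positive")

    @property
    def sill(self) -> float:
        """Total sill tau2 + sigma2, the variogram's upper bound."""
        return self.tau2 + self.sigma2


def matern_correlation(h, phi: float, kappa: float):
    """Matérn correlation rho(h) = {2^(kappa-1) Gamma(kappa)}^-1 (h/phi)^kappa K_kappa(h/phi).

    Defined by continuity as 1 at h = 0.  Underflow at very large h/phi
    (where K_kappa underflows to 0) yields 0, the correct limit.

    Parameters
    ----------
    h : array_like
        Non-negative separation distances (km).
    phi, kappa : float
        Distance and smoothness parameters, both > 0.
    """
    if phi <= 0 or kappa <= 0:
        raise ValueError("phi and kappa must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    u = h / phi
    out = np.zeros_like(u)
    pos = u > 0
    up = u[pos]
    with np.errstate(over="ignore", invalid="ignore"):
        # closed forms / fast Bessel routines for the common smoothness
        # values on the profiling grid; generic kv otherwise
        if kappa == 0.5:
            val = np.exp(-up)
        elif kappa == 1.5:
            val = np.exp(-up) * (1.0 + up)
        elif kappa == 2.5:
            val = np.exp(-up) * (1.0 + up + up ** 2 / 3.0)
        elif kappa == 1.0:
            val = up * special.k1(up)
        elif kappa == 2.0:
            # K2(u) = K0(u) + 2 K1(u)/u by the Bessel recurrence
            val = up ** 2 / 2.0 * (special.k0(up) + 2.0 * special.k1(up) / up)
        else:
            val = (
                2.0 ** (1.0 - kappa)
                / special.gamma(kappa)
                * up ** kappa
                * special.kv(kappa, up)
            )
    out[pos] = np.nan_to_num(val, nan=0.0, posinf=0.0, neginf=0.0)
    out[~pos] = 1.0
    # guard tiny overshoots from Bessel evaluation near the origin
    return np.clip(out, 0.0, 1.0) if out.ndim else float(np.clip(out, 0.0, 1.0))


def pairwise_distances(locations: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
    """Planar Euclidean distance matrix for projected (easting, northing) km."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    other = locations if other is None else np.atleast_2d(np.asarray(other, dtype=float))
    return cdist(locations, other)


def build_correlation(locations: np.ndarray, phi: float, kappa: float) -> np.ndarray:
    """Matérn correlation matrix R with R_ij = rho(||s_i - s_j||)."""
    return matern_correlation(pairwise_distances(locations), phi, kappa)


def build_covariance(locations: np.ndarray, params: MaternParams) -> np.ndarray:
    """Covariance C = tau2 * I + sigma2 * R of the observation vector.

    Duplicate locations are legal: they share the correlated effect
    (off-diagonal sigma2) but have independent nuggets.
    """
    n = np.atleast_2d(locations).shape[0]
    C = params.sigma2 * build_correlation(locations, params.phi, params.kappa)
    C[np.diag_indices(n)] += params.tau2
    return C


def variogram(h, params: MaternParams):
    """Semivariance gamma(h) = tau2 + sigma2 * (1 - rho(h)); gamma(0) = 0.

    The returned curve is the model variogram: half the expected squared
    difference between observations at separation h, approaching the sill
    tau2 + sigma2 as h grows.
    """
    h = np.asarray(h, dtype=float)
    rho = matern_correlation(h, params.phi, params.kappa)
    g = params.tau2 + params.sigma2 * (1.0 - rho)
    return np.where(h == 0, 0.0, g)


def chol_with_jitter(C: np.ndarray, max_tries: int = 5):
    """Cholesky factor of C, escalating diagonal jitter on failure.

    Jitter starts at 1e-10 of the mean diagonal and grows tenfold up to
    1e-6 before giving up; needed for tau2 = 0 with near-duplicate
    close-pair locations.
    """
    mean_diag = float(np.mean(np.diag(C)))
    jitter = 0.0
    for attempt in range(max_tries):
        try:
            return cho_factor(C + jitter * np.eye(C.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = mean_diag * 10.0 ** (-10 + attempt)
    raise np.linalg.LinAlgError(
        "covariance matrix not positive definite even after diagonal jitter"
    )


def solve_chol(factor, b: np.ndarray) -> np.ndarray:
    """Solve C x = b given a factor from :func:`chol_with_jitter`."""
    return cho_solve(factor, b)


def cholesky_lower(C: np.ndarray, max_tries: int = 5) -> np.ndarray:
    """Plain lower-triangular Cholesky factor with escalating jitter.

    Unlike :func:`chol_with_jitter` (whose cho_factor output is only valid
    inside cho_solve / solve_triangular) the returned matrix is a genuine
    triangular factor, safe for direct products such as field simulation.
    """
    mean_diag = float(np.mean(np.diag(C)))
    jitter = 0.0
    for attempt in range(max_tries):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
        except np.linalg.LinAlgError:
            jitter = mean_diag * 10.0 ** (-10 + attempt)
    raise np.linalg.LinAlgError(
        "covariance matrix not positive definite even after diagonal jitter"
    )
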