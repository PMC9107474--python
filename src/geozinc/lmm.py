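"""Fitting the Matérn spatial linear mixed model by ML or REML.

Estimation follows the classical geostatistical likelihood approach: the
fixed effects are profiled out by generalised least squares at every
candidate covariance, and the overall variance scale is profiled out in
closed form, leaving a two-dimensional numerical search over the
nugget-to-sill ratio nu = tau2/sigma2 and the distance parameter phi (both
on log scale).  The smoothness kappa is never optimised continuously; it is
profiled over a discrete grid (``profile_kappa``), which is the standard
remedy for its notoriously flat likelihood.

Nested fixed-effect structures fitted by ML are compared with the
log-likelihood-ratio statistic L = 2(l1 - l0), referred to chi-square with
as many degrees of freedom as added effects.  REML likelihoods are refused
for such comparisons because the residual likelihood is not comparable
across fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_solve, solve_triangular

from .matern import MaternParams, chol_with_jitter

__all__ = [
    "SpatialLMMFit",
    "LRTResult",
    "ModelComparison",
    "loglik_at",
    "fit_lmm",
    "profile_kappa",
    "lrt",
    "wald",
    "variogram_of",
    "compare_models",
]

# log(nu) search box: nu = tau2/sigma2 from essentially pure-signal to
# essentially pure-nugget
_LOG_NU_BOUNDS = (-13.8, 13.8)


@dataclass
class SpatialLMMFit:
    """A fitted spatial LMM: GLS fixed effects plus Matérn random effects."""

    beta: np.ndarray
    fixed_effect_names: list[str]
    matern: MaternParams
    loglik: float
    method: str  # "ML" or "REML"
    n: int
    beta_cov: np.ndarray = field(repr=False, default=None)
    data_hash: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.fixed_effect_names):
            raise ValueError("beta and fixed_effect_names lengths differ")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")

    def beta_se(self) -> np.ndarray:
        """GLS standard errors from (X' C^-1 X)^-1."""
        return np.sqrt(np.diag(self.beta_cov))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "loglik": self.loglik,
            "fixed_effects": dict(zip(self.fixed_effect_names, self.beta.tolist())),
            "tau2": self.matern.tau2,
            "sigma2": self.matern.sigma2,
            "phi": self.matern.phi,
            "kappa": self.matern.kappa,
        }


@dataclass(frozen=True)
class LRTResult:
    """Log-likelihood-ratio test of nested ML fits: L = 2(l1 - l0) ~ chi2_df."""

    L: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ModelComparison:
    """Adjusted R2 measures from random-effect variance reduction.

    r2_adj is the drop in total random variance (tau2 + sigma2) relative to
    the null model; r2_adj_c is the drop in the correlated variance sigma2
    alone.  None for r2_adj_c signals a null model without correlated
    variance.
    """

    r2_adj: float
    r2_adj_c: float | None


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _gls(L_factor, X: np.ndarray, y: np.ndarray):
    """GLS quantities given the Cholesky factor of the correlation-scale matrix A.

    Returns beta_hat, the whitened residual quadratic form r'A^-1 r, and
    log|X'A^-1 X| pieces needed by both likelihoods.
    """
    L = L_factor[0]
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    quad = float(resid @ resid)
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' A^-1 X not positive definite")
    return beta, quad, logdet_XtX, XtX


def _profiled_negloglik(log_nu: float, log_phi: float, d_cond: np.ndarray, X: np.ndarray,
                        y: np.ndarray, kappa: float, method: str, cov_cache=None):
    """Negative profile log-likelihood over (nu, phi); scale sigma2 closed-form.

    Writes C = sigma2 * A with A = nu*I + R(phi).  For ML the profile MLE of
    sigma2 is r'A^-1 r / n; for REML it is r'A^-1 r / (n - p).  Distances
    arrive in condensed (upper-triangle) form so the Bessel function is
    evaluated only once per pair.

    ``cov_cache`` memoises the X-independent work (Matérn evaluation,
    Cholesky factor, log-determinant) keyed on (log_nu, log_phi): during
    sequential selection many fits on the same locations re-visit the same
    covariance points.
    """
    from scipy.spatial.distance import squareform

    from .matern import matern_correlation

    n, p = X.shape
    nu = np.exp(log_nu)
    phi = np.exp(log_phi)
    key = (float(log_nu), float(log_phi))
    cached = cov_cache.get(key) if cov_cache is not None else None
    if cached is not None:
        factor, logdet_A = cached
    else:
        A = squareform(matern_correlation(d_cond, phi, kappa))
        A[np.diag_indices(n)] += 1.0 + nu
        try:
            factor = chol_with_jitter(A)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
        # cap the cache by memory (~400 MB of factors)
        if cov_cache is not None and len(cov_cache) * n * n * 8 < 4e8:
            cov_cache[key] = (factor, logdet_A)
    try:
        beta, quad, logdet_XtX, XtX = _gls(factor, X, y)
    except np.linalg.LinAlgError:
        return np.inf, None
    if quad <= 0:
        return np.inf, None
    if method == "ML":
        s2 = quad / n
        nll = 0.5 * (n * np.log(2.0 * np.pi * s2) + logdet_A + n)
    else:  # REML
        s2 = quad / (n - p)
        # log|X' C^-1 X| = log|X' A^-1 X| - p log s2
        nll = 0.5 * (
            (n - p) * np.log(2.0 * np.pi * s2)
            + logdet_A
            + logdet_XtX
            - p * np.log(s2)
            + (n - p)
        )
    return nll, (beta, s2, nu, phi, factor, XtX)


def loglik_at(locations, X, y, params: MaternParams, method: str = "ML"):
    """Exact log-likelihood at given covariance parameters, beta by GLS.

    The ML value equals the multivariate-normal log-density of y with mean
    X beta_hat(GLS) and covariance tau2*I + sigma2*R; the REML value carries
    the standard -0.5 log|X' C^-1 X| adjustment on n - p degrees of freedom.
    Returns (loglik, beta_hat, beta_cov).
    """
    X = _design(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    from .matern import build_covariance

    C = build_covariance(np.asarray(locations, float), params)
    factor = chol_with_jitter(C)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    beta, quad, logdet_XtCX, XtCX = _gls(factor, X, y)
    if method == "ML":
        ll = -0.5 * (n * np.log(2.0 * np.pi) + logdet_C + quad)
    elif method == "REML":
        # canonical residual likelihood of orthonormal error contrasts Ky
        # (KX = 0): log|K C K'| = log|C| + log|X'C^-1 X| - log|X'X|
        sign, logdet_XtX = np.linalg.slogdet(X.T @ X)
        ll = -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdet_C + logdet_XtCX
                     - logdet_XtX + quad)
    else:
        raise ValueError(f"unknown method {method!r}")
    beta_cov = np.linalg.inv(XtCX)
    return ll, beta, beta_cov


_DEFAULT_STARTS = ((0.4, None), (2.0, None), (0.05, None))


def fit_lmm(locations, X, y, fixed_effect_names=None, kappa: float = 1.0,
            method: str = "ML", starts=None, phi_bounds=None,
            xatol: float = 1e-4, fatol: float = 1e-7,
            cov_cache=None) -> SpatialLMMFit:
    """Fit the spatial LMM, maximising the (residual) profile likelihood.

    Parameters
    ----------
    locations : (n, 2) array
        Projected coordinates in km.
    X : (n, p) array
        Fixed-effects design matrix (include the intercept column).
    y : (n,) array
        Response.
    fixed_effect_names : list of str, optional
        Column names for reporting; defaults to x0..x{p-1}.
    kappa : float
        Matérn smoothness, held fixed (profile over a grid with
        :func:`profile_kappa`).
    method : {"ML", "REML"}
    starts : iterable of (nu, phi) pairs, optional
        Optimiser restart points; ``phi = None`` means a data-driven value
        (a fraction of the maximum inter-point distance).  The best restart
        wins, so the reported log-likelihood is non-decreasing in the number
        of starts.
    phi_bounds : (low, high), optional
        Search bounds for phi in km; default spans from half the smallest
        non-zero distance to twice the domain diameter.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"unknown method {method!r}")
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    X = _design(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if fixed_effect_names is None:
        fixed_effect_names = [f"x{j}" for j in range(p)]
    if n <= p + 3:
        raise ValueError("too few observations for the number of fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design matrix is rank deficient")

    from scipy.spatial.distance import pdist

    d_cond = pdist(locations)
    dmax = float(d_cond.max()) if d_cond.size else 0.0
    if dmax == 0:
        raise ValueError("all locations coincide")
    if phi_bounds is None:
        dpos = d_cond[d_cond > 0]
        phi_bounds = (max(float(dpos.min()) / 2.0, 1e-8 * dmax), 2.0 * dmax)
    log_phi_bounds = (np.log(phi_bounds[0]), np.log(phi_bounds[1]))

    if starts is None:
        starts = [
            (nu, phi if phi is not None else f * dmax)
            for (nu, phi), f in zip(_DEFAULT_STARTS, (0.15, 0.05, 0.4))
        ]

    def objective(theta):
        log_nu = np.clip(theta[0], *_LOG_NU_BOUNDS)
        log_phi = np.clip(theta[1], *log_phi_bounds)
        return _profiled_negloglik(log_nu, log_phi, d_cond, X, y, kappa, method,
                                   cov_cache=cov_cache)[0]

    best = None
    for nu0, phi0 in starts:
        x0 = np.array([np.log(nu0), np.log(np.clip(phi0, *phi_bounds))])
        # a generous initial simplex reaches the optimum in fewer
        # reflections than Nelder-Mead's default 5% perturbation
        simplex = np.array([x0, x0 + [0.4, 0.0], x0 + [0.0, 0.4]])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 400,
                     "initial_simplex": simplex},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("spatial LMM optimisation failed to converge from all starts")

    log_nu = float(np.clip(best.x[0], *_LOG_NU_BOUNDS))
    log_phi = float(np.clip(best.x[1], *log_phi_bounds))
    nll, aux = _profiled_negloglik(log_nu, log_phi, d_cond, X, y, kappa, method,
                                   cov_cache=cov_cache)
    beta, s2, nu, phi, _, _ = aux
    sigma2 = s2
    tau2 = nu * s2
    params = MaternParams(tau2=tau2, sigma2=sigma2, phi=phi, kappa=kappa)
    # report the exact likelihood and GLS covariance at the optimum
    ll, beta, beta_cov = loglik_at(locations, X, y, params, method)
    return SpatialLMMFit(
        beta=beta,
        fixed_effect_names=list(fixed_effect_names),
        matern=params,
        loglik=float(ll),
        method=method,
        n=n,
        beta_cov=beta_cov,
        data_hash=_data_hash(locations, X, y),
    )


def _data_hash(locations, X, y) -> int:
    h = hash((locations.tobytes(), np.asarray(y, float).tobytes()))
    return h & 0x7FFFFFFF


def profile_kappa(locations, X, y, kappa_grid=(0.25, 0.5, 1.0, 1.5, 2.0, 2.5),
                  method: str = "ML", fixed_effect_names=None):
    """Profile the Matérn smoothness over a discrete grid.

    Refits the model at each kappa and returns ``(best_kappa, fits)`` where
    ``fits`` maps each converged kappa to its :class:`SpatialLMMFit`.  The
    winning kappa (largest log-likelihood) is conventionally then reused for
    every subsequent model on the same data.
    """
    kappa_grid = list(kappa_grid)
    if not kappa_grid:
        raise ValueError("kappa grid is empty")
    fits: dict[float, SpatialLMMFit] = {}
    for k in kappa_grid:
        try:
            fits[k] = fit_lmm(locations, X, y, fixed_effect_names=fixed_effect_names,
                              kappa=k, method=method)
        except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"kappa={k}: fit failed ({exc}); grid point skipped")
    if not fits:
        raise RuntimeError("no kappa grid point converged")
    best = max(fits, key=lambda k: fits[k].loglik)
    return best, fits


def lrt(fit0: SpatialLMMFit, fit1: SpatialLMMFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits (fit0 nested in fit1).

    L = 2(l1 - l0), clipped at zero against optimiser noise, referred to the
    upper tail of chi-square with df = number of added fixed effects.
    """
    if fit0.method != "ML" or fit1.method != "ML":
        raise ValueError("LRT requires both fits by ML; REML likelihoods are "
                         "not comparable across fixed-effect structures")
    if fit0.data_hash != fit1.data_hash or fit0.n != fit1.n:
        raise ValueError("LRT requires both models fitted to identical data")
    extra = set(fit1.fixed_effect_names) - set(fit0.fixed_effect_names)
    if set(fit0.fixed_effect_names) - set(fit1.fixed_effect_names):
        raise ValueError("fit0 fixed effects must be a subset of fit1's")
    df = len(extra)
    if df == 0:
        return LRTResult(L=0.0, df=0, p_value=1.0)
    L = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    p = float(stats.chi2.sf(L, df))
    return LRTResult(L=L, df=df, p_value=p)


def wald(fit: SpatialLMMFit, coefficient_name: str):
    """Wald test of a single coefficient: (beta_hat/SE)^2 referred to chi2_1.

    Returns ``(statistic, p_value)``.  The SE comes from the GLS covariance
    (X' C^-1 X)^-1 at the fitted covariance parameters.
    """
    try:
        j = fit.fixed_effect_names.index(coefficient_name)
    except ValueError:
        raise KeyError(f"coefficient {coefficient_name!r} not in fit") from None
    var = fit.beta_cov[j, j]
    if var <= 0 or not np.isfinite(var):
        raise np.linalg.LinAlgError("singular information for Wald test")
    W = float(fit.beta[j] ** 2 / var)
    return W, float(stats.chi2.sf(W, 1))


def variogram_of(fit: SpatialLMMFit, distances=None):
    """Model variogram gamma(h) = tau2 + sigma2 (1 - rho(h)) of a fit.

    Returns ``(distances, semivariances)`` on a default grid out to five
    distance parameters if no grid is supplied.
    """
    from .matern import variogram

    if distances is None:
        distances = np.linspace(0.0, 5.0 * fit.matern.phi, 201)
    distances = np.asarray(distances, dtype=float)
    return distances, variogram(distances, fit.matern)


def compare_models(null_fit, fit) -> ModelComparison:
    """Variance-explained summary of a model against the null model.

    Accepts fits or bare :class:`~geozinc.matern.MaternParams`.  Computes

    - ``r2_adj``  = [(tau2_0 + sigma2_0) - (tau2_1 + sigma2_1)] / (tau2_0 + sigma2_0)
    - ``r2_adj_c`` = (sigma2_0 - sigma2_1) / sigma2_0

    the proportions of total and of spatially correlated random variance
    removed by the added fixed effects.  ``r2_adj_c`` is None when the null
    model has no correlated variance.
    """
    m0 = null_fit.matern if isinstance(null_fit, SpatialLMMFit) else null_fit
    m1 = fit.matern if isinstance(fit, SpatialLMMFit) else fit
    total0 = m0.tau2 + m0.sigma2
    if total0 <= 0:
        raise ValueError("null model has zero total random variance")
    r2_adj = (total0 - (m1.tau2 + m1.sigma2)) / total0
    r2_adj_c = None if m0.sigma2 == 0 else (m0.sigma2 - m1.sigma2) / m0.sigma2
    return ModelComparison(r2_adj=float(r2_adj), r2_adj_c=r2_adj_c)
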