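"""EM fitting of one five-component Gaussian mixture on the transformed scale.

Each mixture variant is defined by a mean model (1..4), a constraint flag for
the mixing proportions (free, or Hardy-Weinberg binomial ratios driven by a
single allele frequency) and a starting configuration of component means.
The E-step computes posterior dosage memberships in log space; the M-step
re-estimates mixing proportions in closed form and the mean-model parameters
plus the common standard deviation by weighted nonlinear least squares,
warm-started from the current parameters.

Fitting is fully deterministic: both start configurations are deterministic
functions of the data and no random numbers are used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .model import (
    DOSAGES,
    MODEL_PARAM_NAMES,
    PARAM_LOWER_BOUNDS,
    PLOIDY,
    MeanModelParams,
    asr_transform,
    hwe_proportions,
    mean_model_eval,
    parameter_count,
)

# Convergence and numerical safeguards (transformed scale).
MAX_ITER = 500
LOGLIK_TOL = 1e-6
SIGMA_FLOOR = 1e-4

#: Equidistant start grid endpoints: asr(0.02) .. asr(0.98).
EQUIDISTANT_LO = asr_transform(0.02)
EQUIDISTANT_HI = asr_transform(0.98)


class FitFailure(RuntimeError):
    """A single mixture fit failed numerically; callers treat it per-start."""


@dataclass
class MixtureFit:
    """One converged (or stopped) mixture fit and its selection statistics."""

    model_id: int
    hwe_constrained: bool
    params: MeanModelParams
    mu: np.ndarray
    sigma: float
    pi: np.ndarray
    p: float | None
    loglik: float
    k: int
    bic: float
    n: int
    posteriors: np.ndarray
    converged: bool
    n_iter: int
    start_label: str
    loglik_path: list[float] = field(default_factory=list)

    @property
    def p_allele_a(self) -> float | None:
        """Frequency of the a allele implied by the HWE constraint."""
        return None if self.p is None else 1.0 - self.p


def start_means_equidistant() -> np.ndarray:
    """Five equally spaced start means on the transformed scale.

    Spans asr(0.02) to asr(0.98), i.e. 0.142 to 1.429, covering the usable
    ratio range while avoiding the exact boundaries.
    """
    return np.linspace(EQUIDISTANT_LO, EQUIDISTANT_HI, 5)


def start_means_clustering(y: np.ndarray) -> np.ndarray:
    """Five start means from complete-linkage hierarchical clustering of y.

    The dendrogram is cut at five groups and the group means returned in
    ascending order.  When fewer than five distinct groups emerge the means
    are padded by inserting the midpoint of the widest adjacent gap until
    five values exist; fully degenerate input (all observations identical)
    yields five identical means, which callers should replace with the
    equidistant grid.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 5:
        raise ValueError("clustering start requires at least 5 observations")
    Z = linkage(y.reshape(-1, 1), method="complete")
    labels = fcluster(Z, t=5, criterion="maxclust")
    means = np.sort([y[labels == g].mean() for g in np.unique(labels)])
    means = np.unique(means)
    if means.size == 1:
        return np.repeat(means, 5)
    while means.size < 5:
        gaps = np.diff(means)
        i = int(np.argmax(gaps))
        means = np.sort(np.append(means, 0.5 * (means[i] + means[i + 1])))
    return means


def _log_normal_pdf(y: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    z = (y[:, None] - mu[None, :]) / sigma
    return -0.5 * z**2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)


def e_step(y, mu, sigma, pi, return_loglik: bool = False):
    """Posterior membership probabilities of each observation in each class.

    Computed in log space with log-sum-exp normalization.  Rows whose total
    density underflows to zero fall back to the prior ``pi``.  With
    ``return_loglik`` also returns the observed-data log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    logjoint = logpi[None, :] + _log_normal_pdf(y, mu, sigma)
    lognorm = logsumexp(logjoint, axis=1)
    bad = ~np.isfinite(lognorm)
    with np.errstate(invalid="ignore"):
        post = np.exp(logjoint - lognorm[:, None])
    if bad.any():
        post[bad] = pi
    if return_loglik:
        loglik = float(lognorm.sum()) if not bad.any() else -np.inf
        return post, loglik
    return post


def mixture_loglik(y, mu, sigma, pi) -> float:
    """Observed-data log-likelihood of a five-component normal mixture."""
    _, ll = e_step(y, mu, sigma, pi, return_loglik=True)
    return ll


def m_step_proportions(posteriors: np.ndarray, hwe_constrained: bool):
    """Update mixing proportions from posteriors.

    Free: column means.  HWE: closed-form dosage-weighted binomial MLE of
    the b-allele frequency, ``p = sum_ij post_ij (4 - x_j) / (4 n)``, then
    the binomial proportions from it.  Returns ``(pi, p_or_None)``.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.size == 0:
        raise ValueError("empty posterior matrix")
    if not hwe_constrained:
        return post.mean(axis=0), None
    n = post.shape[0]
    p = float((post * (PLOIDY - DOSAGES)[None, :]).sum() / (PLOIDY * n))
    p = min(max(p, 0.0), 1.0)
    return hwe_proportions(p), p


def _bounds_for(names: list[str]):
    lower = np.array([PARAM_LOWER_BOUNDS[n] for n in names])
    upper = np.full(len(names), np.inf)
    return lower, upper


def _free_names(model_id: int, fixed: dict[str, float] | None) -> list[str]:
    fixed = fixed or {}
    return [n for n in MODEL_PARAM_NAMES[model_id] if n not in fixed]


def m_step_means(
    y,
    posteriors,
    model_id: int,
    current_params: MeanModelParams,
    fixed: dict[str, float] | None = None,
    sigma_floor: float = SIGMA_FLOOR,
):
    """Weighted nonlinear least-squares update of mean-model parameters and sigma.

    Minimizes ``sum_ij post_ij (y_i - mu_j(theta))^2`` subject to the
    parameter bounds.  The double sum collapses exactly into five residuals
    ``sqrt(W_j) (ybar_j - mu_j(theta))`` plus a theta-independent
    within-class term, with ``W_j`` the posterior column mass and ``ybar_j``
    the posterior-weighted class mean.  ``sigma**2`` is the minimized
    weighted residual sum of squares divided by n, floored at
    ``sigma_floor``.
    """
    y = np.asarray(y, dtype=float)
    post = np.asarray(posteriors, dtype=float)
    n = y.size
    W = post.sum(axis=0)
    Sy = post.T @ y
    Syy = post.T @ (y * y)
    mu_cur = mean_model_eval(current_params, DOSAGES)
    ybar = np.where(W > 0, Sy / np.where(W > 0, W, 1.0), mu_cur)
    within = float(np.clip(Syy - W * ybar**2, 0.0, None).sum())
    sqw = np.sqrt(W)

    names = _free_names(model_id, fixed)
    lower, upper = _bounds_for(names)
    x0 = np.clip(current_params.to_vector(fixed), lower + 1e-12, None)

    def resid(vec):
        prm = MeanModelParams.from_vector(model_id, vec, fixed)
        return sqw * (ybar - mean_model_eval(prm, DOSAGES))

    if names:
        try:
            sol = least_squares(resid, x0, bounds=(lower, upper))
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            raise FitFailure(f"NLS M-step failed: {exc}") from exc
        if not np.all(np.isfinite(sol.x)):
            raise FitFailure("NLS M-step returned non-finite parameters")
        new_params = MeanModelParams.from_vector(model_id, sol.x, fixed)
    else:
        new_params = current_params
    mu_new = mean_model_eval(new_params, DOSAGES)
    rss = within + float((W * (ybar - mu_new) ** 2).sum())
    sigma = max(np.sqrt(rss / n), sigma_floor)
    return new_params, sigma


def params_from_start_means(
    start_means,
    model_id: int,
    fixed: dict[str, float] | None = None,
) -> MeanModelParams:
    """Project five start means onto a mean model by unweighted least squares."""
    start_means = np.asarray(start_means, dtype=float)
    names = _free_names(model_id, fixed)
    lower, upper = _bounds_for(names)
    # Neutral initial guess: small backgrounds, curvature off, r solved from
    # the central start mean under the no-background linear model.
    f2 = float(np.clip(np.sin(start_means[2]) ** 2, 0.01, 0.99))
    init = {"c1": 0.05, "c2": 0.05, "c": 0.05, "r": np.clip(1.0 / f2 - 1.0, 1e-3, 1e3), "d": 0.01}
    x0 = np.clip(np.array([init[n] for n in names]), lower + 1e-12, None)
    if not names:
        return MeanModelParams.from_vector(model_id, [], fixed)

    def resid(vec):
        prm = MeanModelParams.from_vector(model_id, vec, fixed)
        return mean_model_eval(prm, DOSAGES) - start_means

    sol = least_squares(resid, x0, bounds=(lower, upper))
    if not np.all(np.isfinite(sol.x)):
        raise FitFailure("start-mean projection returned non-finite parameters")
    return MeanModelParams.from_vector(model_id, sol.x, fixed)


def _sigma_init(y: np.ndarray, start_means: np.ndarray, sigma_floor: float) -> float:
    """Pooled within-group SD of the hard assignment to the nearest start mean."""
    nearest = np.argmin(np.abs(y[:, None] - start_means[None, :]), axis=1)
    rss = float(((y - start_means[nearest]) ** 2).sum())
    return max(np.sqrt(rss / y.size), sigma_floor)


def fit_mixture(
    y,
    model_id: int,
    hwe_constrained: bool,
    start_means,
    *,
    start_label: str = "",
    fixed: dict[str, float] | None = None,
    max_iter: int = MAX_ITER,
    tol: float = LOGLIK_TOL,
    sigma_floor: float = SIGMA_FLOOR,
    min_obs: int = 10,
) -> MixtureFit:
    """Fit one mixture variant by EM from a given start configuration.

    Parameters are initialized by projecting the start means onto the mean
    model; sigma starts at the pooled within-group SD of the hard start
    assignment; mixing proportions start uniform (free) or at allele
    frequency 0.5 (HWE).  Iterates E/M until the log-likelihood changes by
    less than ``tol`` or ``max_iter`` is reached.

    Raises
    ------
    FitFailure
        On degenerate data (zero spread) or numerical failure; the marker
        pipeline records such failures per start and continues.
    """
    y = np.asarray(y, dtype=float)
    if y.size < min_obs:
        raise FitFailure(f"need at least {min_obs} observations, got {y.size}")
    if float(np.ptp(y)) < 1e-12:
        raise FitFailure("degenerate data: all observations identical")
    start_means = np.asarray(start_means, dtype=float)

    params = params_from_start_means(start_means, model_id, fixed)
    sigma = _sigma_init(y, start_means, sigma_floor)
    if hwe_constrained:
        p = 0.5
        pi = hwe_proportions(p)
    else:
        p = None
        pi = np.full(5, 0.2)

    ll_prev = -np.inf
    ll_path: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = mean_model_eval(params, DOSAGES)
        post, ll = e_step(y, mu, sigma, pi, return_loglik=True)
        ll_path.append(ll)
        if not np.isfinite(ll):
            raise FitFailure("non-finite log-likelihood")
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        pi, p = m_step_proportions(post, hwe_constrained)
        params, sigma = m_step_means(
            y, post, model_id, params, fixed=fixed, sigma_floor=sigma_floor
        )

    mu = mean_model_eval(params, DOSAGES)
    post, ll = e_step(y, mu, sigma, pi, return_loglik=True)
    if not np.isfinite(ll):
        raise FitFailure("non-finite log-likelihood at convergence")
    if ll_path and ll != ll_path[-1]:
        ll_path.append(ll)
    k = parameter_count(model_id, hwe_constrained)
    bic = -2.0 * ll + k * np.log(y.size)
    return MixtureFit(
        model_id=model_id,
        hwe_constrained=hwe_constrained,
        params=params,
        mu=mu,
        sigma=float(sigma),
        pi=np.asarray(pi, dtype=float),
        p=p,
        loglik=ll,
        k=k,
        bic=float(bic),
        n=int(y.size),
        posteriors=post,
        converged=converged,
        n_iter=n_iter,
        start_label=start_label,
        loglik_path=ll_path,
    )
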