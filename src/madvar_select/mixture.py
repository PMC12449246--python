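"""Two-component Gaussian mixture fitting and the weighted-density intersection cutoff.

A two-component univariate normal mixture is fitted by EM to the score
distribution; component 1 models the near-zero peak and component 2 the
variable tail.  The cutoff is the x where the weighted component densities
are equal,

    lambda1 * phi(x; mu1, sigma1) = lambda2 * phi(x; mu2, sigma2),

which after taking logs reduces to the quadratic A*x^2 + B*x + C = 0 with

    A = 1/(2*sigma2^2) - 1/(2*sigma1^2)
    B = mu1/sigma1^2 - mu2/sigma2^2
    C = mu2^2/(2*sigma2^2) - mu1^2/(2*sigma1^2) + ln(lambda1*sigma2 / (lambda2*sigma1))

Of the (up to) two real roots, the one inside (mu1, mu2) is the class
boundary between the two populations; a second crossing in a tail is kept as
a diagnostic only.  When the variances are (numerically) equal the equation
is linear with solution (mu1+mu2)/2 + sigma^2 * ln(lambda1/lambda2) / (mu2-mu1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ScoreVector, ThresholdResult
from .exceptions import FitError, InvalidInputError, InvalidParameterError, NoIntersectionError

__all__ = [
    "MixtureFit",
    "fit_two_component_gmm",
    "intersect_distributions",
    "weighted_density_intersection",
    "gmm_cutoff",
]

_EQUAL_VARIANCE_TOL = 1e-12  # |A| below this -> treat as equal variances


@dataclass(frozen=True)
class MixtureFit:
    """Parameters of a fitted two-component univariate normal mixture.

    Components are ordered so ``mu1 <= mu2`` (component 1 is the near-zero
    peak).  ``loglik`` is the final observed-data log-likelihood.
    """

    lambda1: float
    lambda2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float = float("nan")
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        if not math.isclose(self.lambda1 + self.lambda2, 1.0, abs_tol=1e-12):
            raise InvalidInputError("mixing proportions must sum to 1")
        if not (0 < self.lambda1 < 1):
            raise InvalidInputError("mixing proportions must be in (0, 1)")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise InvalidInputError("component standard deviations must be > 0")
        if self.mu1 > self.mu2:
            raise InvalidInputError("components must be ordered so mu1 <= mu2")


def _em(x, lam, mu, sig, tol, max_iter, sigma_floor):
    """Plain EM for a 2-component normal mixture; returns (params, loglik_path)."""
    lam = np.array(lam, dtype=float)
    mu = np.array(mu, dtype=float)
    sig = np.array(sig, dtype=float)
    loglik_path = []
    prev = -np.inf
    for it in range(1, max_iter + 1):
        # E step
        log_comp = np.stack([
            np.log(lam[k]) + stats.norm.logpdf(x, mu[k], sig[k]) for k in (0, 1)
        ])
        log_mix = np.logaddexp(log_comp[0], log_comp[1])
        loglik = float(np.sum(log_mix))
        loglik_path.append(loglik)
        resp = np.exp(log_comp - log_mix)
        # M step
        nk = resp.sum(axis=1)
        lam = nk / x.size
        mu = (resp @ x) / nk
        sig = np.sqrt(np.maximum((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk, 0.0))
        if np.any(sig < sigma_floor):
            raise FitError("component standard deviation collapsed")
        if loglik - prev < tol and it > 1:
            return (lam, mu, sig), loglik_path, True
        prev = loglik
    return (lam, mu, sig), loglik_path, False


def fit_two_component_gmm(
    s: ScoreVector | np.ndarray,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    return_loglik_path: bool = False,
):
    """Fit a 2-component normal mixture to scores by EM.

    Initialization is deterministic: component means at the 10th and 90th
    percentiles, equal weights, pooled standard deviation.  ``seed`` only
    controls the perturbation applied on restarts after a degenerate fit
    (a component's sigma collapsing below 1e-6 times the data SD); up to 3
    restarts are attempted before raising :class:`FitError`.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be > 0")
    x = np.asarray(s.scores if isinstance(s, ScoreVector) else s, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("scores contain non-finite values")
    if x.size < 10:
        raise InvalidInputError("mixture fitting needs at least 10 scores")

    data_sd = float(np.std(x))
    if data_sd == 0:
        raise InvalidInputError("all scores identical; mixture is degenerate")
    # floor on a robust scale: heavy-tailed scores (e.g. epsilon-floored
    # bio/tech ratios) inflate the plain SD by orders of magnitude, which
    # would put the collapse floor above the near-zero component's true width
    robust_sd = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    sigma_floor = 1e-6 * (robust_sd if robust_sd > 0 else data_sd)

    mu0 = np.percentile(x, [10.0, 90.0])
    init = (np.array([0.5, 0.5]), mu0.copy(), np.array([data_sd, data_sd]))
    rng = np.random.default_rng(seed)
    last_err = None
    for attempt in range(4):
        try:
            (lam, mu, sig), path, converged = _em(
                x, *init, tol=tol, max_iter=max_iter, sigma_floor=sigma_floor)
            break
        except FitError as err:
            last_err = err
            jitter = rng.normal(scale=0.1 * data_sd, size=2)
            init = (np.array([0.5, 0.5]), mu0 + jitter,
                    np.array([data_sd, data_sd]) * rng.uniform(0.5, 1.5, size=2))
    else:
        raise FitError(f"mixture fit degenerate after 3 restarts: {last_err}")

    order = np.argsort(mu)
    lam, mu, sig = lam[order], mu[order], sig[order]
    fit = MixtureFit(
        lambda1=float(lam[0]), lambda2=float(lam[1]),
        mu1=float(mu[0]), mu2=float(mu[1]),
        sigma1=float(sig[0]), sigma2=float(sig[1]),
        loglik=path[-1], converged=converged, n_iter=len(path),
    )
    if return_loglik_path:
        return fit, np.array(path)
    return fit


def weighted_density_intersection(
    lambda1: float, mu1: float, sigma1: float,
    lambda2: float, mu2: float, sigma2: float,
) -> float:
    """Root of lambda1*phi(x;mu1,sigma1) = lambda2*phi(x;mu2,sigma2) between the means.

    Symmetric in the component labels (swapping components gives the same x).
    Raises :class:`NoIntersectionError` (carrying any real roots found) when
    the densities do not cross between the component means, which happens
    when one component dominates the whole interval.
    """
    if mu1 > mu2:  # the equality is label-symmetric; canonicalize
        lambda1, mu1, sigma1, lambda2, mu2, sigma2 = lambda2, mu2, sigma2, lambda1, mu1, sigma1
    if not mu1 < mu2:
        raise InvalidInputError("component means must satisfy mu1 < mu2 (strictly)")
    v1, v2 = sigma1 ** 2, sigma2 ** 2
    a = 1.0 / (2.0 * v2) - 1.0 / (2.0 * v1)
    b = mu1 / v1 - mu2 / v2
    c = (mu2 ** 2 / (2.0 * v2) - mu1 ** 2 / (2.0 * v1)
         + math.log(lambda1 * sigma2 / (lambda2 * sigma1)))

    if abs(a) < _EQUAL_VARIANCE_TOL:
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise NoIntersectionError(
                "weighted densities never intersect (negative discriminant)")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]

    inside = [r for r in roots if mu1 < r < mu2]
    if not inside:
        raise NoIntersectionError(
            f"no density crossing inside ({mu1:.6g}, {mu2:.6g}); "
            f"roots found at {sorted(roots)}",
            roots=sorted(roots),
        )
    return float(inside[0])


def intersect_distributions(f: MixtureFit) -> float:
    """x where the two weighted component densities of a fit are equal, inside (mu1, mu2)."""
    return weighted_density_intersection(
        f.lambda1, f.mu1, f.sigma1, f.lambda2, f.mu2, f.sigma2)


def gmm_cutoff(
    s: ScoreVector,
    seed: int = 0,
    log_transform: bool = False,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ThresholdResult:
    """Mixture-intersection cutoff on a score vector.

    With ``log_transform`` the mixture is fitted to ``log1p(scores)`` and the
    intersection is back-transformed with ``expm1`` — useful when the variance
    tail is very heavy.  A failed intersection is re-raised with a hint to
    fall back to the MAD cutoff.
    """
    x = np.asarray(s.scores, dtype=float)
    fit_scores = np.log1p(x) if log_transform else x
    fit = fit_two_component_gmm(
        ScoreVector(fit_scores, list(s.feature_ids), score_name="custom"),
        seed=seed, tol=tol, max_iter=max_iter)
    try:
        xs = intersect_distributions(fit)
    except NoIntersectionError as err:
        raise NoIntersectionError(
            f"{err}; consider the MAD cutoff (mad_cutoff) as a fallback",
            roots=err.roots) from err
    cutoff = float(np.expm1(xs)) if log_transform else float(xs)
    return ThresholdResult(
        cutoff=cutoff,
        method="gmm_intersection",
        params={
            "lambda1": fit.lambda1, "lambda2": fit.lambda2,
            "mu1": fit.mu1, "mu2": fit.mu2,
            "sigma1": fit.sigma1, "sigma2": fit.sigma2,
            "loglik": fit.loglik, "converged": fit.converged, "n_iter": fit.n_iter,
            "log_transform": log_transform, "intersection": float(xs), "seed": seed,
        },
        n_selected=int(np.sum(x > cutoff)),
        n_total=x.size,
    )
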