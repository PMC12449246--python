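"""Per-feature selection scores: variance and the mean-variance trend model.

Two scores are supported.  The first is the plain unbiased sample variance of
each feature across samples.  The second comes from mean-variance trend
modelling: a smooth non-negative trend of total variance against mean
abundance is fitted across all features, the trend value at a feature's mean
is taken as its *technical* variance and the residual as its *biological*
variance, and a one-sided test of "biological variance <= 0" yields per-feature
p-values and Benjamini-Hochberg FDRs.  The bio/tech ratio is itself
right-skewed and can be thresholded by any of the cutoff methods in
:mod:`madvar_select.thresholding`.

The trend fitter is a lowess regression of variance on mean with fitted
values clamped at zero; it approximates (and does not replicate) the
parametric/loess hybrid used by scran's ``modelGeneVar``.  The p-value uses
the normal-approximation standard error of a sample variance,
``SE = tech * sqrt(2 / (n - 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import FeatureMatrix, ScoreVector
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "TrendFit",
    "compute_feature_variance",
    "shift_nonnegative",
    "fit_mean_variance_trend",
    "bio_tech_ratio",
    "fdr_filter",
]


def compute_feature_variance(m: FeatureMatrix) -> ScoreVector:
    """Unbiased (n-1 denominator) sample variance per feature."""
    if m.n_samples < 2:
        raise InvalidInputError("variance requires at least 2 samples")
    var = m.values.var(axis=1, ddof=1)
    return ScoreVector(var, list(m.feature_ids), score_name="variance")


def shift_nonnegative(m: FeatureMatrix) -> FeatureMatrix:
    """Shift the whole matrix so its global minimum is zero.

    No-op when the matrix is already non-negative.  A global additive shift
    leaves every per-feature variance unchanged; it only matters for methods
    that assume non-negative abundances.
    """
    lo = m.values.min()
    if lo >= 0:
        return m
    return FeatureMatrix(m.values - lo, list(m.feature_ids), list(m.sample_ids))


@dataclass(frozen=True)
class TrendFit:
    """Per-feature decomposition of total variance into trend (tech) + residual (bio).

    ``bio + tech == total_var`` holds exactly by construction.  ``fdr`` is the
    Benjamini-Hochberg step-up adjustment of the one-sided p-values.
    ``trend`` maps mean abundance to the fitted technical variance.
    """

    feature_ids: list[str]
    mean: np.ndarray
    total_var: np.ndarray
    tech: np.ndarray
    bio: np.ndarray
    p_value: np.ndarray
    fdr: np.ndarray
    trend: Callable[[np.ndarray], np.ndarray]
    n_samples: int
    span: float


def _trend_evaluator(grid_x: np.ndarray, grid_y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    def evaluate(x):
        return np.interp(np.asarray(x, dtype=float), grid_x, grid_y)
    return evaluate


def fit_mean_variance_trend(m: FeatureMatrix, span: float = 0.3) -> TrendFit:
    """Fit the mean-variance trend and decompose each feature's variance.

    Parameters
    ----------
    m : FeatureMatrix
        Pre-normalized abundance matrix; negative matrices should be passed
        through :func:`shift_nonnegative` first.
    span : float
        Lowess span (fraction of features in each local fit), in (0, 1].

    Returns
    -------
    TrendFit with per-feature mean, total/tech/bio variance, one-sided
    p-value for the null "bio <= 0", and BH FDR.
    """
    if not (0 < span <= 1):
        raise InvalidParameterError(f"span must be in (0, 1], got {span}")
    if m.n_features < 20:
        raise InvalidInputError("trend fitting needs at least 20 features")
    n = m.n_samples
    mean = m.values.mean(axis=1)
    total_var = m.values.var(axis=1, ddof=1)
    if np.ptp(mean) == 0:
        raise InvalidInputError("all feature means identical; trend is degenerate")

    fitted = lowess(total_var, mean, frac=span, return_sorted=True)
    grid_x, grid_y = fitted[:, 0], fitted[:, 1]
    # collapse ties in x so interpolation is well defined
    ux, inverse = np.unique(grid_x, return_inverse=True)
    uy = np.bincount(inverse, weights=grid_y) / np.bincount(inverse)
    uy = np.clip(uy, 0.0, None)
    trend = _trend_evaluator(ux, uy)

    tech = trend(mean)
    bio = total_var - tech

    # z-test against bio <= 0 with SE = tech * sqrt(2/(n-1)); where the trend
    # is exactly zero the test degenerates and the sign of bio decides.
    se = tech * np.sqrt(2.0 / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, bio / np.where(se > 0, se, 1.0), np.sign(bio) * np.inf)
    z = np.where((se == 0) & (bio == 0), 0.0, z)
    p = stats.norm.sf(z)
    fdr = multipletests(p, method="fdr_bh")[1]

    return TrendFit(
        feature_ids=list(m.feature_ids),
        mean=mean,
        total_var=total_var,
        tech=tech,
        bio=bio,
        p_value=p,
        fdr=fdr,
        trend=trend,
        n_samples=n,
        span=span,
    )


def bio_tech_ratio(t: TrendFit, epsilon: float = 1e-8) -> ScoreVector:
    """Ratio of biological to technical variance, floored at ``epsilon`` in the denominator."""
    if epsilon <= 0:
        raise InvalidParameterError("epsilon must be > 0")
    scores = t.bio / np.maximum(t.tech, epsilon)
    return ScoreVector(scores, list(t.feature_ids), score_name="biotech_ratio")


def fdr_filter(t: TrendFit, alpha: float = 0.05) -> set[str]:
    """Features with FDR <= alpha and positive biological variance."""
    if not (0 < alpha < 1):
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    keep = (t.fdr <= alpha) & (t.bio > 0)
    return {f for f, k in zip(t.feature_ids, keep) if k}
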