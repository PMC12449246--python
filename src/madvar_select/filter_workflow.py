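"""User-facing filtering workflows.

`madvar` is the complete workflow: it accepts either a features-by-samples
matrix or a precomputed score vector, detects the input type, computes the
MAD-based variance cutoff, and either returns the filtered matrix (matrix
input) or just the cutoff value (vector input).  A must-genes list rescues
named features from filtering, and exploration mode emits the score density
with the cutoff annotated so the user can judge where the cutoff falls
relative to the near-zero peak.

`select_features` generalizes this to the full score x threshold grid:
{variance, bio/tech ratio} x {madvar, elbow, knee, gmm, fdr}, nine valid
combinations in total (the FDR threshold only applies to the trend-model
scoring path).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats

from .containers import FeatureMatrix, ScoreVector, ThresholdResult
from .exceptions import InvalidInputError, InvalidParameterError
from .mixture import gmm_cutoff
from .scoring import (
    bio_tech_ratio,
    compute_feature_variance,
    fdr_filter,
    fit_mean_variance_trend,
    shift_nonnegative,
)
from .thresholding import elbow_cutoff, knee_cutoff, mad_cutoff

logger = logging.getLogger(__name__)

__all__ = [
    "FilterOutcome",
    "DensityCurve",
    "madvar",
    "apply_cutoff",
    "exploration_density",
    "select_features",
    "VALID_COMBINATIONS",
]

VALID_COMBINATIONS = (
    ("variance", "madvar"),
    ("variance", "elbow"),
    ("variance", "knee"),
    ("variance", "gmm"),
    ("biotech_ratio", "fdr"),
    ("biotech_ratio", "madvar"),
    ("biotech_ratio", "elbow"),
    ("biotech_ratio", "knee"),
    ("biotech_ratio", "gmm"),
)


@dataclass(frozen=True)
class DensityCurve:
    """Plot-ready kernel density of a score vector with the cutoff annotated."""

    grid: np.ndarray
    density: np.ndarray
    cutoff: float


@dataclass(frozen=True)
class FilterOutcome:
    """Result of applying a threshold to a feature matrix.

    ``kept_ids`` and ``dropped_ids`` partition the input features and both
    preserve input order.  ``must_kept`` lists features retained only because
    they were requested via must-genes (their score is at or below the
    cutoff).  ``matrix`` is the row-subset filtered matrix when the workflow
    was run on a matrix; ``density`` is populated in exploration mode.
    """

    kept_ids: list[str]
    dropped_ids: list[str]
    threshold: ThresholdResult
    must_kept: list[str] = field(default_factory=list)
    matrix: FeatureMatrix | None = None
    density: DensityCurve | None = None

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


def apply_cutoff(
    m: FeatureMatrix,
    s: ScoreVector,
    t: ThresholdResult,
    must_genes: Iterable[str] = (),
) -> FilterOutcome:
    """Keep features with score strictly above the cutoff, plus any must-genes.

    Feature order of the input matrix is preserved in both partitions.
    Must-genes absent from the matrix raise a warning, not an error.
    """
    if list(s.feature_ids) != list(m.feature_ids):
        raise InvalidInputError("score vector is not aligned with the matrix features")
    must = list(dict.fromkeys(str(g) for g in must_genes))
    present = set(m.feature_ids)
    missing = [g for g in must if g not in present]
    if missing:
        warnings.warn(f"must-genes not found in the input: {missing}", stacklevel=2)
    must_present = {g for g in must if g in present}

    # explicit no-knee result: the cutoff is the min score but nothing is filtered
    keep_all = dict(t.params).get("knee_found") is False

    kept, dropped, rescued = [], [], []
    for fid, score in zip(m.feature_ids, s.scores):
        if keep_all or score > t.cutoff:
            kept.append(fid)
        elif fid in must_present:
            kept.append(fid)
            rescued.append(fid)
        else:
            dropped.append(fid)
    if not kept:
        logger.warning("cutoff %.6g excludes every feature", t.cutoff)
    return FilterOutcome(
        kept_ids=kept,
        dropped_ids=dropped,
        threshold=t,
        must_kept=rescued,
        matrix=m.subset(kept),
    )


def exploration_density(s: ScoreVector, t: ThresholdResult, n_grid: int = 256) -> DensityCurve:
    """Gaussian KDE of the scores on an even grid over [min, max], Silverman bandwidth."""
    if n_grid < 64:
        raise InvalidParameterError("n_grid must be >= 64")
    x = np.asarray(s.scores, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty score vector")
    if np.ptp(x) == 0:
        raise InvalidInputError("all scores identical; density is degenerate")
    kde = sp_stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), n_grid)
    return DensityCurve(grid=grid, density=kde(grid), cutoff=t.cutoff)


def madvar(
    data: FeatureMatrix | ScoreVector | np.ndarray,
    mads: float = 2.0,
    must_genes: Iterable[str] = (),
    explore: bool = False,
    scale_constant: float = 1.0,
):
    """The complete MAD-based variance filtering workflow.

    Matrix input -> per-feature variances are computed, the cutoff
    ``median + mads * MAD`` is applied, and a :class:`FilterOutcome` holding
    the filtered matrix is returned.  One-dimensional input (a precomputed
    score vector or plain array) -> only the cutoff value is returned.
    A two-dimensional input with a single row is treated as a matrix, with a
    warning.
    """
    if isinstance(data, FeatureMatrix):
        m = data
    elif isinstance(data, ScoreVector):
        return mad_cutoff(data, mads=mads, scale_constant=scale_constant).cutoff
    else:
        arr = np.asarray(data, dtype=float)
        if arr.size == 0:
            raise InvalidInputError("empty input")
        if arr.ndim == 1:
            s = ScoreVector(arr, [f"f{i}" for i in range(arr.size)], score_name="custom")
            return mad_cutoff(s, mads=mads, scale_constant=scale_constant).cutoff
        if arr.ndim == 2:
            if arr.shape[0] == 1:
                warnings.warn("1 x n input treated as a single-feature matrix", stacklevel=2)
            m = FeatureMatrix(arr, [f"f{i}" for i in range(arr.shape[0])],
                              [f"s{j}" for j in range(arr.shape[1])])
        else:
            raise InvalidInputError(f"cannot interpret input with ndim={arr.ndim}")

    scores = compute_feature_variance(m)
    t = mad_cutoff(scores, mads=mads, scale_constant=scale_constant)
    outcome = apply_cutoff(m, scores, t, must_genes=must_genes)
    if explore:
        density = exploration_density(scores, t)
        outcome = FilterOutcome(
            kept_ids=outcome.kept_ids, dropped_ids=outcome.dropped_ids,
            threshold=outcome.threshold, must_kept=outcome.must_kept,
            matrix=outcome.matrix, density=density)
    return outcome


def select_features(
    m: FeatureMatrix,
    score: str = "variance",
    method: str = "madvar",
    params: Mapping[str, object] | None = None,
    must_genes: Sequence[str] = (),
) -> FilterOutcome:
    """Run one cell of the score x threshold grid on a matrix.

    ``score`` is ``variance`` or ``biotech_ratio`` (mean-variance trend
    model); ``method`` is one of ``madvar``, ``elbow``, ``knee``, ``gmm`` or
    ``fdr``.  The FDR method selects features whose biological variance is
    significantly positive and is only defined for the trend-model path.
    ``params`` tunes the underlying method (``mads``, ``scale_constant``,
    ``sensitivity``, ``seed``, ``log_transform``, ``span``, ``alpha``,
    ``epsilon``).
    """
    params = dict(params or {})
    if (score, method) not in VALID_COMBINATIONS:
        raise InvalidParameterError(
            f"unknown score/method combination ({score!r}, {method!r}); "
            f"valid: {VALID_COMBINATIONS}")

    trend = None
    if score == "variance":
        scores = compute_feature_variance(m)
    else:
        shifted = shift_nonnegative(m)
        trend = fit_mean_variance_trend(shifted, span=float(params.get("span", 0.3)))
        scores = bio_tech_ratio(trend, epsilon=float(params.get("epsilon", 1e-8)))

    if method == "fdr":
        alpha = float(params.get("alpha", 0.05))
        keep_set = fdr_filter(trend, alpha=alpha)
        t = ThresholdResult(
            cutoff=alpha,
            method="fdr",
            params={"alpha": alpha, "rule": "fdr <= alpha and bio > 0",
                    "span": trend.span, "n_samples": trend.n_samples},
            n_selected=len(keep_set),
            n_total=m.n_features,
        )
        must = list(dict.fromkeys(str(g) for g in must_genes))
        present = set(m.feature_ids)
        missing = [g for g in must if g not in present]
        if missing:
            warnings.warn(f"must-genes not found in the input: {missing}", stacklevel=2)
        rescue = {g for g in must if g in present}
        kept = [f for f in m.feature_ids if f in keep_set or f in rescue]
        dropped = [f for f in m.feature_ids if f not in keep_set and f not in rescue]
        return FilterOutcome(
            kept_ids=kept, dropped_ids=dropped, threshold=t,
            must_kept=[f for f in kept if f in rescue and f not in keep_set],
            matrix=m.subset(kept))

    if method == "madvar":
        t = mad_cutoff(scores, mads=float(params.get("mads", 2.0)),
                       scale_constant=float(params.get("scale_constant", 1.0)))
    elif method == "elbow":
        t = elbow_cutoff(scores)
    elif method == "knee":
        t = knee_cutoff(scores, sensitivity=float(params.get("sensitivity", 1.0)))
    else:  # gmm
        t = gmm_cutoff(scores, seed=int(params.get("seed", 0)),
                       log_transform=bool(params.get("log_transform", False)))
    return apply_cutoff(m, scores, t, must_genes=must_genes)
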