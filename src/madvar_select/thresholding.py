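"""Data-driven cutoffs on a score vector: MAD, elbow, and Kneedle knee.

The MAD cutoff exploits the right-skewed shape of per-feature variance
distributions in quantitative omics data: most features sit in a near-zero
peak (invariant features) with a long right tail of variable features.  The
cutoff

    cutoff = median(x) + mads * MAD,   MAD = median(|x_i - median(x)|)

marks the end of the near-zero peak.  Note the MAD here uses scale constant
1.0 by default (the literal robust-scale definition); pass
``scale_constant=1.4826`` to match R's ``mad()`` normal-consistency default.

The elbow cutoff ranks scores in decreasing order and takes the score at the
maximum discrete second derivative of the ranked curve.  The knee cutoff is
the Kneedle algorithm (Satopaa et al. 2011) on the rank-vs-score curve.
"""

from __future__ import annotations

import numpy as np

from .containers import ScoreVector, ThresholdResult
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["mad_cutoff", "elbow_cutoff", "knee_cutoff"]


def _scores(s: ScoreVector) -> np.ndarray:
    x = np.asarray(s.scores, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty score vector")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("scores contain non-finite values")
    return x


def mad_cutoff(s: ScoreVector, mads: float = 2.0, scale_constant: float = 1.0) -> ThresholdResult:
    """Median + mads * MAD cutoff on the score distribution.

    Selection keeps scores strictly greater than the cutoff (ties at the
    cutoff belong to the near-zero peak and are excluded).
    """
    if mads < 0:
        raise InvalidParameterError(f"mads must be >= 0, got {mads}")
    if scale_constant <= 0:
        raise InvalidParameterError("scale_constant must be > 0")
    x = _scores(s)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med))) * scale_constant
    cutoff = med + mads * mad
    n_selected = int(np.sum(x > cutoff))
    return ThresholdResult(
        cutoff=cutoff,
        method="madvar",
        params={"median": med, "mad": mad, "mads": mads, "scale_constant": scale_constant},
        n_selected=n_selected,
        n_total=x.size,
    )


def elbow_cutoff(s: ScoreVector) -> ThresholdResult:
    """Cutoff at the maximum second derivative of the decreasingly ranked scores.

    With scores sorted s[1] >= ... >= s[m], the discrete second difference
    d[i] = s[i+1] - 2*s[i] + s[i-1] is evaluated at every interior rank and
    the elbow is the rank maximizing it (ties resolved to the smallest rank).
    The cutoff is the score at the elbow rank; selection keeps scores
    strictly above it.
    """
    x = _scores(s)
    if np.unique(x).size < 3:
        raise InvalidInputError("elbow needs at least 3 distinct score values")
    ranked = np.sort(x)[::-1]
    d2 = ranked[2:] - 2.0 * ranked[1:-1] + ranked[:-2]
    elbow_interior = int(np.argmax(d2))  # first max on ties
    elbow_rank = elbow_interior + 1  # 0-based index into `ranked`
    cutoff = float(ranked[elbow_rank])
    return ThresholdResult(
        cutoff=cutoff,
        method="elbow",
        params={"elbow_rank": elbow_rank + 1, "second_difference": float(d2[elbow_interior])},
        n_selected=int(np.sum(x > cutoff)),
        n_total=x.size,
    )


def _kneedle(y_ranked: np.ndarray, sensitivity: float):
    """Kneedle on a decreasingly ranked curve; returns (knee index, diagnostics).

    The curve is min-max normalized on both axes, transformed to canonical
    increasing-concave shape (auto-detecting convex vs concave), and the knee
    is the first local maximum of the difference curve confirmed by the
    sensitivity-adjusted threshold rule.
    """
    m = y_ranked.size
    x_n = np.linspace(0.0, 1.0, m)
    span = y_ranked[0] - y_ranked[-1]
    if span == 0:
        return None, {"shape": "flat"}
    y_n = (y_ranked - y_ranked[-1]) / span  # decreasing 1 -> 0

    # convex if the curve lies below the descending chord y = 1 - x
    convex = float(np.mean(y_n - (1.0 - x_n))) < 0
    if convex:
        # increasing concave transform of a decreasing convex curve
        y_t = 1.0 - y_n
        x_t = x_n
        flipped = False
    else:
        y_t = y_n[::-1]
        x_t = x_n
        flipped = True

    diff = y_t - x_t
    # strict-left local maxima (plateaus collapse to their first point)
    lmx = [i for i in range(1, m - 1) if diff[i] > diff[i - 1] and diff[i] >= diff[i + 1]]
    if not lmx:
        return None, {"shape": "convex" if convex else "concave"}

    t_step = sensitivity * np.mean(np.diff(x_t))
    knee_t = None
    for k, i in enumerate(lmx):
        threshold = diff[i] - t_step
        stop = lmx[k + 1] if k + 1 < len(lmx) else m
        for j in range(i + 1, stop):
            if diff[j] < threshold:
                knee_t = i
                break
        if knee_t is not None:
            break
    if knee_t is None:
        return None, {"shape": "convex" if convex else "concave"}

    knee = (m - 1 - knee_t) if flipped else knee_t
    return knee, {"shape": "convex" if convex else "concave", "difference": float(diff[knee_t])}


def knee_cutoff(s: ScoreVector, sensitivity: float = 1.0) -> ThresholdResult:
    """Kneedle knee of the decreasingly ranked score curve.

    When no knee exists (e.g. a straight line), returns an explicit no-knee
    result whose cutoff is the minimum score with all features selected; the
    ``params['knee_found']`` flag records this.
    """
    if sensitivity <= 0:
        raise InvalidParameterError("sensitivity must be > 0")
    x = _scores(s)
    if x.size < 5:
        raise InvalidInputError("knee detection needs at least 5 points")
    ranked = np.sort(x)[::-1]
    knee, diag = _kneedle(ranked, sensitivity)
    if knee is None:
        return ThresholdResult(
            cutoff=float(ranked[-1]),
            method="knee",
            params={"knee_found": False, "sensitivity": sensitivity, **diag},
            n_selected=x.size,
            n_total=x.size,
        )
    cutoff = float(ranked[knee])
    return ThresholdResult(
        cutoff=cutoff,
        method="knee",
        params={"knee_found": True, "knee_rank": knee + 1, "sensitivity": sensitivity, **diag},
        n_selected=int(np.sum(x > cutoff)),
        n_total=x.size,
    )
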