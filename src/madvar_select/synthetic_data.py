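"""Synthetic omics-like data with a right-skewed per-feature variance structure.

Quantitative omics matrices (normalized expression, relative protein
abundance) typically show a right-skewed distribution of per-feature
variances: a dominant near-zero peak of invariant features plus a long right
tail of variable features.  This module generates matrices and score vectors
with exactly that structure and known ground-truth labels, so that
threshold-recovery and benchmark behaviour can be tested against truth.

`generate_matrix` builds a features x samples matrix in which a chosen
fraction of features is invariant (i.i.d. noise with a small SD) and the
remainder draw a true variance from a gamma distribution; variable features
additionally receive per-group mean offsets so that sample-group structure
is recoverable by clustering.  `generate_variance_mixture` samples a score
vector directly from the two-population model (truncated-normal near-zero
peak + gamma tail).

Defaults: 1000 features x 40 samples, 70% invariant with SD 0.05 around a
baseline of 5 (log-scale expression units), variable-feature variances from
Gamma(shape=2, scale=1), 4 sample groups with group-effect SD 1.  These are
the conditions used throughout the test-suite simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import FeatureMatrix, ScoreVector
from .exceptions import InvalidParameterError

__all__ = ["SyntheticSpec", "generate_matrix", "generate_variance_mixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic matrix generator."""

    n_features: int = 1000
    n_samples: int = 40
    frac_invariant: float = 0.7
    invariant_sd: float = 0.05
    variable_var_shape: float = 2.0
    variable_var_scale: float = 1.0
    n_groups: int = 4
    group_effect_sd: float = 1.0
    baseline: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise InvalidParameterError("n_samples must be >= 4")
        if not (0 <= self.frac_invariant <= 1):
            raise InvalidParameterError("frac_invariant must be in [0, 1]")
        if self.invariant_sd <= 0:
            raise InvalidParameterError("invariant_sd must be > 0")
        if self.variable_var_shape <= 0 or self.variable_var_scale <= 0:
            raise InvalidParameterError("gamma parameters must be > 0")
        if not (1 <= self.n_groups <= self.n_samples):
            raise InvalidParameterError("need 1 <= n_groups <= n_samples")
        if self.group_effect_sd < 0:
            raise InvalidParameterError("group_effect_sd must be >= 0")
        if self.n_features < 1:
            raise InvalidParameterError("n_features must be >= 1")


@dataclass(frozen=True)
class SyntheticLabels:
    """Ground truth accompanying a generated matrix."""

    feature_type: np.ndarray  # "invariant" | "variable", one per feature
    true_variance: np.ndarray  # per-feature generative variance
    sample_group: np.ndarray  # integer group per sample
    group_offsets: np.ndarray = field(default=None)  # (n_variable, n_groups) mean shifts


def generate_matrix(spec: SyntheticSpec) -> tuple[FeatureMatrix, SyntheticLabels]:
    """Generate a labelled features x samples matrix per the spec.

    Invariant features are i.i.d. N(baseline, invariant_sd^2) across samples.
    Variable features draw a true variance from
    Gamma(variable_var_shape, variable_var_scale) and values from
    N(baseline + group offset, true variance), where each (feature, group)
    offset is N(0, group_effect_sd^2).  Group effects shift means only, so the
    invariant/variable labels stay crisp.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_inv = round(spec.frac_invariant * spec.n_features)
    n_var = spec.n_features - n_inv

    groups = np.arange(spec.n_samples) % spec.n_groups
    feature_type = np.array(["invariant"] * n_inv + ["variable"] * n_var)

    inv_block = rng.normal(spec.baseline, spec.invariant_sd, size=(n_inv, spec.n_samples))

    true_var = np.concatenate([
        np.full(n_inv, spec.invariant_sd ** 2),
        rng.gamma(spec.variable_var_shape, spec.variable_var_scale, size=n_var),
    ])
    offsets = rng.normal(0.0, spec.group_effect_sd, size=(n_var, spec.n_groups)) \
        if spec.group_effect_sd > 0 else np.zeros((n_var, spec.n_groups))
    var_means = spec.baseline + offsets[:, groups]  # (n_var, n_samples)
    var_block = rng.normal(var_means, np.sqrt(true_var[n_inv:])[:, None])

    values = np.vstack([inv_block, var_block]) if n_var else inv_block
    m = FeatureMatrix(
        values,
        [f"feat{i:05d}" for i in range(spec.n_features)],
        [f"sample{j:03d}" for j in range(spec.n_samples)],
    )
    labels = SyntheticLabels(
        feature_type=feature_type,
        true_variance=true_var,
        sample_group=groups,
        group_offsets=offsets,
    )
    return m, labels


def generate_variance_mixture(
    n: int = 5000,
    lambda1: float = 0.6,
    peak_params: tuple[float, float] = (0.05, 0.02),
    tail_params: tuple[float, float] = (2.0, 1.0),
    seed: int = 0,
) -> tuple[ScoreVector, np.ndarray]:
    """Sample a right-skewed score vector from the two-population variance model.

    ``round(n * lambda1)`` values come from a normal near-zero peak truncated
    at zero (``peak_params`` = (mean, sd)) and the rest from a gamma tail
    (``tail_params`` = (shape, scale)).  Returns the scores together with an
    array of origin labels ("peak" / "tail"), both in peak-then-tail order.
    """
    if not (0 < lambda1 <= 1):
        raise InvalidParameterError("lambda1 must be in (0, 1]")
    if n < 100:
        raise InvalidParameterError("n must be >= 100")
    mu, sd = peak_params
    shape, scale = tail_params
    if sd <= 0 or shape <= 0 or scale <= 0:
        raise InvalidParameterError("peak sd and gamma parameters must be > 0")

    rng = np.random.default_rng(seed)
    n_peak = round(n * lambda1)
    n_tail = n - n_peak
    peak = stats.truncnorm.rvs((0 - mu) / sd, np.inf, loc=mu, scale=sd,
                               size=n_peak, random_state=rng)
    tail = rng.gamma(shape, scale, size=n_tail)
    scores = np.concatenate([peak, tail])
    labels = np.array(["peak"] * n_peak + ["tail"] * n_tail)
    s = ScoreVector(scores, [f"feat{i:05d}" for i in range(n)], score_name="variance")
    return s, labels
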