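"""Core in-memory containers: feature matrices, score vectors, threshold results.

A :class:`FeatureMatrix` is a dense features-by-samples numeric table with
unique string identifiers on both axes; it is the object being filtered.
A :class:`ScoreVector` holds one selection score per feature (variance, the
bio/tech variance ratio, or anything user-supplied); it is the object that
the thresholding methods operate on.  A :class:`ThresholdResult` records a
cutoff together with full provenance (method name and every parameter needed
to reconstruct the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

SCORE_NAMES = ("variance", "biotech_ratio", "custom")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise InvalidInputError(f"duplicate {what}: {sorted(set(dups))[:5]} ...")
    return ids


@dataclass(frozen=True)
class FeatureMatrix:
    """Features x samples numeric matrix with unique identifiers.

    Invariants enforced at construction: unique feature and sample ids whose
    lengths match the matrix shape, at least two samples (variance needs
    n >= 2), and no missing values (rows with missing entries must be dropped
    upstream; see :func:`madvar_select.cli_io.read_matrix`).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidInputError(f"matrix must be 2-D, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", _check_unique(self.feature_ids, "feature ids"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample ids"))
        n_feat, n_samp = values.shape
        if len(self.feature_ids) != n_feat:
            raise InvalidInputError(
                f"{len(self.feature_ids)} feature ids for {n_feat} rows")
        if len(self.sample_ids) != n_samp:
            raise InvalidInputError(
                f"{len(self.sample_ids)} sample ids for {n_samp} columns")
        if n_samp < 2:
            raise InvalidInputError("at least 2 samples are required")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError(
                "matrix contains missing or non-finite values; "
                "drop incomplete rows before constructing a FeatureMatrix")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        """Row-subset preserving this matrix's feature order."""
        wanted = set(feature_ids)
        idx = [i for i, f in enumerate(self.feature_ids) if f in wanted]
        return FeatureMatrix(self.values[idx], [self.feature_ids[i] for i in idx],
                             list(self.sample_ids))


@dataclass(frozen=True)
class ScoreVector:
    """One real-valued selection score per feature."""

    scores: np.ndarray
    feature_ids: list[str]
    score_name: str = "custom"

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float).ravel()
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "feature_ids", _check_unique(self.feature_ids, "feature ids"))
        if len(self.feature_ids) != scores.size:
            raise InvalidInputError(
                f"{len(self.feature_ids)} feature ids for {scores.size} scores")
        if self.score_name not in SCORE_NAMES:
            raise InvalidInputError(
                f"score_name must be one of {SCORE_NAMES}, got {self.score_name!r}")
        if self.score_name == "variance" and scores.size and np.nanmin(scores) < 0:
            raise InvalidInputError("variance scores must be non-negative")

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class ThresholdResult:
    """A cutoff applied to a ScoreVector, with provenance.

    ``params`` records everything needed to reconstruct ``cutoff``; e.g. for
    the MAD method it holds ``median``, ``mad``, ``mads`` and
    ``scale_constant`` so that ``cutoff == median + mads * mad`` exactly.
    """

    cutoff: float
    method: str  # madvar | elbow | knee | gmm_intersection | fdr
    params: Mapping[str, object] = field(default_factory=dict)
    n_selected: int = 0
    n_total: int = 0

    def __post_init__(self):
        if not (0 <= self.n_selected <= self.n_total):
            raise InvalidInputError(
                f"n_selected={self.n_selected} outside [0, {self.n_total}]")
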