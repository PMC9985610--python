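"""Inference of incomplete feature vectors via SR-weighted memory lookup.

The trained network tolerates inputs where unknown features hold the
sentinel -1: its softmax output is still a probability vector over the
stored states, which acts as a weighted pointer into the memory matrix.
Multiplying that pointer with the memory matrix,

    m_interpolated = p^T M(m),

yields a convex combination of stored memories — an interpolated feature
vector whose every component lies within the observed range of that
feature. Note the known entries of the input are *not* clamped: the
returned vector is wholly reconstructed from memory, so even known
features may shift slightly.

``evaluate_dissimilarity`` quantifies reconstruction quality on held-out
states: for each number k of masked features it reports the mean absolute
prediction error per feature as a percentage of that feature's range
(max - min) over the training memory, plus the variance of that mean
across independently trained models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import TrainedModel
from .space import MISSING_SENTINEL, PartialFeatureVector, SemanticSpace

__all__ = ["InterpolationResult", "DissimilarityReport", "interpolate", "evaluate_dissimilarity"]


@dataclass(frozen=True)
class InterpolationResult:
    """An interpolated feature vector and the SR pointer that produced it."""

    predicted_features: np.ndarray
    sr_prediction: np.ndarray
    input: PartialFeatureVector


@dataclass(frozen=True)
class DissimilarityReport:
    """Per-feature reconstruction error versus number of masked features.

    ``mean_percent[i, j]`` is the mean dissimilarity (percent of feature
    j's training range) with ``n_missing[i]`` features masked, averaged
    over models, test states and random masks; ``model_variance`` is the
    variance of the per-model means.
    """

    n_missing: tuple[int, ...]
    feature_names: tuple[str, ...]
    mean_percent: np.ndarray  # (len(n_missing), n_features)
    model_variance: np.ndarray  # same shape
    n_models: int

    def best_feature_accuracy(self, k: int = 0) -> float:
        """100 minus the smallest per-feature dissimilarity at k masked."""
        row = self.mean_percent[self.n_missing.index(k)]
        return float(100.0 - row.min())

    def worst_feature_dissimilarity(self, k: int) -> float:
        """Largest per-feature dissimilarity (percent) at k masked."""
        return float(self.mean_percent[self.n_missing.index(k)].max())


def interpolate(
    model: TrainedModel,
    memory: SemanticSpace,
    partial: PartialFeatureVector | np.ndarray,
) -> InterpolationResult:
    """Reconstruct a full feature vector from a partial one.

    The partial vector — sentinels included, untouched — is fed through
    the network; the resulting successor probabilities weight the rows of
    the memory matrix.
    """
    if not isinstance(partial, PartialFeatureVector):
        partial = PartialFeatureVector(np.asarray(partial, dtype=float))
    if partial.values.shape[0] != memory.n_features:
        raise ValueError(
            f"partial vector has {partial.values.shape[0]} entries, "
            f"memory has {memory.n_features} features"
        )
    p = np.asarray(model.predict_proba(partial.values), dtype=float)
    if p.shape[0] != memory.n_states:
        raise ValueError("model output width does not match the memory matrix")
    return InterpolationResult(
        predicted_features=p @ memory.features,
        sr_prediction=p,
        input=partial,
    )


def evaluate_dissimilarity(
    models: Sequence[TrainedModel],
    memory: SemanticSpace,
    test_space: SemanticSpace,
    n_missing_range: Iterable[int] = range(0, 7),
    mask_reps: int = 10,
    seed: int | None = None,
) -> DissimilarityReport:
    """Mean per-feature reconstruction error for 0..k masked features.

    For every model, test state and repetition, ``k`` feature positions are
    masked uniformly at random without replacement, the vector interpolated,
    and each feature's absolute error recorded as a percentage of that
    feature's (max - min) range over the training memory. For ``k = 0``
    a single unmasked pass per state is evaluated (masks play no role).
    """
    if not models:
        raise ValueError("need at least one trained model")
    ks = tuple(int(k) for k in n_missing_range)
    n_feat = memory.n_features
    if any(k < 0 or k >= n_feat for k in ks):
        raise ValueError(f"number of masked features must lie in [0, {n_feat})")
    if test_space.n_features != n_feat:
        raise ValueError("test space and memory disagree on feature count")

    ranges = memory.feature_ranges()
    if np.any(ranges == 0):
        raise ValueError("every feature needs a non-zero range over the memory matrix")
    rng = np.random.default_rng(seed)

    per_model = np.empty((len(models), len(ks), n_feat))
    for mi, model in enumerate(models):
        for ki, k in enumerate(ks):
            reps = 1 if k == 0 else mask_reps
            errors = np.empty((test_space.n_states * reps, n_feat))
            row = 0
            for truth in test_space.features:
                for _ in range(reps):
                    vals = truth.copy()
                    if k:
                        vals[rng.choice(n_feat, size=k, replace=False)] = MISSING_SENTINEL
                    pred = interpolate(model, memory, PartialFeatureVector(vals)).predicted_features
                    errors[row] = np.abs(pred - truth) / ranges * 100.0
                    row += 1
            per_model[mi, ki] = errors.mean(axis=0)

    return DissimilarityReport(
        n_missing=ks,
        feature_names=memory.feature_names,
        mean_percent=per_model.mean(axis=0),
        model_variance=per_model.var(axis=0),
        n_models=len(models),
    )
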