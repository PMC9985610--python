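"""Stochastic training-pair generation from a semantic space and its SR.

Each training pair is produced by (i) choosing a start state uniformly at
random, (ii) multiplicatively jittering every feature of its stored memory
by an independent factor uniform in [1 - p, 1 + p] (default p = 0.15), and
(iii) drawing a successor-state label by inverse-CDF sampling from the
row-normalized SR row of the start state. Because each state has several
near-equally-likely successors, the label is intrinsically ambiguous — the
Bayes-optimal top-1 accuracy equals the mean of the per-row maximum
probability, not 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .space import SemanticSpace
from .successor import SRMatrix

__all__ = [
    "TrainingSample",
    "SampleSet",
    "draw_successor",
    "perturb_features",
    "generate_samples",
]

DEFAULT_PERTURBATION = 0.15


class TrainingSample(NamedTuple):
    input: np.ndarray
    label: int


@dataclass(frozen=True)
class SampleSet:
    """Generated (perturbed input, successor label) pairs with a held-out split."""

    inputs: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # (n_samples,) int successor-state indices
    train_indices: np.ndarray
    val_indices: np.ndarray
    seed: int | None

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def __getitem__(self, i: int) -> TrainingSample:
        return TrainingSample(self.inputs[i], int(self.labels[i]))

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        return self.inputs[self.train_indices], self.labels[self.train_indices]

    @property
    def validation(self) -> tuple[np.ndarray, np.ndarray]:
        return self.inputs[self.val_indices], self.labels[self.val_indices]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.inputs, columns=[f"x{j}" for j in range(self.inputs.shape[1])])
        df["label"] = self.labels
        df.to_csv(path, index=False)


def draw_successor(sr: SRMatrix, state: int, uniform_draw: float) -> int:
    """Inverse-CDF draw of a successor index from a normalized SR row.

    Returns the first index whose cumulative probability exceeds
    ``uniform_draw`` (a number in [0, 1)).
    """
    n = sr.n_states
    if not 0 <= state < n:
        raise IndexError(f"state {state} out of range [0, {n})")
    if not 0.0 <= uniform_draw < 1.0:
        raise ValueError("uniform_draw must lie in [0, 1)")
    cdf = np.cumsum(sr.normalized[state])
    return int(np.searchsorted(cdf, uniform_draw, side="right"))


def perturb_features(
    memory: np.ndarray,
    max_fraction: float = DEFAULT_PERTURBATION,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiply each feature by an independent factor uniform in [1-p, 1+p].

    A multiplicative jitter keeps the perturbation scale-free across
    features whose magnitudes span eight orders (grams to tonnes).
    """
    if max_fraction < 0:
        raise ValueError("max_fraction must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    memory = np.asarray(memory, dtype=float)
    factors = rng.uniform(1.0 - max_fraction, 1.0 + max_fraction, size=memory.shape)
    return memory * factors


def generate_samples(
    space: SemanticSpace,
    sr: SRMatrix,
    n_samples: int = 50_000,
    validation_fraction: float = 0.1,
    seed: int | None = None,
    perturbation: float = DEFAULT_PERTURBATION,
) -> SampleSet:
    """Generate a SampleSet of perturbed inputs with sampled successor labels.

    The last ``validation_fraction`` of the generated pairs is held out for
    validation; since pairs are i.i.d. the split is itself random.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be at least 10")
    if space.n_states != sr.n_states:
        raise ValueError("space and SR matrix disagree on the number of states")
    rng = np.random.default_rng(seed)
    n = space.n_states

    starts = rng.integers(0, n, size=n_samples)
    draws = rng.random(n_samples)
    factors = rng.uniform(1.0 - perturbation, 1.0 + perturbation, size=(n_samples, space.n_features))
    inputs = space.features[starts] * factors

    cdf = np.cumsum(sr.normalized, axis=1)
    # Row-wise inverse-CDF: first column whose cumulative mass exceeds the draw.
    labels = (cdf[starts] > draws[:, None]).argmax(axis=1)

    n_val = round(n_samples * validation_fraction)
    idx = np.arange(n_samples)
    return SampleSet(
        inputs=inputs,
        labels=labels.astype(np.int64),
        train_indices=idx[: n_samples - n_val],
        val_indices=idx[n_samples - n_val :],
        seed=seed,
    )
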