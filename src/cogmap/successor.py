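"""Ground-truth transition and successor-representation matrices.

The transition matrix T treats semantic similarity as closeness in feature
space: the unnormalized weight between two distinct states is the inverse
Euclidean distance between their feature vectors, the diagonal is zero (a
state never succeeds itself), and rows are normalized to probabilities.

The successor representation (SR) for discount factor gamma and horizon t is
the truncated discounted occupancy sum

    M = sum_{k=0..t} gamma^k T^k,        T^0 = I,

so each row of M sums to the geometric partial sum (1 - gamma^(t+1)) /
(1 - gamma) (or t+1 at gamma = 1). Small gamma keeps M close to the
identity (a fine-grained, local map); gamma -> 1 spreads occupancy over the
whole space (a coarse, global map). The row-normalized form of M is the
probability distribution used for successor sampling and for comparison
with the network's softmax output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .space import SemanticSpace

__all__ = [
    "TransitionMatrix",
    "SRMatrix",
    "ValueVector",
    "compute_transition_matrix",
    "compute_sr_matrix",
    "compute_value",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic state-transition matrix derived from feature distances."""

    probs: np.ndarray
    state_names: tuple[str, ...]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "state_names", tuple(self.state_names))
        n = len(self.state_names)
        if probs.shape != (n, n):
            raise ValueError("probs must be square and match state_names")

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class SRMatrix:
    """Truncated discounted successor matrix for a given (gamma, horizon)."""

    values: np.ndarray
    gamma: float
    horizon_t: int
    state_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "state_names", tuple(self.state_names))

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    @property
    def normalized(self) -> np.ndarray:
        """Row-stochastic form: each row rescaled to a probability vector."""
        return self.values / self.values.sum(axis=1, keepdims=True)

    @property
    def row_sum(self) -> float:
        """Closed-form common row sum: geometric partial sum of gamma."""
        if self.gamma == 1.0:
            return float(self.horizon_t + 1)
        return (1.0 - self.gamma ** (self.horizon_t + 1)) / (1.0 - self.gamma)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "states": list(self.state_names),
                "gamma": self.gamma,
                "t": self.horizon_t,
                "matrix": self.values.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SRMatrix":
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:  # raw JSON string, not a path
            pass
        obj = json.loads(text)
        return cls(np.array(obj["matrix"], dtype=float), obj["gamma"], obj["t"], obj["states"])


@dataclass(frozen=True)
class ValueVector:
    """Expected discounted future reward per state, v = M r."""

    v: np.ndarray
    reward: np.ndarray


def compute_transition_matrix(space: SemanticSpace) -> TransitionMatrix:
    """Build T from inverse Euclidean feature distances.

    Off-diagonal weight between states s and s' is ``1 / ||m_s - m_s'||``;
    the diagonal is forced to zero and each row divided by its sum. Raises
    if any two states share an identical feature vector (the inverse
    distance would be infinite).
    """
    feats = space.features
    diff = feats[:, None, :] - feats[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    off = ~np.eye(space.n_states, dtype=bool)
    collisions = np.argwhere((dist == 0) & off)
    if collisions.size:
        i, j = collisions[0]
        raise ValueError(
            f"states {space.state_names[i]!r} and {space.state_names[j]!r} "
            "have identical feature vectors (zero distance)"
        )
    weights = np.zeros_like(dist)
    weights[off] = 1.0 / dist[off]
    probs = weights / weights.sum(axis=1, keepdims=True)
    return TransitionMatrix(probs, space.state_names)


def unnormalized_weights(space: SemanticSpace) -> np.ndarray:
    """Symmetric inverse-distance weight matrix before row normalization."""
    feats = space.features
    diff = feats[:, None, :] - feats[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    off = ~np.eye(space.n_states, dtype=bool)
    weights = np.zeros_like(dist)
    weights[off] = 1.0 / dist[off]
    return weights


def compute_sr_matrix(T: TransitionMatrix, gamma: float, horizon_t: int = 10) -> SRMatrix:
    """Truncated SR: ``sum_{k=0..horizon_t} gamma^k T^k``."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if horizon_t < 0:
        raise ValueError("horizon_t must be non-negative")
    n = T.n_states
    values = np.eye(n)
    power = np.eye(n)
    for k in range(1, horizon_t + 1):
        power = power @ T.probs
        values = values + gamma**k * power
    return SRMatrix(values, float(gamma), int(horizon_t), T.state_names)


def compute_value(sr: SRMatrix, reward: np.ndarray | None = None) -> ValueVector:
    """Expected discounted future reward v = M r (unit reward by default)."""
    n = sr.n_states
    r = np.ones(n) if reward is None else np.asarray(reward, dtype=float).ravel()
    if r.shape != (n,):
        raise ValueError(f"reward must have length {n}, got {r.shape}")
    return ValueVector(sr.values @ r, r)
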