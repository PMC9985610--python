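"""The successor-prediction network and its training loop.

A three-layer feed-forward network maps a (possibly perturbed or partially
masked) feature vector to a softmax distribution over the stored states:
input and hidden layers have one unit per feature with ReLU activations,
the output layer one unit per state. Training minimises categorical
cross-entropy against sampled successor labels with Adam. Defaults follow
the reference protocol for the animal space: 7-7-32 units, 500 epochs,
batch size 50, learning rate 0.001, 50,000 samples with a 10% validation
split.

The trained network's output row for the unperturbed memory of each state,
stacked over states, is the learned successor-representation matrix; it is
compared against the row-normalized ground-truth SR by entry-wise RMSE.
Because successor labels are sampled from rows with several comparable
probabilities, top-1 accuracy saturates near the Bayes ceiling (the mean
per-row maximum of the normalized SR, about 0.3 for the animal space at
discount 0.7) rather than near 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sampling import SampleSet
from .space import SemanticSpace
from .successor import SRMatrix

__all__ = [
    "NetworkConfig",
    "TrainedModel",
    "EvaluationReport",
    "train",
    "assemble_sr_matrix",
    "rmse",
    "accuracy",
    "bayes_ceiling",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimisation hyperparameters."""

    n_input: int
    n_hidden: int
    n_output: int
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 50
    seed: int | None = None
    minmax_scale_inputs: bool = False

    @classmethod
    def for_space(cls, space: SemanticSpace, **kwargs) -> "NetworkConfig":
        """Input and hidden width = n_features, output width = n_states."""
        return cls(
            n_input=space.n_features,
            n_hidden=space.n_features,
            n_output=space.n_states,
            **kwargs,
        )


@dataclass
class TrainedModel:
    """Weights, config and per-epoch history of a trained network."""

    config: NetworkConfig
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    history: dict[str, list[float]] = field(default_factory=dict)
    state_names: tuple[str, ...] | None = None
    input_scale: tuple[np.ndarray, np.ndarray] | None = None  # (min, range)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax output for one vector or a batch of vectors."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if self.input_scale is not None:
            lo, rng = self.input_scale
            X = (X - lo) / rng
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        Z = H @ self.W2 + self.b2
        Z = Z - Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        P = E / E.sum(axis=1, keepdims=True)
        return P[0] if single else P

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Top-1 state index; ties broken toward the lowest index."""
        return np.argmax(np.atleast_2d(self.predict_proba(X)), axis=1)

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "config": {
                    k: getattr(self.config, k)
                    for k in (
                        "n_input", "n_hidden", "n_output", "learning_rate",
                        "epochs", "batch_size", "seed", "minmax_scale_inputs",
                    )
                },
                "weights": {
                    "W1": self.W1.tolist(), "b1": self.b1.tolist(),
                    "W2": self.W2.tolist(), "b2": self.b2.tolist(),
                },
                "history": self.history,
                "state_names": list(self.state_names) if self.state_names else None,
                "input_scale": (
                    [self.input_scale[0].tolist(), self.input_scale[1].tolist()]
                    if self.input_scale is not None else None
                ),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedModel":
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:  # raw JSON string, not a path
            pass
        obj = json.loads(text)
        scale = obj.get("input_scale")
        return cls(
            config=NetworkConfig(**obj["config"]),
            W1=np.array(obj["weights"]["W1"]),
            b1=np.array(obj["weights"]["b1"]),
            W2=np.array(obj["weights"]["W2"]),
            b2=np.array(obj["weights"]["b2"]),
            history=obj.get("history", {}),
            state_names=tuple(obj["state_names"]) if obj.get("state_names") else None,
            input_scale=(np.array(scale[0]), np.array(scale[1])) if scale else None,
        )


@dataclass(frozen=True)
class EvaluationReport:
    """RMSE against the normalized ground-truth SR plus final accuracies."""

    rmse: float
    final_train_accuracy: float
    final_validation_accuracy: float
    gamma: float
    horizon_t: int


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def train(
    space: SemanticSpace,
    samples: SampleSet,
    config: NetworkConfig | None = None,
) -> TrainedModel:
    """Train the successor-prediction network on a sample set.

    Returns the model with per-epoch ``loss`` / ``accuracy`` /
    ``val_loss`` / ``val_accuracy`` history. Fully deterministic for a
    fixed ``config.seed``.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    config = NetworkConfig.for_space(space) if config is None else config
    if samples.labels.max() >= config.n_output:
        raise ValueError("sample labels exceed the configured output width")

    X_train, y_train = samples.train
    X_val, y_val = samples.validation
    if X_train.shape[1] != config.n_input:
        raise ValueError("sample feature width does not match the configured input width")

    scale = None
    if config.minmax_scale_inputs:
        lo = X_train.min(axis=0)
        rng_ = X_train.max(axis=0) - lo
        rng_[rng_ == 0] = 1.0
        scale = (lo, rng_)
        X_train = (X_train - lo) / rng_
        X_val = (X_val - lo) / rng_

    rng = np.random.default_rng(config.seed)
    W1 = _glorot_uniform(rng, config.n_input, config.n_hidden)
    b1 = np.zeros(config.n_hidden)
    W2 = _glorot_uniform(rng, config.n_hidden, config.n_output)
    b2 = np.zeros(config.n_output)

    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [],
    }
    if config.epochs > 0:
        from ._kernel import adam_train_loop

        shuffle_seed = int(rng.integers(0, 2**31 - 1))
        hist = adam_train_loop(
            np.ascontiguousarray(X_train, dtype=float),
            np.ascontiguousarray(y_train, dtype=np.int64),
            np.ascontiguousarray(X_val, dtype=float),
            np.ascontiguousarray(y_val, dtype=np.int64),
            W1, b1, W2, b2,
            config.epochs, config.batch_size, config.learning_rate, shuffle_seed,
        )
        history["loss"] = hist[:, 0].tolist()
        history["accuracy"] = hist[:, 1].tolist()
        if len(X_val):
            history["val_loss"] = hist[:, 2].tolist()
            history["val_accuracy"] = hist[:, 3].tolist()

    return TrainedModel(
        config=config, W1=W1, b1=b1, W2=W2, b2=b2,
        history=history, state_names=space.state_names, input_scale=scale,
    )


def assemble_sr_matrix(model: TrainedModel, space: SemanticSpace) -> np.ndarray:
    """Stack the network's softmax rows for all unperturbed memories.

    Row i is the predicted successor distribution for state i's stored
    feature vector; the stacked matrix is the learned SR (row-stochastic
    by construction).
    """
    if model.config.n_output != space.n_states:
        raise ValueError(
            f"model predicts {model.config.n_output} states but the space has "
            f"{space.n_states}"
        )
    return np.asarray(model.predict_proba(space.features))


def rmse(predicted: np.ndarray, ground_truth: np.ndarray) -> float:
    """Root-mean-squared error over all matrix entries."""
    predicted = np.asarray(predicted, dtype=float)
    ground_truth = np.asarray(ground_truth, dtype=float)
    if predicted.shape != ground_truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {ground_truth.shape}")
    return float(np.sqrt(np.mean((predicted - ground_truth) ** 2)))


def accuracy(model: TrainedModel, inputs: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of samples whose top-1 prediction matches the sampled label."""
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("no samples to score")
    return float((model.predict(inputs) == labels).mean())


def bayes_ceiling(sr: SRMatrix) -> float:
    """Best achievable top-1 accuracy against sampled successor labels.

    With uniform start states the optimal classifier picks each row's modal
    successor, so its accuracy is the mean per-row maximum probability of
    the normalized SR.
    """
    return float(sr.normalized.max(axis=1).mean())


def evaluate(
    model: TrainedModel,
    space: SemanticSpace,
    sr: SRMatrix,
) -> EvaluationReport:
    """Bundle the RMSE of the assembled SR with the final history accuracies."""
    learned = assemble_sr_matrix(model, space)
    return EvaluationReport(
        rmse=rmse(learned, sr.normalized),
        final_train_accuracy=model.history["accuracy"][-1] if model.history.get("accuracy") else float("nan"),
        final_validation_accuracy=model.history["val_accuracy"][-1] if model.history.get("val_accuracy") else float("nan"),
        gamma=sr.gamma,
        horizon_t=sr.horizon_t,
    )
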