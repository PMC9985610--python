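"""End-to-end convenience runner: table -> SR -> samples -> trained network.

One master seed fans out, via ``numpy.random.SeedSequence``, into
independent streams for sample generation and weight initialisation, so a
whole run is reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import EvaluationReport, NetworkConfig, TrainedModel, evaluate, train
from .sampling import DEFAULT_PERTURBATION, SampleSet, generate_samples
from .space import SemanticSpace, load_space
from .successor import SRMatrix, compute_sr_matrix, compute_transition_matrix

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    space: SemanticSpace
    sr: SRMatrix
    samples: SampleSet
    model: TrainedModel
    evaluation: EvaluationReport


def run_pipeline(
    space: SemanticSpace | str = "animals_train",
    gamma: float = 0.7,
    horizon_t: int = 10,
    n_samples: int = 50_000,
    epochs: int = 500,
    batch_size: int = 50,
    learning_rate: float = 0.001,
    perturbation: float = DEFAULT_PERTURBATION,
    seed: int | None = None,
    zscore_features: bool = False,
    minmax_scale_inputs: bool = False,
) -> PipelineResult:
    """Run the full study pipeline for one discount factor.

    Builds the inverse-distance transition matrix, the truncated SR,
    a freshly sampled training set, and trains the softmax network;
    returns all intermediates plus the evaluation report (RMSE against
    the normalized ground truth, final accuracies).
    """
    if isinstance(space, str):
        space = load_space(space)
    if zscore_features:
        space = space.zscored()
    if seed is not None:
        ss = np.random.SeedSequence(seed)
        sample_seed, net_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    else:
        sample_seed = net_seed = None

    T = compute_transition_matrix(space)
    sr = compute_sr_matrix(T, gamma=gamma, horizon_t=horizon_t)
    samples = generate_samples(
        space, sr, n_samples=n_samples, seed=sample_seed, perturbation=perturbation
    )
    config = NetworkConfig.for_space(
        space,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        seed=net_seed,
        minmax_scale_inputs=minmax_scale_inputs,
    )
    model = train(space, samples, config)
    return PipelineResult(space, sr, samples, model, evaluate(model, space, sr))
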