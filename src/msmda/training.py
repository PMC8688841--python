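"""Training loop plumbing and the averaged multi-classifier inference rule.

The functions here are thin wrappers over :class:`msmda.estimators.MSMDAClassifier`,
which owns the optimization loop; batch sampling, prediction and accuracy
live here so both the estimator and the evaluation runners share them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .data import ConfigurationError, DomainDataset, MultiSourceTask
from .losses import KernelSpec, LossWeights, softmax
from .network import ModelParams, branch_forward, cfe_forward

__all__ = ["TrainConfig", "TrainHistory", "make_samplers", "train",
           "predict", "evaluate_accuracy", "TrainingError"]


class TrainingError(RuntimeError):
    """Raised when the optimization diverges (non-finite loss)."""


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 0.01
    optimizer: str = "adam"
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    alignment: str = "mmd_multi"   # mmd_multi | mmd_single | coral | none
    mmd_estimator: str = "biased"
    alpha_progress: str = "step"   # step | epoch
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.alignment not in ("mmd_multi", "mmd_single", "coral", "none"):
            raise ValueError(f"unknown alignment {self.alignment!r}")


@dataclass
class TrainHistory:
    """Per-step loss records plus optional per-epoch target accuracy."""

    records: list[dict] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)

    def column(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records])


def _batch_stream(n: int, m: int, rng: np.random.Generator):
    """Yield index batches of exactly m rows; each permutation is exhausted
    before reshuffling, wrapping around when a batch straddles epochs."""
    order = rng.permutation(n)
    pos = 0
    while True:
        batch = np.empty(m, dtype=np.int64)
        filled = 0
        while filled < m:
            take = min(m - filled, n - pos)
            batch[filled:filled + take] = order[pos:pos + take]
            filled += take
            pos += take
            if pos == n:
                order = rng.permutation(n)
                pos = 0
        yield batch


def make_samplers(domains: list[DomainDataset], m: int, seed: int):
    """Independent, deterministic batch-index streams, one per domain."""
    if m < 1:
        raise ValueError("batch size must be >= 1")
    streams = []
    for i, d in enumerate(domains):
        if d.n_samples < 1:
            raise ConfigurationError(f"domain {d.domain_id!r} is empty")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 100 + i]))
        streams.append(_batch_stream(d.n_samples, m, rng))
    return streams


def predict(params: ModelParams, X) -> tuple[np.ndarray, np.ndarray]:
    """Average the N branch softmax predictions; argmax (lowest index wins)."""
    X = np.asarray(X, dtype=np.float64)
    q = cfe_forward(params, X)
    acc = None
    for i in range(params.config.n_sources):
        _, logits = branch_forward(params, q, i)
        p = softmax(logits).data
        acc = p if acc is None else acc + p
    probs = acc / params.config.n_sources
    return probs, np.argmax(probs, axis=1)


def evaluate_accuracy(params: ModelParams, target: DomainDataset) -> float:
    if target.labels is None:
        raise ValueError("target domain has no labels to evaluate against")
    _, labels = predict(params, target.features)
    return float(np.mean(labels == target.labels))


def train(task: MultiSourceTask, model_config=None, train_config: TrainConfig | None = None):
    """Train MS-MDA on a task; returns (ModelParams, TrainHistory).

    Thin wrapper over :class:`msmda.estimators.MSMDAClassifier`.
    """
    from .estimators import MSMDAClassifier

    tcfg = train_config or TrainConfig()
    kw = {}
    if model_config is not None:
        kw = dict(hidden_dims=model_config.cfe_hidden_dims,
                  cfe_out_dim=model_config.cfe_out_dim,
                  dsfe_out_dim=model_config.dsfe_out_dim,
                  leaky_slope=model_config.leaky_slope)
    est = MSMDAClassifier(
        epochs=tcfg.epochs, batch_size=tcfg.batch_size,
        learning_rate=tcfg.learning_rate, alignment=tcfg.alignment,
        n_kernels=tcfg.kernel.n_kernels,
        kernel_mul=tcfg.kernel.bandwidth_ladder_base,
        bandwidth_anchor=tcfg.kernel.bandwidth_anchor,
        mmd_estimator=tcfg.mmd_estimator,
        beta_weight=tcfg.weights.beta_weight,
        beta_mode=tcfg.weights.beta_mode,
        disc_start_fraction=tcfg.weights.disc_start_fraction,
        alpha_progress=tcfg.alpha_progress,
        normalization="none",  # the wrapper trains on the task as given
        random_state=tcfg.seed, **kw,
    )
    est.fit(task)
    return est.params_, est.history_
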