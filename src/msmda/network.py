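"""The multi-branch adaptation network.

Architecture: a common feature extractor (CFE) shared by all domains —
three affine layers, each followed by LeakyReLU, tapering from the input
width (310 for 62 electrodes x 5 bands) to 64 — then, per source domain,
a branch made of a domain-specific feature extractor (DSFE: one affine
layer + LeakyReLU, 64 -> 32) and a domain-specific classifier (DSC: one
affine layer to the class logits, no activation; softmax is applied only
inside losses and at inference).  Branch i pairs source i with the
target; the target passes through every branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, as_tensor

__all__ = ["ModelConfig", "ModelParams", "BranchOutputs", "init_model",
           "cfe_forward", "branch_forward", "full_forward", "n_parameters",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    input_dim: int = 310
    cfe_hidden_dims: tuple[int, ...] = (256, 128)
    cfe_out_dim: int = 64
    dsfe_out_dim: int = 32
    n_classes: int = 3
    n_sources: int = 1
    leaky_slope: float = 0.01

    def __post_init__(self):
        self.cfe_hidden_dims = tuple(int(h) for h in self.cfe_hidden_dims)
        dims = (self.input_dim, *self.cfe_hidden_dims, self.cfe_out_dim,
                self.dsfe_out_dim, self.n_classes, self.n_sources)
        if any(d < 1 for d in dims):
            raise ValueError("all dimensions and counts must be >= 1")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")

    @property
    def cfe_dims(self) -> list[int]:
        return [self.input_dim, *self.cfe_hidden_dims, self.cfe_out_dim]


@dataclass
class ModelParams:
    """Learned weights: CFE layers + per-branch DSFE/DSC layers."""

    config: ModelConfig
    cfe: list[tuple[Tensor, Tensor]]
    dsfe: list[tuple[Tensor, Tensor]]
    dsc: list[tuple[Tensor, Tensor]]

    def parameters(self) -> list[Tensor]:
        out = []
        for W, b in (*self.cfe, *self.dsfe, *self.dsc):
            out.extend((W, b))
        return out

    def arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layers in (("cfe", self.cfe), ("dsfe", self.dsfe),
                             ("dsc", self.dsc)):
            for i, (W, b) in enumerate(layers):
                out[f"{name}{i}_W"] = W.data
                out[f"{name}{i}_b"] = b.data
        return out


@dataclass
class BranchOutputs:
    """Per-branch features and logits for one forward pass."""

    common_source: list[Tensor]   # q_i^S, one per branch
    common_target: Tensor         # q^T (CFE applied once)
    source_features: list[Tensor]  # r_i^S
    target_features: list[Tensor]  # r_i^T
    source_logits: list[Tensor]
    target_logits: list[Tensor]


def _affine_init(rng: np.random.Generator, fan_in: int, fan_out: int
                 ) -> tuple[Tensor, Tensor]:
    # uniform fan-in init, the standard default for small MLP layers
    bound = 1.0 / np.sqrt(fan_in)
    W = Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)),
               requires_grad=True)
    b = Tensor(rng.uniform(-bound, bound, size=(fan_out,)), requires_grad=True)
    return W, b


def init_model(cfg: ModelConfig, seed: int = 0) -> ModelParams:
    """Deterministic fan-based random initialization; branches independent."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    dims = cfg.cfe_dims
    cfe = [_affine_init(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
    dsfe = [_affine_init(rng, cfg.cfe_out_dim, cfg.dsfe_out_dim)
            for _ in range(cfg.n_sources)]
    dsc = [_affine_init(rng, cfg.dsfe_out_dim, cfg.n_classes)
           for _ in range(cfg.n_sources)]
    return ModelParams(config=cfg, cfe=cfe, dsfe=dsfe, dsc=dsc)


def n_parameters(cfg: ModelConfig) -> int:
    dims = cfg.cfe_dims
    total = sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))
    total += cfg.n_sources * (cfg.cfe_out_dim * cfg.dsfe_out_dim + cfg.dsfe_out_dim)
    total += cfg.n_sources * (cfg.dsfe_out_dim * cfg.n_classes + cfg.n_classes)
    return total


def cfe_forward(params: ModelParams, X) -> Tensor:
    """Common feature extractor: three affine+LeakyReLU layers."""
    h = as_tensor(X)
    if h.shape[-1] != params.config.input_dim:
        raise ValueError(
            f"expected {params.config.input_dim} input features, got {h.shape[-1]}"
        )
    slope = params.config.leaky_slope
    for W, b in params.cfe:
        h = (h @ W + b).leaky_relu(slope)
    return h


def branch_forward(params: ModelParams, q, branch: int) -> tuple[Tensor, Tensor]:
    """DSFE (affine + LeakyReLU) then DSC (affine, no activation)."""
    if not 0 <= branch < params.config.n_sources:
        raise IndexError(f"branch {branch} out of range "
                         f"[0, {params.config.n_sources})")
    q = as_tensor(q)
    W, b = params.dsfe[branch]
    r = (q @ W + b).leaky_relu(params.config.leaky_slope)
    Wc, bc = params.dsc[branch]
    logits = r @ Wc + bc
    return r, logits


def full_forward(params: ModelParams, source_batches, target_batch
                 ) -> BranchOutputs:
    """One multi-branch pass: CFE once per batch, target through every branch."""
    if len(source_batches) != params.config.n_sources:
        raise ValueError(
            f"expected {params.config.n_sources} source batches, "
            f"got {len(source_batches)}"
        )
    m = as_tensor(target_batch).shape[0]
    for sb in source_batches:
        if as_tensor(sb).shape[0] != m:
            raise ValueError("all batches must share the same size m "
                             "(the MMD estimator assumes equal m)")
    qT = cfe_forward(params, target_batch)
    qS, rS, rT, lS, lT = [], [], [], [], []
    for i, sb in enumerate(source_batches):
        qi = cfe_forward(params, sb)
        ri, li = branch_forward(params, qi, i)
        rti, lti = branch_forward(params, qT, i)
        qS.append(qi)
        rS.append(ri)
        rT.append(rti)
        lS.append(li)
        lT.append(lti)
    return BranchOutputs(common_source=qS, common_target=qT,
                         source_features=rS, target_features=rT,
                         source_logits=lS, target_logits=lT)


def save_checkpoint(params: ModelParams, path) -> None:
    """Single-file container: weights + embedded JSON config."""
    arrays = params.arrays()
    arrays["_config_json"] = np.frombuffer(
        json.dumps(asdict(params.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelParams:
    with np.load(path) as z:
        cfg_dict = json.loads(bytes(z["_config_json"].tobytes()).decode())
        cfg_dict["cfe_hidden_dims"] = tuple(cfg_dict["cfe_hidden_dims"])
        cfg = ModelConfig(**cfg_dict)
        params = init_model(cfg, seed=0)
        for name, layers in (("cfe", params.cfe), ("dsfe", params.dsfe),
                             ("dsc", params.dsc)):
            for i, (W, b) in enumerate(layers):
                W.data = z[f"{name}{i}_W"].astype(np.float64)
                b.data = z[f"{name}{i}_b"].astype(np.float64)
    return params
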