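"""Training losses and the adaptation-weight schedule.

The total objective is  L = L_cls + α·L_MMD + β·L_disc :

* L_cls — sum over branches of the mean cross-entropy of each branch's
  source predictions against its source labels.
* L_MMD — per branch, the squared maximum mean discrepancy between the
  branch's source and target DSFE features, summed over branches.  The
  kernel is a multi-bandwidth Gaussian RBF by default (geometric ladder
  around the median pairwise squared distance of the pooled batch, the
  DAN-lineage convention); single-bandwidth RBF and linear kernels are
  available, as is a CORAL covariance-alignment alternative.
* L_disc — summed over ordered branch pairs i ≠ j, the mean absolute
  difference between the branches' softmax predictions on the target
  batch; it pulls the N classifiers toward agreement.

α ramps from 0 to ~1 along training progress p via 2/(1+e^(−10p)) − 1, so
early training focuses on classification before alignment kicks in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor

__all__ = ["KernelSpec", "LossWeights", "mmd_squared", "coral_loss",
           "classification_loss", "discrepancy_loss", "alpha_schedule",
           "total_loss", "log_softmax", "softmax"]

logger = logging.getLogger(__name__)


@dataclass
class KernelSpec:
    kind: str = "rbf_multi"          # rbf_multi | rbf_single | linear
    n_kernels: int = 5
    bandwidth_ladder_base: float = 2.0
    bandwidth_anchor: str | float = "median_pairwise"

    def __post_init__(self):
        if self.kind not in ("rbf_multi", "rbf_single", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")


@dataclass
class LossWeights:
    beta_weight: float = 0.01
    beta_mode: str = "times_alpha"    # times_alpha | constant
    disc_start_fraction: float = 0.0

    def __post_init__(self):
        if self.beta_weight < 0:
            raise ValueError("beta_weight must be >= 0")
        if self.beta_mode not in ("times_alpha", "constant"):
            raise ValueError(f"unknown beta_mode {self.beta_mode!r}")
        if not 0.0 <= self.disc_start_fraction <= 1.0:
            raise ValueError("disc_start_fraction must be in [0, 1]")


# --------------------------------------------------------------------- helpers
def _sq_dists(A: Tensor, B: Tensor) -> Tensor:
    a2 = (A * A).sum(axis=1, keepdims=True)
    b2 = (B * B).sum(axis=1, keepdims=True)
    return a2 + b2.T - 2.0 * (A @ B.T)


def _bandwidths(pooled_sqdist: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if isinstance(spec.bandwidth_anchor, (int, float)):
        anchor = float(spec.bandwidth_anchor)
    else:
        off_diag = pooled_sqdist[~np.eye(pooled_sqdist.shape[0], dtype=bool)]
        anchor = float(np.median(off_diag)) if off_diag.size else 0.0
        if anchor <= 0.0:
            logger.warning("degenerate batch (zero median pairwise distance); "
                           "falling back to fixed bandwidth 1.0")
            anchor = 1.0
    if spec.kind == "rbf_single":
        return np.array([anchor])
    k = spec.n_kernels
    base = spec.bandwidth_ladder_base
    return anchor * base ** (np.arange(k) - k // 2)


def _mmd_tensor(A: Tensor, B: Tensor, spec: KernelSpec,
                estimator: str = "biased") -> Tensor:
    """Squared-MMD graph node between equal-size batches A and B."""
    m = A.shape[0]
    if B.shape[0] != m:
        raise ValueError(f"MMD needs equal batch sizes, got {m} and {B.shape[0]}")
    if spec.kind == "linear":
        kaa, kbb, kab = A @ A.T, B @ B.T, A @ B.T
    else:
        pooled = np.vstack([A.data, B.data])
        p2 = (pooled ** 2).sum(axis=1)
        pooled_sq = p2[:, None] + p2[None, :] - 2.0 * pooled @ pooled.T
        bws = _bandwidths(pooled_sq, spec)  # detached from the graph
        daa, dbb, dab = _sq_dists(A, A), _sq_dists(B, B), _sq_dists(A, B)

        def kernel(d: Tensor) -> Tensor:
            ks = [(d * (-1.0 / bw)).exp() for bw in bws]
            acc = ks[0]
            for k in ks[1:]:
                acc = acc + k
            return acc / len(ks)

        kaa, kbb, kab = kernel(daa), kernel(dbb), kernel(dab)
    if estimator == "biased":
        return kaa.mean() + kbb.mean() - 2.0 * kab.mean()
    if estimator == "unbiased":
        if m < 2:
            raise ValueError("unbiased MMD needs m >= 2")
        diag_a = Tensor(np.eye(m)) * kaa
        diag_b = Tensor(np.eye(m)) * kbb
        c = 1.0 / (m * (m - 1))
        return ((kaa.sum() - diag_a.sum()) * c
                + (kbb.sum() - diag_b.sum()) * c
                - 2.0 * kab.mean())
    raise ValueError(f"unknown estimator {estimator!r}")


def mmd_squared(A, B, kernel: KernelSpec | None = None,
                estimator: str = "biased") -> float:
    """Squared MMD between two m x d batches (non-negative scalar)."""
    kernel = kernel or KernelSpec()
    val = _mmd_tensor(as_tensor(np.asarray(A, dtype=np.float64)),
                      as_tensor(np.asarray(B, dtype=np.float64)),
                      kernel, estimator).item()
    if estimator == "biased" and val < -1e-9:  # pragma: no cover
        raise AssertionError(f"biased MMD estimate {val} < -1e-9")
    return max(val, 0.0) if estimator == "biased" else val


def coral_loss(A, B) -> float:
    """Covariance alignment ‖C_S − C_T‖²_F / (4d²)."""
    return _coral_tensor(as_tensor(np.asarray(A, dtype=np.float64)),
                         as_tensor(np.asarray(B, dtype=np.float64))).item()


def _coral_tensor(A: Tensor, B: Tensor) -> Tensor:
    d = A.shape[1]

    def cov(X: Tensor) -> Tensor:
        n = X.shape[0]
        Xc = X - X.mean(axis=0, keepdims=True)
        return (Xc.T @ Xc) / max(n - 1, 1)

    diff = cov(A) - cov(B)
    return (diff * diff).sum() / (4.0 * d * d)


# ---------------------------------------------------------------- predictions
def log_softmax(logits: Tensor) -> Tensor:
    z = logits - np.max(logits.data, axis=1, keepdims=True)  # constant shift
    return z - (z.exp().sum(axis=1, keepdims=True)).log()


def softmax(logits: Tensor) -> Tensor:
    return log_softmax(logits).exp()


def classification_loss(per_branch_logits, per_branch_labels) -> Tensor:
    """Σ over branches of the mean source cross-entropy."""
    total = None
    for logits, labels in zip(per_branch_logits, per_branch_labels, strict=True):
        logits = as_tensor(logits)
        labels = np.asarray(labels, dtype=np.int64)
        m, C = logits.shape
        if labels.min() < 0 or labels.max() >= C:
            raise ValueError(f"labels outside [0, {C})")
        onehot = np.zeros((m, C))
        onehot[np.arange(m), labels] = 1.0
        term = -(log_softmax(logits) * onehot).sum() / m
        total = term if total is None else total + term
    if total is None:
        raise ValueError("need at least one branch")
    return total


def discrepancy_loss(per_branch_target_probs) -> Tensor:
    """Σ over ordered pairs i ≠ j of mean |Ŷ_i − Ŷ_j| over all entries."""
    probs = [as_tensor(p) for p in per_branch_target_probs]
    shapes = {p.shape for p in probs}
    if len(shapes) != 1:
        raise ValueError(f"branch predictions disagree in shape: {shapes}")
    for p in probs:
        rows = p.data.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-6):
            raise ValueError("rows of branch predictions must sum to 1")
    total = Tensor(0.0)
    for i, pi in enumerate(probs):
        for j, pj in enumerate(probs):
            if i != j:
                total = total + (pi - pj).abs().mean()
    return total


def alpha_schedule(step: int, total_steps: int) -> float:
    """α(p) = 2/(1+e^(−10p)) − 1 with progress p = step/total_steps."""
    if total_steps < 1:
        raise ValueError("total_steps must be >= 1")
    if not 0 <= step <= total_steps:
        raise ValueError("step must be in [0, total_steps]")
    p = step / total_steps
    return 2.0 / (1.0 + math.exp(-10.0 * p)) - 1.0


def total_loss(cls, mmd_sum, disc, weights: LossWeights,
               step: int, total_steps: int):
    """Weighted total L = L_cls + α·L_MMD + β_eff·L_disc and a log record.

    Accepts graph tensors (training) or plain floats.  The discrepancy
    term is zeroed while step < disc_start_fraction·total_steps.
    """
    alpha = alpha_schedule(step, total_steps)
    beta_eff = (weights.beta_weight * alpha
                if weights.beta_mode == "times_alpha" else weights.beta_weight)
    if step < weights.disc_start_fraction * total_steps:
        beta_eff = 0.0
    L = cls + alpha * mmd_sum + beta_eff * disc
    rec = {
        "cls": float(cls.item() if isinstance(cls, Tensor) else cls),
        "mmd": float(mmd_sum.item() if isinstance(mmd_sum, Tensor) else mmd_sum),
        "disc": float(disc.item() if isinstance(disc, Tensor) else disc),
        "alpha": alpha,
        "beta_eff": beta_eff,
        "total": float(L.item() if isinstance(L, Tensor) else L),
    }
    return L, rec
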