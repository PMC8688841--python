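"""Feature normalization strategies for trial x F DE-feature matrices.

Three standardization scopes are supported — per feature column
("electrode-wise", each column is one electrode-band pair), per trial row
("sample-wise") and over the whole matrix ("global-wise") — together with
two application orders for multi-source data: normalize each source
independently and then concatenate, or concatenate first and normalize
with pooled statistics.  The target domain is always normalized with its
own statistics, since pooled source statistics need not be available at
inference time.

The statistic is the z-score with population (1/n) variance by default;
min-max to [0, 1] is available via ``statistic="minmax"``.  Zero-variance
slices are centered and the divisor forced to 1, so constant inputs map
to zeros rather than NaN.
"""

from __future__ import annotations

from dataclasses import replace
from enum import Enum

import numpy as np

from .data import ConfigurationError, DataError, DomainDataset

__all__ = [
    "NormalizationType",
    "NormalizationOrder",
    "normalize_matrix",
    "apply_order",
    "normalize_task_domains",
]


class NormalizationType(str, Enum):
    NONE = "none"
    ELECTRODE_WISE = "electrode_wise"
    SAMPLE_WISE = "sample_wise"
    GLOBAL_WISE = "global_wise"
    # pools each electrode's band columns into one slice; a labeled variant
    # for the normalization study, not one of the three canonical types
    ELECTRODE_POOLED = "electrode_pooled"


class NormalizationOrder(str, Enum):
    NORMALIZE_THEN_CONCAT = "normalize_then_concat"
    CONCAT_THEN_NORMALIZE = "concat_then_normalize"


def _zscore(X: np.ndarray, axis) -> np.ndarray:
    mean = X.mean(axis=axis, keepdims=True)
    std = X.std(axis=axis, keepdims=True)  # population std
    std = np.where(std == 0.0, 1.0, std)
    return (X - mean) / std


def _minmax(X: np.ndarray, axis) -> np.ndarray:
    lo = X.min(axis=axis, keepdims=True)
    hi = X.max(axis=axis, keepdims=True)
    span = np.where(hi - lo == 0.0, 1.0, hi - lo)
    return (X - lo) / span


def normalize_matrix(X: np.ndarray,
                     kind: NormalizationType | str = NormalizationType.ELECTRODE_WISE,
                     statistic: str = "zscore",
                     n_bands: int = 5) -> np.ndarray:
    """Standardize a single n x F matrix with its own statistics."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.size == 0:
        raise DataError(f"expected a non-empty 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise DataError("matrix contains non-finite values")
    kind = NormalizationType(kind)
    fn = {"zscore": _zscore, "minmax": _minmax}[statistic]
    if kind is NormalizationType.NONE:
        return X.copy()
    if kind is NormalizationType.ELECTRODE_WISE:
        return fn(X, axis=0)
    if kind is NormalizationType.SAMPLE_WISE:
        return fn(X, axis=1)
    if kind is NormalizationType.GLOBAL_WISE:
        return fn(X, axis=(0, 1))
    # electrode_pooled: statistics pooled over each electrode's band columns
    n, F = X.shape
    if F % n_bands != 0:
        raise DataError(
            f"electrode_pooled needs n_features divisible by n_bands={n_bands}"
        )
    cube = X.reshape(n, F // n_bands, n_bands)
    return fn(cube, axis=(0, 2)).reshape(n, F)


def apply_order(domains: list[DomainDataset],
                kind: NormalizationType | str,
                order: NormalizationOrder | str = NormalizationOrder.NORMALIZE_THEN_CONCAT,
                statistic: str = "zscore") -> list[DomainDataset]:
    """Normalize a list of source domains under one of the two orders.

    ``normalize_then_concat`` treats every domain independently;
    ``concat_then_normalize`` stacks all domains row-wise, normalizes the
    pool once, and splits back preserving row provenance.
    """
    if not domains:
        raise ConfigurationError("apply_order needs at least one domain")
    kind = NormalizationType(kind)
    order = NormalizationOrder(order)
    if order is NormalizationOrder.NORMALIZE_THEN_CONCAT:
        return [
            replace(d, features=normalize_matrix(d.features, kind, statistic))
            for d in domains
        ]
    pooled = np.vstack([d.features for d in domains])
    pooled = normalize_matrix(pooled, kind, statistic)
    out, row = [], 0
    for d in domains:
        out.append(replace(d, features=pooled[row:row + d.n_samples]))
        row += d.n_samples
    return out


def normalize_task_domains(sources: list[DomainDataset], target: DomainDataset,
                           kind: NormalizationType | str,
                           order: NormalizationOrder | str = NormalizationOrder.NORMALIZE_THEN_CONCAT,
                           statistic: str = "zscore"):
    """Normalize sources under ``order``; the target always uses its own stats."""
    kind = NormalizationType(kind)
    srcs = apply_order(sources, kind, order, statistic)
    tgt = replace(target, features=normalize_matrix(target.features, kind, statistic))
    return srcs, tgt
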