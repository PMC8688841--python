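"""Core data model: domains, multi-source tasks and transfer protocols.

A *domain* is one subject-session's trial x feature matrix of
differential-entropy (DE) features with optional integer emotion labels.
Transfer experiments consume a :class:`MultiSourceTask`: N labeled source
domains plus one target domain whose labels are held out during training
and used only for final evaluation (transductive unsupervised domain
adaptation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "DomainDataset",
    "MultiSourceTask",
    "DomainCollection",
    "validate_domain",
    "reshape_channel_band",
    "build_cross_session_tasks",
    "build_cross_subject_tasks",
    "DataError",
    "SchemaError",
    "ConfigurationError",
]


class DataError(ValueError):
    """Non-finite or otherwise corrupt feature values."""


class SchemaError(ValueError):
    """Labels or shapes inconsistent with the declared schema."""


class ConfigurationError(ValueError):
    """A protocol or experiment was requested on an unsuitable collection."""


@dataclass
class DomainDataset:
    """One domain's feature matrix (n_samples x n_features) + labels."""

    features: np.ndarray
    labels: Optional[np.ndarray] = None
    domain_id: str = ""

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise SchemaError(
                f"domain {self.domain_id!r}: features must be 2-D, "
                f"got shape {self.features.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).ravel()

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def without_labels(self) -> "DomainDataset":
        return replace(self, labels=None)


@dataclass
class MultiSourceTask:
    """N labeled sources + one target; the unit of one transfer experiment.

    Target labels, when stored, are evaluation-only; the training path
    never reads them.
    """

    sources: list[DomainDataset]
    target: DomainDataset
    n_classes: int
    task_id: str = ""

    def __post_init__(self):
        if len(self.sources) < 1:
            raise SchemaError("a task needs at least one source domain")
        widths = {d.n_features for d in self.sources} | {self.target.n_features}
        if len(widths) != 1:
            raise SchemaError(f"inconsistent n_features across domains: {widths}")
        for d in self.sources:
            if d.labels is None:
                raise SchemaError(f"source domain {d.domain_id!r} has no labels")
            validate_domain(d, self.n_classes)
        validate_domain(self.target.without_labels(), self.n_classes)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_features(self) -> int:
        return self.target.n_features


@dataclass
class DomainCollection:
    """(subject_index, session_index) -> DomainDataset grid, 1-based indices."""

    domains: dict[tuple[int, int], DomainDataset]
    n_classes: int

    def __post_init__(self):
        widths = {d.n_features for d in self.domains.values()}
        if len(widths) > 1:
            raise SchemaError(f"inconsistent n_features across collection: {widths}")

    @property
    def subjects(self) -> list[int]:
        return sorted({s for s, _ in self.domains})

    @property
    def sessions(self) -> list[int]:
        return sorted({k for _, k in self.domains})

    def get(self, subject: int, session: int) -> DomainDataset:
        try:
            return self.domains[(subject, session)]
        except KeyError:
            raise ConfigurationError(
                f"collection has no domain for subject {subject}, session {session}"
            ) from None


def validate_domain(d: DomainDataset, n_classes: int) -> DomainDataset:
    """Check finiteness and label range; return ``d`` unchanged if valid."""
    if d.n_samples < 1:
        raise SchemaError(f"domain {d.domain_id!r} is empty")
    if not np.all(np.isfinite(d.features)):
        bad = int(np.count_nonzero(~np.isfinite(d.features)))
        raise DataError(
            f"domain {d.domain_id!r} contains {bad} non-finite feature value(s)"
        )
    if d.labels is not None:
        if len(d.labels) != d.n_samples:
            raise SchemaError(
                f"domain {d.domain_id!r}: {len(d.labels)} labels for "
                f"{d.n_samples} samples"
            )
        if d.labels.min(initial=0) < 0 or d.labels.max(initial=0) >= n_classes:
            raise SchemaError(
                f"domain {d.domain_id!r}: labels outside [0, {n_classes})"
            )
    return d


def reshape_channel_band(tensor: np.ndarray) -> np.ndarray:
    """Merge a trials x channels x bands array into trials x (channels*bands).

    Column ordering is row-major by channel then band: output column
    ``c * n_bands + b`` holds channel ``c``, band ``b``.  For 62 channels and
    5 bands this produces the conventional trial x 310 layout.
    """
    tensor = np.asarray(tensor, dtype=np.float64)
    if tensor.ndim != 3:
        raise SchemaError(f"expected 3-D trials x channels x bands, got {tensor.shape}")
    t, c, b = tensor.shape
    return tensor.reshape(t, c * b)


def _task_from(sources: list[DomainDataset], target: DomainDataset,
               n_classes: int, task_id: str) -> MultiSourceTask:
    return MultiSourceTask(sources=list(sources), target=target,
                           n_classes=n_classes, task_id=task_id)


def build_cross_session_tasks(coll: DomainCollection,
                              rotate_target: bool = False) -> list[MultiSourceTask]:
    """One task per subject: earlier sessions are sources, the last session
    is the target.  With ``rotate_target=True`` every session takes a turn
    as target (full leave-one-session-out; an extension beyond the default
    fixed-target protocol).
    """
    sessions = coll.sessions
    if len(sessions) < 2:
        raise ConfigurationError("cross-session transfer needs >= 2 sessions")
    tasks: list[MultiSourceTask] = []
    for subj in coll.subjects:
        target_sessions = sessions if rotate_target else [sessions[-1]]
        for tgt in target_sessions:
            srcs = [coll.get(subj, k) for k in sessions if k != tgt]
            tasks.append(_task_from(srcs, coll.get(subj, tgt), coll.n_classes,
                                    task_id=f"subj{subj:02d}/target-sess{tgt}"))
    return tasks


def build_cross_subject_tasks(coll: DomainCollection,
                              rotate_target: bool = False) -> list[MultiSourceTask]:
    """One task per session: earlier subjects are sources, the last subject
    is the target (native subject ordering).  ``rotate_target=True`` gives
    full leave-one-subject-out rotation.
    """
    subjects = coll.subjects
    if len(subjects) < 2:
        raise ConfigurationError("cross-subject transfer needs >= 2 subjects")
    tasks: list[MultiSourceTask] = []
    for sess in coll.sessions:
        target_subjects = subjects if rotate_target else [subjects[-1]]
        for tgt in target_subjects:
            srcs = [coll.get(s, sess) for s in subjects if s != tgt]
            tasks.append(_task_from(srcs, coll.get(tgt, sess), coll.n_classes,
                                    task_id=f"sess{sess}/target-subj{tgt:02d}"))
    return tasks
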