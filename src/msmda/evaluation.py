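"""Experiment harnesses: protocol runs, ablations, sweeps and grids.

Every runner trains with paired seeds and shared data across the
conditions it contrasts, so differences in accuracy reflect the method,
not sampling.  Aggregates are reported as mean ± population std across
tasks (and seeds when several are supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .data import (ConfigurationError, DomainCollection, MultiSourceTask,
                   build_cross_session_tasks, build_cross_subject_tasks)
from .estimators import MSMDAClassifier, SingleBranchDAClassifier
from .normalization import NormalizationOrder, NormalizationType

__all__ = ["MethodSpec", "ResultRecord", "run_protocol", "run_task",
           "run_single_branch_baseline", "run_ablation", "run_source_sweep",
           "run_normalization_grid", "aggregate"]

ABLATION_VARIANTS = ("full", "w/o MMD", "w/o disc", "w/o both")


@dataclass(frozen=True)
class MethodSpec:
    name: str = "msmda"                  # msmda | single_branch
    alignment: str = "mmd_multi"         # mmd_multi | mmd_single | coral | none
    use_disc: bool = True
    combine_sources: bool = False

    def __post_init__(self):
        if self.name not in ("msmda", "single_branch"):
            raise ValueError(f"unknown method {self.name!r}")
        if self.name == "msmda" and self.combine_sources:
            raise ValueError("msmda never combines sources")
        if self.name == "single_branch" and not self.combine_sources:
            raise ValueError("single_branch must combine sources")
        if self.name == "single_branch" and self.use_disc:
            raise ValueError("single_branch has one classifier; no discrepancy")


@dataclass
class ResultRecord:
    task_id: str
    method: MethodSpec
    accuracy: float
    seed: int
    normalization: str = "electrode_wise"
    norm_order: str = "normalize_then_concat"
    variant: str = ""
    final_losses: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError(f"accuracy {self.accuracy} outside [0, 1]")


def make_estimator(method: MethodSpec, seed: int = 0, **overrides):
    cls = SingleBranchDAClassifier if method.combine_sources else MSMDAClassifier
    kwargs = dict(overrides)
    # method-owned settings take precedence over generic config overrides
    kwargs["alignment"] = method.alignment
    kwargs["random_state"] = seed
    if not method.use_disc:
        kwargs["beta_weight"] = 0.0
    return cls(**kwargs)


def run_task(task: MultiSourceTask, method: MethodSpec, seed: int = 0,
             variant: str = "", **overrides) -> ResultRecord:
    """Train one method on one task; evaluate on the held-out target labels."""
    if task.target.labels is None:
        raise ConfigurationError(f"task {task.task_id!r} has no target labels "
                                 "to evaluate against")
    est = make_estimator(method, seed=seed, **overrides)
    est.fit(task)
    acc = float(np.mean(est.predict(task.target.features) == task.target.labels))
    last = est.history_.records[-1]
    return ResultRecord(
        task_id=task.task_id, method=method, accuracy=acc, seed=seed,
        normalization=str(est.normalization), norm_order=str(est.norm_order),
        variant=variant,
        final_losses={k: last[k] for k in ("total", "cls", "mmd", "disc", "alpha")})


def aggregate(records: list[ResultRecord]) -> tuple[float, float]:
    """Mean and population std of accuracy across records."""
    accs = np.array([r.accuracy for r in records])
    return float(accs.mean()), float(accs.std())


def _build_tasks(coll: DomainCollection, protocol: str) -> list[MultiSourceTask]:
    if protocol == "cross_session":
        return build_cross_session_tasks(coll)
    if protocol == "cross_subject":
        return build_cross_subject_tasks(coll)
    raise ConfigurationError(f"unknown protocol {protocol!r}")


def run_protocol(coll: DomainCollection, protocol: str,
                 method: MethodSpec = MethodSpec(), seeds=(0,),
                 **overrides):
    """All tasks of a protocol, each trained per seed; returns
    ((mean, std), records)."""
    tasks = _build_tasks(coll, protocol)
    records = [run_task(t, method, seed=s, **overrides)
               for t in tasks for s in seeds]
    return aggregate(records), records


def run_single_branch_baseline(task: MultiSourceTask, alignment: str = "mmd_multi",
                               seed: int = 0, **overrides) -> ResultRecord:
    """Source-combine baseline on this paper's backbone: multi-kernel MMD is
    DAN-style, single-kernel DDC-style, CORAL DCORAL-style, none source-only."""
    method = MethodSpec(name="single_branch", alignment=alignment,
                        use_disc=False, combine_sources=True)
    return run_task(task, method, seed=seed, **overrides)


def _ablation_method(variant: str, base: MethodSpec) -> tuple[MethodSpec, dict]:
    """α forced 0 == no alignment term; β forced 0 == no discrepancy term."""
    if variant == "full":
        return base, {}
    if variant == "w/o MMD":
        return _dc_replace(base, alignment="none"), {}
    if variant == "w/o disc":
        return _dc_replace(base, use_disc=False), {}
    if variant == "w/o both":
        return _dc_replace(base, alignment="none", use_disc=False), {}
    raise ValueError(f"unknown ablation variant {variant!r}")


def run_ablation(task: MultiSourceTask, seeds=(0,),
                 base: MethodSpec = MethodSpec(), **overrides) -> list[ResultRecord]:
    """Four rows — full, w/o MMD, w/o disc, w/o both — under shared seeds."""
    records = []
    for variant in ABLATION_VARIANTS:
        method, extra = _ablation_method(variant, base)
        for s in seeds:
            records.append(run_task(task, method, seed=s, variant=variant,
                                    **{**overrides, **extra}))
    return records


def run_source_sweep(source_of_tasks, max_sources: int,
                     protocol: str | None = None, seeds=(0,), ks=None,
                     method: MethodSpec = MethodSpec(), **overrides):
    """Accuracy as a function of the number of source branches.

    For k = 1..max_sources (or the ks given), sources are the FIRST k
    domains of each task.  Accepts a MultiSourceTask or a collection plus
    protocol.  Returns a list of (k, mean_accuracy, records) triples.
    """
    if isinstance(source_of_tasks, MultiSourceTask):
        tasks = [source_of_tasks]
    else:
        tasks = _build_tasks(source_of_tasks, protocol)
    if any(t.n_sources < max_sources for t in tasks):
        raise ConfigurationError(
            f"tasks have fewer than {max_sources} source domains")
    ks = list(ks) if ks is not None else list(range(1, max_sources + 1))
    curve = []
    for k in ks:
        records = []
        for t in tasks:
            sub = MultiSourceTask(sources=t.sources[:k], target=t.target,
                                  n_classes=t.n_classes,
                                  task_id=f"{t.task_id}/k{k}")
            for s in seeds:
                records.append(run_task(sub, method, seed=s,
                                        variant=f"k={k}", **overrides))
        curve.append((k, aggregate(records)[0], records))
    return curve


def run_normalization_grid(source_of_tasks, methods=None, protocol: str | None = None,
                           seeds=(0,), **overrides):
    """{none, electrode, sample, global} x {2 orders} x methods grid.

    Cells where the order provably cannot matter — every msmda cell
    (sources are never concatenated) and every ``none`` cell — are run
    once and annotated ``order_invariant`` instead of re-run.
    """
    if isinstance(source_of_tasks, MultiSourceTask):
        tasks = [source_of_tasks]
    else:
        tasks = _build_tasks(source_of_tasks, protocol)
    if methods is None:
        methods = [MethodSpec(),
                   MethodSpec(name="single_branch", alignment="mmd_multi",
                              use_disc=False, combine_sources=True)]
    types = [NormalizationType.NONE, NormalizationType.ELECTRODE_WISE,
             NormalizationType.SAMPLE_WISE, NormalizationType.GLOBAL_WISE]
    rows = []
    for method in methods:
        for kind in types:
            invariant = (not method.combine_sources
                         or kind is NormalizationType.NONE)
            cached = None
            for order in (NormalizationOrder.NORMALIZE_THEN_CONCAT,
                          NormalizationOrder.CONCAT_THEN_NORMALIZE):
                if invariant and cached is not None:
                    records = cached
                else:
                    records = [run_task(t, method, seed=s,
                                        normalization=kind.value,
                                        norm_order=order.value, **overrides)
                               for t in tasks for s in seeds]
                    cached = records
                mean, std = aggregate(records)
                rows.append({"method": method.name, "alignment": method.alignment,
                             "normalization": kind.value, "order": order.value,
                             "order_invariant": invariant,
                             "mean_accuracy": mean, "std_accuracy": std,
                             "records": records})
    return rows
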