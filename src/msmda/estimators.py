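"""Scikit-learn style estimators for multi-source domain adaptation.

:class:`MSMDAClassifier` trains one adaptation branch per source domain:
a shared common feature extractor, per-source feature extractors whose
source/target features are aligned with a kernel MMD penalty, and
per-source softmax classifiers whose target predictions are pulled toward
agreement by an L1 discrepancy penalty; inference averages the branch
predictions.  :class:`SingleBranchDAClassifier` is the source-combine
strategy: all sources are concatenated into one domain and a single
branch is trained — with multi-kernel MMD this is a DAN-style baseline,
with a single kernel DDC-style, with correlation alignment DCORAL-style,
and with no alignment a source-only model.

Both estimators are transductive: ``fit`` sees the unlabeled target
features, and ``predict`` is typically called on those same features.

Example
-------
>>> from msmda.synthetic import SyntheticConfig, generate_multisource
>>> task = generate_multisource(SyntheticConfig(n_domains=3, n_per_domain=60,
...                                             n_electrodes=4, seed=1))
>>> clf = MSMDAClassifier(epochs=5, batch_size=32, random_state=0)
>>> labels = clf.fit(task).predict(task.target.features)
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Adam, Tensor
from .data import DomainDataset, MultiSourceTask, validate_domain
from .losses import (KernelSpec, LossWeights, _coral_tensor, _mmd_tensor,
                     classification_loss, discrepancy_loss, softmax,
                     total_loss)
from .network import ModelConfig, full_forward, init_model
from .normalization import NormalizationOrder, NormalizationType, normalize_task_domains
from .training import (TrainHistory, TrainingError, evaluate_accuracy,
                       make_samplers, predict)

__all__ = ["MSMDAClassifier", "SingleBranchDAClassifier"]


class MSMDAClassifier(ClassifierMixin, BaseEstimator):
    """Multi-source marginal distribution adaptation classifier.

    Parameters follow the reference training recipe: a 3-affine-layer
    common extractor (input → hidden_dims → cfe_out_dim, LeakyReLU after
    every affine layer), one 64→32 extractor + 32→C linear classifier per
    source, Adam at lr 0.01 for 200 epochs with batch size 256, electrode-
    wise z-scoring of every domain, a sigmoid ramp on the MMD weight α,
    and discrepancy weight ``beta_weight`` (0.01), by default multiplied
    by α and active for the whole of training.
    """

    _combine_sources = False

    def __init__(self, hidden_dims=(256, 128), cfe_out_dim=64, dsfe_out_dim=32,
                 leaky_slope=0.01, epochs=200, batch_size=256,
                 learning_rate=0.01, alignment="mmd_multi", n_kernels=5,
                 kernel_mul=2.0, bandwidth_anchor="median_pairwise",
                 mmd_estimator="biased", beta_weight=0.01,
                 beta_mode="times_alpha", disc_start_fraction=0.0,
                 alpha_progress="step", normalization="electrode_wise",
                 norm_order="normalize_then_concat", norm_statistic="zscore",
                 random_state=0):
        self.hidden_dims = hidden_dims
        self.cfe_out_dim = cfe_out_dim
        self.dsfe_out_dim = dsfe_out_dim
        self.leaky_slope = leaky_slope
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.alignment = alignment
        self.n_kernels = n_kernels
        self.kernel_mul = kernel_mul
        self.bandwidth_anchor = bandwidth_anchor
        self.mmd_estimator = mmd_estimator
        self.beta_weight = beta_weight
        self.beta_mode = beta_mode
        self.disc_start_fraction = disc_start_fraction
        self.alpha_progress = alpha_progress
        self.normalization = normalization
        self.norm_order = norm_order
        self.norm_statistic = norm_statistic
        self.random_state = random_state

    # ------------------------------------------------------------------ input
    def _as_task(self, X, y, domain) -> MultiSourceTask:
        if isinstance(X, MultiSourceTask):
            return X
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if domain is None:
            raise ValueError(
                "array input needs a `domain` vector assigning each row to a "
                "domain; rows with y == -1 form the (unlabeled) target domain"
            )
        domain = np.asarray(domain)
        target_mask = y == -1
        tgt_domains = set(np.unique(domain[target_mask]))
        if len(tgt_domains) != 1:
            raise ValueError("exactly one domain must be fully unlabeled "
                             "(y == -1) to serve as target")
        tgt = tgt_domains.pop()
        n_classes = int(y[~target_mask].max()) + 1
        sources = []
        for d in sorted(set(domain[~target_mask]), key=str):
            rows = domain == d
            sources.append(DomainDataset(features=X[rows], labels=y[rows],
                                         domain_id=str(d)))
        target = DomainDataset(features=X[domain == tgt], domain_id=str(tgt))
        return MultiSourceTask(sources=sources, target=target,
                               n_classes=n_classes)

    def _prepared_domains(self, task: MultiSourceTask):
        """Normalize (per config), then optionally combine sources."""
        sources = [validate_domain(d, task.n_classes) for d in task.sources]
        target = task.target.without_labels()  # labels never reach training
        kind = NormalizationType(self.normalization)
        if kind is not NormalizationType.NONE:
            order = (NormalizationOrder(self.norm_order)
                     if self._combine_sources
                     else NormalizationOrder.NORMALIZE_THEN_CONCAT)
            sources, target = normalize_task_domains(
                sources, target, kind, order, self.norm_statistic)
        if self._combine_sources and len(sources) > 1:
            sources = [DomainDataset(
                features=np.vstack([d.features for d in sources]),
                labels=np.concatenate([d.labels for d in sources]),
                domain_id="combined")]
        return sources, target

    # -------------------------------------------------------------------- fit
    def fit(self, X, y=None, *, domain=None, eval_target_labels=None):
        """Train on N labeled sources and the unlabeled target features.

        ``X`` may be a :class:`MultiSourceTask`, or a stacked array with
        ``y`` (−1 marks target rows) and a per-row ``domain`` vector.
        ``eval_target_labels``, if given explicitly, enables per-epoch
        target accuracy logging; the optimization itself never reads them.
        """
        task = self._as_task(X, y, domain)
        sources, target = self._prepared_domains(task)
        n_sources = len(sources)
        mcfg = ModelConfig(
            input_dim=task.n_features, cfe_hidden_dims=tuple(self.hidden_dims),
            cfe_out_dim=self.cfe_out_dim, dsfe_out_dim=self.dsfe_out_dim,
            n_classes=task.n_classes, n_sources=n_sources,
            leaky_slope=self.leaky_slope)
        kernel = KernelSpec(
            kind="rbf_single" if self.alignment == "mmd_single" else "rbf_multi",
            n_kernels=self.n_kernels,
            bandwidth_ladder_base=self.kernel_mul,
            bandwidth_anchor=self.bandwidth_anchor)
        weights = LossWeights(beta_weight=self.beta_weight,
                              beta_mode=self.beta_mode,
                              disc_start_fraction=self.disc_start_fraction)
        seed = int(self.random_state or 0)

        params = init_model(mcfg, seed=seed)
        opt = Adam(params.parameters(), lr=self.learning_rate)
        m = int(self.batch_size)
        domains = sources + [target]
        samplers = make_samplers(domains, m, seed)
        steps_per_epoch = max(
            math.ceil(max(d.n_samples for d in domains) / m), 1)
        total_steps = int(self.epochs) * steps_per_epoch
        history = TrainHistory()
        use_disc = self.beta_weight > 0 and n_sources > 1
        eval_domain = None
        if eval_target_labels is not None:
            eval_domain = DomainDataset(features=target.features,
                                        labels=np.asarray(eval_target_labels),
                                        domain_id="eval")

        for step in range(total_steps):
            idx = [next(s) for s in samplers]
            src_batches = [d.features[ix] for d, ix in zip(sources, idx[:-1])]
            src_labels = [d.labels[ix] for d, ix in zip(sources, idx[:-1])]
            tgt_batch = target.features[idx[-1]]

            out = full_forward(params, src_batches, tgt_batch)
            cls = classification_loss(out.source_logits, src_labels)

            if self.alignment == "none":
                mmd_sum = 0.0
            else:
                align = (_coral_tensor if self.alignment == "coral"
                         else lambda a, b: _mmd_tensor(a, b, kernel,
                                                       self.mmd_estimator))
                mmd_sum = None
                for rs, rt in zip(out.source_features, out.target_features):
                    t = align(rs, rt)
                    mmd_sum = t if mmd_sum is None else mmd_sum + t

            disc = (discrepancy_loss([softmax(l) for l in out.target_logits])
                    if use_disc else 0.0)

            if self.alpha_progress == "epoch":
                sched = (step // steps_per_epoch, int(self.epochs))
            else:
                sched = (step, total_steps)
            L, rec = total_loss(cls, mmd_sum, disc, weights, *sched)
            if not np.isfinite(rec["total"]):
                raise TrainingError(f"non-finite loss at step {step}: {rec}")

            opt.zero_grad()
            L.backward()
            opt.step()
            rec["step"] = step
            rec["epoch"] = step // steps_per_epoch
            history.records.append(rec)
            if eval_domain is not None and (step + 1) % steps_per_epoch == 0:
                history.epoch_accuracy.append(
                    evaluate_accuracy(params, eval_domain))

        self.params_ = params
        self.history_ = history
        self.classes_ = np.arange(task.n_classes)
        self.n_features_in_ = task.n_features
        self.n_sources_ = n_sources
        self.model_config_ = mcfg
        return self

    def predict(self, X):
        probs, labels = predict(self.params_, self._transform_target(X))
        return self.classes_[labels]

    def predict_proba(self, X):
        probs, _ = predict(self.params_, self._transform_target(X))
        return probs

    def _transform_target(self, X):
        from .normalization import normalize_matrix
        X = np.asarray(X, dtype=np.float64)
        kind = NormalizationType(self.normalization)
        if kind is NormalizationType.NONE:
            return X
        return normalize_matrix(X, kind, self.norm_statistic)


class SingleBranchDAClassifier(MSMDAClassifier):
    """Source-combine baseline: one branch over the concatenated sources."""

    _combine_sources = True
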