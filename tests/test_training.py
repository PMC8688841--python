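"""Training loop: samplers, gradients through the full objective,
label-blindness, history bookkeeping and the averaged inference rule."""

import numpy as np
import pytest
from dataclasses import replace

from msmda._autodiff import Tensor
from msmda.data import DomainDataset, MultiSourceTask
from msmda.estimators import MSMDAClassifier
from msmda.losses import (KernelSpec, LossWeights, _mmd_tensor,
                          classification_loss, discrepancy_loss, softmax,
                          total_loss)
from msmda.network import ModelConfig, full_forward, init_model
from msmda.studies import no_shift_config
from msmda.synthetic import generate_multisource
from msmda.training import evaluate_accuracy, make_samplers, predict, train
from conftest import TINY_NET


def _domain(n, f=3, seed=0, labels=True):
    rng = np.random.default_rng(seed)
    return DomainDataset(features=rng.normal(size=(n, f)),
                         labels=rng.integers(0, 2, size=n) if labels else None,
                         domain_id=f"d{seed}")


class TestSamplers:
    def test_epoch_permutation_exhaustive_before_reshuffle(self):
        (stream,) = make_samplers([_domain(10)], m=5, seed=0)
        first_epoch = np.concatenate([next(stream), next(stream)])
        assert sorted(first_epoch) == list(range(10))

    def test_wraparound_batch_still_full_size(self):
        (stream,) = make_samplers([_domain(3)], m=5, seed=1)
        batch = next(stream)
        assert len(batch) == 5
        assert set(batch) == {0, 1, 2}  # first full permutation + 2 repeats

    def test_streams_independent_across_domains(self):
        s1, s2 = make_samplers([_domain(30, seed=1), _domain(30, seed=2)],
                               m=30, seed=0)
        assert not np.array_equal(next(s1), next(s2))

    def test_deterministic_given_seed(self):
        a = [next(make_samplers([_domain(8)], 4, seed=5)[0]) for _ in range(1)]
        b = [next(make_samplers([_domain(8)], 4, seed=5)[0]) for _ in range(1)]
        np.testing.assert_array_equal(a, b)


def test_objective_gradient_matches_finite_differences(rng):
    """Autodiff gradient of the full step loss (cls + α·MMD + β·disc)
    against central finite differences on a handful of weights."""
    cfg = ModelConfig(input_dim=4, cfe_hidden_dims=(4, 3), cfe_out_dim=3,
                      dsfe_out_dim=2, n_classes=2, n_sources=2)
    params = init_model(cfg, seed=0)
    srcs = [rng.normal(size=(6, 4)) for _ in range(2)]
    labels = [rng.integers(0, 2, size=6) for _ in range(2)]
    tgt = rng.normal(size=(6, 4))
    # fixed anchor: the median-pairwise bandwidth is treated as a constant
    # of the step (not differentiated), so it must be pinned for the check
    kernel = KernelSpec(bandwidth_anchor=1.0)
    weights = LossWeights(beta_weight=0.5, beta_mode="constant")

    def loss_value():
        out = full_forward(params, srcs, tgt)
        cls = classification_loss(out.source_logits, labels)
        mmd = None
        for rs, rt in zip(out.source_features, out.target_features):
            t = _mmd_tensor(rs, rt, kernel)
            mmd = t if mmd is None else mmd + t
        disc = discrepancy_loss([softmax(l) for l in out.target_logits])
        L, _ = total_loss(cls, mmd, disc, weights, 5, 10)
        return L

    L = loss_value()
    L.backward()
    checked = 0
    for p in (params.cfe[0][0], params.dsfe[0][0], params.dsc[1][0],
              params.cfe[2][1]):
        flat_idx = [(0,) * p.data.ndim, (p.data.shape[0] - 1,) * p.data.ndim
                    if p.data.ndim == 1 else (p.data.shape[0] - 1,
                                              p.data.shape[1] - 1)]
        for idx in flat_idx:
            eps = 1e-6
            orig = p.data[idx]
            p.data[idx] = orig + eps
            hi = loss_value().item()
            p.data[idx] = orig - eps
            lo = loss_value().item()
            p.data[idx] = orig
            numeric = (hi - lo) / (2 * eps)
            analytic = p.grad[idx]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8)
            checked += 1
    assert checked == 8


class TestTrainLoop:
    def test_easy_task_reaches_high_accuracy(self):
        task = generate_multisource(no_shift_config(0, n_domains=3))
        est = MSMDAClassifier(hidden_dims=(32,), cfe_out_dim=16, dsfe_out_dim=8,
                              epochs=15, batch_size=64, random_state=0)
        est.fit(task)
        acc = np.mean(est.predict(task.target.features) == task.target.labels)
        assert acc >= 0.95

    def test_alpha_starts_at_zero_and_increases(self, tiny_task):
        est = MSMDAClassifier(**TINY_NET, random_state=0).fit(tiny_task)
        alphas = est.history_.column("alpha")
        assert alphas[0] == 0.0
        assert np.all(np.diff(alphas) > 0)

    def test_history_conserves_total_loss(self, tiny_task):
        est = MSMDAClassifier(**TINY_NET, random_state=0).fit(tiny_task)
        for rec in est.history_.records:
            expected = (rec["cls"] + rec["alpha"] * rec["mmd"]
                        + rec["beta_eff"] * rec["disc"])
            assert rec["total"] == pytest.approx(expected, abs=1e-9)

    def test_target_labels_never_influence_training(self, tiny_task):
        garbage = replace(tiny_task.target,
                          labels=np.full(tiny_task.target.n_samples, 12345))
        poisoned = MultiSourceTask(sources=tiny_task.sources, target=garbage,
                                   n_classes=tiny_task.n_classes)
        a = MSMDAClassifier(**TINY_NET, random_state=0).fit(tiny_task)
        b = MSMDAClassifier(**TINY_NET, random_state=0).fit(poisoned)
        for pa, pb in zip(a.params_.parameters(), b.params_.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_train_wrapper_returns_params_and_history(self, tiny_task):
        from msmda.training import TrainConfig

        params, history = train(tiny_task, train_config=TrainConfig(
            epochs=2, batch_size=16, seed=0))
        assert len(history.records) > 0
        assert params.config.n_sources == tiny_task.n_sources

    def test_epoch_accuracy_logged_only_when_labels_supplied(self, tiny_task):
        est = MSMDAClassifier(**TINY_NET, random_state=0)
        est.fit(tiny_task)
        assert est.history_.epoch_accuracy == []
        est2 = MSMDAClassifier(**TINY_NET, random_state=0)
        est2.fit(tiny_task, eval_target_labels=tiny_task.target.labels)
        assert len(est2.history_.epoch_accuracy) == TINY_NET["epochs"]


class TestPredict:
    def _zeroed(self, n_sources=2, n_classes=2):
        cfg = ModelConfig(input_dim=3, cfe_hidden_dims=(3, 3), cfe_out_dim=3,
                          dsfe_out_dim=2, n_classes=n_classes,
                          n_sources=n_sources)
        params = init_model(cfg, seed=0)
        for W, b in (*params.cfe, *params.dsfe, *params.dsc):
            W.data[:] = 0.0
            b.data[:] = 0.0
        return params

    def test_branch_average_hand_example(self):
        params = self._zeroed()
        # zero DSC weights make logits equal the bias: set per-branch biases
        params.dsc[0][1].data[:] = np.log([0.8, 0.2])
        params.dsc[1][1].data[:] = np.log([0.4, 0.6])
        probs, labels = predict(params, np.zeros((1, 3)))
        np.testing.assert_allclose(probs, [[0.6, 0.4]], atol=1e-12)
        assert labels[0] == 0

    def test_identical_branches_average_to_single_branch(self):
        params = self._zeroed()
        for i in (0, 1):
            params.dsc[i][1].data[:] = np.log([0.3, 0.7])
        probs, _ = predict(params, np.zeros((2, 3)))
        np.testing.assert_allclose(probs, [[0.3, 0.7]] * 2, atol=1e-12)

    def test_exact_tie_breaks_to_lowest_index(self):
        params = self._zeroed()
        probs, labels = predict(params, np.zeros((3, 3)))
        np.testing.assert_allclose(probs, 0.5)
        assert np.all(labels == 0)

    def test_rows_sum_to_one(self, tiny_task):
        est = MSMDAClassifier(**TINY_NET, random_state=0).fit(tiny_task)
        probs = est.predict_proba(tiny_task.target.features)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestEvaluateAccuracy:
    def test_counting(self):
        cfg = ModelConfig(input_dim=3, cfe_hidden_dims=(3, 3), cfe_out_dim=3,
                          dsfe_out_dim=2, n_classes=2, n_sources=1)
        params = init_model(cfg, seed=0)
        for W, b in (*params.cfe, *params.dsfe, *params.dsc):
            W.data[:] = 0.0
            b.data[:] = 0.0  # ties everywhere -> predicts class 0
        target = DomainDataset(features=np.zeros((4, 3)),
                               labels=[0, 0, 0, 1])
        assert evaluate_accuracy(params, target) == pytest.approx(0.75)

    def test_missing_labels_rejected(self):
        cfg = ModelConfig(input_dim=2, cfe_hidden_dims=(2, 2), cfe_out_dim=2,
                          dsfe_out_dim=2, n_classes=2, n_sources=1)
        params = init_model(cfg, seed=0)
        with pytest.raises(ValueError):
            evaluate_accuracy(params, DomainDataset(features=np.zeros((2, 2))))
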