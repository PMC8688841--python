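"""Loss functions: MMD vs a naive double-sum oracle, cross-entropy,
prediction discrepancy, and the α ramp."""

import math

import numpy as np
import pytest

from msmda._autodiff import Tensor
from msmda.losses import (KernelSpec, LossWeights, alpha_schedule,
                          classification_loss, coral_loss, discrepancy_loss,
                          log_softmax, mmd_squared, softmax, total_loss)

LINEAR = KernelSpec(kind="linear")


def naive_mmd(A, B, spec: KernelSpec) -> float:
    """Independent O(m²) oracle: explicit three-term double sums."""
    if spec.kind == "linear":
        kern = lambda x, y: float(np.dot(x, y))
    else:
        pooled = np.vstack([A, B])
        sq = []
        for i in range(len(pooled)):
            for j in range(len(pooled)):
                if i != j:
                    sq.append(np.sum((pooled[i] - pooled[j]) ** 2))
        anchor = float(np.median(sq)) if sq else 0.0
        anchor = anchor if anchor > 0 else 1.0
        if spec.kind == "rbf_single":
            bws = [anchor]
        else:
            k = spec.n_kernels
            bws = [anchor * spec.bandwidth_ladder_base ** (i - k // 2)
                   for i in range(k)]
        kern = lambda x, y: float(np.mean(
            [math.exp(-np.sum((x - y) ** 2) / bw) for bw in bws]))
    m, n = len(A), len(B)
    kaa = sum(kern(a, a2) for a in A for a2 in A) / m ** 2
    kbb = sum(kern(b, b2) for b in B for b2 in B) / n ** 2
    kab = sum(kern(a, b) for a in A for b in B) / (m * n)
    return kaa + kbb - 2 * kab


class TestMMD:
    def test_identical_batches_give_zero(self, rng):
        A = rng.normal(size=(6, 3))
        for kind in ("linear", "rbf_single", "rbf_multi"):
            assert mmd_squared(A, A, KernelSpec(kind=kind)) <= 1e-9

    def test_linear_kernel_hand_example(self):
        assert mmd_squared([[0.0]], [[1.0]], LINEAR) == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["linear", "rbf_single", "rbf_multi"])
    def test_matches_naive_oracle(self, kind, rng):
        spec = KernelSpec(kind=kind)
        for _ in range(5):
            m, d = rng.integers(2, 10), rng.integers(1, 5)
            A, B = rng.normal(size=(m, d)), rng.normal(size=(m, d)) + 0.5
            assert mmd_squared(A, B, spec) == pytest.approx(
                naive_mmd(A, B, spec), abs=1e-6)

    def test_linear_kernel_equals_squared_mean_difference(self, rng):
        A, B = rng.normal(size=(8, 4)), rng.normal(size=(8, 4)) + 1.0
        diff = A.mean(axis=0) - B.mean(axis=0)
        assert mmd_squared(A, B, LINEAR) == pytest.approx(
            float(diff @ diff), abs=1e-9)

    def test_unequal_batch_sizes_rejected(self):
        with pytest.raises(ValueError):
            mmd_squared(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_degenerate_batch_falls_back_to_unit_bandwidth(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="msmda.losses"):
            val = mmd_squared(np.zeros((3, 2)), np.zeros((3, 2)))
        assert val == pytest.approx(0.0)
        assert any("bandwidth" in r.message for r in caplog.records)

    def test_unbiased_estimator_near_zero_for_same_distribution(self, rng):
        A, B = rng.normal(size=(40, 2)), rng.normal(size=(40, 2))
        biased = mmd_squared(A, B, estimator="biased")
        unbiased = mmd_squared(A, B, estimator="unbiased")
        assert unbiased < biased  # removing the diagonal shrinks the estimate

    def test_coral_zero_for_identical_covariance(self, rng):
        A = rng.normal(size=(10, 3))
        assert coral_loss(A, A.copy()) == pytest.approx(0.0)
        assert coral_loss(A, A + 5.0) == pytest.approx(0.0)  # mean-invariant


class TestClassificationLoss:
    def test_uniform_logits_give_log_C(self):
        logits = np.zeros((4, 3))
        val = classification_loss([logits], [np.array([0, 1, 2, 0])]).item()
        assert val == pytest.approx(math.log(3), abs=1e-12)

    def test_saturated_correct_prediction_near_zero(self):
        logits = np.array([[1000.0, 0.0]])
        assert classification_loss([logits], [np.array([0])]).item() < 1e-6

    def test_branch_sum_contract(self, rng):
        logits = rng.normal(size=(5, 3))
        labels = rng.integers(0, 3, size=5)
        one = classification_loss([logits], [labels]).item()
        two = classification_loss([logits, logits], [labels, labels]).item()
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            classification_loss([np.zeros((1, 2))], [np.array([2])])


class TestDiscrepancyLoss:
    def test_single_branch_is_zero(self):
        assert discrepancy_loss([np.array([[0.3, 0.7]])]).item() == 0.0

    def test_ordered_pair_hand_example(self):
        val = discrepancy_loss([np.array([[1.0, 0.0]]),
                                np.array([[0.0, 1.0]])]).item()
        assert val == pytest.approx(2.0)  # both ordered pairs, mean |diff| = 1

    def test_identical_predictions_give_zero(self):
        p = np.array([[0.2, 0.8], [0.5, 0.5]])
        assert discrepancy_loss([p, p, p]).item() == 0.0

    def test_symmetric_under_branch_permutation(self, rng):
        z = rng.normal(size=(4, 3))
        ps = [softmax(Tensor(z + i)).data for i in range(3)]
        a = discrepancy_loss(ps).item()
        b = discrepancy_loss([ps[2], ps[0], ps[1]]).item()
        assert a == pytest.approx(b, abs=1e-12)

    def test_duplicated_branch_doubles_distinct_pair(self, rng):
        z = rng.normal(size=(3, 2))
        p1 = softmax(Tensor(z)).data
        p2 = softmax(Tensor(z + 1.0)).data
        pair = discrepancy_loss([p1, p2]).item()
        triple = discrepancy_loss([p1, p1, p2]).item()
        assert triple == pytest.approx(2 * pair, abs=1e-12)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            discrepancy_loss([np.array([[0.5, 0.1]]), np.array([[0.5, 0.1]])])


class TestAlphaSchedule:
    def test_closed_form_points(self):
        assert alpha_schedule(0, 100) == 0.0
        assert alpha_schedule(50, 100) == pytest.approx(0.98661, abs=1e-5)
        assert alpha_schedule(100, 100) == pytest.approx(
            2 / (1 + math.exp(-10)) - 1, abs=1e-12)

    def test_strictly_increasing(self):
        vals = [alpha_schedule(i, 1000) for i in range(1001)]
        assert np.all(np.diff(vals) > 0)


class TestTotalLoss:
    def test_step_zero_reduces_to_classification(self):
        L, rec = total_loss(1.7, 5.0, 3.0, LossWeights(), 0, 10)
        assert L == pytest.approx(1.7)
        assert rec["alpha"] == 0.0 and rec["beta_eff"] == 0.0

    def test_disc_start_fraction_gates_constant_beta(self):
        w = LossWeights(beta_weight=0.01, beta_mode="constant",
                        disc_start_fraction=0.2)
        _, early = total_loss(1.0, 0.0, 9.0, w, 1, 10)
        _, late = total_loss(1.0, 0.0, 9.0, w, 3, 10)
        assert early["beta_eff"] == 0.0
        assert late["beta_eff"] == 0.01

    def test_weighted_arithmetic_at_saturated_alpha(self):
        w = LossWeights(beta_weight=0.01, beta_mode="constant")
        L, rec = total_loss(1.0, 1.0, 1.0, w, 10_000, 10_000)
        # α saturates at 2/(1+e⁻¹⁰)−1 ≈ 0.9999, so L ≈ 1 + α + 0.01
        assert L == pytest.approx(2.01, abs=2e-4)
        assert rec["total"] == pytest.approx(
            rec["cls"] + rec["alpha"] * rec["mmd"]
            + rec["beta_eff"] * rec["disc"], abs=1e-12)
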