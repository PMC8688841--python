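"""Run configuration: nested, validated, serializable.

Defaults are the reference training recipe (Adam lr 0.01, 200 epochs,
batch 256, electrode-wise normalization, multi-kernel MMD with a sigmoid
α ramp, discrepancy weight 0.01 applied over the whole of training).
Unknown keys are rejected.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict

__all__ = ["RunConfig", "load_run_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    hidden_dims: tuple[int, ...] = (256, 128)
    cfe_out_dim: int = 64
    dsfe_out_dim: int = 32
    leaky_slope: float = 0.01


class KernelSection(_Strict):
    kind: str = "rbf_multi"
    n_kernels: int = 5
    bandwidth_ladder_base: float = 2.0
    bandwidth_anchor: str | float = "median_pairwise"


class LossSection(_Strict):
    kernel: KernelSection = KernelSection()
    beta_weight: float = 0.01
    beta_mode: str = "times_alpha"
    disc_start_fraction: float = 0.0
    mmd_estimator: str = "biased"
    alignment: str = "mmd_multi"


class TrainSection(_Strict):
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 0.01
    seed: int = 0
    alpha_progress: str = "step"


class NormalizationSection(_Strict):
    type: str = "electrode_wise"
    order: str = "normalize_then_concat"
    statistic: str = "zscore"


class SyntheticSection(_Strict):
    n_subjects: int = 3
    n_sessions: int = 3
    n_classes: int = 3
    n_per_domain: int = 300
    n_electrodes: int = 16
    n_bands: int = 5
    class_separation: float = 0.5
    domain_offset_scale: float = 1.5
    domain_gain_scale: float = 0.4
    noise_sd: float = 0.8


class RunConfig(_Strict):
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    loss: LossSection = LossSection()
    normalization: NormalizationSection = NormalizationSection()
    synthetic: SyntheticSection = SyntheticSection()

    def estimator_kwargs(self) -> dict:
        """Estimator overrides; alignment and seed stay with the MethodSpec
        and the runner's seed list, so they are not included here."""
        return dict(
            hidden_dims=tuple(self.model.hidden_dims),
            cfe_out_dim=self.model.cfe_out_dim,
            dsfe_out_dim=self.model.dsfe_out_dim,
            leaky_slope=self.model.leaky_slope,
            epochs=self.train.epochs,
            batch_size=self.train.batch_size,
            learning_rate=self.train.learning_rate,
            n_kernels=self.loss.kernel.n_kernels,
            kernel_mul=self.loss.kernel.bandwidth_ladder_base,
            bandwidth_anchor=self.loss.kernel.bandwidth_anchor,
            mmd_estimator=self.loss.mmd_estimator,
            beta_weight=self.loss.beta_weight,
            beta_mode=self.loss.beta_mode,
            disc_start_fraction=self.loss.disc_start_fraction,
            alpha_progress=self.train.alpha_progress,
            normalization=self.normalization.type,
            norm_order=self.normalization.order,
            norm_statistic=self.normalization.statistic,
        )


def load_run_config(path=None, seed: int | None = None) -> RunConfig:
    if path is None:
        cfg = RunConfig()
    else:
        import yaml

        with open(path) as fh:
            cfg = RunConfig.model_validate(yaml.safe_load(fh) or {})
    if seed is not None:
        cfg.train.seed = int(seed)
    return cfg
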