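"""Alternating three-stage optimization and final inference.

Each training iteration runs three sub-steps on a pseudo-spot mini-batch
paired with a freshly masked real-ST batch:

1. encoder + decoder minimize ``lambda * L_MSE + (1 - lambda) * (L_C + L_D)``
   (masked reconstruction plus the adversarial pair), all other parameters
   frozen;
2. classifier + discriminator minimize ``lambda * L_C + (1 - lambda) * L_D``
   on a fresh, gradient-stopped forward pass through the encoder;
3. encoder + predictor minimize the proportion loss ``L_P`` on the pseudo
   batch.

The classifier is trained with correct domain labels and the discriminator
with flipped ones; the encoder, minimizing both, is pushed toward latent
features the two domains share.  Inference simply composes encoder and
predictor on the (unmasked) real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autograd import Adam, Tensor
from .data_io import ExpressionMatrix
from .masking import generate_mask
from .metrics import ProportionMatrix
from .networks import (
    LatentRep,
    ModelConfig,
    SpaDAMAModel,
    classifier_loss,
    discriminator_loss,
    predictor_loss,
)
from .pseudo_spots import PseudoSpotBatch


@dataclass
class TrainingConfig:
    epochs: int = 200
    batch_size: int = 2048
    learning_rate: float = 0.01
    rho: float = 0.3
    lambda_: float = 0.5
    seed: int = 0
    latent_split: float = 0.5
    grad_clip: float | None = 5.0
    model: ModelConfig | None = None

    def __post_init__(self):
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda_ must be in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


@dataclass
class TrainingTrace:
    """Per-iteration loss records for convergence monitoring."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kv) -> None:
        self.records.append(kv)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["epoch", "iteration", "L_stage1", "L_MSE", "L_C", "L_D",
                     "L_stage2", "L_P"],
        )


@dataclass
class Optimizers:
    stage1: Adam  # encoder + decoder
    stage2: Adam  # classifier + discriminator
    stage3: Adam  # encoder + predictor

    @classmethod
    def for_model(cls, model: SpaDAMAModel, config: TrainingConfig) -> "Optimizers":
        kw = dict(lr=config.learning_rate, clip_norm=config.grad_clip)
        return cls(
            stage1=Adam(model.params_encoder + model.params_decoder, **kw),
            stage2=Adam(model.params_classifier + model.params_discriminator, **kw),
            stage3=Adam(model.params_encoder + model.params_predictor, **kw),
        )


def _check_finite(value: float, stage: str) -> float:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss in training sub-step {stage}: {value}")
    return value


def _zero_all(model: SpaDAMAModel) -> None:
    for p in model.all_params():
        p.grad = None


def training_iteration(
    real_raw: np.ndarray,
    pseudo_X: np.ndarray,
    pseudo_Y: np.ndarray,
    model: SpaDAMAModel,
    config: TrainingConfig,
    opts: Optimizers,
    rng: np.random.Generator,
) -> dict:
    """One three-sub-step iteration; returns the loss record.

    ``real_raw`` is the normalized real-ST batch (masking is applied here,
    fresh every iteration); ``pseudo_X``/``pseudo_Y`` are the normalized
    pseudo-spot batch and its proportion labels.
    """
    lam = config.lambda_
    n_real, n_genes = real_raw.shape
    mask = generate_mask(n_real, n_genes, config.rho, rng)
    masked = real_raw * (1.0 - mask.M)
    mask_t = Tensor(mask.M)
    n_masked = max(mask.M.sum(), 1.0)

    # -- sub-step 1: encoder + decoder ------------------------------------
    H_R = model.encode(masked, training=True)
    X_hat = model.decode(H_R, training=True)
    diff = (X_hat - Tensor(real_raw)) * mask_t
    L_MSE = (diff ** 2).sum() * (1.0 / n_masked)
    H_S = model.encode(pseudo_X, training=True)
    L_C = classifier_loss(model.classify(H_R.first_half), model.classify(H_S.first_half))
    L_D = discriminator_loss(
        model.discriminate(H_R.second_half), model.discriminate(H_S.second_half)
    )
    L1 = lam * L_MSE + (1.0 - lam) * (L_C + L_D)
    _zero_all(model)
    L1.backward()
    opts.stage1.step()
    rec = {
        "L_stage1": _check_finite(float(L1.data), "1 (encoder/decoder)"),
        "L_MSE": float(L_MSE.data),
        "L_C": float(L_C.data),
        "L_D": float(L_D.data),
    }

    # -- sub-step 2: classifier + discriminator ---------------------------
    # fresh forward pass with the encoder frozen (inference mode, detached)
    H_R2 = LatentRep(model.encode(masked, training=False).H.detach(), model.config.d_classifier)
    H_S2 = LatentRep(model.encode(pseudo_X, training=False).H.detach(), model.config.d_classifier)
    L_C2 = classifier_loss(model.classify(H_R2.first_half), model.classify(H_S2.first_half))
    L_D2 = discriminator_loss(
        model.discriminate(H_R2.second_half), model.discriminate(H_S2.second_half)
    )
    L2 = lam * L_C2 + (1.0 - lam) * L_D2
    _zero_all(model)
    L2.backward()
    opts.stage2.step()
    rec["L_stage2"] = _check_finite(float(L2.data), "2 (classifier/discriminator)")

    # -- sub-step 3: encoder + predictor ----------------------------------
    H_S3 = model.encode(pseudo_X, training=True)
    Y = model.predict_proportions(H_S3, training=True)
    L_P = predictor_loss(Y, Tensor(pseudo_Y))
    _zero_all(model)
    L_P.backward()
    opts.stage3.step()
    rec["L_P"] = _check_finite(float(L_P.data), "3 (encoder/predictor)")
    return rec


def train(
    st: ExpressionMatrix,
    pseudo: PseudoSpotBatch,
    config: TrainingConfig,
) -> tuple[SpaDAMAModel, TrainingTrace]:
    """Train on a normalized real-ST matrix and a labelled pseudo-spot batch.

    Epochs iterate shuffled pseudo-spot mini-batches; each is paired with a
    real-ST batch (the full matrix when it fits in ``batch_size``, else a
    random subset) carrying a freshly sampled mask.  Fully reproducible
    from ``config.seed``.
    """
    if st.n_obs == 0 or pseudo.n_spots == 0:
        raise ValueError("empty training inputs")
    if list(st.gene_ids) != list(pseudo.X_S.gene_ids):
        raise ValueError("real ST and pseudo-ST gene panels differ")
    model_cfg = config.model or ModelConfig(latent_split=config.latent_split, seed=config.seed)
    model_cfg.n_genes = st.n_genes
    model_cfg.n_types = len(pseudo.type_names)
    model = SpaDAMAModel(model_cfg, list(st.gene_ids), list(pseudo.type_names))
    opts = Optimizers.for_model(model, config)
    rng = np.random.default_rng(config.seed)
    trace = TrainingTrace()
    n_pseudo, n_real = pseudo.n_spots, st.n_obs
    bs = min(config.batch_size, n_pseudo)
    for epoch in range(config.epochs):
        order = rng.permutation(n_pseudo)
        for it, start in enumerate(range(0, n_pseudo, bs)):
            idx = order[start:start + bs]
            if idx.size < 2:  # batch norm needs more than one observation
                continue
            if n_real <= config.batch_size:
                real = st.values
            else:
                real = st.values[rng.choice(n_real, size=config.batch_size, replace=False)]
            rec = training_iteration(
                real, pseudo.X_S.values[idx], pseudo.Y_r[idx], model, config, opts, rng
            )
            trace.append(epoch=epoch, iteration=it, **rec)
    return model, trace


def infer(st: ExpressionMatrix, model: SpaDAMAModel) -> ProportionMatrix:
    """Predict per-spot cell-type proportions for normalized real ST data.

    No masking is applied; batch normalization uses frozen running
    statistics, so repeated calls are identical.
    """
    if list(st.gene_ids) != list(model.gene_ids):
        missing = sorted(set(model.gene_ids) - set(st.gene_ids))
        raise ValueError(
            "gene panel mismatch between query data and model"
            + (f"; missing genes: {missing[:20]}" if missing else " (order differs)")
        )
    H = model.encode(st.values, training=False)
    Y = model.predict_proportions(H, training=False)
    return ProportionMatrix(Y.data, list(model.type_names), list(st.obs_ids))
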