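"""Model components: encoder, decoder, classifier, discriminator, predictor.

The encoder maps (masked) expression profiles into a shared latent space.
Its output is split column-wise: the first block feeds a domain classifier
trained to tell real from pseudo spots, the second a discriminator trained
with deliberately flipped labels; together they pull the two domains'
latent distributions toward each other.  A decoder reconstructs masked
entries, and a softmax-headed predictor maps the full latent vector to
cell-type proportions.

All components are plain multilayer perceptrons with LeakyReLU activations
and batch normalization on the first layer of the encoder and predictor,
built on the package's autograd tensors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Adam, Tensor, parameter, softmax_rows


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``latent_split`` is the fraction of latent columns given to the
    classifier branch; 0.5 (an equal split) is the default, with 0.25 and
    0.75 as the supported alternatives.  ``latent_dim`` must make the split
    exact.
    """

    n_genes: int = 0
    n_types: int = 0
    latent_dim: int = 128
    enc_hidden: int = 512
    dec_hidden: tuple[int, int] = (256, 512)
    clf_hidden: int = 64
    pred_hidden: int = 64
    leaky_slope: float = 0.01
    latent_split: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.latent_split not in (0.25, 0.5, 0.75):
            raise ValueError("latent_split must be one of 0.25, 0.5, 0.75")
        d1 = self.latent_dim * self.latent_split
        if self.latent_dim < 2 or d1 != int(d1) or not 0 < int(d1) < self.latent_dim:
            raise ValueError(
                f"latent_dim {self.latent_dim} incompatible with split {self.latent_split}"
            )

    @property
    def d_classifier(self) -> int:
        return int(self.latent_dim * self.latent_split)


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = parameter(rng, (n_in, n_out), fan_in=n_in)
        self.b = parameter(rng, (n_out,), fan_in=n_in)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class BatchNorm:
    """Feature-wise batch normalization with learnable scale and shift.

    Training mode normalizes by batch statistics and updates exponential
    running averages; inference mode uses the frozen running statistics, so
    inference is deterministic and batch-size independent.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            n = x.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta

    @property
    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    @property
    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


@dataclass
class LatentRep:
    """Latent matrix plus its column split into classifier/discriminator halves."""

    H: Tensor
    d_classifier: int

    @property
    def first_half(self) -> Tensor:
        return self.H.slice_cols(0, self.d_classifier)

    @property
    def second_half(self) -> Tensor:
        return self.H.slice_cols(self.d_classifier, self.H.shape[1])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class SpaDAMAModel:
    """Parameter container for all five components."""

    def __init__(self, config: ModelConfig, gene_ids: list[str], type_names: list[str]):
        if config.n_genes == 0:
            config.n_genes = len(gene_ids)
        if config.n_types == 0:
            config.n_types = len(type_names)
        if config.n_genes != len(gene_ids) or config.n_types != len(type_names):
            raise ValueError("config dimensions disagree with gene panel / type names")
        self.config = config
        self.gene_ids = list(gene_ids)
        self.type_names = list(type_names)
        rng = np.random.default_rng(config.seed)
        g, d, k = config.n_genes, config.latent_dim, config.n_types
        self.enc0 = Linear(rng, g, config.enc_hidden)
        self.enc_bn = BatchNorm(config.enc_hidden)
        self.enc1 = Linear(rng, config.enc_hidden, d)
        h0, h1 = config.dec_hidden
        self.dec0 = Linear(rng, d, h0)
        self.dec_bn0 = BatchNorm(h0)
        self.dec1 = Linear(rng, h0, h1)
        self.dec_bn1 = BatchNorm(h1)
        self.dec2 = Linear(rng, h1, g)
        d1 = config.d_classifier
        self.clf0 = Linear(rng, d1, config.clf_hidden)
        self.clf1 = Linear(rng, config.clf_hidden, 1)
        self.dis0 = Linear(rng, d - d1, config.clf_hidden)
        self.dis1 = Linear(rng, config.clf_hidden, 1)
        self.pred0 = Linear(rng, d, config.pred_hidden)
        self.pred_bn = BatchNorm(config.pred_hidden)
        self.pred1 = Linear(rng, config.pred_hidden, k)

    # -- parameter groups --------------------------------------------------

    @property
    def params_encoder(self) -> list[Tensor]:
        return self.enc0.params + self.enc_bn.params + self.enc1.params

    @property
    def params_decoder(self) -> list[Tensor]:
        return (
            self.dec0.params + self.dec_bn0.params + self.dec1.params
            + self.dec_bn1.params + self.dec2.params
        )

    @property
    def params_classifier(self) -> list[Tensor]:
        return self.clf0.params + self.clf1.params

    @property
    def params_discriminator(self) -> list[Tensor]:
        return self.dis0.params + self.dis1.params

    @property
    def params_predictor(self) -> list[Tensor]:
        return self.pred0.params + self.pred_bn.params + self.pred1.params

    def all_params(self) -> list[Tensor]:
        return (
            self.params_encoder + self.params_decoder + self.params_classifier
            + self.params_discriminator + self.params_predictor
        )

    def all_buffers(self) -> list[np.ndarray]:
        return [
            self.enc_bn.running_mean, self.enc_bn.running_var,
            self.dec_bn0.running_mean, self.dec_bn0.running_var,
            self.dec_bn1.running_mean, self.dec_bn1.running_var,
            self.pred_bn.running_mean, self.pred_bn.running_var,
        ]

    # -- forward passes ----------------------------------------------------

    def encode(self, X, training: bool = False) -> LatentRep:
        x = _as_tensor(X)
        if x.shape[1] != self.config.n_genes:
            raise ValueError(
                f"input has {x.shape[1]} genes, model expects {self.config.n_genes}"
            )
        h = self.enc_bn(self.enc0(x), training).leaky_relu(self.config.leaky_slope)
        return LatentRep(self.enc1(h), self.config.d_classifier)

    def decode(self, H, training: bool = False) -> Tensor:
        h = H.H if isinstance(H, LatentRep) else _as_tensor(H)
        if h.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent width {h.shape[1]} does not match latent_dim "
                f"{self.config.latent_dim}"
            )
        s = self.config.leaky_slope
        h = self.dec_bn0(self.dec0(h), training).leaky_relu(s)
        h = self.dec_bn1(self.dec1(h), training).leaky_relu(s)
        return self.dec2(h)

    def classify(self, H1) -> Tensor:
        h = _as_tensor(H1)
        if h.shape[1] != self.config.d_classifier:
            raise ValueError("classifier input width mismatch")
        return self.clf1(self.clf0(h).leaky_relu(self.config.leaky_slope)).sigmoid()

    def discriminate(self, H2) -> Tensor:
        h = _as_tensor(H2)
        if h.shape[1] != self.config.latent_dim - self.config.d_classifier:
            raise ValueError("discriminator input width mismatch")
        return self.dis1(self.dis0(h).leaky_relu(self.config.leaky_slope)).sigmoid()

    def predict_proportions(self, H, training: bool = False) -> Tensor:
        h = H.H if isinstance(H, LatentRep) else _as_tensor(H)
        if h.shape[1] != self.config.latent_dim:
            raise ValueError("predictor input width mismatch")
        z = self.pred_bn(self.pred0(h), training).leaky_relu(self.config.leaky_slope)
        return softmax_rows(self.pred1(z))

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: all tensors plus gene panel and config."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.all_params())}
        arrays.update({f"b{i}": b for i, b in enumerate(self.all_buffers())})
        meta = {
            "gene_ids": self.gene_ids,
            "type_names": self.type_names,
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "n_genes", "n_types", "latent_dim", "enc_hidden", "clf_hidden",
                    "pred_hidden", "leaky_slope", "latent_split", "seed")},
                "dec_hidden": list(self.config.dec_hidden),
            },
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:  # keep the caller's extension (np.savez appends .npz)
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SpaDAMAModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta"]))
            cfg = meta["config"]
            cfg["dec_hidden"] = tuple(cfg["dec_hidden"])
            model = cls(ModelConfig(**cfg), meta["gene_ids"], meta["type_names"])
            for i, p in enumerate(model.all_params()):
                p.data[...] = npz[f"p{i}"]
            for i, b in enumerate(model.all_buffers()):
                b[...] = npz[f"b{i}"]
        return model


# ---------------------------------------------------------------------------
# losses

_EPS = 1e-7


def bce(y, y_hat):
    """Mean binary cross entropy; predictions are clipped to [eps, 1-eps].

    Accepts autograd tensors (returns a tensor in the graph) or plain
    arrays (returns a float).
    """
    tensor_out = isinstance(y_hat, Tensor)
    y_t, p = _as_tensor(y), _as_tensor(y_hat)
    if y_t.data.size != p.data.size:
        raise ValueError("bce: target and prediction lengths differ")
    p = p.clip(_EPS, 1.0 - _EPS)
    loss = -(y_t * p.log() + (1.0 - y_t) * (1.0 - p).log()).mean()
    return loss if tensor_out else float(loss.data)


def classifier_loss(O_CR, O_CS):
    """BCE against the correct domain labels: real spots 1, pseudo spots 0."""
    out_r, out_s = _as_tensor(O_CR), _as_tensor(O_CS)
    loss = bce(np.ones(out_r.data.size), out_r) + bce(np.zeros(out_s.data.size), out_s)
    if isinstance(O_CR, Tensor) or isinstance(O_CS, Tensor):
        return loss
    return float(loss.data)


def discriminator_loss(O_DR, O_DS):
    """BCE with deliberately flipped labels: real spots 0, pseudo spots 1."""
    out_r, out_s = _as_tensor(O_DR), _as_tensor(O_DS)
    loss = bce(np.zeros(out_r.data.size), out_r) + bce(np.ones(out_s.data.size), out_s)
    if isinstance(O_DR, Tensor) or isinstance(O_DS, Tensor):
        return loss
    return float(loss.data)


def predictor_loss(Y, Y_r):
    """Mean over spots of the squared Euclidean distance between proportion rows."""
    y, yr = _as_tensor(Y), _as_tensor(Y_r)
    if y.shape != yr.shape:
        raise ValueError("predictor_loss: shape mismatch")
    loss = ((y - yr) ** 2).sum(axis=1).mean()
    return loss if isinstance(Y, Tensor) else float(loss.data)
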