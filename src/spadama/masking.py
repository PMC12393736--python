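"""Random masking of the spatial expression matrix.

Masking hides a fraction rho of matrix entries; the autoencoder is trained
to reconstruct the hidden values, which forces the encoder to learn
features robust to dropout-like corruption.  Convention: mask value 1 means
the entry is masked (zeroed on input, scored on reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix


@dataclass
class Mask:
    M: np.ndarray  # binary, 1 = masked
    rho: float

    def __post_init__(self):
        self.M = np.asarray(self.M)
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")


def generate_mask(
    n_spots: int, n_genes: int, rho: float, rng: np.random.Generator
) -> Mask:
    """Independent per-entry Bernoulli(rho) mask."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"masking rate must be in [0, 1], got {rho}")
    M = (rng.random((n_spots, n_genes)) < rho).astype(np.float64)
    return Mask(M=M, rho=rho)


def apply_mask(X: ExpressionMatrix, mask: Mask) -> ExpressionMatrix:
    """Zero the masked entries, leaving the rest unchanged."""
    if X.values.shape != mask.M.shape:
        raise ValueError(
            f"shape mismatch: matrix {X.values.shape} vs mask {mask.M.shape}"
        )
    return ExpressionMatrix(
        X.values * (1.0 - mask.M), X.obs_ids, X.gene_ids, X.obs_kind
    )


def masked_mse(X_hat: np.ndarray, X: np.ndarray | ExpressionMatrix, mask: Mask) -> float:
    """Mean squared reconstruction error over the masked entries only.

    The squared norm of (X_hat - X) restricted to masked positions is
    divided by the masked-entry count, so the loss scale does not drift
    with rho; zero when nothing is masked.
    """
    x = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X)
    x_hat = np.asarray(X_hat)
    if not (x.shape == x_hat.shape == mask.M.shape):
        raise ValueError("X_hat, X and mask shapes must all match")
    if not (np.isfinite(x).all() and np.isfinite(x_hat).all()):
        raise ValueError("masked_mse requires finite inputs")
    n_masked = mask.M.sum()
    if n_masked == 0:
        return 0.0
    return float((((x_hat - x) * mask.M) ** 2).sum() / n_masked)
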