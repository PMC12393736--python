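"""Fully synthetic references and ground-truth spatial datasets.

The generator plants a disjoint marker block per cell type on top of
log-normal per-gene baseline rates and draws counts from a negative
binomial, the standard overdispersed noise model for scRNA-seq.  A
ground-truth spatial dataset is then assembled exactly the way pseudo-spots
are built — summing sampled cell profiles per a known composition — but
from a held-out half of the reference cells, so the cells a model trains on
never appear in the spots it is evaluated on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data_io import CellTypeLabels, ExpressionMatrix
from .metrics import ProportionMatrix


@dataclass
class FixtureSpec:
    """Synthetic-dataset parameters.

    ``signal`` is the fold-elevation of a type's marker genes over
    baseline (1 = no signal); ``noise`` is the negative-binomial
    dispersion (variance = mu + noise * mu^2; 0 = Poisson); ``alpha`` is
    the symmetric Dirichlet concentration for spot compositions (small
    values give near one-hot spots).
    """

    K: int = 5
    G: int = 200
    markers_per_type: int = 20
    cells_per_type: int = 200
    n_spots: int = 500
    signal: float = 8.0
    noise: float = 0.25
    alpha: float = 1.0
    spatial_pattern: Literal["random", "blocks"] = "random"
    seed: int = 0
    mu_t: float = 10.0
    sigma_t: float = 5.0
    t_bounds: tuple[int, int] = (2, 30)

    def __post_init__(self):
        if self.K * self.markers_per_type > self.G:
            raise ValueError("marker blocks exceed the gene count")
        for name in ("K", "G", "markers_per_type", "cells_per_type", "n_spots"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.K < 2:
            raise ValueError("need at least two cell types")

    @property
    def type_names(self) -> list[str]:
        return [f"type_{k}" for k in range(self.K)]

    def marker_block(self, k: int) -> np.ndarray:
        return np.arange(k * self.markers_per_type, (k + 1) * self.markers_per_type)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mean).astype(np.float64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.float64)


def make_reference(spec: FixtureSpec) -> tuple[ExpressionMatrix, CellTypeLabels]:
    """Simulate a labelled scRNA-seq reference with planted marker blocks."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    base = rng.lognormal(mean=0.0, sigma=0.5, size=spec.G)
    n_cells = spec.K * spec.cells_per_type
    means = np.tile(base, (n_cells, 1))
    labels = []
    for k in range(spec.K):
        rows = slice(k * spec.cells_per_type, (k + 1) * spec.cells_per_type)
        means[rows, spec.marker_block(k)] *= spec.signal
        labels.extend([f"type_{k}"] * spec.cells_per_type)
    counts = _nb_counts(rng, means, spec.noise)
    obs_ids = [f"cell_{i}" for i in range(n_cells)]
    gene_ids = [f"gene_{j}" for j in range(spec.G)]
    ref = ExpressionMatrix(counts, obs_ids, gene_ids, "cells")
    return ref, CellTypeLabels(labels, spec.type_names)


def holdout_split(spec: FixtureSpec, labels: CellTypeLabels) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-type half split: (training indices, held-out indices)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    idx = labels.indices()
    train, hold = [], []
    for k in range(labels.n_types):
        cells = np.flatnonzero(idx == k)
        perm = rng.permutation(cells)
        half = perm.size // 2
        train.append(perm[:half])
        hold.append(perm[half:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(hold))


def region_labels(spec: FixtureSpec) -> np.ndarray:
    """Region index per spot for the blocks pattern (contiguous quarters)."""
    n_regions = min(4, spec.K)
    return np.arange(spec.n_spots) * n_regions // spec.n_spots


def make_ground_truth_st(
    spec: FixtureSpec,
    ref: ExpressionMatrix,
    labels: CellTypeLabels,
) -> tuple[ExpressionMatrix, ProportionMatrix]:
    """Build raw-count spots with known proportions from held-out cells.

    Spot composition: Dirichlet(alpha) proportions (region-tilted for the
    blocks pattern), a clamped-normal cell count t, and a multinomial draw
    of per-type cell counts; the realized counts/t vector is the exact
    ground truth.  Cells are sampled with replacement from the held-out
    half of each type.
    """
    _, hold = holdout_split(spec, labels)
    type_idx = labels.indices()
    hold_by_type = [hold[type_idx[hold] == k] for k in range(spec.K)]
    for k, cells in enumerate(hold_by_type):
        if cells.size == 0:
            raise ValueError(f"no held-out cells for type_{k}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,)))
    regions = region_labels(spec) if spec.spatial_pattern == "blocks" else None
    raw = np.zeros((spec.n_spots, spec.G))
    Y = np.zeros((spec.n_spots, spec.K))
    t_min, t_max = spec.t_bounds
    for s in range(spec.n_spots):
        alpha_vec = np.full(spec.K, spec.alpha)
        if regions is not None:
            # tilt each region toward its own subset of types
            alpha_vec[np.arange(spec.K) % (regions.max() + 1) == regions[s]] *= 8.0
        p = rng.dirichlet(alpha_vec)
        t = int(np.clip(round(rng.normal(spec.mu_t, spec.sigma_t)), t_min, t_max))
        counts = rng.multinomial(t, p)
        Y[s] = counts / t
        for k in np.flatnonzero(counts):
            picks = rng.choice(hold_by_type[k], size=counts[k], replace=True)
            raw[s] += ref.values[picks].sum(axis=0)
    spot_ids = [f"spot_{s}" for s in range(spec.n_spots)]
    st = ExpressionMatrix(raw, spot_ids, list(ref.gene_ids), "spots")
    truth = ProportionMatrix(Y, spec.type_names, spot_ids)
    return st, truth
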