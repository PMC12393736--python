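"""Pseudo-spot simulation from a labelled scRNA-seq reference.

A pseudo-spot mimics a multi-cell capture location: draw a cell count t and
a type count c from clamped normal distributions, pick c types uniformly,
partition t cells among them uniformly at random, sample that many cells
(with replacement within each type) and sum their raw count profiles.  The
realized cell-type fractions are the spot's supervision label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import CellTypeLabels, ExpressionMatrix, normalize


@dataclass
class PseudoSpotParams:
    """Composition model for simulated spots.

    ``mu_t``/``sigma_t`` parameterize the normal for cells per spot,
    ``mu_c``/``sigma_c`` the normal for distinct cell types per spot;
    draws are rounded and clamped to ``t_bounds`` and [1, min(K, t)].
    Defaults describe Visium-like occupancy (a handful to a few tens of
    cells per 55-micron spot).
    """

    n_spots: int = 10000
    mu_t: float = 10.0
    sigma_t: float = 5.0
    mu_c: float = 4.0
    sigma_c: float = 2.0
    t_bounds: tuple[int, int] = (2, 30)
    seed: int = 0
    target_sum: float = 1e4

    def __post_init__(self):
        t_min, t_max = self.t_bounds
        if t_min < 1 or t_max < t_min:
            raise ValueError("t_bounds must satisfy 1 <= t_min <= t_max")
        if not (t_min <= self.mu_t <= t_max):
            raise ValueError("mu_t must lie within t_bounds")
        if self.sigma_t < 0 or self.sigma_c < 0:
            raise ValueError("sigma_t and sigma_c must be nonnegative")
        if self.n_spots < 1:
            raise ValueError("n_spots must be positive")


@dataclass
class PseudoSpotBatch:
    """Simulated spots with exact ground-truth proportion labels."""

    X_S: ExpressionMatrix
    Y_r: np.ndarray  # (n_spots, K), rows on the simplex
    composition: list[dict[int, int]]  # per spot: type index -> cell count
    type_names: list[str]
    X_raw: np.ndarray | None = None  # pre-normalization summed counts

    @property
    def n_spots(self) -> int:
        return self.X_S.n_obs


def _spot_rng(seed: int, spot: int) -> np.random.Generator:
    # counter-derived substream: spot i's draws never depend on n_spots
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(spot,)))


def sample_composition(
    params: PseudoSpotParams, K: int, rng: np.random.Generator
) -> dict[int, int]:
    """Draw one spot's type -> cell-count map.

    t ~ round N(mu_t, sigma_t) clamped to t_bounds; c ~ round N(mu_c,
    sigma_c) clamped to [1, min(K, t)]; c distinct types chosen uniformly;
    t split into c positive parts by c-1 distinct cuts among the t-1 gaps
    (every ordered composition equally likely).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    t_min, t_max = params.t_bounds
    t = int(np.clip(round(rng.normal(params.mu_t, params.sigma_t)), t_min, t_max))
    c = int(np.clip(round(rng.normal(params.mu_c, params.sigma_c)), 1, min(K, t)))
    types = rng.choice(K, size=c, replace=False)
    if c == 1:
        parts = np.array([t])
    else:
        cuts = np.sort(rng.choice(t - 1, size=c - 1, replace=False)) + 1
        parts = np.diff(np.concatenate(([0], cuts, [t])))
    return {int(k): int(n) for k, n in zip(types, parts)}


def generate_pseudo_spots(
    ref: ExpressionMatrix,
    labels: CellTypeLabels,
    params: PseudoSpotParams,
) -> PseudoSpotBatch:
    """Simulate ``params.n_spots`` labelled pseudo-spots from the reference.

    Spot raw expression is the sum of the sampled cells' raw-count rows;
    the batch is then library-size normalized with the same target as the
    real ST data.  Fully reproducible from ``params.seed``.
    """
    type_idx = labels.indices()
    cells_by_type: list[np.ndarray] = []
    for k, name in enumerate(labels.type_names):
        idx = np.flatnonzero(type_idx == k)
        if idx.size == 0:
            raise ValueError(f"cell type {name!r} has no cells in the reference")
        cells_by_type.append(idx)
    K = labels.n_types
    n = params.n_spots
    raw = np.zeros((n, ref.n_genes))
    Y = np.zeros((n, K))
    composition: list[dict[int, int]] = []
    for s in range(n):
        rng = _spot_rng(params.seed, s)
        comp = sample_composition(params, K, rng)
        t = sum(comp.values())
        for k, cnt in comp.items():
            picks = rng.choice(cells_by_type[k], size=cnt, replace=True)
            raw[s] += ref.values[picks].sum(axis=0)
            Y[s, k] = cnt / t
        composition.append(comp)
    obs_ids = [f"pseudo_{s}" for s in range(n)]
    x_raw = ExpressionMatrix(raw, obs_ids, list(ref.gene_ids), "spots")
    x_norm = normalize(x_raw, target_sum=params.target_sum)
    return PseudoSpotBatch(
        X_S=x_norm, Y_r=Y, composition=composition,
        type_names=list(labels.type_names), X_raw=raw,
    )
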