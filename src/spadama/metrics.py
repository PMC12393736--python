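"""Deconvolution evaluation metrics.

Per cell type, the truth and prediction are compared across spots with
Pearson correlation (PCC), a global structural-similarity index (SSIM),
root-mean-square error (RMSE) and base-2 Jensen-Shannon divergence (JS).
An Accuracy Score (AS) composites the four across competing methods by
normalized ranks, and region AUC scores how well summed proportions of a
region's constituent types separate spots inside the region from those
outside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import roc_auc_score


@dataclass
class ProportionMatrix:
    """Spots x cell-types proportion matrix; every row lies on the simplex."""

    values: np.ndarray
    type_names: list[str]
    spot_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.spot_ids), len(self.type_names)
        ):
            raise ValueError("proportion matrix shape does not match identifiers")
        if (self.values < -1e-9).any():
            raise ValueError("proportions must be nonnegative")
        rowsum = self.values.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            raise ValueError(
                f"row {self.spot_ids[bad]!r} sums to {rowsum[bad]}, expected 1"
            )

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.type_names.index(name)]


def pcc(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Pearson correlation between truth and prediction; NaN if constant."""
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape or x.size < 2:
        raise ValueError("pcc requires two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(x_hat) == 0:
        warnings.warn("pcc undefined for a constant vector; returning NaN")
        return float("nan")
    return float(stats.pearsonr(x, x_hat)[0])


_C1, _C2 = 0.01, 0.03


def ssim(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Global structural similarity with stabilizers C1=0.01, C2=0.03.

    Each vector is min-max scaled to [0, 1] first, so the score compares
    shape rather than absolute level; a constant vector (unscalable) gives
    NaN.
    """
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape or x.size == 0:
        raise ValueError("ssim requires two equal-length nonempty vectors")
    if np.ptp(x) == 0 or np.ptp(x_hat) == 0:
        warnings.warn("ssim undefined for a constant vector; returning NaN")
        return float("nan")
    x = (x - x.min()) / np.ptp(x)
    y = (x_hat - x_hat.min()) / np.ptp(x_hat)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(
        (2 * mx * my + _C1) * (2 * cov + _C2)
        / ((mx**2 + my**2 + _C1) * (vx + vy + _C2))
    )


def rmse(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Root mean squared error across spots."""
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape or x.size == 0:
        raise ValueError("rmse requires two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((x - x_hat) ** 2)))


def js(p: np.ndarray, p_hat: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence between two spatial distributions.

    Inputs are nonnegative weights over spots, normalized to sum 1 before
    evaluation; the base-2 logarithm bounds the result in [0, 1].
    """
    p, q = np.asarray(p, float), np.asarray(p_hat, float)
    if p.shape != q.shape:
        raise ValueError("js requires equal-length vectors")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("js requires nonnegative vectors")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("js undefined for an all-zero vector")
    return float(jensenshannon(p, q, base=2) ** 2)


def accuracy_score(method_metrics: dict[str, dict[str, float]]) -> dict[str, float]:
    """Rank-composite Accuracy Score across competing methods.

    Per metric, methods are ranked so the best performer receives the top
    rank N (largest mean PCC/SSIM; smallest mean RMSE/JS); tied methods
    share the mean of their ranks.  Ranks are divided by N and the four
    normalized ranks averaged, so AS lies in (0, 1] with 1 for a method
    strictly best on all four metrics.
    """
    methods = list(method_metrics)
    if len(methods) < 2:
        raise ValueError("accuracy_score needs at least two methods")
    for m in methods:
        for key in ("pcc", "ssim", "rmse", "js"):
            if key not in method_metrics[m] or not np.isfinite(method_metrics[m][key]):
                raise ValueError(f"method {m!r} is missing metric {key!r}")
    n = len(methods)
    ranks = np.zeros(n)
    for key, higher_better in (("pcc", True), ("ssim", True), ("rmse", False), ("js", False)):
        vals = np.array([method_metrics[m][key] for m in methods])
        r = stats.rankdata(vals if higher_better else -vals)  # best gets rank N
        ranks += r / n
    return {m: float(ranks[i] / 4.0) for i, m in enumerate(methods)}


def region_auc(scores: np.ndarray, region_labels: np.ndarray) -> float:
    """AUC for separating in-region from out-of-region spots.

    ``scores`` are typically the summed predicted proportions of the
    region's constituent cell types; ties contribute one half, per the
    Mann-Whitney rank formulation.
    """
    y = np.asarray(region_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("region_auc requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, float)))


def celltype_correlation(Y: ProportionMatrix) -> np.ndarray:
    """K x K Pearson correlation between inferred per-type abundances.

    Constant columns yield NaN rows/columns (flagged, not fatal); the
    diagonal is 1 for every nonconstant type.
    """
    A = Y.values
    if A.shape[0] < 2:
        raise ValueError("celltype_correlation requires at least two spots")
    constant = np.ptp(A, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant abundance for types {[Y.type_names[i] for i in np.flatnonzero(constant)]}; "
            "correlations flagged as NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(A, rowvar=False)
    R[constant, :] = np.nan
    R[:, constant] = np.nan
    return R


@dataclass
class MetricsReport:
    """Per-type and aggregate metrics for one prediction against truth."""

    per_type: dict[str, dict[str, float]]
    means: dict[str, float]
    accuracy_scores: dict[str, float] | None = None
    region_aucs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"per_type": self.per_type, "means": self.means}
        if self.accuracy_scores is not None:
            out["accuracy_scores"] = self.accuracy_scores
        if self.region_aucs:
            out["region_aucs"] = self.region_aucs
        return out


def evaluate(truth: ProportionMatrix, pred: ProportionMatrix) -> MetricsReport:
    """Compute PCC/SSIM/RMSE/JS per cell type and their unweighted means.

    Types whose truth or prediction is constant across spots produce NaN
    PCC/SSIM entries, which are excluded from the means.
    """
    if truth.type_names != pred.type_names:
        raise ValueError("truth and prediction cell types differ")
    if truth.values.shape != pred.values.shape:
        raise ValueError("truth and prediction shapes differ")
    per_type: dict[str, dict[str, float]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, name in enumerate(truth.type_names):
            x, y = truth.values[:, k], pred.values[:, k]
            entry = {"rmse": rmse(x, y)}
            entry["pcc"] = pcc(x, y) if x.size >= 2 else float("nan")
            entry["ssim"] = ssim(x, y)
            entry["js"] = js(x, y) if x.sum() > 0 and y.sum() > 0 else float("nan")
            per_type[name] = entry
    means = {
        key: float(np.nanmean([per_type[t][key] for t in per_type]))
        for key in ("pcc", "ssim", "rmse", "js")
    }
    return MetricsReport(per_type=per_type, means=means)
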