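"""Alpha diversity, median-of-ratios normalization, variance-stabilizing
transform, PCA, and PC-trait correlations.

The normalization follows the median-of-ratios construction: per-feature
geometric means over samples, per-sample size factor = median count/geomean
ratio over features, rescaled to geometric mean 1. The VST is the closed-form
antiderivative of ``1/sqrt(v(q))`` for the NB variance trend
``v(q) = (1 + a1) q + a0 q^2`` (asymptotic dispersion ``a0``, Poisson-like
extra term ``a1``), scaled to match ``log2`` at large counts:

    vst(q) = log2( (b + 2 a0 q + 2 sqrt(a0 q (b + a0 q))) / (4 a0) ),
    b = 1 + a1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .core import CountTable


@dataclass
class NormalizedTable:
    """Size-factor-normalized, variance-stabilized feature x sample matrix."""

    values: pd.DataFrame
    size_factors: pd.Series
    rank: str = "ASV"

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        geo = float(np.exp(np.mean(np.log(self.size_factors))))
        if abs(geo - 1.0) > 1e-6:
            raise ValueError("size factors must have geometric mean 1")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def alpha_diversity(rel: np.ndarray) -> tuple[float, float, float]:
    """Shannon (-sum p ln p), Simpson (1 - sum p^2) and inverse Simpson
    (1 / sum p^2) diversity of one relative-abundance profile."""
    p = np.asarray(rel, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("input must be a probability vector summing to 1")
    nz = p[p > 0]
    shannon = float(-np.sum(nz * np.log(nz)))
    ssq = float(np.sum(p**2))
    return shannon, 1.0 - ssq, 1.0 / ssq


def alpha_diversity_table(counts: CountTable) -> pd.DataFrame:
    """Per-sample alpha diversity metrics from raw counts."""
    totals = counts.counts.sum(axis=0)
    rows = {}
    for s in counts.samples:
        rel = counts.counts[s].to_numpy() / totals[s]
        sh, si, inv = alpha_diversity(rel)
        rows[s] = {"shannon": sh, "simpson": si, "inv_simpson": inv}
    return pd.DataFrame(rows).T.rename_axis("sample_id")


def size_factors(counts: CountTable, fallback: bool = True) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The classic estimator uses only features positive in every sample; for
    sparse tables (``fallback=True``, the default) features' geometric means
    are taken over their nonzero entries instead, and each sample's median
    ratio runs over the features it actually observed.
    """
    mat = counts.counts.to_numpy(dtype=float)
    positive_rows = np.all(mat > 0, axis=1)
    if positive_rows.any():
        loggeo = np.mean(np.log(mat[positive_rows]), axis=1)
        ratios = np.log(mat[positive_rows]) - loggeo[:, None]
        logsf = np.median(ratios, axis=0)
    elif fallback:
        with np.errstate(divide="ignore"):
            logmat = np.where(mat > 0, np.log(mat), np.nan)
        loggeo = np.nanmean(logmat, axis=1)
        usable = np.isfinite(loggeo)
        if not usable.any():
            raise ValueError("no usable features for size factor estimation")
        ratios = logmat[usable] - loggeo[usable, None]
        logsf = np.nanmedian(ratios, axis=0)
        if np.any(~np.isfinite(logsf)):
            raise ValueError("a sample shares no features with the rest")
    else:
        raise ValueError(
            "no feature is positive in all samples; enable the "
            "positive-counts fallback (fallback=True)"
        )
    logsf = logsf - logsf.mean()  # geometric mean 1
    return pd.Series(np.exp(logsf), index=counts.samples, name="size_factor")


def vst(
    counts: CountTable,
    sf: pd.Series,
    dispersion_trend: tuple[float, float],
) -> NormalizedTable:
    """Variance-stabilizing transform of size-factor-normalized counts.

    ``dispersion_trend`` is ``(a0, a1)`` from the fitted mean-dispersion
    trend ``alpha(mu) = a0 + a1 / mu``; the implied NB variance of a
    normalized count ``q`` is ``(1 + a1) q + a0 q^2``.
    """
    a0, a1 = dispersion_trend
    if a0 <= 0:
        raise ValueError("asymptotic dispersion a0 must be > 0")
    if a1 < 0:
        raise ValueError("a1 must be >= 0")
    q = counts.counts.to_numpy(dtype=float) / sf.reindex(counts.samples).to_numpy()
    values = pd.DataFrame(
        vst_transform(q, a0, a1), index=counts.counts.index,
        columns=counts.counts.columns,
    )
    return NormalizedTable(values, sf.reindex(counts.samples), rank=counts.rank)


def vst_transform(q, a0: float, a1: float) -> np.ndarray:
    """The closed-form VST of normalized counts ``q`` (vectorized)."""
    q = np.asarray(q, dtype=float)
    b = 1.0 + a1
    inner = b + 2.0 * a0 * q + 2.0 * np.sqrt(a0 * q * (b + a0 * q))
    return np.log2(inner / (4.0 * a0))


def pca(values: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples with features as variables (no unit-variance scaling).

    Returns per-sample scores and explained-variance fractions. The sign of
    each component is fixed so its largest-magnitude feature loading is
    positive. A constant matrix yields zero scores and zero explained
    fractions.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    n_components = min(n_components, values.shape[1], values.shape[0])
    x = values.to_numpy(dtype=float).T  # samples x features
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0):
        scores = np.zeros((x.shape[0], n_components))
        return (
            pd.DataFrame(scores, index=values.columns,
                         columns=[f"PC{i + 1}" for i in range(n_components)]),
            np.zeros(n_components),
        )
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(centered)
    loadings = model.components_
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return (
        pd.DataFrame(scores, index=values.columns,
                     columns=[f"PC{i + 1}" for i in range(n_components)]),
        model.explained_variance_ratio_,
    )


def trait_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
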