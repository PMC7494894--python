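"""Negative-binomial Wald differential-abundance testing and ternary
encoding of longitudinal results.

Two pairwise testing frameworks cover the study design:

* **cross-treatment** — each treatment pair at each sampling day
  (3 pairs x 5 days = 15 comparisons);
* **within-treatment** — each post-immunization day against the
  pre-immunization baseline within each group (3 groups x 4 days = 12).

Each comparison fits, per feature, an NB GLM with a log link on the two
selected sample cells (two-level design: intercept + group indicator), log
size factors as offsets, and a fixed per-feature dispersion estimated once
per rank on all samples. The group coefficients are profiled directly
(saturated two-cell design), with a weak Gaussian ridge on each log-scale
group mean so that features observed in only one cell converge to large but
finite fold changes. The Wald statistic is
``z = (beta_a - beta_b) / sqrt(1/I_a + 1/I_b)`` with ``I_g`` the observed
information of the group fit; two-sided normal p-values are BH-corrected
within the comparison's feature set.

Per-feature dispersions are Cox-Reid-adjusted profile maximum-likelihood
estimates (variance = mu + alpha mu^2) with a floor of 1e-8, optionally
shrunk in log-space toward a robust mean-dispersion trend
``alpha(mu) = a0 + a1/mu``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import (
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    TREATMENTS,
    agglomerate,
    bh_adjust,
)
from .ordination import size_factors as _size_factors

logger = logging.getLogger(__name__)

_DISP_FLOOR = 1e-8
#: sd (natural-log scale) of the weak ridge on group log-means
_PRIOR_SD = 4.0


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Comparison:
    """One pairwise test: treatments at a day (cross) or a day against the
    pre-immunization baseline within a treatment (within)."""

    framework: str  # "cross_treatment" | "within_treatment"
    group_a: str
    group_b: str
    dpi: int
    baseline_dpi: int | None = None
    rank: str = "ASV"

    def __post_init__(self) -> None:
        if self.framework == "cross_treatment":
            if self.group_a == self.group_b:
                raise ValueError("cross-treatment comparison needs distinct groups")
        elif self.framework == "within_treatment":
            if self.group_a != self.group_b:
                raise ValueError("within-treatment comparison uses one group")
            if self.baseline_dpi is None:
                raise ValueError("within-treatment comparison needs baseline_dpi")
            if self.dpi == self.baseline_dpi:
                raise ValueError("within-treatment days must differ")
        else:
            raise ValueError(f"unknown framework {self.framework!r}")

    @property
    def label(self) -> str:
        if self.framework == "cross_treatment":
            return f"{self.group_a}_vs_{self.group_b}@{self.dpi}"
        return f"{self.group_a}:{self.dpi}_vs_{self.baseline_dpi}"

    def cells(self, metadata: SampleMetadata) -> tuple[list[str], list[str]]:
        if self.framework == "cross_treatment":
            return (
                metadata.select(self.group_a, self.dpi),
                metadata.select(self.group_b, self.dpi),
            )
        return (
            metadata.select(self.group_a, self.dpi),
            metadata.select(self.group_a, self.baseline_dpi),
        )


@dataclass
class DiffResult:
    """Per-feature differential-abundance results for one comparison."""

    comparison: Comparison
    table: pd.DataFrame  # base_mean, l2fc, se, stat, p, p_adj

    @property
    def features(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class TernaryPattern:
    """A {-1, 0, 1} digit per comparison time point."""

    digits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d not in (-1, 0, 1) for d in self.digits):
            raise ValueError("ternary digits must be in {-1, 0, 1}")

    @property
    def label(self) -> str:
        return ",".join(str(d) for d in self.digits)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


def _nb_profile_ll(counts: np.ndarray, mu: np.ndarray,
                   log_alpha: np.ndarray,
                   cell_codes: np.ndarray | None = None) -> np.ndarray:
    """Cox-Reid-adjusted NB log-likelihood, vectorized over features.

    ``counts``/``mu``: (features x samples); ``log_alpha``: (features,).
    ``cell_codes`` gives the design cell of each sample for the Cox-Reid
    degrees-of-freedom adjustment (one mean parameter per cell); ``None``
    means a single intercept.
    """
    alpha = np.exp(log_alpha)[:, None]
    r = 1.0 / alpha
    pos = mu > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (
            gammaln(counts + r) - gammaln(r) - gammaln(counts + 1.0)
            + r * np.log(r / (r + mu))
            + counts * np.log(mu / (r + mu))
        )
    ll = np.where(pos, terms, 0.0).sum(axis=1)
    w = mu / (1.0 + alpha * mu)
    if cell_codes is None:
        cr = 0.5 * np.log(np.maximum(w.sum(axis=1), 1e-300))
    else:
        cr = np.zeros(counts.shape[0])
        for code in np.unique(cell_codes):
            wc = w[:, cell_codes == code].sum(axis=1)
            cr += 0.5 * np.log(np.maximum(wc, 1.0e-8))
    return ll - cr


def fit_dispersion(
    counts: CountTable,
    sf: pd.Series,
    shrink_weight: float = 0.5,
    cells: pd.Series | None = None,
) -> tuple[pd.Series, tuple[float, float]]:
    """Per-feature NB dispersions and the mean-dispersion trend ``(a0, a1)``.

    Dispersions are Cox-Reid-adjusted profile MLEs (grid search plus a
    vectorized golden-section refinement on log alpha), floored at 1e-8.
    ``cells`` optionally assigns each sample a design-cell label (e.g.
    treatment x day); per-feature means are then profiled within cells, so
    real group x time effects do not masquerade as dispersion. The trend
    ``alpha(mu) = a0 + a1/mu`` is fitted by Huber robust regression over
    features with normalized mean > 1; per-feature values are then shrunk
    toward it in log-space with weight ``shrink_weight`` (0 = raw MLE,
    1 = trend).
    """
    if counts.shape[1] < 4:
        raise ValueError("dispersion estimation needs at least 4 samples")
    sf_vec = sf.reindex(counts.samples).to_numpy(dtype=float)
    mat = counts.counts.to_numpy(dtype=float)
    if cells is not None:
        codes = pd.Categorical(cells.reindex(counts.samples)).codes.astype(np.int64)
    else:
        codes = np.zeros(len(counts.samples), dtype=np.int64)
    norm = mat / sf_vec
    q_cell = np.empty_like(norm)
    for code in np.unique(codes):
        mask = codes == code
        q_cell[:, mask] = norm[:, mask].mean(axis=1, keepdims=True)
    q = norm.mean(axis=1)
    nonzero = q > 0
    mle = np.full(mat.shape[0], _DISP_FLOOR)

    if nonzero.any():
        c = mat[nonzero]
        mu = q_cell[nonzero] * sf_vec[None, :]
        cell_codes = codes if cells is not None else None
        lo_bound, hi_bound = np.log(1e-8), np.log(20.0)
        grid = np.linspace(lo_bound, hi_bound, 43)
        lls = np.stack([
            _nb_profile_ll(c, mu, np.full(c.shape[0], g), cell_codes)
            for g in grid
        ])
        best = np.argmax(lls, axis=0)
        step = grid[1] - grid[0]
        lo = np.clip(grid[best] - step, lo_bound, hi_bound)
        hi = np.clip(grid[best] + step, lo_bound, hi_bound)
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        for _ in range(25):
            x1 = hi - gr * (hi - lo)
            x2 = lo + gr * (hi - lo)
            f1 = _nb_profile_ll(c, mu, x1, cell_codes)
            f2 = _nb_profile_ll(c, mu, x2, cell_codes)
            take1 = f1 > f2
            hi = np.where(take1, x2, hi)
            lo = np.where(take1, lo, x1)
        mle[nonzero] = np.maximum(np.exp((lo + hi) / 2.0), _DISP_FLOOR)

    trend = _fit_trend(q, mle)
    a0, a1 = trend
    fitted = np.maximum(a0 + np.divide(a1, q, out=np.full_like(q, np.inf),
                                       where=q > 0), _DISP_FLOOR)
    w = float(np.clip(shrink_weight, 0.0, 1.0))
    shrunk = np.exp((1.0 - w) * np.log(mle) + w * np.log(fitted))
    shrunk = np.maximum(shrunk, _DISP_FLOOR)
    return pd.Series(shrunk, index=counts.features, name="dispersion"), trend


def _fit_trend(q: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Robust fit of ``alpha = a0 + a1/mu`` over informative features."""
    use = (q > 1.0) & (alpha > _DISP_FLOOR * 2)
    if use.sum() < 3:
        a0 = float(np.median(alpha[q > 0])) if (q > 0).any() else 0.01
        return max(a0, 1e-4), 0.0
    import statsmodels.api as sm

    x = sm.add_constant(1.0 / q[use])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.RLM(alpha[use], x, M=sm.robust.norms.HuberT()).fit()
            a0, a1 = float(fit.params[0]), float(fit.params[1])
        except Exception:  # pragma: no cover - singular fallback
            a0, a1 = float(np.median(alpha[use])), 0.0
    return max(a0, 1e-4), max(a1, 0.0)


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------


def _fit_cell(counts_cell: np.ndarray, sf_cell: np.ndarray,
              alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profile the per-feature log mean of one cell (vectorized Newton).

    Maximizes the ridge-penalized NB log-likelihood in ``beta`` where
    ``mu_ij = exp(beta_i) * sf_j``. Returns (beta, information, converged).
    """
    a = alpha[:, None]
    q0 = (counts_cell / sf_cell).mean(axis=1)
    beta = np.log(np.maximum(q0, 1e-8))
    prior_prec = 1.0 / _PRIOR_SD**2
    grad = np.zeros_like(beta)
    info = np.ones_like(beta)
    for _ in range(100):
        mu = np.exp(beta)[:, None] * sf_cell[None, :]
        denom = 1.0 + a * mu
        grad = ((counts_cell - mu) / denom).sum(axis=1) - beta * prior_prec
        info = (mu / denom).sum(axis=1) + prior_prec
        step = np.clip(grad / info, -3.0, 3.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    converged = np.abs(grad) < 1e-6 * np.maximum(info, 1.0)
    return beta, info, converged


def wald_test(
    counts: CountTable,
    metadata: SampleMetadata,
    sf: pd.Series,
    dispersions: pd.Series,
    comparison: Comparison,
    alpha: float = 0.05,
) -> DiffResult:
    """NB Wald test of ``group_a`` over ``group_b`` for one comparison.

    Features with zero counts in both cells are dropped before BH
    correction; non-converged features are reported with ``p = NaN`` and
    likewise excluded from the BH denominator.
    """
    cell_a, cell_b = comparison.cells(metadata)
    if len(cell_a) < 3 or len(cell_b) < 3:
        raise ValueError(
            f"comparison {comparison.label}: both cells need >= 3 samples "
            f"(got {len(cell_a)}, {len(cell_b)})"
        )
    mat_a = counts.counts[cell_a].to_numpy(dtype=float)
    mat_b = counts.counts[cell_b].to_numpy(dtype=float)
    sf_a = sf.reindex(cell_a).to_numpy(dtype=float)
    sf_b = sf.reindex(cell_b).to_numpy(dtype=float)
    disp = dispersions.reindex(counts.features).to_numpy(dtype=float)

    keep = (mat_a.sum(axis=1) + mat_b.sum(axis=1)) > 0
    n_feat = counts.shape[0]
    out = pd.DataFrame(
        {
            "base_mean": np.nan, "l2fc": np.nan, "se": np.nan,
            "stat": np.nan, "p": np.nan, "p_adj": np.nan,
        },
        index=counts.counts.index, dtype=float,
    )
    if keep.any():
        beta_a, info_a, conv_a = _fit_cell(mat_a[keep], sf_a, disp[keep])
        beta_b, info_b, conv_b = _fit_cell(mat_b[keep], sf_b, disp[keep])
        converged = conv_a & conv_b
        se_nat = np.sqrt(1.0 / info_a + 1.0 / info_b)
        diff = beta_a - beta_b
        z = diff / se_nat
        p = 2.0 * stats.norm.sf(np.abs(z))
        p[~converged] = np.nan
        base = np.concatenate([mat_a[keep] / sf_a, mat_b[keep] / sf_b], axis=1).mean(axis=1)
        ln2 = np.log(2.0)
        out.loc[keep, "base_mean"] = base
        out.loc[keep, "l2fc"] = diff / ln2
        out.loc[keep, "se"] = se_nat / ln2
        out.loc[keep, "stat"] = z
        out.loc[keep, "p"] = p
        tested = out["p"].notna()
        if tested.any():
            out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return DiffResult(comparison, out)


# ---------------------------------------------------------------------------
# Frameworks
# ---------------------------------------------------------------------------

_CROSS_PAIRS = (("EAE", "naive"), ("CFA", "naive"), ("EAE", "CFA"))


def design_comparisons(
    days: Sequence[int], rank: str = "ASV"
) -> list[Comparison]:
    """All cross-treatment (pairs x days) and within-treatment
    (groups x post-baseline days) comparisons, deterministically ordered."""
    days = list(days)
    baseline = days[0]
    comparisons: list[Comparison] = []
    for ga, gb in _CROSS_PAIRS:
        for d in days:
            comparisons.append(Comparison("cross_treatment", ga, gb, d, rank=rank))
    for g in TREATMENTS:
        for d in days[1:]:
            comparisons.append(
                Comparison("within_treatment", g, g, d, baseline_dpi=baseline,
                           rank=rank)
            )
    return comparisons


def run_frameworks(
    counts: CountTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyTable | None = None,
    rank: str = "ASV",
    shrink_weight: float = 0.5,
) -> dict[Comparison, DiffResult]:
    """Run every design comparison at ``rank``.

    If ``rank`` differs from the table's rank the ASV table is agglomerated
    first (requires ``taxonomy``). Size factors are global: estimated once
    from the finest table provided (the ASV table when agglomerating, whose
    dense feature set gives a stable median-of-ratios) and reused at every
    rank; dispersions are estimated once on all samples at the requested
    rank. Comparisons whose design cells are missing are skipped with a
    warning.
    """
    sf = _size_factors(counts)
    if rank != counts.rank:
        if taxonomy is None:
            raise ValueError("taxonomy required to agglomerate to another rank")
        counts = agglomerate(counts, taxonomy, rank)
    meta = metadata.table.reindex(counts.samples)
    cells = meta["treatment"].astype(str) + "@" + meta["dpi"].astype(str)
    dispersions, _ = fit_dispersion(counts, sf, shrink_weight=shrink_weight,
                                    cells=cells)
    days = sorted(metadata.table["dpi"].unique())
    results: dict[Comparison, DiffResult] = {}
    for comparison in design_comparisons(days, rank=rank):
        cell_a, cell_b = comparison.cells(metadata)
        if len(cell_a) < 3 or len(cell_b) < 3:
            logger.warning("skipping %s: missing design cell", comparison.label)
            continue
        results[comparison] = wald_test(counts, metadata, sf, dispersions, comparison)
    return results


# ---------------------------------------------------------------------------
# Ternary encoding
# ---------------------------------------------------------------------------


def ternary_encode(results: Sequence[pd.Series], alpha: float = 0.05) -> TernaryPattern:
    """Encode one feature's ordered per-day results as a ternary pattern.

    A digit is 1 if ``p_adj < alpha`` and ``l2fc > 0``, -1 if
    ``p_adj < alpha`` and ``l2fc < 0``, and 0 otherwise (including
    ``p_adj`` exactly at ``alpha``, and untested/NaN results).
    """
    digits = []
    for row in results:
        p_adj = row.get("p_adj", np.nan)
        l2fc = row.get("l2fc", np.nan)
        if np.isnan(p_adj) or np.isnan(l2fc) or p_adj >= alpha or l2fc == 0:
            digits.append(0)
        else:
            digits.append(1 if l2fc > 0 else -1)
    return TernaryPattern(tuple(digits))


#: the six per-feature ternary frameworks: three cross-treatment pairs and
#: three within-treatment groups
def framework_patterns(
    results: Mapping[Comparison, DiffResult], alpha: float = 0.05
) -> dict[str, pd.Series]:
    """Per-feature ternary pattern labels for each of the six frameworks."""
    out: dict[str, pd.Series] = {}
    for ga, gb in _CROSS_PAIRS:
        sel = sorted(
            (c for c in results if c.framework == "cross_treatment"
             and (c.group_a, c.group_b) == (ga, gb)),
            key=lambda c: c.dpi,
        )
        if sel:
            out[f"{ga}/{gb}"] = _patterns_for(results, sel, alpha)
    for g in TREATMENTS:
        sel = sorted(
            (c for c in results if c.framework == "within_treatment"
             and c.group_a == g),
            key=lambda c: c.dpi,
        )
        if sel:
            out[f"{g}:post/pre"] = _patterns_for(results, sel, alpha)
    return out


def _patterns_for(results, comparisons, alpha) -> pd.Series:
    frameworks = {c.framework for c in comparisons}
    if len(frameworks) > 1:
        raise ValueError("cannot mix frameworks in one pattern")
    features = results[comparisons[0]].table.index
    labels = {}
    for f in features:
        rows = [results[c].table.loc[f] for c in comparisons]
        labels[f] = ternary_encode(rows, alpha=alpha).label
    return pd.Series(labels, name="pattern").reindex(features)
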