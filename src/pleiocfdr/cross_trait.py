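"""Cross-trait shared-signal diagnostics.

Three quantities relate the target trait to a secondary trait before any
conditional-FDR modelling:

* **fold enrichment** — the fraction of target-associated variants
  (p_target < 0.05) among secondary-trait-associated variants
  (p_cond < 0.05), relative to that fraction in the full variant set;
* **genomic Spearman correlation** — the rank correlation, across
  independent LD blocks, of a per-block association statistic for each
  trait (here -log10 of the block's minimum p-value);
* **robust trend** — an iteratively reweighted least squares (Huber) line
  through per-trait (correlation, enrichment) points, as used to summarise
  many candidate conditioning traits at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import GenomicIntervals

__all__ = [
    "EnrichmentResult",
    "BlockCorrelationResult",
    "TrendFit",
    "fold_enrichment",
    "block_spearman",
    "irls_trend",
]


@dataclass
class EnrichmentResult:
    fold: float
    n_total: int
    n_target_assoc: int
    n_cond_assoc: int
    n_both: int
    alpha_target: float
    alpha_cond: float


@dataclass
class BlockCorrelationResult:
    rho: float
    pvalue: float
    n_blocks_used: int
    per_block_stat_target: np.ndarray
    per_block_stat_cond: np.ndarray


@dataclass
class TrendFit:
    slope: float
    intercept: float
    slope_ci: tuple
    pvalue: float
    n_points: int
    converged: bool
    n_iterations: int = 0


def fold_enrichment(
    pairs: pd.DataFrame,
    alpha_target: float = 0.05,
    alpha_cond: float = 0.05,
) -> EnrichmentResult:
    """Fold increase of target-trait association within the conditioning set.

    fold = (n_both / n_cond_assoc) / (n_target_assoc / n_total), with strict
    '<' cutoffs on both traits.  A fold of 1 means no cross-trait sharing;
    larger values mean the secondary trait's associated variants are enriched
    for target-trait association.
    """
    if not len(pairs):
        raise ValueError("pairs frame is empty")
    if not (0 < alpha_target < 1 and 0 < alpha_cond < 1):
        raise ValueError("alphas must lie in (0, 1)")
    pt = pairs["p_target"].to_numpy()
    pc = pairs["p_cond"].to_numpy()
    n_total = len(pairs)
    t = pt < alpha_target
    c = pc < alpha_cond
    n_t, n_c, n_b = int(t.sum()), int(c.sum()), int((t & c).sum())
    if n_c == 0 or n_t == 0:
        raise ValueError("enrichment undefined: no associated variants for one trait at the given alphas")
    fold = (n_b / n_c) / (n_t / n_total)
    return EnrichmentResult(fold, n_total, n_t, n_c, n_b, alpha_target, alpha_cond)


def block_spearman(pairs: pd.DataFrame, blocks: GenomicIntervals) -> BlockCorrelationResult:
    """Genomic Spearman correlation across independent LD blocks.

    The per-block, per-trait statistic is -log10 of the minimum p-value among
    the block's variants; blocks containing no variant are omitted.  The
    correlation is Spearman's rho over the block-statistic vectors.
    """
    block_idx = blocks.assign(pairs["chrom"].to_numpy(dtype=str), pairs["pos"].to_numpy())
    inside = block_idx >= 0
    df = pd.DataFrame(
        {
            "block": block_idx[inside],
            "p_target": pairs["p_target"].to_numpy()[inside],
            "p_cond": pairs["p_cond"].to_numpy()[inside],
        }
    )
    grp = df.groupby("block").min()
    if len(grp) < 3:
        raise ValueError("fewer than 3 usable LD blocks; rank correlation undefined")
    stat_t = -np.log10(grp["p_target"].to_numpy())
    stat_c = -np.log10(grp["p_cond"].to_numpy())
    rho, pv = stats.spearmanr(stat_t, stat_c)
    return BlockCorrelationResult(float(rho), float(pv), len(grp), stat_t, stat_c)


def irls_trend(
    x,
    y,
    huber_c: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> TrendFit:
    """Robust trend line by iteratively reweighted least squares.

    Huber weights (tuning constant 1.345, 95% Gaussian efficiency) damp the
    influence of outlying traits; the slope's p-value and 95% CI come from
    the final weighted least-squares fit's t-statistic.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 (x, y) points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; trend undefined")

    X = sm.add_constant(x)
    w = np.ones_like(x)
    coef = np.zeros(2)
    converged = False
    it = 0
    fit = None
    for it in range(1, max_iter + 1):
        fit = sm.WLS(y, X, weights=w).fit()
        new_coef = fit.params
        resid = y - X @ new_coef
        # robust scale: normalized median absolute deviation of residuals
        scale = stats.median_abs_deviation(resid, scale="normal")
        if scale == 0:
            converged = True
            coef = new_coef
            break
        u = np.abs(resid / scale)
        w = np.where(u <= huber_c, 1.0, huber_c / np.maximum(u, 1e-300))
        if np.max(np.abs(new_coef - coef)) < tol:
            coef = new_coef
            converged = True
            break
        coef = new_coef
    ci = fit.conf_int(alpha=0.05)
    return TrendFit(
        slope=float(coef[1]),
        intercept=float(coef[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        pvalue=float(fit.pvalues[1]),
        n_points=int(x.size),
        converged=converged,
        n_iterations=it,
    )
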