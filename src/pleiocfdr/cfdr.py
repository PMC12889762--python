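"""Conditional false discovery rate estimation for pleiotropy-informed GWAS.

The conditional FDR of a variant is the probability that it carries no true
association with the target trait, given that its observed p-values for the
target and for a genetically related conditioning trait are both as small or
smaller than observed.  Following the empirical-Bayes view of the FDR, it is
estimated from the joint empirical distribution of the paired p-values::

    cFDR(p1, p2) = min(1, p1 * N(P2 <= p2) / N(P1 <= p1, P2 <= p2))

with counts N taken over a reference set of variant pairs.  Because
linkage disequilibrium makes neighbouring variants statistically dependent,
the reference set is an LD-pruned random subset, and the final per-variant
value is the mean over many pruning iterations (500 by default, pruned at
r² < 0.2 on a random permutation).

The user-facing entry point is :class:`CfdrModel`, whose :meth:`~CfdrModel.fit`
returns a :class:`CfdrResults` carrying the per-variant averaged cFDR, the
between-iteration SD, and a :meth:`~CfdrResults.summary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._fastpath import greedy_keep, prefix_dominance_counts
from .ld import LDReference

__all__ = ["CfdrConfig", "CfdrModel", "CfdrResults", "empirical_cfdr", "random_ld_prune", "averaged_cfdr"]


@dataclass(frozen=True)
class CfdrConfig:
    """Settings for the averaged conditional-FDR estimator.

    Parameters
    ----------
    n_iterations
        Number of random LD-pruning iterations averaged over (default 500).
    prune_r2
        Pruning threshold: every retained reference pair has r² strictly
        below this (default 0.2).
    min_stratum_count
        Minimum number of reference pairs in the conditioning stratum
        N(P2 <= p2); smaller strata are widened to the smallest p2 threshold
        reaching this count (fallback: the full reference set).
    cap_at_one
        Clip estimates at 1 (the estimate is a probability).
    monotonize
        Optionally enforce monotone non-decreasing cFDR in p1 within
        conditioning strata via a cumulative minimum (off by default).
    base_seed
        Iteration k draws its pruning permutation from seed ``base_seed + k``.
    """

    n_iterations: int = 500
    prune_r2: float = 0.2
    min_stratum_count: int = 50
    cap_at_one: bool = True
    monotonize: bool = False
    base_seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 < self.prune_r2 <= 1):
            raise ValueError("prune_r2 must lie in (0, 1]")


def random_ld_prune(n_or_ids, ld: LDReference | None, r2_max: float, rng_seed: int) -> np.ndarray:
    """Random-order greedy LD pruning.

    Walks a uniformly random permutation of the variants; a variant is kept
    iff its r² with every already-kept variant is strictly below ``r2_max``.
    Returns the kept variant indices in ascending order (so the result does
    not depend on the input listing, only on the seed).
    """
    n = n_or_ids if isinstance(n_or_ids, (int, np.integer)) else len(n_or_ids)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n).astype(np.int64)
    if ld is None or ld.matrix.nnz == 0:
        return np.arange(n, dtype=np.int64)
    indptr, indices, data = ld.csr_arrays()
    kept = greedy_keep(order, indptr, indices, data, float(r2_max))
    return np.flatnonzero(kept).astype(np.int64)


def empirical_cfdr(
    p1_ref: np.ndarray,
    p2_ref: np.ndarray,
    p1_eval: np.ndarray,
    p2_eval: np.ndarray,
    min_stratum_count: int = 50,
    cap_at_one: bool = True,
) -> np.ndarray:
    """Raw counting conditional-FDR estimate at the given evaluation points.

    All comparisons are inclusive (<=).  If the conditioning stratum
    N(P2 <= p2) holds fewer than ``min_stratum_count`` reference pairs, the
    threshold is relaxed to the smallest p2' >= p2 achieving that count
    (falling back to the full reference set when it is smaller than the
    minimum).  Evaluation points with an empty joint count — possible only
    for points outside the reference set — get cFDR = 1, signalling no
    support.
    """
    p1_ref = np.asarray(p1_ref, dtype=np.float64)
    p2_ref = np.asarray(p2_ref, dtype=np.float64)
    p1_eval = np.asarray(p1_eval, dtype=np.float64)
    p2_eval = np.asarray(p2_eval, dtype=np.float64)
    R = len(p1_ref)
    if R == 0:
        raise ValueError("reference pair set is empty")

    p2_sorted = np.sort(p2_ref)
    n2 = np.searchsorted(p2_sorted, p2_eval, side="right").astype(np.int64)
    if R < min_stratum_count:
        n2 = np.full_like(n2, R)
    else:
        relaxed = np.searchsorted(p2_sorted, p2_sorted[min_stratum_count - 1], side="right")
        n2 = np.where(n2 < min_stratum_count, relaxed, n2)

    # joint counts by a p2-ordered sweep with a Fenwick tree over p1 ranks
    p2_order = np.argsort(p2_ref, kind="stable")
    p1_sorted = np.sort(p1_ref)
    p1_rank = np.empty(R, dtype=np.int64)
    p1_rank[np.argsort(p1_ref, kind="stable")] = np.arange(R)
    ref_p1_rank_by_p2 = p1_rank[p2_order]
    eval_p1_count = np.searchsorted(p1_sorted, p1_eval, side="right").astype(np.int64)
    eval_order = np.argsort(n2, kind="stable").astype(np.int64)
    joint = prefix_dominance_counts(ref_p1_rank_by_p2, n2, eval_p1_count, eval_order)

    out = np.ones(len(p1_eval), dtype=np.float64)
    ok = joint > 0
    out[ok] = p1_eval[ok] * n2[ok] / joint[ok]
    if cap_at_one:
        np.minimum(out, 1.0, out=out)
    return out


def _monotonize(cfdr: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Cumulative minimum of cFDR along decreasing p1 (global pass)."""
    order = np.argsort(p1, kind="stable")[::-1]
    out = cfdr.copy()
    out[order] = np.minimum.accumulate(out[order])
    return out


def averaged_cfdr(
    pairs: pd.DataFrame,
    ld: LDReference | None,
    config: CfdrConfig | None = None,
) -> pd.DataFrame:
    """Functional wrapper: fit a :class:`CfdrModel` and return its frame."""
    return CfdrModel(pairs, ld=ld, config=config).fit().frame


class CfdrModel:
    """Conditional-FDR model for one target trait given one conditioning trait.

    Parameters
    ----------
    pairs
        Harmonized per-variant frame with columns ``p_target`` and ``p_cond``
        (plus ``variant_id, chrom, pos`` carried through to the results);
        typically the output of :func:`pleiocfdr.io.harmonize_pair` with
        exclusion regions already applied.
    ld
        Pairwise-r² reference over the same variants, in the same order.
        ``None`` disables pruning (every variant enters the reference set).
    config
        A :class:`CfdrConfig`; defaults are 500 iterations with random
        pruning at r² < 0.2.
    """

    def __init__(self, pairs: pd.DataFrame, ld: LDReference | None = None, config: CfdrConfig | None = None):
        for col in ("p_target", "p_cond"):
            if col not in pairs.columns:
                raise ValueError(f"pairs frame lacks required column {col!r}")
        if not len(pairs):
            raise ValueError("pairs frame is empty")
        if ld is not None and len(ld) != len(pairs):
            raise ValueError("LD reference and pairs frame cover different variant sets")
        self.pairs = pairs.reset_index(drop=True)
        self.ld = ld
        self.config = config or CfdrConfig()
        self.p_target = self.pairs["p_target"].to_numpy(dtype=np.float64)
        self.p_cond = self.pairs["p_cond"].to_numpy(dtype=np.float64)

    @classmethod
    def from_tables(
        cls,
        target: pd.DataFrame,
        cond: pd.DataFrame,
        ld: LDReference | None = None,
        config: CfdrConfig | None = None,
        exclusions=None,
    ) -> "CfdrModel":
        """Harmonize two summary-statistics tables and build the model.

        ``exclusions`` (a :class:`pleiocfdr.io.GenomicIntervals`) is applied
        after harmonization; the LD reference is subset to the surviving
        variants.
        """
        from .io import apply_exclusions, harmonize_pair

        pairs = harmonize_pair(target, cond)
        pairs = apply_exclusions(pairs, exclusions)
        if ld is not None:
            ld = ld.subset(pairs["variant_id"].to_numpy())
        return cls(pairs, ld=ld, config=config)

    def fit(self) -> "CfdrResults":
        """Run the pruning iterations and average the per-variant estimates."""
        cfg = self.config
        m = len(self.pairs)
        total = np.zeros(m)
        total_sq = np.zeros(m)
        static_reference = self.ld is None or self.ld.matrix.nnz == 0
        n_done = 0
        cached = None
        for k in range(1, cfg.n_iterations + 1):
            if static_reference and cached is not None:
                vals = cached
            else:
                keep = random_ld_prune(m, self.ld, cfg.prune_r2, cfg.base_seed + k)
                vals = empirical_cfdr(
                    self.p_target[keep],
                    self.p_cond[keep],
                    self.p_target,
                    self.p_cond,
                    min_stratum_count=cfg.min_stratum_count,
                    cap_at_one=cfg.cap_at_one,
                )
                if cfg.monotonize:
                    vals = _monotonize(vals, self.p_target)
                if static_reference:
                    cached = vals
            total += vals
            total_sq += vals * vals
            n_done = k
        mean = total / n_done
        if n_done > 1:
            var = np.maximum(total_sq - n_done * mean * mean, 0.0) / (n_done - 1)
            sd = np.sqrt(var)
        else:
            sd = np.zeros(m)
        return CfdrResults(self, mean, sd, n_done)


class CfdrResults:
    """Per-variant averaged conditional FDR with iteration provenance."""

    def __init__(self, model: CfdrModel, cfdr_mean: np.ndarray, cfdr_sd: np.ndarray, n_iterations_used: int):
        self.model = model
        self.cfdr_mean = cfdr_mean
        self.cfdr_sd = cfdr_sd
        self.n_iterations_used = n_iterations_used

    @property
    def frame(self) -> pd.DataFrame:
        """Per-variant results table (Manhattan-plot ready)."""
        out = pd.DataFrame(
            {
                "variant_id": self.model.pairs.get("variant_id", pd.RangeIndex(len(self.cfdr_mean)).astype(str)),
                "chrom": self.model.pairs.get("chrom", "0"),
                "pos": self.model.pairs.get("pos", 0),
                "p_target": self.model.p_target,
                "p_cond": self.model.p_cond,
                "cfdr_mean": self.cfdr_mean,
                "cfdr_sd": self.cfdr_sd,
            }
        )
        out["n_iterations_used"] = self.n_iterations_used
        return out

    def significant(self, threshold: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["cfdr_mean"] < threshold].reset_index(drop=True)

    def loci(self, locus_config=None, source: str = "analysis"):
        """Collapse the results into independent loci (clump then merge)."""
        from .loci import clump, merge_loci

        clumps = clump(self.frame, self.model.ld, config=locus_config)
        return merge_loci([(lead, members, source) for lead, members in clumps], config=locus_config)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")

    def summary(self) -> str:
        cfg = self.model.config
        f = self.frame
        lines = [
            "Conditional FDR results",
            "=======================",
            f"variants:              {len(f)}",
            f"iterations used:       {self.n_iterations_used}",
            f"pruning r2 threshold:  {cfg.prune_r2}",
            f"min stratum count:     {cfg.min_stratum_count}",
            f"cFDR < 0.05:           {int((f['cfdr_mean'] < 0.05).sum())}",
            f"cFDR < 0.10:           {int((f['cfdr_mean'] < 0.10).sum())}",
            f"median cFDR:           {np.median(f['cfdr_mean']):.4g}",
            f"mean iteration SD:     {np.mean(f['cfdr_sd']):.4g}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<CfdrResults: {len(self.cfdr_mean)} variants, {self.n_iterations_used} iterations>"
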