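"""Paired GWAS summary-statistics simulator with block LD and pleiotropy.

Effects are injected directly at the z-score level (a non-centrality
parameterization) rather than through genotypes: the pipeline consumes only
summary statistics, and z-level simulation makes power and false-discovery
targets analytically controllable.

The genome is a sequence of independent LD blocks with exchangeable
within-block correlation.  Each block draws a causal class from the
four-groups mixture (null / target-only / conditioning-only / shared); a
causal block has exactly one causal variant whose trait z-score is
``N(delta, 1)`` with ``delta`` the trait non-centrality (bivariate-normal
across traits for shared blocks).  Non-causal variants see the causal
signal through the LD factor::

    z_j = sqrt(r2) * z_causal + sqrt(1 - r2) * eps_j

so every within-block pair of z-scores has squared correlation ``r2``, which
is what the accompanying LD reference reports.  Two-sided p-values are
``2 * Phi(-|z|)``.  An independent replication cohort for the target trait
redraws all noise with non-centralities scaled by ``rep_scale``.  Ground
truth (per-variant class, causal flags) is returned for scoring realized
false-discovery proportions and power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import P_FLOOR, CANONICAL_COLUMNS, GenomicIntervals
from .ld import LDReference
from .loci import Locus

__all__ = ["SyntheticConfig", "SimulatedStudy", "simulate_pair", "truth_metrics"]

_CLASSES = np.array(["null", "t1_only", "t2_only", "shared"])

# fixed non-ambiguous allele pairs cycled over variants; replication rows may
# list them swapped (with the sign flipped) to exercise harmonization
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one simulated two-trait GWAS.

    The default genome is 500 independent blocks of 10 variants (5,000
    variants) spaced 1 Mb apart on one chromosome, with within-block LD
    r² = 0.5 — strong enough that random pruning at r² < 0.2 keeps one
    variant per block and clumping at r² >= 0.1 groups block-mates.  The
    four-groups mixture defaults to 85% null blocks and 5% in each non-null
    class; causal non-centralities have SD 4 (comfortably detectable at a
    few thousand variants without being deterministic), shared effects
    correlate at 0.8, and the replication cohort's non-centralities are
    halved, mimicking a smaller independent case-control sample.
    """

    n_blocks: int = 500
    snps_per_block: int = 10
    block_spacing_bp: int = 1_000_000
    within_block_r2: float = 0.5
    pi_null: float = 0.85
    pi_t1: float = 0.05
    pi_t2: float = 0.05
    pi_shared: float = 0.05
    effect_sd_t1: float = 4.0
    effect_sd_t2: float = 4.0
    effect_corr_shared: float = 0.8
    n_cond_cohorts: int = 1
    rep_scale: float = 0.5
    n_eff: int = 4000
    chrom: str = "1"
    within_block_spacing_bp: int = 1_000
    seed: int = 0

    def __post_init__(self):
        pis = (self.pi_null, self.pi_t1, self.pi_t2, self.pi_shared)
        if abs(sum(pis) - 1.0) > 1e-12 or min(pis) < 0:
            raise ValueError("causal-class probabilities must be a simplex summing to 1")
        if not 0 <= self.within_block_r2 < 1:
            raise ValueError("within_block_r2 must lie in [0, 1)")
        if self.n_cond_cohorts not in (1, 2):
            raise ValueError("n_cond_cohorts must be 1 or 2")
        if self.rep_scale <= 0:
            raise ValueError("rep_scale must be positive")


@dataclass
class SimulatedStudy:
    """Everything one pipeline run needs, plus the generating truth."""

    target: pd.DataFrame
    conditioning: list
    replication: pd.DataFrame
    truth: pd.DataFrame
    ld: LDReference
    blocks: GenomicIntervals
    config: SyntheticConfig

    def harmonized(self, cohort: int = 0) -> pd.DataFrame:
        from .io import harmonize_pair

        return harmonize_pair(self.target, self.conditioning[cohort])


def _draw_z(rng, delta_per_block, causal_col, cfg) -> np.ndarray:
    """Block-factor z-scores: causal variant N(delta,1), LD-attenuated rest."""
    B, S = cfg.n_blocks, cfg.snps_per_block
    r = np.sqrt(cfg.within_block_r2)
    e0 = rng.standard_normal(B)
    z_causal = delta_per_block + e0
    eps = rng.standard_normal((B, S))
    z = r * z_causal[:, None] + np.sqrt(1.0 - cfg.within_block_r2) * eps
    z[np.arange(B), causal_col] = z_causal
    return z.ravel()


def _table(cfg, variant_ids, chrom, pos, alleles, z, swap_mask=None) -> pd.DataFrame:
    f = 0.3  # dummy allele frequency for effect-size scaling
    se = 1.0 / np.sqrt(2.0 * cfg.n_eff * f * (1.0 - f))
    beta = z * se
    ea = np.array([a for a, _ in alleles], dtype=object)
    oa = np.array([b for _, b in alleles], dtype=object)
    if swap_mask is not None:
        ea, oa = ea.copy(), oa.copy()
        ea[swap_mask], oa[swap_mask] = oa[swap_mask], ea[swap_mask]
        beta = np.where(swap_mask, -beta, beta)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "se": np.full(len(z), se),
            "pvalue": p,
        }
    )[CANONICAL_COLUMNS]


def simulate_pair(config: SyntheticConfig | None = None) -> SimulatedStudy:
    """Generate one synthetic two-trait study with ground truth.

    Returns target and conditioning discovery tables, an independent
    replication table for the target trait, per-variant truth labels, the
    block LD reference, and the block intervals.  Fixed config (including
    seed) gives bit-identical output.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    B, S = cfg.n_blocks, cfg.snps_per_block
    M = B * S

    classes = rng.choice(4, size=B, p=[cfg.pi_null, cfg.pi_t1, cfg.pi_t2, cfg.pi_shared])
    causal_col = rng.integers(0, S, size=B)

    # trait non-centralities per block; shared blocks draw correlated effects
    raw = rng.standard_normal((B, 2))
    rho = cfg.effect_corr_shared
    d1 = raw[:, 0] * cfg.effect_sd_t1
    d2 = (rho * raw[:, 0] + np.sqrt(1 - rho**2) * raw[:, 1]) * cfg.effect_sd_t2
    delta1 = np.where(np.isin(classes, (1, 3)), np.where(classes == 3, d1, raw[:, 0] * cfg.effect_sd_t1), 0.0)
    delta2 = np.where(np.isin(classes, (2, 3)), np.where(classes == 3, d2, raw[:, 1] * cfg.effect_sd_t2), 0.0)

    block_start = np.arange(B, dtype=np.int64) * cfg.block_spacing_bp + 1
    pos = (block_start[:, None] + np.arange(S, dtype=np.int64)[None, :] * cfg.within_block_spacing_bp).ravel()
    variant_ids = np.array([f"v{b}_{j}" for b in range(B) for j in range(S)], dtype=object)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(M)]
    block_index = np.repeat(np.arange(B), S)

    target = _table(cfg, variant_ids, cfg.chrom, pos, alleles, _draw_z(rng, delta1, causal_col, cfg))
    conditioning = [
        _table(cfg, variant_ids, cfg.chrom, pos, alleles, _draw_z(rng, delta2, causal_col, cfg))
        for _ in range(cfg.n_cond_cohorts)
    ]
    swap_mask = rng.random(M) < 0.5
    replication = _table(
        cfg, variant_ids, cfg.chrom, pos, alleles,
        _draw_z(rng, cfg.rep_scale * delta1, causal_col, cfg),
        swap_mask=swap_mask,
    )

    truth = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": cfg.chrom,
            "pos": pos,
            "block": block_index,
            "class": _CLASSES[classes][block_index],
            "is_causal": (np.arange(M) % S) == causal_col[block_index],
        }
    )
    ld = LDReference.from_blocks(variant_ids, block_index, cfg.within_block_r2)
    last_pos = block_start + (S - 1) * cfg.within_block_spacing_bp
    blocks = GenomicIntervals([(cfg.chrom, int(s - 1), int(e)) for s, e in zip(block_start, last_pos)])
    return SimulatedStudy(target, conditioning, replication, truth, ld, blocks, cfg)


def truth_metrics(
    discovered_loci: "list[Locus]",
    truth: pd.DataFrame,
    blocks: GenomicIntervals | None = None,
) -> tuple[float, float]:
    """Score discovered loci against the generating truth.

    A locus is a true positive iff its span overlaps a block whose
    target-trait class is ``t1_only`` or ``shared``.  Returns
    ``(fdp, power)``: the false-discovery proportion over loci (0 when there
    are no discoveries) and the fraction of target-causal blocks recovered
    by at least one locus (distinct blocks, so power never exceeds 1).
    """
    spans = (
        truth.groupby(["chrom", "block"])
        .agg(start=("pos", "min"), end=("pos", "max"), cls=("class", "first"))
        .reset_index()
    )
    causal = spans[spans["cls"].isin(["t1_only", "shared"])]
    n_causal = len(causal)
    if not discovered_loci:
        return 0.0, 0.0
    tp = 0
    hit_blocks = set()
    for locus in discovered_loci:
        sub = causal[causal["chrom"] == locus.chrom]
        overlap = sub[(sub["end"] >= locus.start) & (sub["start"] <= locus.end)]
        if len(overlap):
            tp += 1
            hit_blocks.update(overlap["block"].tolist())
    fp = len(discovered_loci) - tp
    fdp = fp / len(discovered_loci)
    power = len(hit_blocks) / n_causal if n_causal else 0.0
    return fdp, power
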