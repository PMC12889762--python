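import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiocfdr import (
    SyntheticConfig,
    block_spearman,
    fold_enrichment,
    harmonize_pair,
    simulate_pair,
    truth_metrics,
)
from pleiocfdr.loci import Locus


class TestSimulatePair:
    def test_fixed_seed_bit_identical(self):
        cfg = SyntheticConfig(n_blocks=30, seed=5)
        a, b = simulate_pair(cfg), simulate_pair(cfg)
        pd.testing.assert_frame_equal(a.target, b.target)
        pd.testing.assert_frame_equal(a.conditioning[0], b.conditioning[0])
        pd.testing.assert_frame_equal(a.replication, b.replication)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_invalid_simplex_raises(self):
        with pytest.raises(ValueError, match="simplex"):
            SyntheticConfig(pi_null=0.5, pi_t1=0.1, pi_t2=0.1, pi_shared=0.1)

    def test_null_pvalues_are_uniform(self):
        cfg = SyntheticConfig(
            n_blocks=1000, snps_per_block=10, pi_null=1.0, pi_t1=0.0, pi_t2=0.0, pi_shared=0.0, seed=8
        )
        s = simulate_pair(cfg)
        ks = stats.kstest(s.target["pvalue"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_within_block_z_correlation_matches_config(self):
        cfg = SyntheticConfig(
            n_blocks=2000, snps_per_block=5, pi_null=1.0, pi_t1=0.0, pi_t2=0.0, pi_shared=0.0,
            within_block_r2=0.5, seed=9,
        )
        s = simulate_pair(cfg)
        z = stats.norm.isf(s.target["pvalue"].to_numpy() / 2) * np.sign(s.target["beta"].to_numpy())
        zb = z.reshape(cfg.n_blocks, cfg.snps_per_block)
        # mean pairwise correlation between distinct non-causal mates is r2
        causal = s.truth["is_causal"].to_numpy().reshape(cfg.n_blocks, -1)
        cors = []
        for j in range(1, cfg.snps_per_block):
            a = zb[:, 0][~causal[:, 0] & ~causal[:, j]]
            b = zb[:, j][~causal[:, 0] & ~causal[:, j]]
            cors.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(cors) == pytest.approx(cfg.within_block_r2, abs=0.05)

    def test_ld_reference_reports_block_structure(self):
        s = simulate_pair(SyntheticConfig(n_blocks=10, snps_per_block=3, seed=1))
        assert s.ld.r2("v0_0", "v0_1") == 0.5
        assert s.ld.r2("v0_0", "v1_0") == 0.0
        assert len(s.blocks) == 10

    def test_exactly_one_causal_variant_per_block(self, small_study):
        per_block = small_study.truth.groupby("block")["is_causal"].sum()
        assert (per_block == 1).all()

    def test_no_ld_prune_keeps_everything(self):
        from pleiocfdr import random_ld_prune

        s = simulate_pair(SyntheticConfig(n_blocks=20, within_block_r2=0.0, seed=2))
        kept = random_ld_prune(len(s.ld), s.ld, 0.2, 3)
        assert len(kept) == 20 * SyntheticConfig.snps_per_block

    def test_two_conditioning_cohorts(self):
        s = simulate_pair(SyntheticConfig(n_blocks=20, n_cond_cohorts=2, seed=3))
        assert len(s.conditioning) == 2
        assert not s.conditioning[0]["pvalue"].equals(s.conditioning[1]["pvalue"])

    def test_replication_harmonizes_back_to_discovery_frame(self):
        """Allele-swapped replication rows recover the discovery effect sign."""
        s = simulate_pair(SyntheticConfig(n_blocks=50, seed=6, rep_scale=1.0))
        pairs = harmonize_pair(s.replication, s.target)
        assert {"concordant", "flipped"} == set(pairs["alignment"].unique())
        flipped = pairs[pairs["alignment"] == "flipped"]
        rep_idx = s.replication.set_index("variant_id")
        tgt_idx = s.target.set_index("variant_id")
        for vid in flipped["variant_id"].head(5):
            assert rep_idx.at[vid, "effect_allele"] == tgt_idx.at[vid, "other_allele"]


class TestCrossTraitMonotonicity:
    def test_shared_fraction_drives_fold_and_rho(self):
        """Mean enrichment and block correlation rise with the shared-causal rate."""
        folds, rhos = [], []
        for pi_sh in (0.0, 0.05, 0.15):
            f_acc, r_acc = [], []
            for rep in range(20):
                cfg = SyntheticConfig(
                    n_blocks=150, seed=900 + rep,
                    pi_shared=pi_sh, pi_null=0.9 - pi_sh, pi_t1=0.05, pi_t2=0.05,
                )
                s = simulate_pair(cfg)
                pairs = s.harmonized()
                f_acc.append(fold_enrichment(pairs).fold)
                r_acc.append(block_spearman(pairs, s.blocks).rho)
            folds.append(np.mean(f_acc))
            rhos.append(np.mean(r_acc))
        assert folds[0] < folds[1] < folds[2]
        assert rhos[0] < rhos[1] < rhos[2]

    def test_pure_null_conditioning_gives_fold_near_one(self):
        folds = []
        for rep in range(20):
            cfg = SyntheticConfig(n_blocks=1000, seed=700 + rep, pi_shared=0.0, pi_t2=0.0,
                                  pi_null=0.9, pi_t1=0.1)
            s = simulate_pair(cfg)
            folds.append(fold_enrichment(s.harmonized()).fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)


class TestTruthMetrics:
    def test_perfect_discovery_zero_fdp(self, small_study):
        spans = small_study.truth.groupby("block").agg(start=("pos", "min"), end=("pos", "max"),
                                                       cls=("class", "first"))
        causal = spans[spans["cls"].isin(["t1_only", "shared"])]
        loci = [
            Locus("1", int(r.start), int(r.end), f"L{i}", 0.01, int(r.start), 1e-6, [], "tier1", {"US"})
            for i, r in enumerate(causal.itertuples())
        ]
        fdp, power = truth_metrics(loci, small_study.truth, small_study.blocks)
        assert fdp == 0.0
        assert power == 1.0

    def test_zero_discoveries(self, small_study):
        assert truth_metrics([], small_study.truth, small_study.blocks) == (0.0, 0.0)

    def test_null_region_locus_counts_as_false(self, small_study):
        null_block = small_study.truth[small_study.truth["class"] == "null"]["block"].iloc[0]
        span = small_study.truth[small_study.truth["block"] == null_block]["pos"]
        loci = [Locus("1", int(span.min()), int(span.max()), "L0", 0.01, int(span.min()), 1e-6, [],
                      "tier1", {"US"})]
        fdp, power = truth_metrics(loci, small_study.truth, small_study.blocks)
        assert fdp == 1.0 and power == 0.0
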