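from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pleiocfdr import CfdrConfig, CfdrModel, LDReference, bh_adjust, empirical_cfdr, random_ld_prune

from conftest import brute_force_cfdr


def _ld(ids, pairs):
    return LDReference.from_pairs(ids, pairs)


class TestRandomLdPrune:
    def test_no_ld_keeps_everything(self):
        ld = LDReference.from_blocks(["a", "b", "c"], np.array([0, 1, 2]), 0.5)
        kept = random_ld_prune(3, ld, 0.2, rng_seed=1)
        assert kept.tolist() == [0, 1, 2]

    def test_complete_clique_keeps_exactly_one(self):
        ld = LDReference.from_blocks(["a", "b", "c"], np.array([0, 0, 0]), 1.0)
        for seed in range(20):
            kept = random_ld_prune(3, ld, 0.2, rng_seed=seed)
            assert len(kept) == 1

    def test_chain_outcomes_match_greedy_enumeration(self):
        # A-B r2=0.5, B-C r2=0.5, A-C r2=0: greedy over any of the 6
        # permutations yields either {B} (B first) or {A, C}
        ld = _ld(["A", "B", "C"], {("A", "B"): 0.5, ("B", "C"): 0.5})
        expected = set()
        for perm in permutations(range(3)):
            kept = []
            for v in perm:
                if all(ld.r2(ld.variant_ids[v], ld.variant_ids[k]) < 0.2 for k in kept):
                    kept.append(v)
            expected.add(frozenset(kept))
        assert expected == {frozenset({1}), frozenset({0, 2})}
        seen = set()
        for seed in range(1000):
            seen.add(frozenset(random_ld_prune(3, ld, 0.2, seed).tolist()))
        assert seen == expected

    def test_kept_set_is_pairwise_below_threshold(self, small_study):
        ld = small_study.ld
        kept = random_ld_prune(len(ld), ld, 0.2, rng_seed=7)
        sub = ld.matrix[kept][:, kept]
        assert sub.nnz == 0 or sub.data.max() < 0.2

    def test_empty_input(self):
        assert random_ld_prune(0, None, 0.2, 1).size == 0


class TestEmpiricalCfdr:
    def test_five_pair_toy_example(self):
        ref = np.array([[0.001, 0.002], [0.01, 0.5], [0.5, 0.01], [0.9, 0.9], [0.04, 0.03]])
        out = empirical_cfdr(ref[:, 0], ref[:, 1], np.array([0.001]), np.array([0.002]), min_stratum_count=1)
        assert out[0] == pytest.approx(0.001)

    def test_p_target_one_capped_at_one(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.random(100), rng.random(100)
        out = empirical_cfdr(p1, p2, np.array([1.0, 1.0]), np.array([0.3, 1.0]))
        assert (out == 1.0).all()

    def test_uninformative_conditioning_reduces_to_ebayes_fdr(self):
        rng = np.random.default_rng(3)
        p1 = rng.random(100)
        ones = np.ones(100)
        out = empirical_cfdr(p1, ones, p1, ones, min_stratum_count=1)
        rank = np.array([(p1 <= v).sum() for v in p1])
        expected = np.minimum(p1 * 100 / rank, 1.0)
        np.testing.assert_allclose(out, expected, rtol=0, atol=0)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(3, 60))
        seed = data.draw(st.integers(0, 10_000))
        msc = data.draw(st.sampled_from([1, 5, 50]))
        rng = np.random.default_rng(seed)
        p1, p2 = rng.random(n), rng.random(n)
        # ties exercised by rounding half the instances to one decimal
        if data.draw(st.booleans()):
            p1, p2 = np.ceil(p1 * 10) / 10, np.ceil(p2 * 10) / 10
        out = empirical_cfdr(p1, p2, p1, p2, min_stratum_count=msc)
        expected = brute_force_cfdr(p1, p2, p1, p2, min_stratum_count=msc)
        np.testing.assert_allclose(out, expected, rtol=0, atol=0)

    def test_external_eval_points_and_stratum_guard(self):
        rng = np.random.default_rng(5)
        p1, p2 = rng.random(200), rng.random(200)
        e1, e2 = rng.random(50), rng.random(50) ** 3  # push some strata small
        out = empirical_cfdr(p1, p2, e1, e2, min_stratum_count=50)
        expected = brute_force_cfdr(p1, p2, e1, e2, min_stratum_count=50)
        np.testing.assert_allclose(out, expected, rtol=0, atol=0)
        assert ((out >= 0) & (out <= 1)).all()


class TestCfdrModel:
    def _pairs(self, p1, p2):
        n = len(p1)
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "chrom": "1",
                "pos": np.arange(n) * 1000 + 1,
                "p_target": p1,
                "p_cond": p2,
            }
        )

    def test_single_iteration_no_ld_equals_empirical_cfdr(self):
        rng = np.random.default_rng(11)
        p1, p2 = rng.random(80), rng.random(80)
        res = CfdrModel(self._pairs(p1, p2), ld=None, config=CfdrConfig(n_iterations=1)).fit()
        np.testing.assert_allclose(res.cfdr_mean, empirical_cfdr(p1, p2, p1, p2), atol=0)
        assert (res.cfdr_sd == 0).all()

    def test_same_seed_bit_identical(self, small_study):
        pairs = small_study.harmonized()
        cfg = CfdrConfig(n_iterations=10, base_seed=99)
        r1 = CfdrModel(pairs, ld=small_study.ld, config=cfg).fit()
        r2 = CfdrModel(pairs, ld=small_study.ld, config=cfg).fit()
        np.testing.assert_array_equal(r1.cfdr_mean, r2.cfdr_mean)
        np.testing.assert_array_equal(r1.cfdr_sd, r2.cfdr_sd)

    def test_different_seed_differs(self, small_study):
        pairs = small_study.harmonized()
        r1 = CfdrModel(pairs, ld=small_study.ld, config=CfdrConfig(n_iterations=5, base_seed=1)).fit()
        r2 = CfdrModel(pairs, ld=small_study.ld, config=CfdrConfig(n_iterations=5, base_seed=2)).fit()
        assert not np.array_equal(r1.cfdr_mean, r2.cfdr_mean)

    def test_estimates_bounded_in_unit_interval(self, small_study):
        res = CfdrModel(small_study.harmonized(), ld=small_study.ld, config=CfdrConfig(n_iterations=5)).fit()
        assert ((res.cfdr_mean >= 0) & (res.cfdr_mean <= 1)).all()
        assert (res.cfdr_sd >= 0).all()
        assert res.n_iterations_used == 5

    def test_uninformative_cond_monotonized_equals_bh(self):
        rng = np.random.default_rng(21)
        p1 = rng.random(200)
        pairs = self._pairs(p1, np.ones(200))
        cfg = CfdrConfig(n_iterations=1, monotonize=True, min_stratum_count=1)
        res = CfdrModel(pairs, ld=None, config=cfg).fit()
        np.testing.assert_allclose(res.cfdr_mean, bh_adjust(p1), rtol=1e-12)

    def test_uninformative_cond_selection_nested_in_bh(self):
        rng = np.random.default_rng(22)
        p1 = rng.random(500)
        pairs = self._pairs(p1, np.ones(500))
        res = CfdrModel(pairs, ld=None, config=CfdrConfig(n_iterations=1, min_stratum_count=1)).fit()
        sel_cfdr = set(np.flatnonzero(res.cfdr_mean < 0.05))
        sel_bh = set(np.flatnonzero(bh_adjust(p1) < 0.05))
        # raw thresholding selects a subset; monotonization recovers BH exactly
        assert sel_cfdr <= sel_bh

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CfdrConfig(n_iterations=0)
        with pytest.raises(ValueError):
            CfdrConfig(prune_r2=0.0)
        with pytest.raises(ValueError):
            CfdrModel(pd.DataFrame({"p_target": [], "p_cond": []}))

    def test_summary_mentions_key_quantities(self, small_study):
        res = CfdrModel(small_study.harmonized(), ld=small_study.ld, config=CfdrConfig(n_iterations=2)).fit()
        text = res.summary()
        assert "iterations used:       2" in text
        assert "variants:" in text
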