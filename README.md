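# pleiocfdr

Pleiotropy-informed GWAS discovery via the **conditional false discovery
rate** (cFDR): test the association of genetic variants with a target trait
while leveraging their association with a genetically related secondary
trait.  Built for analysts who have two (or three) GWAS summary-statistics
tables — a target scan, one or two conditioning scans, and optionally an
independent replication cohort — and want more discovered loci than the
target scan alone supports, with honest calibration diagnostics.

The per-variant estimate is the empirical two-trait FDR

    cFDR(p1, p2) = min(1, p1 · N(P2 ≤ p2) / N(P1 ≤ p1, P2 ≤ p2))

averaged over many random LD-pruning iterations (default 500, pruned at
r² < 0.2), where p1 is the target-trait p-value, p2 the conditioning-trait
p-value, and the counts run over the pruned reference pairs.  Downstream,
variants below a relaxed cFDR threshold are clumped at r² < 0.1, leads
within ±250 kb merge into loci (tiered at 5% / 10%), and new leads are
tested in a replication cohort with Benjamini–Hochberg adjustment and an
exact binomial enrichment-over-chance test.  Cross-trait diagnostics (fold
enrichment, genomic Spearman correlation over independent LD blocks, a
Huber-robust trend across candidate conditioning traits) quantify whether a
secondary trait is worth conditioning on.  A block-LD synthetic generator
with a four-groups shared/specific causal mixture makes every stage testable
without access-controlled cohort data.  See `docs/methods.md` for the model
and all numerical choices.

## Worked example

```python
from pleiocfdr import CfdrModel, CfdrConfig, SyntheticConfig, simulate_pair, tier_summary

study = simulate_pair(SyntheticConfig(pi_shared=0.10, pi_null=0.80,
                                      effect_sd_t1=5.0, effect_sd_t2=5.0, seed=8))
model = CfdrModel.from_tables(study.target, study.conditioning[0],
                              ld=study.ld, config=CfdrConfig(n_iterations=50, base_seed=1))
results = model.fit()
print(results.summary())
loci = results.loci(source="US")
print(tier_summary(loci))
```

prints

```
Conditional FDR results
=======================
variants:              5000
iterations used:       50
pruning r2 threshold:  0.2
min stratum count:     50
cFDR < 0.05:           383
cFDR < 0.10:           469
median cFDR:           0.8156
mean iteration SD:     0.03122
{'n_loci': 101, 'tier1': 75, 'tier2': 26, 'both_sources': 0, 'single_source': 101}
```

i.e. of 5,000 simulated variants, 383 fall below the 5% conditional FDR,
collapsing to 75 tier-1 loci (5% threshold) plus 26 more at the relaxed 10%
tier — in this configuration about a fifth more tier-1 loci than
Benjamini–Hochberg on the target p-values alone recovers (63 on the same
data), because shared causal blocks borrow strength from the conditioning
trait.  With real
tables the entry point is the same (`CfdrModel.from_tables`, or
`read_sumstats` + `harmonize_pair` for full control), with built-in
exclusion of the MHC and 8p23.1 complex-LD regions.

The same chain is scriptable from the shell:

```sh
pleiocfdr simulate --seed 7 --out sim/
pleiocfdr cfdr --target sim/target.tsv --cond sim/conditioning_0.tsv \
               --ld sim/ld.tsv --iterations 50 --seed 1 --out cfdr.tsv
pleiocfdr clump --cfdr-tsv cfdr.tsv --ld sim/ld.tsv --out loci.tsv
pleiocfdr replicate --loci loci.tsv --disc sim/target.tsv --rep sim/replication.tsv --out rep.tsv
```

or end-to-end from a YAML config via `pleiocfdr pipeline --config run.yaml`,
which writes per-stage TSVs plus a run-metadata JSON (config, seeds, input
checksums) sufficient to reproduce every output byte-for-byte.

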