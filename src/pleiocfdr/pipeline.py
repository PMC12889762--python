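"""End-to-end orchestration of the pleiotropy-informed GWAS pipeline.

One :func:`run_pipeline` call executes: harmonize each conditioning cohort
against the target -> apply exclusion regions -> (optional) 1-df p-value
recomputation -> per-cohort averaged conditional FDR -> per-cohort clumping
-> cross-cohort locus merging -> tier summary -> (optional) replication
lookup.  Every stage writes a TSV under the output directory, and a
run-metadata JSON records the config, seeds, input checksums and stage
timings so any run can be re-executed byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io as sio
from .cfdr import CfdrConfig, CfdrModel
from .cross_trait import block_spearman, fold_enrichment
from .ld import LDReference
from .loci import LocusConfig, clump, loci_frame, merge_loci, tier_summary
from .replication import lookup_replication
from .simulate import SyntheticConfig, simulate_pair

__all__ = ["PipelineConfig", "run_pipeline", "write_simulated_study", "load_config"]

log = logging.getLogger("pleiocfdr")


@dataclasses.dataclass
class PipelineConfig:
    """Structured pipeline settings (typically loaded from YAML)."""

    output_dir: str = "pleiocfdr_out"
    target: str | None = None
    conditioning: list = dataclasses.field(default_factory=list)
    labels: list = dataclasses.field(default_factory=list)
    replication: str | None = None
    ld_table: str | None = None
    exclusions_bed: str | None = None
    use_default_exclusions: bool = False
    blocks_bed: str | None = None
    recompute_1df: bool = False
    column_map: dict = dataclasses.field(default_factory=dict)
    cfdr: CfdrConfig = dataclasses.field(default_factory=CfdrConfig)
    locus: LocusConfig = dataclasses.field(default_factory=LocusConfig)
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        paths = [self.target, *self.conditioning]
        if self.replication:
            paths.append(self.replication)
        for p in (self.ld_table, self.exclusions_bed, self.blocks_bed):
            if p:
                paths.append(p)
        for p in paths:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"pipeline input not found: {p}")


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfdr_cfg = CfdrConfig(**raw.pop("cfdr", {}))
    locus_cfg = LocusConfig(**raw.pop("locus", {}))
    return PipelineConfig(cfdr=cfdr_cfg, locus=locus_cfg, **raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_record(cfg: PipelineConfig) -> dict:
    rec = dataclasses.asdict(cfg)
    return rec


def write_simulated_study(study, outdir) -> dict:
    """Write all simulator outputs in the canonical dialects; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"target": outdir / "target.tsv", "replication": outdir / "replication.tsv"}
    sio.write_sumstats(study.target, paths["target"])
    sio.write_sumstats(study.replication, paths["replication"])
    paths["conditioning"] = []
    for i, tab in enumerate(study.conditioning):
        p = outdir / f"conditioning_{i}.tsv"
        sio.write_sumstats(tab, p)
        paths["conditioning"].append(p)
    paths["truth"] = outdir / "truth.tsv"
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["blocks"] = outdir / "blocks.bed"
    study.blocks.to_bed(paths["blocks"])
    paths["ld"] = outdir / "ld.tsv"
    study.ld.to_table().to_csv(paths["ld"], sep="\t", index=False, float_format="%.17g")
    paths["config"] = outdir / "synthetic_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(study.config), fh, indent=2, sort_keys=True)
    return {k: (str(v) if not isinstance(v, list) else [str(x) for x in v]) for k, v in paths.items()}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full chain; returns a dict of output paths and summaries."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate_paths()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta: dict = {"config": _config_record(cfg), "stages": {}, "inputs": {}}
    outputs: dict = {}

    def timed(name):
        t0 = time.perf_counter()

        def done():
            meta["stages"][name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s finished in %.2fs", name, meta["stages"][name])

        return done

    for p in [cfg.target, *cfg.conditioning] + ([cfg.replication] if cfg.replication else []):
        meta["inputs"][str(p)] = _sha256(p)

    done = timed("read")
    target, rep_t = sio.read_sumstats(cfg.target, cfg.column_map or None)
    conds = [sio.read_sumstats(p, cfg.column_map or None)[0] for p in cfg.conditioning]
    labels = list(cfg.labels) or [f"cond{i}" for i in range(len(conds))]
    done()

    if cfg.recompute_1df:
        done = timed("recompute_1df")
        target, _ = sio.recompute_p_1df(target)
        done()

    exclusions = None
    if cfg.exclusions_bed:
        exclusions = sio.GenomicIntervals.from_bed(cfg.exclusions_bed)
    elif cfg.use_default_exclusions:
        exclusions = sio.DEFAULT_EXCLUSIONS

    ld = None
    if cfg.ld_table:
        tab = pd.read_csv(cfg.ld_table, sep="\t")
        ld = LDReference.from_table(target["variant_id"].tolist(), tab)

    all_leads = []
    per_cohort = {}
    for label, cond in zip(labels, conds):
        done = timed(f"cfdr[{label}]")
        pairs = sio.harmonize_pair(target, cond)
        pairs = sio.apply_exclusions(pairs, exclusions)
        sub_ld = ld.subset(pairs["variant_id"].to_numpy()) if ld is not None else None
        model = CfdrModel(pairs, ld=sub_ld, config=cfg.cfdr)
        res = model.fit()
        path = outdir / f"cfdr_{label}.tsv"
        res.to_tsv(path)
        outputs[f"cfdr_{label}"] = str(path)
        done()

        done = timed(f"enrich[{label}]")
        try:
            enr = fold_enrichment(pairs)
            per_cohort[label] = {"fold": enr.fold, "n_both": enr.n_both}
        except ValueError:
            per_cohort[label] = {"fold": None}
        if cfg.blocks_bed:
            blocks = sio.GenomicIntervals.from_bed(cfg.blocks_bed)
            bs = block_spearman(pairs, blocks)
            per_cohort[label]["rho"] = bs.rho
            per_cohort[label]["n_blocks"] = bs.n_blocks_used
        done()

        done = timed(f"clump[{label}]")
        clumps = clump(res.frame, sub_ld, cfg.locus)
        all_leads.extend((lead, members, label) for lead, members in clumps)
        done()

    done = timed("merge_loci")
    loci = merge_loci(all_leads, cfg.locus)
    ldf = loci_frame(loci)
    loci_path = outdir / "loci.tsv"
    ldf.to_csv(loci_path, sep="\t", index=False, float_format="%.17g")
    outputs["loci"] = str(loci_path)
    summary = tier_summary(loci, cfg.locus)
    pd.DataFrame([summary]).to_csv(outdir / "tier_summary.tsv", sep="\t", index=False)
    outputs["tier_summary"] = str(outdir / "tier_summary.tsv")
    done()

    if cfg.replication:
        done = timed("replication")
        rep_table, _ = sio.read_sumstats(cfg.replication, cfg.column_map or None)
        rep = lookup_replication(loci, target, rep_table)
        rep_path = outdir / "replication.tsv"
        rep.records.to_csv(rep_path, sep="\t", index=False, float_format="%.17g")
        outputs["replication"] = str(rep_path)
        b = rep.binomial
        pd.DataFrame(
            [{"k_success": b.k_success, "n_trials": b.n_trials, "p0": b.p0, "p_value": b.p_value}]
        ).to_csv(outdir / "replication_summary.tsv", sep="\t", index=False)
        outputs["replication_summary"] = str(outdir / "replication_summary.tsv")
        summary["replication"] = rep.summary()
        done()

    meta["tier_summary"] = {k: v for k, v in summary.items()}
    meta["cross_trait"] = per_cohort
    meta_path = outdir / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    outputs["run_metadata"] = str(meta_path)
    outputs["summary"] = summary
    return outputs
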