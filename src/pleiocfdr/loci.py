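"""Independent-locus identification: LD clumping and distance-based merging.

Variants passing the relaxed cFDR threshold are clumped around lead variants
at an r² threshold of 0.1; leads within ±250 kb of each other (single
linkage, so chains collapse) are merged into one locus represented by its
most significant lead.  Cross-analysis locus sets (e.g. conditioning on two
cohorts of the same secondary trait) are produced by pooling the per-analysis
leads and re-running the same merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDReference

__all__ = ["LocusConfig", "Locus", "clump", "merge_loci", "tier_summary", "loci_frame"]


@dataclass(frozen=True)
class LocusConfig:
    clump_r2: float = 0.1
    merge_window: int = 250_000
    tier1_threshold: float = 0.05
    tier2_threshold: float = 0.10

    def __post_init__(self):
        if not self.tier1_threshold < self.tier2_threshold:
            raise ValueError("tier1_threshold must be < tier2_threshold")
        if self.merge_window <= 0:
            raise ValueError("merge_window must be positive")


@dataclass
class Lead:
    """A clump: one independent lead variant plus its dependent members."""

    variant_id: str
    chrom: str
    pos: int
    cfdr: float
    p_target: float
    members: list = field(default_factory=list)  # (variant_id, pos) incl. the lead


@dataclass
class Locus:
    """An independent genomic region formed by merging nearby leads."""

    chrom: str
    start: int
    end: int
    lead_variant: str
    lead_value: float
    lead_pos: int
    lead_p_target: float
    member_variants: list
    tier: str
    sources: set


def clump(
    results: pd.DataFrame,
    ld: LDReference | None,
    config: LocusConfig | None = None,
) -> list[tuple[Lead, list]]:
    """Greedy LD clumping of cFDR results below the relaxed threshold.

    Variants are visited in ascending ``cfdr_mean`` (ties by ascending
    ``p_target``, then ``variant_id``); a variant becomes a lead iff its r²
    with every existing lead is strictly below ``clump_r2``, otherwise it
    joins the first lead (in creation order) with r² >= clump_r2.
    """
    config = config or LocusConfig()
    df = results[results["cfdr_mean"] < config.tier2_threshold]
    if not len(df):
        return []
    df = df.sort_values(["cfdr_mean", "p_target", "variant_id"], kind="mergesort")

    leads: list[Lead] = []
    for row in df.itertuples(index=False):
        assigned = None
        if ld is not None:
            for lead in leads:
                if ld.r2(row.variant_id, lead.variant_id) >= config.clump_r2:
                    assigned = lead
                    break
        if assigned is None:
            lead = Lead(
                variant_id=row.variant_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                cfdr=float(row.cfdr_mean),
                p_target=float(row.p_target),
                members=[(row.variant_id, int(row.pos))],
            )
            leads.append(lead)
        else:
            assigned.members.append((row.variant_id, int(row.pos)))
    return [(lead, lead.members) for lead in leads]


def merge_loci(
    leads: "list[tuple[Lead, list, str]]",
    config: LocusConfig | None = None,
) -> list[Locus]:
    """Single-linkage merge of leads within ``merge_window`` on a chromosome.

    The locus representative is the merged lead with the smallest cFDR (ties
    by p_target); locus start/end span all member variant positions; sources
    accumulate the contributing analysis labels; the tier is tier1 when the
    representative's cFDR is below ``tier1_threshold``, else tier2.

    Accepts either ``(lead, members, source_label)`` triples or
    :class:`Locus` objects (so re-merging a merged set is possible and
    idempotent).
    """
    config = config or LocusConfig()
    rows = []
    for item in leads:
        if isinstance(item, Locus):
            rows.append(
                dict(
                    chrom=item.chrom,
                    pos=item.lead_pos,
                    cfdr=item.lead_value,
                    p_target=item.lead_p_target,
                    variant_id=item.lead_variant,
                    members=list(item.member_variants),
                    span=(item.start, item.end),
                    sources=set(item.sources),
                )
            )
        else:
            lead, members, source = item
            rows.append(
                dict(
                    chrom=lead.chrom,
                    pos=lead.pos,
                    cfdr=lead.cfdr,
                    p_target=lead.p_target,
                    variant_id=lead.variant_id,
                    members=list(members),
                    span=(min(p for _, p in members), max(p for _, p in members)),
                    sources={source},
                )
            )
    if not rows:
        return []

    rows.sort(key=lambda r: (r["chrom"], r["pos"], r["variant_id"]))
    loci: list[Locus] = []
    group: list[dict] = []

    def flush(group: list[dict]) -> None:
        rep = min(group, key=lambda r: (r["cfdr"], r["p_target"], r["variant_id"]))
        members: list = []
        seen = set()
        for r in group:
            for mv in r["members"]:
                key = mv[0] if isinstance(mv, tuple) else mv
                if key not in seen:
                    seen.add(key)
                    members.append(mv)
        start = min(min(r["span"][0] for r in group), min(r["pos"] for r in group))
        end = max(max(r["span"][1] for r in group), max(r["pos"] for r in group))
        sources = set().union(*(r["sources"] for r in group))
        tier = "tier1" if rep["cfdr"] < config.tier1_threshold else "tier2"
        loci.append(
            Locus(
                chrom=group[0]["chrom"],
                start=start,
                end=end,
                lead_variant=rep["variant_id"],
                lead_value=rep["cfdr"],
                lead_pos=rep["pos"],
                lead_p_target=rep["p_target"],
                member_variants=members,
                tier=tier,
                sources=sources,
            )
        )

    for r in rows:
        if group and r["chrom"] == group[-1]["chrom"] and r["pos"] - group[-1]["pos"] <= config.merge_window:
            group.append(r)
        else:
            if group:
                flush(group)
            group = [r]
    if group:
        flush(group)
    return loci


def tier_summary(loci: list[Locus], config: LocusConfig | None = None) -> dict:
    """Counts per tier and per source combination."""
    config = config or LocusConfig()
    counts = {
        "n_loci": len(loci),
        "tier1": sum(1 for l in loci if l.tier == "tier1"),
        "tier2": sum(1 for l in loci if l.tier == "tier2"),
        "both_sources": sum(1 for l in loci if len(l.sources) > 1),
        "single_source": sum(1 for l in loci if len(l.sources) == 1),
    }
    return counts


def loci_frame(loci: list[Locus]) -> pd.DataFrame:
    """Tabular view: one row per locus, members as a comma-joined field."""
    return pd.DataFrame(
        {
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "lead_variant": [l.lead_variant for l in loci],
            "lead_cfdr": [l.lead_value for l in loci],
            "tier": [l.tier for l in loci],
            "sources": [",".join(sorted(l.sources)) for l in loci],
            "n_members": [len(l.member_variants) for l in loci],
            "members": [
                ",".join(m[0] if isinstance(m, tuple) else m for m in l.member_variants) for l in loci
            ],
        }
    )
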