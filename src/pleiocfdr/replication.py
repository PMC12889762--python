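"""Replication of new lead variants in an independent cohort.

For each lead variant the replication table is queried (after harmonizing to
the discovery allele frame): nominal replication is p < 0.05, FDR replication
is a Benjamini-Hochberg adjusted p < 0.05 across the tested leads, and
effect-direction consistency compares the sign of the discovery and
replication log odds ratios.  Whether more leads replicate nominally than
chance would allow is assessed with an exact one-sided binomial test against
a per-lead success probability equal to the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import harmonize_pair
from .loci import Locus

__all__ = ["ReplicationSummary", "BinomialTestResult", "lookup_replication", "bh_adjust", "binomial_enrichment"]


@dataclass
class BinomialTestResult:
    k_success: int
    n_trials: int
    p0: float
    p_value: float


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, scale by n/rank, enforce monotonicity by a cumulative
    minimum from the largest, cap at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_enrichment(k_success: int, n_trials: int, p0: float = 0.05) -> BinomialTestResult:
    """Exact one-sided (upper tail) binomial test: P(X >= k), X ~ Bin(n, p0)."""
    if not 0 <= k_success <= n_trials:
        raise ValueError("need 0 <= k_success <= n_trials")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    pv = stats.binomtest(k_success, n_trials, p0, alternative="greater").pvalue
    return BinomialTestResult(k_success, n_trials, p0, float(pv))


@dataclass
class ReplicationSummary:
    """Per-lead replication records plus the enrichment-over-chance test."""

    records: pd.DataFrame
    binomial: BinomialTestResult

    @property
    def n_tested(self) -> int:
        return self.binomial.n_trials

    @property
    def n_nominal(self) -> int:
        return self.binomial.k_success

    @property
    def n_fdr(self) -> int:
        return int((self.records["fdr_pass"] == True).sum())  # noqa: E712 - column holds pd.NA

    def summary(self) -> str:
        b = self.binomial
        return (
            f"Replication: {b.k_success}/{b.n_trials} leads at nominal p < {b.p0:g} "
            f"({self.n_fdr} past BH-FDR 5%); binomial enrichment p = {b.p_value:.2g}"
        )


def lookup_replication(
    leads: "list[Locus] | pd.DataFrame",
    disc_table: pd.DataFrame,
    rep_table: pd.DataFrame,
    alpha: float = 0.05,
) -> ReplicationSummary:
    """Test lead variants in an independent replication cohort.

    Parameters
    ----------
    leads
        Loci (or a frame with a ``lead_variant`` column) whose lead variants
        are tested.
    disc_table, rep_table
        Discovery and replication summary statistics; the replication table
        is harmonized to the discovery allele frame so effect directions are
        comparable.  Leads absent from the replication data are reported as
        missing and excluded from the binomial trial count.
    alpha
        Nominal significance level, also the binomial chance probability.

    Notes
    -----
    Strand-ambiguous (A/T, C/G) leads keep their p-value comparison but
    their ``direction_consistent`` field is left undetermined.
    """
    if isinstance(leads, pd.DataFrame):
        lead_ids = list(leads["lead_variant"])
    else:
        lead_ids = [l.lead_variant for l in leads]

    pairs = harmonize_pair(rep_table, disc_table, drop_mismatched=True)
    # frame: p_target/beta_target are the replication cohort's, in its own
    # allele frame; flip replication betas for allele-swapped records so both
    # cohorts are expressed on the discovery effect allele.
    rep_idx = pairs.set_index("variant_id")
    disc_idx = disc_table.set_index("variant_id")

    rows = []
    for vid in lead_ids:
        rec = {
            "variant_id": vid,
            "p_rep": np.nan,
            "beta_disc": np.nan,
            "beta_rep": np.nan,
            "direction_consistent": pd.NA,
            "missing": True,
        }
        if vid in disc_idx.index:
            rec["beta_disc"] = disc_idx.at[vid, "beta"]
        if vid in rep_idx.index:
            r = rep_idx.loc[vid]
            rec["missing"] = False
            rec["p_rep"] = r["p_target"]
            beta_rep = r["beta_target"]
            if r["alignment"] == "flipped":
                beta_rep = -beta_rep
            rec["beta_rep"] = beta_rep
            if (
                r["alignment"] in ("concordant", "flipped")
                and np.isfinite(beta_rep)
                and np.isfinite(rec["beta_disc"])
            ):
                rec["direction_consistent"] = bool(np.sign(beta_rep) == np.sign(rec["beta_disc"]))
        rows.append(rec)
    records = pd.DataFrame(rows)

    tested = ~records["missing"]
    records["p_rep_adj"] = np.nan
    if tested.any():
        records.loc[tested, "p_rep_adj"] = bh_adjust(records.loc[tested, "p_rep"].to_numpy())
    records["nominal_pass"] = (records["p_rep"] < alpha).astype(object)
    records["fdr_pass"] = (records["p_rep_adj"] < alpha).astype(object)
    records.loc[~tested, ["nominal_pass", "fdr_pass"]] = pd.NA

    k = int(records.loc[tested, "nominal_pass"].sum())
    n = int(tested.sum())
    binom = binomial_enrichment(k, n, alpha) if n > 0 else BinomialTestResult(0, 0, alpha, 1.0)
    return ReplicationSummary(records=records, binomial=binom)
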