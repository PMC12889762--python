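"""Reading, validation, harmonization and filtering of GWAS summary statistics.

Summary-statistics tables are plain :class:`pandas.DataFrame` objects with the
canonical columns ``variant_id, chrom, pos, effect_allele, other_allele, beta,
se, pvalue``.  Coordinates are 1-based inclusive (the GWAS convention);
interval files are BED, 0-based half-open, and printed genomic ranges such as
"chr6:25,119,106-33,854,733" are interpreted as 1-based inclusive and
converted on load.

Validation drops offending rows rather than failing: p-values outside (0, 1]
(exact zeros are floored, see :data:`P_FLOOR`), non-positive standard errors,
and duplicated variants.  The counts are returned in a :class:`ReadReport`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "P_FLOOR",
    "CANONICAL_COLUMNS",
    "ReadReport",
    "GenomicIntervals",
    "read_sumstats",
    "validate_sumstats",
    "write_sumstats",
    "recompute_p_1df",
    "harmonize_pair",
    "apply_exclusions",
]

#: Floor applied to p-values of exactly 0 so -log10 grids stay finite.
P_FLOOR = 1e-300

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
]

#: PLINK-association-style header accepted out of the box.
PLINK_COLUMN_MAP = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
}

_MANDATORY = ("variant_id", "chrom", "pos", "pvalue")

# Watson-Crick complement used for strand checks.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ReadReport:
    """Row-level accounting for one table read/validation pass."""

    n_input: int = 0
    n_valid: int = 0
    n_invalid_p: int = 0
    n_floored_p: int = 0
    n_invalid_se: int = 0
    n_duplicate: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_valid}/{self.n_input} rows kept "
            f"(invalid p: {self.n_invalid_p}, floored p: {self.n_floored_p}, "
            f"invalid se: {self.n_invalid_se}, duplicates: {self.n_duplicate})"
        )


class GenomicIntervals:
    """A disjoint set of genomic intervals, stored 0-based half-open.

    Overlapping or touching intervals on one chromosome are merged on
    construction, so membership queries and block assignment are well defined.
    """

    def __init__(self, intervals: "list[tuple[str, int, int]] | pd.DataFrame", merge: bool = True):
        if isinstance(intervals, pd.DataFrame):
            df = intervals[["chrom", "start", "end"]].copy()
        else:
            df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end (0-based half-open)")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        if merge and len(df):
            merged = []
            for chrom, grp in df.groupby("chrom", sort=True):
                cur_s, cur_e = None, None
                for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
                    if cur_s is None:
                        cur_s, cur_e = s, e
                    elif s <= cur_e:
                        cur_e = max(cur_e, e)
                    else:
                        merged.append((chrom, cur_s, cur_e))
                        cur_s, cur_e = s, e
                merged.append((chrom, cur_s, cur_e))
            df = pd.DataFrame(merged, columns=["chrom", "start", "end"])
        self.df = df

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_bed(cls, path) -> "GenomicIntervals":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"], comment="#"
        )
        return cls(df)

    @classmethod
    def from_ranges_1based(cls, ranges: list[tuple[str, int, int]]) -> "GenomicIntervals":
        """Build from 1-based inclusive ranges, e.g. printed genomic coordinates."""
        return cls([(c, s - 1, e) for c, s, e in ranges])

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def contains(self, chrom: np.ndarray, pos_1based: np.ndarray) -> np.ndarray:
        """Vectorized membership of 1-based positions; returns a boolean mask."""
        return self.assign(chrom, pos_1based) >= 0

    def assign(self, chrom: np.ndarray, pos_1based: np.ndarray) -> np.ndarray:
        """Index of the interval containing each position, or -1."""
        chrom = np.asarray(chrom, dtype=str)
        pos0 = np.asarray(pos_1based, dtype=np.int64) - 1  # to 0-based
        out = np.full(len(pos0), -1, dtype=np.int64)
        for c, grp in self.df.groupby("chrom", sort=False):
            m = chrom == c
            if not m.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = np.searchsorted(starts, pos0[m], side="right") - 1
            ok = (idx >= 0) & (pos0[m] < ends[np.clip(idx, 0, None)])
            sub = np.full(m.sum(), -1, dtype=np.int64)
            sub[ok] = grp.index.to_numpy()[idx[ok]]
            out[m] = sub
        return out

    def to_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


#: The complex-LD exclusion set applied before the conditional FDR fit:
#: the MHC on chromosome 6 and the 8p23.1 inversion region (GRCh37).
DEFAULT_EXCLUSIONS = GenomicIntervals.from_ranges_1based(
    [("6", 25_119_106, 33_854_733), ("8", 7_200_000, 12_500_000)]
)


def _normalize_chrom(c: pd.Series) -> pd.Series:
    return c.astype(str).str.replace("^chr", "", regex=True)


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, ReadReport]:
    """Enforce table invariants, dropping and counting offending rows.

    Rules: p = 0 is floored to :data:`P_FLOOR`; p outside (0, 1] is dropped;
    se <= 0 (when beta present) is dropped; duplicated
    (chrom, pos, effect_allele, other_allele) keep the smallest-p occurrence.
    """
    report = ReadReport(n_input=len(df))
    df = df.copy()

    p = pd.to_numeric(df["pvalue"], errors="coerce")
    floored = p == 0.0
    report.n_floored_p = int(floored.sum())
    p = p.where(~floored, P_FLOOR)
    bad_p = ~(p > 0) | (p > 1)
    report.n_invalid_p = int(bad_p.sum())
    df["pvalue"] = p
    df = df[~bad_p]

    if "se" in df.columns and df["se"].notna().any():
        se = pd.to_numeric(df["se"], errors="coerce")
        has_beta = df["beta"].notna() if "beta" in df.columns else pd.Series(False, index=df.index)
        bad_se = has_beta & ~(se > 0)
        report.n_invalid_se = int(bad_se.sum())
        df = df[~bad_se]

    key = ["chrom", "pos", "effect_allele", "other_allele"]
    key = [k for k in key if k in df.columns]
    df = df.sort_values("pvalue", kind="mergesort")
    dup = df.duplicated(subset=key, keep="first") | df.duplicated(subset=["variant_id"], keep="first")
    report.n_duplicate = int(dup.sum())
    df = df[~dup]

    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    report.n_valid = len(df)
    return df, report


def read_sumstats(path, column_map: dict[str, str] | None = None) -> tuple[pd.DataFrame, ReadReport]:
    """Read a tab/whitespace-delimited summary-statistics table.

    Parameters
    ----------
    path
        File path or file-like object with a header row.
    column_map
        Maps canonical names (``variant_id, chrom, pos, effect_allele,
        other_allele, beta, se, pvalue``) to the file's column names.  The
        canonical names themselves and PLINK-style ``SNP/CHR/BP/A1/A2/BETA/
        SE/P`` headers are recognized without a map.

    Returns
    -------
    (table, report)
        Validated table in canonical column order plus the drop accounting.

    Raises
    ------
    ValueError
        If a mandatory column is missing or no valid rows remain.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype={"variant_id": str}, float_precision="round_trip")
    cmap = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = cmap.get(canon)
        if src is None:
            if canon in raw.columns:
                src = canon
            elif PLINK_COLUMN_MAP[canon] in raw.columns:
                src = PLINK_COLUMN_MAP[canon]
            else:
                continue
        if src not in raw.columns:
            raise ValueError(f"column_map refers to missing column {src!r} for {canon!r}")
        rename[src] = canon
    df = raw.rename(columns=rename)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} not found in {path!r}")
    for col in ("effect_allele", "other_allele", "beta", "se"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    df["chrom"] = _normalize_chrom(df["chrom"])
    df["pos"] = pd.to_numeric(df["pos"]).astype(np.int64)
    for col in ("beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col].replace(".", np.nan), errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().replace({"NAN": np.nan, ".": np.nan})
    df, report = validate_sumstats(df)
    if not len(df):
        raise ValueError(f"no valid rows remain after validation of {path!r}")
    return df, report


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write the canonical dialect: tab-delimited, header, '.' for missing."""
    out = df[CANONICAL_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.17g")


def sumstats_roundtrip_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """True when two canonical tables are value-identical (read/write check)."""
    buf_a, buf_b = _io.StringIO(), _io.StringIO()
    write_sumstats(a, buf_a)
    write_sumstats(b, buf_b)
    return buf_a.getvalue() == buf_b.getvalue()


def recompute_p_1df(df: pd.DataFrame) -> tuple[pd.DataFrame, ReadReport]:
    """Recompute p-values as 1-df chi-square upper tails of (beta/se)^2.

    Used when the source association scan's p-values are deflated relative to
    the Wald statistic; rows with se = 0 or missing beta/se are dropped.
    """
    report = ReadReport(n_input=len(df))
    df = df.copy()
    ok = df["beta"].notna() & (df["se"] > 0)
    report.n_invalid_se = int((~ok).sum())
    df = df[ok].copy()
    z2 = (df["beta"] / df["se"]) ** 2
    df["pvalue"] = np.maximum(stats.chi2.sf(z2, df=1), P_FLOOR)
    report.n_valid = len(df)
    return df.reset_index(drop=True), report


def _alignment_flags(t: pd.DataFrame, c: pd.DataFrame) -> np.ndarray:
    """Per-row allele alignment: concordant / flipped / ambiguous / mismatched."""
    ta = t["effect_allele"].to_numpy(dtype=object)
    tb = t["other_allele"].to_numpy(dtype=object)
    ca = c["effect_allele"].to_numpy(dtype=object)
    cb = c["other_allele"].to_numpy(dtype=object)

    flags = np.full(len(t), "mismatched", dtype=object)

    def comp(x):
        return np.array([_COMPLEMENT.get(a, "?") if isinstance(a, str) else "?" for a in x], dtype=object)

    missing = pd.isna(ta) | pd.isna(tb) | pd.isna(ca) | pd.isna(cb)
    same = (ta == ca) & (tb == cb)
    swapped = (ta == cb) & (tb == ca)
    same_c = (comp(ta) == ca) & (comp(tb) == cb)
    swapped_c = (comp(ta) == cb) & (comp(tb) == ca)
    palindromic = np.array(
        [isinstance(a, str) and _COMPLEMENT.get(a) == b for a, b in zip(ta, tb)], dtype=bool
    )

    flags[same | same_c] = "concordant"
    flags[(swapped | swapped_c) & ~(same | same_c)] = "flipped"
    flags[palindromic & ~missing] = "ambiguous"
    # p-value-only records (no allele columns) are usable for (p1, p2) work
    flags[missing] = "concordant"
    return flags


def harmonize_pair(
    target: pd.DataFrame,
    cond: pd.DataFrame,
    drop_mismatched: bool = True,
) -> pd.DataFrame:
    """Pair target and conditioning tables variant-by-variant.

    The join is on ``variant_id``; when fewer than half of the IDs match, a
    positional (chrom, pos) join is used instead and flagged in the
    ``join_mode`` attribute.  Allele comparison (with strand complement) sets
    ``alignment`` per row: strand-ambiguous A/T and C/G variants are kept for
    p-value work but excluded by default from effect-direction comparisons
    (see ``direction_usable``); allele-mismatched records are dropped.

    Effect sizes stay in the target table's allele frame — the conditioning
    trait contributes only its p-value, so no sign flip is ever applied here.

    Returns a frame with columns ``variant_id, chrom, pos, p_target, p_cond,
    beta_target, se_target, alignment, direction_usable``.
    """
    t = target.set_index("variant_id", drop=False)
    c = cond.set_index("variant_id", drop=False)
    shared = t.index.intersection(c.index)
    join_mode = "variant_id"
    if len(shared) < 0.5 * min(len(t), len(c)):
        t2 = target.set_index(["chrom", "pos"], drop=False)
        c2 = cond.set_index(["chrom", "pos"], drop=False)
        shared2 = t2.index.intersection(c2.index)
        if len(shared2) > len(shared):
            t, c, shared, join_mode = t2, c2, shared2, "position"
    if len(shared) == 0:
        raise ValueError("no overlapping variants between target and conditioning tables")
    t = t.loc[shared]
    c = c.loc[shared]

    flags = _alignment_flags(t, c)
    out = pd.DataFrame(
        {
            "variant_id": t["variant_id"].to_numpy(),
            "chrom": t["chrom"].to_numpy(),
            "pos": t["pos"].to_numpy(),
            "p_target": t["pvalue"].to_numpy(),
            "p_cond": c["pvalue"].to_numpy(),
            "beta_target": t["beta"].to_numpy(),
            "se_target": t["se"].to_numpy(),
            "alignment": flags,
        }
    )
    out["direction_usable"] = out["alignment"] == "concordant"
    # 'flipped' records refer to the same alleles listed in the opposite order;
    # the target frame is authoritative, so they remain direction-usable.
    out.loc[out["alignment"] == "flipped", "direction_usable"] = True
    if drop_mismatched:
        out = out[out["alignment"] != "mismatched"]
    out.attrs["join_mode"] = join_mode
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def apply_exclusions(df: pd.DataFrame, regions: GenomicIntervals | None) -> pd.DataFrame:
    """Remove variants whose 1-based position falls inside any interval."""
    if regions is None or len(regions) == 0 or not len(df):
        return df.reset_index(drop=True)
    mask = regions.contains(df["chrom"].to_numpy(dtype=str), df["pos"].to_numpy())
    return df[~mask].reset_index(drop=True)
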