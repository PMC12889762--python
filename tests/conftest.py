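import io as _io

import numpy as np
import pandas as pd
import pytest

from pleiocfdr import SyntheticConfig, simulate_pair


def brute_force_cfdr(p1_ref, p2_ref, p1_eval, p2_eval, min_stratum_count=50, cap_at_one=True):
    """O(M*R) double-loop counting oracle for the conditional FDR estimate."""
    p1_ref = np.asarray(p1_ref, float)
    p2_ref = np.asarray(p2_ref, float)
    R = len(p1_ref)
    out = np.empty(len(p1_eval))
    p2_sorted = np.sort(p2_ref)
    for i, (p1, p2) in enumerate(zip(p1_eval, p2_eval)):
        n2 = int((p2_ref <= p2).sum())
        thr = p2
        if n2 < min_stratum_count:
            if R < min_stratum_count:
                thr = np.inf
            else:
                thr = p2_sorted[min_stratum_count - 1]
            n2 = int((p2_ref <= thr).sum())
        joint = int(((p1_ref <= p1) & (p2_ref <= thr)).sum())
        if joint == 0:
            out[i] = 1.0
        else:
            out[i] = p1 * n2 / joint
    if cap_at_one:
        out = np.minimum(out, 1.0)
    return out


def make_sumstats(rows, columns=None):
    """Build a canonical summary-statistics frame from short row tuples."""
    columns = columns or ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue"]
    return pd.DataFrame(rows, columns=columns)


@pytest.fixture
def tiny_table():
    return make_sumstats(
        [
            ("rs1", "1", 1000, "A", "G", 0.10, 0.05, 0.04),
            ("rs2", "1", 2000, "C", "T", -0.20, 0.05, 0.30),
            ("rs3", "2", 5000, "G", "A", 0.05, 0.05, 0.90),
        ]
    )


@pytest.fixture
def sumstats_file(tmp_path, tiny_table):
    path = tmp_path / "sumstats.tsv"
    tiny_table.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study shared across read-only tests."""
    return simulate_pair(SyntheticConfig(n_blocks=100, seed=42))
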