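"""Sparse pairwise-r² linkage-disequilibrium reference.

Stores a symmetric sparse map (variant_i, variant_j) -> r² restricted to
nearby pairs; an absent pair means r² = 0 and r²(i, i) = 1 implicitly.
Internally a CSR matrix over integer variant indices so the greedy pruning
and clumping kernels can walk neighbour lists directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["LDReference"]


class LDReference:
    def __init__(self, variant_ids: "list[str] | np.ndarray", matrix: sparse.csr_matrix):
        self.variant_ids = np.asarray(variant_ids, dtype=object)
        self.index = {v: i for i, v in enumerate(self.variant_ids)}
        m = sparse.csr_matrix(matrix, dtype=np.float64)
        m.setdiag(0)  # the diagonal is implicit
        m.eliminate_zeros()
        if (m != m.T).nnz:
            m = m.maximum(m.T)
        self.matrix = m

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_pairs(cls, variant_ids, pairs: "dict[tuple[str, str], float]") -> "LDReference":
        """Build from a {(id_i, id_j): r2} mapping (symmetrized)."""
        idx = {v: i for i, v in enumerate(variant_ids)}
        n = len(idx)
        rows, cols, vals = [], [], []
        for (a, b), r2 in pairs.items():
            if a == b:
                continue
            i, j = idx[a], idx[b]
            rows += [i, j]
            cols += [j, i]
            vals += [r2, r2]
        m = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        return cls(variant_ids, m)

    @classmethod
    def from_blocks(cls, variant_ids, block_index: np.ndarray, r2: float) -> "LDReference":
        """Exchangeable LD: every within-block pair has the same r², 0 across blocks."""
        block_index = np.asarray(block_index)
        n = len(block_index)
        rows, cols = [], []
        order = np.argsort(block_index, kind="stable")
        for _, members in pd.Series(order).groupby(block_index[order]):
            mem = members.to_numpy()
            if len(mem) < 2:
                continue
            ii, jj = np.meshgrid(mem, mem, indexing="ij")
            off = ii != jj
            rows.append(ii[off])
            cols.append(jj[off])
        if rows:
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            m = sparse.coo_matrix(
                (np.full(len(rows), r2), (rows, cols)), shape=(n, n)
            ).tocsr()
        else:
            m = sparse.csr_matrix((n, n))
        return cls(variant_ids, m)

    @classmethod
    def from_table(cls, variant_ids, table: pd.DataFrame) -> "LDReference":
        """Build from a long-format frame with columns id_a, id_b, r2."""
        return cls.from_pairs(
            variant_ids,
            {(a, b): float(r) for a, b, r in table[["id_a", "id_b", "r2"]].itertuples(index=False)},
        )

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.variant_ids)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return float(self.matrix[self.index[a], self.index[b]])

    def csr_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(indptr, indices, data) views for the numba kernels."""
        m = self.matrix
        return m.indptr.astype(np.int64), m.indices.astype(np.int64), m.data

    def subset(self, variant_ids) -> "LDReference":
        """Restrict to the given variants (order preserved)."""
        idx = np.array([self.index[v] for v in variant_ids], dtype=np.int64)
        return LDReference(variant_ids, self.matrix[idx][:, idx])

    def to_table(self) -> pd.DataFrame:
        coo = sparse.triu(self.matrix, k=1).tocoo()
        return pd.DataFrame(
            {
                "id_a": self.variant_ids[coo.row],
                "id_b": self.variant_ids[coo.col],
                "r2": coo.data,
            }
        )
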