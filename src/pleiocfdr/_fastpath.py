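"""Compiled inner loops: greedy LD pruning and 2D dominance counting.

The dominance counter answers, for every evaluation point, how many reference
pairs satisfy (p1_ref <= p1_eval, p2_ref <= t_eval) by a single sweep over the
reference sorted by p2 with a Fenwick tree over p1 ranks — O((M+R) log R)
instead of the O(M*R) double loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["greedy_keep", "prefix_dominance_counts"]


@njit(cache=True)
def greedy_keep(order, indptr, indices, data, r2_max):
    """Greedy independent-set pass over ``order``.

    A variant is kept iff its r² with every already-kept variant is < r2_max.
    ``indptr/indices/data`` are the CSR arrays of the symmetric r² matrix.
    """
    n = indptr.shape[0] - 1
    kept = np.zeros(n, dtype=np.bool_)
    for k in range(order.shape[0]):
        v = order[k]
        ok = True
        for e in range(indptr[v], indptr[v + 1]):
            if data[e] >= r2_max and kept[indices[e]]:
                ok = False
                break
        if ok:
            kept[v] = True
    return kept


@njit(cache=True)
def _fenwick_add(tree, i):
    i += 1
    while i < tree.shape[0]:
        tree[i] += 1
        i += i & (-i)


@njit(cache=True)
def _fenwick_prefix(tree, i):
    # sum of positions [0, i]
    s = 0
    i += 1
    while i > 0:
        s += tree[i]
        i -= i & (-i)
    return s


@njit(cache=True)
def prefix_dominance_counts(ref_p1_rank_by_p2, eval_prefix_len, eval_p1_count, eval_order):
    """Joint counts N(p1_ref <= p1_eval, p2-rank of ref < prefix_len).

    Parameters
    ----------
    ref_p1_rank_by_p2 : int64[R]
        For the reference sorted ascending by p2: the rank (0-based position
        in the p1-sorted reference) of each element's p1 value.
    eval_prefix_len : int64[M]
        Per eval point, how many p2-sorted reference elements fall at or
        below its conditioning threshold.
    eval_p1_count : int64[M]
        Per eval point, count of reference p1 values <= its p1 (i.e. the
        exclusive upper rank bound for the Fenwick query).
    eval_order : int64[M]
        Eval indices sorted by ascending prefix_len (the sweep order).
    """
    R = ref_p1_rank_by_p2.shape[0]
    M = eval_prefix_len.shape[0]
    tree = np.zeros(R + 1, dtype=np.int64)
    out = np.zeros(M, dtype=np.int64)
    j = 0
    for k in range(M):
        i = eval_order[k]
        target = eval_prefix_len[i]
        while j < target:
            _fenwick_add(tree, ref_p1_rank_by_p2[j])
            j += 1
        q = eval_p1_count[i]
        if q > 0:
            out[i] = _fenwick_prefix(tree, q - 1)
    return out
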