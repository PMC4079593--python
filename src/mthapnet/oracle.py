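"""Exhaustive Steiner-tree reference for small haplotype instances.

Independent of the median-joining implementation: computes the exact minimal
connection length of a haplotype set under weighted Hamming distance by
Dreyfus–Wagner dynamic programming over the full product space of observed
per-column states (every vector in that space is a candidate Steiner point;
in the Hamming metric no other candidate can help).  Intended for validating
network construction on instances with a handful of haplotypes and variable
sites — the state space grows as the product of per-column state counts.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from .errors import InputError


def steiner_minimal_length(
    vectors: Sequence[Sequence[str]],
    weights: Sequence[int] | None = None,
    max_space: int = 20000,
) -> int:
    """Exact minimal total length of a Steiner tree connecting ``vectors``.

    ``weights``: per-column integer weights (default all 1).  Raises
    InputError when the candidate product space exceeds ``max_space``.
    """
    terms = sorted({tuple(v) for v in vectors})
    if not terms:
        raise InputError("no terminal vectors")
    if len(terms) == 1:
        return 0
    ncol = len(terms[0])
    if any(len(t) != ncol for t in terms):
        raise InputError("ragged state vectors")
    w = np.asarray(list(weights) if weights is not None else [1] * ncol,
                   dtype=np.int64)
    if len(w) != ncol:
        raise InputError("one weight per column required")

    col_states = [sorted({t[i] for t in terms}) for i in range(ncol)]
    space = 1
    for st in col_states:
        space *= len(st)
        if space > max_space:
            raise InputError(f"candidate space exceeds {max_space} vertices")

    verts = list(itertools.product(*col_states))
    index = {v: i for i, v in enumerate(verts)}
    V = len(verts)
    codes = np.empty((V, ncol), dtype=np.int16)
    for i, v in enumerate(verts):
        for c in range(ncol):
            codes[i, c] = col_states[c].index(v[c])

    dist = np.zeros((V, V), dtype=np.int64)
    for c in range(ncol):
        col = codes[:, c]
        dist += w[c] * (col[:, None] != col[None, :])

    t0 = index[terms[0]]
    others = [index[t] for t in terms[1:]]
    k = len(others)
    full = (1 << k) - 1

    D = {}
    for b, t in enumerate(others):
        D[1 << b] = dist[t].copy()
    for mask in sorted(range(1, full + 1), key=lambda m: m.bit_count()):
        if mask.bit_count() < 2:
            continue
        merged = np.full(V, np.iinfo(np.int64).max // 4, dtype=np.int64)
        low = mask & -mask
        sub = (mask - 1) & mask
        while sub:
            if sub & low:  # canonical half of each partition
                np.minimum(merged, D[sub] + D[mask ^ sub], out=merged)
            sub = (sub - 1) & mask
        D[mask] = (merged[:, None] + dist).min(axis=0)
    return int(D[full][t0])
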