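"""Independent brute-force oracles used to pin expected values.

Each oracle deliberately recomputes its quantity by a different route than
the implementation under test: exhaustive enumeration of nested structures,
anti-diagonal sums of a pair-compatibility matrix, pair-counting U
statistics, and naive sliding-window motif search.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}
MIN_HAIRPIN = 3


def enumerate_structures(seq: str, max_span: int | None = None) -> list[frozenset]:
    """All nested structures (sets of pairs) with hairpins >= 3, by explicit
    recursion over the leftmost base.  Feasible up to ~12 nt."""
    n = len(seq)
    span = max_span if max_span is not None else n

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple:
        if j - i <= 0:
            return (frozenset(),)
        out = list(structs(i + 1, j))
        for k in range(i + MIN_HAIRPIN + 1, min(j, i + span + 1)):
            if seq[i] + seq[k] in PAIRS:
                for left in structs(i + 1, k):
                    for right in structs(k + 1, j):
                        out.append(left | right | {(i, k)})
        return tuple(out)

    return list(structs(0, n))


def boltzmann_weights(structures, pair_weight: float) -> np.ndarray:
    return np.array([pair_weight ** len(s) for s in structures], dtype=float)


def exact_unpaired_by_enumeration(
    seq: str, pair_weight: float, max_span: int | None = None
) -> np.ndarray:
    structures = enumerate_structures(seq, max_span)
    w = boltzmann_weights(structures, pair_weight)
    z = w.sum()
    out = np.zeros(len(seq))
    for struct, weight in zip(structures, w):
        paired = {i for p in struct for i in p}
        for i in range(len(seq)):
            if i not in paired:
                out[i] += weight
    return out / z


def expected_intersite_pairs_by_enumeration(
    seq: str, a: tuple[int, int], b: tuple[int, int], pair_weight: float,
    max_span: int | None = None,
) -> float:
    """Boltzmann-expected number of pairs with one end in [a) and one in [b)."""
    structures = enumerate_structures(seq, max_span)
    w = boltzmann_weights(structures, pair_weight)
    counts = np.array(
        [
            sum(
                1
                for i, j in struct
                if (a[0] <= i < a[1] and b[0] <= j < b[1])
                or (b[0] <= i < b[1] and a[0] <= j < a[1])
            )
            for struct in structures
        ],
        dtype=float,
    )
    return float((counts * w).sum() / w.sum())


def revcomp_bp_by_antidiagonal(a: str, b: str) -> int:
    """Max base pairs over ungapped antiparallel registers = the maximal
    anti-diagonal sum of the pair-compatibility matrix M[i,j]."""
    m = np.array([[1 if a[i] + b[j] in PAIRS else 0 for j in range(len(b))] for i in range(len(a))])
    best = 0
    for c in range(len(a) + len(b) - 1):
        total = sum(m[i, c - i] for i in range(len(a)) if 0 <= c - i < len(b))
        best = max(best, int(total))
    return best


def mannwhitney_exact_by_value_assignment(x, y, direction: str) -> float:
    """Exact one-tailed Mann-Whitney p by enumerating which pooled VALUES go
    to x, with U computed by direct pair counting (wins + half-ties)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(xs, ys) -> float:
        return sum(
            1.0 if xv > yv else (0.5 if xv == yv else 0.0) for xv in xs for yv in ys
        )

    u_obs = u_of(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(u_of(xs, ys))
    us = np.array(us)
    if direction == "less":
        return float(np.mean(us <= u_obs + 1e-9))
    return float(np.mean(us >= u_obs - 1e-9))


def naive_scan(seq: str, kmers: list[str]) -> set[tuple[int, int]]:
    """O(len * k * |kmers|) sliding-window exact-match positions."""
    hits = set()
    for kmer in kmers:
        k = len(kmer)
        for pos in range(len(seq) - k + 1):
            if seq[pos : pos + k] == kmer:
                hits.add((pos, pos + k))
    return hits


def bh_by_hand(p: list[float]) -> list[float]:
    """q_i = min over j with p_j >= p_i of p_(j) * m / rank(j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        q[i] = min(
            min(p[order[r]] * m / (r + 1) for r in range(pos, m)), 1.0
        )
    return q
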