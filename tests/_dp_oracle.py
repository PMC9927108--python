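"""Independent exact dynamic-programming alignment oracle for tests.

A plain Smith-Waterman local aligner (match +1, mismatch -1, gap -2) with
full traceback, jit-compiled with numba. It shares no code with the
package's infix-alignment identity estimator and serves as the reference
for identity/coverage values and for a brute-force re-simulation of the
greedy dereplication rule.
"""

from __future__ import annotations

import numba
import numpy as np

_MATCH, _MISMATCH, _GAP = 1, -1, -2


@numba.njit(cache=True)
def _sw_stats(q: np.ndarray, t: np.ndarray) -> tuple[int, int, int]:
    """Best local alignment of q in t; returns (matches, columns, target_span)."""
    n, m = len(q), len(t)
    h = np.zeros((n + 1, m + 1), dtype=np.int16)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = _MATCH if qi == t[j - 1] else _MISMATCH
            v = h[i - 1, j - 1] + s
            v2 = h[i - 1, j] + _GAP
            v3 = h[i, j - 1] + _GAP
            if v2 > v:
                v = v2
            if v3 > v:
                v = v3
            if v < 0:
                v = 0
            h[i, j] = v
            if v > best:
                best, bi, bj = v, i, j
    i, j = bi, bj
    matches, cols = 0, 0
    while i > 0 and j > 0 and h[i, j] > 0:
        s = _MATCH if q[i - 1] == t[j - 1] else _MISMATCH
        if h[i, j] == h[i - 1, j - 1] + s:
            if q[i - 1] == t[j - 1]:
                matches += 1
            cols += 1
            i -= 1
            j -= 1
        elif h[i, j] == h[i - 1, j] + _GAP:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return matches, cols, bj - j


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def dp_ani(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Exact-DP identity and coverage with the package's conventions:
    identity = matches / alignment columns, coverage = aligned span of
    the longer sequence / its length."""
    if len(seq_a) <= len(seq_b):
        query, target = seq_a, seq_b
    else:
        query, target = seq_b, seq_a
    matches, cols, span = _sw_stats(_encode(query), _encode(target))
    if cols == 0:
        return 0.0, 0.0
    return matches / cols, span / len(target)


def greedy_dereplicate_oracle(
    contigs: dict[str, str], identity_thr: float = 0.95, coverage_thr: float = 0.70
) -> dict[str, list[str]]:
    """Brute-force simulation of greedy longest-first centroid clustering
    using the exact-DP aligner. Returns centroid -> member list."""
    order = sorted(contigs, key=lambda c: (-len(contigs[c]), c))
    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for cid in order:
        for rep in centroids:
            ident, cov = dp_ani(contigs[cid], contigs[rep])
            if ident >= identity_thr and cov >= coverage_thr:
                members[rep].append(cid)
                break
        else:
            centroids.append(cid)
            members[cid] = [cid]
    return members
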