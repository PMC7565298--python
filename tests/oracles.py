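"""Independent brute-force / closed-form oracles used by the tests.

Everything here is deliberately naive: exhaustive enumeration and
direct formula transcription, sharing no code paths with the package
implementations they check (the duplex oracle shares only the structure
scorer, which the DP tests exercise separately against hand sums).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from smoltmir.energy import DEFAULT_MODEL
from smoltmir.targets import score_structure

RNA_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def brute_force_duplex_mfe(window: str, mirna: str, max_bulge: int = 9, max_internal: int = 9,
                           require_helix: tuple[int, int] | None = None) -> float:
    """Enumerate every antiparallel pairing, score each, return the minimum.

    Partial pairings that already violate pairability or loop limits are
    pruned (appending pairs never repairs an earlier violation).
    """
    m, L = len(mirna), len(window)
    best = math.inf

    def rec(pairs: list[tuple[int, int]], i_min: int, j_max: int) -> None:
        nonlocal best
        for i in range(i_min, m + 1):
            for j in range(1, j_max + 1):
                cand = pairs + [(i, j)]
                try:
                    e = score_structure(cand, mirna, window, DEFAULT_MODEL, max_bulge, max_internal)
                except ValueError:
                    continue
                if _helix_ok(cand, require_helix) and e < best:
                    best = e
                rec(cand, i + 1, j - 1)

    rec([], 1, L)
    return best


def _helix_ok(pairs: list[tuple[int, int]], constraint: tuple[int, int] | None) -> bool:
    if constraint is None:
        return True
    lo, hi = constraint
    sub = {i: j for i, j in pairs if lo <= i <= hi}
    if set(sub) != set(range(lo, hi + 1)):
        return False
    return all(sub[i + 1] == sub[i] - 1 for i in range(lo, hi))


def naive_seed_scan(utr: str, mirna: str) -> list[int]:
    """Sliding 7-mer window, base-by-base Watson-Crick comparison."""
    seed = mirna[1:8]  # positions 2-8, 0-based slice
    out = []
    for start in range(len(utr) - 6):
        window = utr[start : start + 7]
        # antiparallel: seed position 2 pairs the last window base
        if all(RNA_COMP[s] == w for s, w in zip(seed, reversed(window))):
            out.append(start + 1)
    return out


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Literal step-up definition: padj_(i) = min_{j>=i} min(1, m*p_(j)/j)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for rank_idx in range(m):
        candidates = [min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_idx, m)]
        adj_sorted[rank_idx] = min(candidates)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def hypergeom_upper_tail_enum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws (N <= 12)."""
    population = list(range(N))
    successes = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(population, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def naive_trim(read: str, adapter: str, min_overlap: int) -> str | None:
    """Leftmost position where a >=min_overlap adapter prefix matches."""
    for p in range(len(read)):
        L = min(len(adapter), len(read) - p)
        if L < min_overlap:
            break
        if read[p : p + L] == adapter[:L]:
            return read[:p]
    return None


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
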