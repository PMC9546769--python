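"""Independent brute-force oracles used to validate the implementations.

These deliberately re-derive each statistic by exhaustive enumeration or
direct simulation; they never call the code paths they check.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np


def brute_force_match(umi: str, upstream: str, max_m: int, motif: str,
                      spacer: str = "CTAAC",
                      adjacent_only: bool = False) -> Optional[int]:
    """Enumerate every (mismatch level, offset) pair explicitly."""
    tail = {"none": "", "GGG": "GGG", "spacer_ggg": spacer + "GGG"}[motif]
    for m in range(max_m + 1):
        query = umi[m:] + tail
        if not query:
            continue
        offsets = ([len(upstream) - len(query)] if adjacent_only
                   else range(len(upstream) - len(query) + 1))
        for off in offsets:
            if off >= 0 and upstream[off:off + len(query)] == query:
                return m
    return None


def brute_force_r1_match(seq: str, adapter: str, spacer: str, anchor: str,
                         min_suffix: int) -> Optional[tuple[int, str]]:
    """Enumerate every admissible adapter suffix length explicitly,
    longest first; return (suffix_len, umi) or None."""
    for L in range(len(adapter), min_suffix - 1, -1):
        prefix = adapter[len(adapter) - L:]
        need = L + 8 + len(spacer) + len(anchor)
        if len(seq) < need or not seq.startswith(prefix):
            continue
        if seq[L + 8:need] == spacer + anchor:
            return L, seq[L:L + 8]
    return None


def kendall_tau_b(x, y) -> float:
    """O(n^2) pair enumeration with the tie-corrected tau-b denominator."""
    x = list(x)
    y = list(y)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif (dx > 0) == (dy > 0):
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def monte_carlo_match_probability(m: int, motif_len: int = 0,
                                  n_draws: int = 200_000, seed: int = 0,
                                  window: int = 20, umi_len: int = 8
                                  ) -> float:
    """Direct simulation of the random-match null: probability that a
    uniform random (umi_len - m + motif_len)-mer occurs in a uniform random
    window."""
    rng = np.random.default_rng(seed)
    L = umi_len - m + motif_len
    bases = np.array(list("ACGT"))
    hits = 0
    for _ in range(n_draws):
        query = "".join(bases[rng.integers(0, 4, L)])
        win = "".join(bases[rng.integers(0, 4, window)])
        if query in win:
            hits += 1
    return hits / n_draws


def monte_carlo_filter_null(max_m: int, n_draws: int = 200_000,
                            seed: int = 0) -> float:
    """Probability that a random UMI matches a random window at any level
    <= max_m (motif-free), by direct simulation."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    hits = 0
    for _ in range(n_draws):
        umi = "".join(bases[rng.integers(0, 4, 8)])
        win = "".join(bases[rng.integers(0, 4, 20)])
        if brute_force_match(umi, win, max_m, "none") is not None:
            hits += 1
    return hits / n_draws


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
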