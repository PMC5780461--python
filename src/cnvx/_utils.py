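"""Shared helpers: seed derivation, interval arithmetic, multiple testing."""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests


def derive_seed(seed: int, *labels: str) -> int:
    """Derive a stable per-stage child seed from a global seed.

    Uses SHA-256 over ``"<seed>:<label>:..."`` so every stage gets an
    independent, reproducible stream regardless of call order. The result
    fits in a signed 32-bit integer.
    """
    key = ":".join([str(int(seed)), *labels]).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Interval arithmetic (0-based, half-open throughout)
# ---------------------------------------------------------------------------

def overlap_len(s1: int, e1: int, s2: int, e2: int) -> int:
    """Length of the overlap between [s1,e1) and [s2,e2)."""
    return max(0, min(e1, e2) - max(s1, s2))


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted, disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in ivs if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_len(ivs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))


def intersect_len(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> int:
    """Total bp shared by two interval sets (each merged internally first)."""
    am, bm = merge_intervals(a), merge_intervals(b)
    i = j = 0
    shared = 0
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if e > s:
            shared += e - s
        if am[i][1] < bm[j][1]:
            i += 1
        else:
            j += 1
    return shared
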