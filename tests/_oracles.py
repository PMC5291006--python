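"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-box double loops, dict-based
k-mer counting, hand recursion) and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def naive_box_masses(img: np.ndarray, b: int) -> list[float]:
    """Mass of every fully contained b x b box, one explicit slice at a time."""
    h, w = img.shape
    return [
        float(img[i : i + b, j : j + b].sum())
        for i in range(h - b + 1)
        for j in range(w - b + 1)
    ]


def naive_lacunarity(img: np.ndarray, b: int) -> float:
    """Lambda(b) = Z2/Z1^2 computed from the explicit per-box mass list."""
    masses = np.array(naive_box_masses(img, b))
    z1 = masses.mean()
    z2 = (masses ** 2).mean()
    return z2 / z1 ** 2


def naive_kmer_counts(symbols: str, L: int) -> dict[str, int]:
    """Plain sliding-window k-mer counting for pure sequences."""
    counts: dict[str, int] = {}
    for i in range(len(symbols) - L + 1):
        kmer = symbols[i : i + L]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def quadrant_position(s: str) -> tuple[int, int]:
    """Recursive quadrant addressing with M1 = [[a, c], [g, t]], done by
    explicit interval halving rather than bit arithmetic."""
    top = {"a", "c"}
    left = {"a", "g"}
    r0, r1 = 0, 2 ** len(s)
    c0, c1 = 0, 2 ** len(s)
    for ch in s:
        rm, cm = (r0 + r1) // 2, (c0 + c1) // 2
        if ch in top:
            r1 = rm
        else:
            r0 = rm
        if ch in left:
            c1 = cm
        else:
            c0 = cm
    assert r1 - r0 == 1 and c1 - c0 == 1
    return r0, c0
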