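"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and scipy's peak
machinery) so that agreement between them and the implementation is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# peak detection


def bf_local_maxima(x: np.ndarray) -> list[int]:
    """All local maxima; a flat-topped run counts once at its middle sample."""
    out = []
    i, n = 1, len(x)
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def bf_prominence(x: np.ndarray, p: int) -> float:
    """Topographic prominence: height above the higher of the two flanking bases."""
    left_min = x[p]
    for j in range(p - 1, -1, -1):
        if x[j] > x[p]:
            break
        left_min = min(left_min, x[j])
    right_min = x[p]
    for j in range(p + 1, len(x)):
        if x[j] > x[p]:
            break
        right_min = min(right_min, x[j])
    return x[p] - max(left_min, right_min)


def bf_select_by_distance(x: np.ndarray, cand: list[int], min_distance: int) -> list[int]:
    """Keep the higher of any two maxima closer than min_distance."""
    keep = {p: True for p in cand}
    for p in sorted(cand, key=lambda p: -x[p]):
        if not keep[p]:
            continue
        for q in cand:
            if q != p and keep[q] and abs(q - p) < min_distance:
                keep[q] = False
    return [p for p in cand if keep[p]]


def bf_detect_peaks(
    x: np.ndarray,
    prominence_frac: float = 0.05,
    min_distance: int = 3,
    min_height: float = 1000.0,
) -> list[int]:
    """Exhaustive peak finder: maxima -> height filter -> distance -> prominence."""
    x = np.asarray(x, dtype=float)
    if x.size == 0 or x.max() <= 0:
        return []
    cand = [p for p in bf_local_maxima(x) if x[p] >= min_height]
    cand = bf_select_by_distance(x, cand, min_distance)
    pmin = x.max() * prominence_frac
    return [p for p in cand if bf_prominence(x, p) >= pmin]


# ---------------------------------------------------------------------------
# alignment paths


def bf_enumerate(peak_lists: list[list[float]]) -> list[tuple]:
    """Recursive enumeration of all missing-augmented paths (minus all-missing)."""
    def rec(i: int) -> list[tuple]:
        if i == len(peak_lists):
            return [()]
        tails = rec(i + 1)
        out = []
        for head in list(peak_lists[i]) + [None]:
            out.extend((head, *t) for t in tails)
        return out
    return [p for p in rec(0) if any(e is not None for e in p)]


def bf_stats(path: tuple, threshold: float) -> tuple[float, float, float]:
    present = [e for e in path if e is not None]
    n, m = len(path), len(present)
    mean = float(np.sum(present)) / m
    var = (float(np.sum((np.asarray(present) - mean) ** 2)) + (n - m) * threshold**2) / n
    return mean, var, 1.0 / (var + 1.0)


def bf_select(peak_lists: list[list[float]], threshold: float) -> list[tuple]:
    """Repeated max-scan selection with the same deterministic tie-breaks."""
    paths = bf_enumerate(peak_lists)
    remaining = {(i, a) for i, lst in enumerate(peak_lists) for a in lst}
    chosen = []
    while remaining:
        best = None
        best_key = None
        for p in paths:
            mean, var, score = bf_stats(p, threshold)
            m = sum(e is not None for e in p)
            key = (-score, -m, mean, tuple(math.inf if e is None else e for e in p))
            if best_key is None or key < best_key:
                best, best_key = p, key
        chosen.append(best)
        used = {(i, e) for i, e in enumerate(best) if e is not None}
        remaining -= used
        paths = [
            p for p in paths
            if not used & {(i, e) for i, e in enumerate(p) if e is not None}
        ]
    return chosen
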