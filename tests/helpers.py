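"""Independent brute-force oracles shared by unit and acceptance tests.

Everything here is deliberately naive (exhaustive enumeration, direct
formula evaluation) and shares no code path with the implementation it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def circular_diff_oracle(a: float, b: float) -> float:
    """min(|a−b| mod 360, 360 − |a−b| mod 360) evaluated literally."""
    d = abs((a % 360.0) - (b % 360.0))
    return min(d, 360.0 - d)


def mcq_oracle(diffs) -> float:
    """Direct circular mean of differences via component sums."""
    s = sum(math.sin(math.radians(d)) for d in diffs)
    c = sum(math.cos(math.radians(d)) for d in diffs)
    return math.degrees(math.atan2(s, c))


def lcs_length_oracle(s: str, t: str) -> int:
    """Longest common subsequence length by exhaustive enumeration."""
    best = 0
    for r in range(min(len(s), len(t)), 0, -1):
        for sub in itertools.combinations(s, r):
            if _is_subsequence(sub, t):
                return r
    return best


def _is_subsequence(sub, t) -> bool:
    it = iter(t)
    return all(ch in it for ch in sub)


def lcs_ta_oracle(sin_sums, cos_sums, counts, runs, threshold):
    """Longest segment with pooled MCQ <= threshold over all O(n^2) windows.

    ``runs`` lists [start, stop) index ranges that are contiguous in both
    chains; per-position component sums are given.  Returns the best
    (length, mcq, start) with ties broken by smaller MCQ then leftmost.
    """
    best = (0, float("nan"), None)
    for lo, hi in runs:
        for start in range(lo, hi):
            for stop in range(start + 1, hi + 1):
                n = int(np.sum(counts[start:stop]))
                if n == 0:
                    continue
                s = float(np.sum(sin_sums[start:stop]))
                c = float(np.sum(cos_sums[start:stop]))
                if math.hypot(s, c) < 1e-12:
                    continue
                val = math.degrees(math.atan2(s, c))
                if val > threshold:
                    continue
                length = stop - start
                if length > best[0] or (
                    length == best[0] and best[2] is not None and val < best[1] - 1e-12
                ):
                    best = (length, val, start)
    return best


def pam_brute_force(d: np.ndarray, k: int) -> float:
    """Optimal k-medoid cost by exhaustive search over all medoid sets."""
    n = len(d)
    best = math.inf
    for medoids in itertools.combinations(range(n), k):
        cost = float(d[:, list(medoids)].min(axis=1).sum())
        best = min(best, cost)
    return best


def random_euclidean_matrix(rng: np.random.Generator, n: int):
    """Exactly-Euclidean distance matrix from random planar points."""
    pts = rng.uniform(-5.0, 5.0, size=(n, 2))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return pts, d
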