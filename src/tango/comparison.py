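"""Torsion-space comparison of a model against a target.

The elementary quantity is the circular difference

    Δ(a, b) = min(|a − b|, 360° − |a − b|)  ∈ [0°, 180°]

and differences are aggregated with the Mean of Circular Quantities

    MCQ(D) = atan2( Σ_{d∈D} sin d,  Σ_{d∈D} cos d )

which stays in [0°, 180°] because every d is.  The MCQ can be pooled over
the whole structure (global), restricted to one residue (per-residue heat
map rows), or to any subset of angle kinds.  LCS-TA searches for the
longest run of consecutively paired residues whose pooled MCQ stays at or
below a threshold, by binary search on the segment length with a sliding
window over prefix sums of (sin d, cos d).

Residues of target and model are paired by the longest common subsequence
of their one-letter sequences (case-insensitive, so modified residues are
matched via their parent letter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .torsion_core import AngleKind, ResidueTorsions

__all__ = [
    "DEFAULT_ANGLES",
    "SEVERITY_BINS",
    "AngleDifference",
    "McqValue",
    "LcsSegment",
    "PerResidueMcq",
    "angle_diff",
    "mcq",
    "severity_bin",
    "pair_residues",
    "per_residue_mcq",
    "global_mcq",
    "coverage_fractions",
    "lcs_ta",
]

#: Default comparison set: the six backbone torsions plus the glycosidic χ.
DEFAULT_ANGLES: tuple[AngleKind, ...] = (
    AngleKind.alpha, AngleKind.beta, AngleKind.gamma, AngleKind.delta,
    AngleKind.epsilon, AngleKind.zeta, AngleKind.chi,
)

#: Severity bands for per-residue MCQ heat maps: [0,15), [15,30), [30,60), [60,180].
SEVERITY_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 15.0, "0-15"),
    (15.0, 30.0, "15-30"),
    (30.0, 60.0, "30-60"),
    (60.0, 180.0, ">60"),
)


def _check_selection(sel: Sequence[AngleKind]) -> tuple[AngleKind, ...]:
    sel = tuple(sel)
    if not sel:
        raise ConfigError("angle selection must be non-empty")
    if AngleKind.pseudorotation in sel:
        raise ConfigError(
            "the pseudorotation phase is derived from nu0-nu4 and is not a "
            "torsion; it cannot enter MCQ sums"
        )
    return sel


@dataclass(frozen=True)
class AngleDifference:
    kind: Optional[AngleKind]
    delta: float  # degrees in [0, 180]; NaN = undefined

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.delta))


@dataclass(frozen=True)
class McqValue:
    degrees: float  # in [0, 180]; NaN = undefined
    n_terms: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.degrees))


@dataclass(frozen=True)
class PerResidueMcq:
    target_position: int  # 0-based position in the target torsion list
    model_position: Optional[int]  # None if the target residue is unpaired
    mcq: McqValue
    severity: Optional[str]


@dataclass(frozen=True)
class LcsSegment:
    target_start: Optional[int]  # 0-based target position, None if length 0
    model_start: Optional[int]
    length: int
    mcq: McqValue


def angle_diff(a: float, b: float, kind: Optional[AngleKind] = None) -> AngleDifference:
    """Minimum circular difference of two angles in degrees."""
    if a is None or b is None or not (np.isfinite(a) and np.isfinite(b)):
        return AngleDifference(kind, float("nan"))
    d = abs(a % 360.0 - b % 360.0)
    return AngleDifference(kind, min(d, 360.0 - d))


def _mcq_from_sums(s: float, c: float, n: int) -> McqValue:
    if n == 0 or math.hypot(s, c) < 1e-12:
        return McqValue(float("nan"), n)
    return McqValue(math.degrees(math.atan2(s, c)), n)


def mcq(diffs: Sequence) -> McqValue:
    """MCQ over angular differences (floats in degrees or AngleDifference).

    Undefined differences are skipped; ``n_terms`` counts only the defined
    ones.  With zero defined terms the result is undefined.
    """
    vals = []
    for d in diffs:
        v = d.delta if isinstance(d, AngleDifference) else float(d)
        if np.isfinite(v):
            vals.append(v)
    if not vals:
        return McqValue(float("nan"), 0)
    rad = np.radians(np.asarray(vals))
    return _mcq_from_sums(float(np.sin(rad).sum()), float(np.cos(rad).sum()), len(vals))


def severity_bin(mcq_degrees: float) -> Optional[str]:
    """Severity band of a per-residue MCQ value; None when undefined."""
    if not np.isfinite(mcq_degrees):
        return None
    for lo, hi, label in SEVERITY_BINS:
        if lo <= mcq_degrees < hi or (label == ">60" and mcq_degrees >= lo):
            return label
    return None


# ---------------------------------------------------------------------------
# Residue pairing (longest common subsequence)

def pair_residues(target_seq: str, model_seq: str) -> list[tuple[int, int]]:
    """Longest common subsequence pairing of two sequences.

    Letters are compared case-insensitively (modified residues carry
    lowercase parent letters).  Among co-optimal tracebacks the
    leftmost-in-target, then leftmost-in-model solution is returned.
    An empty pairing (no common letter) is a valid result.
    """
    s = target_seq.upper()
    t = model_seq.upper()
    n, m = len(s), len(t)
    # L[i][j] = LCS length of suffixes s[i:], t[j:]
    L = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if s[i] == t[j]:
                L[i, j] = L[i + 1, j + 1] + 1
            else:
                L[i, j] = max(L[i + 1, j], L[i, j + 1])
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m and L[i, j] > 0:
        if s[i] == t[j] and L[i, j] == L[i + 1, j + 1] + 1:
            pairs.append((i, j))
            i += 1
            j += 1
        elif L[i, j + 1] == L[i, j]:
            j += 1  # keep the earliest target index available
        else:
            i += 1
    return pairs


# ---------------------------------------------------------------------------
# MCQ scopes

def _pair_sums(
    target: Sequence[ResidueTorsions],
    model: Sequence[ResidueTorsions],
    pairing: Sequence[tuple[int, int]],
    sel: Sequence[AngleKind],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair (Σ sin Δ, Σ cos Δ, count) over defined selected differences."""
    sel = _check_selection(sel)
    k = len(pairing)
    s = np.zeros(k)
    c = np.zeros(k)
    n = np.zeros(k, dtype=int)
    for idx, (ti, mi) in enumerate(pairing):
        for kind in sel:
            d = angle_diff(target[ti].get(kind), model[mi].get(kind)).delta
            if np.isfinite(d):
                r = math.radians(d)
                s[idx] += math.sin(r)
                c[idx] += math.cos(r)
                n[idx] += 1
    return s, c, n


def per_residue_mcq(
    target: Sequence[ResidueTorsions],
    model: Sequence[ResidueTorsions],
    pairing: Sequence[tuple[int, int]],
    sel: Sequence[AngleKind] = DEFAULT_ANGLES,
) -> list[PerResidueMcq]:
    """One MCQ (and severity band) per target residue.

    Unpaired target residues are reported with an undefined MCQ so heat-map
    rows keep the full target length.
    """
    s, c, n = _pair_sums(target, model, pairing, sel)
    by_target = {ti: (mi, idx) for idx, (ti, mi) in enumerate(pairing)}
    rows: list[PerResidueMcq] = []
    for ti in range(len(target)):
        if ti in by_target:
            mi, idx = by_target[ti]
            value = _mcq_from_sums(s[idx], c[idx], int(n[idx]))
            rows.append(PerResidueMcq(ti, mi, value, severity_bin(value.degrees)))
        else:
            rows.append(PerResidueMcq(ti, None, McqValue(float("nan"), 0), None))
    return rows


def global_mcq(
    target: Sequence[ResidueTorsions],
    model: Sequence[ResidueTorsions],
    pairing: Sequence[tuple[int, int]],
    sel: Sequence[AngleKind] = DEFAULT_ANGLES,
) -> McqValue:
    """MCQ pooled over all defined differences of all paired residues.

    This pools the set of differences directly — it is *not* the average of
    per-residue MCQ values.
    """
    s, c, n = _pair_sums(target, model, pairing, sel)
    return _mcq_from_sums(float(s.sum()), float(c.sum()), int(n.sum()))


def coverage_fractions(
    rows: Sequence[PerResidueMcq],
    thresholds: Sequence[float] = (15.0, 30.0, 60.0),
) -> tuple[list[float], int]:
    """Fraction of defined per-residue MCQs strictly below each threshold.

    Returns ``(fractions, n_defined)``; fractions are NaN when no residue
    has a defined MCQ.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ConfigError("thresholds must be sorted ascending")
    vals = np.asarray([r.mcq.degrees for r in rows if r.mcq.defined])
    if vals.size == 0:
        return [float("nan")] * len(thresholds), 0
    return [float(np.mean(vals < t)) for t in thresholds], int(vals.size)


# ---------------------------------------------------------------------------
# LCS-TA

def lcs_ta(
    target: Sequence[ResidueTorsions],
    model: Sequence[ResidueTorsions],
    pairing: Sequence[tuple[int, int]],
    sel: Sequence[AngleKind] = DEFAULT_ANGLES,
    threshold: float = 15.0,
) -> LcsSegment:
    """Longest continuous segment with pooled MCQ ≤ ``threshold``.

    Only runs of pairing positions consecutive in *both* chains count as
    continuous.  Candidate lengths are probed with a sliding window whose
    pooled MCQ comes from prefix sums of (sin Δ, cos Δ): a binary search on
    the length finds a feasible segment quickly, and because the circular
    mean of a window is not strictly monotone in its length (a window can
    satisfy the threshold while its sub-windows do not), any lengths above
    the binary-search result are then verified by a descending sweep, so the
    returned length always equals the exhaustive optimum.  Ties between
    equal-length segments are broken by smaller MCQ, then leftmost position.
    Returns a zero-length segment when no single residue qualifies.
    """
    if threshold <= 0:
        raise ConfigError("LCS-TA threshold must be positive")
    s, c, n = _pair_sums(target, model, pairing, sel)
    # Split the pairing into maximal runs consecutive in both chains.
    runs: list[tuple[int, int]] = []  # [start, stop) indices into pairing
    start = 0
    for idx in range(1, len(pairing)):
        t_prev, m_prev = pairing[idx - 1]
        t_cur, m_cur = pairing[idx]
        if t_cur != t_prev + 1 or m_cur != m_prev + 1:
            runs.append((start, idx))
            start = idx
    if pairing:
        runs.append((start, len(pairing)))

    ps = np.concatenate([[0.0], np.cumsum(s)])
    pc = np.concatenate([[0.0], np.cumsum(c)])
    pn = np.concatenate([[0], np.cumsum(n)])

    def best_window(length: int) -> Optional[tuple[float, int]]:
        """Best (mcq, pairing start index) over windows of exactly `length`."""
        best: Optional[tuple[float, int]] = None
        for lo, hi in runs:
            if hi - lo < length:
                continue
            starts = np.arange(lo, hi - length + 1)
            sw = ps[starts + length] - ps[starts]
            cw = pc[starts + length] - pc[starts]
            nw = pn[starts + length] - pn[starts]
            with np.errstate(invalid="ignore"):
                vals = np.degrees(np.arctan2(sw, cw))
            ok = (nw > 0) & (np.hypot(sw, cw) >= 1e-12) & (vals <= threshold)
            if not ok.any():
                continue
            vals = np.where(ok, vals, np.inf)
            w = int(np.argmin(vals))  # smallest MCQ, leftmost on ties
            if best is None or vals[w] < best[0] - 1e-12:
                best = (float(vals[w]), int(starts[w]))
        return best

    max_len = max((hi - lo for lo, hi in runs), default=0)
    lo_len, hi_len = 1, max_len
    found: Optional[tuple[int, float, int]] = None  # (length, mcq, start)
    while lo_len <= hi_len:
        mid = (lo_len + hi_len) // 2
        hit = best_window(mid)
        if hit is not None:
            found = (mid, hit[0], hit[1])
            lo_len = mid + 1
        else:
            hi_len = mid - 1
    # Non-monotone feasibility: sweep the lengths the binary search skipped.
    floor = found[0] if found else 0
    for length in range(max_len, floor, -1):
        hit = best_window(length)
        if hit is not None:
            found = (length, hit[0], hit[1])
            break
    if found is None:
        return LcsSegment(None, None, 0, McqValue(float("nan"), 0))
    length, value, w = found
    cnt = int(pn[w + length] - pn[w])
    ti, mi = pairing[w]
    return LcsSegment(ti, mi, length, McqValue(value, cnt))
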