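"""Torsion and pseudo-torsion angles, sugar pucker, and glycosidic state.

A nucleotide is described by six backbone torsions (α, β, γ, δ, ε, ζ), the
glycosidic torsion χ, five endocyclic ribose torsions ν0–ν4, and four
pseudo-torsions (η, θ, η′, θ′) defined over non-bonded P / C4' / C1' atoms
of adjacent residues.  The five ν angles are summarized by the
pseudorotation phase

    P = atan2( (ν4 + ν1) − (ν3 + ν0),  2·ν2·(sin 36° + sin 72°) )

normalized into [0°, 360°).  P = 0° is the C2'-exo-C3'-endo twist, and every
18° sector corresponds to a named envelope or twist conformation
(P = 90° → O4'-endo, P = 270° → O4'-exo).

Undefined quantities (chain termini, breaks, missing atoms, degenerate
geometry) are represented as NaN degrees rather than exceptions, so one bad
residue never aborts a whole-structure run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .model import NucleicChain, Residue

__all__ = [
    "AngleKind",
    "ResidueTorsions",
    "dihedral",
    "dihedrals",
    "residue_torsions",
    "chain_torsions",
    "pseudorotation",
    "pucker_name",
    "classify_glycosidic",
    "wrap_half",
    "wrap_full",
]


class AngleKind(Enum):
    """The 17 angular quantities computed per residue."""

    alpha = "alpha"
    beta = "beta"
    gamma = "gamma"
    delta = "delta"
    epsilon = "epsilon"
    zeta = "zeta"
    chi = "chi"
    nu0 = "nu0"
    nu1 = "nu1"
    nu2 = "nu2"
    nu3 = "nu3"
    nu4 = "nu4"
    eta = "eta"
    theta = "theta"
    eta_prime = "eta_prime"
    theta_prime = "theta_prime"
    pseudorotation = "P"

    @property
    def symbol(self) -> str:
        return _SYMBOLS[self]


_SYMBOLS = {
    AngleKind.alpha: "α", AngleKind.beta: "β", AngleKind.gamma: "γ",
    AngleKind.delta: "δ", AngleKind.epsilon: "ε", AngleKind.zeta: "ζ",
    AngleKind.chi: "χ", AngleKind.nu0: "ν0", AngleKind.nu1: "ν1",
    AngleKind.nu2: "ν2", AngleKind.nu3: "ν3", AngleKind.nu4: "ν4",
    AngleKind.eta: "η", AngleKind.theta: "θ", AngleKind.eta_prime: "η′",
    AngleKind.theta_prime: "θ′", AngleKind.pseudorotation: "P",
}

#: Torsion kinds (everything except the derived pseudorotation phase).
TORSION_KINDS = tuple(k for k in AngleKind if k is not AngleKind.pseudorotation)

_NU_KINDS = (AngleKind.nu0, AngleKind.nu1, AngleKind.nu2, AngleKind.nu3, AngleKind.nu4)


def wrap_half(x):
    """Wrap degrees into (−180, 180]."""
    x = np.asarray(x, dtype=float)
    out = -((-x + 180.0) % 360.0 - 180.0)
    out = np.where(out == -180.0, 180.0, out)
    return out if out.ndim else float(out)


def wrap_full(x):
    """Wrap degrees into [0, 360)."""
    x = np.asarray(x, dtype=float)
    out = x % 360.0
    return out if out.ndim else float(out)


def dihedrals(quads: np.ndarray) -> np.ndarray:
    """Dihedral angles for an array of atom quadruples.

    Parameters
    ----------
    quads : ndarray, shape (..., 4, 3)
        Coordinates of the four points of each quadruple.  NaN coordinates
        propagate to a NaN angle.

    Returns
    -------
    ndarray of degrees in (−180, 180], NaN where degenerate (coincident
    central atoms or collinear triples).

    The sign follows the IUPAC convention: looking from the second atom
    toward the third, a clockwise rotation of the far bond is positive.
    """
    quads = np.asarray(quads, dtype=float)
    b1 = quads[..., 1, :] - quads[..., 0, :]
    b2 = quads[..., 2, :] - quads[..., 1, :]
    b3 = quads[..., 3, :] - quads[..., 2, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.einsum("...i,...i->...", n1, n2)
        b2_len = np.linalg.norm(b2, axis=-1)
        y = np.einsum("...i,...i->...", np.cross(n1, b2), n2) / b2_len
        ang = np.degrees(np.arctan2(y, x))
        # Degeneracy: zero-length central bond or collinear triples.
        s1 = np.linalg.norm(n1, axis=-1) / np.maximum(
            np.linalg.norm(b1, axis=-1) * b2_len, 1e-300
        )
        s2 = np.linalg.norm(n2, axis=-1) / np.maximum(
            b2_len * np.linalg.norm(b3, axis=-1), 1e-300
        )
        bad = (b2_len < 1e-9) | (s1 < 1e-9) | (s2 < 1e-9)
    ang = np.where(bad, np.nan, ang)
    ang = np.where(ang == -180.0, 180.0, ang)
    return ang


def dihedral(a, b, c, d) -> float:
    """Dihedral angle (degrees) of four points; NaN if degenerate."""
    quad = np.stack([np.asarray(p, dtype=float) for p in (a, b, c, d)])
    return float(dihedrals(quad))


# ---------------------------------------------------------------------------
# Pseudorotation and pucker naming

_SIN36_SIN72 = math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))

# Envelope names at the odd 18°-sector centers of the pseudorotation wheel.
_ENVELOPES = {
    18: "C3'-endo", 54: "C4'-exo", 90: "O4'-endo", 126: "C1'-exo",
    162: "C2'-endo", 198: "C3'-exo", 234: "C4'-endo", 270: "O4'-exo",
    306: "C1'-endo", 342: "C2'-exo",
}


def pucker_name(p_degrees: float) -> Optional[str]:
    """Name the 18°-wide pseudorotation sector containing ``p_degrees``.

    Odd sectors (centers 18°, 54°, ...) are envelopes; even sectors are the
    twists named after their two flanking envelopes, e.g. P = 0° lies in the
    C2'-exo-C3'-endo twist sector.
    """
    if p_degrees is None or not np.isfinite(p_degrees):
        return None
    sector = int(round(wrap_full(p_degrees) / 18.0)) % 20
    center = sector * 18
    if sector % 2 == 1:
        return _ENVELOPES[center]
    prev_env = _ENVELOPES[(center - 18) % 360]
    next_env = _ENVELOPES[(center + 18) % 360]
    return f"{prev_env}-{next_env}"


def pseudorotation(nu: Sequence[float]) -> tuple[float, Optional[str]]:
    """Pseudorotation phase P (degrees in [0, 360)) and pucker name.

    ``nu`` holds ν0–ν4 in degrees.  Returns ``(nan, None)`` if any ν is
    undefined or the ring is essentially flat (numerator and denominator
    both ≈ 0); the two-argument arctangent keeps the ν2 ≤ 0 half of the
    wheel in the correct quadrant.
    """
    nu = [float(v) for v in nu]
    if len(nu) != 5:
        raise ValueError("pseudorotation requires exactly five nu angles")
    if any(not np.isfinite(v) for v in nu):
        return float("nan"), None
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = 2.0 * nu[2] * _SIN36_SIN72
    if math.hypot(num, den) < 1e-9:
        return float("nan"), None
    p = wrap_full(math.degrees(math.atan2(num, den)))
    return p, pucker_name(p)


def classify_glycosidic(chi: float) -> str:
    """``syn`` iff χ ∈ (−90°, 90°], ``anti`` otherwise, ``undefined`` on NaN."""
    if chi is None or not np.isfinite(chi):
        return "undefined"
    c = wrap_half(chi)
    return "syn" if -90.0 < c <= 90.0 else "anti"


# ---------------------------------------------------------------------------
# Per-residue angle computation

@dataclass
class ResidueTorsions:
    """The full angular record of one residue.

    ``angles`` maps every :class:`AngleKind` to degrees (NaN = undefined).
    ``residue`` may be None for synthetic torsion tables used in
    comparison-only workflows.
    """

    angles: dict[AngleKind, float]
    residue: Optional[Residue] = None
    pucker: Optional[str] = None
    glycosidic: str = "undefined"

    def get(self, kind: AngleKind) -> float:
        return self.angles.get(kind, float("nan"))

    def defined(self, kind: AngleKind) -> bool:
        return bool(np.isfinite(self.get(kind)))


# Atom quadruples for intra-residue torsions: (name, residue offset).
_INTRA_QUADS = {
    AngleKind.beta: (("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0)),
    AngleKind.gamma: (("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0)),
    AngleKind.delta: (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)),
    AngleKind.nu0: (("C4'", 0), ("O4'", 0), ("C1'", 0), ("C2'", 0)),
    AngleKind.nu1: (("O4'", 0), ("C1'", 0), ("C2'", 0), ("C3'", 0)),
    AngleKind.nu2: (("C1'", 0), ("C2'", 0), ("C3'", 0), ("C4'", 0)),
    AngleKind.nu3: (("C2'", 0), ("C3'", 0), ("C4'", 0), ("O4'", 0)),
    AngleKind.nu4: (("C3'", 0), ("C4'", 0), ("O4'", 0), ("C1'", 0)),
}

# Inter-residue quadruples with (need_prev, need_next) break requirements.
_INTER_QUADS = {
    AngleKind.alpha: ((("O3'", -1), ("P", 0), ("O5'", 0), ("C5'", 0)), True, False),
    AngleKind.epsilon: ((("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1)), False, True),
    AngleKind.zeta: ((("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1)), False, True),
    AngleKind.eta: ((("C4'", -1), ("P", 0), ("C4'", 0), ("P", 1)), True, True),
    AngleKind.theta: ((("P", 0), ("C4'", 0), ("P", 1), ("C4'", 1)), False, True),
    AngleKind.eta_prime: ((("C1'", -1), ("P", 0), ("C1'", 0), ("P", 1)), True, True),
    AngleKind.theta_prime: ((("P", 0), ("C1'", 0), ("P", 1), ("C1'", 1)), False, True),
}

_BACKBONE_NAMES = ("P", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'", "C2'", "O4'")


def chain_torsions(chain: NucleicChain) -> list[ResidueTorsions]:
    """Compute every angle for every residue of ``chain`` (vectorized)."""
    n = len(chain)
    if n == 0:
        return []
    coords: dict[str, np.ndarray] = {}
    for name in _BACKBONE_NAMES:
        arr = np.full((n, 3), np.nan)
        for i, res in enumerate(chain.residues):
            pos = res.coord(name)
            if pos is not None:
                arr[i] = pos
        coords[name] = arr

    # Glycosidic quadruple end atoms depend on the base class.
    gl_n = np.full((n, 3), np.nan)
    gl_c = np.full((n, 3), np.nan)
    for i, res in enumerate(chain.residues):
        cls = res.base_class
        if cls == "purine":
            nn, cc = res.coord("N9"), res.coord("C4")
        elif cls == "pyrimidine":
            nn, cc = res.coord("N1"), res.coord("C2")
        else:
            nn = cc = None
        if nn is not None:
            gl_n[i] = nn
        if cc is not None:
            gl_c[i] = cc

    def shifted(name: str, offset: int) -> np.ndarray:
        arr = coords[name]
        out = np.full_like(arr, np.nan)
        if offset == 0:
            return arr
        if offset > 0:
            out[:-offset] = arr[offset:]
        else:
            out[-offset:] = arr[:offset]
        return out

    break_after = np.zeros(n, dtype=bool)
    for b in chain.breaks:
        if 0 <= b < n:
            break_after[b] = True
    prev_ok = np.zeros(n, dtype=bool)
    prev_ok[1:] = ~break_after[:-1]
    # next_ok[i]: residue i+1 exists and no break between i and i+1
    next_ok = np.zeros(n, dtype=bool)
    next_ok[:-1] = ~break_after[:-1]

    values: dict[AngleKind, np.ndarray] = {}
    for kind, quad in _INTRA_QUADS.items():
        pts = np.stack([shifted(nm, off) for nm, off in quad], axis=1)
        values[kind] = dihedrals(pts)
    for kind, (quad, need_prev, need_next) in _INTER_QUADS.items():
        pts = np.stack([shifted(nm, off) for nm, off in quad], axis=1)
        vals = dihedrals(pts)
        mask = np.ones(n, dtype=bool)
        if need_prev:
            mask &= prev_ok
        if need_next:
            mask &= next_ok
        values[kind] = np.where(mask, vals, np.nan)
    chi_pts = np.stack([coords["O4'"], coords["C1'"], gl_n, gl_c], axis=1)
    values[AngleKind.chi] = dihedrals(chi_pts)

    out: list[ResidueTorsions] = []
    for i, res in enumerate(chain.residues):
        angles = {kind: float(values[kind][i]) for kind in values}
        p, name = pseudorotation([angles[k] for k in _NU_KINDS])
        angles[AngleKind.pseudorotation] = p
        out.append(
            ResidueTorsions(
                angles=angles,
                residue=res,
                pucker=name,
                glycosidic=classify_glycosidic(angles[AngleKind.chi]),
            )
        )
    return out


def residue_torsions(chain: NucleicChain, i: int) -> ResidueTorsions:
    """Angular record for residue ``i`` (0-based) of ``chain``."""
    if not 0 <= i < len(chain):
        raise IndexError(f"residue index {i} outside chain of length {len(chain)}")
    return chain_torsions(chain)[i]
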