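"""Synthetic polynucleotide construction from prescribed torsion angles.

Chains are grown atom by atom with natural-extension (NeRF) placement:
each new atom is positioned from three predecessors using an ideal bond
length, an ideal bond angle, and the prescribed dihedral, so every
prescribed backbone/glycosidic torsion is realized exactly (to float
precision) regardless of the bond-geometry constants.

The ribose ring cannot carry five prescribed torsions with rigid ideal
bonds and angles (a closed 5-ring with fixed lengths and angles is
overdetermined), so the sugar pucker is prescribed through the standard
cosine model ν_j = τm·cos(P + 144°·(j−2)): the ring is solved by
least-squares adjustment of in-plane vertex angles and out-of-plane
displacements until the measured ν angles match the model, with soft
restraints keeping bond lengths near their ideal values.  The solved ring
is rigidly attached to the backbone about the shared C3'–C4' bond, a move
that leaves all endocyclic torsions invariant.

Fixtures built here are geometrically self-consistent, not energetically
plausible — which is all that round-trip testing of the angle machinery
requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from io import StringIO
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
import biotite.structure.io.pdbx as _pdbx

from .errors import BuildError, ConfigError, EmptyStructureError, FormatError
from .model import Atom, NucleicChain, Residue, StructureModel
from .torsion_core import AngleKind, dihedral, dihedrals, wrap_half

__all__ = [
    "TorsionPrescription",
    "build_chain",
    "perturb",
    "write_structure",
    "random_prescription",
]

# Ideal bond lengths (Å) and angles (degrees) from standard nucleic-acid
# geometry; small deviations are irrelevant because NeRF realizes the
# prescribed dihedrals exactly for any such constants.
BOND_LENGTHS = {
    ("O3'", "P"): 1.607,
    ("P", "O5'"): 1.593,
    ("O5'", "C5'"): 1.440,
    ("C5'", "C4'"): 1.510,
    ("C3'", "O3'"): 1.423,
    ("C2'", "O2'"): 1.413,
    ("C1'", "N"): 1.470,
    ("N9", "C4"): 1.374,
    ("N9", "C8"): 1.372,
    ("N1", "C2"): 1.383,
    ("N1", "C6"): 1.367,
}
RING_BONDS = {
    ("C1'", "C2'"): 1.528,
    ("C2'", "C3'"): 1.525,
    ("C3'", "C4'"): 1.524,
    ("C4'", "O4'"): 1.453,
    ("O4'", "C1'"): 1.414,
}
BOND_ANGLES = {
    ("C3'", "O3'", "P"): 119.7,
    ("O3'", "P", "O5'"): 104.0,
    ("P", "O5'", "C5'"): 120.9,
    ("O5'", "C5'", "C4'"): 111.5,
    ("C5'", "C4'", "C3'"): 115.5,
    ("C4'", "C3'", "O3'"): 110.6,
    ("C3'", "C2'", "O2'"): 110.0,
    ("O4'", "C1'", "N"): 108.2,
    ("C1'", "N9", "C4"): 126.0,
    ("C1'", "N9", "C8"): 127.0,
    ("C1'", "N1", "C2"): 117.5,
    ("C1'", "N1", "C6"): 121.0,
}

# Fixed placement constants (degrees) for atoms whose torsion is not part of
# a prescription: they only set plausible substituent directions.
_TORSION_C2_OFFSET = -122.6  # dihedral(C5',C4',C3',C2') relative to delta
_TORSION_O2 = -120.0         # dihedral(C4',C3',C2',O2')
_TORSION_N = -120.0          # dihedral(C4',O4',C1',N)

_PRESCRIBED = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")

_RES_NAMES = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "DT"}


@dataclass
class TorsionPrescription:
    """Per-residue target torsions for a synthetic chain.

    All angle arrays have one entry per residue, in degrees.  ``alpha[0]``
    and the last ``epsilon``/``zeta`` entries are geometrically unused (the
    corresponding angles are undefined at the termini).  The sugar pucker is
    prescribed as a pseudorotation phase ``pucker_phase`` (degrees, [0,360))
    and amplitude ``pucker_amplitude`` (τm, degrees).
    """

    sequence: str
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    epsilon: np.ndarray
    zeta: np.ndarray
    chi: np.ndarray
    pucker_phase: np.ndarray
    pucker_amplitude: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ConfigError("prescription sequence must be non-empty")
        bad = set(self.sequence.upper()) - set("ACGUT")
        if bad:
            raise ConfigError(f"unsupported sequence letters: {sorted(bad)}")
        for name in _PRESCRIBED + ("pucker_phase", "pucker_amplitude"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape == ():
                arr = np.full(n, float(arr))
            if arr.shape != (n,):
                raise ConfigError(f"{name} must have one value per residue")
            setattr(self, name, arr)

    @classmethod
    def uniform(
        cls,
        sequence: str,
        *,
        alpha: float = -68.0,
        beta: float = 178.0,
        gamma: float = 54.0,
        delta: float = 82.0,
        epsilon: float = -153.0,
        zeta: float = -71.0,
        chi: float = -158.0,
        pucker_phase: float = 13.0,
        pucker_amplitude: float = 38.0,
    ) -> "TorsionPrescription":
        """A-form-helix-like prescription with every residue identical."""
        n = len(sequence)
        return cls(
            sequence=sequence,
            **{
                name: np.full(n, val)
                for name, val in [
                    ("alpha", alpha), ("beta", beta), ("gamma", gamma),
                    ("delta", delta), ("epsilon", epsilon), ("zeta", zeta),
                    ("chi", chi), ("pucker_phase", pucker_phase),
                    ("pucker_amplitude", pucker_amplitude),
                ]
            },
        )

    def copy(self) -> "TorsionPrescription":
        return replace(
            self,
            **{
                name: np.array(getattr(self, name))
                for name in _PRESCRIBED + ("pucker_phase", "pucker_amplitude")
            },
        )

    def kind_array(self, kind: AngleKind) -> np.ndarray:
        if kind.name not in _PRESCRIBED:
            raise ConfigError(f"{kind.name} is not a prescribable torsion")
        return getattr(self, kind.name)


def random_prescription(
    n_residues: int,
    rng: np.random.Generator,
    sequence: Optional[str] = None,
) -> TorsionPrescription:
    """Uniformly random prescription: torsions in (−180°, 180°], phase in
    [0°, 360°), amplitude in [35°, 45°] — the study conditions for the
    round-trip tests, covering the entire torsion space."""
    if sequence is None:
        sequence = "".join(rng.choice(list("ACGU"), size=n_residues))
    angles = {
        name: wrap_half(rng.uniform(-180.0, 180.0, size=n_residues))
        for name in _PRESCRIBED
    }
    return TorsionPrescription(
        sequence=sequence,
        pucker_phase=rng.uniform(0.0, 360.0, size=n_residues),
        pucker_amplitude=rng.uniform(35.0, 45.0, size=n_residues),
        **angles,
    )


# ---------------------------------------------------------------------------
# Geometry primitives

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C so that angle(B,C,D) = ``angle_deg`` and
    dihedral(A,B,C,D) = ``torsion_deg`` exactly."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _unit(c - b)
    nrm = _unit(np.cross(b - a, bc))
    m = np.cross(nrm, bc)
    d_local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor),
         -bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * nrm


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    cth, sth = math.cos(angle_rad), math.sin(angle_rad)
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + sth * k + (1 - cth) * (k @ k)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector ``u`` onto unit vector ``v``."""
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180° about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return _rotation_about(_unit(perp), math.pi)
    axis = _unit(np.cross(u, v))
    return _rotation_about(axis, math.acos(max(-1.0, min(1.0, c))))


# ---------------------------------------------------------------------------
# Ribose ring solver

_RING_ORDER = ("C1'", "C2'", "C3'", "C4'", "O4'")
# nu quadruples as indices into _RING_ORDER
_NU_IDX = (
    (3, 4, 0, 1),  # nu0: C4'-O4'-C1'-C2'
    (4, 0, 1, 2),  # nu1: O4'-C1'-C2'-C3'
    (0, 1, 2, 3),  # nu2: C1'-C2'-C3'-C4'
    (1, 2, 3, 4),  # nu3: C2'-C3'-C4'-O4'
    (2, 3, 4, 0),  # nu4: C3'-C4'-O4'-C1'
)
_RING_BOND_TARGETS = np.array(
    [RING_BONDS[("C1'", "C2'")], RING_BONDS[("C2'", "C3'")],
     RING_BONDS[("C3'", "C4'")], RING_BONDS[("C4'", "O4'")],
     RING_BONDS[("O4'", "C1'")]]
)


def _ring_coords(params: np.ndarray, radius: float) -> np.ndarray:
    """Pentagon with per-atom radial offsets (params[:5]) and out-of-plane
    displacements (params[5:], mean-removed to fix the gauge)."""
    r = radius + params[:5]
    z = params[5:]
    theta = np.radians(90.0 + 72.0 * np.arange(5))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z - z.mean()])


def _ring_nus(coords: np.ndarray) -> np.ndarray:
    quads = np.stack([coords[list(q)] for q in _NU_IDX])
    return dihedrals(quads)


def target_nus(phase_deg: float, amplitude_deg: float) -> np.ndarray:
    """Cosine pucker model: ν_j = τm·cos(P + 144°·(j−2))."""
    j = np.arange(5)
    return amplitude_deg * np.cos(np.radians(phase_deg + 144.0 * (j - 2.0)))


@lru_cache(maxsize=4096)
def _solve_ring(phase_key: float, amp_key: float) -> tuple[tuple[tuple[float, float, float], ...], float]:
    """Ring coordinates realizing the cosine-model ν targets.

    Returns (coords as tuples in _RING_ORDER, max |ν residual| in degrees).
    Cached per (phase, amplitude) pair.
    """
    radius = float(np.mean(_RING_BOND_TARGETS)) / (2.0 * math.sin(math.pi / 5.0))
    targets = target_nus(phase_key, amp_key)

    if abs(amp_key) < 1e-9:
        coords = _ring_coords(np.zeros(10), radius)
        return tuple(map(tuple, coords)), 0.0

    def residuals(params: np.ndarray) -> np.ndarray:
        coords = _ring_coords(params, radius)
        nus = _ring_nus(coords)
        bonds = np.linalg.norm(np.roll(coords, -1, axis=0) - coords, axis=1)
        # Soft bond restraint: nu targets dominate, bonds keep ~0.01 Å slack.
        return np.concatenate(
            [nus - targets, 2.0 * (bonds - _RING_BOND_TARGETS)]
        )

    # Initial guess: out-of-plane cosine mode with amplitude/phase probed so
    # the optimizer starts on the right branch of the pseudorotation wheel.
    amp0 = 0.0095 * amp_key  # ≈ 0.38 Å at τm = 40°
    j = np.arange(5)

    def probe(phi: float) -> float:
        z = amp0 * np.cos(phi + np.radians(144.0 * j))
        coords = _ring_coords(np.concatenate([np.zeros(5), z]), radius)
        nus = _ring_nus(coords)
        num = (nus[4] + nus[1]) - (nus[3] + nus[0])
        den = 2.0 * nus[2] * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
        return math.degrees(math.atan2(num, den))

    p0 = probe(0.0)
    slope = 1.0 if (wrap_half(probe(0.3) - p0) > 0) else -1.0
    phi0 = slope * math.radians(wrap_half(phase_key - p0))
    z0 = amp0 * np.cos(phi0 + np.radians(144.0 * j))
    x0 = np.concatenate([np.zeros(5), z0])

    sol = least_squares(residuals, x0, method="lm", xtol=1e-8, ftol=1e-8)
    coords = _ring_coords(sol.x, radius)
    resid = float(np.max(np.abs(_ring_nus(coords) - targets)))
    return tuple(map(tuple, coords)), resid


def _ribose_ring(phase: float, amplitude: float, residue_label: str) -> dict[str, np.ndarray]:
    coords, resid = _solve_ring(round(float(phase) % 360.0, 9), round(float(amplitude), 9))
    if resid > 1.0:
        raise BuildError(
            f"ring closure failed at residue {residue_label}: max nu residual "
            f"{resid:.3f}° exceeds 1°"
        )
    return {name: np.array(c) for name, c in zip(_RING_ORDER, coords)}


def _attach_ring(
    ring: dict[str, np.ndarray],
    c4_w: np.ndarray,
    c3_w: np.ndarray,
    c5_w: np.ndarray,
    delta_deg: float,
) -> dict[str, np.ndarray]:
    """Rigidly place the solved ring onto the backbone C4'/C3' pair.

    The residual degree of freedom (rotation about the shared C3'–C4' axis,
    which leaves all ν torsions invariant) is fixed by putting C2' at a
    tetrahedral offset from the prescribed O3' direction:
    dihedral(C5',C4',C3',C2') = δ + offset.
    """
    rot = _rotation_between(_unit(ring["C3'"] - ring["C4'"]), _unit(c3_w - c4_w))
    placed = {nm: c4_w + rot @ (p - ring["C4'"]) for nm, p in ring.items()}
    axis = _unit(c3_w - c4_w)
    target = wrap_half(delta_deg + _TORSION_C2_OFFSET)
    current = dihedral(c5_w, c4_w, c3_w, placed["C2'"])
    # Probe the rotation sign numerically to stay convention-proof.
    probe_rot = _rotation_about(axis, 1e-4)
    probed = dihedral(c5_w, c4_w, c3_w, c4_w + probe_rot @ (placed["C2'"] - c4_w))
    sign = 1.0 if wrap_half(probed - current) > 0 else -1.0
    spin = _rotation_about(axis, sign * math.radians(wrap_half(target - current)))
    moved = {}
    for nm, p in placed.items():
        if nm in ("C3'", "C4'"):
            moved[nm] = p
        else:
            moved[nm] = c4_w + spin @ (p - c4_w)
    return moved


# ---------------------------------------------------------------------------
# Chain assembly

def build_chain(
    prescription: TorsionPrescription,
    chain_id: str = "A",
    model_number: int = 1,
) -> StructureModel:
    """Build full-atom coordinates realizing ``prescription``.

    Every prescribed α…ζ and χ is realized exactly by NeRF placement; the
    sugar ring realizes the cosine pucker model within the solver residual
    (raising :class:`BuildError` above 1°).  The resulting model carries the
    prescription on its ``prescription`` attribute for later perturbation.
    """
    p = prescription
    n = len(p.sequence)
    per_res: list[dict[str, np.ndarray]] = []
    prev: Optional[dict[str, np.ndarray]] = None
    for i, letter in enumerate(p.sequence.upper()):
        atoms: dict[str, np.ndarray] = {}
        if prev is None:
            atoms["P"] = np.zeros(3)
            atoms["O5'"] = np.array([BOND_LENGTHS[("P", "O5'")], 0.0, 0.0])
            ang = math.radians(BOND_ANGLES[("P", "O5'", "C5'")])
            atoms["C5'"] = atoms["O5'"] + BOND_LENGTHS[("O5'", "C5'")] * np.array(
                [-math.cos(ang), math.sin(ang), 0.0]
            )
        else:
            atoms["P"] = nerf(
                prev["C4'"], prev["C3'"], prev["O3'"],
                BOND_LENGTHS[("O3'", "P")], BOND_ANGLES[("C3'", "O3'", "P")],
                p.epsilon[i - 1],
            )
            atoms["O5'"] = nerf(
                prev["C3'"], prev["O3'"], atoms["P"],
                BOND_LENGTHS[("P", "O5'")], BOND_ANGLES[("O3'", "P", "O5'")],
                p.zeta[i - 1],
            )
            atoms["C5'"] = nerf(
                prev["O3'"], atoms["P"], atoms["O5'"],
                BOND_LENGTHS[("O5'", "C5'")], BOND_ANGLES[("P", "O5'", "C5'")],
                p.alpha[i],
            )
        atoms["C4'"] = nerf(
            atoms["P"], atoms["O5'"], atoms["C5'"],
            BOND_LENGTHS[("C5'", "C4'")], BOND_ANGLES[("O5'", "C5'", "C4'")],
            p.beta[i],
        )
        label = f"{chain_id}/{letter}{i + 1}"
        ring = _ribose_ring(p.pucker_phase[i], p.pucker_amplitude[i], label)
        c3c4 = float(np.linalg.norm(ring["C3'"] - ring["C4'"]))
        atoms["C3'"] = nerf(
            atoms["O5'"], atoms["C5'"], atoms["C4'"],
            c3c4, BOND_ANGLES[("C5'", "C4'", "C3'")], p.gamma[i],
        )
        atoms["O3'"] = nerf(
            atoms["C5'"], atoms["C4'"], atoms["C3'"],
            BOND_LENGTHS[("C3'", "O3'")], BOND_ANGLES[("C4'", "C3'", "O3'")],
            p.delta[i],
        )
        ring_w = _attach_ring(ring, atoms["C4'"], atoms["C3'"], atoms["C5'"], p.delta[i])
        atoms["C1'"] = ring_w["C1'"]
        atoms["C2'"] = ring_w["C2'"]
        atoms["O4'"] = ring_w["O4'"]
        if letter != "T":  # 2'-OH absent in thymidine (deoxyribose)
            atoms["O2'"] = nerf(
                atoms["C4'"], atoms["C3'"], atoms["C2'"],
                BOND_LENGTHS[("C2'", "O2'")], BOND_ANGLES[("C3'", "C2'", "O2'")],
                _TORSION_O2,
            )
        purine = letter in "AG"
        n_name, cg_name, far_name = ("N9", "C4", "C8") if purine else ("N1", "C2", "C6")
        n_atom = nerf(
            atoms["C4'"], atoms["O4'"], atoms["C1'"],
            BOND_LENGTHS[("C1'", "N")], BOND_ANGLES[("O4'", "C1'", "N")],
            _TORSION_N,
        )
        atoms[n_name] = n_atom
        atoms[cg_name] = nerf(
            atoms["O4'"], atoms["C1'"], n_atom,
            BOND_LENGTHS[(n_name, cg_name)],
            BOND_ANGLES[("C1'", n_name, cg_name)],
            p.chi[i],
        )
        atoms[far_name] = nerf(
            atoms["O4'"], atoms["C1'"], n_atom,
            BOND_LENGTHS[(n_name, far_name)],
            BOND_ANGLES[("C1'", n_name, far_name)],
            wrap_half(p.chi[i] + 180.0),
        )
        per_res.append(atoms)
        prev = atoms

    residues = []
    for i, (letter, atoms) in enumerate(zip(p.sequence.upper(), per_res)):
        residues.append(
            Residue(
                chain_id=chain_id,
                auth_number=i + 1,
                insertion_code="",
                name=_RES_NAMES[letter],
                one_letter=letter,
                atoms={
                    nm: Atom(name=nm, element=nm[0], position=pos)
                    for nm, pos in atoms.items()
                },
            )
        )
    chain = NucleicChain(chain_id=chain_id, residues=residues, breaks=set())
    model = StructureModel(model_number=model_number, chains=[chain], source_format=None)
    model.prescription = prescription.copy()
    return model


def perturb(
    model: StructureModel,
    kinds: Sequence[AngleKind],
    offset: float,
    positions: Optional[Sequence[int]] = None,
) -> StructureModel:
    """Rebuild ``model`` with selected torsions shifted by ``offset`` degrees
    at ``positions`` (default: every residue); all other angles unchanged."""
    base = getattr(model, "prescription", None)
    if base is None:
        raise ConfigError("perturb requires a model produced by build_chain")
    p = base.copy()
    n = len(p.sequence)
    idx = list(range(n)) if positions is None else sorted(set(positions))
    if idx and not (0 <= idx[0] and idx[-1] < n):
        raise ConfigError(f"positions outside chain of length {n}")
    for kind in kinds:
        arr = p.kind_array(kind)
        arr[idx] = wrap_half(arr[idx] + offset)
    chain = model.chains[0]
    return build_chain(p, chain_id=chain.chain_id, model_number=model.model_number)


# ---------------------------------------------------------------------------
# Writers

def _to_atom_array(model: StructureModel):
    atoms = [
        (chain, res, atom)
        for chain in model.chains
        for res in chain.residues
        for atom in res.atoms.values()
    ]
    if not atoms:
        raise EmptyStructureError("cannot serialize an empty model")
    n = len(atoms)
    arr = struc.AtomArray(n)
    # Fixed-column PDB precision; mmCIF uses the same rounded values so both
    # serializations carry identical coordinates.
    arr.coord = np.round(
        np.array([a.position for _, _, a in atoms], dtype=float), 3
    )
    arr.chain_id = np.array([c.chain_id for c, _, _ in atoms])
    arr.res_id = np.array([r.auth_number for _, r, _ in atoms])
    arr.ins_code = np.array([r.insertion_code for _, r, _ in atoms])
    arr.res_name = np.array([r.name for _, r, _ in atoms])
    arr.atom_name = np.array([a.name for _, _, a in atoms])
    arr.element = np.array([a.element for _, _, a in atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.array([a.occupancy for _, _, a in atoms]))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_structure(model: StructureModel, format: str = "pdb") -> str:
    """Serialize ``model`` as PDB or mmCIF text round-trippable through
    :func:`tango.structure_io.parse_structure`."""
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown output format: {format!r}")
    arr = _to_atom_array(model)
    if format == "pdb":
        too_long = [c for c in {str(x) for x in arr.chain_id} if len(c) > 1]
        if too_long:
            raise FormatError(
                f"PDB format allows single-character chain ids; got {sorted(too_long)}"
            )
        pfile = _pdb.PDBFile()
        pfile.set_structure(arr)
        buf = StringIO()
        pfile.write(buf)
        return buf.getvalue()
    cfile = _pdbx.CIFFile()
    _pdbx.set_structure(cfile, arr, data_block="synthetic")
    buf = StringIO()
    cfile.write(buf)
    return buf.getvalue()
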