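"""Reading PDB / PDBx-mmCIF files into the nucleic-acid hierarchy.

Parsing itself is delegated to biotite; this module filters the atom table
down to nucleotides, resolves alternate locations deterministically
(highest occupancy wins, ties broken by the lexicographically smallest
altloc id), flags chain breaks, and exposes model/chain/range selection.
"""

from __future__ import annotations

import io
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
import biotite.structure.io.pdbx as _pdbx

from .errors import EmptyStructureError, FormatError, SelectionError
from .model import (
    MODIFIED_ONE_LETTER,
    STANDARD_ONE_LETTER,
    Atom,
    NucleicChain,
    Residue,
    Selection,
    StructureModel,
)

__all__ = ["parse_structure", "detect_breaks", "select", "detect_format"]

#: Default O3'(i)-P(i+1) distance (Å) above which the backbone is considered
#: broken: ~1.6 Å covalent bond plus generous slack.
DEFAULT_BREAK_CUTOFF = 2.5


def detect_format(text: str) -> str:
    """Guess ``pdb`` vs ``mmcif`` from the leading tokens of the file."""
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("data_") or stripped.startswith("loop_"):
            return "mmcif"
        return "pdb"
    raise FormatError("empty input: no parseable content")


def parse_structure(
    text: str,
    format_hint: Optional[str] = None,
    break_cutoff: float = DEFAULT_BREAK_CUTOFF,
) -> list[StructureModel]:
    """Parse PDB or mmCIF text into a list of :class:`StructureModel`.

    All models are returned.  Non-nucleotide residues (waters, ions, amino
    acids) are dropped; modified nucleotides are retained.  Altlocs are
    resolved and chain breaks flagged with ``break_cutoff``.

    Raises
    ------
    FormatError
        If the content cannot be parsed in either format.
    EmptyStructureError
        If no nucleic-acid residue survives filtering.
    """
    fmt = format_hint or detect_format(text)
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format hint: {fmt!r}")
    try:
        arrays = _read_models(text, fmt)
    except (FormatError, EmptyStructureError):
        raise
    except Exception as exc:  # biotite raises assorted exception types
        raise FormatError(f"cannot parse input as {fmt}: {exc}") from exc

    models = []
    for number, atoms in arrays:
        chains = _chains_from_atoms(atoms, break_cutoff)
        if chains:
            models.append(
                StructureModel(model_number=number, chains=chains, source_format=fmt)
            )
    if not models:
        raise EmptyStructureError("input contains no nucleic-acid residues")
    return models


def _read_models(text: str, fmt: str):
    extra = ["occupancy"]
    if fmt == "pdb":
        pfile = _pdb.PDBFile.read(io.StringIO(text))
        count = pfile.get_model_count()
        return [
            (m, pfile.get_structure(model=m, altloc="all", extra_fields=extra))
            for m in range(1, count + 1)
        ]
    cfile = _pdbx.CIFFile.read(io.StringIO(text))
    count = _pdbx.get_model_count(cfile)
    return [
        (m, _pdbx.get_structure(cfile, model=m, altloc="all", extra_fields=extra))
        for m in range(1, count + 1)
    ]


def _is_nucleotide(atom_names: set[str]) -> bool:
    # A sugar (C1' + O4') is the common denominator of regular and modified
    # nucleotides; waters, ions and amino acids have neither.
    return "C1'" in atom_names and "O4'" in atom_names


def _one_letter(res_name: str, atom_names: set[str]) -> str:
    name = res_name.upper()
    if name in STANDARD_ONE_LETTER:
        return STANDARD_ONE_LETTER[name]
    if name in MODIFIED_ONE_LETTER:
        return MODIFIED_ONE_LETTER[name]
    # Unknown modified code: guess the parent from base atoms.
    if "N9" in atom_names and "C4" in atom_names:
        return "g" if "O6" in atom_names else ("a" if "N6" in atom_names else "n")
    if "N1" in atom_names and "C2" in atom_names:
        if "N4" in atom_names:
            return "c"
        if "O4" in atom_names:
            return "t" if ("C7" in atom_names or "C5M" in atom_names) else "u"
    return "n"


def _resolve_altlocs(cand: list[Atom]) -> Atom:
    # Highest occupancy wins; ties broken by smallest altloc id.
    def key(a: Atom):
        occ = a.occupancy if np.isfinite(a.occupancy) else 0.0
        return (-occ, a.altloc)

    return sorted(cand, key=key)[0]


def _chains_from_atoms(atoms, break_cutoff: float) -> list[NucleicChain]:
    n = atoms.array_length()
    if n == 0:
        return []
    chain_ids = atoms.chain_id
    res_ids = atoms.res_id
    ins_codes = atoms.ins_code
    res_names = atoms.res_name
    atom_names = atoms.atom_name
    elements = atoms.element
    occupancies = (
        atoms.occupancy
        if "occupancy" in atoms.get_annotation_categories()
        else np.ones(n)
    )
    altlocs = (
        atoms.altloc_id
        if "altloc_id" in atoms.get_annotation_categories()
        else np.full(n, "", dtype="U1")
    )

    chains: list[NucleicChain] = []
    current: Optional[NucleicChain] = None
    i = 0
    while i < n:
        # Group the contiguous run of atoms with one (chain, res_id, ins) key.
        key = (chain_ids[i], res_ids[i], ins_codes[i])
        j = i
        while j < n and (chain_ids[j], res_ids[j], ins_codes[j]) == key:
            j += 1
        names_here = set(atom_names[i:j])
        if _is_nucleotide(names_here):
            if current is None or current.chain_id != key[0]:
                current = NucleicChain(chain_id=str(key[0]))
                chains.append(current)
            by_name: dict[str, list[Atom]] = {}
            for k in range(i, j):
                alt = str(altlocs[k]).strip().strip(".")
                atom = Atom(
                    name=str(atom_names[k]),
                    element=str(elements[k]),
                    position=atoms.coord[k].astype(float),
                    occupancy=float(occupancies[k]),
                    altloc=alt,
                )
                by_name.setdefault(atom.name, []).append(atom)
            resolved = {nm: _resolve_altlocs(cand) for nm, cand in by_name.items()}
            current.residues.append(
                Residue(
                    chain_id=str(key[0]),
                    auth_number=int(key[1]),
                    insertion_code=str(key[2]).strip(),
                    name=str(res_names[i]),
                    one_letter=_one_letter(str(res_names[i]), names_here),
                    atoms=resolved,
                )
            )
        i = j
    return [detect_breaks(c, cutoff=break_cutoff) for c in chains if len(c) > 0]


def detect_breaks(chain: NucleicChain, cutoff: float = DEFAULT_BREAK_CUTOFF) -> NucleicChain:
    """Flag backbone breaks: position *i* is broken iff the O3'(i)-P(i+1)
    distance exceeds ``cutoff`` or either atom is missing."""
    breaks: set[int] = set()
    for i in range(len(chain) - 1):
        o3 = chain.residues[i].coord("O3'")
        p = chain.residues[i + 1].coord("P")
        if o3 is None or p is None or float(np.linalg.norm(o3 - p)) > cutoff:
            breaks.add(i)
    chain.breaks = breaks
    return chain


def select(models: Sequence[StructureModel], sel: Selection) -> list[NucleicChain]:
    """Trim ``models`` down to the chains/ranges named by ``sel``.

    Residue identities (author numbers, insertion codes) and break flags are
    preserved; break positions are re-indexed into the trimmed chain.
    """
    by_number = {m.model_number: m for m in models}
    if sel.model_number not in by_number:
        raise SelectionError(
            f"model {sel.model_number} not present; available: {sorted(by_number)}"
        )
    model = by_number[sel.model_number]
    wanted = sel.chain_ids if sel.chain_ids is not None else model.chain_ids
    out: list[NucleicChain] = []
    for cid in wanted:
        try:
            chain = model.chain(cid)
        except KeyError:
            raise SelectionError(
                f"chain {cid!r} not present in model {model.model_number}; "
                f"available: {model.chain_ids}"
            ) from None
        lo, hi = (0, len(chain)) if sel.residue_range is None else sel.residue_range
        if not (0 <= lo <= hi <= len(chain)):
            raise SelectionError(
                f"range [{lo}, {hi}) outside chain {cid!r} of length {len(chain)}"
            )
        trimmed = NucleicChain(
            chain_id=chain.chain_id,
            residues=chain.residues[lo:hi],
            breaks={b - lo for b in chain.breaks if lo <= b < hi - 1},
        )
        out.append(trimmed)
    return out
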