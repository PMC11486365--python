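"""Atomic hierarchy for nucleic-acid structures.

The hierarchy is deliberately small: a :class:`StructureModel` holds
:class:`NucleicChain` objects, which hold ordered :class:`Residue` objects,
which map canonical atom names (``P``, ``O5'``, ``C1'``, ...) to
:class:`Atom` records.  Internal indices are 0-based half-open; everything
user-facing is rendered with author residue numbers and insertion codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "NucleicChain",
    "StructureModel",
    "Selection",
]

#: Canonical sequence letters for the standard nucleotides.
STANDARD_ONE_LETTER = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "T",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U", "THY": "T",
}

#: One-letter parents for common modified nucleotides (methylations,
#: pseudouridine, dihydrouridine, ...).  Lowercase marks "modified".
MODIFIED_ONE_LETTER = {
    "PSU": "u", "H2U": "u", "4SU": "u", "5MU": "t", "OMU": "u", "UR3": "u",
    "1MA": "a", "2MA": "a", "6MA": "a", "MA6": "a", "OMA": "a", "A2M": "a",
    "5MC": "c", "OMC": "c", "4OC": "c", "M4C": "c", "CBV": "c",
    "1MG": "g", "2MG": "g", "7MG": "g", "M2G": "g", "OMG": "g", "G7M": "g",
    "YG": "g", "YYG": "g", "QUO": "g", "I": "i", "INO": "i",
}


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates in Å."""

    name: str
    element: str
    position: np.ndarray  # shape (3,)
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    """One nucleotide with its atoms after altloc resolution."""

    chain_id: str
    auth_number: int
    insertion_code: str
    name: str
    one_letter: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def base_class(self) -> str:
        """``purine`` / ``pyrimidine`` / ``unknown`` from base atoms.

        Classification is structural, not name-based, so modified purines
        with exotic residue codes are still recognized: any residue carrying
        the glycosidic nitrogen N9 together with ring atom C4 is a purine;
        one with N1 and C2 (and no N9) is a pyrimidine.
        """
        if "N9" in self.atoms and "C4" in self.atoms:
            return "purine"
        if "N1" in self.atoms and "C2" in self.atoms and "N9" not in self.atoms:
            return "pyrimidine"
        return "unknown"

    def coord(self, name: str) -> Optional[np.ndarray]:
        atom = self.atoms.get(name)
        return None if atom is None else atom.position

    @property
    def label(self) -> str:
        ins = self.insertion_code or ""
        return f"{self.chain_id}/{self.name}{self.auth_number}{ins}"


@dataclass
class NucleicChain:
    """An ordered run of nucleotides plus chain-break bookkeeping.

    ``breaks`` holds 0-based positions *i* such that the backbone is broken
    between residue *i* and residue *i + 1* (missing O3'/P or an O3'-P
    distance beyond the covalent cutoff).  Inter-residue angles are never
    computed across a break.
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    breaks: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class StructureModel:
    """One model of a (possibly multi-model) structure file."""

    model_number: int
    chains: list[NucleicChain] = field(default_factory=list)
    source_format: Optional[str] = None  # "pdb" | "mmcif" | None (synthetic)

    def chain(self, chain_id: str) -> NucleicChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


@dataclass
class Selection:
    """Model / chain / residue-range selection.

    ``residue_range`` is a 0-based half-open span over chain positions
    (*not* author numbers); the CLI translates 1-based inclusive author
    ranges into this form.
    """

    model_number: int = 1
    chain_ids: Optional[Sequence[str]] = None  # None = all chains
    residue_range: Optional[tuple[int, int]] = None  # None = full chain
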