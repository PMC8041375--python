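"""Minimal structure handling: residue coordinates and inter-residue distances.

Supports distance-stratified benchmarking and statements about long-range
couplings (pairs tens of Å apart).  PDB text is parsed with gemmi; only
ATOM records of the first model are kept, one entry per (chain, residue).
Two distance definitions are exposed: Cα–Cα (``ca``) and the minimum over
all heavy-atom pairs (``min_heavy``, the default for stratification).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple, Union

import gemmi
import numpy as np

from .errors import StructureError

__all__ = ["ResidueCoordinates", "StructureIndex", "read_structure", "residue_distance"]


@dataclass(frozen=True)
class ResidueCoordinates:
    """Coordinates of one residue's atoms.

    ``position`` is the PDB residue number with any insertion code
    appended (e.g. ``"72"`` or ``"60A"``).  ``atoms`` maps atom names to
    (x, y, z) in Å; ``elements`` carries the element symbol per atom for
    hydrogen filtering.
    """

    chain: str
    position: str
    name: str
    atoms: Dict[str, Tuple[float, float, float]]
    elements: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.chain}:{self.position} has no atoms")
        for atom, xyz in self.atoms.items():
            if not all(np.isfinite(xyz)):
                raise StructureError(
                    f"non-finite coordinates for atom {atom} in {self.chain}:{self.position}"
                )

    @property
    def heavy_atoms(self) -> Dict[str, Tuple[float, float, float]]:
        """Atoms that are not hydrogen or deuterium."""
        return {
            name: xyz
            for name, xyz in self.atoms.items()
            if self.elements.get(name, "").upper() not in ("H", "D")
        }


def read_structure(pdb_text: str) -> List[ResidueCoordinates]:
    """Parse PDB text into per-residue coordinates.

    Only ATOM records of the first model are used; HETATM records are
    ignored.  For alternate locations of the same atom name the highest
    occupancy wins, ties resolved by altloc letter (blank, then 'A', ...).
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"could not parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise StructureError("PDB text contains no model")
    model = st[0]

    residues: List[ResidueCoordinates] = []
    for chain in model:
        for res in chain:
            if res.het_flag != "A":  # HETATM / water
                continue
            chosen: Dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = chosen.get(atom.name)
                key = (-atom.occ, atom.altloc or " ")
                if prev is None or key < (-prev.occ, prev.altloc or " "):
                    chosen[atom.name] = atom
            if not chosen:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                ResidueCoordinates(
                    chain=chain.name,
                    position=f"{res.seqid.num}{icode}",
                    name=res.name,
                    atoms={
                        n: (a.pos.x, a.pos.y, a.pos.z) for n, a in chosen.items()
                    },
                    elements={n: a.element.name for n, a in chosen.items()},
                )
            )
    if not residues:
        raise StructureError("no ATOM records found in PDB text")
    return residues


ResidueRef = Union[str, Tuple[str, Union[int, str]]]


def _parse_ref(ref: ResidueRef) -> Tuple[str, str]:
    """Normalise a residue reference ('A:72', ('A', 72), '72') to
    (chain, position-string)."""
    if isinstance(ref, tuple):
        chain, pos = ref
        return str(chain), str(pos)
    text = str(ref)
    if ":" in text:
        chain, pos = text.split(":", 1)
        return chain, pos
    return "", text


class StructureIndex:
    """Lookup helper mapping (chain, position) to ResidueCoordinates.

    When a reference omits the chain it matches any chain, provided the
    position is unambiguous.
    """

    def __init__(self, residues: List[ResidueCoordinates]):
        self._residues = residues
        self._by_key = {(r.chain, r.position): r for r in residues}

    def find(self, ref: ResidueRef) -> ResidueCoordinates:
        chain, pos = _parse_ref(ref)
        if chain:
            res = self._by_key.get((chain, pos))
            if res is None:
                raise StructureError(f"residue {chain}:{pos} not found in structure")
            return res
        matches = [r for r in self._residues if r.position == pos]
        if not matches:
            raise StructureError(f"residue {pos} not found in structure")
        if len(matches) > 1:
            chains = ", ".join(sorted(r.chain for r in matches))
            raise StructureError(
                f"residue {pos} is ambiguous (chains {chains}); qualify as 'chain:{pos}'"
            )
        return matches[0]


def residue_distance(
    structure: List[ResidueCoordinates],
    res_a: ResidueRef,
    res_b: ResidueRef,
    mode: str = "min_heavy",
) -> float:
    """Distance in Å between two residues.

    ``mode='ca'`` gives the Cα–Cα Euclidean distance; ``mode='min_heavy'``
    the minimum over all non-hydrogen atom pairs.  Missing residues or a
    missing Cα raise :class:`StructureError` naming the culprit.
    """
    index = structure if isinstance(structure, StructureIndex) else StructureIndex(structure)
    a = index.find(res_a)
    b = index.find(res_b)
    if mode == "ca":
        coords = []
        for res in (a, b):
            if "CA" not in res.atoms:
                raise StructureError(f"residue {res.chain}:{res.position} has no CA atom")
            coords.append(np.asarray(res.atoms["CA"]))
        return float(np.linalg.norm(coords[0] - coords[1]))
    if mode == "min_heavy":
        xa = np.array(list(a.heavy_atoms.values()), dtype=float)
        xb = np.array(list(b.heavy_atoms.values()), dtype=float)
        if xa.size == 0 or xb.size == 0:
            culprit = a if xa.size == 0 else b
            raise StructureError(
                f"residue {culprit.chain}:{culprit.position} has no heavy atoms"
            )
        diff = xa[:, None, :] - xb[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=-1)).min())
    raise ValueError(f"unknown distance mode {mode!r} (expected 'ca' or 'min_heavy')")
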