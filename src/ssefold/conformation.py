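"""All-atom model container for a full RNA chain."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import CoordSet

__all__ = ["Conformation"]

_ELEMENT_OF = {"P": "P", "O": "O", "N": "N", "C": "C", "S": "S"}


def element_of(atom_name: str) -> str:
    return _ELEMENT_OF.get(atom_name.strip("'0123456789")[:1], "C")


@dataclass
class Conformation:
    """Per-residue atom names and coordinates for one RNA chain.

    Residues are indexed 0..n-1 in sequence order; ``chain_breaks`` lists
    residue indices *i* after which the backbone is not covalently
    continuous (no O3'(i)-P(i+1) bond expected).  ``provenance`` records
    where each piece of the model came from (template choices, seeds).
    """

    sequence: str
    labels: list[tuple[int, str]]
    xyz: np.ndarray
    chain_breaks: set[int] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if len(self.labels) != len(self.xyz):
            raise ValueError("labels and xyz length mismatch")
        resis = {r for r, _ in self.labels}
        if resis and (min(resis) < 0 or max(resis) >= len(self.sequence)):
            raise ValueError("residue index out of range of sequence")
        if resis != set(range(len(self.sequence))):
            missing = set(range(len(self.sequence))) - resis
            raise ValueError(f"residues without atoms: {sorted(missing)[:5]}...")
        self._index: dict[tuple[int, str], int] = {
            lab: k for k, lab in enumerate(self.labels)
        }

    # -- construction -------------------------------------------------

    @classmethod
    def from_residues(
        cls,
        sequence: str,
        residues: Sequence[Mapping[str, np.ndarray]],
        chain_breaks: Iterable[int] = (),
        provenance: dict | None = None,
    ) -> "Conformation":
        if len(residues) != len(sequence):
            raise ValueError("one atom mapping per residue required")
        labels: list[tuple[int, str]] = []
        coords: list[np.ndarray] = []
        for i, atoms in enumerate(residues):
            for name, pos in atoms.items():
                labels.append((i, name))
                coords.append(np.asarray(pos, dtype=float))
        return cls(
            sequence,
            labels,
            np.array(coords),
            set(chain_breaks),
            provenance or {},
        )

    # -- access --------------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def residue_atoms(self, i: int) -> dict[str, np.ndarray]:
        return {
            name: self.xyz[k]
            for k, (r, name) in enumerate(self.labels)
            if r == i
        }

    def atom(self, i: int, name: str) -> np.ndarray:
        try:
            return self.xyz[self._index[(i, name)]]
        except KeyError:
            raise KeyError(f"no atom {name!r} in residue {i}") from None

    def has_atom(self, i: int, name: str) -> bool:
        return (i, name) in self._index

    def set_atom(self, i: int, name: str, pos: np.ndarray) -> None:
        self.xyz[self._index[(i, name)]] = np.asarray(pos, dtype=float)

    def coords(self, atom_names: set[str] | None = None) -> CoordSet:
        """A CoordSet view (copy) of all atoms, or a named-atom subset."""
        if atom_names is None:
            return CoordSet(list(self.labels), self.xyz.copy())
        sel = [k for k, (_, nm) in enumerate(self.labels) if nm in atom_names]
        return CoordSet([self.labels[k] for k in sel], self.xyz[sel].copy())

    def with_coords(self, cs: CoordSet) -> "Conformation":
        """Return a copy whose coordinates are taken from a matching CoordSet."""
        if cs.labels != self.labels:
            raise ValueError("coordinate set labels do not match conformation")
        return Conformation(
            self.sequence,
            list(self.labels),
            cs.xyz.copy(),
            set(self.chain_breaks),
            dict(self.provenance),
            self.chain_id,
        )

    def copy(self) -> "Conformation":
        return Conformation(
            self.sequence,
            list(self.labels),
            self.xyz.copy(),
            set(self.chain_breaks),
            dict(self.provenance),
            self.chain_id,
        )

    # -- geometry helpers ---------------------------------------------

    def backbone_gaps(self) -> list[tuple[int, float]]:
        """O3'(i)-P(i+1) distances for all covalently expected junctions."""
        out = []
        for i in range(self.n_residues - 1):
            if i in self.chain_breaks:
                continue
            if not (self.has_atom(i, "O3'") and self.has_atom(i + 1, "P")):
                continue
            d = float(np.linalg.norm(self.atom(i, "O3'") - self.atom(i + 1, "P")))
            out.append((i, d))
        return out
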