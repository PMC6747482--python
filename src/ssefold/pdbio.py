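"""PDB reading and writing for RNA conformations (via gemmi).

Only the first RNA chain of each model is read; residue names ``A``,
``C``, ``G``, ``U`` and the common two/three-character variants (``RA``,
``A5``, ``A3``, ...) are mapped to single-letter bases.  Multi-MODEL
files yield one :class:`~ssefold.conformation.Conformation` per model.
"""

from __future__ import annotations

import gemmi
import numpy as np

from .conformation import Conformation, element_of

__all__ = ["read_pdb", "read_pdb_models", "write_pdb", "write_models"]

_RES_MAP = {}
for _b in "ACGU":
    for _nm in (_b, "R" + _b, _b + "5", _b + "3", "R" + _b + "5", "R" + _b + "3"):
        _RES_MAP[_nm] = _b
_RES_MAP["T"] = "U"
_RES_MAP["DT"] = "U"


def _chain_to_conformation(chain: gemmi.Chain) -> Conformation | None:
    seq = []
    residues = []
    breaks: set[int] = set()
    prev_o3 = None
    for res in chain:
        base = _RES_MAP.get(res.name.strip())
        if base is None:
            continue
        atoms = {}
        for atom in res:
            if atom.element.name == "H":
                continue
            atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if not atoms:
            continue
        if seq and prev_o3 is not None and "P" in atoms:
            if np.linalg.norm(prev_o3 - atoms["P"]) > 2.5:
                breaks.add(len(seq) - 1)
        elif seq:
            breaks.add(len(seq) - 1)
        prev_o3 = atoms.get("O3'")
        seq.append(base)
        residues.append(atoms)
    if not seq:
        return None
    conf = Conformation.from_residues("".join(seq), residues, breaks)
    conf.chain_id = chain.name or "A"
    return conf


def read_pdb_models(path) -> list[Conformation]:
    """Read every MODEL block of a PDB file as a separate conformation."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    out = []
    for model in st:
        for chain in model:
            conf = _chain_to_conformation(chain)
            if conf is not None:
                out.append(conf)
                break  # first RNA chain per model
    if not out:
        raise ValueError(f"no RNA chain found in {path}")
    return out


def read_pdb(path) -> Conformation:
    """Read the first RNA chain of the first model."""
    return read_pdb_models(path)[0]


def write_pdb(conf: Conformation, path) -> None:
    write_models([conf], path)


def write_models(confs: list[Conformation], path) -> None:
    """Write conformations as MODEL/ENDMDL blocks (1-based residue numbers)."""
    lines = []
    multi = len(confs) > 1
    for m, conf in enumerate(confs, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for k, (resi, name) in enumerate(conf.labels):
            x, y, z = conf.xyz[k]
            el = element_of(name)
            nm = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {nm:<4s} {conf.sequence[resi]:>3s} "
                f"{conf.chain_id:1s}{resi + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {el:>2s}"
            )
            serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
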