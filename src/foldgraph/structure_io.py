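"""Reading and writing protein structures as ordered C-alpha traces.

Structure comparison here operates purely on the backbone geometry of a
single chain, so a structure is reduced to the ordered list of C-alpha
coordinates.  Multi-chain PDB files are split into one record per chain;
all non-C-alpha atoms, HETATM records and alternate conformers beyond the
first are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = ["ProteinStructure", "load_structures", "write_structure"]


@dataclass
class ProteinStructure:
    """A single chain reduced to its ordered C-alpha trace.

    Parameters
    ----------
    id : str
        Identifier, typically ``<stem>_<chain>``.
    ca_coords : (n_residues, 3) ndarray
        C-alpha coordinates in Angstrom, in chain order.
    class_label : str, optional
        Fold-class label, used only by the classification probe.
    """

    id: str
    ca_coords: np.ndarray
    class_label: str | None = None
    n_residues: int = field(init=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(
                f"ca_coords must be (N, 3); got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.id}: non-finite C-alpha coordinates")
        self.ca_coords = coords
        self.n_residues = len(coords)


def load_structures(path: str | Path, fmt: str = "pdb") -> list[ProteinStructure]:
    """Load every chain of a PDB file as a :class:`ProteinStructure`.

    Chains appear in file order.  Residues lacking a C-alpha atom are
    skipped with a warning; chains with zero C-alpha atoms are omitted.
    Alternate locations resolve to the first conformer (biotite default).

    Raises
    ------
    ValueError
        If the format is unsupported or the file cannot be parsed.
    """
    if fmt != "pdb":
        raise ValueError(f"unsupported format: {fmt!r}")
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises several parse error types
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc

    atoms = atoms[~atoms.hetero]
    structures: list[ProteinStructure] = []
    seen: list[str] = []
    for chain_id in atoms.chain_id:
        if chain_id not in seen:
            seen.append(chain_id)
    for chain_id in seen:
        chain = atoms[atoms.chain_id == chain_id]
        n_res = struc.get_residue_count(chain)
        ca = chain[chain.atom_name == "CA"]
        if ca.array_length() == 0:
            warnings.warn(
                f"{path.name} chain {chain_id}: no C-alpha atoms, omitted"
            )
            continue
        if ca.array_length() < n_res:
            warnings.warn(
                f"{path.name} chain {chain_id}: "
                f"{n_res - ca.array_length()} residue(s) without C-alpha skipped"
            )
        sid = f"{path.stem}_{chain_id}" if len(seen) > 1 else path.stem
        # PDB coordinates carry exactly 3 decimals; rounding the float32
        # values biotite returns recovers the printed decimals losslessly
        coords = np.round(ca.coord.astype(np.float64), 3)
        structures.append(ProteinStructure(id=sid, ca_coords=coords))
    return structures


def write_structure(s: ProteinStructure, path: str | Path) -> None:
    """Write a minimal PDB with one CA ATOM record per residue.

    Residues are numbered sequentially from 1 on chain A; coordinates keep
    PDB precision (3 decimals).
    """
    n = s.n_residues
    atoms = struc.AtomArray(n)
    # round to PDB precision in float64 first so the float32 cast cannot
    # flip a value across the 0.0005 rounding boundary
    atoms.coord = np.round(np.asarray(s.ca_coords), 3).astype(np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "GLY")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
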