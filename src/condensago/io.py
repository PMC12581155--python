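"""PDB-format reference structures and YAML run configuration.

Reference dimers are exchanged in PDB format (coordinates in
Angstrom on disk, nm in memory).  Coarse-grained sites map to one
atom record per bead: CA for peptide beads and P/C4'/N1 for the RNA
phosphate/sugar/base beads.
"""

from __future__ import annotations

import numpy as np
import yaml

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

_CG_ATOM_NAMES = ("CA", "P", "C4'", "N1")


def read_reference_pdb(path, atom_names=_CG_ATOM_NAMES):
    """CG-site coordinates (nm) and integer chain labels from a PDB."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    sel = np.isin(atoms.atom_name, list(atom_names))
    atoms = atoms[sel]
    if atoms.array_length() == 0:
        raise ValueError("no CG-mappable atoms found in PDB")
    chain_ids = {c: i for i, c in enumerate(dict.fromkeys(atoms.chain_id))}
    labels = np.array([chain_ids[c] for c in atoms.chain_id])
    return atoms.coord / 10.0, labels


def write_reference_pdb(path, coords_nm, chain_labels,
                        residue_codes=None) -> None:
    """Write CG beads as CA records, one residue per bead."""
    coords_nm = np.asarray(coords_nm, dtype=float)
    n = len(coords_nm)
    atoms = bst.AtomArray(n)
    atoms.coord = coords_nm * 10.0
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    atoms.chain_id = np.array([letters[int(c) % 26] for c in chain_labels])
    res_ids = np.zeros(n, dtype=int)
    within = {}
    for i, c in enumerate(chain_labels):
        within[c] = within.get(c, 0) + 1
        res_ids[i] = within[c]
    atoms.res_id = res_ids
    atoms.res_name = np.array(
        ["ALA" if residue_codes is None else "GLY" for _ in range(n)])
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def load_run_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_run_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
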