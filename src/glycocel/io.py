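"""File I/O: ring geometries from XYZ/SDF, ensembles to SDF + manifest."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .pucker import RingAtomSet
from .records import ConformerRecord, manifest

__all__ = ["ring_from_xyz", "ring_from_sdf", "write_ensemble_sdf", "write_manifest"]


def _select_ring(symbols, coords, indices, mol=None):
    if indices is None:
        if mol is None:
            raise ValueError("six ring-atom indices required for XYZ input")
        from .grid_enum import perceive_pyranose_ring

        ring = perceive_pyranose_ring(mol)
        indices = [ring[k] for k in ("O5", "C1", "C2", "C3", "C4", "C5")]
    if len(indices) != 6:
        raise ValueError("exactly six ring-atom indices required")
    return RingAtomSet(coords[list(indices)], tuple(symbols[i] for i in indices))


def ring_from_xyz(path, indices: Sequence[int] | None = None) -> RingAtomSet:
    """Ring atoms from an XYZ file; indices are 0-based into the file order."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return _select_ring(symbols, np.array(coords), indices)


def ring_from_sdf(path, indices: Sequence[int] | None = None) -> RingAtomSet:
    """Ring atoms from the first record of an SDF; ring perceived if no indices."""
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=True)
    if mol is None:
        raise ValueError(f"unreadable SDF: {path}")
    coords = np.array(mol.GetConformer().GetPositions())
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    return _select_ring(symbols, coords, indices, mol=mol)


def write_ensemble_sdf(records: list[ConformerRecord], path) -> int:
    """Multi-record SDF of the successful conformers; returns count written."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    n = 0
    for rec in records:
        mol = rec.provenance.get("mol")
        if mol is None or not rec.ok:
            continue
        m = Chem.Mol(mol)
        m.SetProp("_Name", f"conf_{rec.conf_id}")
        if rec.energy is not None:
            m.SetProp("energy_kj", f"{rec.energy:.6f}")
        if rec.rotamer:
            m.SetProp("rotamer", rec.rotamer)
        writer.write(m, confId=rec.conf_id if mol.GetNumConformers() > 1 else -1)
        n += 1
    writer.close()
    return n


def write_manifest(records: list[ConformerRecord], path) -> None:
    manifest(records).to_csv(path, index=False, float_format="%.6f")
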