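"""Conformer records: one 3D structure with provenance and energetics.

The record is the common currency between the grid enumerator, the
energy backends, the thermochemistry layer, the CEL-map builder and the
IR pipeline.  Energies are kJ/mol throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["ConformerRecord", "manifest"]


@dataclass
class ConformerRecord:
    """A single conformer with provenance, energies and vibrational data."""

    conf_id: int
    symbols: list[str] | None = None
    coords: np.ndarray | None = None  # (N, 3) A
    energy: float | None = None  # electronic (or forcefield) energy, kJ/mol
    gibbs: float | None = None  # free energy, kJ/mol
    frequencies: np.ndarray | None = None  # cm^-1
    intensities: np.ndarray | None = None  # km/mol (arbitrary for surrogates)
    n_imaginary: int = 0
    rotamer: str | None = None  # "R1" | "R2"
    dihedrals: tuple[float, float, float] | None = None  # requested grid values
    status: str = "ok"  # "ok" | "failed"
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def has_imaginary(self) -> bool:
        return self.n_imaginary > 0

    def best_energy(self) -> float | None:
        """Gibbs free energy when available, else the electronic energy."""
        return self.gibbs if self.gibbs is not None else self.energy


def manifest(records: list[ConformerRecord]) -> pd.DataFrame:
    """One row per record: dihedrals, rotamer, status, energies."""
    rows = []
    for r in records:
        d = r.dihedrals or (None, None, None)
        rows.append(
            {
                "conf_id": r.conf_id,
                "d1": d[0],
                "d2": d[1],
                "d3": d[2],
                "rotamer": r.rotamer,
                "status": r.status,
                "energy_kj": r.energy,
                "gibbs_kj": r.gibbs,
                "n_imaginary": r.n_imaginary,
            }
        )
    return pd.DataFrame(rows)
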