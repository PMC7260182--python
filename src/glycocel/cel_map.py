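"""Conformational-energy-landscape (CEL) maps over the puckering sphere.

A CEL map bins an ensemble of optimized conformers into slices of the
Cremer-Pople sphere and keeps, per slice cell, the lowest relative Gibbs
free energy.  The slice scheme realizes "one cell per canonical
conformer region": two polar caps (the chairs), two half-chair/envelope
tiers and the equatorial boat/skew belt, the three non-polar bands cut
into twelve 30-deg phi bins centered on the canonical phi values -- 38
cells in total, in bijection with the 38 canonical conformers.

Maps for the two acyl rotamers R1 (participation-capable) and R2 (free
oxocarbenium) share one energy zero so their minima are directly
comparable; the R1-vs-R2 gap is the computational read-out for whether
long-range participation (LRP) is favorable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import pucker
from .records import ConformerRecord
from .thermo import CEL_TEMPERATURE

__all__ = [
    "CELMap",
    "RotamerComparison",
    "SliceBinning",
    "build_map",
    "find_local_minima",
    "compare_rotamers",
    "export_heatmap",
    "collapse_duplicates",
]

KCAL = 4.184  # kJ per kcal


@dataclass(frozen=True)
class SliceBinning:
    """theta-band edges (deg) and phi bin width (deg) for non-polar bands.

    Default band edges separate pole caps, the two H/E tiers and the
    equator belt at the midpoints between canonical tiers (chair 0 deg,
    H/E tier ~52.7 deg, equator 90 deg).
    """

    theta_edges: tuple = (0.0, 26.4, 71.4, 108.6, 153.6, 180.0)
    phi_width: float = 30.0

    @property
    def n_bands(self) -> int:
        return len(self.theta_edges) - 1

    def phi_bins(self, band: int) -> int:
        if band == 0 or band == self.n_bands - 1:
            return 1  # polar caps
        return int(round(360.0 / self.phi_width))

    def cell_of(self, theta: float, phi: float | None) -> tuple[int, int]:
        band = min(
            int(np.searchsorted(self.theta_edges, theta, side="right")) - 1,
            self.n_bands - 1,
        )
        band = max(band, 0)
        if self.phi_bins(band) == 1 or phi is None:
            return (band, 0)
        shifted = (phi + self.phi_width / 2.0) % 360.0
        return (band, int(shifted // self.phi_width))

    def cell_label(self, cell: tuple[int, int]) -> str:
        """Name of the canonical conformer whose region the cell realizes."""
        band, pbin = cell
        if self.phi_bins(band) == 1:
            theta_c = 0.0 if band == 0 else 180.0
            phi_c = None
        else:
            theta_c = 0.5 * (self.theta_edges[band] + self.theta_edges[band + 1])
            phi_c = pbin * self.phi_width
        best, best_d = None, math.inf
        for ref in pucker.canonical_conformers():
            d = pucker._great_circle_distance(theta_c, phi_c, ref.theta_ref, ref.phi_ref)
            if d < best_d - 1e-12:
                best, best_d = ref.name, d
        return best


@dataclass
class CELMap:
    """Binned relative free-energy surface for one rotamer."""

    rotamer: str
    cells: dict  # (band, phi_bin) -> ConformerRecord (lowest energy in cell)
    reference_energy: float  # kJ/mol; the zero of the map
    binning: SliceBinning = field(default_factory=SliceBinning)
    contour_interval: float = 0.5  # kcal/mol
    missing_cells: list = field(default_factory=list)
    n_skipped: int = 0

    def relative_energy(self, cell: tuple[int, int]) -> float:
        """Cell energy relative to the reference, kJ/mol."""
        return self.cells[cell].best_energy() - self.reference_energy

    def min_cell(self) -> tuple[int, int]:
        return min(self.cells, key=self.relative_energy)

    def min_energy(self) -> float:
        return self.relative_energy(self.min_cell())

    def table(self) -> pd.DataFrame:
        rows = []
        for cell in sorted(self.cells):
            rec = self.cells[cell]
            p = pucker.cp_coordinates(rec.coords) if rec.coords is not None else None
            rows.append(
                {
                    "theta_band": cell[0],
                    "phi_bin": cell[1],
                    "conformer": self.binning.cell_label(cell),
                    "delta_g_kj": round(self.relative_energy(cell), 6),
                    "theta": None if p is None or not p.defined else round(p.theta, 3),
                    "phi": None if p is None or not p.defined else round(p.phi, 3),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RotamerComparison:
    """Head-to-head of the R1 and R2 map minima (energies in kcal/mol)."""

    best_r1_kcal: float
    best_r1_conformer: str
    best_r2_kcal: float
    best_r2_conformer: str
    ddg_kcal: float  # G(R1) - G(R2); negative favors the participating rotamer
    threshold_kcal: float
    verdict: str  # "LRP-favorable" | "LRP-unfavorable" | "indeterminate"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=2)


def collapse_duplicates(
    records: Sequence[ConformerRecord],
    rmsd_tol: float = 0.1,
    energy_tol: float = 0.1,
) -> list[ConformerRecord]:
    """Drop conformers duplicating an earlier one.

    Two records collapse when their heavy-atom coordinate RMSD (no
    re-superposition: grid structures share a frame) is below
    ``rmsd_tol`` A and their energies agree within ``energy_tol`` kJ/mol.
    """
    kept: list[ConformerRecord] = []
    for r in records:
        dup = False
        if r.coords is not None and r.energy is not None:
            for k in kept:
                if k.coords is None or k.coords.shape != r.coords.shape:
                    continue
                if (
                    abs((k.energy or 0.0) - r.energy) <= energy_tol
                    and float(np.sqrt(np.mean((k.coords - r.coords) ** 2))) <= rmsd_tol
                ):
                    dup = True
                    break
        if not dup:
            kept.append(r)
    return kept


def _record_pucker(rec: ConformerRecord, ring_indices=None) -> pucker.PuckerCoordinates:
    coords = rec.coords
    if ring_indices is not None:
        coords = coords[list(ring_indices)]
    elif coords.shape[0] != 6:
        raise ValueError("ring_indices required for records with more than six atoms")
    return pucker.cp_coordinates(coords)


def build_map(
    records: Sequence[ConformerRecord],
    rotamer: str,
    binning: SliceBinning | None = None,
    reference_energy: float | None = None,
    ring_indices: Sequence[int] | None = None,
    contour_interval: float = 0.5,
) -> CELMap:
    """Assemble the CEL map of one rotamer from an optimized ensemble.

    Each successful record is located on the puckering sphere via
    ``pucker.cp_coordinates`` and assigned to exactly one slice cell; a
    cell keeps its minimum-energy member (ties broken by input order).
    ``reference_energy`` defaults to the ensemble minimum (self-
    referenced map, min dG = 0); pass the global minimum across both
    rotamers to make R1/R2 maps directly comparable.
    """
    binning = binning or SliceBinning()
    pool = [r for r in records if r.rotamer == rotamer]
    if not pool:
        raise ValueError(f"no records for rotamer {rotamer!r}")
    cells: dict = {}
    failed_points = []
    n_skipped = 0
    for rec in pool:
        if not rec.ok:
            failed_points.append(rec.dihedrals)
            continue
        if rec.best_energy() is None or rec.coords is None:
            n_skipped += 1
            continue
        p = _record_pucker(rec, ring_indices)
        if not p.defined:
            # planar rings land in the north polar cap by convention
            cell = binning.cell_of(0.0, None)
        else:
            cell = binning.cell_of(p.theta, p.phi)
        cur = cells.get(cell)
        if cur is None or rec.best_energy() < cur.best_energy() - 1e-12:
            cells[cell] = rec
    if not cells:
        raise ValueError("all records failed or lacked energies")
    ref = (
        min(r.best_energy() for r in cells.values())
        if reference_energy is None
        else reference_energy
    )
    all_cells = {
        (b, p) for b in range(binning.n_bands) for p in range(binning.phi_bins(b))
    }
    missing = sorted(all_cells - set(cells))
    return CELMap(
        rotamer=rotamer,
        cells=cells,
        reference_energy=ref,
        binning=binning,
        contour_interval=contour_interval,
        missing_cells=missing,
        n_skipped=n_skipped,
    )


def _neighbors(cell: tuple[int, int], binning: SliceBinning):
    band, pbin = cell
    nb = []
    npb = binning.phi_bins(band)
    if npb > 1:  # phi neighbors, periodic
        nb.append((band, (pbin - 1) % npb))
        nb.append((band, (pbin + 1) % npb))
    for b2 in (band - 1, band + 1):
        if b2 < 0 or b2 >= binning.n_bands:
            continue
        npb2 = binning.phi_bins(b2)
        if npb2 == 1:
            nb.append((b2, 0))
        elif npb == 1:  # polar cap touches every bin of the adjacent band
            nb.extend((b2, p) for p in range(npb2))
        else:
            nb.extend((b2, (pbin + d) % npb2) for d in (-1, 0, 1))
    return nb


def find_local_minima(cel: CELMap) -> list[tuple[tuple[int, int], ConformerRecord]]:
    """Occupied cells not exceeded by any occupied neighbor, sorted by dG.

    On a flat surface every occupied cell qualifies (degenerate but
    documented behavior).
    """
    out = []
    for cell in cel.cells:
        e = cel.relative_energy(cell)
        if all(
            e <= cel.relative_energy(nb) + 1e-12
            for nb in _neighbors(cell, cel.binning)
            if nb in cel.cells
        ):
            out.append((cell, cel.cells[cell]))
    out.sort(key=lambda t: (cel.relative_energy(t[0]), t[0]))
    return out


def compare_rotamers(
    map_r1: CELMap, map_r2: CELMap, threshold_kcal: float = 0.5
) -> RotamerComparison:
    """Relative stability of the participating (R1) vs free (R2) rotamer.

    ddG = G(R1_min) - G(R2_min) in kcal/mol; below -threshold the
    dioxolenium-forming rotamer is more stable (LRP-favorable), above
    +threshold it is less stable, in between the call is indeterminate.
    Both maps must share an energy zero.
    """
    if abs(map_r1.reference_energy - map_r2.reference_energy) > 1e-6:
        raise ValueError("maps must be referenced to a common energy zero")
    c1, c2 = map_r1.min_cell(), map_r2.min_cell()
    g1 = map_r1.relative_energy(c1) / KCAL
    g2 = map_r2.relative_energy(c2) / KCAL
    ddg = g1 - g2
    if ddg < -threshold_kcal:
        verdict = "LRP-favorable"
    elif ddg > threshold_kcal:
        verdict = "LRP-unfavorable"
    else:
        verdict = "indeterminate"
    return RotamerComparison(
        best_r1_kcal=g1,
        best_r1_conformer=map_r1.binning.cell_label(c1),
        best_r2_kcal=g2,
        best_r2_conformer=map_r2.binning.cell_label(c2),
        ddg_kcal=ddg,
        threshold_kcal=threshold_kcal,
        verdict=verdict,
    )


def export_heatmap(cel: CELMap, path_prefix: str) -> tuple[str, str]:
    """Write `<prefix>.png` (contoured heat map) and `<prefix>.csv` (cell table).

    The figure shows relative energy (kcal/mol) over (phi, theta) with
    contour lines spaced by the map's contour interval (default 0.5
    kcal/mol, the conventional spacing for these maps).  The CSV is
    byte-stable for a given map.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cel.table()
    csv_path = f"{path_prefix}.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")

    # rasterize cells onto a (theta, phi) image for plotting
    tgrid = np.linspace(0.0, 180.0, 181)
    pgrid = np.linspace(0.0, 360.0, 361)
    img = np.full((tgrid.size, pgrid.size), np.nan)
    for i, th in enumerate(tgrid):
        for j, ph in enumerate(pgrid):
            cell = cel.binning.cell_of(th, ph % 360.0)
            if cell in cel.cells:
                img[i, j] = cel.relative_energy(cell) / KCAL
    fig, ax = plt.subplots(figsize=(7, 4))
    mesh = ax.pcolormesh(pgrid, tgrid, img, cmap="viridis_r", shading="auto")
    finite = img[np.isfinite(img)]
    if finite.size:
        levels = np.arange(0.0, finite.max() + cel.contour_interval, cel.contour_interval)
        if levels.size > 1:
            ax.contour(pgrid, tgrid, np.nan_to_num(img, nan=finite.max()),
                       levels=levels, colors="k", linewidths=0.4)
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("theta (deg)")
    ax.invert_yaxis()
    ax.set_title(f"CEL map, rotamer {cel.rotamer}")
    fig.colorbar(mesh, ax=ax, label="dG (kcal/mol)")
    png_path = f"{path_prefix}.png"
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return png_path, csv_path
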