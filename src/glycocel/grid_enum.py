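"""Dihedral-grid enumeration and constrained conformer generation.

The complete pucker space of a six-membered ring is spanned by scanning
three alternating endocyclic dihedrals -- C1-C2-C3-C4, C3-C4-C5-O5 and
C5-O5-C1-C2 -- from -60 to +60 deg in 15 deg steps: 9^3 = 729 prefixed
conformations per acyl rotamer.  The acyl rotamer (R1: carbonyl pointing
toward C1, participation-capable; R2: pointing away) is a fourth,
two-valued torsional coordinate.

Two execution paths share the grid:

* ring-only (toy) path: the ring geometry realizing a dihedral triple is
  solved in closed loop through the Cremer-Pople parametrization (3
  pucker degrees of freedom <-> 3 alternating dihedrals) and scored by
  an analytic backend;
* molecular path: the solved ring seeds a distance-geometry embedding of
  the full molecule, which is then minimized under harmonic torsion
  restraints by a forcefield backend, with a verification pass on the
  constrained dihedrals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .pucker import RingAtomSet, cp_coordinates, _J
from .records import ConformerRecord

__all__ = [
    "DihedralGridPoint",
    "GridSpec",
    "generate_grid",
    "ring_from_dihedrals",
    "perceive_pyranose_ring",
    "detect_rotamer_torsion",
    "embed_constrained",
    "run_grid",
    "DIHEDRAL_QUADS",
]

#: ring-index quadruples (into the O5,C1..C5 ordering) of the scanned dihedrals
DIHEDRAL_QUADS = ((1, 2, 3, 4), (3, 4, 5, 0), (5, 0, 1, 2))

ROTAMER_TARGETS = {"R1": 0.0, "R2": 180.0}


@dataclass(frozen=True)
class DihedralGridPoint:
    """One prefixed conformation: three ring dihedrals plus a rotamer label."""

    d1: float  # C1-C2-C3-C4, deg
    d2: float  # C3-C4-C5-O5, deg
    d3: float  # C5-O5-C1-C2, deg
    rotamer: str = "R1"


@dataclass(frozen=True)
class GridSpec:
    """Scan range and step for the three ring dihedrals."""

    lo: float = -60.0
    hi: float = 60.0
    step: float = 15.0
    rotamer_targets: dict = field(default_factory=lambda: dict(ROTAMER_TARGETS))

    def values(self) -> np.ndarray:
        span = self.hi - self.lo
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = span / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"range {self.lo}..{self.hi} not divisible by step {self.step}"
            )
        return self.lo + self.step * np.arange(int(round(n)) + 1)


def generate_grid(spec: GridSpec | None = None, rotamer: str = "R1") -> list[DihedralGridPoint]:
    """Cartesian product of the per-dihedral value lists for one rotamer.

    Deterministic lexicographic ordering by (d1, d2, d3); the default
    spec yields 9^3 = 729 points.
    """
    spec = spec or GridSpec()
    vals = spec.values()
    return [
        DihedralGridPoint(float(a), float(b), float(c), rotamer)
        for a, b, c in itertools.product(vals, vals, vals)
    ]


# --------------------------------------------------------------------------
# dihedral triple <-> ring geometry (via the Cremer-Pople modes)
# --------------------------------------------------------------------------

def _dihedral(coords: np.ndarray, quad: tuple[int, int, int, int]) -> float:
    # sign convention matches RDKit's rdMolTransforms.GetDihedralDeg
    p0, p1, p2, p3 = (coords[i] for i in quad)
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(-float(np.dot(m, n2)), float(np.dot(n1, n2))))


def ring_dihedrals(coords: np.ndarray) -> tuple[float, float, float]:
    """The three scanned dihedrals of a ring in canonical atom order."""
    return tuple(_dihedral(coords, q) for q in DIHEDRAL_QUADS)


def _ring_from_q(q2x: float, q2y: float, q3: float, bond: float = 1.45) -> np.ndarray:
    z = (
        math.sqrt(1.0 / 3.0) * (q2x * np.cos(4 * np.pi * _J / 6) - q2y * np.sin(4 * np.pi * _J / 6))
        + math.sqrt(1.0 / 6.0) * q3 * (-1.0) ** _J
    )
    ang = -2.0 * np.pi * _J / 6.0
    return np.column_stack([bond * np.cos(ang), bond * np.sin(ang), z])


def ring_from_dihedrals(
    d1: float, d2: float, d3: float, tol: float = 1.0
) -> tuple[RingAtomSet | None, float]:
    """Solve for a closed ring realizing the three alternating dihedrals.

    Memoized: grid runs revisit the same 729 triples for every rotamer
    and backend.  See the cached worker below for the method.
    """
    return _ring_from_dihedrals_cached(round(d1, 6), round(d2, 6), round(d3, 6), tol)


@lru_cache(maxsize=4096)
def _ring_from_dihedrals_cached(
    d1: float, d2: float, d3: float, tol: float
) -> tuple[RingAtomSet | None, float]:
    """Solve for a closed ring whose three alternating dihedrals match.

    The ring is parametrized by the three Cremer-Pople mode amplitudes
    (q2x, q2y, q3), which guarantees closure; a least-squares solve
    matches the dihedral targets.  Returns (ring, max residual in deg);
    ring is None when the residual exceeds ``tol`` (geometrically
    unsatisfiable corner of the grid).
    """
    target = np.array([d1, d2, d3], dtype=float)

    def resid(x):
        c = _ring_from_q(*x)
        return np.array(ring_dihedrals(c)) - target

    best = None
    # pucker-sign ambiguity: try both chair-like starting basins
    for x0 in ((0.05, 0.05, 0.3), (0.05, 0.05, -0.3), (0.3, 0.3, 0.0)):
        sol = least_squares(resid, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12)
        err = float(np.max(np.abs(sol.fun)))
        if best is None or err < best[1]:
            best = (sol.x, err)
        if err < 1e-6:
            break
    x, err = best
    if err > tol:
        return None, err
    return RingAtomSet(_ring_from_q(*x)), err


# --------------------------------------------------------------------------
# ring / rotamer perception on RDKit molecules
# --------------------------------------------------------------------------

def perceive_pyranose_ring(mol, explicit: Sequence[int] | None = None) -> dict[str, int]:
    """Map canonical ring labels O5, C1..C5 to atom indices.

    ``explicit`` supplies six indices already in canonical order.
    Otherwise the first six-membered ring containing exactly one oxygen
    is used; C1 is the ring-oxygen neighbor that is cationic or sp2
    (anomeric/oxocarbenium), falling back to the neighbor carrying an
    exocyclic oxygen, then to the lower atom index.
    """
    if explicit is not None:
        if len(explicit) != 6:
            raise ValueError("explicit ring selection must have six indices")
        return dict(zip(("O5", "C1", "C2", "C3", "C4", "C5"), explicit))
    ri = mol.GetRingInfo()
    ring = None
    for r in ri.AtomRings():
        if len(r) != 6:
            continue
        oxy = [i for i in r if mol.GetAtomWithIdx(i).GetSymbol() == "O"]
        if len(oxy) == 1:
            ring = list(r)
            o5 = oxy[0]
            break
    if ring is None:
        raise ValueError("no six-membered ring with exactly one oxygen found")
    # orient the cycle starting at O5
    k = ring.index(o5)
    cyc = ring[k:] + ring[:k]
    nb1, nb2 = cyc[1], cyc[-1]

    def c1_score(idx: int) -> tuple:
        a = mol.GetAtomWithIdx(idx)
        exo_o = any(
            n.GetSymbol() == "O" and n.GetIdx() not in ring for n in a.GetNeighbors()
        )
        from rdkit.Chem import HybridizationType

        return (
            a.GetFormalCharge() > 0,
            a.GetHybridization() == HybridizationType.SP2,
            exo_o,
            -idx,
        )

    if c1_score(nb2) > c1_score(nb1):
        cyc = [cyc[0]] + cyc[1:][::-1]
    return dict(zip(("O5", "C1", "C2", "C3", "C4", "C5"), cyc))


def detect_rotamer_torsion(mol, ring: dict[str, int]) -> tuple[int, int, int, int]:
    """Locate the acyl C-O rotamer torsion (ref, C_attach, O_ester, C_carbonyl).

    Searches for an ester oxygen bonded to a ring (or exocyclic CH2)
    carbon on one side and a carbonyl carbon on the other.  The
    reference atom is the attachment carbon's heavy-atom neighbor lying
    toward C1 around the ring, so the R1 target (0 deg, syn) points the
    carbonyl toward the anomeric center and R2 (180 deg) away from it.
    """
    ring_idx = set(ring.values())
    order = [ring["C1"], ring["C2"], ring["C3"], ring["C4"], ring["C5"], ring["O5"]]
    for o in mol.GetAtoms():
        if o.GetSymbol() != "O" or o.GetIdx() in ring_idx or o.GetDegree() != 2:
            continue
        nbrs = [n for n in o.GetNeighbors()]
        carbonyl = attach = None
        for n in nbrs:
            if n.GetSymbol() != "C":
                continue
            if any(
                b.GetBondTypeAsDouble() == 2.0
                and b.GetOtherAtom(n).GetSymbol() == "O"
                for b in n.GetBonds()
            ):
                carbonyl = n
            else:
                attach = n
        if carbonyl is None or attach is None:
            continue
        # reference: heavy neighbor of the attachment carbon nearest C1
        cand = [
            n.GetIdx()
            for n in attach.GetNeighbors()
            if n.GetIdx() != o.GetIdx() and n.GetAtomicNum() > 1
        ]
        if not cand:
            continue

        def toward_c1(idx: int) -> int:
            return order.index(idx) if idx in order else 99

        ref = min(cand, key=toward_c1)
        return (ref, attach.GetIdx(), o.GetIdx(), carbonyl.GetIdx())
    raise ValueError("no acyl ester C-O torsion found (ester attachment required)")


# --------------------------------------------------------------------------
# constrained embedding
# --------------------------------------------------------------------------

def embed_constrained(
    mol,
    point: DihedralGridPoint,
    backend,
    spec: GridSpec | None = None,
    ring: dict[str, int] | None = None,
    conf_id: int = 0,
    seed: int = 7,
    tol: float = 1.0,
) -> ConformerRecord:
    """Produce one optimized conformer at a grid point.

    When ``mol`` is None the ring-only path is used: the dihedral triple
    is converted to a closed ring geometry and scored by the backend
    (which must accept bare ring coordinates, e.g. the toy backend).

    Otherwise the full molecule is embedded with the solved ring as a
    coordinate map, minimized under torsion restraints on the three ring
    dihedrals and the rotamer torsion, and verified: a conformer whose
    constrained dihedrals deviate more than ``tol`` deg is returned with
    status "failed" (the CEL map records the cell as missing).
    """
    spec = spec or GridSpec()
    ring_set, err = ring_from_dihedrals(point.d1, point.d2, point.d3)
    if ring_set is None:
        return ConformerRecord(
            conf_id=conf_id,
            rotamer=point.rotamer,
            dihedrals=(point.d1, point.d2, point.d3),
            status="failed",
            provenance={"reason": f"ring closure residual {err:.2f} deg"},
        )
    if mol is None:
        e = backend.energy(ring_set.coords, point.rotamer)
        return ConformerRecord(
            conf_id=conf_id,
            symbols=list(ring_set.labels),
            coords=ring_set.coords,
            energy=e,
            rotamer=point.rotamer,
            dihedrals=(point.d1, point.d2, point.d3),
            provenance={"path": "ring-only", "backend": backend.name},
        )

    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit.Geometry import Point3D

    if ring is None:
        ring = perceive_pyranose_ring(mol)
    labels = ("O5", "C1", "C2", "C3", "C4", "C5")
    mol = Chem.Mol(mol)
    coord_map = {
        ring[lab]: Point3D(*ring_set.coords[i]) for i, lab in enumerate(labels)
    }
    cid = -1
    for rand_coords, s in ((False, seed), (True, seed), (False, seed + 1), (True, seed + 1)):
        params = AllChem.ETKDGv3()
        params.randomSeed = s
        params.useRandomCoords = rand_coords
        params.SetCoordMap(coord_map)
        cid = AllChem.EmbedMolecule(mol, params)
        if cid >= 0:
            break
    if cid < 0:
        return ConformerRecord(
            conf_id=conf_id,
            rotamer=point.rotamer,
            dihedrals=(point.d1, point.d2, point.d3),
            status="failed",
            provenance={"reason": "embedding failure"},
        )
    ridx = [ring[lab] for lab in labels]
    quads = [tuple(ridx[i] for i in q) for q in DIHEDRAL_QUADS]
    targets = [point.d1, point.d2, point.d3]
    constraints = [(*q, t) for q, t in zip(quads, targets)]
    try:
        rot_quad = detect_rotamer_torsion(mol, ring)
        rot_target = spec.rotamer_targets[point.rotamer]
        constraints.append((*rot_quad, rot_target))
    except ValueError:
        rot_quad = None
    energy, _ = backend.optimize(mol, cid, torsion_constraints=constraints)
    coords = np.array(mol.GetConformer(cid).GetPositions())
    achieved = [_dihedral(coords, q) for q in quads]
    dev = max(
        abs((a - t + 180.0) % 360.0 - 180.0) for a, t in zip(achieved, targets)
    )
    status = "ok" if dev <= tol else "failed"
    return ConformerRecord(
        conf_id=conf_id,
        symbols=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        energy=energy,
        rotamer=point.rotamer,
        dihedrals=(point.d1, point.d2, point.d3),
        status=status,
        provenance={
            "path": "molecular",
            "backend": backend.name,
            "dihedral_deviation_deg": dev,
            "achieved": achieved,
            "mol": mol,
        },
    )


def run_grid(
    mol,
    backend,
    spec: GridSpec | None = None,
    rotamers: Sequence[str] = ("R1", "R2"),
    seed: int = 7,
) -> list[ConformerRecord]:
    """Enumerate the grid for each rotamer and embed every point."""
    spec = spec or GridSpec()
    out: list[ConformerRecord] = []
    cid = 0
    for rot in rotamers:
        for pt in generate_grid(spec, rot):
            out.append(
                embed_constrained(mol, pt, backend, spec=spec, conf_id=cid, seed=seed)
            )
            cid += 1
    return out
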