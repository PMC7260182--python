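"""Pluggable energy/frequency backends.

Three tiers share one contract:

* :class:`ToyPuckerBackend` -- an analytic surface over the puckering
  sphere and the acyl-rotamer torsion.  Deterministic, gradient-free,
  desk-scale; used to plant known minima for end-to-end validation.
* :class:`ForceFieldBackend` -- RDKit MMFF94/UFF: constrained
  optimization, energies, and surrogate vibrational analysis (numerical
  Hessian of the forcefield plus fixed-charge dipole derivatives for IR
  intensities).  Also serves as the screening-backend slot that a
  semi-empirical method occupies in a production setup.
* :class:`GaussianAdapter` -- file-based interface to an external
  quantum-chemistry program using a widely used input/log dialect.  The
  program itself is never run here; the adapter writes input decks and
  parses logs into the neutral interchange records.

Energies are hartree inside QC results and kJ/mol at every other
boundary; conversions are exact round trips.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants

__all__ = [
    "HARTREE_TO_KJ",
    "KCAL_TO_KJ",
    "hartree_to_kj",
    "kj_to_hartree",
    "QCResult",
    "ParseError",
    "EnergyBackend",
    "ToyWell",
    "ToyPuckerBackend",
    "ForceFieldBackend",
    "GaussianAdapter",
    "write_interchange",
    "read_interchange",
]

HARTREE_TO_KJ = constants.physical_constants["Hartree energy"][0] * constants.N_A / 1000.0
KCAL_TO_KJ = constants.calorie  # 4.184


def hartree_to_kj(e: float) -> float:
    return e * HARTREE_TO_KJ


def kj_to_hartree(e: float) -> float:
    return e / HARTREE_TO_KJ


class ParseError(ValueError):
    """A QC log was truncated or missing a required section."""


@dataclass
class QCResult:
    """Parsed quantum-chemistry result (energy in hartree)."""

    energy: float
    symbols: list[str]
    coords: np.ndarray  # (N, 3) A
    frequencies: np.ndarray = field(default_factory=lambda: np.array([]))
    intensities: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.size != self.intensities.size:
            raise ValueError("frequency and intensity lists must have equal length")

    @property
    def n_imaginary(self) -> int:
        return int(np.sum(self.frequencies < 0))

    @property
    def energy_kj(self) -> float:
        return hartree_to_kj(self.energy)


class EnergyBackend:
    """Contract for energy providers.

    Subclasses declare ``capabilities`` (subset of {"energy", "optimize",
    "frequencies", "intensities"}) and honor exactly those.
    """

    name: str = "abstract"
    capabilities: frozenset = frozenset()
    level: str = ""
    solvent: str | None = None

    def energy(self, *args, **kwargs) -> float:  # kJ/mol
        raise NotImplementedError

    def optimize(self, *args, **kwargs):
        raise NotImplementedError

    def frequencies(self, *args, **kwargs):
        raise NotImplementedError


# --------------------------------------------------------------------------
# toy analytic backend
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyWell:
    """A Gaussian well planted on the puckering sphere.

    ``theta``/``phi`` in degrees, ``depth`` in kJ/mol (positive = a
    stabilization), ``width`` = Gaussian sigma in degrees of great-circle
    distance, and the rotamer whose surface carries the well (None = both).
    """

    theta: float
    phi: float | None
    depth: float
    width: float = 25.0
    rotamer: str | None = None


class ToyPuckerBackend(EnergyBackend):
    """Analytic energy as a function of (theta, phi, rotamer).

    E = baseline - sum_wells depth * exp(-d^2 / 2 width^2) + offset[rotamer]

    with d the great-circle distance (deg) to the well center.  Smooth,
    deterministic, and its global/local minima are known by construction,
    which makes it the parameter-recovery oracle for the CEL pipeline.
    """

    name = "toy"
    capabilities = frozenset({"energy"})
    level = "analytic pucker surface"

    def __init__(
        self,
        wells: Sequence[ToyWell],
        baseline: float = 50.0,
        rotamer_offsets: dict[str, float] | None = None,
    ):
        self.wells = tuple(wells)
        self.baseline = float(baseline)
        self.rotamer_offsets = dict(rotamer_offsets or {})

    def energy_at(self, theta: float, phi: float, rotamer: str | None = None) -> float:
        from .pucker import _great_circle_distance

        e = self.baseline + self.rotamer_offsets.get(rotamer, 0.0)
        for w in self.wells:
            if w.rotamer is not None and rotamer is not None and w.rotamer != rotamer:
                continue
            d = _great_circle_distance(theta, phi, w.theta, w.phi)
            e -= w.depth * math.exp(-(d * d) / (2.0 * w.width * w.width))
        return e

    def energy(self, ring_coords, rotamer: str | None = None) -> float:
        """Energy of a ring geometry (6x3 array or RingAtomSet)."""
        from .pucker import cp_coordinates

        p = cp_coordinates(ring_coords)
        if not p.defined:
            return self.baseline + self.rotamer_offsets.get(rotamer, 0.0)
        return self.energy_at(p.theta, p.phi, rotamer)


# --------------------------------------------------------------------------
# RDKit forcefield backend
# --------------------------------------------------------------------------

# conversion: kcal/(mol A^2 amu) -> s^-2
_FF_HESS_TO_SI = KCAL_TO_KJ * 1000.0 / constants.N_A / 1e-20 / constants.atomic_mass
_TO_WAVENUMBER = 1.0 / (2.0 * math.pi * constants.c * 100.0)


class ForceFieldBackend(EnergyBackend):
    """Classical-forcefield energies via RDKit (MMFF94 with UFF fallback).

    Provides constrained optimization (harmonic torsion restraints plus a
    verification pass by the caller), single-point energies, and a
    surrogate vibrational analysis: the mass-weighted numerical Hessian
    of the forcefield gives harmonic frequencies, and Gasteiger-charge
    dipole derivatives give relative IR intensities.  This is a
    fixed-charge approximation, adequate for exercising the pipeline, not
    for quantitative band intensities.
    """

    name = "forcefield"
    capabilities = frozenset({"energy", "optimize", "frequencies", "intensities"})
    level = "MMFF94/UFF"

    def __init__(self, prefer: str = "mmff", torsion_force_constant: float = 1.0e4):
        self.prefer = prefer
        self.k_torsion = torsion_force_constant

    def _get_ff(self, mol, conf_id: int):
        from rdkit.Chem import AllChem

        if self.prefer == "mmff" and AllChem.MMFFHasAllMoleculeParams(mol):
            props = AllChem.MMFFGetMoleculeProperties(mol)
            return AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf_id), "mmff"
        return AllChem.UFFGetMoleculeForceField(mol, confId=conf_id), "uff"

    def energy(self, mol, conf_id: int = -1) -> float:
        ff, _ = self._get_ff(mol, conf_id)
        return ff.CalcEnergy() * KCAL_TO_KJ

    def optimize(
        self,
        mol,
        conf_id: int = -1,
        torsion_constraints: Sequence[tuple[int, int, int, int, float]] = (),
        max_iters: int = 500,
    ) -> tuple[float, bool]:
        """Minimize one conformer; returns (energy kJ/mol, converged).

        ``torsion_constraints`` are (i, j, k, l, target_deg) quadruples
        restrained harmonically at the target during minimization.
        """
        ff, flavor = self._get_ff(mol, conf_id)
        for (i, j, k, l, deg) in torsion_constraints:
            if flavor == "mmff":
                ff.MMFFAddTorsionConstraint(i, j, k, l, False, deg, deg, self.k_torsion)
            else:
                ff.UFFAddTorsionConstraint(i, j, k, l, False, deg, deg, self.k_torsion)
        ff.Initialize()
        status = ff.Minimize(maxIts=max_iters)
        # energy re-evaluated without restraint terms
        ff2, _ = self._get_ff(mol, conf_id)
        return ff2.CalcEnergy() * KCAL_TO_KJ, status == 0

    def frequencies(
        self, mol, conf_id: int = -1, step: float = 1.0e-3
    ) -> tuple[np.ndarray, np.ndarray, int]:
        """Surrogate harmonic frequencies (cm^-1), IR intensities, n_imaginary.

        Central-difference Hessian of the forcefield gradient,
        mass-weighted and diagonalized; the six smallest-|eigenvalue|
        modes (translation/rotation) are discarded.  Intensities are
        |sum_i q_i l_i|^2 per mode from Gasteiger charges (arbitrary
        units, non-negative).
        """
        from rdkit.Chem import AllChem

        n = mol.GetNumAtoms()
        conf = mol.GetConformer(conf_id)
        x0 = np.array(conf.GetPositions(), dtype=float).ravel()
        ff, _ = self._get_ff(mol, conf_id)

        def grad(x: np.ndarray) -> np.ndarray:
            for a in range(n):
                conf.SetAtomPosition(a, x[3 * a : 3 * a + 3].tolist())
            ff.Initialize()
            return np.array(ff.CalcGrad(), dtype=float)

        dim = 3 * n
        hess = np.empty((dim, dim))
        for c in range(dim):
            xp = x0.copy(); xp[c] += step
            xm = x0.copy(); xm[c] -= step
            hess[:, c] = (grad(xp) - grad(xm)) / (2.0 * step)
        for a in range(n):  # restore geometry
            conf.SetAtomPosition(a, x0[3 * a : 3 * a + 3].tolist())
        hess = 0.5 * (hess + hess.T)

        masses = np.array([at.GetMass() for at in mol.GetAtoms()], dtype=float)
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
        mw = hess * inv_sqrt_m[:, None] * inv_sqrt_m[None, :] * _FF_HESS_TO_SI
        evals, evecs = np.linalg.eigh(mw)
        order = np.argsort(np.abs(evals))
        vib = np.sort(order[6:])  # drop 6 translation/rotation modes
        lam = evals[vib]
        freqs = np.sign(lam) * np.sqrt(np.abs(lam)) * _TO_WAVENUMBER

        AllChem.ComputeGasteigerCharges(mol)
        q = np.array(
            [at.GetDoubleProp("_GasteigerCharge") for at in mol.GetAtoms()], dtype=float
        )
        q = np.nan_to_num(q)
        modes = (evecs[:, vib] * inv_sqrt_m[:, None]).T.reshape(len(vib), n, 3)
        mu_deriv = np.einsum("i,kid->kd", q, modes)
        intens = np.sum(mu_deriv**2, axis=1)

        idx = np.argsort(freqs)
        freqs, intens = freqs[idx], intens[idx]
        return freqs, intens, int(np.sum(freqs < -1.0))


# --------------------------------------------------------------------------
# external QC dialect adapter
# --------------------------------------------------------------------------

_SOLVENT_NAMES = {
    "dichloromethane": "Dichloromethane",
    "dcm": "Dichloromethane",
    "ch2cl2": "Dichloromethane",
    "water": "Water",
}

_JOB_KEYWORDS = {
    "opt": "opt",
    "freq": "freq",
    "opt+freq": "opt freq",
    "single-point": "",
}


class GaussianAdapter(EnergyBackend):
    """Writes input decks for, and parses logs from, a common QC dialect.

    The external program is interfaced, never executed: the adapter is
    the boundary where cluster-scale electronic structure would plug in.
    """

    name = "gaussian"
    capabilities = frozenset({"energy", "frequencies", "intensities"})

    def __init__(self, level: str = "B3LYP/6-311G(d,p)", solvent: str | None = None):
        self.level = level
        self.solvent = solvent

    def write_input(
        self,
        symbols: Sequence[str],
        coords: np.ndarray,
        charge: int = 0,
        multiplicity: int = 1,
        job: str = "opt",
        constraints: Sequence[tuple[int, int, int, int]] = (),
        title: str = "glycocel job",
    ) -> str:
        """Emit a byte-stable input deck.

        ``constraints`` are 0-based dihedral quadruples frozen during
        optimization (written 1-based in the deck).  Raises a
        configuration error for unsupported job types.
        """
        if job not in _JOB_KEYWORDS:
            raise ValueError(f"unsupported job type {job!r}")
        if constraints and job not in ("opt", "opt+freq"):
            raise ValueError("dihedral constraints require an optimization job")
        route = ["#p", self.level]
        kw = _JOB_KEYWORDS[job]
        if constraints:
            kw = kw.replace("opt", "opt=modredundant")
        if kw:
            route.append(kw)
        if self.solvent:
            name = _SOLVENT_NAMES.get(self.solvent.lower(), self.solvent)
            route.append(f"scrf=(pcm,solvent={name})")
        lines = [" ".join(route), "", title, "", f"{charge} {multiplicity}"]
        coords = np.asarray(coords, dtype=float)
        for s, (x, y, z) in zip(symbols, coords):
            lines.append(f" {s:<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
        lines.append("")
        for (i, j, k, l) in constraints:
            lines.append(f"D {i + 1} {j + 1} {k + 1} {l + 1} F")
        if constraints:
            lines.append("")
        return "\n".join(lines) + "\n"

    @staticmethod
    def parse_output(text: str, expect_frequencies: bool = False) -> QCResult:
        """Parse a log into a QCResult; raises ParseError naming what is missing."""
        energies = re.findall(
            r"SCF Done:\s+E\([^)]+\)\s*=\s*(-?\d+\.\d+)", text
        )
        if not energies:
            raise ParseError("missing SCF energy section")
        energy = float(energies[-1])

        lines = text.splitlines()
        starts = [
            i for i, ln in enumerate(lines)
            if "Standard orientation:" in ln or "Input orientation:" in ln
        ]
        if not starts:
            raise ParseError("missing geometry (orientation) section")
        from rdkit.Chem import GetPeriodicTable

        pt = GetPeriodicTable()
        symbols, coords = [], []
        atom_re = re.compile(
            r"^\s*\d+\s+(\d+)\s+\S+\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$"
        )
        for ln in lines[starts[-1] + 1 :]:
            m = atom_re.match(ln)
            if m:
                symbols.append(pt.GetElementSymbol(int(m.group(1))))
                coords.append([float(m.group(i)) for i in (2, 3, 4)])
            elif symbols and "----" in ln:
                break
        if not symbols:
            raise ParseError("empty geometry block")

        freqs = [
            float(v)
            for m in re.findall(r"Frequencies\s*--\s*(.+)", text)
            for v in m.split()
        ]
        intens = [
            float(v)
            for m in re.findall(r"IR Inten\s*--\s*(.+)", text)
            for v in m.split()
        ]
        if expect_frequencies and not freqs:
            raise ParseError("missing frequency block")
        return QCResult(
            energy=energy,
            symbols=symbols,
            coords=np.array(coords),
            frequencies=np.array(freqs),
            intensities=np.array(intens) if intens else np.zeros(len(freqs)),
        )


# --------------------------------------------------------------------------
# neutral interchange format (JSON lines, one record per conformer)
# --------------------------------------------------------------------------

def write_interchange(results: Sequence[QCResult], path) -> None:
    """Serialize QC results to the line-oriented neutral interchange file."""
    with open(path, "w") as fh:
        for r in results:
            fh.write(
                json.dumps(
                    {
                        "energy_hartree": r.energy,
                        "symbols": list(r.symbols),
                        "coords": np.asarray(r.coords).tolist(),
                        "frequencies": r.frequencies.tolist(),
                        "intensities": r.intensities.tolist(),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_interchange(path) -> list[QCResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(
                QCResult(
                    energy=d["energy_hartree"],
                    symbols=d["symbols"],
                    coords=np.array(d["coords"]),
                    frequencies=np.array(d["frequencies"]),
                    intensities=np.array(d["intensities"]),
                )
            )
    return out
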