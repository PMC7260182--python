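"""Harmonic / quasi-harmonic thermochemistry and Boltzmann weighting.

Rigid-rotor--harmonic-oscillator (RRHO) corrections from harmonic
frequencies.  The quasi-harmonic scheme guards the entropy against the
divergence of nearly-free torsional modes by raising every frequency
below a cutoff (default 100 cm^-1) to the cutoff before the entropy
evaluation; enthalpic terms keep the raw frequencies.  An alternative
quasi-harmonic flavor interpolates the entropy toward a free-rotor
expression; only frequency raising is implemented here.

Units: frequencies in cm^-1, temperatures in K, energies in kJ/mol,
entropies in J/(mol K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants

__all__ = [
    "ThermoResult",
    "thermo_corrections",
    "boltzmann_weights",
    "CEL_TEMPERATURE",
    "IR_TEMPERATURE",
    "QH_CUTOFF",
]

#: default temperature for conformational-energy-landscape free energies (K)
CEL_TEMPERATURE = 213.15
#: default temperature for IR-ensemble free energies (K)
IR_TEMPERATURE = 298.0
#: default quasi-harmonic frequency-raising cutoff (cm^-1)
QH_CUTOFF = 100.0

R = constants.R  # J/(mol K)
# hc/k in cm*K: converts wavenumber to a vibrational temperature
_HC_OVER_K = constants.h * constants.c * 100.0 / constants.k
# ZPE per cm^-1 in kJ/mol: N_A * h * c / 2
_ZPE_PER_CM = constants.N_A * constants.h * constants.c * 100.0 / 2.0 / 1000.0


@dataclass(frozen=True)
class ThermoResult:
    """RRHO thermochemical corrections at one temperature."""

    zpe: float  # kJ/mol
    thermal: float  # enthalpy correction beyond ZPE, kJ/mol
    entropy: float  # total entropy, J/(mol K)
    gibbs_correction: float  # zpe + thermal - T*S, kJ/mol
    temperature: float  # K
    scheme: str  # "harmonic" | "quasi-harmonic"
    gibbs: float | None = None  # electronic + correction, when electronic given

    def apply(self, electronic_kj: float) -> float:
        """Gibbs free energy (kJ/mol) for a given electronic energy."""
        return electronic_kj + self.gibbs_correction


def _vibrational_entropy(freqs: np.ndarray, T: float) -> float:
    if freqs.size == 0:
        return 0.0
    x = _HC_OVER_K * freqs / T
    return float(R * np.sum(x / np.expm1(x) - np.log(-np.expm1(-x))))


def _vibrational_thermal(freqs: np.ndarray, T: float) -> float:
    """Thermal vibrational energy beyond ZPE, kJ/mol."""
    if freqs.size == 0:
        return 0.0
    x = _HC_OVER_K * freqs / T
    return float(R * T * np.sum(x / np.expm1(x))) / 1000.0


def _trans_rot(T: float, mass_amu: float | None, inertia_amu_A2, sigma: int):
    """Ideal-gas translational/rotational entropy (J/mol K) and enthalpy (kJ/mol)."""
    S = 0.0
    H = 0.0
    if mass_amu is not None:
        m = mass_amu * constants.atomic_mass
        p = constants.atm
        lam3 = (2.0 * np.pi * m * constants.k * T / constants.h**2) ** 1.5
        S += R * (np.log(lam3 * constants.k * T / p) + 2.5)
        H += 2.5 * R * T / 1000.0  # 3/2 RT + pV
    if inertia_amu_A2 is not None:
        I = np.asarray(inertia_amu_A2, dtype=float) * constants.atomic_mass * 1e-20
        I = I[I > 1e-60]
        if I.size >= 3:
            theta = constants.hbar**2 / (2.0 * I * constants.k)
            q_rot = np.sqrt(np.pi) / sigma * np.sqrt(np.prod(T / theta))
            S += R * (np.log(q_rot) + 1.5)
            H += 1.5 * R * T / 1000.0
        elif I.size > 0:  # linear
            theta = constants.hbar**2 / (2.0 * I[0] * constants.k)
            S += R * (np.log(T / (sigma * theta)) + 1.0)
            H += R * T / 1000.0
    return S, H


def thermo_corrections(
    frequencies: Sequence[float],
    T: float = IR_TEMPERATURE,
    scheme: str = "quasi-harmonic",
    qh_cutoff: float = QH_CUTOFF,
    *,
    mass_amu: float | None = None,
    inertia_amu_A2: Sequence[float] | None = None,
    symmetry_number: int = 1,
    electronic_kj: float | None = None,
) -> ThermoResult:
    """RRHO thermochemical corrections from harmonic frequencies.

    Parameters
    ----------
    frequencies
        Real harmonic frequencies in cm^-1.  Negative entries (imaginary
        modes) are rejected: screen them out upstream using the
        imaginary-frequency flag of the conformer record.
    T, scheme, qh_cutoff
        Temperature; "harmonic" or "quasi-harmonic"; under the
        quasi-harmonic scheme frequencies below ``qh_cutoff`` are raised
        to the cutoff for the entropy evaluation only.
    mass_amu, inertia_amu_A2, symmetry_number
        When supplied, translational and rigid-rotor rotational ideal-gas
        contributions (1 atm standard state) are included; the symmetry
        number defaults to 1, appropriate for asymmetric cations.
    electronic_kj
        Optional electronic energy; when given, ``gibbs`` is filled in.

    Both schemes agree exactly when every frequency >= ``qh_cutoff``.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if scheme not in ("harmonic", "quasi-harmonic"):
        raise ValueError(f"unknown scheme {scheme!r}")
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size and freqs.min() <= 0:
        raise ValueError(
            "negative/zero frequency encountered: remove imaginary modes "
            "(see the conformer record's imaginary-frequency flag) before "
            "computing thermochemistry"
        )
    zpe = float(_ZPE_PER_CM * freqs.sum())
    entropy_freqs = freqs
    if scheme == "quasi-harmonic":
        entropy_freqs = np.maximum(freqs, qh_cutoff)
    S_vib = _vibrational_entropy(entropy_freqs, T)
    H_vib = _vibrational_thermal(freqs, T)
    S_tr, H_tr = _trans_rot(T, mass_amu, inertia_amu_A2, symmetry_number)
    entropy = S_vib + S_tr
    thermal = H_vib + H_tr
    gcorr = zpe + thermal - T * entropy / 1000.0
    gibbs = None if electronic_kj is None else electronic_kj + gcorr
    return ThermoResult(
        zpe=zpe,
        thermal=thermal,
        entropy=entropy,
        gibbs_correction=gcorr,
        temperature=T,
        scheme=scheme,
        gibbs=gibbs,
    )


def boltzmann_weights(gibbs_kj: Sequence[float], T: float = IR_TEMPERATURE) -> np.ndarray:
    """Normalized Boltzmann populations exp(-dG/RT) / sum.

    Energies are shifted by their minimum before exponentiation, so the
    weights are invariant to a constant offset and numerically safe for
    large energy spreads.
    """
    g = np.asarray(gibbs_kj, dtype=float)
    if g.size == 0:
        raise ValueError("at least one free energy required")
    if T <= 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(g - g.min()) * 1000.0 / (R * T))
    return w / w.sum()
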