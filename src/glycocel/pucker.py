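"""Cremer-Pople puckering analysis for six-membered rings.

The conformation of a pyranose-like ring is located on the Cremer-Pople
sphere by a total puckering amplitude ``Q`` (A) and two angles: the polar
angle ``theta`` (0-180 deg, poles = chairs) and the azimuthal phase
``phi`` (0-360 deg, equator = boats/skew-boats).

Conventions
-----------
* Ring atoms are ordered ``O5 -> C1 -> C2 -> C3 -> C4 -> C5`` (index
  ``j = 0..5``).  With the standard Cremer-Pople phase choice this places
  the 4C1 chair of a D-pyranose at ``theta = 0``.
* Angles are degrees at every public boundary; radians internally.

The 38 canonical IUPAC conformers (2 chairs C, 6 boats B, 6 skew-boats S,
12 half-chairs H, 12 envelopes E) are not hard-coded as a (theta, phi)
table: each descriptor encodes a signed out-of-plane displacement pattern
(e.g. 4H3 = C4 up, C3 down) and the reference position is obtained by
pushing that pattern through the same Cremer-Pople transform used for
classification, which keeps the table consistent with the phase
convention by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RingAtomSet",
    "PuckerCoordinates",
    "CanonicalConformer",
    "InvalidGeometryError",
    "cp_coordinates",
    "classify_conformer",
    "ideal_ring_geometry",
    "canonical_conformers",
    "UNCLASSIFIABLE",
    "PLANARITY_THRESHOLD",
]

RING_LABELS = ("O5", "C1", "C2", "C3", "C4", "C5")

#: below this total amplitude (A) theta/phi are numerically meaningless
PLANARITY_THRESHOLD = 0.1


class InvalidGeometryError(ValueError):
    """Raised for degenerate ring geometries (coincident/collinear atoms)."""


@dataclass(frozen=True)
class RingAtomSet:
    """Six ring atoms, ordered O5->C1->C2->C3->C4->C5, coordinates in A."""

    coords: np.ndarray
    labels: tuple = RING_LABELS

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (6, 3):
            raise ValueError(f"expected (6, 3) coordinates, got {coords.shape}")
        object.__setattr__(self, "coords", coords)
        if len(self.labels) != 6:
            raise ValueError("exactly six ring-atom labels required")


@dataclass(frozen=True)
class PuckerCoordinates:
    """Cremer-Pople (Q, theta, phi); angles undefined when Q ~ 0."""

    Q: float
    theta: float | None
    phi: float | None

    @property
    def defined(self) -> bool:
        return self.theta is not None


@dataclass(frozen=True)
class CanonicalConformer:
    """One of the 38 canonical ring shapes with its reference sphere point."""

    name: str
    theta_ref: float
    phi_ref: float | None  # None for the poles, where phi is arbitrary
    family: str = ""  # C, B, S, H or E


#: sentinel returned by classify_conformer for quasi-planar rings
UNCLASSIFIABLE = CanonicalConformer("planar/unclassifiable", float("nan"), None, "")

_J = np.arange(6)
_COS2 = np.cos(4.0 * np.pi * _J / 6.0)
_SIN2 = np.sin(4.0 * np.pi * _J / 6.0)
_ALT = (-1.0) ** _J


def _pucker_from_z(z: np.ndarray) -> tuple[float, float, float, float]:
    """(q2, phi2_rad, q3, Q) from out-of-plane displacements."""
    q2c = math.sqrt(1.0 / 3.0) * float(np.dot(z, _COS2))
    q2s = -math.sqrt(1.0 / 3.0) * float(np.dot(z, _SIN2))
    q3 = math.sqrt(1.0 / 6.0) * float(np.dot(z, _ALT))
    q2 = math.hypot(q2c, q2s)
    phi2 = math.atan2(q2s, q2c) % (2.0 * math.pi)
    return q2, phi2, q3, math.hypot(q2, q3)


def mean_plane_displacements(ring: RingAtomSet) -> np.ndarray:
    """Out-of-plane displacements z_j relative to the Cremer-Pople mean plane.

    The displacements satisfy sum(z) = 0 exactly (up to roundoff).
    """
    r = ring.coords - ring.coords.mean(axis=0)
    if np.min(np.linalg.norm(np.diff(np.vstack([r, r[:1]]), axis=0), axis=1)) < 1e-6:
        raise InvalidGeometryError("coincident ring atoms")
    rp = (r * np.sin(2.0 * np.pi * _J / 6.0)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2.0 * np.pi * _J / 6.0)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise InvalidGeometryError("degenerate (collinear) ring geometry")
    return r @ (n / norm)


def cp_coordinates(ring: RingAtomSet | np.ndarray) -> PuckerCoordinates:
    """Cremer-Pople (Q, theta, phi) of a six-membered ring.

    Parameters
    ----------
    ring
        ``RingAtomSet`` or a plain (6, 3) coordinate array in the
        canonical O5->C1->...->C5 order.

    Returns
    -------
    PuckerCoordinates
        Q in A, theta in [0, 180] deg, phi in [0, 360) deg.  For a planar
        ring (Q = 0) theta and phi are ``None``.
    """
    if not isinstance(ring, RingAtomSet):
        ring = RingAtomSet(np.asarray(ring, dtype=float))
    z = mean_plane_displacements(ring)
    q2, phi2, q3, Q = _pucker_from_z(z)
    if Q < 1e-10:
        return PuckerCoordinates(Q=0.0, theta=None, phi=None)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(phi2) % 360.0
    return PuckerCoordinates(Q=Q, theta=theta, phi=phi)


# --- canonical conformer table (derived from displacement patterns) --------

def _pattern_position(z_pattern: Sequence[float]) -> tuple[float, float | None]:
    z = np.asarray(z_pattern, dtype=float)
    z = z - z.mean()
    q2, phi2, q3, Q = _pucker_from_z(z)
    theta = math.degrees(math.atan2(q2, q3))
    if q2 < 1e-12:  # pole
        return theta, None
    return theta, math.degrees(phi2) % 360.0


def _unit(*up: int):
    def make(*down: int) -> list[float]:
        z = [0.0] * 6
        for i in up:
            z[i] = 1.0
        for i in down:
            z[i] = -1.0
        return z

    return make


_IDX = {"O": 0, "1": 1, "2": 2, "3": 3, "4": 4, "5": 5}


def _build_canonical_table() -> tuple[CanonicalConformer, ...]:
    entries: list[tuple[str, str, list[float]]] = []
    # chairs: fully alternating pattern; 4C1 has C4 up / C1 down
    entries.append(("4C1", "C", list(_ALT)))
    entries.append(("1C4", "C", list(-_ALT)))
    # boats: para pair exo, both on the same side
    for a, b in ((1, 4), (2, 5), (3, 0)):
        sup = f"{'O' if a == 0 else a},{'O' if b == 0 else b}"
        if (a, b) == (3, 0):
            sup = "O,3"  # ring oxygen cited first by convention
        entries.append((f"{sup}B", "B", _unit(a, b)()))
        entries.append((f"B{sup}", "B", _unit()(a, b)))
    # skew-boats: 1,3-related pair on opposite sides
    for name, a, b in (
        ("1S3", "1", "3"),
        ("3S1", "3", "1"),
        ("1S5", "1", "5"),
        ("5S1", "5", "1"),
        ("OS2", "O", "2"),
        ("2SO", "2", "O"),
    ):
        entries.append((name, "S", _unit(_IDX[a])(_IDX[b])))
    # envelopes: single exo atom
    for k, sym in enumerate(("O", "1", "2", "3", "4", "5")):
        entries.append((f"{sym}E", "E", _unit(k)()))
        entries.append((f"E{sym}", "E", _unit()(k)))
    # half-chairs: adjacent pair on opposite sides
    for a, b in ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)):
        sa = "O" if a == 0 else str(a)
        sb = "O" if b == 0 else str(b)
        entries.append((f"{sa}H{sb}", "H", _unit(a)(b)))
        entries.append((f"{sb}H{sa}", "H", _unit(b)(a)))
    table = []
    for name, family, pattern in entries:
        theta, phi = _pattern_position(pattern)
        table.append(CanonicalConformer(name, theta, phi, family))
    assert len(table) == 38
    return tuple(table)


_CANONICAL: tuple[CanonicalConformer, ...] = _build_canonical_table()


def canonical_conformers() -> tuple[CanonicalConformer, ...]:
    """The 38 canonical conformers with their reference (theta, phi)."""
    return _CANONICAL


def _great_circle_distance(t1: float, p1: float | None, t2: float, p2: float | None) -> float:
    """Central angle (deg) between two points on the puckering sphere."""
    t1r, t2r = math.radians(t1), math.radians(t2)
    dp = math.radians((p1 or 0.0) - (p2 or 0.0))
    c = math.cos(t1r) * math.cos(t2r) + math.sin(t1r) * math.sin(t2r) * math.cos(dp)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def classify_conformer(
    p: PuckerCoordinates, threshold: float = PLANARITY_THRESHOLD
) -> CanonicalConformer:
    """Nearest canonical conformer by great-circle distance on the sphere.

    Rings with ``Q < threshold`` (default 0.1 A) are reported as
    ``UNCLASSIFIABLE`` rather than being forced onto a canonical point.
    Ties are broken by table order (chairs, boats, skews, envelopes,
    half-chairs, each in the construction order above).
    """
    if p.Q < threshold or not p.defined:
        return UNCLASSIFIABLE
    best = None
    best_d = math.inf
    for ref in _CANONICAL:
        d = _great_circle_distance(p.theta, p.phi, ref.theta_ref, ref.phi_ref)
        if d < best_d - 1e-12:
            best_d = d
            best = ref
    return best


def conformer_by_name(name: str) -> CanonicalConformer:
    for ref in _CANONICAL:
        if ref.name == name:
            return ref
    raise KeyError(f"unknown canonical conformer {name!r}")


def ideal_ring_geometry(
    target: CanonicalConformer | PuckerCoordinates | str,
    amplitude: float = 0.55,
    bond_length: float = 1.45,
) -> RingAtomSet:
    """Construct an idealized ring at a requested puckering-sphere position.

    Atoms are placed on a circle of radius ``bond_length`` (the planar
    hexagon bond length) and displaced along the ring normal by the pure
    Cremer-Pople modes, so ``cp_coordinates`` round-trips exactly to the
    target (theta, phi) at amplitude ``Q = amplitude``.

    ``target`` may be a canonical conformer (or its name) or explicit
    ``PuckerCoordinates``; in the latter case the target's own Q is used
    unless it is undefined.
    """
    if isinstance(target, str):
        target = conformer_by_name(target)
    if isinstance(target, CanonicalConformer):
        theta, phi, Q = target.theta_ref, target.phi_ref or 0.0, amplitude
    else:
        Q = target.Q if target.Q > 0 else amplitude
        if not target.defined:
            Q = target.Q  # planar request
            theta, phi = 0.0, 0.0
        else:
            theta, phi = target.theta, target.phi or 0.0
    if Q < 0:
        raise ValueError("amplitude must be non-negative")
    tr, pr = math.radians(theta), math.radians(phi)
    q2, q3 = Q * math.sin(tr), Q * math.cos(tr)
    z = (
        math.sqrt(1.0 / 3.0) * q2 * np.cos(pr + 4.0 * np.pi * _J / 6.0)
        + math.sqrt(1.0 / 6.0) * q3 * _ALT
    )
    # clockwise in-plane placement puts the Cremer-Pople normal along +z
    ang = -2.0 * np.pi * _J / 6.0
    coords = np.column_stack(
        [bond_length * np.cos(ang), bond_length * np.sin(ang), z]
    )
    return RingAtomSet(coords)
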