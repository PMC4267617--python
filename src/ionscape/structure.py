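"""Per-residue conformational descriptors: glycosidic angle with anti/syn
classification and furanose pseudorotation (phase, amplitude, conformer class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Frame, Topology

__all__ = [
    "PuckerResult",
    "GlycosidicResult",
    "dihedral",
    "glycosidic_angle",
    "sugar_pucker",
    "residue_coordinates",
    "PUCKER_CLASSES",
]

#: conformer class per 36-degree sector of the pseudorotation phase
PUCKER_CLASSES = (
    "C3'-endo",
    "C4'-exo",
    "O4'-endo",
    "C1'-exo",
    "C2'-endo",
    "C3'-exo",
    "C4'-endo",
    "O4'-exo",
    "C1'-endo",
    "C2'-exo",
)

_RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")
# endocyclic torsions nu_0..nu_4 as atom quadruples over the ring
_RING_TORSIONS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

_PURINES = frozenset("AG")


@dataclass
class PuckerResult:
    phase: float  # degrees in [0, 360)
    amplitude: float  # degrees
    conformer: str  # one of PUCKER_CLASSES, or "undefined" for a flat ring
    undefined: bool = False


@dataclass
class GlycosidicResult:
    chi: float  # degrees in (-180, 180]
    conformer: str  # anti / syn / intermediate


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral angle (degrees, in (-180, 180])."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("three consecutive points are collinear; dihedral undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def residue_coordinates(
    frame: Frame, topology: Topology, chain: str, residue_index: int
) -> dict[str, np.ndarray]:
    """Atom name -> coordinate map for one residue."""
    mask = (topology.chains == chain) & (topology.residue_indices == residue_index)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"residue {chain}:{residue_index} not found")
    return {topology.names[i]: frame.coordinates[i] for i in idx}


def glycosidic_angle(
    coords: dict[str, np.ndarray],
    base: str,
    intermediate_band: float = 10.0,
) -> GlycosidicResult:
    """Chi torsion and anti/syn class of a nucleotide.

    Quadruple O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines.
    anti is chi in (-180, -90] U (90, 180], syn is (-90, 90], with a
    configurable band around +/-90 classified as intermediate.
    """
    quad = ("O4'", "C1'", "N9", "C4") if base in _PURINES else ("O4'", "C1'", "N1", "C2")
    try:
        pts = [coords[name] for name in quad]
    except KeyError as exc:
        raise ValueError(f"missing atom {exc.args[0]} for chi of base {base}") from exc
    chi = dihedral(*pts)
    if min(abs(abs(chi) - 90.0), 360.0 - abs(abs(chi) - 90.0)) < intermediate_band:
        conformer = "intermediate"
    elif -90.0 < chi <= 90.0:
        conformer = "syn"
    else:
        conformer = "anti"
    return GlycosidicResult(chi=chi, conformer=conformer)


def sugar_pucker(
    coords: dict[str, np.ndarray], flat_threshold: float = 1.0
) -> PuckerResult:
    """Pseudorotation phase and amplitude from the five endocyclic torsions.

    Standard linear combination: tan(P) = ((nu4 + nu1) - (nu3 + nu0)) /
    (2 nu2 (sin 36 + sin 72)); amplitude = nu2 / cos(P), with P shifted by
    180 degrees when nu2 < 0 so that the amplitude is non-negative.
    """
    missing = [a for a in _RING_ATOMS if a not in coords]
    if missing:
        raise ValueError(f"missing ring atoms {missing}")
    nu = np.array([dihedral(*(coords[a] for a in quad)) for quad in _RING_TORSIONS])
    denom = 2.0 * nu[2] * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
    if abs(nu[2]) < 1e-12:
        phase = 90.0 if (nu[4] + nu[1]) - (nu[3] + nu[0]) >= 0 else 270.0
        amplitude = abs((nu[4] + nu[1]) - (nu[3] + nu[0])) / (
            2.0 * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
        )
    else:
        # atan2 on (numerator, denominator) already lands the phase in the
        # half-plane matching the sign of nu2, so amplitude comes out >= 0
        phase = math.degrees(math.atan2((nu[4] + nu[1]) - (nu[3] + nu[0]), denom))
        amplitude = nu[2] / math.cos(math.radians(phase))
    phase %= 360.0
    if amplitude < flat_threshold:
        return PuckerResult(phase, amplitude, "undefined", undefined=True)
    sector = int(phase // 36.0) % 10
    return PuckerResult(phase, amplitude, PUCKER_CLASSES[sector])
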