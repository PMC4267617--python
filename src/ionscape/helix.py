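"""Global helical axis construction and cylindrical coordinates.

The axis is a single straight line per frame, the total-least-squares fit
through per-base-pair reference centers.  A reference center is the midpoint
of the two strands' reference points; a strand's reference point for a pair
is the midpoint of its C1' atom and its glycosidic-reference nitrogen
(purine N9; pyrimidine N4 by default, N1 selectable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Topology, Trajectory

__all__ = [
    "HelixFrame",
    "pair_reference_centers",
    "fit_axis",
    "cylindrical_r",
    "axial_z",
    "bend_residual",
    "helix_frames",
]

_PURINES = frozenset("AG")


@dataclass
class HelixFrame:
    """Per-frame straight axis: origin point, unit direction, pair centers."""

    origin: np.ndarray
    direction: np.ndarray
    pair_centers: np.ndarray  # (n_pairs, 3)
    axial_extent: tuple[float, float]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if not np.isclose(norm, 1.0, atol=1e-9):
            self.direction = self.direction / norm
        z0, z1 = self.axial_extent
        if not z0 < z1:
            raise ValueError(f"degenerate axial extent {self.axial_extent}")


def _strand_reference_point(
    frame: Frame, topology: Topology, chain: str, resi: int, pyrimidine_ref: str
) -> np.ndarray:
    base_arr = topology.bases[
        (topology.chains == chain) & (topology.residue_indices == resi)
    ]
    if base_arr.size == 0:
        raise ValueError(f"residue {chain}:{resi} not found")
    base = base_arr[0]
    nref = "N9" if base in _PURINES else pyrimidine_ref
    pts = []
    for name in ("C1'", nref):
        idx = topology.select(names=[name], chain=chain, residue_index=resi)
        if idx.size != 1:
            raise ValueError(
                f"residue {chain}:{resi} ({base}) missing reference atom {name}"
            )
        pts.append(frame.coordinates[idx[0]])
    return 0.5 * (pts[0] + pts[1])


def pair_reference_centers(
    frame: Frame, topology: Topology, pyrimidine_ref: str = "N4"
) -> np.ndarray:
    """One reference center per base pair, ordered by strand-1 residue index."""
    pairing = topology.pairing_map()
    c1 = topology.duplex_chains[0]
    centers = []
    for resi in topology.residues_of(c1):
        partner_chain, partner_resi = pairing[(c1, resi)]
        p1 = _strand_reference_point(frame, topology, c1, resi, pyrimidine_ref)
        p2 = _strand_reference_point(
            frame, topology, partner_chain, partner_resi, pyrimidine_ref
        )
        centers.append(0.5 * (p1 + p2))
    return np.array(centers)


def fit_axis(pair_centers: np.ndarray) -> HelixFrame:
    """Total-least-squares line through the centers.

    The direction is the principal component of the centered points, with its
    sign chosen toward increasing strand-1 residue index (first -> last
    center).  The axial extent is the projection interval of the first and
    last centers.
    """
    centers = np.asarray(pair_centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 2 or centers.shape[1] != 3:
        raise ValueError("need at least two 3-D pair centers")
    origin = centers.mean(axis=0)
    rel = centers - origin
    if np.allclose(rel, 0, atol=1e-12):
        raise ValueError("all pair centers coincide; axis undefined")
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    direction = vt[0]
    if np.dot(centers[-1] - centers[0], direction) < 0:
        direction = -direction
    z_first = float(np.dot(centers[0] - origin, direction))
    z_last = float(np.dot(centers[-1] - origin, direction))
    return HelixFrame(
        origin=origin,
        direction=direction,
        pair_centers=centers,
        axial_extent=(min(z_first, z_last), max(z_first, z_last)),
    )


def cylindrical_r(point: np.ndarray, hf: HelixFrame) -> float | np.ndarray:
    """Perpendicular distance of point(s) to the axis line."""
    rel = np.asarray(point, dtype=float) - hf.origin
    z = np.tensordot(rel, hf.direction, axes=([-1], [0]))
    perp = rel - np.multiply.outer(z, hf.direction)
    return np.sqrt(np.sum(perp * perp, axis=-1))


def axial_z(point: np.ndarray, hf: HelixFrame) -> float | np.ndarray:
    """Signed axial coordinate of point(s) along the axis direction."""
    rel = np.asarray(point, dtype=float) - hf.origin
    return np.tensordot(rel, hf.direction, axes=([-1], [0]))


def bend_residual(hf: HelixFrame) -> float:
    """Maximum point-to-line residual of the pair centers (Angstrom).

    A straight duplex gives ~0; a bent one a residual of order the bend
    amplitude.  Used as a diagnostic for the straight-axis assumption.
    """
    return float(np.max(cylindrical_r(hf.pair_centers, hf)))


def helix_frames(
    traj: Trajectory, pyrimidine_ref: str = "N4", trim_ends: int = 0
) -> list[HelixFrame]:
    """Fit an axis for every frame of the trajectory."""
    out = []
    for i in range(traj.n_frames):
        centers = pair_reference_centers(traj.frame(i), traj.topology, pyrimidine_ref)
        if trim_ends:
            centers = centers[trim_ends:-trim_ends]
        out.append(fit_axis(centers))
    return out
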