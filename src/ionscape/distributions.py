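"""Spatial distribution statistics: cylindrical concentration profiles (CDF),
radial distribution functions (RDF), coordination numbers, cumulative ionic
charge accumulation, and time-window convergence series."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import Trajectory, min_image_displacement, pairwise_min_image_distances
from .helix import HelixFrame, axial_z, cylindrical_r

__all__ = [
    "DistributionResult",
    "ConvergenceSeries",
    "compute_cdf",
    "compute_rdf",
    "first_peak",
    "coordination_number",
    "charge_accumulation",
    "convergence_series",
]

#: particles/A^3 -> mol/L
_M_PER_INV_A3 = 1e27 / 6.02214076e23


@dataclass
class DistributionResult:
    """Binned profile with raw counts for error propagation.

    ``kind`` is one of ``cdf`` (molar concentration vs cylindrical radius),
    ``rdf`` (dimensionless g(r)) or ``charge`` (normalized cumulative charge,
    reported at the right bin edges).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    raw_counts: np.ndarray
    n_frames: int
    species: str
    kind: str
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ConvergenceSeries:
    """Profiles over nested time windows sharing a start time."""

    windows: list[tuple[float, float]]
    profiles: list[DistributionResult]
    sup_diffs: np.ndarray  # sup-norm difference between consecutive profiles


def _block_stderr(per_frame: np.ndarray, times: np.ndarray, block_ps: float) -> np.ndarray:
    """Standard error per bin from block means over frames (autocorrelation guard)."""
    if len(per_frame) < 2:
        return np.zeros(per_frame.shape[1])
    span = times[-1] - times[0]
    n_blocks = max(2, int(span / block_ps)) if span > 0 else 2
    n_blocks = min(n_blocks, len(per_frame))
    blocks = np.array_split(per_frame, n_blocks, axis=0)
    means = np.array([b.mean(axis=0) for b in blocks])
    return means.std(axis=0, ddof=1) / math.sqrt(len(means))


def _cylinder_membership(
    coords: np.ndarray, hf: HelixFrame, box: np.ndarray, axial: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """Radii of points (min-image relative to the axis origin) plus an axial
    in-bounds mask and the axial height used for shell volumes."""
    rel = min_image_displacement(coords, hf.origin, box)
    pts = hf.origin + rel
    r = np.atleast_1d(cylindrical_r(pts, hf))
    z = np.atleast_1d(axial_z(pts, hf))
    if axial == "duplex":
        z0, z1 = hf.axial_extent
        mask = (z >= z0) & (z <= z1)
        height = z1 - z0
    elif axial == "full_box":
        mask = np.ones(len(r), dtype=bool)
        height = float(np.min(box))
    else:
        raise ValueError(f"axial must be 'duplex' or 'full_box', got {axial!r}")
    return r, mask, height


def _check_r_max(r_max: float, traj: Trajectory, meta: dict) -> None:
    half_min_edge = float(traj.box.min()) / 2.0
    if r_max > half_min_edge:
        meta["warning"] = (
            f"r_max {r_max} A exceeds half the smallest box edge "
            f"({half_min_edge:.2f} A); outer bins under-sample the box"
        )


def compute_cdf(
    traj: Trajectory,
    species: str,
    hf_per_frame: Sequence[HelixFrame],
    r_max: float = 30.0,
    dr: float = 0.5,
    window: tuple[float, float] | None = None,
    axial: str = "duplex",
    block_ps: float = 1000.0,
) -> DistributionResult:
    """Molar ion concentration in cylindrical shells around the helix axis.

    Per bin: <count in shell> / (N_A * shell volume), shells bounded axially
    by the frame's axial extent (or the full box height), averaged over the
    frames of the window.
    """
    frames = traj.window_frames(window)
    ion_idx = traj.species_indices(species)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    per_frame_counts = np.zeros((len(frames), n_bins))
    heights = np.zeros(len(frames))
    for k, f in enumerate(frames):
        hf = hf_per_frame[f]
        if ion_idx.size:
            r, mask, height = _cylinder_membership(
                traj.coordinates[f][ion_idx], hf, traj.box[f], axial
            )
            per_frame_counts[k], _ = np.histogram(r[mask], bins=edges)
        else:
            height = (
                hf.axial_extent[1] - hf.axial_extent[0]
                if axial == "duplex"
                else float(np.min(traj.box[f]))
            )
        heights[k] = height
    mean_height = float(heights.mean())
    shell_vol = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * mean_height
    per_frame_conc = per_frame_counts / shell_vol * _M_PER_INV_A3
    values = per_frame_conc.mean(axis=0)
    meta = {
        "axial": axial,
        "mean_height": mean_height,
        "shell_volumes": shell_vol,
        "mean_in_cylinder_count": float(per_frame_counts.sum(axis=1).mean()),
    }
    _check_r_max(r_max, traj, meta)
    return DistributionResult(
        bin_edges=edges,
        values=values,
        raw_counts=per_frame_counts.sum(axis=0).astype(int),
        n_frames=len(frames),
        species=species,
        kind="cdf",
        stderr=_block_stderr(per_frame_conc, traj.times[frames], block_ps),
        meta=meta,
    )


def compute_rdf(
    traj: Trajectory,
    species: str,
    site_atoms: np.ndarray,
    r_max: float = 10.0,
    dr: float = 0.1,
    window: tuple[float, float] | None = None,
    block_ps: float = 1000.0,
) -> DistributionResult:
    """g(r) of the species around the selected site atoms.

    Normalization: <pair count in [r, r+dr)> / (n_sites * rho_bulk * shell
    volume); rho_bulk is the whole-box species number density.
    """
    site_atoms = np.asarray(site_atoms, dtype=int)
    if site_atoms.size == 0:
        raise ValueError("site selection is empty")
    frames = traj.window_frames(window)
    ion_idx = traj.species_indices(species)
    box_vol = float(np.prod(traj.box[frames], axis=1).mean())
    rho_bulk = ion_idx.size / box_vol
    if rho_bulk == 0:
        raise ValueError(f"no ions of species {species!r}: bulk density is zero")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    per_frame_counts = np.zeros((len(frames), n_bins))
    for k, f in enumerate(frames):
        d = pairwise_min_image_distances(
            traj.coordinates[f][site_atoms], traj.coordinates[f][ion_idx], traj.box[f]
        )
        per_frame_counts[k], _ = np.histogram(d.ravel(), bins=edges)
    shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = site_atoms.size * rho_bulk * shell_vol
    per_frame_g = per_frame_counts / norm
    meta = {"rho_bulk": rho_bulk, "n_sites": int(site_atoms.size), "box_volume": box_vol}
    _check_r_max(r_max, traj, meta)
    return DistributionResult(
        bin_edges=edges,
        values=per_frame_g.mean(axis=0),
        raw_counts=per_frame_counts.sum(axis=0).astype(int),
        n_frames=len(frames),
        species=species,
        kind="rdf",
        stderr=_block_stderr(per_frame_g, traj.times[frames], block_ps),
        meta=meta,
    )


def _prominence(dist: DistributionResult, height: float) -> float:
    # scale with the profile so sampling-noise spikes on tall peaks are skipped
    vmax = float(np.max(dist.values)) if dist.values.size else 0.0
    return max(height / 2.0, 0.25 * vmax)


def first_peak(
    dist: DistributionResult, height: float = 1.5
) -> tuple[float, float] | None:
    """Location and height of the first qualifying local maximum.

    A maximum qualifies when it exceeds ``height`` and is prominent relative
    to the profile (noise spikes are skipped).  Returns None when nothing
    qualifies (monotone or flat profiles), rather than raising.
    """
    if dist.kind not in ("cdf", "rdf"):
        raise ValueError(f"first_peak undefined for kind {dist.kind!r}")
    peaks, _ = find_peaks(dist.values, height=height, prominence=_prominence(dist, height))
    if peaks.size == 0:
        return None
    i = int(peaks[0])
    return float(dist.bin_centers[i]), float(dist.values[i])


def first_minimum_after_peak(
    dist: DistributionResult, height: float = 1.5
) -> float | None:
    """Radius of the first prominent local minimum following the first peak."""
    pk = first_peak(dist, height=height)
    if pk is None:
        return None
    start = int(np.searchsorted(dist.bin_centers, pk[0]))
    tail = dist.values[start:]
    trough, _ = find_peaks(-tail, prominence=_prominence(dist, height))
    if trough.size:
        return float(dist.bin_centers[start + int(trough[0])])
    # profile decays to a flat floor with no rebound: first bin at the floor
    floor = tail <= tail.min() + 1e-12
    if floor.any():
        return float(dist.bin_centers[start + int(np.argmax(floor))])
    return None


def coordination_number(dist: DistributionResult, r_cut: float) -> float:
    """Mean neighbor count within r_cut, integrated from a stored RDF.

    N(r) = rho_bulk * sum_{bins < r_cut} g(r) * shell_volume; evaluated from
    the raw pair counts so the identity with direct counting is exact at bin
    edges.
    """
    if dist.kind != "rdf" or "rho_bulk" not in dist.meta:
        raise ValueError("coordination_number needs an RDF with stored rho_bulk")
    if r_cut <= dist.bin_edges[0] or r_cut > dist.bin_edges[-1] + 1e-9:
        raise ValueError(
            f"r_cut {r_cut} outside binned range "
            f"[{dist.bin_edges[0]}, {dist.bin_edges[-1]}]"
        )
    inside = dist.bin_edges[1:] <= r_cut + 1e-9
    total_pairs = dist.raw_counts[inside].sum()
    return float(total_pairs / (dist.n_frames * dist.meta["n_sites"]))


def charge_accumulation(
    traj: Trajectory,
    hf_per_frame: Sequence[HelixFrame],
    species_charges: dict[str, float],
    r_max: float = 30.0,
    dr: float = 0.5,
    window: tuple[float, float] | None = None,
    axial: str = "duplex",
) -> DistributionResult:
    """Cumulative ionic charge within cylindrical radius r, normalized by the
    magnitude of the duplex net charge.  Values are reported at the right bin
    edges; Q(0) = 0 by construction."""
    net = traj.topology.net_charge
    if net == 0:
        raise ValueError("duplex net charge is zero; normalization undefined")
    frames = traj.window_frames(window)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    per_frame_q = np.zeros((len(frames), n_bins))
    counts = np.zeros(n_bins)
    for label in species_charges:
        if label not in traj.species:
            raise ValueError(f"species {label!r} has no atoms in the trajectory")
    for k, f in enumerate(frames):
        hf = hf_per_frame[f]
        binned_q = np.zeros(n_bins)
        for label, z_charge in species_charges.items():
            idx = traj.species_indices(label)
            if idx.size == 0:
                continue
            r, mask, _ = _cylinder_membership(
                traj.coordinates[f][idx], hf, traj.box[f], axial
            )
            hist, _ = np.histogram(r[mask], bins=edges)
            binned_q += z_charge * hist
            counts += hist
        per_frame_q[k] = np.cumsum(binned_q)
    values = per_frame_q.mean(axis=0) / abs(net)
    meta = {"net_charge": net, "axial": axial}
    _check_r_max(r_max, traj, meta)
    return DistributionResult(
        bin_edges=edges,
        values=values,
        raw_counts=counts.astype(int),
        n_frames=len(frames),
        species="+".join(sorted(species_charges)),
        kind="charge",
        meta=meta,
    )


def convergence_series(
    windows: Sequence[tuple[float, float]],
    compute: Callable[[tuple[float, float]], DistributionResult],
) -> ConvergenceSeries:
    """Profiles over nested windows plus sup-norm differences between
    consecutive profiles (shrinking differences indicate stationarity)."""
    windows = [tuple(map(float, w)) for w in windows]
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    starts = {w[0] for w in windows}
    if len(starts) != 1:
        raise ValueError(f"windows must share a start time, got starts {sorted(starts)}")
    ends = [w[1] for w in windows]
    if any(b <= a for a, b in zip(ends, ends[1:])):
        raise ValueError("window end times must be strictly increasing")
    profiles = [compute(w) for w in windows]
    diffs = np.array(
        [
            float(np.max(np.abs(p2.values - p1.values)))
            for p1, p2 in zip(profiles, profiles[1:])
        ]
    )
    return ConvergenceSeries(windows=windows, profiles=profiles, sup_diffs=diffs)
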