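"""Occupancy, residence-time kinetics, binding distances and pocket detection.

Occupancy semantics: a site (single atom or atom group) is occupied in a
frame when at least one ion of the species lies within the cutoff of at
least one atom of the selection, under minimum-image distances.  An ion may
contribute to the occupancy of more than one site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RegionLabel, Trajectory, classify_region, pairwise_min_image_distances

__all__ = [
    "OccupancyTrace",
    "ResidenceResult",
    "BindingDistanceStats",
    "Pocket",
    "DIRECT_CUTOFFS",
    "MEDIATED_CUTOFF",
    "occupancy_trace",
    "occupancy_fraction",
    "occupancy_by_sequence",
    "residence_time",
    "binding_distance_stats",
    "detect_pockets",
]

#: direct-binding cutoffs per species (Angstrom); overridable everywhere
DIRECT_CUTOFFS: dict[str, float] = {"Na+": 3.0, "K+": 3.5, "Mg2+": 5.0}
#: water-mediated binding cutoff (one intervening water), all species
MEDIATED_CUTOFF: float = 6.0


@dataclass
class OccupancyTrace:
    """Binary occupancy series p(t) for one site selection."""

    p: np.ndarray  # uint8, one entry per sampled frame
    dt: float  # ps
    site: str
    cutoff: float
    species: str

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.uint8)
        if self.p.size and not np.isin(self.p, (0, 1)).all():
            raise ValueError("occupancy values must be 0/1")


@dataclass
class ResidenceResult:
    """Occupancy autocorrelation C(t) and fitted residence time."""

    lags: np.ndarray  # ps
    C: np.ndarray  # normalized by C(0)
    tau_R: float  # ns (nan when censored)
    fit_r2: float
    censored: bool


@dataclass
class BindingDistanceStats:
    mean: float  # Angstrom (nan when undefined)
    sd: float
    n_bound_frames: int
    window: tuple[float, float] | None
    undefined: bool = False


@dataclass
class Pocket:
    """One ion held simultaneously by several duplex electronegative atoms."""

    ion_index: int
    member_atoms: tuple[int, ...]
    frame_span: tuple[int, int]  # inclusive frame indices
    dwell_ns: float
    member_names: tuple[str, ...] = ()


def occupancy_trace(
    traj: Trajectory,
    site: np.ndarray,
    species: str,
    cutoff: float,
    window: tuple[float, float] | None = None,
) -> OccupancyTrace:
    site = np.asarray(site, dtype=int)
    if site.size == 0:
        raise ValueError("site selection is empty")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    frames = traj.window_frames(window)
    ion_idx = traj.species_indices(species)
    p = np.zeros(len(frames), dtype=np.uint8)
    if ion_idx.size and cutoff > 0:
        # chunked broadcasting keeps memory bounded on long traces
        chunk = max(1, int(2_000_000 // max(1, site.size * ion_idx.size)))
        cut2 = cutoff * cutoff
        for s in range(0, len(frames), chunk):
            fr = frames[s : s + chunk]
            a = traj.coordinates[np.ix_(fr, site)]
            b = traj.coordinates[np.ix_(fr, ion_idx)]
            d = a[:, :, None, :] - b[:, None, :, :]
            box = traj.box[fr][:, None, None, :]
            d -= box * np.round(d / box)
            dist2 = np.sum(d * d, axis=-1)
            p[s : s + chunk] = (dist2 < cut2).any(axis=(1, 2))
    names = ",".join(sorted(set(traj.topology.names[site])))
    return OccupancyTrace(p=p, dt=traj.dt, site=names, cutoff=cutoff, species=species)


def occupancy_fraction(trace: OccupancyTrace) -> float:
    """Percentage of frames with the site occupied."""
    if trace.p.size == 0:
        raise ValueError("empty occupancy trace")
    return 100.0 * float(trace.p.mean())


def occupancy_by_sequence(
    traj: Trajectory,
    species: str,
    cutoff: float,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-nucleotide, per-region occupancy table.

    Both strands are assigned display positions in their own 5'->3' order
    (the second strand thereby reversed relative to the pairing alignment),
    so that for a palindromic duplex column i carries the same base on both
    strands and converged occupancies mirror across strands.
    """
    topo = traj.topology
    chains = topo.duplex_chains
    rows = []
    for strand_i, chain in enumerate(chains, start=1):
        residues = topo.residues_of(chain)
        for pos, resi in enumerate(residues, start=1):
            display = pos
            base = topo.bases[
                (topo.chains == chain) & (topo.residue_indices == resi)
            ][0]
            for region in (
                RegionLabel.MAJOR,
                RegionLabel.MINOR,
                RegionLabel.BACKBONE_OPRIME,
                RegionLabel.PHOSPHATE,
            ):
                sel = topo.select(chain=chain, residue_index=resi, region=region)
                if sel.size == 0:
                    occ = 0.0
                else:
                    occ = occupancy_fraction(
                        occupancy_trace(traj, sel, species, cutoff, window)
                    )
                rows.append(
                    {
                        "strand": strand_i,
                        "chain": chain,
                        "residue": resi,
                        "display_position": display,
                        "base": base,
                        "region": region.value,
                        "occupancy_pct": occ,
                    }
                )
    return pd.DataFrame(rows)


def residence_time(
    trace: OccupancyTrace,
    lag_min: float = 10.0,
    lag_max: float = 1000.0,
    lag_step: float = 10.0,
    censor_threshold: float = 0.9,
    fit_floor: float = 0.15,
) -> ResidenceResult:
    """Residence time from the occupancy autocorrelation.

    C(t) = sum over origins of p(t0) p(t0 + t), normalized per valid origin
    and then by C(0).  tau_R comes from a weighted log-linear least-squares
    fit (weights C(t), free intercept) restricted to lags with
    C(t) > fit_floor, which keeps the flat re-binding plateau at long lags
    from biasing the decay constant; the result is censored when C barely
    decays over the grid.
    """
    p = trace.p.astype(float)
    if p.sum() == 0:
        raise ValueError("site never occupied; residence time undefined")
    dt = trace.dt
    lag_frames = np.arange(lag_min, lag_max + lag_step / 2, lag_step) / dt
    lag_frames = np.unique(np.round(lag_frames).astype(int))
    lag_frames = lag_frames[(lag_frames > 0) & (lag_frames < len(p))]
    if lag_frames.size < 2:
        raise ValueError("trace too short for the requested lag grid")
    c0 = float(np.mean(p * p))
    C = np.empty(lag_frames.size)
    for i, L in enumerate(lag_frames):
        C[i] = np.mean(p[:-L] * p[L:])
    C /= c0
    lags_ps = lag_frames * dt
    censored = bool(C[-1] > censor_threshold)
    tau = np.nan
    r2 = np.nan
    pos = C > max(0.0, fit_floor)
    if pos.sum() < 2:
        pos = C > 0
    if not censored and pos.sum() >= 2:
        x = lags_ps[pos]
        y = np.log(C[pos])
        w = C[pos]
        wm_x = np.average(x, weights=w)
        wm_y = np.average(y, weights=w)
        slope = np.sum(w * (x - wm_x) * (y - wm_y)) / np.sum(w * (x - wm_x) ** 2)
        if slope >= 0:
            censored = True
        else:
            tau = -1.0 / slope / 1000.0  # ps -> ns
            yhat = wm_y + slope * (x - wm_x)
            ss_res = np.sum(w * (y - yhat) ** 2)
            ss_tot = np.sum(w * (y - wm_y) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ResidenceResult(lags=lags_ps, C=C, tau_R=tau, fit_r2=r2, censored=censored)


def binding_distance_stats(
    traj: Trajectory,
    site_atom: int,
    species: str,
    cutoff: float,
    window: tuple[float, float] | None = "trailing",
    trailing_ps: float = 10_000.0,
) -> BindingDistanceStats:
    """Mean +/- sd of the nearest bound-ion distance over bound frames.

    The default window is the trailing 10-ns-equivalent span of the
    trajectory; unbound frames are excluded.
    """
    if window == "trailing":
        t_end = float(traj.times[-1])
        window = (max(float(traj.times[0]), t_end - trailing_ps), t_end)
    frames = traj.window_frames(window)
    ion_idx = traj.species_indices(species)
    site_pos = traj.coordinates[:, site_atom, :]
    dists = []
    for f in frames:
        d = pairwise_min_image_distances(
            site_pos[f][None, :], traj.coordinates[f][ion_idx], traj.box[f]
        )[0]
        bound = d[d < cutoff]
        if bound.size:
            dists.append(bound.min())
    if not dists:
        return BindingDistanceStats(np.nan, np.nan, 0, window, undefined=True)
    arr = np.array(dists)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return BindingDistanceStats(float(arr.mean()), sd, int(arr.size), window)


def detect_pockets(
    traj: Trajectory,
    species: str,
    cutoff: float,
    min_sites: int = 2,
    min_dwell_ns: float = 0.0,
    window: tuple[float, float] | None = None,
) -> list[Pocket]:
    """Maximal intervals where one ion stays within cutoff of >= min_sites
    duplex electronegative (O/N) atoms simultaneously.

    The reported member set is the intersection of bound atoms over the
    interval, so every member is within cutoff in every frame of the span.
    """
    if min_sites < 2:
        raise ValueError("min_sites must be >= 2")
    topo = traj.topology
    elneg = np.flatnonzero(topo.duplex_mask & np.isin(topo.elements, ["O", "N"]))
    frames = traj.window_frames(window)
    ion_idx = traj.species_indices(species)
    pockets: list[Pocket] = []
    for ion in ion_idx:
        current: set[int] | None = None
        start = 0
        for k, f in enumerate(frames):
            d = pairwise_min_image_distances(
                traj.coordinates[f][[ion]], traj.coordinates[f][elneg], traj.box[f]
            )[0]
            bound = set(elneg[d < cutoff].tolist())
            if current is None:
                if len(bound) >= min_sites:
                    current, start = bound, k
                continue
            merged = current & bound
            if len(merged) >= min_sites:
                current = merged
            else:
                pockets.append(_close_pocket(traj, ion, current, frames, start, k - 1))
                current, start = (bound, k) if len(bound) >= min_sites else (None, k)
        if current is not None:
            pockets.append(
                _close_pocket(traj, ion, current, frames, start, len(frames) - 1)
            )
    pockets = [p for p in pockets if p.dwell_ns >= min_dwell_ns]
    return pockets


def _close_pocket(
    traj: Trajectory,
    ion: int,
    members: set[int],
    frames: np.ndarray,
    start: int,
    end: int,
) -> Pocket:
    dwell_ps = (end - start + 1) * traj.dt
    member_tuple = tuple(sorted(members))
    names = tuple(traj.topology.names[list(member_tuple)])
    return Pocket(
        ion_index=int(ion),
        member_atoms=member_tuple,
        frame_span=(int(frames[start]), int(frames[end])),
        dwell_ns=dwell_ps / 1000.0,
        member_names=names,
    )
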