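"""Ground-truth generators: idealized CG duplex builder, telegraph binding
simulator, Brownian ion simulator, and hydration-shell sampler.

The duplex geometry is idealized rather than crystallographic: topology,
handedness, sugar pucker and glycosidic classes, and approximate groove
geometry are guaranteed; atomic accuracy is not.  All generators are
seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve

from .core import Atom, ION_CHARGES, Topology, Trajectory
from .structure import sugar_pucker

__all__ = [
    "FORM_PARAMS",
    "DuplexSpec",
    "TelegraphSpec",
    "BrownianSpec",
    "build_duplex",
    "simulate_telegraph",
    "simulate_brownian",
    "generate_hydration_shell",
    "hydration_shell_trajectory",
    "ring_coordinates",
]

_RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")

#: default helical parameters per form.  Twist is per dinucleotide step
#: (two alternating values for the Z forms); pucker phase and chi per base.
FORM_PARAMS: dict[str, dict] = {
    "B-DNA": dict(
        twist=(36.0,), rise=3.38, displacement=0.8, rna=False,
        pucker={"C": 162.0, "G": 162.0}, amplitude=38.0,
        chi={"C": -105.0, "G": -105.0},
    ),
    "A-RNA": dict(
        twist=(32.7,), rise=2.81, displacement=4.0, rna=True,
        pucker={"C": 18.0, "G": 18.0}, amplitude=38.0,
        chi={"C": -160.0, "G": -160.0},
    ),
    "Z-DNA": dict(
        twist=(-9.0, -51.0), rise=3.7, displacement=3.0, rna=False,
        pucker={"C": 162.0, "G": 18.0}, amplitude=38.0,
        chi={"C": -150.0, "G": 60.0},  # syn guanine, anti cytosine
    ),
    "Z-RNA": dict(
        twist=(-9.0, -51.0), rise=3.7, displacement=3.0, rna=True,
        pucker={"C": 162.0, "G": 18.0}, amplitude=38.0,
        chi={"C": -150.0, "G": 60.0},
    ),
}

_COMPLEMENT = {"C": "G", "G": "C"}


@dataclass
class DuplexSpec:
    form: str = "B-DNA"
    sequence: str = "CGCGCGCGCGCG"
    box: float = 82.0
    overrides: dict = field(default_factory=dict)


@dataclass
class TelegraphSpec:
    """Two-state (bound/unbound) binding process with exponential dwell times."""

    k_on: float  # 1/ns
    k_off: float  # 1/ns; mean bound duration = 1/k_off
    dt: float = 10.0  # ps
    T: float = 100.0  # ns
    seed: int = 0
    site: tuple[float, float, float] | None = None
    sigma: float = 0.3  # bound-position jitter, A
    box: float = 40.0
    #: unbound positions are uniform outside this radius of the site, so the
    #: occupancy trace at the direct cutoff reproduces the event list exactly
    exclusion: float = 4.0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if self.dt > 10.0 + 1e-9:
            raise ValueError("dt must be <= 10 ps to resolve the lag grid")


@dataclass
class BrownianSpec:
    n: int
    D: float  # A^2/ps
    box: float = 40.0
    dt: float = 10.0  # ps
    T: float = 10.0  # ns
    seed: int = 0
    #: optional attractive Gaussian wells: (center, depth_kT, width_A)
    wells: tuple = ()

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")


# ---------------------------------------------------------------------------
# furanose ring construction
# ---------------------------------------------------------------------------

def _ring_from_params(q: float, phi: float) -> np.ndarray:
    """Pentagon with out-of-plane displacements; rows ordered as _RING_ATOMS."""
    j = np.arange(5)
    theta = 2.0 * np.pi * j / 5.0
    r0 = 1.45 / (2.0 * math.sin(math.pi / 5.0))
    xy = r0 * np.c_[np.cos(theta), np.sin(theta)]
    z = q * np.cos(phi + 4.0 * np.pi * j / 5.0)
    return np.c_[xy, z]


def ring_coordinates(phase: float, amplitude: float) -> dict[str, np.ndarray]:
    """Furanose ring coordinates with the requested pseudorotation state.

    Solves for the displacement-model parameters whose estimated
    (phase, amplitude) match the targets, so the round trip through
    ``sugar_pucker`` is exact to solver tolerance.
    """
    if amplitude <= 0:
        flat = _ring_from_params(0.0, 0.0)
        return dict(zip(_RING_ATOMS, flat))

    def residual(params: np.ndarray) -> list[float]:
        q, phi = params
        coords = dict(zip(_RING_ATOMS, _ring_from_params(abs(q), phi)))
        res = sugar_pucker(coords, flat_threshold=0.0)
        d_phase = (res.phase - phase + 180.0) % 360.0 - 180.0
        return [res.amplitude - amplitude, d_phase]

    # coarse scan for a starting phase offset, then root-find
    best = None
    for phi0 in np.linspace(0, 2 * np.pi, 13):
        r = residual(np.array([amplitude / 100.0, phi0]))
        score = abs(r[1])
        if best is None or score < best[1]:
            best = (phi0, score)
    sol = fsolve(residual, np.array([amplitude / 100.0, best[0]]), full_output=False)
    coords = dict(zip(_RING_ATOMS, _ring_from_params(abs(sol[0]), sol[1])))
    return coords


# ---------------------------------------------------------------------------
# internal-coordinate atom placement
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from reference chain a-b-c with bond |CD|, angle BCD and
    torsion ABCD (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            -bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# planar base templates (2-D, embedded into 3-D at build time)
# ---------------------------------------------------------------------------

def _polygon(center: np.ndarray, radius: float, angles_deg: list[float]) -> list[np.ndarray]:
    return [
        center + radius * np.array([math.cos(math.radians(a)), math.sin(math.radians(a))])
        for a in angles_deg
    ]


def _cytosine_2d() -> dict[str, np.ndarray]:
    center = np.array([1.39, 0.0])
    ring = _polygon(center, 1.39, [180, 120, 60, 0, -60, -120])
    atoms = dict(zip(("N1", "C2", "N3", "C4", "C5", "C6"), ring))
    atoms["O2"] = atoms["C2"] + 1.23 * (atoms["C2"] - center) / 1.39
    atoms["N4"] = atoms["C4"] + 1.34 * (atoms["C4"] - center) / 1.39
    return atoms


def _guanine_2d() -> dict[str, np.ndarray]:
    side5 = 1.37
    r5 = side5 / (2.0 * math.sin(math.pi / 5.0))
    c5 = np.array([r5, 0.0])
    n9, c4, c5a, n7, c8 = _polygon(c5, r5, [180, 108, 36, -36, -108])
    atoms = {"N9": n9, "C4": c4, "C5": c5a, "N7": n7, "C8": c8}
    # hexagon fused on the C4-C5 edge, on the side away from the pentagon
    mid = 0.5 * (c4 + c5a)
    edge = c5a - c4
    side6 = float(np.linalg.norm(edge))
    e = edge / side6
    nrm = np.array([-e[1], e[0]])
    if np.dot(nrm, mid - c5) < 0:
        nrm = -nrm
    hex_center = mid + nrm * side6 * math.sqrt(3.0) / 2.0
    ang4 = math.degrees(math.atan2(c4[1] - hex_center[1], c4[0] - hex_center[0]))
    ang5 = math.degrees(math.atan2(c5a[1] - hex_center[1], c5a[0] - hex_center[0]))
    step = 60.0 if (ang5 - ang4) % 360.0 > 180.0 else -60.0
    n3, c2, n1, c6 = _polygon(
        hex_center, side6, [ang4 + step, ang4 + 2 * step, ang4 + 3 * step, ang4 + 4 * step]
    )
    atoms.update({"N3": n3, "C2": c2, "N1": n1, "C6": c6})
    atoms["O6"] = c6 + 1.23 * (c6 - hex_center) / side6
    atoms["N2"] = c2 + 1.34 * (c2 - hex_center) / side6
    return atoms


_BASE_2D = {"C": _cytosine_2d(), "G": _guanine_2d()}
_GLYC_N = {"C": "N1", "G": "N9"}
_CHI_REF = {"C": "C2", "G": "C4"}  # fourth atom of the chi quadruple
_RING_MEMBERS = {
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "G": ("N9", "C4", "C5", "N7", "C8", "N3", "C2", "N1", "C6"),
}


def _embed_base(
    coords: dict[str, np.ndarray], base: str, chi: float
) -> dict[str, np.ndarray]:
    """Attach the planar base to the sugar with the requested chi torsion."""
    n_name, ref_name = _GLYC_N[base], _CHI_REF[base]
    n3d = _nerf(coords["C4'"], coords["O4'"], coords["C1'"], 1.48, 108.0, -122.0)
    ref3d = _nerf(coords["O4'"], coords["C1'"], n3d, 1.37, 126.0, chi)
    t2d = _BASE_2D[base]
    n2d, ref2d = t2d[n_name], t2d[ref_name]
    u2 = ref2d - n2d
    u2 /= np.linalg.norm(u2)
    v2 = np.array([-u2[1], u2[0]])
    u = ref3d - n3d
    u /= np.linalg.norm(u)
    to_c1 = coords["C1'"] - n3d
    w = np.cross(u, to_c1)
    w /= np.linalg.norm(w)
    v = np.cross(w, u)
    out = {n_name: n3d, ref_name: ref3d}
    for name, p2 in t2d.items():
        if name in out:
            continue
        rel = p2 - n2d
        out[name] = n3d + np.dot(rel, u2) * u + np.dot(rel, v2) * v
    return out


def _nucleotide_template(base: str, params: dict) -> dict[str, np.ndarray]:
    """One nucleotide in a local frame: sugar ring from the pseudorotation
    target, backbone by internal coordinates, base plane by chi."""
    coords = dict(ring_coordinates(params["pucker"][base], params["amplitude"]))
    coords["C5'"] = _nerf(coords["C2'"], coords["C3'"], coords["C4'"], 1.51, 109.5, -120.0)
    coords["O5'"] = _nerf(coords["C3'"], coords["C4'"], coords["C5'"], 1.42, 110.0, 54.0)
    coords["P"] = _nerf(coords["C4'"], coords["C5'"], coords["O5'"], 1.59, 120.0, 180.0)
    coords["OP1"] = _nerf(coords["C5'"], coords["O5'"], coords["P"], 1.48, 108.0, -60.0)
    coords["OP2"] = _nerf(coords["C5'"], coords["O5'"], coords["P"], 1.48, 108.0, 60.0)
    coords["O3'"] = _nerf(coords["C1'"], coords["C2'"], coords["C3'"], 1.42, 110.0, -122.0)
    if params["rna"]:
        coords["O2'"] = _nerf(coords["O4'"], coords["C1'"], coords["C2'"], 1.41, 110.0, 118.0)
    coords.update(_embed_base(coords, base, params["chi"][base]))
    return coords


def _orient_for_pair(coords: dict[str, np.ndarray], base: str, displacement: float) -> dict[str, np.ndarray]:
    """Rotate/translate a nucleotide into the base-pair frame for strand 1.

    The base ring centroid lands near the axis (offset along +y), the ring
    plane becomes ~z=0, and the centroid->C1' direction points toward the
    backbone at a fixed azimuth.
    """
    ring = np.array([coords[a] for a in _RING_MEMBERS[base]])
    centroid = ring.mean(axis=0)
    rel = ring - centroid
    _, _, vt = np.linalg.svd(rel)
    normal = vt[2]
    # deterministic chirality: normal aligned with first-ring-bond cross product
    a0, a1 = _RING_MEMBERS[base][0], _RING_MEMBERS[base][1]
    a2 = _RING_MEMBERS[base][-1] if base == "C" else "C8"
    handed = np.cross(coords[a1] - coords[a0], coords[a2] - coords[a0])
    if np.dot(normal, handed) < 0:
        normal = -normal
    u = coords["C1'"] - centroid
    u = u - np.dot(u, normal) * normal
    u /= np.linalg.norm(u)
    e2 = np.cross(normal, u)
    local = np.array([u, e2, normal])  # rows: orthonormal triad
    az = math.radians(130.0)  # centroid->C1' azimuth in the pair frame
    target = np.array(
        [
            [math.cos(az), math.sin(az), 0.0],
            [-math.sin(az), math.cos(az), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    rot = target.T @ local
    offset = np.array([0.0, displacement - 1.8, 0.3])
    return {k: rot @ (v - centroid) + offset for k, v in coords.items()}


_FLIP = np.diag([1.0, -1.0, -1.0])  # dyad: rotation by pi about the x-axis

_PAIR_REF = {"C": "N4", "G": "N9"}  # strand reference atoms (matches the axis fit)


def _equalize_phosphate_radius(templates: dict[str, dict[str, np.ndarray]]) -> None:
    """Rotate the C nucleotide about the vertical line through its own pair
    reference point until its phosphorus sits at the same distance from the
    helix axis as the G phosphorus.

    The rotation leaves the reference point (hence the pair center and axis
    collinearity) unchanged, so in the assembled ideal helix every phosphorus
    ends up at one common cylindrical radius.
    """
    from scipy.optimize import brentq

    t_c, t_g = templates["C"], templates["G"]
    a_c = 0.5 * (t_c["C1'"] + t_c[_PAIR_REF["C"]])
    b_g = 0.5 * (t_g["C1'"] + t_g[_PAIR_REF["G"]])
    center = 0.5 * (a_c + _FLIP @ b_g)
    target = float(np.linalg.norm((_FLIP @ t_g["P"])[:2] - center[:2]))

    def mismatch(phi: float) -> float:
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        p = a_c[:2] + rot @ (t_c["P"][:2] - a_c[:2])
        return float(np.linalg.norm(p - center[:2])) - target

    grid = np.linspace(-math.pi, math.pi, 181)
    vals = [mismatch(g) for g in grid]
    root = None
    best = None
    for g0, g1, v0, v1 in zip(grid, grid[1:], vals, vals[1:]):
        if v0 == 0.0:
            cand = g0
        elif v0 * v1 < 0:
            cand = brentq(mismatch, g0, g1, xtol=1e-12)
        else:
            continue
        if best is None or abs(cand) < best:
            root, best = cand, abs(cand)
    if root is None:
        return  # geometrically unreachable; leave radii unequal
    c, s = math.cos(root), math.sin(root)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    templates["C"] = {k: a_c + rot @ (v - a_c) for k, v in t_c.items()}


def _rotation_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_duplex(spec: DuplexSpec | None = None, **kwargs) -> Trajectory:
    """Assemble an idealized duplex as a one-frame trajectory.

    Residue i of strand 1 pairs residue N+1-i of strand 2 (antiparallel, via
    an exact dyad flip, so pair flavors are mirror images).  Pair reference
    centers sit exactly on the global z-axis.  The 5'-terminal residue of
    each strand carries no phosphate group: a 12-bp duplex has 22 phosphates
    and net formal charge -22e.
    """
    if spec is None:
        spec = DuplexSpec(**kwargs)
    seq = spec.sequence.upper()
    if len(seq) % 2 or any(b not in "CG" for b in seq):
        raise ValueError("sequence must be even-length over the CG alphabet")
    if any(a == b for a, b in zip(seq, seq[1:])):
        raise ValueError("sequence must alternate C and G")
    if spec.form not in FORM_PARAMS:
        raise ValueError(f"unknown form {spec.form!r}; choose from {sorted(FORM_PARAMS)}")
    params = {**FORM_PARAMS[spec.form], **spec.overrides}
    n = len(seq)
    templates = {
        b: _orient_for_pair(_nucleotide_template(b, params), b, params["displacement"])
        for b in "CG"
    }
    _equalize_phosphate_radius(templates)

    # one local pair per flavor, re-centered so its reference center is the origin
    def _pair(base1: str) -> dict[tuple[int, str], np.ndarray]:
        base2 = _COMPLEMENT[base1]
        s1 = templates[base1]
        s2 = {k: _FLIP @ v for k, v in templates[base2].items()}
        # same reference convention as the axis fit (purine N9, pyrimidine N4)
        ref_atom = {"C": "N4", "G": "N9"}
        refs = []
        for s, b in ((s1, base1), (s2, base2)):
            refs.append(0.5 * (s["C1'"] + s[ref_atom[b]]))
        center = 0.5 * (refs[0] + refs[1])
        out = {}
        for k, v in s1.items():
            out[(1, k)] = v - center
        for k, v in s2.items():
            out[(2, k)] = v - center
        return out

    pair_flavors = {b: _pair(b) for b in "CG"}

    twists = params["twist"]
    rise = params["rise"]
    placed: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    theta = 0.0
    for i in range(1, n + 1):
        base1 = seq[i - 1]
        rot = _rotation_z(theta)
        shift = np.array([0.0, 0.0, (i - 1) * rise])
        local = pair_flavors[base1]
        s1_res = {k: rot @ v + shift for (s, k), v in local.items() if s == 1}
        s2_res = {k: rot @ v + shift for (s, k), v in local.items() if s == 2}
        placed[("A", i)] = s1_res
        placed[("B", n + 1 - i)] = s2_res
        theta += twists[(i - 1) % len(twists)]

    backbone_order = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'"]
    if params["rna"]:
        backbone_order.append("O2'")
    backbone_order.append("C1'")

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for chain in ("A", "B"):
        for resi in range(1, n + 1):
            res_coords = placed[(chain, resi)]
            base = seq[resi - 1] if chain == "A" else _COMPLEMENT[seq[n - resi]]
            # stable order: backbone first, then base atoms sorted by name
            base_atoms = sorted(set(res_coords) - set(backbone_order))
            for name in backbone_order + base_atoms:
                if resi == 1 and name in ("P", "OP1", "OP2"):
                    continue  # 5'-terminal residue: no phosphate group
                charge = -1.0 if name == "P" else 0.0
                element = name[0]
                atoms.append(Atom(name, element, resi, base, chain, charge))
                coords.append(res_coords[name])
    arr = np.array(coords)
    # center the duplex in the box
    arr += spec.box / 2.0 - (arr.max(axis=0) + arr.min(axis=0)) / 2.0
    topo = Topology(atoms)
    return Trajectory(topo, arr[None], np.array([spec.box] * 3), dt=1.0, species={})


# ---------------------------------------------------------------------------
# stochastic simulators
# ---------------------------------------------------------------------------

def simulate_telegraph(spec: TelegraphSpec) -> tuple[Trajectory, list[dict]]:
    """Alternating exponential bound/unbound process, rendered as one static
    site atom plus one ion.  Bound frames jitter the ion about the site;
    unbound frames place it uniformly in the box.  Returns the trajectory and
    the ground-truth event list."""
    rng = np.random.default_rng(spec.seed)
    T_ps = spec.T * 1000.0
    events: list[dict] = []
    t = 0.0
    state = 0  # start unbound
    while t < T_ps:
        rate = spec.k_on if state == 0 else spec.k_off  # 1/ns
        dur = rng.exponential(1000.0 / rate)  # ps
        events.append({"state": state, "t_start_ps": t, "t_end_ps": min(t + dur, T_ps)})
        t += dur
        state = 1 - state
    n_frames = int(math.floor(T_ps / spec.dt)) + 1
    times = np.arange(n_frames) * spec.dt
    frame_state = events_to_states(events, spec.dt, n_frames)

    site = np.array(spec.site) if spec.site is not None else np.full(3, spec.box / 2.0)
    coords = np.empty((n_frames, 2, 3))
    coords[:, 0, :] = site
    bound = frame_state.astype(bool)
    coords[bound, 1, :] = site + rng.normal(0.0, spec.sigma, size=(int(bound.sum()), 3))
    n_unbound = int((~bound).sum())
    free = rng.uniform(0.0, spec.box, size=(n_unbound, 3))
    # redraw unbound positions inside the exclusion zone (min-image distance)
    for _ in range(200):
        d = free - site
        d -= spec.box * np.round(d / spec.box)
        bad = np.sum(d * d, axis=1) < spec.exclusion**2
        if not bad.any():
            break
        free[bad] = rng.uniform(0.0, spec.box, size=(int(bad.sum()), 3))
    coords[~bound, 1, :] = free

    atoms = [
        Atom("O6", "O", 1, "G", "A", 0.0),
        Atom("Na", "Na", 2, "", "X", ION_CHARGES["Na+"]),
    ]
    traj = Trajectory(
        Topology(atoms),
        coords,
        np.array([spec.box] * 3),
        times=times,
        species={"Na+": np.array([1])},
    )
    return traj, events


def events_to_states(events: list[dict], dt: float, n_frames: int) -> np.ndarray:
    """Per-frame bound/unbound state (0/1) sampled from a telegraph event list."""
    times = np.arange(n_frames) * dt
    starts = np.array([e["t_start_ps"] for e in events])
    states = np.array([e["state"] for e in events])
    return states[np.searchsorted(starts, times, side="right") - 1].astype(np.uint8)


def simulate_brownian(spec: BrownianSpec) -> Trajectory:
    """Overdamped Euler-Maruyama diffusion with periodic wrap and optional
    attractive Gaussian wells (depth in kT, kT = 1)."""
    rng = np.random.default_rng(spec.seed)
    step_sigma = math.sqrt(2.0 * spec.D * spec.dt)
    if step_sigma > spec.box / 4.0:
        raise ValueError("step sigma exceeds box/4; reduce dt or D")
    n_frames = int(math.floor(spec.T * 1000.0 / spec.dt)) + 1
    pos = rng.uniform(0.0, spec.box, size=(spec.n, 3))
    out = np.empty((n_frames, spec.n, 3))
    out[0] = pos
    box = np.array([spec.box] * 3)
    wells = [
        (np.asarray(c, dtype=float), float(depth), float(width))
        for c, depth, width in spec.wells
    ]
    for w in wells:
        if w[2] <= 0:
            raise ValueError("well width must be positive")
    for f in range(1, n_frames):
        drift = np.zeros_like(pos)
        for center, depth, width in wells:
            d = pos - center
            d -= box * np.round(d / box)
            s2 = np.sum(d * d, axis=1, keepdims=True)
            # U = -depth * exp(-s^2 / 2 width^2); drift = -D grad(U) dt
            drift += -spec.D * spec.dt * depth * d / width**2 * np.exp(
                -s2 / (2.0 * width**2)
            )
        noise = rng.normal(0.0, step_sigma, size=pos.shape) if spec.D > 0 else 0.0
        pos = np.mod(pos + drift + noise, spec.box)
        out[f] = pos
    atoms = [Atom("Na", "Na", i + 1, "", "X", 1.0) for i in range(spec.n)]
    times = np.arange(n_frames) * spec.dt
    return Trajectory(
        Topology(atoms), out, box, times=times, species={"Na+": np.arange(spec.n)}
    )


def generate_hydration_shell(
    n_shell: int,
    d0: float,
    sigma: float,
    rho_bulk: float,
    box: float,
    seed: int | np.random.Generator = 0,
    min_separation: float = 2.0,
    max_retries: int = 2000,
) -> np.ndarray:
    """Water-oxygen point cloud around a central ion at the box center.

    ``n_shell`` points at radius Gaussian(d0, sigma) with uniform directions,
    rejecting shell-shell overlaps below ``min_separation``; bulk points at
    uniform density outside 1.5*d0 of the ion.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if n_shell < 0:
        raise ValueError("n_shell must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = np.full(3, box / 2.0)
    shell: list[np.ndarray] = []
    tries = 0
    while len(shell) < n_shell:
        if tries > max_retries:
            raise RuntimeError(
                f"shell overlap rejection failed after {max_retries} retries"
            )
        r = rng.normal(d0, sigma)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        p = center + r * v
        if all(np.linalg.norm(p - s) >= min_separation for s in shell):
            shell.append(p)
        tries += 1
    n_bulk = int(round(rho_bulk * box**3))
    bulk: list[np.ndarray] = []
    excl = 1.5 * d0
    while len(bulk) < n_bulk:
        p = rng.uniform(0.0, box, size=3)
        if np.linalg.norm(p - center) > excl:
            bulk.append(p)
    pts = shell + bulk
    return np.array(pts) if pts else np.empty((0, 3))


def hydration_shell_trajectory(
    n_frames: int,
    n_shell: int = 6,
    d0: float = 2.43,
    sigma: float = 0.1,
    rho_bulk: float = 0.0,
    box: float = 20.0,
    seed: int = 0,
    ion: str = "Na+",
) -> Trajectory:
    """Independent shell configurations stacked as frames around a fixed ion."""
    rng = np.random.default_rng(seed)
    frames = []
    center = np.full(3, box / 2.0)
    for _ in range(n_frames):
        pts = generate_hydration_shell(n_shell, d0, sigma, rho_bulk, box, seed=rng)
        frames.append(np.vstack([center[None], pts]))
    coords = np.stack(frames)
    n_pts = coords.shape[1] - 1
    el = {"Na+": "Na", "K+": "K", "Mg2+": "Mg"}[ion]
    atoms = [Atom(el, el, 1, "", "X", ION_CHARGES[ion])]
    atoms += [Atom("O", "O", i + 2, "", "W", 0.0) for i in range(n_pts)]
    return Trajectory(
        Topology(atoms),
        coords,
        np.array([box] * 3),
        dt=1.0,
        species={ion: np.array([0]), "WAT-O": np.arange(1, n_pts + 1)},
    )
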