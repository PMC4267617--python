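"""Core domain model: atoms, topology, trajectory, region labels, periodic geometry.

Units are Angstrom and picosecond throughout.  Coordinates are 0-based arrays;
residue indices are 1-based as in PDB files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "RegionLabel",
    "classify_region",
    "normalize_atom_name",
    "min_image_displacement",
    "min_image_distance",
    "load_structure",
    "write_pdb",
    "write_xyz",
    "ION_CHARGES",
    "SPECIES_ALIASES",
]

NUCLEOTIDE_BASES = frozenset("ACGUT")

#: formal charge per ion species label (elementary-charge units)
ION_CHARGES: dict[str, float] = {
    "Na+": +1.0,
    "K+": +1.0,
    "Mg2+": +2.0,
    "Cl-": -1.0,
    "WAT-O": 0.0,
}

#: residue-name spellings mapped to canonical species labels
SPECIES_ALIASES: dict[str, str] = {
    "NA": "Na+", "NA+": "Na+", "SOD": "Na+",
    "K": "K+", "K+": "K+", "POT": "K+",
    "MG": "Mg2+", "MG2": "Mg2+", "MG2+": "Mg2+",
    "CL": "Cl-", "CL-": "Cl-", "CIM": "Cl-",
    "WAT": "WAT-O", "HOH": "WAT-O", "TIP3": "WAT-O",
}

#: residue-name spellings for nucleotides -> one-letter base
_BASE_ALIASES: dict[str, str] = {}
for _b in "ACGUT":
    for _suffix in ("", "3", "5", "N"):
        _BASE_ALIASES[f"D{_b}{_suffix}"] = _b
        _BASE_ALIASES[f"{_b}{_suffix}"] = _b
for _name, _b in (("ADE", "A"), ("CYT", "C"), ("GUA", "G"), ("URA", "U"), ("THY", "T")):
    _BASE_ALIASES[_name] = _b


def normalize_atom_name(name: str) -> str:
    """Canonicalize atom-name spelling across PDB dialects.

    Accepts unicode primes, asterisk-primed names ("O5*") and the legacy
    O1P/O2P phosphate-oxygen names.
    """
    n = name.strip().replace("′", "'").replace("*", "'")
    if n == "O1P":
        n = "OP1"
    elif n == "O2P":
        n = "OP2"
    return n


class RegionLabel(str, Enum):
    """Groove/backbone classification of a duplex atom."""

    MAJOR = "major"
    MINOR = "minor"
    BACKBONE_OPRIME = "backbone_Oprime"
    PHOSPHATE = "phosphate"
    OTHER = "other"


# groove conventions for the CG alphabet; identical for right- and left-handed
# duplex forms.
_MAJOR_ATOMS = {"C": {"N4"}, "G": {"O6", "N7"}}
_MINOR_ATOMS = {"C": {"O2", "N1"}, "G": {"N2", "N3", "N9"}}
_OPRIME_ATOMS = {"O5'", "O4'", "O3'", "O2'"}
_PHOSPHATE_ATOMS = {"OP1", "OP2"}


@dataclass(frozen=True)
class Atom:
    """A single atom with its residue context and formal charge (e units)."""

    name: str
    element: str
    residue_index: int
    base: str  # one of A/C/G/U/T for nucleotides, "" otherwise
    chain: str
    formal_charge: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_atom_name(self.name))

    @property
    def is_nucleotide(self) -> bool:
        return self.base in NUCLEOTIDE_BASES


def classify_region(atom: Atom) -> RegionLabel:
    """Assign the groove/backbone region label of a duplex atom.

    The convention follows the standard CG-pair assignment: C(N4), G(O6, N7)
    are major groove; C(O2, N1), G(N2, N3, N9) minor groove; the primed
    backbone oxygens and the two phosphate oxygens get their own labels.
    Everything else (carbons, phosphorus, ...) is ``other``.
    """
    if not atom.is_nucleotide:
        raise ValueError(
            f"cannot classify atom {atom.name!r}: unknown base {atom.base!r}"
        )
    name = atom.name
    if name in _PHOSPHATE_ATOMS:
        return RegionLabel.PHOSPHATE
    if name in _OPRIME_ATOMS:
        return RegionLabel.BACKBONE_OPRIME
    if name in _MAJOR_ATOMS.get(atom.base, ()):
        return RegionLabel.MAJOR
    if name in _MINOR_ATOMS.get(atom.base, ()):
        return RegionLabel.MINOR
    return RegionLabel.OTHER


class Topology:
    """Ordered atom list plus duplex bookkeeping (pairing map, net charge)."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.chains = np.array([a.chain for a in self.atoms])
        self.residue_indices = np.array([a.residue_index for a in self.atoms])
        self.bases = np.array([a.base for a in self.atoms])
        self.formal_charges = np.array([a.formal_charge for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def duplex_mask(self) -> np.ndarray:
        return np.isin(self.bases, list(NUCLEOTIDE_BASES))

    @property
    def duplex_indices(self) -> np.ndarray:
        return np.flatnonzero(self.duplex_mask)

    @property
    def duplex_chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.is_nucleotide and a.chain not in seen:
                seen.append(a.chain)
        return seen

    def residues_of(self, chain: str) -> list[int]:
        mask = (self.chains == chain) & self.duplex_mask
        return sorted(set(self.residue_indices[mask].tolist()))

    @property
    def n_phosphates(self) -> int:
        mask = (self.names == "P") & self.duplex_mask
        return int(mask.sum())

    @property
    def net_charge(self) -> float:
        """Net formal charge of the duplex (e units)."""
        return float(self.formal_charges[self.duplex_mask].sum())

    def pairing_map(self) -> dict[tuple[str, int], tuple[str, int]]:
        """Antiparallel pairing: residue i of strand 1 <-> residue N+1-i of strand 2.

        Returned as an involution over (chain, residue_index) keys.
        """
        chains = self.duplex_chains
        if len(chains) != 2:
            raise ValueError(f"duplex needs exactly 2 chains, found {chains}")
        c1, c2 = chains
        r1, r2 = self.residues_of(c1), self.residues_of(c2)
        if len(r1) != len(r2):
            raise ValueError("strands differ in residue count")
        n = len(r1)
        pairing: dict[tuple[str, int], tuple[str, int]] = {}
        for i in range(n):
            a, b = (c1, r1[i]), (c2, r2[n - 1 - i])
            pairing[a] = b
            pairing[b] = a
        return pairing

    def select(
        self,
        names: Iterable[str] | None = None,
        chain: str | None = None,
        residue_index: int | None = None,
        base: str | None = None,
        region: RegionLabel | None = None,
    ) -> np.ndarray:
        """Indices of duplex atoms matching all provided criteria."""
        mask = self.duplex_mask.copy()
        if names is not None:
            mask &= np.isin(self.names, [normalize_atom_name(n) for n in names])
        if chain is not None:
            mask &= self.chains == chain
        if residue_index is not None:
            mask &= self.residue_indices == residue_index
        if base is not None:
            mask &= self.bases == base
        if region is not None:
            reg = np.array(
                [
                    classify_region(a).value if a.is_nucleotide else ""
                    for a in self.atoms
                ]
            )
            mask &= reg == region.value
        return np.flatnonzero(mask)


@dataclass
class Frame:
    """One snapshot: coordinates (n_atoms, 3) in Angstrom, orthorhombic box, time in ps."""

    coordinates: np.ndarray
    box: np.ndarray  # (3,) edge lengths
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise ValueError(f"box edges must be positive, got {self.box}")


class Trajectory:
    """Time-ordered frames over a fixed topology, with a species index map."""

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        box: np.ndarray,
        times: np.ndarray | None = None,
        dt: float | None = None,
        species: Mapping[str, np.ndarray] | None = None,
    ):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.ndim == 2:
            coordinates = coordinates[None]
        if coordinates.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate count {coordinates.shape[1]} != atom count {topology.n_atoms}"
            )
        self.topology = topology
        self.coordinates = coordinates
        box = np.asarray(box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box.reshape(1, 3), (len(coordinates), 3)).copy()
        self.box = box
        if times is None:
            dt = 1.0 if dt is None else float(dt)
            times = np.arange(len(coordinates)) * dt
        times = np.asarray(times, dtype=float)
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame times must be uniformly spaced")
        self.times = times
        self.species: dict[str, np.ndarray] = {
            k: np.asarray(v, dtype=int) for k, v in (species or {}).items()
        }

    @property
    def n_frames(self) -> int:
        return len(self.coordinates)

    @property
    def dt(self) -> float:
        """Sampling interval in ps."""
        if len(self.times) < 2:
            return 1.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.box[i], float(self.times[i]))

    def species_indices(self, label: str) -> np.ndarray:
        if label not in self.species:
            raise KeyError(
                f"species {label!r} not in trajectory (have {sorted(self.species)})"
            )
        return self.species[label]

    def window_frames(self, window: tuple[float, float] | None) -> np.ndarray:
        """Frame indices with time in [t_start, t_end] (ps); None means all."""
        if window is None:
            return np.arange(self.n_frames)
        t0, t1 = float(window[0]), float(window[1])
        if t1 < t0:
            raise ValueError(f"window end {t1} before start {t0}")
        idx = np.flatnonzero((self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9))
        if idx.size == 0:
            raise ValueError(
                f"window [{t0}, {t1}] ps selects no frames "
                f"(trajectory spans [{self.times[0]}, {self.times[-1]}] ps)"
            )
        return idx


# ---------------------------------------------------------------------------
# periodic-boundary geometry (orthorhombic only)
# ---------------------------------------------------------------------------

def min_image_displacement(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) p - q for an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> float | np.ndarray:
    """Euclidean distance under the minimum-image convention."""
    d = min_image_displacement(p, q, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_min_image_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """(len(a), len(b)) min-image distance matrix."""
    d = a[:, None, :] - b[None, :, :]
    box = np.asarray(box, dtype=float)
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# structure / trajectory I/O
# ---------------------------------------------------------------------------

def _element_of(atom_name: str) -> str:
    n = normalize_atom_name(atom_name)
    for sym in ("CL", "NA", "MG", "BR"):
        if n.upper().startswith(sym):
            return sym.capitalize()
    return n[0]


def _atoms_from_arrays(
    atom_names: Sequence[str],
    res_names: Sequence[str],
    res_ids: Sequence[int],
    chain_ids: Sequence[str],
    elements: Sequence[str] | None = None,
) -> tuple[list[Atom], dict[str, list[int]]]:
    """Build Atom records and a species map from PDB-style annotation arrays.

    Formal charges follow the residue-template convention: -1 on each
    phosphorus (standing for the phosphate group), ion charges from the
    species label, 0 elsewhere.
    """
    atoms: list[Atom] = []
    species: dict[str, list[int]] = {}
    for i, (an, rn, ri, ch) in enumerate(zip(atom_names, res_names, res_ids, chain_ids)):
        an = normalize_atom_name(an)
        rn = rn.strip().upper()
        el = elements[i].strip().capitalize() if elements is not None and elements[i].strip() else _element_of(an)
        if rn in _BASE_ALIASES:
            base = _BASE_ALIASES[rn]
            charge = -1.0 if an == "P" else 0.0
            atoms.append(Atom(an, el, int(ri), base, str(ch), charge))
        elif rn in SPECIES_ALIASES:
            label = SPECIES_ALIASES[rn]
            if label == "WAT-O" and not an.startswith("O"):
                atoms.append(Atom(an, el, int(ri), "", str(ch), 0.0))
                continue
            charge = ION_CHARGES[label]
            atoms.append(Atom(an, el, int(ri), "", str(ch), charge))
            species.setdefault(label, []).append(i)
        else:
            atoms.append(Atom(an, el, int(ri), "", str(ch), 0.0))
    return atoms, species


_RES_NAME_FOR_SPECIES = {"Na+": "NA", "K+": "K", "Mg2+": "MG", "Cl-": "CL", "WAT-O": "WAT"}


def load_structure(
    path: str | Path,
    dialect: str = "pdb_multimodel",
    dt: float = 1.0,
    topology: Topology | None = None,
    box: Sequence[float] | None = None,
    species_map: Mapping[str, Sequence[int]] | None = None,
) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a per-frame XYZ file.

    For the XYZ dialect a companion ``topology`` and ``box`` must be supplied
    (the format carries neither).  MODEL records become frames; the box is
    read from CRYST1 unless overridden.  ``species_map`` overrides the map
    inferred from residue names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "pdb_multimodel":
        traj = _load_pdb(path, dt=dt, box_override=box)
    elif dialect == "xyz_frames":
        if topology is None or box is None:
            raise ValueError("xyz_frames dialect requires companion topology and box")
        traj = _load_xyz(path, topology, np.asarray(box, dtype=float), dt=dt)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if species_map is not None:
        traj.species = {k: np.asarray(v, dtype=int) for k, v in species_map.items()}
    return traj


def _load_pdb(path: Path, dt: float, box_override: Sequence[float] | None) -> Trajectory:
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ValueError(f"failed to parse PDB {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms parsed")
    coords = np.asarray(stack.coord, dtype=float)
    if box_override is not None:
        box = np.asarray(box_override, dtype=float)
    else:
        if stack.box is None:
            raise ValueError(f"{path}: no CRYST1 box in frame 1 and no box supplied")
        b = np.asarray(stack.box, dtype=float)
        diag = np.einsum("...ii->...i", b)
        offdiag = b - diag[..., None] * np.eye(3)
        if not np.allclose(offdiag, 0, atol=1e-6):
            raise ValueError("triclinic boxes are not supported")
        box = diag if diag.ndim == 2 else np.broadcast_to(diag, (len(coords), 3))
    atoms, species = _atoms_from_arrays(
        stack.atom_name, stack.res_name, stack.res_id, stack.chain_id,
        elements=stack.element if hasattr(stack, "element") else None,
    )
    topo = Topology(atoms)
    return Trajectory(topo, coords, box, dt=dt, species=species)


def _load_xyz(path: Path, topology: Topology, box: np.ndarray, dt: float) -> Trajectory:
    frames: list[np.ndarray] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed XYZ count line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame at line {i + 1}")
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    arr = np.stack(frames)
    if arr.shape[1] != topology.n_atoms:
        raise ValueError(
            f"{path}: atom count mismatch across frames vs topology "
            f"({arr.shape[1]} != {topology.n_atoms})"
        )
    element_species = {"Na": "Na+", "K": "K+", "Mg": "Mg2+", "Cl": "Cl-"}
    species: dict[str, list[int]] = {}
    for i, a in enumerate(topology.atoms):
        if not a.is_nucleotide and a.element in element_species:
            species.setdefault(element_species[a.element], []).append(i)
    return Trajectory(topology, arr, box, dt=dt, species=species)


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB with CRYST1, one MODEL per frame."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    topo = traj.topology
    n = topo.n_atoms
    ion_label: dict[int, str] = {}
    for label, idx in traj.species.items():
        for i in idx:
            ion_label[int(i)] = label
    has_o2p: set[tuple[str, int]] = {
        (a.chain, a.residue_index) for a in topo.atoms if a.name == "O2'"
    }
    res_names = []
    for i, a in enumerate(topo.atoms):
        if a.is_nucleotide:
            rna = (a.chain, a.residue_index) in has_o2p
            res_names.append(a.base if rna else "D" + a.base)
        elif i in ion_label:
            res_names.append(_RES_NAME_FOR_SPECIES[ion_label[i]])
        else:
            res_names.append("UNK")
    res_names = np.array(res_names)
    arrays = []
    for f in range(traj.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = traj.coordinates[f]
        arr.atom_name = topo.names
        arr.element = np.char.upper(topo.elements.astype(str))
        arr.chain_id = topo.chains
        arr.res_id = topo.residue_indices
        arr.res_name = res_names
        arr.hetero = ~topo.duplex_mask
        arr.box = np.diag(traj.box[f])
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a plain per-frame XYZ dialect (element x y z)."""
    topo = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{topo.n_atoms}\n")
            fh.write(f"t= {traj.times[f]:.6f} ps\n")
            for el, xyz in zip(topo.elements, traj.coordinates[f]):
                fh.write(f"{el:<4s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n")
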