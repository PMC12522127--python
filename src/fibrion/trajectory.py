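"""Trajectory data model, readers/writers, atom selection, and the PBC distance kernel.

The in-memory model is deliberately small: a :class:`SystemTopology` (per-atom
identity plus a single group tag), a list of :class:`Frame` objects (positions
in angstrom and an orthorhombic box), and :class:`Selection` (named index sets
with an anchor rule).  File I/O goes through MDAnalysis, which already handles
PDB/GRO/XTC/DCD and their unit conventions (everything is converted to
angstrom on read); the model here is what the analysis kernels operate on.

Only orthorhombic cells are supported: the minimum-image convention then
reduces to a per-axis nearest-integer wrap, which is what
:func:`min_image_distance` implements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptySelectionError,
    FormatError,
    TopologyMismatchError,
    UnsupportedBoxError,
)

__all__ = [
    "SystemTopology",
    "Frame",
    "Trajectory",
    "Selection",
    "load_system",
    "select_group",
    "min_image_displacement",
    "min_image_distance",
    "write_pdb",
    "write_gro",
    "write_tsv",
]

# Residue-name vocabularies used to assign the single group tag per atom.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}
WATER_RESNAMES = {"SOL", "WAT", "HOH", "TIP3", "TIP", "SPC", "T3P", "TP3"}
# residue name -> ion species symbol
ION_RESNAMES = {
    "NA": "NA", "SOD": "NA", "NA+": "NA",
    "CL": "CL", "CLA": "CL", "CL-": "CL",
    "K": "K", "POT": "K", "K+": "K",
    "MG": "MG", "MG2": "MG",
    "CA": "CA", "CAL": "CA",
    "HPO4": "HPO4", "HPO": "HPO4", "PO4": "HPO4",
    "H2PO4": "H2PO4", "H2P": "H2PO4",
    "SO4": "SO4",
}
# species whose contacts are measured from a single anchor atom (phosphorus
# for the phosphate anions, as the distances are defined from the P atom)
SINGLE_ANCHOR_SPECIES = {"HPO4": "P", "H2PO4": "P"}

_TWO_LETTER_ELEMENTS = {"NA", "CL", "MG", "CA", "FE", "ZN", "MN", "BR", "CU", "NI"}
_MONATOMIC_ION_ELEMENT = {"NA": "NA", "CL": "CL", "K": "K", "MG": "MG", "CA": "CA"}


def infer_element(atom_name: str, residue_name: str) -> str:
    """Infer an element symbol from an atom name.

    PDB files frequently ship without the element column; the leading letters
    of the atom name are used, with an override table so that monatomic-ion
    residues (NA, CL, MG, K, CA) resolve to the ion element rather than
    nitrogen/carbon/etc.
    """
    resname = residue_name.strip().upper()
    if resname in ION_RESNAMES and ION_RESNAMES[resname] in _MONATOMIC_ION_ELEMENT:
        return _MONATOMIC_ION_ELEMENT[ION_RESNAMES[resname]]
    letters = "".join(c for c in atom_name.strip() if c.isalpha()).upper()
    if not letters:
        raise FormatError(f"cannot infer element from atom name {atom_name!r}")
    if letters[:2] in _TWO_LETTER_ELEMENTS:
        return letters[:2]
    return letters[0]


def _group_tag(residue_name: str, element: str) -> str:
    resname = residue_name.strip().upper()
    if resname in AMINO_ACIDS:
        return "protein"
    if resname in WATER_RESNAMES:
        return "water"
    if resname in ION_RESNAMES:
        return f"ion:{ION_RESNAMES[resname]}"
    return "other"


@dataclass
class SystemTopology:
    """Per-atom identity: names, elements, residue labels, chain, group tag.

    Atom indices are implicit array positions (0..n-1).  Each atom carries
    exactly one group tag: ``protein``, ``water``, ``ion:<species>`` or
    ``other``.
    """

    atom_names: np.ndarray          # str array, shape (n,)
    elements: np.ndarray            # str array
    residue_indices: np.ndarray     # int array
    residue_names: np.ndarray       # str array
    chain_ids: np.ndarray           # str array
    groups: np.ndarray              # str array (tags)

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for name in ("elements", "residue_indices", "residue_names", "chain_ids", "groups"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise TopologyMismatchError(
                    f"topology field {name} has length {arr.shape}, expected ({n},)"
                )
            setattr(self, name, arr)
        self.atom_names = np.asarray(self.atom_names)
        self.residue_indices = np.asarray(self.residue_indices, dtype=np.int64)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def indices_where(self, mask: np.ndarray) -> np.ndarray:
        return np.flatnonzero(mask)


@dataclass
class Frame:
    """One snapshot: time (ps), positions (n,3) in angstrom, orthorhombic box edges."""

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise FormatError(f"positions must be (n, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("non-finite coordinates in frame")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise UnsupportedBoxError(f"box must be 3 positive edge lengths, got {self.box}")


@dataclass
class Trajectory:
    """An ordered sequence of frames over a fixed topology."""

    topology: SystemTopology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise FormatError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.positions.shape[0] != n:
                raise TopologyMismatchError(
                    f"frame {i} has {fr.positions.shape[0]} atoms, topology has {n}"
                )
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise FormatError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def coords(self) -> np.ndarray:
        """Stacked positions, shape (n_frames, n_atoms, 3)."""
        return np.stack([fr.positions for fr in self.frames])

    def boxes(self) -> np.ndarray:
        return np.stack([fr.box for fr in self.frames])


@dataclass
class Selection:
    """A named atom subset with an anchor rule.

    ``anchor_rule`` is one of ``all_atoms``, ``heavy_atoms_only``,
    ``single_anchor_atom``; the indices already honour the rule (e.g. a
    phosphate selection with a phosphorus anchor contains only P atoms).
    """

    name: str
    species: str
    atom_indices: np.ndarray
    anchor_rule: str = "all_atoms"

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(sorted(set(int(i) for i in np.atleast_1d(self.atom_indices))), dtype=np.int64)
        if self.atom_indices.size == 0:
            raise EmptySelectionError(f"selection {self.name!r} is empty")

    def __len__(self) -> int:
        return int(self.atom_indices.size)


# ---------------------------------------------------------------------------
# PBC distance kernel
# ---------------------------------------------------------------------------

def min_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum image of an orthorhombic box."""
    delta = np.asarray(delta, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    return delta - box * np.round(delta / box)


def min_image_distance(p, q, box) -> float:
    """Minimum-image Euclidean distance between two points in an orthorhombic box.

    Symmetric in ``p, q``; the result never exceeds half the box diagonal.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q)) and np.all(np.isfinite(box))):
        raise ValueError("non-finite input to min_image_distance")
    if np.any(box <= 0):
        raise UnsupportedBoxError(f"box edges must be positive, got {box}")
    d = min_image_displacement(p - q, box)
    return float(np.linalg.norm(d))


def pairwise_min_image_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances, shape (len(a), len(b))."""
    delta = a[:, None, :] - b[None, :, :]
    delta = min_image_displacement(delta, np.asarray(box, dtype=np.float64))
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _check_orthorhombic(dimensions, context: str) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise UnsupportedBoxError(f"{context}: no box information present")
    dims = np.asarray(dimensions, dtype=np.float64)
    if dims.shape[0] >= 6 and not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise UnsupportedBoxError(
            f"{context}: only orthorhombic boxes are supported (angles {dims[3:6]})"
        )
    if np.any(dims[:3] <= 0):
        raise UnsupportedBoxError(f"{context}: box edges must be positive ({dims[:3]})")
    return dims[:3].copy()


def load_system(structure_path, trajectory_path=None) -> Trajectory:
    """Read a structure (PDB/GRO) and optional trajectory (XTC/DCD/multi-frame PDB).

    All coordinates are stored in angstrom (nm-based formats are converted on
    read).  Elements are inferred from atom names when the file does not
    provide them.  A trajectory whose atom count differs from the structure
    raises :class:`TopologyMismatchError`.
    """
    import MDAnalysis as mda

    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FormatError(f"structure file not found: {structure_path}")
    if trajectory_path is not None and not Path(trajectory_path).exists():
        raise FormatError(f"trajectory file not found: {trajectory_path}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory_path is None:
                u = mda.Universe(str(structure_path))
            else:
                u = mda.Universe(str(structure_path), str(trajectory_path))
        except (ValueError, IndexError, KeyError) as exc:
            msg = str(exc)
            if trajectory_path is not None and (
                isinstance(exc, IndexError) or "number of atoms" in msg.lower()
            ):
                raise TopologyMismatchError(
                    f"trajectory {trajectory_path} does not match structure "
                    f"{structure_path}: {msg}"
                ) from exc
            raise FormatError(f"could not parse {structure_path}: {msg}") from exc
        except (OSError, EOFError) as exc:
            raise FormatError(f"unreadable file: {exc}") from exc

        atoms = u.atoms
        names = atoms.names.astype(str)
        resnames = atoms.resnames.astype(str)
        resids = atoms.resids.astype(np.int64)
        if hasattr(atoms, "chainIDs"):
            chains = np.array([c if str(c).strip() else "A" for c in atoms.chainIDs], dtype=object)
        else:
            chains = np.array([str(s) for s in atoms.segids], dtype=object)
        elements = np.array(
            [infer_element(n, r) for n, r in zip(names, resnames)], dtype=object
        )
        groups = np.array([_group_tag(r, e) for r, e in zip(resnames, elements)], dtype=object)

        topo = SystemTopology(
            atom_names=names.astype(object),
            elements=elements,
            residue_indices=resids,
            residue_names=resnames.astype(object),
            chain_ids=chains,
            groups=groups,
        )

        frames: list[Frame] = []
        last_time = -np.inf
        for i, ts in enumerate(u.trajectory):
            box = _check_orthorhombic(ts.dimensions, f"frame {i}")
            t = float(ts.time) if np.isfinite(ts.time) else float(i)
            if t <= last_time:      # formats without real times: fall back to frame index
                t = last_time + 1.0
            last_time = t
            frames.append(Frame(time=t, positions=ts.positions.astype(np.float64), box=box))

    return Trajectory(topology=topo, frames=frames)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_group(traj: Trajectory, spec: str) -> Selection:
    """Resolve a selection expression against a trajectory's topology.

    Supported expressions:

    - ``protein`` / ``protein_heavy`` — all protein atoms / excluding hydrogens
    - ``water_O`` — water oxygen atoms
    - ``ion:<SPECIES>`` — e.g. ``ion:NA``; phosphate species obey their
      single-anchor rule and return only the phosphorus atoms
    - ``resid <a>-<b>`` — protein heavy atoms in a residue-index range

    An expression that matches no atoms raises :class:`EmptySelectionError`.
    """
    topo = traj.topology
    spec = spec.strip()
    is_h = topo.elements == "H"

    if spec in ("protein", "protein_heavy"):
        mask = topo.groups == "protein"
        if spec == "protein_heavy":
            mask &= ~is_h
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise EmptySelectionError(f"no atoms match {spec!r}")
        rule = "heavy_atoms_only" if spec == "protein_heavy" else "all_atoms"
        return Selection(name=spec, species="protein_heavy" if spec == "protein_heavy" else "protein",
                         atom_indices=idx, anchor_rule=rule)

    if spec in ("water_O", "water_o"):
        mask = (topo.groups == "water") & (topo.elements == "O")
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise EmptySelectionError("no water oxygen atoms in topology")
        return Selection(name="water_O", species="water_O", atom_indices=idx,
                         anchor_rule="single_anchor_atom")

    if spec.lower().startswith("ion:"):
        species = spec.split(":", 1)[1].strip().upper()
        mask = topo.groups == f"ion:{species}"
        if species in SINGLE_ANCHOR_SPECIES:
            mask &= topo.elements == SINGLE_ANCHOR_SPECIES[species]
            rule = "single_anchor_atom"
        else:
            rule = "all_atoms"
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise EmptySelectionError(
                f"no atoms match ion species {species!r} in topology"
            )
        return Selection(name=spec, species=species, atom_indices=idx, anchor_rule=rule)

    if spec.lower().startswith("resid"):
        body = spec.split(None, 1)[1]
        if "-" in body:
            lo, hi = (int(x) for x in body.split("-"))
        else:
            lo = hi = int(body)
        mask = (
            (topo.groups == "protein")
            & ~is_h
            & (topo.residue_indices >= lo)
            & (topo.residue_indices <= hi)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise EmptySelectionError(f"no protein heavy atoms in resid range {lo}-{hi}")
        return Selection(name=spec, species="protein_heavy", atom_indices=idx,
                         anchor_rule="heavy_atoms_only")

    raise EmptySelectionError(f"unrecognised selection expression {spec!r}")


# ---------------------------------------------------------------------------
# Writers (plain-text formats used for fixtures and synthetic output)
# ---------------------------------------------------------------------------

def write_pdb(traj: Trajectory, path) -> None:
    """Write a multi-frame PDB (MODEL/ENDMDL) with a CRYST1 record per the first box."""
    topo = traj.topology
    path = Path(path)
    with path.open("w") as fh:
        for m, fr in enumerate(traj.frames, start=1):
            fh.write(
                "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f P 1           1\n"
                % (fr.box[0], fr.box[1], fr.box[2], 90.0, 90.0, 90.0)
            )
            fh.write(f"MODEL     {m:4d}\n")
            for i in range(topo.n_atoms):
                name = str(topo.atom_names[i])[:4]
                resname = str(topo.residue_names[i])[:4]
                chain = (str(topo.chain_ids[i]) or "A")[0]
                resid = int(topo.residue_indices[i]) % 10000
                x, y, z = fr.positions[i]
                element = str(topo.elements[i])[:2]
                fh.write(
                    "ATOM  %5d %-4s %-4s%s%4d    %8.3f%8.3f%8.3f  1.00  0.00          %2s\n"
                    % ((i + 1) % 100000, name, resname, chain, resid, x, y, z, element.rjust(2))
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_gro(traj: Trajectory, path, frame: int = 0) -> None:
    """Write a single frame as a GRO file (coordinates converted to nm)."""
    topo = traj.topology
    fr = traj.frames[frame]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"fibrion synthetic system, t= {fr.time:.3f} ps\n")
        fh.write(f"{topo.n_atoms:5d}\n")
        for i in range(topo.n_atoms):
            resid = int(topo.residue_indices[i]) % 100000
            resname = str(topo.residue_names[i])[:5]
            name = str(topo.atom_names[i])[:5]
            x, y, z = fr.positions[i] / 10.0
            fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n" % (resid, resname, name, (i + 1) % 100000, x, y, z))
        fh.write("%10.5f%10.5f%10.5f\n" % tuple(fr.box / 10.0))


def write_tsv(traj: Trajectory, path) -> None:
    """Plain TSV coordinate dump: one row per (frame, atom), angstrom units."""
    topo = traj.topology
    path = Path(path)
    with path.open("w") as fh:
        fh.write("frame\ttime_ps\tatom\tname\tresname\tresid\tgroup\tx\ty\tz\tbox_x\tbox_y\tbox_z\n")
        for f, fr in enumerate(traj.frames):
            bx, by, bz = fr.box
            for i in range(topo.n_atoms):
                x, y, z = fr.positions[i]
                fh.write(
                    f"{f}\t{fr.time:.6f}\t{i}\t{topo.atom_names[i]}\t{topo.residue_names[i]}\t"
                    f"{topo.residue_indices[i]}\t{topo.groups[i]}\t"
                    f"{x:.6f}\t{y:.6f}\t{z:.6f}\t{bx:.6f}\t{by:.6f}\t{bz:.6f}\n"
                )
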