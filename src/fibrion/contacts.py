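"""Ion-protein contact analysis.

Pipeline: per-ion minimum distances to the protein surface
(:func:`min_distances`), their histogram (:func:`distance_distribution`),
contact cutoffs from the minima between the histogram's peaks
(:func:`find_cutoffs`), per-ion residence fractions and the immobile/mobile
split (:func:`retention_fractions`), and per-residue contact occupancy
(:func:`residue_occupancy`).

Conventions encoded here: distances use heavy protein atoms only (hydrogens
excluded) and the ion selection's anchor rule (phosphorus for phosphate
anions); "in contact" means distance <= cutoff (closed interval); an ion is
immobile when its first-cutoff residence fraction is strictly greater than
0.5 — exactly half the frames is mobile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DegenerateDistributionError,
    EmptyDistributionError,
    EmptySelectionError,
    ParameterError,
)
from .trajectory import Selection, Trajectory, min_image_displacement

__all__ = [
    "DistanceSeries",
    "DistanceDistribution",
    "CutoffSet",
    "RetentionRecord",
    "ResidueOccupancy",
    "min_distances",
    "distance_distribution",
    "find_cutoffs",
    "retention_fractions",
    "residue_occupancy",
    "SPECIES_FIXED_CUTOFFS",
]

# Per-species fixed first cutoffs (angstrom) for when auto-minima detection is
# not wanted or not possible: Cl 3.5, Mg 3.0, phosphate 5.0.
SPECIES_FIXED_CUTOFFS = {"CL": 3.5, "MG": 3.0, "HPO4": 5.0, "H2PO4": 5.0}
DEFAULT_FALLBACK_CUTOFF = 5.0


@dataclass
class DistanceSeries:
    """Per-ion, per-frame minimum distance (angstrom) to the protein selection."""

    species: str
    ion_atom_indices: np.ndarray        # (n_ions,)
    distances: np.ndarray               # (n_ions, n_frames)
    times: np.ndarray                   # (n_frames,)

    @property
    def n_ions(self) -> int:
        return self.distances.shape[0]

    @property
    def n_frames(self) -> int:
        return self.distances.shape[1]


@dataclass
class DistanceDistribution:
    """Histogram of all (ion, frame) distances up to ``r_max``.

    ``density`` is normalized to unit integral over [0, r_max]; ``smoothed``
    is a moving-average copy used only for peak/minimum finding — the raw
    counts are preserved.
    """

    edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    smoothed: np.ndarray
    bin_width: float
    smooth_window: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class CutoffSet:
    """First (direct-contact) and optional second (shell-mediated) cutoff."""

    species: str
    cutoff1: float
    cutoff2: Optional[float] = None
    provenance: str = "auto_minima"     # or "fixed"

    def __post_init__(self) -> None:
        if self.cutoff1 <= 0:
            raise ParameterError("cutoff1 must be positive")
        if self.cutoff2 is not None and self.cutoff2 <= self.cutoff1:
            raise ParameterError("cutoff2 must exceed cutoff1")


@dataclass
class RetentionRecord:
    """Residence fractions of one ion within the cutoffs."""

    ion: int                    # row in the DistanceSeries
    atom_index: int             # topology atom index of the anchor
    f1: float                   # fraction of frames with d <= cutoff1
    f2: Optional[float]         # fraction within cutoff2 (None without one)
    immobile: bool              # strictly f1 > 0.5


@dataclass
class ResidueOccupancy:
    residue_index: int
    residue_name: str
    chain: str
    occupancy: float            # fraction of frames with any ion within cutoff1


def _frame_chunks(n_frames: int, per_pair_budget: int, n_pairs: int):
    chunk = max(1, int(per_pair_budget // max(n_pairs, 1)))
    for start in range(0, n_frames, chunk):
        yield start, min(start + chunk, n_frames)


def _pair_distances(ion_xyz: np.ndarray, prot_xyz: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Distances for a chunk of frames, shape (chunk, n_ions, n_prot)."""
    delta = ion_xyz[:, :, None, :] - prot_xyz[:, None, :, :]
    delta = min_image_displacement(delta, boxes[:, None, None, :])
    return np.sqrt(np.einsum("fipx,fipx->fip", delta, delta))


def min_distances(traj: Trajectory, ion_sel: Selection, protein_sel: Selection) -> DistanceSeries:
    """Per-frame minimum-image minimum distance from each ion anchor to the protein.

    The protein selection must be heavy-atoms-only; the ion selection's
    anchor rule is already baked into its indices.
    """
    if len(ion_sel) == 0 or len(protein_sel) == 0:
        raise EmptySelectionError("ion and protein selections must be non-empty")
    if protein_sel.anchor_rule != "heavy_atoms_only":
        raise ParameterError("protein selection must be heavy-atoms-only")
    if np.any(traj.topology.elements[protein_sel.atom_indices] == "H"):
        raise ParameterError("protein selection contains hydrogen atoms")

    coords = traj.coords()
    boxes = traj.boxes()
    ion_xyz = coords[:, ion_sel.atom_indices]
    prot_xyz = coords[:, protein_sel.atom_indices]
    n_frames = traj.n_frames
    out = np.empty((len(ion_sel), n_frames))
    n_pairs = len(ion_sel) * len(protein_sel)
    for a, b in _frame_chunks(n_frames, per_pair_budget=4_000_000, n_pairs=n_pairs):
        d = _pair_distances(ion_xyz[a:b], prot_xyz[a:b], boxes[a:b])
        out[:, a:b] = d.min(axis=2).T
    return DistanceSeries(
        species=ion_sel.species,
        ion_atom_indices=ion_sel.atom_indices.copy(),
        distances=out,
        times=traj.times,
    )


def distance_distribution(
    series: DistanceSeries,
    bin_width: float = 0.1,
    r_max: float = 10.0,
    smooth_window: int = 5,
) -> DistanceDistribution:
    """Histogram all (ion, frame) distances up to ``r_max``.

    Density is normalized to integrate to one over [0, r_max]; a centred
    moving average of ``smooth_window`` bins is attached for peak finding.
    """
    if bin_width <= 0 or r_max <= bin_width:
        raise ParameterError("need bin_width > 0 and r_max > bin_width")
    if smooth_window < 1:
        raise ParameterError("smooth_window must be >= 1")
    d = series.distances.ravel()
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(d[d <= edges[-1]], bins=edges)
    total = counts.sum()
    if total == 0:
        raise EmptyDistributionError(f"no distances below r_max={r_max} A")
    density = counts / (total * bin_width)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(density, kernel, mode="same")
    return DistanceDistribution(
        edges=edges, counts=counts, density=density, smoothed=smoothed,
        bin_width=bin_width, smooth_window=smooth_window,
    )


def _plateau_argmin(values: np.ndarray, lo: int, hi: int) -> int:
    """Index of the minimum of values[lo:hi]; the midpoint bin on a plateau."""
    seg = values[lo:hi]
    vmin = seg.min()
    flat = np.flatnonzero(np.isclose(seg, vmin, rtol=0.0, atol=1e-12 + 1e-9 * abs(vmin)))
    # use the central contiguous run containing the first minimum
    runs = np.split(flat, np.flatnonzero(np.diff(flat) > 1) + 1)
    first = runs[0]
    return lo + int(first[(len(first) - 1) // 2])


def find_cutoffs(
    dist: DistanceDistribution,
    expected_peaks: int = 2,
    fallback_cutoff: float = DEFAULT_FALLBACK_CUTOFF,
    species: str = "",
) -> CutoffSet:
    """Locate contact cutoffs at the minima between the distribution's peaks.

    With ``expected_peaks=2`` the two tallest local maxima of the smoothed
    density define cutoff1 (minimum between the peaks) and cutoff2 (minimum
    between the second peak and the density's return to near-baseline or the
    tail).  With ``expected_peaks=1``, or when only one peak is present, the
    single fixed fallback (default 5.0 angstrom) is returned with
    provenance "fixed".  Plateau minima resolve to their midpoint bin.
    """
    if expected_peaks not in (1, 2):
        raise ParameterError("expected_peaks must be 1 or 2")
    g = dist.smoothed
    centers = dist.centers
    # a usable peak must rise well above bin-count jitter and above the
    # typical density level (a flat histogram has no meaningful maximum)
    peaks, props = find_peaks(g, prominence=0.05 * g.max())
    peaks = peaks[g[peaks] >= 1.2 * np.median(g)]
    if expected_peaks == 1:
        return CutoffSet(species=species, cutoff1=fallback_cutoff, provenance="fixed")
    if peaks.size == 0:
        raise DegenerateDistributionError("no local maximum in the smoothed density")
    if peaks.size < 2:
        return CutoffSet(species=species, cutoff1=fallback_cutoff, provenance="fixed")

    top2 = peaks[np.argsort(g[peaks])[-2:]]
    p1, p2 = int(top2.min()), int(top2.max())
    c1_idx = _plateau_argmin(g, p1 + 1, p2 + 1)
    cutoff1 = float(centers[c1_idx])

    # second cutoff: minimum between the second peak and the return of the
    # density to near-baseline (5% of the second peak), or the tail
    baseline = 0.05 * g[p2]
    after = np.flatnonzero(g[p2 + 1:] <= baseline)
    hi = (p2 + 1 + int(after[0]) + 1) if after.size else len(g)
    if hi <= p2 + 1:
        hi = len(g)
    c2_idx = _plateau_argmin(g, p2 + 1, hi)
    cutoff2 = float(centers[c2_idx])
    if cutoff2 <= cutoff1:
        cutoff2 = None
    return CutoffSet(species=species, cutoff1=cutoff1, cutoff2=cutoff2,
                     provenance="auto_minima")


def retention_fractions(series: DistanceSeries, cutoffs: CutoffSet) -> list[RetentionRecord]:
    """Residence fractions per ion; immobile means strictly more than half the frames."""
    d = series.distances
    f1 = (d <= cutoffs.cutoff1).mean(axis=1)
    f2 = (d <= cutoffs.cutoff2).mean(axis=1) if cutoffs.cutoff2 is not None else None
    records = []
    for i in range(series.n_ions):
        records.append(
            RetentionRecord(
                ion=i,
                atom_index=int(series.ion_atom_indices[i]),
                f1=float(f1[i]),
                f2=None if f2 is None else float(f2[i]),
                immobile=bool(f1[i] > 0.5),
            )
        )
    return records


def residue_occupancy(
    traj: Trajectory,
    protein_sel: Selection,
    ion_sel: Selection,
    cutoffs: CutoffSet,
) -> list[ResidueOccupancy]:
    """Fraction of frames each protein residue has any ion within cutoff1.

    A residue is in contact in a frame when the minimum-image distance from
    any of its heavy atoms to any ion anchor is <= cutoff1.  Every residue in
    the protein selection is reported, including those never contacted.
    """
    topo = traj.topology
    prot_idx = protein_sel.atom_indices
    keys = [
        (str(topo.chain_ids[i]), int(topo.residue_indices[i]), str(topo.residue_names[i]))
        for i in prot_idx
    ]
    uniq = sorted(set(keys))
    key_to_row = {k: r for r, k in enumerate(uniq)}
    atom_res = np.array([key_to_row[k] for k in keys])

    coords = traj.coords()
    boxes = traj.boxes()
    ion_xyz = coords[:, ion_sel.atom_indices]
    prot_xyz = coords[:, prot_idx]
    n_frames = traj.n_frames
    hits = np.zeros(len(uniq), dtype=np.int64)
    n_pairs = len(ion_sel) * len(prot_idx)
    for a, b in _frame_chunks(n_frames, per_pair_budget=4_000_000, n_pairs=n_pairs):
        d = _pair_distances(ion_xyz[a:b], prot_xyz[a:b], boxes[a:b])
        atom_contact = (d.min(axis=1) <= cutoffs.cutoff1)      # (chunk, n_prot)
        for f in range(atom_contact.shape[0]):
            touched = np.unique(atom_res[atom_contact[f]])
            hits[touched] += 1
    return [
        ResidueOccupancy(residue_index=k[1], residue_name=k[2], chain=k[0],
                         occupancy=float(hits[r] / n_frames))
        for k, r in ((k, key_to_row[k]) for k in uniq)
    ]
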