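"""Radial distribution functions, coordination numbers, and hydration-class summaries.

g(r) is the ratio of the observed water-oxygen density in the spherical shell
[r, r+dr) around a set of center atoms to a reference bulk density, averaged
over frames; minimum-image distances are used throughout.  The coordination
number is computed two ways and they must agree: directly, as the cumulative
mean pair count within r, and by integrating the RDF
(CN(r) = 4 pi rho_ref * integral of g(r') r'^2 dr').  The direct count is the
headline value; the integral form exists as an internal consistency check.

The reference density defaults to the box-average water-oxygen density
(count / box volume, averaged over frames), which is what trajectory-analysis
tools conventionally use; pass ``rho_ref`` to override it when excluded
volume makes the box average unrepresentative of bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .contacts import CutoffSet, RetentionRecord
from .errors import BoxSizeError, EmptySelectionError, NoShellError, ParameterError
from .trajectory import Selection, Trajectory, min_image_displacement

__all__ = [
    "RDFResult",
    "ClassHydration",
    "HydrationSummary",
    "rdf",
    "cn_from_integral",
    "first_shell_minimum",
    "hydration_summary",
]


@dataclass
class RDFResult:
    r: np.ndarray               # bin centers, angstrom
    g: np.ndarray               # dimensionless
    cn: np.ndarray              # cumulative mean water count within bin edge
    rho_ref: float              # reference water-O density, per cubic angstrom
    dr: float
    n_centers: int
    n_frames: int
    counts: np.ndarray          # mean pair count per shell (per center, per frame)
    first_min: Optional[float] = None

    @property
    def edges(self) -> np.ndarray:
        return np.arange(0.0, (len(self.r) + 0.5) * self.dr, self.dr)

    def cn_at(self, radius: float) -> float:
        """Direct-count coordination number at ``radius`` (nearest bin edge)."""
        idx = min(int(np.floor(radius / self.dr)), len(self.cn) - 1)
        return float(self.cn[idx])


def rdf(
    traj: Trajectory,
    center_sel: Selection,
    water_O_sel: Selection,
    r_max: float = 8.0,
    dr: float = 0.05,
    rho_ref: Optional[float] = None,
) -> RDFResult:
    """Water-oxygen RDF and coordination number around the center selection."""
    if dr <= 0 or r_max <= dr:
        raise ParameterError("need dr > 0 and r_max > dr")
    if len(center_sel) == 0 or len(water_O_sel) == 0:
        raise EmptySelectionError("center and water selections must be non-empty")
    if np.intersect1d(center_sel.atom_indices, water_O_sel.atom_indices).size:
        raise ParameterError("center and water selections must be disjoint")
    half_min_edge = float(traj.boxes().min() / 2.0)
    if r_max > half_min_edge + 1e-9:
        raise BoxSizeError(
            f"r_max={r_max} A exceeds half the smallest box edge ({half_min_edge:.2f} A)"
        )

    coords = traj.coords()
    boxes = traj.boxes()
    centers_xyz = coords[:, center_sel.atom_indices]
    water_xyz = coords[:, water_O_sel.atom_indices]
    edges = np.arange(0.0, r_max + 0.5 * dr, dr)
    nbins = len(edges) - 1
    total = np.zeros(nbins, dtype=np.float64)
    vol_sum = 0.0
    n_frames = traj.n_frames
    for f in range(n_frames):
        delta = centers_xyz[f][:, None, :] - water_xyz[f][None, :, :]
        delta = min_image_displacement(delta, boxes[f])
        d = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta)).ravel()
        total += np.histogram(d[d < edges[-1]], bins=edges)[0]
        vol_sum += float(np.prod(boxes[f]))

    n_centers = len(center_sel)
    counts = total / (n_frames * n_centers)
    if rho_ref is None:
        rho_ref = len(water_O_sel) * n_frames / vol_sum
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(shell_vol > 0, counts / (rho_ref * shell_vol), 0.0)
    cn = np.cumsum(counts)
    r_centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=r_centers, g=g, cn=cn, rho_ref=float(rho_ref), dr=dr,
                     n_centers=n_centers, n_frames=n_frames, counts=counts)


def cn_from_integral(result: RDFResult) -> np.ndarray:
    """CN(r) by midpoint quadrature of 4 pi rho g(r') r'^2 dr'.

    Uses the bin-center approximation to the shell volume, so it differs from
    the direct count by quadrature error only; agreement within a couple of
    percent is an internal consistency requirement, not a tunable.
    """
    return np.cumsum(4.0 * np.pi * result.rho_ref * result.g * result.r**2 * result.dr)


def first_shell_minimum(
    result: RDFResult,
    smooth_window: int = 3,
    min_prominence: float = 1.0,
    descent_frac: float = 0.5,
) -> float:
    """r of the first local minimum of smoothed g(r) after the first shell peak.

    The first maximum must be prominent (``min_prominence`` in g units), which
    rejects ideal-gas noise; the accepted minimum must fall below
    ``descent_frac`` of the peak, which skips shoulder noise on the way down.
    A flat stretch (e.g. g reaching zero) counts as the minimum at its onset.
    """
    kernel = np.ones(smooth_window) / smooth_window
    gs = np.convolve(result.g, kernel, mode="same")
    peaks, _ = find_peaks(gs, prominence=min_prominence)
    if peaks.size == 0:
        raise NoShellError("g(r) has no prominent maximum (no first-shell structure)")
    m = int(peaks[0])
    peak_val = gs[m]
    candidate = None
    for j in range(m + 1, len(gs) - 1):
        if gs[j] <= gs[j - 1] and gs[j] <= gs[j + 1]:
            if gs[j] <= descent_frac * peak_val:
                return float(result.r[j])
            if candidate is None or gs[j] < gs[candidate]:
                candidate = j
        if gs[j] > peak_val:        # climbed past the first peak: next shell
            break
    if candidate is not None:
        return float(result.r[candidate])
    # monotone decay to the histogram edge: the last bin is the shell boundary
    if gs[-1] < descent_frac * peak_val:
        return float(result.r[-1])
    raise NoShellError("g(r) is monotone after its maximum; no first-shell minimum")


@dataclass
class ClassHydration:
    """Hydration state of one ion class (immobile / shell / bulk)."""

    name: str
    n_ions: int
    first_min: Optional[float]
    cn_first_min: Optional[float]
    cn_fixed: Optional[float]           # CN at the fixed comparison radius
    water_loss: Optional[float] = None  # CN_bulk - CN_class at each class's first min


@dataclass
class HydrationSummary:
    classes: dict[str, ClassHydration]
    rdfs: dict[str, RDFResult]
    fixed_radius: float


def _classify_ions(retention: list[RetentionRecord], has_cutoff2: bool) -> dict[str, list[int]]:
    """Atom indices per hydration class.

    immobile: f1 > 0.5; shell: resident mostly between the cutoffs
    (f2 > 0.5 but not immobile); bulk: never inside the outermost cutoff.
    """
    classes: dict[str, list[int]] = {"immobile": [], "shell": [], "bulk": []}
    for rec in retention:
        outer = rec.f2 if (has_cutoff2 and rec.f2 is not None) else rec.f1
        if rec.immobile:
            classes["immobile"].append(rec.atom_index)
        elif has_cutoff2 and rec.f2 is not None and rec.f2 > 0.5:
            classes["shell"].append(rec.atom_index)
        if outer == 0.0:
            classes["bulk"].append(rec.atom_index)
    return classes


def hydration_summary(
    traj: Trajectory,
    retention: list[RetentionRecord],
    cutoffs: CutoffSet,
    water_O_sel: Selection,
    r_max: float = 8.0,
    dr: float = 0.05,
    fixed_radius: float = 3.2,
    rho_ref: Optional[float] = None,
    species: str = "",
) -> HydrationSummary:
    """Compare hydration shells of immobile, shell-resident, and bulk ions.

    For each non-empty class the water-oxygen RDF is computed over that
    class's ions, the coordination number is read at the class's own
    first-shell minimum (and at ``fixed_radius`` for cross-species
    comparability), and the water loss relative to the bulk class is
    reported.  Classes with no ions are reported as absent, not as errors.
    """
    groups = _classify_ions(retention, has_cutoff2=cutoffs.cutoff2 is not None)
    classes: dict[str, ClassHydration] = {}
    rdfs: dict[str, RDFResult] = {}
    for name, atom_idx in groups.items():
        if not atom_idx:
            continue
        sel = Selection(name=f"class:{name}", species=species or "ion",
                        atom_indices=np.asarray(atom_idx), anchor_rule="all_atoms")
        res = rdf(traj, sel, water_O_sel, r_max=r_max, dr=dr, rho_ref=rho_ref)
        try:
            fm = first_shell_minimum(res)
            cn_fm = res.cn_at(fm)
        except NoShellError:
            fm, cn_fm = None, None
        res.first_min = fm
        rdfs[name] = res
        classes[name] = ClassHydration(
            name=name, n_ions=len(atom_idx), first_min=fm, cn_first_min=cn_fm,
            cn_fixed=res.cn_at(fixed_radius),
        )
    bulk = classes.get("bulk")
    if bulk is not None and bulk.cn_first_min is not None:
        for cls in classes.values():
            if cls.cn_first_min is not None:
                cls.water_loss = float(bulk.cn_first_min - cls.cn_first_min)
    return HydrationSummary(classes=classes, rdfs=rdfs, fixed_radius=fixed_radius)
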