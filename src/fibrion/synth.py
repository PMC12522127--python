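"""Synthetic trajectories with known ground truth.

Two generators cover the two analysis paths:

* :func:`generate_binding_trajectory` — a static protein-like scaffold with
  attractor sites, plus ions whose bound/free state evolves as a two-state
  Markov chain (per-frame probabilities ``p_on`` free->bound and ``p_off``
  bound->free).  The chain is started from its stationary distribution
  pi = p_on / (p_on + p_off), so the realized bound fraction is an unbiased
  estimate of pi without any burn-in.  Bound ions sit within ``d_bound`` of
  their site; free ions are placed i.i.d. uniformly in the box, at least
  ``2 * d_bound`` from every site (i.i.d. placement makes the analytic error
  bars of downstream estimators exact; there is no diffusive correlation).

* :func:`generate_hydration_trajectory` — static tagged ions, each dressed
  every frame with ``k`` water oxygens placed isotropically at
  ``shell_radius +- shell_jitter``, plus a uniform background of water
  oxygens at number density ``bulk_density`` thinned by an exclusion sphere
  around each ion.  The per-trajectory background count is a Poisson draw
  thinned by the excluded volume, so its mean across seeds is
  ``rho * (V_box - V_excluded)``.

Randomness comes from a single seed feeding named substreams (scaffold,
ions, waters), so e.g. adding background waters never perturbs ion paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import GeometryError, ParameterError
from .trajectory import Frame, SystemTopology, Trajectory

__all__ = [
    "BindingKinetics",
    "HydrationSpec",
    "GroundTruth",
    "generate_binding_trajectory",
    "generate_hydration_trajectory",
    "hydration_preset",
    "dress_with_waters",
]

# substream labels -> child-seed offsets (fixed so streams are independent of
# which other streams are consumed)
_STREAMS = {"scaffold": 0, "ions": 1, "waters": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class BindingKinetics:
    """Two-state (bound/free) Markov kinetics for surface-binding ions."""

    p_on: float = 0.3
    p_off: float = 0.1
    d_bound: float = 2.5        # angstrom jitter radius around the site
    n_sites: int = 8
    n_ions: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_on <= 1.0 and 0.0 <= self.p_off <= 1.0):
            raise ParameterError("p_on and p_off must lie in [0, 1]")
        if self.d_bound <= 0:
            raise ParameterError("d_bound must be positive")
        if self.n_sites < 1 or self.n_ions < 1:
            raise ParameterError("need at least one site and one ion")

    @property
    def stationary_bound_fraction(self) -> float:
        s = self.p_on + self.p_off
        return self.p_on / s if s > 0 else 0.0


@dataclass
class HydrationSpec:
    """First-shell occupancy plus uniform bulk background around tagged ions.

    ``shell_occupancy`` may be a single integer (same shell for every ion) or
    one integer per ion.
    """

    shell_occupancy: Union[int, Sequence[int]] = 6
    shell_radius: float = 2.4       # angstrom
    shell_jitter: float = 0.15      # angstrom, uniform in +- jitter
    bulk_density: float = 0.0       # water oxygens per cubic angstrom
    exclusion_radius: float = 2.0   # no background water inside this sphere
    n_frames: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        ks = np.atleast_1d(np.asarray(self.shell_occupancy, dtype=np.int64))
        if np.any(ks < 0):
            raise ParameterError("shell_occupancy must be non-negative")
        if self.bulk_density < 0:
            raise ParameterError("bulk_density must be non-negative")
        if self.shell_jitter < 0:
            raise ParameterError("shell_jitter must be non-negative")
        if self.shell_radius <= 0:
            raise ParameterError("shell_radius must be positive")
        if self.shell_radius - self.shell_jitter <= 0:
            raise ParameterError("shell_radius - shell_jitter must stay positive")


def hydration_preset(name: str, n_frames: int = 50, seed: int = 0) -> HydrationSpec:
    """Named hydration fixtures.

    ``bulk_monovalent_cation`` emulates the intact first hydration shell of a
    small monovalent cation in bulk water: six shell waters at 2.4 angstrom
    with a 2.0 angstrom core exclusion.  The preset ships without a uniform
    background (bulk_density 0) so the coordination number at the first-shell
    minimum equals the shell occupancy by construction; callers wanting a
    second-shell background can set ``bulk_density`` afterwards.
    """
    if name == "bulk_monovalent_cation":
        return HydrationSpec(
            shell_occupancy=6,
            shell_radius=2.4,
            shell_jitter=0.15,
            bulk_density=0.0,
            exclusion_radius=2.0,
            n_frames=n_frames,
            seed=seed,
        )
    raise ParameterError(f"unknown hydration preset {name!r}")


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style comparisons."""

    bound_states: Optional[np.ndarray] = None        # (n_ions, n_frames) bool
    expected_retention: Optional[np.ndarray] = None  # per-ion stationary pi
    shell_occupancy: Optional[np.ndarray] = None     # per-ion k
    site_residues: Optional[np.ndarray] = None       # per-ion residue index of its site

    @property
    def realized_retention(self) -> np.ndarray:
        if self.bound_states is None:
            raise ValueError("no bound-state record in this ground truth")
        return self.bound_states.mean(axis=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.bound_states is not None:
                fh.write("ion\texpected_retention\trealized_retention\tsite_residue\n")
                for i in range(self.bound_states.shape[0]):
                    site = -1 if self.site_residues is None else int(self.site_residues[i])
                    fh.write(
                        f"{i}\t{self.expected_retention[i]:.6f}\t"
                        f"{self.realized_retention[i]:.6f}\t{site}\n"
                    )
            elif self.shell_occupancy is not None:
                fh.write("ion\tshell_occupancy\n")
                for i, k in enumerate(self.shell_occupancy):
                    fh.write(f"{i}\t{int(k)}\n")


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

# one residue = three heavy atoms; CA is the attractor site
_RESIDUE_TEMPLATE = (
    ("CA", "C", np.array([0.0, 0.0, 0.0])),
    ("CB", "C", np.array([1.5, 0.0, 0.0])),
    ("O", "O", np.array([0.0, 1.2, 0.0])),
)


def _build_scaffold(n_sites: int, box: np.ndarray, d_bound: float):
    """Place ``n_sites`` pseudo-residues on a circle in the box midplane.

    Returns (positions (n_atoms,3), names, elements, resids, site coordinates,
    site residue indices).  Raises GeometryError when sites would be closer
    than twice the binding jitter radius.
    """
    center = box / 2.0
    radius = min(box) / 4.0
    theta = 2 * np.pi * np.arange(n_sites) / n_sites
    sites = center + radius * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1
    )
    if n_sites > 1:
        sep = np.linalg.norm(sites[0] - sites[1])
        if sep <= 2 * d_bound:
            raise GeometryError(
                f"binding sites too dense: spacing {sep:.2f} A <= 2*d_bound "
                f"{2 * d_bound:.2f} A"
            )
    # free ions must fit outside 2*d_bound of every site
    excluded = n_sites * (4.0 / 3.0) * np.pi * (2 * d_bound) ** 3
    if excluded >= 0.5 * float(np.prod(box)):
        raise GeometryError("site exclusion zones fill most of the box")

    positions, names, elements, resids = [], [], [], []
    for r, site in enumerate(sites, start=1):
        for name, elem, offset in _RESIDUE_TEMPLATE:
            positions.append(site + offset)
            names.append(name)
            elements.append(elem)
            resids.append(r)
    return np.asarray(positions), names, elements, resids, sites, np.arange(1, n_sites + 1)


def _sample_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _sample_free(rng: np.random.Generator, n: int, box: np.ndarray,
                 sites: np.ndarray, min_dist: float) -> np.ndarray:
    """Uniform points in the box at least ``min_dist`` from every site."""
    out = np.empty((n, 3))
    need = np.arange(n)
    for _ in range(1000):
        if need.size == 0:
            return out
        cand = rng.random((need.size, 3)) * box
        d2 = ((cand[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
        ok = np.all(d2 > min_dist**2, axis=1)
        out[need[ok]] = cand[ok]
        need = need[~ok]
    raise GeometryError("could not place free ions outside site exclusion zones")


def generate_binding_trajectory(
    kin: BindingKinetics,
    n_frames: int = 1000,
    box=(60.0, 60.0, 60.0),
    species: str = "NA",
    dt: float = 1.0,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate two-state binding ions around a static scaffold.

    Each ion is assigned one attractor site (round-robin over sites) and an
    independent Markov chain initialized at stationarity.  Returns the
    trajectory plus a :class:`GroundTruth` with the realized state sequences.
    """
    box = np.asarray(box, dtype=np.float64)
    if np.any(box <= 0):
        raise ParameterError("box edges must be positive")
    scaffold_pos, names, elements, resids, sites, site_res = _build_scaffold(
        kin.n_sites, box, kin.d_bound
    )
    rng = _rng(kin.seed, "ions")

    pi = kin.stationary_bound_fraction
    states = np.empty((kin.n_ions, n_frames), dtype=bool)
    states[:, 0] = rng.random(kin.n_ions) < pi
    for t in range(1, n_frames):
        u = rng.random(kin.n_ions)
        states[:, t] = np.where(states[:, t - 1], u >= kin.p_off, u < kin.p_on)

    ion_site = np.arange(kin.n_ions) % kin.n_sites
    ion_pos = np.empty((n_frames, kin.n_ions, 3))
    for t in range(n_frames):
        bound = states[:, t]
        nb = int(bound.sum())
        if nb:
            ion_pos[t, bound] = sites[ion_site[bound]] + _sample_in_ball(rng, nb, kin.d_bound)
        nf = kin.n_ions - nb
        if nf:
            ion_pos[t, ~bound] = _sample_free(rng, nf, box, sites, 2 * kin.d_bound)

    n_scaffold = scaffold_pos.shape[0]
    atom_names = np.array(names + [species] * kin.n_ions, dtype=object)
    elems = np.array(elements + [species] * kin.n_ions, dtype=object)
    residue_idx = np.array(resids + list(range(kin.n_sites + 1, kin.n_sites + 1 + kin.n_ions)))
    resnames = np.array(["ALA"] * n_scaffold + [species] * kin.n_ions, dtype=object)
    chains = np.array(["A"] * n_scaffold + ["B"] * kin.n_ions, dtype=object)
    groups = np.array(["protein"] * n_scaffold + [f"ion:{species}"] * kin.n_ions, dtype=object)
    topo = SystemTopology(atom_names, elems, residue_idx, resnames, chains, groups)

    frames = [
        Frame(time=t * dt, positions=np.vstack([scaffold_pos, ion_pos[t]]), box=box)
        for t in range(n_frames)
    ]
    truth = GroundTruth(
        bound_states=states,
        expected_retention=np.full(kin.n_ions, pi),
        site_residues=site_res[ion_site],
    )
    return Trajectory(topology=topo, frames=frames), truth


# ---------------------------------------------------------------------------
# hydration fixture
# ---------------------------------------------------------------------------

def _ion_grid(n_ions: int, box: np.ndarray, min_spacing: float) -> np.ndarray:
    """Even grid of ion positions; PBC-aware spacing check."""
    m = int(np.ceil(n_ions ** (1.0 / 3.0)))
    spacing = box / m
    if np.any(spacing <= min_spacing):
        raise GeometryError(
            f"ion grid spacing {spacing.min():.2f} A too small for shells "
            f"(need > {min_spacing:.2f} A)"
        )
    pts = []
    for i in range(m):
        for j in range(m):
            for k in range(m):
                pts.append(((np.array([i, j, k]) + 0.5) * spacing))
                if len(pts) == n_ions:
                    return np.asarray(pts)
    return np.asarray(pts)


def generate_hydration_trajectory(
    spec: HydrationSpec,
    box=(30.0, 30.0, 30.0),
    n_ions: int = 1,
    species: str = "NA",
    dt: float = 1.0,
) -> tuple[Trajectory, GroundTruth]:
    """Static ions dressed with first-shell waters plus uniform background.

    Shell oxygens are re-drawn isotropically every frame at
    ``shell_radius +- shell_jitter`` around each ion.  The background count is
    a single Poisson(rho * V) draw thinned by the exclusion spheres, then the
    surviving oxygens are re-placed uniformly (outside the exclusions) every
    frame.
    """
    box = np.asarray(box, dtype=np.float64)
    if np.any(box <= 0):
        raise ParameterError("box edges must be positive")
    ks = np.atleast_1d(np.asarray(spec.shell_occupancy, dtype=np.int64))
    if ks.size == 1:
        ks = np.full(n_ions, int(ks[0]))
    if ks.size != n_ions:
        raise ParameterError("shell_occupancy must be scalar or one value per ion")

    r_outer = spec.shell_radius + spec.shell_jitter
    ions = _ion_grid(n_ions, box, min_spacing=2 * r_outer)

    rng_w = _rng(spec.seed, "waters")
    volume = float(np.prod(box))

    # background population: Poisson draw thinned by excluded volume
    n_raw = rng_w.poisson(spec.bulk_density * volume) if spec.bulk_density > 0 else 0
    n_bg = 0
    if n_raw:
        cand = rng_w.random((n_raw, 3)) * box
        d2 = ((cand[:, None, :] - ions[None, :, :]) ** 2).sum(axis=2)
        n_bg = int(np.all(d2 > spec.exclusion_radius**2, axis=1).sum())

    n_shell = int(ks.sum())
    n_waters = n_shell + n_bg
    n_atoms = n_ions + n_waters

    frames = []
    for t in range(spec.n_frames):
        pos = np.empty((n_atoms, 3))
        pos[:n_ions] = ions
        cursor = n_ions
        for i in range(n_ions):
            k = int(ks[i])
            if k:
                v = rng_w.normal(size=(k, 3))
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                radii = spec.shell_radius + spec.shell_jitter * (2 * rng_w.random(k) - 1)
                pos[cursor:cursor + k] = ions[i] + v * radii[:, None]
                cursor += k
        if n_bg:
            placed = 0
            while placed < n_bg:
                cand = rng_w.random((n_bg - placed, 3)) * box
                d2 = ((cand[:, None, :] - ions[None, :, :]) ** 2).sum(axis=2)
                keep = cand[np.all(d2 > spec.exclusion_radius**2, axis=1)]
                pos[cursor + placed:cursor + placed + len(keep)] = keep
                placed += len(keep)
        frames.append(Frame(time=t * dt, positions=pos, box=box))

    atom_names = np.array([species] * n_ions + ["OW"] * n_waters, dtype=object)
    elems = np.array([species] * n_ions + ["O"] * n_waters, dtype=object)
    residue_idx = np.array(list(range(1, n_ions + 1)) + list(range(n_ions + 1, n_ions + 1 + n_waters)))
    resnames = np.array([species] * n_ions + ["SOL"] * n_waters, dtype=object)
    chains = np.array(["I"] * n_ions + ["W"] * n_waters, dtype=object)
    groups = np.array([f"ion:{species}"] * n_ions + ["water"] * n_waters, dtype=object)
    topo = SystemTopology(atom_names, elems, residue_idx, resnames, chains, groups)

    truth = GroundTruth(shell_occupancy=ks)
    return Trajectory(topology=topo, frames=frames), truth


def dress_with_waters(
    traj: Trajectory,
    species: str,
    shell_occupancy: Union[int, Sequence[int]] = 3,
    shell_radius: float = 2.4,
    shell_jitter: float = 0.15,
    seed: int = 0,
) -> Trajectory:
    """Return a copy of ``traj`` with first-shell water oxygens following each ion.

    Each ion of ``species`` gets ``shell_occupancy`` oxygens re-drawn every
    frame at ``shell_radius +- shell_jitter`` around its current position, so
    binding trajectories gain a hydration signal without regenerating them.
    Water draws come from the waters substream: the ion coordinates are
    untouched, bit for bit.
    """
    topo = traj.topology
    ion_idx = np.flatnonzero(topo.groups == f"ion:{species}")
    if ion_idx.size == 0:
        raise ParameterError(f"no ions of species {species!r} in trajectory")
    ks = np.atleast_1d(np.asarray(shell_occupancy, dtype=np.int64))
    if ks.size == 1:
        ks = np.full(ion_idx.size, int(ks[0]))
    if ks.size != ion_idx.size:
        raise ParameterError("shell_occupancy must be scalar or one value per ion")
    n_shell = int(ks.sum())
    rng = _rng(seed, "waters")

    frames = []
    for fr in traj.frames:
        extra = np.empty((n_shell, 3))
        cursor = 0
        for i, k in zip(ion_idx, ks):
            k = int(k)
            if k:
                v = rng.normal(size=(k, 3))
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                radii = shell_radius + shell_jitter * (2 * rng.random(k) - 1)
                extra[cursor:cursor + k] = fr.positions[i] + v * radii[:, None]
                cursor += k
        frames.append(Frame(time=fr.time, positions=np.vstack([fr.positions, extra]), box=fr.box))

    base = topo.n_atoms
    last_res = int(topo.residue_indices.max())
    new_topo = SystemTopology(
        atom_names=np.concatenate([topo.atom_names, np.array(["OW"] * n_shell, dtype=object)]),
        elements=np.concatenate([topo.elements, np.array(["O"] * n_shell, dtype=object)]),
        residue_indices=np.concatenate(
            [topo.residue_indices, np.arange(last_res + 1, last_res + 1 + n_shell)]
        ),
        residue_names=np.concatenate([topo.residue_names, np.array(["SOL"] * n_shell, dtype=object)]),
        chain_ids=np.concatenate([topo.chain_ids, np.array(["W"] * n_shell, dtype=object)]),
        groups=np.concatenate([topo.groups, np.array(["water"] * n_shell, dtype=object)]),
    )
    return Trajectory(topology=new_topo, frames=frames)
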