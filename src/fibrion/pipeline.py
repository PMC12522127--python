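"""Pipeline orchestration: config validation, staged analysis, report bundle.

``run_full_analysis`` chains the three trajectory analyses in order —
contacts/distance distributions, retention and per-residue occupancy, then
hydration by ion class — writing every result as a header-bearing TSV, a
small plot set, and a JSON manifest recording the config, seeds, and package
versions, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .contacts import (
    SPECIES_FIXED_CUTOFFS,
    CutoffSet,
    distance_distribution,
    find_cutoffs,
    min_distances,
    residue_occupancy,
    retention_fractions,
)
from .errors import ConfigError, EmptySelectionError, FibrionError
from .hydration import hydration_summary
from .trajectory import ION_RESNAMES, Trajectory, load_system, select_group

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("fibrion")

KNOWN_SPECIES = sorted(set(ION_RESNAMES.values()))


@dataclass
class RunConfig:
    """Validated configuration for a full analysis run."""

    structure: str
    trajectory: Optional[str] = None
    species: list[str] = field(default_factory=lambda: ["NA"])
    cutoff_mode: str = "auto"               # auto | fixed
    fixed_cutoff1: Optional[float] = None
    fixed_cutoff2: Optional[float] = None
    expected_peaks: int = 2
    fallback_cutoff: float = 5.0
    bin_width: float = 0.1
    r_max_hist: float = 10.0
    smooth_window: int = 5
    rdf_dr: float = 0.05
    rdf_r_max: float = 8.0
    seed: int = 0
    outdir: str = "fibrion_out"

    def __post_init__(self) -> None:
        if self.cutoff_mode not in ("auto", "fixed"):
            raise ConfigError(f"cutoff_mode must be auto|fixed, got {self.cutoff_mode!r}")
        bad = [s for s in self.species if s.upper() not in KNOWN_SPECIES]
        if bad:
            raise ConfigError(
                f"unknown ion species {bad}; known: {', '.join(KNOWN_SPECIES)}"
            )
        self.species = [s.upper() for s in self.species]
        if self.expected_peaks not in (1, 2):
            raise ConfigError("expected_peaks must be 1 or 2")
        for name in ("bin_width", "rdf_dr", "rdf_r_max", "fallback_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.r_max_hist <= self.bin_width:
            raise ConfigError("r_max_hist must exceed bin_width")
        if self.cutoff_mode == "fixed" and self.fixed_cutoff1 is None:
            # species-specific defaults may still apply at run time
            pass

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _cutoffs_for(cfg: RunConfig, species: str, dist) -> CutoffSet:
    if cfg.cutoff_mode == "fixed":
        c1 = cfg.fixed_cutoff1 or SPECIES_FIXED_CUTOFFS.get(species, cfg.fallback_cutoff)
        return CutoffSet(species=species, cutoff1=c1, cutoff2=cfg.fixed_cutoff2,
                         provenance="fixed")
    return find_cutoffs(dist, expected_peaks=cfg.expected_peaks,
                        fallback_cutoff=cfg.fallback_cutoff, species=species)


def _plots(outdir: Path, species: str, dist, cutoffs, records, rdfs) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(dist.centers, dist.density, label="density")
    ax.plot(dist.centers, dist.smoothed, label="smoothed", alpha=0.7)
    ax.axvline(cutoffs.cutoff1, color="k", ls="--", label=f"cutoff1 {cutoffs.cutoff1:.2f}")
    if cutoffs.cutoff2:
        ax.axvline(cutoffs.cutoff2, color="gray", ls=":", label=f"cutoff2 {cutoffs.cutoff2:.2f}")
    ax.set_xlabel("distance ($\\mathrm{\\AA}$)")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(outdir / f"distance_distribution_{species}.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.bar([r.ion for r in records], [r.f1 for r in records])
    ax.axhline(0.5, color="k", ls="--")
    ax.set_xlabel("ion")
    ax.set_ylabel("residence fraction within cutoff1")
    fig.savefig(outdir / f"retention_{species}.png", dpi=100)
    plt.close(fig)

    if rdfs:
        fig, ax = plt.subplots()
        for name, res in rdfs.items():
            ax.plot(res.r, res.g, label=f"g(r) {name}")
            ax.plot(res.r, res.cn, ls="--", label=f"CN {name}")
        ax.set_xlabel("r ($\\mathrm{\\AA}$)")
        ax.legend()
        fig.savefig(outdir / f"rdf_{species}.png", dpi=100)
        plt.close(fig)


def run_full_analysis(config: RunConfig, traj: Optional[Trajectory] = None) -> dict:
    """Execute contacts -> retention -> occupancy -> hydration and write the bundle.

    ``traj`` may be passed directly (e.g. a freshly generated synthetic
    trajectory) to skip file loading.  Returns the manifest dict; any stage
    failure aborts with the stage name while earlier outputs stay on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(handler)

    manifest = {
        "config": asdict(config),
        "versions": {"fibrion": __version__, "numpy": np.__version__},
        "stages_completed": [],
    }
    stage = "load"
    try:
        if traj is None:
            traj = load_system(config.structure, config.trajectory)
        protein = select_group(traj, "protein_heavy")
        try:
            water = select_group(traj, "water_O")
        except EmptySelectionError:
            water = None

        for species in config.species:
            ions = select_group(traj, f"ion:{species}")

            stage = f"contacts:{species}"
            series = min_distances(traj, ions, protein)
            dist = distance_distribution(series, bin_width=config.bin_width,
                                         r_max=config.r_max_hist,
                                         smooth_window=config.smooth_window)
            cutoffs = _cutoffs_for(config, species, dist)
            _write_tsv(
                outdir / f"distances_{species}.tsv",
                ["ion", "atom_index"] + [f"t{t:g}" for t in series.times],
                ([i, series.ion_atom_indices[i]] + [f"{v:.4f}" for v in series.distances[i]]
                 for i in range(series.n_ions)),
            )
            _write_tsv(
                outdir / f"distribution_{species}.tsv",
                ["r_center_A", "count", "density", "smoothed"],
                ((f"{c:.4f}", int(n), f"{d:.8f}", f"{s:.8f}")
                 for c, n, d, s in zip(dist.centers, dist.counts, dist.density, dist.smoothed)),
            )
            manifest["stages_completed"].append(stage)
            manifest.setdefault("cutoffs", {})[species] = {
                "cutoff1": cutoffs.cutoff1, "cutoff2": cutoffs.cutoff2,
                "provenance": cutoffs.provenance,
            }

            stage = f"retention:{species}"
            records = retention_fractions(series, cutoffs)
            _write_tsv(
                outdir / f"retention_{species}.tsv",
                ["ion", "atom_index", "f1", "f2", "immobile"],
                ((r.ion, r.atom_index, f"{r.f1:.6f}",
                  "" if r.f2 is None else f"{r.f2:.6f}", int(r.immobile)) for r in records),
            )
            occ = residue_occupancy(traj, protein, ions, cutoffs)
            _write_tsv(
                outdir / f"occupancy_{species}.tsv",
                ["chain", "resid", "resname", "occupancy"],
                ((o.chain, o.residue_index, o.residue_name, f"{o.occupancy:.6f}") for o in occ),
            )
            manifest["stages_completed"].append(stage)

            stage = f"hydration:{species}"
            rdfs = {}
            if water is not None:
                summary = hydration_summary(
                    traj, records, cutoffs, water,
                    r_max=config.rdf_r_max, dr=config.rdf_dr, species=species,
                )
                rdfs = summary.rdfs
                for name, res in summary.rdfs.items():
                    _write_tsv(
                        outdir / f"rdf_{species}_{name}.tsv",
                        ["r_A", "g", "CN"],
                        ((f"{r:.4f}", f"{gv:.6f}", f"{cv:.6f}")
                         for r, gv, cv in zip(res.r, res.g, res.cn)),
                    )
                _write_tsv(
                    outdir / f"hydration_summary_{species}.tsv",
                    ["class", "n_ions", "first_min_A", "CN_first_min", "CN_fixed", "water_loss"],
                    ((c.name, c.n_ions,
                      "" if c.first_min is None else f"{c.first_min:.3f}",
                      "" if c.cn_first_min is None else f"{c.cn_first_min:.4f}",
                      "" if c.cn_fixed is None else f"{c.cn_fixed:.4f}",
                      "" if c.water_loss is None else f"{c.water_loss:.4f}")
                     for c in summary.classes.values()),
                )
                manifest["stages_completed"].append(stage)
            _plots(outdir, species, dist, cutoffs, records, rdfs)

    except FibrionError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
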