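"""Evaporative saturation mass balance for drying droplets.

A sessile droplet loses water at the rate recorded by a gravimetric
mass-vs-time curve while its solutes are conserved, so each solute's
concentration rises inversely with the remaining water mass:
c(t) = c0 * m_w(0) / m_w(t).  A solute reaches its solubility limit when
c(t) = c_sat, i.e. after the fraction 1 - c0/c_sat of the water has
evaporated — a number that depends only on the concentration ratio, not on
the shape of the drying curve.  The curve fixes *when* that happens.

The solution is treated as dilute (density of water, 1 g/mL); the solute and
buffer contribution to the droplet mass is handled through the explicit
``dry_mass`` parameter.  Concentrations may be molar (mM) or mass-based
(mg/mL) as long as c0 and c_sat of a solute share units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ParameterError

__all__ = [
    "Solute",
    "DropletComposition",
    "MassLossCurve",
    "SaturationTimeline",
    "evaporated_fraction_at_saturation",
    "saturation_times",
    "phosphate_speciation",
    "reference_solubilities",
]

DEFAULT_EQUILIBRATION_H = 0.5   # initial humidity-equilibration window


@dataclass
class Solute:
    name: str
    c0: float       # starting concentration
    c_sat: float    # solubility limit, same units as c0
    unit: str = "mM"

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.c_sat <= 0:
            raise ParameterError(f"{self.name}: concentrations must be positive")

    @property
    def already_saturated(self) -> bool:
        return self.c0 > self.c_sat


@dataclass
class DropletComposition:
    solutes: list[Solute]
    water_mass_g: float

    @classmethod
    def from_volume(cls, solutes: list[Solute], volume_mL: float) -> "DropletComposition":
        # dilute solution: density 1 g/mL
        return cls(solutes=solutes, water_mass_g=volume_mL * 1.0)

    @classmethod
    def from_yaml(cls, path) -> "DropletComposition":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        solutes = [
            Solute(name=s["name"], c0=float(s["c0"]), c_sat=float(s["c_sat"]),
                   unit=s.get("unit", "mM"))
            for s in cfg["solutes"]
        ]
        if "water_mass_g" in cfg:
            return cls(solutes=solutes, water_mass_g=float(cfg["water_mass_g"]))
        return cls.from_volume(solutes, float(cfg["volume_mL"]))


@dataclass
class MassLossCurve:
    times: np.ndarray   # hours
    masses: np.ndarray  # grams

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if self.times.ndim != 1 or self.times.shape != self.masses.shape:
            raise DataError("times and masses must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise DataError("mass curve needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise DataError("times must be strictly increasing")
        if np.any(self.masses <= 0):
            raise DataError("masses must be positive")

    @classmethod
    def from_csv(cls, path) -> "MassLossCurve":
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        try:
            t = df[cols["time_h"]].to_numpy()
            m = df[cols["mass_g"]].to_numpy()
        except KeyError as exc:
            raise DataError(f"mass curve CSV needs columns time_h, mass_g: {exc}") from exc
        return cls(times=t, masses=m)

    def monotone_envelope(self, equilibration_h: float = DEFAULT_EQUILIBRATION_H) -> np.ndarray:
        """Masses forced non-increasing after the equilibration window.

        Small humidity-driven upticks early on are expected; later increases
        are a data-quality problem and are flattened (with a warning) by a
        running-minimum envelope.
        """
        out = self.masses.copy()
        after = self.times > equilibration_h
        if after.any():
            seg = out[after]
            env = np.minimum.accumulate(seg)
            if np.any(seg > env + 1e-12):
                warnings.warn(
                    "mass curve increases after the equilibration window; "
                    "using its monotone envelope", stacklevel=2,
                )
            out[after] = env
        return out


def evaporated_fraction_at_saturation(c0: float, c_sat: float) -> float:
    """Fraction of the water that must evaporate before c0 reaches c_sat.

    Solute amount is conserved and concentration scales inversely with the
    remaining water, so the fraction is 1 - c0/c_sat regardless of the drying
    curve.  A solution already at or above saturation returns 0.
    """
    if c0 <= 0 or c_sat <= 0:
        raise ParameterError("concentrations must be positive")
    if c0 > c_sat:
        return 0.0
    return 1.0 - c0 / c_sat


@dataclass
class SaturationTimeline:
    """Per-solute saturation onset and the concentration traces behind it."""

    entries: pd.DataFrame       # solute, unit, c0, c_sat, f_evap_at_sat, t_sat_h, already_saturated
    trace: pd.DataFrame         # time_h, water_mass_g, + one concentration column per solute

    def t_sat(self, solute: str) -> Optional[float]:
        row = self.entries.loc[self.entries["solute"] == solute]
        if row.empty:
            raise KeyError(solute)
        v = row["t_sat_h"].iloc[0]
        return None if pd.isna(v) else float(v)


def saturation_times(
    curve: MassLossCurve,
    comp: DropletComposition,
    dry_mass_g: float,
    equilibration_h: float = DEFAULT_EQUILIBRATION_H,
) -> SaturationTimeline:
    """When each solute reaches its solubility limit along a drying curve.

    Water mass is m(t) - dry_mass; concentrations scale as
    c(t) = c0 * m_w(0)/m_w(t).  The saturation time is the first crossing of
    c_sat, linearly interpolated on the water mass between samples; a solute
    whose limit is never reached gets no saturation time.
    """
    masses = curve.monotone_envelope(equilibration_h)
    if dry_mass_g >= masses.min():
        raise DataError(
            f"dry_mass {dry_mass_g} g must lie below the smallest recorded mass "
            f"({masses.min()} g)"
        )
    m_w = masses - dry_mass_g
    m_w0 = m_w[0]
    trace = {"time_h": curve.times, "water_mass_g": m_w}

    rows = []
    for s in comp.solutes:
        conc = s.c0 * m_w0 / m_w
        trace[f"c_{s.name}"] = conc
        f_evap = evaporated_fraction_at_saturation(s.c0, s.c_sat)
        if s.already_saturated:
            t_sat = float(curve.times[0])
        else:
            m_target = m_w0 * s.c0 / s.c_sat       # water mass at saturation
            below = np.flatnonzero(m_w <= m_target)
            if below.size == 0:
                t_sat = np.nan
            else:
                j = int(below[0])
                if j == 0 or m_w[j] == m_target:
                    t_sat = float(curve.times[j])
                else:
                    frac = (m_w[j - 1] - m_target) / (m_w[j - 1] - m_w[j])
                    t_sat = float(curve.times[j - 1] + frac * (curve.times[j] - curve.times[j - 1]))
        rows.append(
            dict(solute=s.name, unit=s.unit, c0=s.c0, c_sat=s.c_sat,
                 f_evap_at_sat=f_evap, t_sat_h=t_sat,
                 already_saturated=s.already_saturated)
        )
    return SaturationTimeline(entries=pd.DataFrame(rows), trace=pd.DataFrame(trace))


def phosphate_speciation(total_mM: float, pH: float, pKa2: float = 7.21) -> tuple[float, float]:
    """Split total phosphate into (H2PO4-, HPO4 2-) by Henderson-Hasselbalch.

    [HPO4]/[H2PO4] = 10**(pH - pKa2); the two components sum to the total.
    """
    if not (0.0 < pH < 14.0):
        raise ParameterError("pH must lie in (0, 14)")
    if total_mM < 0:
        raise ParameterError("total phosphate must be non-negative")
    ratio = 10.0 ** (pH - pKa2)
    c_h2po4 = total_mM / (1.0 + ratio)
    return c_h2po4, total_mM - c_h2po4


def reference_solubilities() -> dict:
    """Room-temperature literature solubilities shipped as editable defaults."""
    path = Path(__file__).parent / "data" / "solubilities.yaml"
    with path.open() as fh:
        return yaml.safe_load(fh)
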