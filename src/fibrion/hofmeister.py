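"""Two-dimensional Hofmeister classification of salt-driven fibrinogen morphology.

A one-dimensional Hofmeister ranking (anions alone or cations alone) does not
explain which salts drive dried fibrinogen into nanofibers; the pair does.
This module encodes that empirical scheme as a deterministic lookup: each
cation and anion carries a kosmotropic / intermediate / chaotropic class, a
grid rule maps the pair of classes to a predicted precipitate morphology
(dense fiber networks for kosmotrope-kosmotrope pairs down to smooth films
for chaotrope-chaotrope pairs), and pair-specific overrides record the
observed exceptions, taking precedence over the grid.  The table ships as an
editable YAML; this is an encoding of observations, not a thermodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import yaml

from .errors import UnknownIonError

__all__ = ["IonPairClass", "classify_pair", "supported_ions", "MORPHOLOGIES"]

MORPHOLOGIES = ("dense_fibers", "coarse_or_local_fibers", "rough_nonfibrous", "smooth")
_SCORE = {"kosmotropic": 2, "intermediate": 1, "chaotropic": 0}


@dataclass(frozen=True)
class IonPairClass:
    cation: str
    anion: str
    cation_class: str
    anion_class: str
    predicted_morphology: str
    from_override: bool = False


@lru_cache(maxsize=1)
def _table() -> dict:
    path = Path(__file__).parent / "data" / "hofmeister.yaml"
    with path.open() as fh:
        return yaml.safe_load(fh)


def _normalize(symbol: str) -> str:
    s = symbol.strip().upper().replace("+", "").replace("-", "")
    s = s.replace("2", "") if s in ("MG2", "CA2") else s
    tab = _table()
    return tab.get("aliases", {}).get(s, s)


def supported_ions() -> tuple[list[str], list[str]]:
    tab = _table()
    return sorted(tab["cations"]), sorted(tab["anions"])


def classify_pair(cation: str, anion: str) -> IonPairClass:
    """Predict precipitate morphology for a (cation, anion) pair.

    The prediction is a pure function of the two class labels plus the
    documented pair overrides; unknown ions raise :class:`UnknownIonError`
    listing the supported symbols.
    """
    tab = _table()
    cat = _normalize(cation)
    an = _normalize(anion)
    if cat not in tab["cations"]:
        raise UnknownIonError(
            f"unknown cation {cation!r}; supported: {', '.join(sorted(tab['cations']))}"
        )
    if an not in tab["anions"]:
        raise UnknownIonError(
            f"unknown anion {anion!r}; supported: {', '.join(sorted(tab['anions']))}"
        )
    cat_class = tab["cations"][cat]
    an_class = tab["anions"][an]

    for ov in tab.get("overrides", []):
        if ov["cation"] == cat and ov["anion"] == an:
            return IonPairClass(cat, an, cat_class, an_class,
                                ov["morphology"], from_override=True)
    score = _SCORE[cat_class] + _SCORE[an_class]
    return IonPairClass(cat, an, cat_class, an_class, tab["grid"][score])
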