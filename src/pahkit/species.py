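"""Catalogue of the 16 US-EPA priority PAH species.

Each species carries its aromatic ring count, molecular-weight class
(LMW: 2-3 rings, MMW: 4 rings, HMW: 5-6 rings), its toxic equivalency
factor (TEF) relative to benzo[a]pyrene, and a method detection limit
(MDL, ng/m3) used by the below-detection-limit substitution policy.

The default TEF assignment is the Nisbet-LaGoy scheme; the default MDLs
are the substitution constants a typical HPLC determination of airborne
PAHs reports.  Both are overridable through a catalogue CSV
(``code,rings,tef,mdl``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["PahSpecies", "SpeciesCatalog", "default_catalog", "SPECIES_ORDER"]

#: canonical column order of a sample table's species block
SPECIES_ORDER: tuple[str, ...] = (
    "Nap", "Acy", "Flu", "Ace", "Phe", "Ant", "Flua", "Pyr",
    "Chr", "BaA", "BbF", "BkF", "BaP", "DahA", "BghiP", "IcdP",
)

_MW_CLASS = {2: "LMW", 3: "LMW", 4: "MMW", 5: "HMW", 6: "HMW"}

# (rings, tef, mdl) per species; TEFs: Nisbet-LaGoy; MDLs: typical
# HPLC substitution constants (ng/m3).
_DEFAULTS: dict[str, tuple[int, float, float]] = {
    "Nap":   (2, 0.001, 0.06),
    "Acy":   (3, 0.001, 0.01),
    "Flu":   (3, 0.001, 0.04),
    "Ace":   (3, 0.001, 0.15),
    "Phe":   (3, 0.001, 0.10),
    "Ant":   (3, 0.01,  0.04),
    "Flua":  (4, 0.001, 0.07),
    "Pyr":   (4, 0.001, 0.05),
    "Chr":   (4, 0.01,  0.05),
    "BaA":   (4, 0.1,   0.05),
    "BbF":   (5, 0.1,   0.07),
    "BkF":   (5, 0.1,   0.03),
    "BaP":   (5, 1.0,   0.05),
    "DahA":  (6, 1.0,   0.12),
    "BghiP": (6, 0.01,  0.06),
    "IcdP":  (6, 0.1,   0.04),
}

_VALID_TEFS = (0.001, 0.01, 0.1, 1.0)


@dataclass(frozen=True)
class PahSpecies:
    """One PAH species and its per-species metadata."""

    code: str
    rings: int
    tef: float
    mdl: float

    def __post_init__(self) -> None:
        if self.rings not in _MW_CLASS:
            raise ValueError(f"{self.code}: ring count {self.rings} outside 2-6")
        if self.tef not in _VALID_TEFS:
            raise ValueError(f"{self.code}: TEF {self.tef} not in {_VALID_TEFS}")
        if not self.mdl > 0:
            raise ValueError(f"{self.code}: MDL must be positive, got {self.mdl}")

    @property
    def mw_class(self) -> str:
        """Molecular-weight class implied by the ring count."""
        return _MW_CLASS[self.rings]


class SpeciesCatalog:
    """Ordered, validated collection of exactly 16 PAH species."""

    def __init__(self, species: Iterable[PahSpecies]):
        self._species: dict[str, PahSpecies] = {s.code: s for s in species}
        missing = set(SPECIES_ORDER) - set(self._species)
        extra = set(self._species) - set(SPECIES_ORDER)
        if missing or extra:
            raise ValueError(
                f"catalogue must hold the 16 priority species exactly; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def __getitem__(self, code: str) -> PahSpecies:
        return self._species[code]

    def __iter__(self):
        return (self._species[c] for c in SPECIES_ORDER)

    def __len__(self) -> int:
        return 16

    @property
    def codes(self) -> tuple[str, ...]:
        return SPECIES_ORDER

    def tefs(self) -> Mapping[str, float]:
        return {c: self._species[c].tef for c in SPECIES_ORDER}

    def mdls(self) -> Mapping[str, float]:
        return {c: self._species[c].mdl for c in SPECIES_ORDER}

    def mw_classes(self) -> Mapping[str, str]:
        return {c: self._species[c].mw_class for c in SPECIES_ORDER}

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesCatalog":
        """Read a catalogue CSV with columns ``code,rings,tef,mdl``."""
        df = pd.read_csv(path)
        required = {"code", "rings", "tef", "mdl"}
        if not required.issubset(df.columns):
            raise ValueError(f"catalogue file needs columns {sorted(required)}")
        return cls(
            PahSpecies(str(r.code), int(r.rings), float(r.tef), float(r.mdl))
            for r in df.itertuples(index=False)
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(s.code, s.rings, s.tef, s.mdl) for s in self],
            columns=["code", "rings", "tef", "mdl"],
        ).to_csv(path, index=False)


def default_catalog() -> SpeciesCatalog:
    """The default 16-species catalogue (Nisbet-LaGoy TEFs)."""
    return SpeciesCatalog(
        PahSpecies(code, rings, tef, mdl)
        for code, (rings, tef, mdl) in _DEFAULTS.items()
    )
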