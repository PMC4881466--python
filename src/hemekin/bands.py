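"""Reference-band library: load species band definitions from JSON/YAML
and render them into :class:`~hemekin.spectra.ReferenceSpectrum` objects.

The packaged library (``data/reference_bands.json``) encodes the band
positions of the Arabidopsis hemoglobin variants (wild type, AHb1 H69L,
AHb2 H66L, AHb2 H66L-K69L) in their ferric, ferrous-deoxy and
ferrous-nitrosyl forms, plus generic penta-/hexa-coordinate deoxy
components used for mixture analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .spectra import Band, ReferenceSpectrum, build_reference

__all__ = ["BandLibrary", "SpeciesEntry", "load_band_library"]


@dataclass(frozen=True)
class SpeciesEntry:
    """One species row of a band file."""

    species_id: str
    oxidation: str
    bands: tuple[Band, ...]
    soret_nm: float | None = None
    expected_ligation: str | None = None
    expected_spin: str | None = None
    synthetic_stand_in: bool = False


class BandLibrary:
    """A collection of species band definitions on a shared grid."""

    def __init__(self, entries: list[SpeciesEntry], grid: np.ndarray):
        self._entries = {e.species_id: e for e in entries}
        if len(self._entries) != len(entries):
            raise ValueError("duplicate species_id in band library")
        self.grid = np.asarray(grid, dtype=float)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def species_ids(self) -> list[str]:
        return list(self._entries)

    def entry(self, species_id: str) -> SpeciesEntry:
        try:
            return self._entries[species_id]
        except KeyError:
            raise KeyError(
                f"unknown species '{species_id}'; available: {sorted(self._entries)}"
            ) from None

    def reference(self, species_id: str, grid: np.ndarray | None = None) -> ReferenceSpectrum:
        """Render one species on the library grid (or a caller grid)."""
        e = self.entry(species_id)
        return build_reference(
            e.bands, self.grid if grid is None else grid, species_id=species_id
        )

    def references(self, species_ids: list[str], grid: np.ndarray | None = None):
        return [self.reference(sid, grid) for sid in species_ids]


def _parse(doc: dict) -> BandLibrary:
    g = doc["grid"]
    step = float(g["step_nm"])
    n = int(round((float(g["stop_nm"]) - float(g["start_nm"])) / step))
    grid = float(g["start_nm"]) + step * np.arange(n + 1)
    entries = []
    for sp in doc["species"]:
        bands = tuple(
            Band(center=float(b["center_nm"]), fwhm=float(b["fwhm_nm"]),
                 amplitude=float(b["amplitude"]))
            for b in sp["bands"]
        )
        entries.append(
            SpeciesEntry(
                species_id=sp["species_id"],
                oxidation=sp["oxidation"],
                bands=bands,
                soret_nm=sp.get("soret_nm"),
                expected_ligation=sp.get("expected_ligation"),
                expected_spin=sp.get("expected_spin"),
                synthetic_stand_in=bool(sp.get("synthetic_stand_in", False)),
            )
        )
    return BandLibrary(entries, grid)


def load_band_library(path: str | Path | None = None) -> BandLibrary:
    """Load a band library from JSON or YAML; default: the packaged one."""
    if path is None:
        text = resources.files("hemekin").joinpath("data/reference_bands.json").read_text()
        return _parse(json.loads(text))
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return _parse(yaml.safe_load(text))
    return _parse(json.loads(text))
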