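"""Validated run configuration for the command-line interface.

YAML configs are parsed into a strict hierarchical record (unknown keys
rejected); CLI flags override individual keys.  Every command writes the
resolved configuration beside its outputs so a run can be repeated
exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .presets import PROTEINS

__all__ = ["GridConfig", "KineticsConfig", "TitrationConfig", "RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    start_nm: float = 350.0
    stop_nm: float = 700.0
    step_nm: float = Field(1.0, gt=0)

    def array(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm))
        return self.start_nm + self.step_nm * np.arange(n + 1)


class KineticsConfig(_Strict):
    protein: str = "AHb2_H66L"
    k_nir: float | None = Field(None, gt=0, description="override the preset rate (M^-1 s^-1)")
    nitrite_uM: list[float] = Field(
        default_factory=lambda: [float(c) for c in np.geomspace(10.0, 500.0, 5)]
    )
    total_heme_uM: float = Field(10.0, gt=0)
    ph: float = Field(7.4, gt=0, lt=14)
    ref_ph: float = Field(7.4, gt=0, lt=14)
    proton_order: float = 1.0
    k_rered: float = Field(100.0, ge=0)
    k_no_capture: float = Field(1.0e7, ge=0)
    n_timepoints: int = Field(60, ge=5)
    time_span_folds: float = Field(6.0, gt=0)
    sigma_au: float = Field(0.002, ge=0)

    @model_validator(mode="after")
    def _known_protein(self):
        if self.protein not in PROTEINS:
            raise ValueError(f"unknown protein '{self.protein}'; choose from {list(PROTEINS)}")
        return self

    @property
    def k_nir_effective(self) -> float:
        return self.k_nir if self.k_nir is not None else PROTEINS[self.protein].k_nir


class TitrationConfig(_Strict):
    pk: float = 7.3
    n: float = Field(1.0, gt=0)
    a_acid: float = 1.0
    a_alk: float = 0.4
    ph_min: float = 5.3
    ph_max: float = 11.0
    n_points: int = Field(12, ge=4)
    sigma_au: float = Field(0.01, ge=0)
    monitor_wavelength_nm: float = 557.0

    @model_validator(mode="after")
    def _sane(self):
        if self.a_acid == self.a_alk:
            raise ValueError("a_acid and a_alk must differ")
        if self.ph_max <= self.ph_min:
            raise ValueError("ph_max must exceed ph_min")
        return self

    def ph_grid(self) -> np.ndarray:
        return np.linspace(self.ph_min, self.ph_max, self.n_points)


class RunConfig(_Strict):
    seed: int = 0
    grid: GridConfig = Field(default_factory=GridConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    titration: TitrationConfig = Field(default_factory=TitrationConfig)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (defaults if ``path`` is None), applying flat
    dotted-key overrides like ``{"kinetics.protein": "AHb1_wt"}``."""
    doc: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        doc = loaded
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        node = doc
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return RunConfig.model_validate(doc)
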