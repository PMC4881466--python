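"""Published kinetic and titration parameters for the Arabidopsis
hemoglobin variants, used as ground truth by the reproduction harness.

Rates are bimolecular nitrite-reduction rate constants at pH 7.4 and
25 C; proton orders are the reported slopes of log10(k2) vs -pH over
pH 6-8; pK values are the apparent alkaline-transition pKs of the AHb2
H66L mutant.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProteinPreset", "PROTEINS", "PK_TARGETS", "PENTA_FRACTION_AHB1_DEOXY"]


@dataclass(frozen=True)
class ProteinPreset:
    name: str
    k_nir: float  # M^-1 s^-1 at pH 7.4
    proton_order: float
    deoxy_species: str
    ferric_species: str
    nitrosyl_species: str


PROTEINS: dict[str, ProteinPreset] = {
    "AHb1_wt": ProteinPreset(
        "AHb1_wt", 13.3, 0.92,
        "AHb1_wt_deoxy", "AHb1_wt_ferric", "AHb1_wt_nitrosyl",
    ),
    "AHb2_wt": ProteinPreset(
        "AHb2_wt", 7.3, 0.85,
        "AHb2_wt_deoxy", "AHb2_wt_ferric", "AHb2_wt_nitrosyl",
    ),
    "AHb1_H69L": ProteinPreset(
        "AHb1_H69L", 10.6, 1.01,
        "AHb1_H69L_deoxy", "AHb1_H69L_ferric", "AHb1_H69L_nitrosyl",
    ),
    "AHb2_H66L": ProteinPreset(
        "AHb2_H66L", 171.90, 1.02,
        "AHb2_H66L_deoxy_acidic", "AHb2_H66L_ferric_ph8", "AHb2_H66L_nitrosyl",
    ),
}

#: Apparent pKs of the AHb2 H66L alkaline transitions (pH units) and the
#: pH grids over which each transition is observable.
PK_TARGETS: dict[str, dict] = {
    "ferric_H66L": {"pk": 7.3, "ph_min": 5.3, "ph_max": 11.0, "monitor_nm": 411.0},
    "deoxy_H66L": {"pk": 10.0, "ph_min": 8.0, "ph_max": 12.0, "monitor_nm": 558.0},
}

#: Pentacoordinate molar fraction of ferrous-deoxy AHb1 wild type.
PENTA_FRACTION_AHB1_DEOXY = 0.40
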