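{
  "description": "Gaussian band definitions for pure heme species of the Arabidopsis non-symbiotic hemoglobins AHb1 and AHb2 and their distal-pocket mutants. Band centers follow the published peak positions for each variant/oxidation/pH form; widths and Soret:visible amplitude ratios are package defaults (peak positions, not band shapes, are the published quantities). Species whose positions are not tabulated (wt deoxy components, mutant nitrosyl forms) are synthetic stand-ins and marked as such.",
  "grid": {"start_nm": 350.0, "stop_nm": 700.0, "step_nm": 1.0},
  "defaults": {"soret_fwhm_nm": 14.0, "visible_fwhm_nm": 22.0},
  "species": [
    {
      "species_id": "AHb1_H69L_ferric",
      "oxidation": "ferric",
      "soret_nm": 390,
      "expected_ligation": "five-coordinate",
      "expected_spin": "high",
      "bands": [
        {"center_nm": 390, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 504, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 637, "fwhm_nm": 22.0, "amplitude": 9.0}
      ]
    },
    {
      "species_id": "AHb1_H69L_deoxy",
      "oxidation": "ferrous",
      "soret_nm": 435,
      "expected_ligation": "five-coordinate",
      "expected_spin": "high",
      "bands": [
        {"center_nm": 435, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 540, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 569, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb1_H69L_nitrosyl",
      "oxidation": "ferrous",
      "soret_nm": 417,
      "synthetic_stand_in": true,
      "bands": [
        {"center_nm": 417, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 543, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 565, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb2_H66L_ferric_ph6",
      "oxidation": "ferric",
      "soret_nm": 404,
      "expected_ligation": "mixed",
      "bands": [
        {"center_nm": 404, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 500, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 631, "fwhm_nm": 22.0, "amplitude": 9.0}
      ]
    },
    {
      "species_id": "AHb2_H66L_ferric_ph8",
      "oxidation": "ferric",
      "soret_nm": 408,
      "expected_ligation": "mixed",
      "bands": [
        {"center_nm": 408, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 532, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 562, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb2_H66L_ferric_ph11",
      "oxidation": "ferric",
      "soret_nm": 409,
      "expected_ligation": "mixed",
      "bands": [
        {"center_nm": 409, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 535, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 568, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb2_H66L_deoxy_acidic",
      "oxidation": "ferrous",
      "soret_nm": 422,
      "expected_ligation": "mixed",
      "bands": [
        {"center_nm": 422, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 436, "fwhm_nm": 14.0, "amplitude": 60.0},
        {"center_nm": 560, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb2_H66L_deoxy_alkaline",
      "oxidation": "ferrous",
      "soret_nm": 422,
      "expected_ligation": "six-coordinate",
      "expected_spin": "low",
      "bands": [
        {"center_nm": 422, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 527, "fwhm_nm": 22.0, "amplitude": 12.0},
        {"center_nm": 557, "fwhm_nm": 22.0, "amplitude": 12.0}
      ]
    },
    {
      "species_id": "AHb2_H66L_nitrosyl",
      "oxidation": "ferrous",
      "soret_nm": 416,
      "synthetic_stand_in": true,
      "bands": [
        {"center_nm": 416, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 555, "fwhm_nm": 22.0, "amplitude": 12.0}
      ]
    },
    {
      "species_id": "AHb2_K69L_ferric",
      "oxidation": "ferric",
      "soret_nm": 397,
      "expected_ligation": "five-coordinate",
      "expected_spin": "high",
      "bands": [
        {"center_nm": 397, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 498, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 624, "fwhm_nm": 22.0, "amplitude": 9.0}
      ]
    },
    {
      "species_id": "AHb2_K69L_deoxy",
      "oxidation": "ferrous",
      "soret_nm": 436,
      "expected_ligation": "five-coordinate",
      "expected_spin": "high",
      "bands": [
        {"center_nm": 420, "fwhm_nm": 14.0, "amplitude": 60.0},
        {"center_nm": 436, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 538, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 560, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb1_wt_ferric",
      "oxidation": "ferric",
      "soret_nm": 412,
      "bands": [
        {"center_nm": 412, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 536, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 565, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb1_wt_deoxy",
      "oxidation": "ferrous",
      "soret_nm": 427,
      "synthetic_stand_in": true,
      "expected_ligation": "mixed",
      "bands": [
        {"center_nm": 425, "fwhm_nm": 14.0, "amplitude": 60.0},
        {"center_nm": 435, "fwhm_nm": 14.0, "amplitude": 40.0},
        {"center_nm": 527, "fwhm_nm": 22.0, "amplitude": 7.2},
        {"center_nm": 557, "fwhm_nm": 22.0, "amplitude": 7.2},
        {"center_nm": 540, "fwhm_nm": 22.0, "amplitude": 4.0},
        {"center_nm": 569, "fwhm_nm": 22.0, "amplitude": 4.0}
      ]
    },
    {
      "species_id": "AHb1_wt_nitrosyl",
      "oxidation": "ferrous",
      "soret_nm": 417,
      "bands": [
        {"center_nm": 417, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 543, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 565, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb2_wt_ferric",
      "oxidation": "ferric",
      "soret_nm": 410,
      "bands": [
        {"center_nm": 410, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 534, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 562, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "AHb2_wt_deoxy",
      "oxidation": "ferrous",
      "soret_nm": 425,
      "synthetic_stand_in": true,
      "expected_ligation": "six-coordinate",
      "expected_spin": "low",
      "bands": [
        {"center_nm": 425, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 527, "fwhm_nm": 22.0, "amplitude": 12.0},
        {"center_nm": 557, "fwhm_nm": 22.0, "amplitude": 12.0}
      ]
    },
    {
      "species_id": "AHb2_wt_nitrosyl",
      "oxidation": "ferrous",
      "soret_nm": 416,
      "bands": [
        {"center_nm": 416, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 555, "fwhm_nm": 22.0, "amplitude": 12.0}
      ]
    },
    {
      "species_id": "deoxy_penta_component",
      "oxidation": "ferrous",
      "soret_nm": 435,
      "expected_ligation": "five-coordinate",
      "expected_spin": "high",
      "bands": [
        {"center_nm": 435, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 540, "fwhm_nm": 22.0, "amplitude": 10.0},
        {"center_nm": 569, "fwhm_nm": 22.0, "amplitude": 10.0}
      ]
    },
    {
      "species_id": "deoxy_hexa_component",
      "oxidation": "ferrous",
      "soret_nm": 425,
      "synthetic_stand_in": true,
      "expected_ligation": "six-coordinate",
      "expected_spin": "low",
      "bands": [
        {"center_nm": 425, "fwhm_nm": 14.0, "amplitude": 100.0},
        {"center_nm": 527, "fwhm_nm": 22.0, "amplitude": 12.0},
        {"center_nm": 557, "fwhm_nm": 22.0, "amplitude": 12.0}
      ]
    }
  ]
}
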