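"""Plausible adult laboratory locations and scales for the simulator.

Each entry is (mean, sd, unit), centred inside the standard adult
reference interval for the assay. These are cosmetic anchors so generated
CSVs look like real lab exports; the class signal is injected in
standardised units, so none of the numbers below affect the statistics of
any test — multiplying a feature by a constant leaves its t value
unchanged.

The panel lists the 29 routinely named parameters of an electrolyte /
renal / hepatic / blood-routine / lipid work-up. The study panel size is
34; the remaining five entries (Na, K, Cl, Ca, Mg) are placeholders
standing in for the unenumerated electrolyte block.
"""

REFERENCE_RANGES: dict[str, tuple[float, float, str]] = {
    # renal function
    "Bun": (5.0, 1.3, "mmol/L"),
    "Cr": (80.0, 14.0, "umol/L"),
    "URA": (300.0, 60.0, "umol/L"),
    # acid-base
    "TCO2": (25.0, 2.4, "mmol/L"),
    # hepatic function
    "ALT": (25.0, 9.0, "U/L"),
    "AST": (24.0, 7.0, "U/L"),
    "GGT": (30.0, 14.0, "U/L"),
    "TBIL": (12.0, 4.0, "umol/L"),
    "DBIL": (3.5, 1.3, "umol/L"),
    "IBIL": (8.5, 3.0, "umol/L"),
    # lipids
    "HDL": (1.3, 0.3, "mmol/L"),
    "LDL": (2.9, 0.8, "mmol/L"),
    "CHO": (4.8, 1.0, "mmol/L"),
    "TG": (1.5, 0.6, "mmol/L"),
    # blood routine
    "WBC": (6.5, 1.5, "1e9/L"),
    "RBC": (4.7, 0.45, "1e12/L"),
    "HGB": (140.0, 14.0, "g/L"),
    "HCT": (0.42, 0.035, "L/L"),
    "MCV": (90.0, 4.5, "fL"),
    "MCH": (30.0, 2.0, "pg"),
    "MCHC": (340.0, 10.0, "g/L"),
    "PLT": (250.0, 55.0, "1e9/L"),
    "MPV": (10.0, 0.9, "fL"),
    "PDW": (13.0, 2.0, "%"),
    "NE": (4.0, 1.2, "1e9/L"),
    "LY": (2.0, 0.6, "1e9/L"),
    "MO": (0.5, 0.15, "1e9/L"),
    "EO": (0.15, 0.1, "1e9/L"),
    "BA": (0.03, 0.02, "1e9/L"),
    # electrolyte placeholders completing the 34-parameter panel
    "Na": (140.0, 2.5, "mmol/L"),
    "K": (4.2, 0.35, "mmol/L"),
    "Cl": (103.0, 2.8, "mmol/L"),
    "Ca": (2.4, 0.1, "mmol/L"),
    "Mg": (0.85, 0.08, "mmol/L"),
}

DEFAULT_SCHEMA: list[str] = list(REFERENCE_RANGES)
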