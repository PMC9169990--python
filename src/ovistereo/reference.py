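"""Published reference group summaries for anti-GnRH immunocastration in lambs.

These are the group-level summary statistics (center, dispersion) reported for
a three-group study — saline control and two anti-GnRH vaccine doses (1.0 mL,
0.5 mL), ten Santa Inês lambs per group, slaughtered 90 days after the first
dose.  The raw per-animal measurements were never deposited, so these
summaries play two roles here:

* calibration targets for the synthetic-cohort generator
  (:func:`ovistereo.simulate.default_cohort_params`), and
* inputs for the worked examples (:mod:`ovistereo.worked`), which recompute
  the derived effect percentages from group means.

Centers are means unless the variable is flagged nonparametric below, in
which case the center is a median and the dispersion an interquartile range.
Production estimates are stored in raw counts (not the 1e9 / 1e6 display
scale used when rendering tables).
"""

from __future__ import annotations

GROUPS: tuple[str, str, str] = ("control", "vaccine_1.0mL", "vaccine_0.5mL")

#: Variables whose published summary is median ± IQR rather than mean ± SD.
NONPARAMETRIC_VARIABLES: frozenset[str] = frozenset(
    {
        "LSI", "TLST_per_g",
        "germinative_epithelium", "leydig",
        "PQ_Ar",
        "NSCT_per_g", "DSP", "DSP_per_g", "TSR", "TSR_per_g",
    }
)

# Testis weight and morphometry (per group: (center, dispersion)).
TESTIS_MORPHOMETRY: dict[str, dict[str, tuple[float, float]]] = {
    "TW": {"control": (109.78, 36.99), "vaccine_1.0mL": (22.18, 11.30), "vaccine_0.5mL": (20.15, 6.71)},
    "GSI": {"control": (0.66, 0.17), "vaccine_1.0mL": (0.13, 0.48), "vaccine_0.5mL": (0.13, 0.03)},
    "STD": {"control": (204.60, 14.75), "vaccine_1.0mL": (91.59, 24.57), "vaccine_0.5mL": (87.94, 19.19)},
    "GEH": {"control": (46.71, 4.15), "vaccine_1.0mL": (11.21, 2.22), "vaccine_0.5mL": (10.13, 2.11)},
    "LSI": {"control": (0.0036, 0.0046), "vaccine_1.0mL": (0.0013, 0.0013), "vaccine_0.5mL": (0.0014, 0.0008)},
    "TSI": {"control": (0.28, 0.58), "vaccine_1.0mL": (0.26, 0.45), "vaccine_0.5mL": (0.31, 0.78)},
    "TLST": {"control": (3835.7, 3122.3), "vaccine_1.0mL": (15042.2, 8633.8), "vaccine_0.5mL": (14796.4, 5925.2)},
    "TLST_per_g": {"control": (11.06, 9.85), "vaccine_1.0mL": (264.92, 662.84), "vaccine_0.5mL": (335.49, 431.63)},
}

# Volumetric proportion (%) of testicular parenchyma components.
VOLUMETRIC_PROPORTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "lumen": {"control": (32.77, 9.57), "vaccine_1.0mL": (38.34, 11.05), "vaccine_0.5mL": (42.35, 16.19)},
    "germinative_epithelium": {"control": (54.77, 12.43), "vaccine_1.0mL": (40.87, 22.85), "vaccine_0.5mL": (47.42, 19.11)},
    "tunica_propria": {"control": (4.64, 1.53), "vaccine_1.0mL": (6.42, 1.14), "vaccine_0.5mL": (5.26, 0.43)},
    "leydig": {"control": (1.96, 1.22), "vaccine_1.0mL": (3.43, 1.96), "vaccine_0.5mL": (2.69, 0.73)},
    "blood_vessels": {"control": (0.77, 0.39), "vaccine_1.0mL": (0.93, 0.16), "vaccine_0.5mL": (0.94, 0.19)},
    "connective_tissue": {"control": (7.03, 2.89), "vaccine_1.0mL": (12.31, 3.92), "vaccine_0.5mL": (10.38, 5.11)},
}

# Corrected cell populations per stage-1 tubule cross section (mean ± SD).
CORRECTED_POPULATIONS: dict[str, dict[str, tuple[float, float]]] = {
    "A": {"control": (0.95, 0.12), "vaccine_1.0mL": (2.29, 0.20), "vaccine_0.5mL": (2.54, 0.53)},
    "PL": {"control": (11.46, 3.03), "vaccine_1.0mL": (1.34, 1.23), "vaccine_0.5mL": (1.14, 1.24)},
    "PQ": {"control": (15.44, 3.12), "vaccine_1.0mL": (0.00, 0.00), "vaccine_0.5mL": (0.00, 0.00)},
    "Ar": {"control": (50.29, 5.82), "vaccine_1.0mL": (0.02, 0.06), "vaccine_0.5mL": (0.00, 0.00)},
    "S": {"control": (5.27, 0.79), "vaccine_1.0mL": (10.67, 1.73), "vaccine_0.5mL": (13.25, 2.64)},
}

# Intrinsic spermatogenic yield ratios (1 : value).
INTRINSIC_YIELDS: dict[str, dict[str, tuple[float, float]]] = {
    "A_PL": {"control": (12.37, 3.92), "vaccine_1.0mL": (0.59, 0.54), "vaccine_0.5mL": (0.51, 0.55)},
    "PL_PQ": {"control": (1.37, 0.25), "vaccine_1.0mL": (0.00, 0.00), "vaccine_0.5mL": (0.00, 0.00)},
    "PQ_Ar": {"control": (3.16, 0.33), "vaccine_1.0mL": (0.00, 0.00), "vaccine_0.5mL": (0.00, 0.00)},
    "A_Ar": {"control": (53.79, 9.91), "vaccine_1.0mL": (0.01, 0.03), "vaccine_0.5mL": (0.00, 0.00)},
}

# Sertoli cell indices (1 : value).
SERTOLI_INDICES: dict[str, dict[str, tuple[float, float]]] = {
    "S_A": {"control": (0.18, 0.03), "vaccine_1.0mL": (0.21, 0.03), "vaccine_0.5mL": (0.19, 0.04)},
    "S_PL": {"control": (2.27, 0.93), "vaccine_1.0mL": (0.13, 0.14), "vaccine_0.5mL": (0.09, 0.10)},
    "S_PQ": {"control": (3.05, 1.00), "vaccine_1.0mL": (0.00, 0.00), "vaccine_0.5mL": (0.00, 0.00)},
    "S_Ar": {"control": (9.84, 2.49), "vaccine_1.0mL": (0.00, 0.00), "vaccine_0.5mL": (0.00, 0.00)},
    "S_CG": {"control": (15.36, 4.40), "vaccine_1.0mL": (0.36, 0.16), "vaccine_0.5mL": (0.29, 0.10)},
}

# Production estimates, raw counts (display scale 1e9, or 1e6 for DSP/TSR per gram).
PRODUCTION_ESTIMATES: dict[str, dict[str, tuple[float, float]]] = {
    "NSCT": {"control": (7.05e9, 6.47e9), "vaccine_1.0mL": (55.23e9, 33.80e9), "vaccine_0.5mL": (66.72e9, 30.18e9)},
    "NSCT_per_g": {"control": (0.03e9, 0.049e9), "vaccine_1.0mL": (1.94e9, 6.15e9), "vaccine_0.5mL": (4.04e9, 7.61e9)},
    "DSP": {"control": (4.52e9, 0.97e9), "vaccine_1.0mL": (0.0, 0.0), "vaccine_0.5mL": (0.0, 0.0)},
    "DSP_per_g": {"control": (35.88e6, 8.99e6), "vaccine_1.0mL": (0.0, 0.0), "vaccine_0.5mL": (0.0, 0.0)},
    "TSR": {"control": (47.53e9, 10.25e9), "vaccine_1.0mL": (0.0, 0.0), "vaccine_0.5mL": (0.0, 0.0)},
    "TSR_per_g": {"control": (376.75e6, 250.19e6), "vaccine_1.0mL": (0.0, 0.0), "vaccine_0.5mL": (0.0, 0.0)},
}


def group_means(table: dict[str, dict[str, tuple[float, float]]], variable: str) -> dict[str, float]:
    """Centers of one variable across the three groups."""
    return {g: table[variable][g][0] for g in GROUPS}
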