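"""Morphometric and stereological estimators for testicular tissue.

All estimators work per animal: tubule diameter and epithelium height are
averaged over the measured circular cross sections, volume densities come
from pooled point counts, and the total seminiferous tubule length follows
the classical point-count length estimator — tubular volume divided by the
mean tubule cross-sectional area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import COMPARTMENTS, TUBULAR_COMPARTMENTS, StereologyConfig

__all__ = [
    "summarize_tubule_profiles",
    "volumetric_proportions",
    "gonadosomatic_index",
    "parenchyma_volume_ml",
    "tubular_fraction",
    "total_tubule_length_m",
    "somatic_index",
    "percent_reduction",
    "morphometry_table",
]

#: µm³ per mL (1 mL = 1 cm³ = 1e12 µm³).
_UM3_PER_ML = 1e12
#: µm per m.
_UM_PER_M = 1e6


def summarize_tubule_profiles(
    diameters_um: np.ndarray, heights_um: np.ndarray
) -> tuple[float, float]:
    """Mean seminiferous tubule diameter (STD) and germinative epithelium
    height (GEH) over the measured circular cross sections, in µm.

    Raises ``ValueError`` on empty input or if any epithelium does not fit
    inside its tubule (2*height > diameter).
    """
    d = np.asarray(diameters_um, dtype=float)
    h = np.asarray(heights_um, dtype=float)
    if d.size == 0 or h.size == 0:
        raise ValueError("at least one tubule profile is required")
    if d.shape != h.shape:
        raise ValueError("diameters and heights must have the same length")
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("profile measurements must be > 0")
    if np.any(2 * h > d * (1 + 1e-12)):
        raise ValueError("epithelium height exceeds tubule radius in some profile")
    return float(d.mean()), float(h.mean())


def volumetric_proportions(field_counts: np.ndarray) -> np.ndarray:
    """Volume density (%) of the six tissue compartments from point counts.

    Parameters
    ----------
    field_counts
        Array of shape (n_fields, 6), point tallies per field in the order
        of :data:`ovistereo.config.COMPARTMENTS`.  Fields are pooled before
        converting to percentages, so every counted point carries the same
        weight.

    Returns
    -------
    numpy.ndarray
        Six percentages summing to 100.
    """
    counts = np.atleast_2d(np.asarray(field_counts, dtype=float))
    if counts.shape[1] != len(COMPARTMENTS):
        raise ValueError(f"expected {len(COMPARTMENTS)} compartment columns")
    if np.any(counts < 0):
        raise ValueError("point counts must be non-negative")
    pooled = counts.sum(axis=0)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("total point count is zero")
    return 100.0 * pooled / total


def gonadosomatic_index(paired_testis_mass_g: float, body_mass_g: float) -> float:
    """Gonadosomatic index: percent of body mass in the paired testes."""
    if paired_testis_mass_g <= 0 or body_mass_g <= 0:
        raise ValueError("masses must be > 0")
    return 100.0 * paired_testis_mass_g / body_mass_g


def parenchyma_volume_ml(
    testis_mass_g: float, config: StereologyConfig | None = None
) -> float:
    """Parenchyma volume (mL) from testis mass, discounting non-parenchyma
    (albuginea/mediastinum) and dividing by tissue density."""
    config = config or StereologyConfig()
    if testis_mass_g <= 0:
        raise ValueError("testis mass must be > 0")
    return testis_mass_g * (1.0 - config.nonparenchyma_fraction) / config.tissue_density_g_per_ml


def tubular_fraction(proportions_pct: np.ndarray | dict) -> float:
    """Fraction of parenchyma occupied by the seminiferous (tubular)
    compartment: lumen + germinative epithelium + tunica propria."""
    if isinstance(proportions_pct, dict):
        pct = np.array([proportions_pct[c] for c in COMPARTMENTS], dtype=float)
    else:
        pct = np.asarray(proportions_pct, dtype=float)
    idx = [COMPARTMENTS.index(c) for c in TUBULAR_COMPARTMENTS]
    return float(pct[idx].sum() / 100.0)


def total_tubule_length_m(
    parenchyma_volume_ml: float, tubular_fraction: float, std_um: float
) -> float:
    """Total length of seminiferous tubules (m).

    Treats the tubular compartment as a cylinder of diameter ``std_um``:
    ``TLST = V_tubular / (pi * (STD/2)^2)``, with the volume converted from
    mL to µm³ and the length from µm to m.
    """
    if std_um <= 0:
        raise ValueError("tubule diameter must be > 0")
    if not 0 <= tubular_fraction <= 1:
        raise ValueError("tubular fraction must be in [0, 1]")
    if parenchyma_volume_ml < 0:
        raise ValueError("volume must be >= 0")
    volume_um3 = parenchyma_volume_ml * _UM3_PER_ML * tubular_fraction
    area_um2 = np.pi * (std_um / 2.0) ** 2
    return float(volume_um3 / area_um2 / _UM_PER_M)


def somatic_index(
    component_fraction: float,
    testis_mass_g: float,
    body_mass_g: float,
    config: StereologyConfig | None = None,
) -> float:
    """Percent of body mass allocated to one parenchyma component.

    With the Leydig volume fraction this is the leydigosomatic index (LSI);
    with the tubular fraction, the tubulosomal index (TSI).  Component mass
    is parenchyma mass times the component's volume fraction (density is
    uniform across components).
    """
    config = config or StereologyConfig()
    if not 0 <= component_fraction <= 1:
        raise ValueError("component fraction must be in [0, 1]")
    if body_mass_g <= 0 or testis_mass_g <= 0:
        raise ValueError("masses must be > 0")
    parenchyma_mass = testis_mass_g * (1.0 - config.nonparenchyma_fraction)
    return 100.0 * parenchyma_mass * component_fraction / body_mass_g


def percent_reduction(control_value: float, treated_value: float) -> float:
    """Percent reduction of ``treated_value`` relative to ``control_value``."""
    if control_value <= 0:
        raise ValueError("control value must be > 0")
    return 100.0 * (control_value - treated_value) / control_value


def morphometry_table(raw, config: StereologyConfig | None = None) -> pd.DataFrame:
    """Per-animal morphometry/stereology summary (one row per animal).

    Columns: STD, GEH, TW, GSI, LSI, TSI, TLST, TLST_per_g and the six
    compartment percentages.  ``raw`` is a :class:`ovistereo.io.RawDataset`.
    """
    config = config or StereologyConfig()
    rows = []
    profiles = raw.tubule_profiles.groupby("animal_id")
    fields = raw.point_fields.groupby("animal_id")
    for rec in raw.animals.itertuples(index=False):
        prof = profiles.get_group(rec.animal_id)
        std, geh = summarize_tubule_profiles(
            prof["diameter_um"].to_numpy(), prof["epithelium_height_um"].to_numpy()
        )
        pct = volumetric_proportions(
            fields.get_group(rec.animal_id)[list(COMPARTMENTS)].to_numpy()
        )
        tw = rec.testis_mass_left_g + rec.testis_mass_right_g
        gsi = gonadosomatic_index(tw, rec.body_mass_g)
        vol = parenchyma_volume_ml(tw, config)
        tub_frac = tubular_fraction(pct)
        leydig_frac = pct[COMPARTMENTS.index("leydig")] / 100.0
        tlst = total_tubule_length_m(vol, tub_frac, std)
        row = {
            "animal_id": rec.animal_id,
            "group": rec.group,
            "TW": tw,
            "GSI": gsi,
            "STD": std,
            "GEH": geh,
            "LSI": somatic_index(leydig_frac, tw, rec.body_mass_g, config),
            "TSI": somatic_index(tub_frac, tw, rec.body_mass_g, config),
            "TLST": tlst,
            "TLST_per_g": tlst / tw,
        }
        row.update(dict(zip(COMPARTMENTS, pct)))
        rows.append(row)
    return pd.DataFrame(rows)
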