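"""Corrected cell counts, spermatogenic yields and production estimates.

Raw nuclear (or, for Sertoli cells, nucleolar) profile counts on sections of
finite thickness overcount particles, because a particle is seen in every
section its nucleus touches.  The classical thickness correction multiplies a
raw count by ``T / (T + D)`` for section thickness ``T`` and mean particle
diameter ``D``.  Corrected per-cross-section populations are then scaled to
whole-testis populations with the total seminiferous tubule length: a tubule
of length ``L`` cut into sections of thickness ``T`` yields ``L / T`` cross
sections, so

    total population = corrected count per section * L / T.

Applied to Sertoli cells this gives the total Sertoli population (NSCT); to
round spermatids, the testicular sperm reserve (TSR) at stage 1.  Daily sperm
production (DSP) divides the reserve by the time (days) that one cycle's
round-spermatid cohort represents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CELL_CLASSES, StereologyConfig

__all__ = [
    "NuclearGeometry",
    "abercrombie_factor",
    "abercrombie_correct",
    "inverse_abercrombie",
    "corrected_populations",
    "intrinsic_yields",
    "sertoli_indices",
    "general_yield_percent",
    "meiotic_loss_percent",
    "total_population",
    "daily_sperm_production",
    "cytometry_table",
]

_UM_PER_M = 1e6


@dataclass
class NuclearGeometry:
    """Mean nuclear diameter per cell class (nucleolar for S) and section
    thickness, all in µm."""

    diameters_um: dict[str, float]
    section_thickness_um: float = 3.0

    def __post_init__(self) -> None:
        if self.section_thickness_um <= 0:
            raise ValueError("section thickness must be > 0")
        for cls, d in self.diameters_um.items():
            if d < 0:
                raise ValueError(f"negative nuclear diameter for class {cls!r}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NuclearGeometry":
        """Build from a nuclear_geometry table (cell_class, mean_diameter_um,
        section_thickness_um)."""
        diam = dict(zip(frame["cell_class"], frame["mean_diameter_um"].astype(float)))
        thickness = float(frame["section_thickness_um"].iloc[0])
        return cls(diameters_um=diam, section_thickness_um=thickness)


def abercrombie_factor(section_thickness_um: float, nuclear_diameter_um: float) -> float:
    """Thickness-correction factor ``T / (T + D)``, in (0, 1]."""
    if section_thickness_um <= 0:
        raise ValueError("section thickness must be > 0")
    if nuclear_diameter_um < 0:
        raise ValueError("nuclear diameter must be >= 0")
    return section_thickness_um / (section_thickness_um + nuclear_diameter_um)


def abercrombie_correct(
    raw_count: float, section_thickness_um: float, nuclear_diameter_um: float
) -> float:
    """Correct a raw profile count for section-spanning overcounting."""
    return np.asarray(raw_count, dtype=float) * abercrombie_factor(
        section_thickness_um, nuclear_diameter_um
    )


def inverse_abercrombie(
    corrected_count: float, section_thickness_um: float, nuclear_diameter_um: float
) -> float:
    """Raw profile count that would correct to ``corrected_count``.

    Exact inverse of :func:`abercrombie_correct`; used to back out raw count
    means from published corrected populations.
    """
    return np.asarray(corrected_count, dtype=float) / abercrombie_factor(
        section_thickness_um, nuclear_diameter_um
    )


def corrected_populations(counts: pd.DataFrame, geometry: NuclearGeometry) -> pd.Series:
    """Per-class corrected population per stage-1 cross section.

    ``counts`` has one row per scored tubule and one column per cell class;
    the result is the mean over tubules of the thickness-corrected counts.
    """
    if len(counts) == 0:
        raise ValueError("at least one tubule cross section is required")
    out = {}
    for cls in CELL_CLASSES:
        raw = counts[cls].to_numpy(dtype=float)
        if np.any(raw < 0):
            raise ValueError(f"negative raw count in class {cls!r}")
        out[cls] = float(
            np.mean(
                abercrombie_correct(
                    raw, geometry.section_thickness_um, geometry.diameters_um[cls]
                )
            )
        )
    return pd.Series(out)


def _ratio(numerator: float, denominator: float, label: str) -> float:
    """Yield-ratio convention: 0/0 -> 0, x/0 (x>0) -> NaN with a warning."""
    if numerator < 0 or denominator < 0:
        raise ValueError("cell populations must be >= 0")
    if denominator == 0:
        if numerator == 0:
            return 0.0
        warnings.warn(f"{label}: zero denominator with positive numerator; undefined")
        return float("nan")
    return numerator / denominator


def intrinsic_yields(populations: pd.Series | dict) -> dict[str, float]:
    """Intrinsic spermatogenic yields: A_PL = PL/A, PL_PQ = PQ/PL,
    PQ_Ar = Ar/PQ, A_Ar = Ar/A (each read as "1 : value")."""
    p = dict(populations)
    return {
        "A_PL": _ratio(p["PL"], p["A"], "A_PL"),
        "PL_PQ": _ratio(p["PQ"], p["PL"], "PL_PQ"),
        "PQ_Ar": _ratio(p["Ar"], p["PQ"], "PQ_Ar"),
        "A_Ar": _ratio(p["Ar"], p["A"], "A_Ar"),
    }


def sertoli_indices(populations: pd.Series | dict) -> dict[str, float]:
    """Germ cells supported per Sertoli cell: S_X = X/S per germ class and
    S_CG = (A+PL+PQ+Ar)/S for all germ cells together."""
    p = dict(populations)
    out = {f"S_{cls}": _ratio(p[cls], p["S"], f"S_{cls}") for cls in ("A", "PL", "PQ", "Ar")}
    out["S_CG"] = _ratio(p["A"] + p["PL"] + p["PQ"] + p["Ar"], p["S"], "S_CG")
    return out


def general_yield_percent(a_to_ar: float, config: StereologyConfig | None = None) -> float:
    """Overall spermatogenic efficiency: observed round spermatids per type-A
    spermatogonium as a percentage of the theoretical expansion (256)."""
    config = config or StereologyConfig()
    if a_to_ar < 0:
        raise ValueError("yield ratio must be >= 0")
    return 100.0 * a_to_ar / config.theoretical_ar_per_a


def meiotic_loss_percent(pq_to_ar: float, config: StereologyConfig | None = None) -> float:
    """Percent cell loss across meiosis: shortfall of the observed round
    spermatids per pachytene spermatocyte from the theoretical 4, clamped at
    zero when the observed yield exceeds theory."""
    config = config or StereologyConfig()
    if pq_to_ar < 0:
        raise ValueError("yield ratio must be >= 0")
    loss = 100.0 * (config.theoretical_ar_per_pq - pq_to_ar) / config.theoretical_ar_per_pq
    return max(loss, 0.0)


def total_population(
    corrected_per_section: float, tlst_m: float, section_thickness_um: float
) -> float:
    """Whole-testis population from a corrected per-cross-section count and
    the total tubule length: ``count * (TLST in µm) / thickness``."""
    if section_thickness_um <= 0:
        raise ValueError("section thickness must be > 0")
    if corrected_per_section < 0 or tlst_m < 0:
        raise ValueError("inputs must be >= 0")
    return corrected_per_section * (tlst_m * _UM_PER_M) / section_thickness_um


def daily_sperm_production(tsr: float, config: StereologyConfig | None = None) -> float:
    """Daily sperm production from the testicular sperm reserve."""
    config = config or StereologyConfig()
    if tsr < 0:
        raise ValueError("sperm reserve must be >= 0")
    return tsr / config.sec_duration_days


def cytometry_table(
    raw, morphometry: pd.DataFrame, config: StereologyConfig | None = None
) -> pd.DataFrame:
    """Per-animal cytometry summary (one row per animal).

    Columns: corrected populations (A, PL, PQ, Ar, S), yield ratios, Sertoli
    indices, NSCT, DSP, TSR and their per-gram variants.  ``raw`` is a
    :class:`ovistereo.io.RawDataset`; ``morphometry`` supplies TLST and TW.
    """
    config = config or StereologyConfig()
    geometry = NuclearGeometry.from_frame(raw.nuclear_geometry)
    morpho = morphometry.set_index("animal_id")
    counts_by_animal = raw.stage1_counts.groupby("animal_id")
    rows = []
    for rec in raw.animals.itertuples(index=False):
        pops = corrected_populations(counts_by_animal.get_group(rec.animal_id), geometry)
        tlst = morpho.at[rec.animal_id, "TLST"]
        tw = morpho.at[rec.animal_id, "TW"]
        nsct = total_population(pops["S"], tlst, geometry.section_thickness_um)
        tsr = total_population(pops["Ar"], tlst, geometry.section_thickness_um)
        dsp = daily_sperm_production(tsr, config)
        row = {"animal_id": rec.animal_id, "group": rec.group}
        row.update(pops.to_dict())
        row.update(intrinsic_yields(pops))
        row.update(sertoli_indices(pops))
        row.update(
            {
                "NSCT": nsct,
                "NSCT_per_g": nsct / tw,
                "DSP": dsp,
                "DSP_per_g": dsp / tw,
                "TSR": tsr,
                "TSR_per_g": tsr / tw,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
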