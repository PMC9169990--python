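"""Seeded synthetic-cohort generator for the immunocastration study design.

The study's raw slide measurements were never deposited, so this module
generates per-animal raw measurements (tubule profiles, point-count fields,
stage-1 cell counts) with the statistical structure the analysis assumes:

* body and testis masses: lognormal (strictly positive, right-skewed);
* tubule diameter / epithelium height: hierarchical normal — an animal-level
  mean drawn from the between-animal distribution, profiles drawn around it
  with a within-animal SD, truncated at zero and constrained so the
  epithelium fits inside the tubule;
* point-count fields: per-animal Dirichlet compartment composition, then
  multinomial point tallies per field (between-animal overdispersion with
  exactly ``points_per_field`` points scored per field);
* stage-1 raw counts: per-animal gamma-distributed intensity around the
  group's raw-count mean, Poisson counts per tubule (a hierarchical negative
  binomial; classes with mean 0 are always 0).

Default parameters are calibrated so the analysis pipeline applied to a
large simulated cohort reproduces the published group means: raw count means
are obtained by inverting the thickness correction, and the control body
mass is back-solved from published testis weight and gonadosomatic index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import reference
from .config import CELL_CLASSES, COMPARTMENTS, ParameterError
from .cytometry import inverse_abercrombie
from .io import RawDataset

__all__ = [
    "GroupParams",
    "GeneratorParams",
    "CohortDesign",
    "default_cohort_params",
    "generate_cohort",
]

#: Generator-default mean nuclear diameter per cell class, µm (nucleolar for
#: S).  Field-typical values for ovine testis; the corrected-count
#: calibration is insensitive to them because raw means are derived by
#: inverting the same correction.
DEFAULT_NUCLEAR_DIAMETERS_UM: dict[str, float] = {
    "A": 6.8, "PL": 6.6, "PQ": 9.0, "Ar": 5.4, "S": 2.4,
}

#: Lamb age at slaughter, months (vaccinated at ~4.2 months + 90 days).
_AGE_MEAN, _AGE_SD = 7.2, 0.41

#: Between-animal CV adopted for body mass (unreported in the source tables).
_BODY_MASS_CV = 0.10


@dataclass
class GroupParams:
    """Per-group generator settings.  Tuples are (mean, SD) except the
    three-element tubule tuples, which are (mean, between-animal SD,
    within-animal SD)."""

    body_mass_g: tuple[float, float]
    testis_mass_g: tuple[float, float]          # per single testis, lognormal
    tubule_diameter_um: tuple[float, float, float]
    epithelium_height_um: tuple[float, float, float]
    compartment_weights: tuple[float, ...]      # 6 positive weights, any scale
    compartment_concentration: float = 15.0     # Dirichlet precision
    stage1_raw_means: dict[str, float] = field(default_factory=dict)
    count_dispersion_cv: float = 0.15           # between-animal CV of count intensity
    nuclear_diameters_um: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NUCLEAR_DIAMETERS_UM)
    )

    def validate(self) -> None:
        for name in ("body_mass_g", "testis_mass_g"):
            mean, sd = getattr(self, name)
            if mean <= 0:
                raise ParameterError(f"{name}: mean must be > 0")
            if sd < 0:
                raise ParameterError(f"{name}: SD must be >= 0")
        for name in ("tubule_diameter_um", "epithelium_height_um"):
            mean, between, within = getattr(self, name)
            if mean <= 0:
                raise ParameterError(f"{name}: mean must be > 0")
            if between < 0 or within < 0:
                raise ParameterError(f"{name}: SDs must be >= 0")
        if len(self.compartment_weights) != len(COMPARTMENTS):
            raise ParameterError("compartment_weights must have 6 entries")
        if any(w <= 0 for w in self.compartment_weights):
            raise ParameterError("compartment_weights must be strictly positive")
        if self.compartment_concentration <= 0:
            raise ParameterError("compartment_concentration must be > 0")
        if self.count_dispersion_cv < 0:
            raise ParameterError("count_dispersion_cv must be >= 0")
        for cls in CELL_CLASSES:
            if self.stage1_raw_means.get(cls, 0.0) < 0:
                raise ParameterError(f"stage1_raw_means[{cls!r}] must be >= 0")
            if self.nuclear_diameters_um.get(cls, 0.0) < 0:
                raise ParameterError(f"nuclear_diameters_um[{cls!r}] must be >= 0")

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.compartment_weights, dtype=float)
        return w / w.sum()


@dataclass
class GeneratorParams:
    """Cohort-level generator settings: per-group parameters plus the shared
    sampling protocol (how many profiles/fields/tubules per animal)."""

    groups: dict[str, GroupParams]
    section_thickness_um: float = 3.0
    points_per_field: int = 400
    n_fields: int = 10
    n_profiles: int = 30
    n_stage1_tubules: int = 10

    def validate(self) -> None:
        if self.section_thickness_um <= 0:
            raise ParameterError("section_thickness_um must be > 0")
        if self.points_per_field <= 0:
            raise ParameterError("points_per_field must be > 0 (zero total points)")
        for name in ("n_fields", "n_profiles", "n_stage1_tubules"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for label, gp in self.groups.items():
            try:
                gp.validate()
            except ParameterError as err:
                raise ParameterError(f"group {label!r}: {err}") from err


@dataclass
class CohortDesign:
    """Treatment-group labels, animals per group, and the RNG seed."""

    labels: tuple[str, ...] = reference.GROUPS
    n_per_group: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2 (group statistics need it)")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("group labels must be unique")


def default_cohort_params(section_thickness_um: float = 3.0) -> GeneratorParams:
    """Generator parameters calibrated to the published three-group summaries.

    Calibration targets per group are: testis weight and gonadosomatic index
    (body mass is back-solved as ``100 * TW / GSI``, inflated by ``1 + CV^2``
    so the expected mass ratio hits the GSI target under the lognormal body
    mass), tubule diameter and epithelium height means/SDs, normalized
    compartment proportions, and corrected stage-1 populations (raw count
    means obtained with :func:`ovistereo.cytometry.inverse_abercrombie`).
    Vaccinated-group pachytene and round-spermatid means are set to zero.
    """
    groups: dict[str, GroupParams] = {}
    for g in reference.GROUPS:
        tw_mean, tw_sd = reference.TESTIS_MORPHOMETRY["TW"][g]
        gsi_mean = reference.TESTIS_MORPHOMETRY["GSI"][g][0]
        body_mean = 100.0 * tw_mean / gsi_mean * (1.0 + _BODY_MASS_CV**2)
        std_mean, std_sd = reference.TESTIS_MORPHOMETRY["STD"][g]
        geh_mean, geh_sd = reference.TESTIS_MORPHOMETRY["GEH"][g]
        weights = tuple(
            reference.VOLUMETRIC_PROPORTIONS[c][g][0] for c in COMPARTMENTS
        )
        raw_means = {}
        for cls in CELL_CLASSES:
            corrected = reference.CORRECTED_POPULATIONS[cls][g][0]
            if g != "control" and cls in ("PQ", "Ar"):
                corrected = 0.0  # vaccinated groups: spermatogenesis arrested
            raw_means[cls] = float(
                inverse_abercrombie(
                    corrected, section_thickness_um, DEFAULT_NUCLEAR_DIAMETERS_UM[cls]
                )
            )
        groups[g] = GroupParams(
            body_mass_g=(body_mean, _BODY_MASS_CV * body_mean),
            testis_mass_g=(tw_mean / 2.0, tw_sd / np.sqrt(2.0)),
            tubule_diameter_um=(std_mean, std_sd, 0.08 * std_mean),
            epithelium_height_um=(geh_mean, geh_sd, 0.10 * geh_mean),
            compartment_weights=weights,
            stage1_raw_means=raw_means,
        )
    return GeneratorParams(groups=groups, section_thickness_um=section_thickness_um)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws parameterized by arithmetic mean and SD."""
    if sd == 0:
        return np.full(size, mean) if size else mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Normal draws truncated at zero by rejection (resample non-positives)."""
    draws = np.atleast_1d(rng.normal(mean, sd, size))
    for _ in range(100):
        bad = draws <= 0
        if not bad.any():
            break
        draws[bad] = rng.normal(mean, sd, bad.sum())
    draws = np.clip(draws, np.finfo(float).tiny, None)
    return draws if size is not None else float(draws[0])


def generate_cohort(design: CohortDesign, params: GeneratorParams) -> RawDataset:
    """Generate a validated raw dataset for the given design.

    A single RNG stream seeded from ``design.seed`` is consumed animal by
    animal in group order, so the same seed always reproduces the identical
    dataset byte for byte.
    """
    design.validate()
    params.validate()
    rng = np.random.default_rng(design.seed)

    animals, profiles, fields, stage1 = [], [], [], []
    for group in design.labels:
        gp = params.groups[group]
        weights = gp.normalized_weights
        alpha = weights * gp.compartment_concentration
        for i in range(design.n_per_group):
            aid = f"{group}_{i + 1:02d}"
            body = float(_lognormal(rng, *gp.body_mass_g))
            left = float(_lognormal(rng, *gp.testis_mass_g))
            right = float(_lognormal(rng, *gp.testis_mass_g))
            age = float(_positive_normal(rng, _AGE_MEAN, _AGE_SD))
            animals.append(
                {
                    "animal_id": aid, "group": group, "body_mass_g": body,
                    "testis_mass_left_g": left, "testis_mass_right_g": right,
                    "age_months": age,
                }
            )

            d_mean, d_between, d_within = gp.tubule_diameter_um
            h_mean, h_between, h_within = gp.epithelium_height_um
            animal_d = _positive_normal(rng, d_mean, d_between)
            animal_h = _positive_normal(rng, h_mean, h_between)
            d = _positive_normal(rng, animal_d, d_within, params.n_profiles)
            h = _positive_normal(rng, animal_h, h_within, params.n_profiles)
            h = np.minimum(h, d / 2.0)  # epithelium cannot exceed the radius
            for k in range(params.n_profiles):
                profiles.append(
                    {
                        "animal_id": aid, "profile_idx": k,
                        "diameter_um": d[k], "epithelium_height_um": h[k],
                    }
                )

            composition = rng.dirichlet(alpha)
            tallies = rng.multinomial(params.points_per_field, composition,
                                      size=params.n_fields)
            for k in range(params.n_fields):
                row = {"animal_id": aid, "field_idx": k}
                row.update(dict(zip(COMPARTMENTS, tallies[k].tolist())))
                fields.append(row)

            if gp.count_dispersion_cv > 0:
                shape = 1.0 / gp.count_dispersion_cv**2
                intensity = rng.gamma(shape, 1.0 / shape)
            else:
                intensity = 1.0
            for k in range(params.n_stage1_tubules):
                row = {"animal_id": aid, "tubule_idx": k}
                for cls in CELL_CLASSES:
                    lam = gp.stage1_raw_means.get(cls, 0.0) * intensity
                    row[cls] = int(rng.poisson(lam)) if lam > 0 else 0
                stage1.append(row)

    first = params.groups[design.labels[0]]
    geometry = pd.DataFrame(
        {
            "cell_class": list(CELL_CLASSES),
            "mean_diameter_um": [first.nuclear_diameters_um[c] for c in CELL_CLASSES],
            "section_thickness_um": params.section_thickness_um,
        }
    )
    return RawDataset(
        animals=pd.DataFrame(animals),
        tubule_profiles=pd.DataFrame(profiles),
        point_fields=pd.DataFrame(fields),
        stage1_counts=pd.DataFrame(stage1),
        nuclear_geometry=geometry,
    ).validate()
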