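"""Raw-dataset container, CSV schemas and validated reading/writing.

A raw dataset is five linked CSV tables keyed by ``animal_id``:

* ``animals.csv`` — one row per animal (group, body mass, paired testis masses, age)
* ``tubule_profiles.csv`` — circular tubule cross sections (diameter, epithelium height)
* ``point_fields.csv`` — point-count tallies over six tissue compartments
* ``stage1_counts.csv`` — raw cell counts on stage-1 tubule cross sections
* ``nuclear_geometry.csv`` — per-class mean nuclear diameter and section thickness
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import CELL_CLASSES, COMPARTMENTS


class RawDataError(ValueError):
    """Raised when a raw dataset violates its schema or link constraints."""


SCHEMAS: dict[str, list[str]] = {
    "animals": [
        "animal_id", "group", "body_mass_g",
        "testis_mass_left_g", "testis_mass_right_g", "age_months",
    ],
    "tubule_profiles": ["animal_id", "profile_idx", "diameter_um", "epithelium_height_um"],
    "point_fields": ["animal_id", "field_idx", *COMPARTMENTS],
    "stage1_counts": ["animal_id", "tubule_idx", *CELL_CLASSES],
    "nuclear_geometry": ["cell_class", "mean_diameter_um", "section_thickness_um"],
}

_MEASUREMENT_TABLES = ("tubule_profiles", "point_fields", "stage1_counts")


@dataclass
class RawDataset:
    """In-memory raw dataset: five pandas DataFrames following :data:`SCHEMAS`."""

    animals: pd.DataFrame
    tubule_profiles: pd.DataFrame
    point_fields: pd.DataFrame
    stage1_counts: pd.DataFrame
    nuclear_geometry: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def validate(self) -> "RawDataset":
        """Check schemas, key links, numeric types and per-animal row counts.

        Raises :class:`RawDataError` naming the table/rows at fault.
        """
        for name, cols in SCHEMAS.items():
            frame = self.table(name)
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise RawDataError(f"{name}: missing column(s) {missing}")
        if len(self.animals) == 0:
            raise RawDataError("animals: no animals")
        ids = self.animals["animal_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise RawDataError(f"animals: duplicate animal_id {dupes}")
        known = set(ids)

        numeric_cols = {
            "animals": SCHEMAS["animals"][2:],
            "tubule_profiles": ["diameter_um", "epithelium_height_um"],
            "point_fields": list(COMPARTMENTS),
            "stage1_counts": list(CELL_CLASSES),
            "nuclear_geometry": ["mean_diameter_um", "section_thickness_um"],
        }
        for name, cols in numeric_cols.items():
            frame = self.table(name)
            for col in cols:
                vals = pd.to_numeric(frame[col], errors="coerce")
                bad = frame.index[vals.isna()]
                if len(bad):
                    raise RawDataError(
                        f"{name}: non-numeric value in column {col!r} at row(s) {list(bad[:5])}"
                    )

        for name in _MEASUREMENT_TABLES:
            frame = self.table(name)
            orphan = ~frame["animal_id"].astype(str).isin(known)
            if orphan.any():
                rows = list(frame.index[orphan][:5])
                raise RawDataError(f"{name}: animal_id not in animals table at row(s) {rows}")
            counts = frame.groupby("animal_id").size()
            if set(counts.index.astype(str)) != known:
                missing_ids = sorted(known - set(counts.index.astype(str)))
                raise RawDataError(f"{name}: no measurement rows for animal(s) {missing_ids}")
            if counts.nunique() != 1:
                raise RawDataError(
                    f"{name}: unequal per-animal row counts "
                    f"({dict(counts[counts != counts.mode()[0]])})"
                )

        masses = self.animals[["body_mass_g", "testis_mass_left_g", "testis_mass_right_g"]]
        bad = self.animals.index[(masses <= 0).any(axis=1)]
        if len(bad):
            raise RawDataError(f"animals: non-positive mass at row(s) {list(bad[:5])}")

        geo_classes = set(self.nuclear_geometry["cell_class"])
        missing_cls = [c for c in CELL_CLASSES if c not in geo_classes]
        if missing_cls:
            raise RawDataError(f"nuclear_geometry: missing cell class(es) {missing_cls}")
        if (self.nuclear_geometry["section_thickness_um"] <= 0).any():
            raise RawDataError("nuclear_geometry: section thickness must be > 0")
        return self


def write_raw_dataset(dataset: RawDataset, path: str | Path) -> None:
    """Write the five CSV files of ``dataset`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, cols in SCHEMAS.items():
        dataset.table(name).to_csv(path / f"{name}.csv", index=False, columns=cols)


def read_raw_dataset(path: str | Path) -> RawDataset:
    """Read and validate a raw dataset from directory ``path``."""
    path = Path(path)
    frames = {}
    for name in SCHEMAS:
        file = path / f"{name}.csv"
        if not file.exists():
            raise RawDataError(f"missing file: {file}")
        frames[name] = pd.read_csv(file)
    return RawDataset(**frames).validate()
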