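"""Shared constants and configuration for the stereology pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Tissue compartments scored in point-count fields, in canonical order.
COMPARTMENTS: tuple[str, ...] = (
    "lumen",
    "germinative_epithelium",
    "tunica_propria",
    "leydig",
    "blood_vessels",
    "connective_tissue",
)

#: Compartments counted as part of the seminiferous (tubular) compartment.
TUBULAR_COMPARTMENTS: tuple[str, ...] = (
    "lumen",
    "germinative_epithelium",
    "tunica_propria",
)

#: Cell classes counted on stage-1 tubule cross sections: type-A spermatogonia,
#: pre-leptotene/leptotene spermatocytes, pachytene spermatocytes, round
#: spermatids, and Sertoli cells (counted by nucleolus).
CELL_CLASSES: tuple[str, ...] = ("A", "PL", "PQ", "Ar", "S")


class ParameterError(ValueError):
    """Raised when a configuration or generator parameter is invalid."""


@dataclass
class StereologyConfig:
    """Constants of the stereological model.

    Parameters
    ----------
    tissue_density_g_per_ml
        Mass density used to convert testis mass to parenchyma volume.
        Testicular parenchyma is close to water; 1.0 g/mL by convention.
    nonparenchyma_fraction
        Fraction of testis mass that is albuginea/mediastinum rather than
        parenchyma, in [0, 1). Zero when no separate weighing was done.
    alpha
        Significance level for all group comparisons.
    sec_duration_days
        Time-equivalent divisor converting the testicular sperm reserve at
        stage 1 into a daily production: the number of days one seminiferous
        epithelium cycle's worth of round spermatids represents.
    theoretical_ar_per_a
        Theoretical round spermatids per type-A spermatogonium for a lossless
        spermatogenic process (2**8 = 256 for the standard division scheme).
    theoretical_ar_per_pq
        Theoretical round spermatids per pachytene spermatocyte (4: two
        meiotic divisions).
    theoretical_pq_per_pl
        Theoretical pachytene spermatocytes per pre-leptotene spermatocyte (1).
    """

    tissue_density_g_per_ml: float = 1.0
    nonparenchyma_fraction: float = 0.0
    alpha: float = 0.05
    sec_duration_days: float = 10.5
    theoretical_ar_per_a: float = 256.0
    theoretical_ar_per_pq: float = 4.0
    theoretical_pq_per_pl: float = 1.0

    def __post_init__(self) -> None:
        if self.tissue_density_g_per_ml <= 0:
            raise ParameterError("tissue_density_g_per_ml must be > 0")
        if not 0 <= self.nonparenchyma_fraction < 1:
            raise ParameterError("nonparenchyma_fraction must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if self.sec_duration_days <= 0:
            raise ParameterError("sec_duration_days must be > 0")
        for name in ("theoretical_ar_per_a", "theoretical_ar_per_pq", "theoretical_pq_per_pl"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StereologyConfig":
        return cls(**d)
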