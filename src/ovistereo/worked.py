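"""Worked examples: effect percentages recomputed from published group means.

These are the headline derived numbers of the study — percent reductions of
the morphometric variables under both vaccine doses, the general and meiotic
spermatogenic yields, and the internal-consistency plug-ins for the
production estimates — recomputed here from the published group summaries in
:mod:`ovistereo.reference` using the package's own estimators.
"""

from __future__ import annotations

from . import reference
from .config import StereologyConfig
from .cytometry import general_yield_percent, meiotic_loss_percent, total_population
from .stereology import percent_reduction

__all__ = ["worked_examples", "CORE_REDUCTION_VARIABLES"]

#: Variables over which the "reduction of over 50% in both vaccinated
#: groups" statement is evaluated.
CORE_REDUCTION_VARIABLES = ("TW", "GSI", "STD", "GEH", "LSI")


def worked_examples(config: StereologyConfig | None = None) -> dict[str, float]:
    """Recompute the derived effect percentages from published group means.

    Returns a dict of named quantities:

    * ``std_reduction_pct_*`` — tubule-diameter reduction per dose;
    * ``gsi_reduction_pct_*`` — gonadosomatic-index reduction per dose;
    * ``geh_mean_reduction_pct`` — epithelium-height reduction, averaged
      over the two doses;
    * ``min_core_reduction_pct_*`` — smallest reduction across TW, GSI,
      STD, GEH, LSI per dose;
    * ``general_yield_pct`` — round spermatids formed per type-A
      spermatogonium as % of the theoretical 256 (control A:Ar);
    * ``meiotic_loss_pct`` — meiotic-phase loss from the control PQ:Ar;
    * ``nsct_plugin`` — total Sertoli population from control group means
      (corrected S per section, TLST, section thickness);
    * ``tsr_dsp_ratio`` — ratio of the control sperm-reserve and daily
      sperm-production medians (the implied cycle-time divisor, days).
    """
    config = config or StereologyConfig()
    morpho = reference.TESTIS_MORPHOMETRY
    out: dict[str, float] = {}
    doses = ("vaccine_1.0mL", "vaccine_0.5mL")
    tags = ("vaccine_1_0", "vaccine_0_5")

    for dose, tag in zip(doses, tags):
        out[f"std_reduction_pct_{tag}"] = percent_reduction(
            morpho["STD"]["control"][0], morpho["STD"][dose][0]
        )
        out[f"gsi_reduction_pct_{tag}"] = percent_reduction(
            morpho["GSI"]["control"][0], morpho["GSI"][dose][0]
        )
        out[f"min_core_reduction_pct_{tag}"] = min(
            percent_reduction(morpho[v]["control"][0], morpho[v][dose][0])
            for v in CORE_REDUCTION_VARIABLES
        )
    out["geh_mean_reduction_pct"] = sum(
        percent_reduction(morpho["GEH"]["control"][0], morpho["GEH"][dose][0])
        for dose in doses
    ) / len(doses)

    out["general_yield_pct"] = general_yield_percent(
        reference.INTRINSIC_YIELDS["A_Ar"]["control"][0], config
    )
    out["meiotic_loss_pct"] = meiotic_loss_percent(
        reference.INTRINSIC_YIELDS["PQ_Ar"]["control"][0], config
    )
    out["nsct_plugin"] = total_population(
        reference.CORRECTED_POPULATIONS["S"]["control"][0],
        morpho["TLST"]["control"][0],
        section_thickness_um=3.0,
    )
    out["tsr_dsp_ratio"] = (
        reference.PRODUCTION_ESTIMATES["TSR"]["control"][0]
        / reference.PRODUCTION_ESTIMATES["DSP"]["control"][0]
    )
    return out
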