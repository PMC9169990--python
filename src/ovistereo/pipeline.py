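"""End-to-end orchestration: raw dataset -> per-animal tables -> six group tables.

The six rendered tables mirror the study's results layout:

1. testis weight and morphometry (TW, GSI, STD, GEH, LSI, TSI, TLST, TLST/g)
2. volumetric proportions of the six parenchyma compartments
3. corrected stage-1 cell populations (A, PL, PQ, Ar, S)
4. intrinsic spermatogenic yields (A:PL, PL:PQ, PQ:Ar, A:Ar)
5. Sertoli cell indices (S:A, S:PL, S:PQ, S:Ar, S:CG)
6. production estimates (NSCT, DSP, TSR, total and per gram)

Each row carries the per-group summary (mean ± SD for parametric variables,
median ± IQR for nonparametric ones), compact letters, and the omnibus p.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import COMPARTMENTS, StereologyConfig
from .cytometry import cytometry_table
from .groupstats import GroupComparisonResult, compare_all
from .io import RawDataset
from .stereology import morphometry_table

__all__ = ["PipelineResult", "run_pipeline", "render_table", "write_results", "TABLE_VARIABLES"]

TABLE_VARIABLES: dict[str, list[str]] = {
    "table1": ["TW", "GSI", "STD", "GEH", "LSI", "TSI", "TLST", "TLST_per_g"],
    "table2": list(COMPARTMENTS),
    "table3": ["A", "PL", "PQ", "Ar", "S"],
    "table4": ["A_PL", "PL_PQ", "PQ_Ar", "A_Ar"],
    "table5": ["S_A", "S_PL", "S_PQ", "S_Ar", "S_CG"],
    "table6": ["NSCT", "NSCT_per_g", "DSP", "DSP_per_g", "TSR", "TSR_per_g"],
}

#: Display scale for production estimates (counts are huge; tables print
#: values in units of 1e9 or 1e6).
DISPLAY_SCALE: dict[str, float] = {
    "NSCT": 1e9, "NSCT_per_g": 1e9,
    "DSP": 1e9, "DSP_per_g": 1e6,
    "TSR": 1e9, "TSR_per_g": 1e6,
}


@dataclass
class PipelineResult:
    """All pipeline outputs: per-animal tables, comparison results and the
    six rendered group tables."""

    morphometry: pd.DataFrame
    cytometry: pd.DataFrame
    comparisons: list[GroupComparisonResult]
    tables: dict[str, pd.DataFrame]

    @property
    def comparison_frame(self) -> pd.DataFrame:
        """Flat comparisons table (variable, branch, statistic, p, letters)."""
        rows = []
        for res in self.comparisons:
            row = {
                "variable": res.variable,
                "branch": res.branch,
                "normality_p": res.normality_p,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "note": res.note,
            }
            for g, (center, disp) in res.summaries.items():
                row[f"{g}_center"] = center
                row[f"{g}_dispersion"] = disp
                row[f"{g}_letter"] = res.letters[g]
            rows.append(row)
        return pd.DataFrame(rows)


def run_pipeline(
    raw: RawDataset,
    config: StereologyConfig | None = None,
    alpha: float | None = None,
) -> PipelineResult:
    """Compute per-animal morphometry and cytometry, compare every table
    variable across groups, and assemble the six group tables."""
    config = config or StereologyConfig()
    alpha = config.alpha if alpha is None else alpha
    morpho = morphometry_table(raw, config)
    cyto = cytometry_table(raw, morpho, config)
    per_animal = morpho.merge(cyto.drop(columns="group"), on="animal_id")

    all_vars = [v for tab in TABLE_VARIABLES.values() for v in tab]
    comparisons = compare_all(per_animal, all_vars, alpha=alpha)
    by_var = {res.variable: res for res in comparisons}

    groups = list(dict.fromkeys(raw.animals["group"]))
    tables = {}
    for name, variables in TABLE_VARIABLES.items():
        rows = []
        for var in variables:
            res = by_var[var]
            scale = DISPLAY_SCALE.get(var, 1.0)
            row: dict[str, object] = {"variable": var, "branch": res.branch}
            for g in groups:
                center, disp = res.summaries[g]
                row[f"{g}_center"] = center / scale
                row[f"{g}_dispersion"] = disp / scale
                row[f"{g}_letter"] = res.letters[g]
            row["pvalue"] = res.pvalue
            rows.append(row)
        tables[name] = pd.DataFrame(rows)
    return PipelineResult(morphometry=morpho, cytometry=cyto,
                          comparisons=comparisons, tables=tables)


def _fmt(value: float, decimals: int) -> str:
    if not np.isfinite(value):
        return "NA"
    return f"{np.round(value, decimals):.{decimals}f}"  # numpy rounds half-even


def render_table(table: pd.DataFrame, fmt: str = "markdown", decimals: int = 2) -> str:
    """Render one group table as markdown/csv/tsv text with "center ±
    dispersion letter" cells."""
    groups = [c[: -len("_center")] for c in table.columns if c.endswith("_center")]
    out = pd.DataFrame({"variable": table["variable"]})
    for g in groups:
        cells = []
        for _, row in table.iterrows():
            cell = f"{_fmt(row[f'{g}_center'], decimals)} ± {_fmt(row[f'{g}_dispersion'], decimals)}"
            if row[f"{g}_letter"]:
                cell += f" {row[f'{g}_letter']}"
            cells.append(cell)
        out[g] = cells
    out["P value"] = [_fmt(p, 3) for p in table["pvalue"]]
    if fmt == "markdown":
        return out.to_markdown(index=False)
    sep = "\t" if fmt == "tsv" else ","
    return out.to_csv(index=False, sep=sep)


def write_results(
    result: PipelineResult,
    outdir: str | Path,
    fmt: str = "csv",
    decimals: int = 2,
) -> None:
    """Write per-animal CSVs, the comparisons CSV, and the six tables
    (raw CSV plus rendered text in the requested format)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.morphometry.to_csv(outdir / "morphometry.csv", index=False)
    result.cytometry.to_csv(outdir / "cytometry.csv", index=False)
    result.comparison_frame.to_csv(outdir / "comparisons.csv", index=False)
    ext = {"markdown": "md", "tsv": "tsv", "csv": "csv"}[fmt]
    for name, table in result.tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
        if fmt != "csv":
            (outdir / f"{name}.{ext}").write_text(render_table(table, fmt, decimals))
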