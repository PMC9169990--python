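"""Normality-branched group comparison with compact letter display.

Each variable is tested for normality (Shapiro–Wilk on the pooled
within-group residuals).  Normal variables go through one-way ANOVA with
Tukey HSD pairwise comparisons and are summarized as mean ± SD;
non-normal variables go through Kruskal–Wallis with Dunn's post-hoc
(Holm-adjusted) and are summarized as median ± IQR.  Pairwise results are
rendered as a compact letter display: groups share a letter iff they are
not significantly different.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "GroupComparisonResult",
    "choose_branch",
    "parametric_compare",
    "nonparametric_compare",
    "dunn_posthoc",
    "mannwhitney_posthoc",
    "compact_letters",
    "compare_variable",
    "compare_all",
]


@dataclass
class GroupComparisonResult:
    """Outcome of one variable's group comparison."""

    variable: str
    branch: str                      # "parametric" | "nonparametric" | "degenerate"
    normality_p: float               # NaN when untestable
    statistic: float                 # F or H; NaN when omnibus skipped
    pvalue: float
    pairwise: pd.DataFrame           # symmetric p-value matrix, group x group
    summaries: dict[str, tuple[float, float]]   # group -> (center, dispersion)
    letters: dict[str, str]
    note: str = ""


def _as_groups(values_by_group: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        out[label] = arr
    return out


def choose_branch(
    values_by_group: dict, alpha: float = 0.05, per_group: bool = False
) -> tuple[str, float]:
    """Pick the test family with the Shapiro–Wilk normality test.

    By default the test runs on the pooled within-group residuals (each
    value minus its group mean): per-group normality tests are underpowered
    at n = 10, and the residual-based check is the conventional ANOVA
    diagnostic.  With ``per_group=True`` each group is tested separately
    and the smallest p decides.  Returns ``("parametric", p)`` when
    p >= alpha, else ``("nonparametric", p)``.  Constant data are
    untestable: nonparametric with p = NaN.
    """
    groups = _as_groups(values_by_group)
    for label, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {label!r} needs >= 3 values for the normality test")
    if per_group:
        ps = [
            float(stats.shapiro(v).pvalue) if np.ptp(v) > 0 else float("nan")
            for v in groups.values()
        ]
        if all(np.isnan(p) for p in ps):
            return "nonparametric", float("nan")
        p = float(np.nanmin(ps))
    else:
        residuals = np.concatenate([v - v.mean() for v in groups.values()])
        if np.ptp(residuals) == 0:
            return "nonparametric", float("nan")
        p = float(stats.shapiro(residuals).pvalue)
    return ("parametric" if p >= alpha else "nonparametric"), p


def parametric_compare(
    values_by_group: dict, pairwise: bool = True
) -> tuple[float, float, pd.DataFrame | None]:
    """One-way ANOVA F and p, plus the Tukey HSD pairwise p-value matrix.

    ``pairwise=False`` skips the Tukey step (the studentized-range integral
    dominates the cost) and returns ``None`` as the matrix — useful in
    calibration loops that only need the omnibus test.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    samples = [groups[g] for g in labels]
    f_stat, p = stats.f_oneway(*samples)
    if not pairwise:
        return float(f_stat), float(p), None
    tukey = stats.tukey_hsd(*samples)
    pmat = pd.DataFrame(tukey.pvalue, index=labels, columns=labels)
    return float(f_stat), float(p), pmat


def dunn_posthoc(values_by_group: dict, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal–Wallis.

    z for groups i, j is the mean-rank difference over its null SD with the
    tie correction, ``sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j))``;
    two-sided normal p-values are then adjusted (Holm by default, or
    "bonferroni"; ``adjust=None`` for unadjusted).
    """
    groups = _as_groups(values_by_group)
    labels = list(groups)
    sizes = {g: len(groups[g]) for g in labels}
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for g in labels:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    raw_p = []
    for i, j in pairs:
        gi, gj = labels[i], labels[j]
        se2 = var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj])
        if se2 <= 0:  # every pooled value tied
            raw_p.append(1.0)
            continue
        z = (mean_ranks[gi] - mean_ranks[gj]) / np.sqrt(se2)
        raw_p.append(2.0 * stats.norm.sf(abs(z)))
    if adjust:
        adj = multipletests(raw_p, method=adjust)[1]
    else:
        adj = np.asarray(raw_p)
    pmat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for (i, j), p in zip(pairs, adj):
        pmat.iloc[i, j] = pmat.iloc[j, i] = float(min(p, 1.0))
    return pmat


def mannwhitney_posthoc(values_by_group: dict) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise Mann–Whitney U matrix (alternative
    post-hoc to :func:`dunn_posthoc`)."""
    groups = _as_groups(values_by_group)
    labels = list(groups)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    pmat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            if np.ptp(np.concatenate([groups[gi], groups[gj]])) == 0:
                p = 1.0
            else:
                p = stats.mannwhitneyu(groups[gi], groups[gj]).pvalue
            pmat.loc[gi, gj] = pmat.loc[gj, gi] = float(min(p * n_pairs, 1.0))
    return pmat


def nonparametric_compare(
    values_by_group: dict, posthoc: str = "dunn"
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal–Wallis H and p, plus a pairwise p-value matrix from Dunn–Holm
    (default) or Bonferroni-adjusted pairwise Mann–Whitney."""
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [groups[g] for g in groups]
    h_stat, p = stats.kruskal(*samples)
    if posthoc == "dunn":
        pmat = dunn_posthoc(values_by_group)
    elif posthoc == "mannwhitney":
        pmat = mannwhitney_posthoc(values_by_group)
    else:
        raise ValueError("posthoc must be 'dunn' or 'mannwhitney'")
    return float(h_stat), float(p), pmat


def compact_letters(pairwise, alpha: float = 0.05, labels=None) -> list[str]:
    """Insert-and-absorb compact letter display.

    Groups share a letter iff their pairwise p >= alpha.  Letters are
    assigned in group order starting at "a".
    """
    if isinstance(pairwise, pd.DataFrame):
        labels = list(pairwise.columns)
        pmat = pairwise.to_numpy()
    else:
        pmat = np.asarray(pairwise, dtype=float)
    k = pmat.shape[0]
    if pmat.shape != (k, k):
        raise ValueError("pairwise matrix must be square")

    columns: list[frozenset] = [frozenset(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if pmat[i, j] < alpha:
                new: list[frozenset] = []
                for col in columns:
                    if i in col and j in col:
                        new.append(col - {i})
                        new.append(col - {j})
                    else:
                        new.append(col)
                # absorb: drop duplicates and proper subsets
                new = list(dict.fromkeys(new))
                columns = [
                    c for c in new
                    if c and not any(c < other for other in new)
                ]
    columns.sort(key=lambda c: sorted(c))
    letters = ["" for _ in range(k)]
    for letter_idx, col in enumerate(columns):
        ch = chr(ord("a") + letter_idx)
        for g in sorted(col):
            letters[g] += ch
    return letters


def _summaries(groups: dict, branch: str) -> dict[str, tuple[float, float]]:
    out = {}
    for g, vals in groups.items():
        if branch == "parametric":
            out[g] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
        else:
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            out[g] = (float(q50), float(q75 - q25))
    return out


def compare_variable(
    variable: str, values_by_group: dict, alpha: float = 0.05
) -> GroupComparisonResult:
    """Full comparison of one variable: branch choice, omnibus test,
    pairwise p-values, summaries and letters.

    Degenerate inputs (zero within-group variance everywhere) skip the
    omnibus test: identical groups all share "a"; otherwise groups are
    lettered by exact-tie classes of their constant values.
    """
    groups = _as_groups(values_by_group)
    labels = list(groups)
    all_constant = all(np.ptp(v) == 0 for v in groups.values())
    if all_constant:
        consts = [groups[g][0] for g in labels]
        classes: list[float] = []
        letters = []
        for c in consts:
            if c not in classes:
                classes.append(c)
            letters.append(chr(ord("a") + classes.index(c)))
        note = "degenerate: zero within-group variance; omnibus skipped"
        log.warning("%s: %s", variable, note)
        pmat = pd.DataFrame(
            [[1.0 if ci == cj else 0.0 for cj in consts] for ci in consts],
            index=labels, columns=labels,
        )
        return GroupComparisonResult(
            variable=variable, branch="degenerate", normality_p=float("nan"),
            statistic=float("nan"), pvalue=float("nan"), pairwise=pmat,
            summaries=_summaries(groups, "nonparametric"),
            letters=dict(zip(labels, letters)), note=note,
        )

    branch, norm_p = choose_branch(groups, alpha)
    if branch == "parametric":
        statistic, pvalue, pmat = parametric_compare(groups)
    else:
        statistic, pvalue, pmat = nonparametric_compare(groups)
    letters = compact_letters(pmat, alpha)
    return GroupComparisonResult(
        variable=variable, branch=branch, normality_p=norm_p,
        statistic=statistic, pvalue=pvalue, pairwise=pmat,
        summaries=_summaries(groups, branch),
        letters=dict(zip(labels, letters)),
    )


def compare_all(
    frame: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """Run :func:`compare_variable` for each variable of a per-animal table.

    NaN values (undefined ratios) are dropped per variable; a variable left
    with fewer than 3 values in some group is reported untested with blank
    letters and a warning note.
    """
    group_order = list(dict.fromkeys(frame[group_col]))
    results = []
    for var in variables:
        values = {
            g: frame.loc[frame[group_col] == g, var].dropna().to_numpy()
            for g in group_order
        }
        if any(len(v) < 3 for v in values.values()):
            note = f"{var}: fewer than 3 usable values in some group; not tested"
            log.warning(note)
            results.append(
                GroupComparisonResult(
                    variable=var, branch="untested", normality_p=float("nan"),
                    statistic=float("nan"), pvalue=float("nan"),
                    pairwise=pd.DataFrame(
                        np.ones((len(group_order),) * 2),
                        index=group_order, columns=group_order,
                    ),
                    summaries={
                        g: (float(np.median(v)) if len(v) else float("nan"), float("nan"))
                        for g, v in values.items()
                    },
                    letters={g: "" for g in group_order}, note=note,
                )
            )
            continue
        results.append(compare_variable(var, values, alpha))
    return results
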