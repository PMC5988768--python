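"""Group statistics: ANOVA across degeneration grades, Tukey post-hoc, summary table.

Each imaging configuration (XZ-indented, XZ-non-indented, XY) is analysed
separately: a classical one-way fixed-effects ANOVA over the G0/G1/G2 BRC
groups, Tukey's HSD for the three pairwise comparisons, and reporting-only
checks of normality (Shapiro-Wilk per group) and variance homogeneity
(Bartlett).  The checks do not gate the ANOVA; they are reported alongside
it, matching how the source analysis used them.

Significance legend: *** for p <= 0.001, ** for 0.001 < p <= 0.01, * for
0.01 < p <= 0.05, ns otherwise (global cut 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ShapeMismatchError
from .tissue import CONFIG_LABELS, GRADE_LABELS

PAIRS = (("G0", "G1"), ("G0", "G2"), ("G1", "G2"))

_CONFIG_DISPLAY = {
    "XZ_indented": "XZ - Indented",
    "XZ_nonindented": "XZ - Non-indented",
    "XY": "XY",
}


@dataclass(frozen=True)
class GroupSample:
    """One grade's BRC values (rad/mm), one value per specimen."""

    grade_label: str
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) == 0:
            raise InsufficientDataError(f"group {self.grade_label} is empty")
        if not np.all(np.isfinite(self.values)):
            raise InsufficientDataError(f"group {self.grade_label} has non-finite values")


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    p_adjusted: float
    significant: bool  # at the study's global alpha
    stars: str  # ***, **, *, ns


@dataclass
class StudyResult:
    """Per-group summaries plus ANOVA/Tukey outcomes for one imaging configuration."""

    config_label: str
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    group_n: dict[str, int]
    anova_F: float
    anova_p: float
    bartlett_stat: float
    bartlett_p: float
    shapiro_p: dict[str, float]
    tukey: list[PairwiseComparison]

    def __post_init__(self):
        if not (0.0 <= self.anova_p <= 1.0):
            raise ValueError("anova_p must be a probability")
        if len(self.tukey) != 3:
            raise ValueError("expected exactly 3 pairwise comparisons for 3 groups")


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Star class used in the summary table legend."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= alpha:
        return "*"
    return "ns"


def _check_groups(groups: Sequence[GroupSample]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    arrays = []
    for g in groups:
        if len(g.values) < 2:
            raise InsufficientDataError(f"group {g.grade_label} has fewer than 2 values")
        arrays.append(np.asarray(g.values, dtype=float))
    return arrays


def oneway_anova(groups: Sequence[GroupSample]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: (F, p)."""
    arrays = _check_groups(groups)
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        return 0.0, 1.0  # all observations identical: no variance anywhere
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(
    groups: Sequence[GroupSample], alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Studentized-range adjusted pairwise p-values and decisions at ``alpha``."""
    arrays = _check_groups(groups)
    labels = [g.grade_label for g in groups]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        pmat = np.ones((len(groups), len(groups)))
    else:
        pmat = np.asarray(sps.tukey_hsd(*arrays).pvalue)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(min(1.0, pmat[i, j]))
            out.append(
                PairwiseComparison(
                    pair=(labels[i], labels[j]),
                    p_adjusted=p,
                    significant=p <= alpha,
                    stars=significance_stars(p, alpha),
                )
            )
    return out


def variance_homogeneity(groups: Sequence[GroupSample]) -> tuple[float, float]:
    """Bartlett's test of equal variances: (statistic, p). Reporting-only."""
    arrays = _check_groups(groups)
    if all(np.var(a) == 0 for a in arrays):
        return 0.0, 1.0  # degenerate: every group constant, variances trivially equal
    stat, p = sps.bartlett(*arrays)
    return float(stat), float(p)


def normality_check(groups: Sequence[GroupSample]) -> dict[str, float]:
    """Shapiro-Wilk p per group. Reporting-only; requires n >= 3 (else NaN)."""
    out = {}
    for g in groups:
        if len(g.values) >= 3 and np.ptp(g.values) > 0:
            out[g.grade_label] = float(sps.shapiro(np.asarray(g.values)).pvalue)
        else:
            out[g.grade_label] = float("nan")
    return out


def analyze_configuration(
    config_label: str, groups: Sequence[GroupSample], alpha: float = 0.05
) -> StudyResult:
    """Full statistical analysis of one imaging configuration."""
    arrays = _check_groups(groups)
    f, p = oneway_anova(groups)
    b_stat, b_p = variance_homogeneity(groups)
    return StudyResult(
        config_label=config_label,
        group_mean={g.grade_label: float(np.mean(a)) for g, a in zip(groups, arrays)},
        group_sd={g.grade_label: float(np.std(a, ddof=1)) for g, a in zip(groups, arrays)},
        group_n={g.grade_label: len(g.values) for g in groups},
        anova_F=f,
        anova_p=p,
        bartlett_stat=b_stat,
        bartlett_p=b_p,
        shapiro_p=normality_check(groups),
        tukey=tukey_hsd(groups, alpha),
    )


@dataclass
class StudyReport:
    """Summary-table-shaped report over the three imaging configurations."""

    results: dict[str, StudyResult]  # keyed by config label, study column order

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for label in CONFIG_LABELS:
            res = self.results[label]
            col = {}
            for grade in GRADE_LABELS:
                col[grade] = f"{res.group_mean[grade]:.1f} ± {res.group_sd[grade]:.1f}"
            col["Anova P-value"] = (
                "<0.001" if res.anova_p < 0.001 else f"{res.anova_p:.3f}"
            )
            for comp in res.tukey:
                col[f"{comp.pair[0]} vs. {comp.pair[1]}"] = comp.stars
            cols[_CONFIG_DISPLAY[label]] = col
        return pd.DataFrame(cols)

    def to_text(self) -> str:
        df = self.to_dataframe()
        lines = [
            "Summary of results for phase analysis (retardation gradient, rad/mm)",
            df.to_string(),
            "",
            "Values: mean ± between-sample SD.  Legend: *** p <= 0.001, "
            "** 0.001 < p <= 0.01, * 0.01 < p <= 0.05, ns not significant.",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def summarize_study(results: Mapping[str, StudyResult]) -> StudyReport:
    """Assemble the per-configuration results into the summary-table report.

    All three configurations must be present; columns are emitted in the study
    order (indented, non-indented, XY).
    """
    missing = [c for c in CONFIG_LABELS if c not in results]
    if missing:
        raise ShapeMismatchError(f"missing configuration(s): {missing}")
    return StudyReport(results={c: results[c] for c in CONFIG_LABELS})


def boxplot_figure(samples: pd.DataFrame, path) -> None:
    """Per-configuration boxplots of BRC by grade (visual inspection only).

    ``samples`` needs columns config_label, grade_label, brc.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(CONFIG_LABELS), figsize=(12, 4), sharey=False)
    for ax, label in zip(np.atleast_1d(axes), CONFIG_LABELS):
        sub = samples[samples["config_label"] == label]
        data = [sub[sub["grade_label"] == g]["brc"].values for g in GRADE_LABELS]
        ax.boxplot(data, tick_labels=list(GRADE_LABELS))
        ax.set_title(_CONFIG_DISPLAY[label])
        ax.set_ylabel("BRC (rad/mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
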