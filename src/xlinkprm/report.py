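"""Summary counts, the scaled peak-area heatmap, and group statistics.

Condenses validated-crosslink results into the quantities a reader compares
across tube conditions: roster-level counts (pairs, precursor ions, +12 vs
+24 Da shifts, distinct peptides), a row-scaled heatmap of donor-averaged
areas per condition, per-sample validated counts, and a one-way ANOVA with
Tukey HSD across the four groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import GROUPS, SampleDesign, default_design
from .tables import Table1Row, distinct_peptides
from .validate import ValidationResult

#: Column order of the published heatmap.
HEATMAP_GROUP_ORDER = ("F", "S", "E", "A")


@dataclass(frozen=True)
class CountSummary:
    n_pairs: int
    n_precursor_ions: int
    n_cm12: int
    n_cm24: int
    n_distinct_peptides: int


def summarize_counts(rows: Sequence[Table1Row]) -> CountSummary:
    """Roster-level counts from a crosslink table.

    Distinct peptides use exact sequence identity, so a self-crosslinked
    peptide contributes one.
    """
    return CountSummary(
        n_pairs=len(rows),
        n_precursor_ions=sum(len(r.z_list) for r in rows),
        n_cm12=sum(1 for r in rows if r.cm == 12),
        n_cm24=sum(1 for r in rows if r.cm == 24),
        n_distinct_peptides=len(distinct_peptides(rows)),
    )


def scale_heatmap(
    mean_areas: pd.DataFrame, mode: str = "rowmax"
) -> pd.DataFrame:
    """Scale per-(pair, group) mean areas for heatmap display.

    ``rowmax`` divides each row by its maximum (all-zero rows stay zero), so
    every row's peak condition reads 1. ``zscore`` standardizes each row to
    zero mean / unit variance (constant rows stay zero). Columns are ordered
    F, S, E, A as in the published figure.
    """
    cols = [g for g in HEATMAP_GROUP_ORDER if g in mean_areas.columns]
    cols += [c for c in mean_areas.columns if c not in cols]
    m = mean_areas[cols].astype(float)
    if mode == "rowmax":
        rowmax = m.max(axis=1)
        scaled = m.div(rowmax.where(rowmax > 0, 1.0), axis=0)
    elif mode == "zscore":
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=0)
        scaled = m.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return scaled


def plot_heatmap(matrix: pd.DataFrame, path, cmap: str = "viridis") -> None:
    """Render the scaled-area matrix to SVG/PNG (format from the suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(4.0, max(2.0, 0.18 * len(matrix.index)))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=4)
    ax.set_xlabel("tube condition")
    fig.colorbar(im, ax=ax, label="scaled peak area")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def count_validated_per_sample(
    results: Iterable[ValidationResult],
    min_transitions: int = 5,
    design: SampleDesign | None = None,
) -> dict[str, int]:
    """Validated precursor ions per sample.

    Counts, for each sample, the precursor ions with at least
    ``min_transitions`` surviving transitions in that sample (cohort-level
    acceptance is assumed to have been applied already). Counting is per
    precursor ion, before charge-state merging. Samples of the design with
    no validated ion report zero.
    """
    counts: dict[str, int] = (
        {sid: 0 for sid in design.sample_ids} if design is not None else {}
    )
    for r in results:
        counts.setdefault(r.sample_id, 0)
        if r.accepted and r.n_surviving >= min_transitions:
            counts[r.sample_id] += 1
    return counts


@dataclass(frozen=True)
class PairwiseComparison:
    group_1: str
    group_2: str
    mean_diff: float
    p_adj: float

    @property
    def significant_05(self) -> bool:
        return self.p_adj <= 0.05

    @property
    def significant_0001(self) -> bool:
        return self.p_adj <= 0.0001


@dataclass(frozen=True)
class AnovaTukeyReport:
    f_statistic: float
    p_value: float
    comparisons: tuple[PairwiseComparison, ...]
    degenerate: bool = False

    def comparison(self, g1: str, g2: str) -> PairwiseComparison:
        for c in self.comparisons:
            if {c.group_1, c.group_2} == {g1, g2}:
                return c
        raise KeyError(f"no comparison between {g1!r} and {g2!r}")


def group_anova_tukey(
    per_sample_counts: Mapping[str, int | float],
    design: SampleDesign | None = None,
) -> AnovaTukeyReport:
    """One-way ANOVA plus all pairwise Tukey HSD tests across groups.

    Operates on per-sample validated-crosslink counts (or any per-sample
    statistic). With zero within-group variance everywhere the report is
    flagged degenerate rather than raising.
    """
    dsn = design or default_design()
    groups = [g for g in dsn.groups if dsn.samples_in(g)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples_per_group = []
    for g in groups:
        vals = [float(per_sample_counts[sid]) for sid in dsn.samples_in(g)]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} needs at least two samples")
        samples_per_group.append(np.asarray(vals))

    pooled_var = sum(float(np.var(v, ddof=1)) for v in samples_per_group)
    if pooled_var == 0.0:
        # All groups internally constant, so F is 0/0 (all means equal) or
        # infinite (any difference). Report the limit: perfectly separated
        # constant groups are significant at any level, equal ones are not.
        comps = []
        any_diff = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                diff = float(np.mean(samples_per_group[i]) - np.mean(samples_per_group[j]))
                any_diff = any_diff or diff != 0.0
                comps.append(
                    PairwiseComparison(
                        groups[i], groups[j], diff,
                        p_adj=1.0 if diff == 0.0 else 0.0,
                    )
                )
        return AnovaTukeyReport(
            f_statistic=float("inf") if any_diff else float("nan"),
            p_value=0.0 if any_diff else 1.0,
            comparisons=tuple(comps),
            degenerate=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_val = stats.f_oneway(*samples_per_group)
        tukey = stats.tukey_hsd(*samples_per_group)
    comps = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            comps.append(
                PairwiseComparison(
                    group_1=groups[i],
                    group_2=groups[j],
                    mean_diff=float(
                        np.mean(samples_per_group[i]) - np.mean(samples_per_group[j])
                    ),
                    p_adj=float(tukey.pvalue[i, j]),
                )
            )
    return AnovaTukeyReport(
        f_statistic=float(f_stat), p_value=float(p_val), comparisons=tuple(comps)
    )


def anova_table(report: AnovaTukeyReport) -> pd.DataFrame:
    """Tukey comparisons as a tidy table with the figure's annotation tiers."""
    rows = [
        {
            "group_1": c.group_1,
            "group_2": c.group_2,
            "mean_diff": c.mean_diff,
            "p_adj": c.p_adj,
            "label": (
                "****" if c.significant_0001 else "*" if c.significant_05 else "ns"
            ),
        }
        for c in report.comparisons
    ]
    return pd.DataFrame(rows)
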