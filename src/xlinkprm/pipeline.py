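"""One-call orchestration of the simulated-cohort analysis.

Chains the stages the way the study runs them: simulate (or accept) a PRM
cohort, extract XICs and apply the validation cascade with cohort-level
acceptance, count validated precursor ions per sample, test the tube-
condition groups (one-way ANOVA + Tukey HSD), merge charge states, average
across donors and scale the heatmap matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .report import (
    AnovaTukeyReport,
    count_validated_per_sample,
    group_anova_tukey,
    scale_heatmap,
)
from .simulate import CohortSimulation, SimulationConfig, simulate_cohort
from .validate import (
    FilterConfig,
    ValidationResult,
    average_donors,
    merge_charge_states,
    validate_cohort,
)


@dataclass
class CohortAnalysis:
    simulation: CohortSimulation
    results: list[ValidationResult]
    counts_per_sample: dict[str, int]
    anova: AnovaTukeyReport
    mean_areas: pd.DataFrame
    heatmap: pd.DataFrame


def run_cohort_analysis(
    config: SimulationConfig | None = None,
    filters: FilterConfig | None = None,
) -> CohortAnalysis:
    """Simulate a cohort and push it through the full validation pipeline."""
    cfg = filters or FilterConfig()
    sim = simulate_cohort(config)
    results = validate_cohort(sim.runs, sim.targets, sim.design, cfg)
    counts = count_validated_per_sample(
        results, min_transitions=cfg.min_transitions, design=sim.design
    )
    anova = group_anova_tukey(counts, sim.design)
    merged = merge_charge_states(results)
    means = average_donors(merged, sim.design)
    return CohortAnalysis(
        simulation=sim,
        results=results,
        counts_per_sample=counts,
        anova=anova,
        mean_areas=means,
        heatmap=scale_heatmap(means),
    )
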