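"""End-to-end evaluation pipeline: eligibility, three rules, comparison.

``run_pipeline`` takes a manifest (any mixture of eligible and ineligible
records), applies the study-entry filters, scores every eligible patient
under the frame, milestone and combined rules against the ambulation-based
ground truth, and reports a JSON-serialisable block per rule plus the
chi-square comparison of the combined rule's coincidence rate against the
frame rule's.  The report is deterministic given its inputs, with a fixed
key order for diffability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .classify import (
    DEFAULT_MILESTONE_THRESHOLD_MONTHS,
    DEFAULT_PHENOTYPE_CUTOFF_YEARS,
    PatientRecord,
    Rule,
    apply_eligibility,
    phenotype_from_followup,
    predict_cohort,
)
from .evaluate import (
    ComparisonResult,
    DiagnosticPerformance,
    compare_coincidence_chi2,
    diagnostic_performance,
)
from .gene_model import ExonTable, load_exon_table

__all__ = ["PipelineResult", "RunConfig", "run_pipeline"]

logger = logging.getLogger("dmdframe")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; defaults are the published study's choices."""

    milestone_threshold_months: float = DEFAULT_MILESTONE_THRESHOLD_MONTHS
    phenotype_cutoff_years: float = DEFAULT_PHENOTYPE_CUTOFF_YEARS
    chi2_correction: bool = False
    t_test_pooled: bool = True

    def __post_init__(self) -> None:
        if self.milestone_threshold_months <= 0 or self.phenotype_cutoff_years <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class PipelineResult:
    """Structured pipeline output; ``report`` gives the JSON form."""

    config: RunConfig
    n_input: int
    flow_counts: dict
    eligible: list[PatientRecord]
    performance: dict[Rule, DiagnosticPerformance]
    comparison: ComparisonResult

    @property
    def report(self) -> dict:
        comp = self.comparison
        return {
            "config": {
                "milestone_threshold_months": self.config.milestone_threshold_months,
                "phenotype_cutoff_years": self.config.phenotype_cutoff_years,
                "chi2_correction": self.config.chi2_correction,
            },
            "flow": {
                "n_input": self.n_input,
                "excluded": dict(self.flow_counts),
                "n_eligible": len(self.eligible),
            },
            "rules": {
                rule.value: perf.as_dict() for rule, perf in self.performance.items()
            },
            "comparison": {
                "combined_vs_frame": {
                    "method": comp.method,
                    "statistic": round(comp.statistic, 4),
                    "df": comp.df,
                    "p_value": round(comp.p_value, 4),
                    "warning": comp.warning,
                }
            },
        }


def run_pipeline(
    manifest: list[PatientRecord],
    config: RunConfig | None = None,
    table: ExonTable | None = None,
) -> PipelineResult:
    """Run eligibility filtering, all three prediction rules and the
    coincidence-rate comparison on a cohort manifest."""
    config = config or RunConfig()
    table = table or load_exon_table()

    eligible, flow = apply_eligibility(manifest, config.phenotype_cutoff_years)
    logger.info(
        "eligibility: %d of %d records retained (excluded: %s)",
        len(eligible),
        len(manifest),
        dict(flow),
    )
    truth = [phenotype_from_followup(r, config.phenotype_cutoff_years) for r in eligible]

    performance: dict[Rule, DiagnosticPerformance] = {}
    for rule in (Rule.FRAME, Rule.MILESTONE, Rule.COMBINED):
        predictions = predict_cohort(
            eligible, table, rule, config.milestone_threshold_months
        )
        perf = diagnostic_performance(truth, [p.predicted for p in predictions])
        performance[rule] = perf
        logger.info(
            "%s rule: tp=%d fn=%d fp=%d tn=%d indeterminate=%d",
            rule.value,
            perf.table.tp,
            perf.table.fn,
            perf.table.fp,
            perf.table.tn,
            perf.n_indeterminate,
        )

    comparison = compare_coincidence_chi2(
        performance[Rule.COMBINED],
        performance[Rule.FRAME],
        correction=config.chi2_correction,
    )
    return PipelineResult(
        config=config,
        n_input=len(manifest),
        flow_counts=dict(flow),
        eligible=eligible,
        performance=performance,
        comparison=comparison,
    )


def render_table(result: PipelineResult) -> str:
    """Human-readable summary table of the three rules' performance."""
    header = f"{'Rule':<34}{'Sens %':>8}{'Spec %':>8}{'Coinc %':>9}"
    names = {
        Rule.FRAME: "Reading-frame rule",
        Rule.MILESTONE: "Walking-alone milestone",
        Rule.COMBINED: "Frame rule OR delayed milestone",
    }
    lines = [header, "-" * len(header)]

    def cell(x: float | None) -> str:
        return "--" if x is None else f"{100 * x:.2f}"

    for rule, perf in result.performance.items():
        lines.append(
            f"{names[rule]:<34}{cell(perf.sensitivity):>8}"
            f"{cell(perf.specificity):>8}{cell(perf.coincidence_rate):>9}"
        )
    comp = result.comparison
    lines.append("")
    lines.append(
        f"combined vs frame coincidence: chi2={comp.statistic:.3f}, "
        f"df={comp.df:.0f}, p={comp.p_value:.4f} ({comp.method})"
    )
    return "\n".join(lines)
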