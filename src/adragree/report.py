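"""Assembled study report: tables, statistics suite and sensitivity rerun."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .agreement import (
    AgreementStatistic,
    compare_exact_agreement,
    compare_pairwise_kappas,
    method_suite,
    sensitivity_unassessable_missing,
)
from .categories import CATEGORIES, METHODS, format_estimate
from .diagnostics import (
    RaterGroup,
    group_odds_ratio,
    path_frequencies,
    question_association_test,
    question_reach,
    question_response_counts,
    question_specific_agreement,
)
from .flowchart import Flowchart, load_flowchart, validate_topology
from .io import outcome_distribution


@dataclass
class Report:
    sections: dict = field(default_factory=dict)

    def render(self) -> str:
        out: list[str] = []
        for title, content in self.sections.items():
            out.append(f"== {title} ==")
            out.append(_render(content))
            out.append("")
        return "\n".join(out)


def _render(obj) -> str:
    if isinstance(obj, AgreementStatistic):
        parts = [f"{obj.name}: {format_estimate(obj.estimate)}"]
        if obj.ci_low is not None:
            parts.append(
                f"95% CI {format_estimate(obj.ci_low)} to {format_estimate(obj.ci_high)}"
            )
        if obj.p_value is not None:
            parts.append(f"p = {format_estimate(obj.p_value)}")
        return "  ".join(parts)
    if isinstance(obj, pd.DataFrame):
        return obj.to_string()
    if isinstance(obj, pd.Series):
        return obj.to_string()
    if isinstance(obj, dict):
        return "\n".join(f"{k}: {_render(v)}" for k, v in obj.items())
    return str(obj)


def run_report(
    assessments: pd.DataFrame,
    trace_records=None,
    chart: Flowchart | None = None,
    pe: str = "pooled",
    clinicians=("1", "4"),
    pharmacists=("2", "3"),
) -> Report:
    """Full deterministic analysis of a two-arm assessment dataset.

    Produces the pooled cross-tabulation and agreement suite per method, the
    per-rater-pair grid, the between-method comparisons, the sensitivity
    rerun with unassessable ratings treated as missing, and — when traces are
    supplied — the question-level diagnostics and flowchart topology.
    """
    chart = chart or load_flowchart()
    report = Report()
    suites = {}
    for method in METHODS:
        if not (assessments["method"] == method).any():
            continue
        suite = method_suite(assessments, method, pe=pe)
        suites[method] = suite
        report.sections[f"{method}: pairwise outcome distribution"] = (
            suite["crosstab"].to_frame()
        )
        report.sections[f"{method}: agreement"] = {
            "exact agreement": format_estimate(suite["exact_agreement"]),
            "extreme disagreement": format_estimate(suite["extreme_disagreement"]),
            "specific agreement": suite["specific_agreement"].map(format_estimate),
            "global kappa": suite["global_kappa"],
            "global kappa (linear weights)": suite["global_kappa_linear"],
            "ICC(1,1)": suite["icc_1_1"],
        }
        report.sections[f"{method}: rater pairs"] = suite["per_pair"]
        dist = outcome_distribution(assessments, method)
        report.sections[f"{method}: outcome distribution"] = pd.concat(
            [dist["per_rater"], dist["pooled"].to_frame().T]
        )
    if len(suites) == 2:
        indicators = {}
        for method, suite in suites.items():
            sub = assessments[assessments["method"] == method]
            indicators[method] = (
                sub.groupby("case")["outcome"].nunique() == 1
            ).astype(int)
        a, b = METHODS
        report.sections["difference in exact agreement"] = compare_exact_agreement(
            indicators[a], indicators[b]
        )
        grids = {m: suites[m]["per_pair"].sort_values("pair") for m in METHODS}
        for col, label in (("kappa", "unweighted"), ("kappa_linear", "linear")):
            report.sections[f"pairwise kappas ({label})"] = compare_pairwise_kappas(
                grids[a][col].to_numpy(), grids[b][col].to_numpy()
            )
        sens = sensitivity_unassessable_missing(assessments, pe=pe)
        report.sections["sensitivity (unassessable as missing)"] = {
            m: {
                "n cases": s["crosstab"].n,
                "exact agreement": format_estimate(s["exact_agreement"]),
                "global kappa": s["global_kappa"],
                "ICC(1,1)": s["icc_1_1"],
            }
            for m, s in sens.items()
        }
    if trace_records:
        qtable = question_response_counts(trace_records)
        counts = qtable.counts.copy()
        counts.columns = [f"{r}_{c}" for r, c in counts.columns]
        report.sections["question responses"] = counts
        pvals = {
            q: question_association_test(qtable, q).p_value
            for q in qtable.counts.index
        }
        report.sections["question association p-values"] = pd.Series(pvals)
        groups = (RaterGroup("clinician", tuple(clinicians)),
                  RaterGroup("pharmacist", tuple(pharmacists)))
        if set(clinicians) | set(pharmacists) <= set(qtable.raters):
            for q in ("Q4a", "Q4b"):
                report.sections[f"clinician vs pharmacist OR on {q}"] = (
                    group_odds_ratio(qtable, q, groups)
                )
        report.sections["path frequencies"] = path_frequencies(trace_records, chart)
        report.sections["question reach (beyond Q1)"] = question_reach(
            trace_records, beyond_start=True
        ).map(format_estimate)
        report.sections["question specific agreement"] = (
            question_specific_agreement(trace_records)
        )
        report.sections["flowchart topology"] = validate_topology(chart).render()
    return report
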