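"""File dialects for assessment records and LCAT traces.

Assessment files are comma-separated with one row per rating:
``case, rater, tool, outcome`` where tool is 1 (WHO-UMC) or 2 (LCAT) and the
outcome codes are 1 definite, 2 probable, 3 possible, 4 unlikely,
5 unassessable.  A header row is optional; named columns are matched
case-insensitively with common synonyms.

Trace files carry one row per LCAT assessment: ``case, rater, responses,
outcome`` where ``responses`` is a ten-symbol string over the canonical
question order (``+`` positive, ``-`` negative, ``.`` not reached) and the
outcome uses the same 1..5 codes (5 for a stuck traversal).  Reading a trace
file replays every row on the flowchart and rejects rows whose responses do
not reproduce the recorded outcome.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .categories import (
    CATEGORIES,
    CATEGORY_CODE,
    CODE_CATEGORY,
    CODE_METHOD,
    METHOD_CODE,
)
from .diagnostics import TraceRecord
from .flowchart import Flowchart, load_flowchart, path_signature, trace_from_signature

_COLUMN_SYNONYMS = {
    "case": {"case", "caseid", "case_id", "id"},
    "rater": {"rater", "raterid", "rater_id", "assessor"},
    "method": {"tool", "method"},
    "outcome": {"outcome", "category", "score"},
}


class DataFormatError(ValueError):
    """Raised for malformed assessment or trace files."""


def _rows(path) -> list[list[str]]:
    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]


def read_assessments(path) -> pd.DataFrame:
    """Read and validate an assessment file into long format.

    Returns columns ``case``, ``rater``, ``method`` (labels), ``outcome``
    (labels).  Unknown tool or outcome codes and duplicate
    (case, rater, method) rows are rejected with their row number.
    """
    rows = _rows(path)
    if not rows:
        return pd.DataFrame(columns=["case", "rater", "method", "outcome"])
    header = rows[0]
    positions = {"case": 0, "rater": 1, "method": 2, "outcome": 3}
    start = 0
    if not all(cell.strip().lstrip("-").isdigit() for cell in header[:4]):
        start = 1
        lowered = [c.strip().lower() for c in header]
        for field, names in _COLUMN_SYNONYMS.items():
            hits = [i for i, c in enumerate(lowered) if c in names]
            if len(hits) != 1:
                raise DataFormatError(
                    f"header must name exactly one '{field}' column, got {header}"
                )
            positions[field] = hits[0]
    records = []
    seen = set()
    for lineno, row in enumerate(rows[start:], start=start + 1):
        try:
            case = row[positions["case"]].strip()
            rater = row[positions["rater"]].strip()
            tool = int(row[positions["method"]])
            outcome = int(row[positions["outcome"]])
        except (IndexError, ValueError) as exc:
            raise DataFormatError(f"row {lineno}: malformed record {row}") from exc
        if tool not in CODE_METHOD:
            raise DataFormatError(f"row {lineno}: unknown tool code {tool}")
        if outcome not in CODE_CATEGORY:
            raise DataFormatError(f"row {lineno}: unknown outcome code {outcome}")
        key = (case, rater, tool)
        if key in seen:
            raise DataFormatError(
                f"row {lineno}: duplicate rating for case {case}, rater {rater}, "
                f"tool {tool}"
            )
        seen.add(key)
        records.append(
            {"case": _maybe_int(case), "rater": rater,
             "method": CODE_METHOD[tool], "outcome": CODE_CATEGORY[outcome]}
        )
    return pd.DataFrame(records, columns=["case", "rater", "method", "outcome"])


def _maybe_int(s: str):
    return int(s) if s.lstrip("-").isdigit() else s


def write_assessments(assessments: pd.DataFrame, path) -> None:
    """Write long-format assessments using the numeric file codes."""
    df = assessments.copy()
    df["tool"] = df["method"].map(METHOD_CODE)
    df["outcome"] = df["outcome"].map(CATEGORY_CODE)
    df[["case", "rater", "tool", "outcome"]].to_csv(path, index=False)


def read_traces(path, chart: Flowchart | None = None) -> list[TraceRecord]:
    """Read a trace file, replaying every row on the flowchart."""
    chart = chart or load_flowchart()
    rows = _rows(path)
    if not rows:
        return []
    start = 0
    if rows[0] and rows[0][0].strip().lower() in ("case", "caseid", "case_id"):
        start = 1
    records = []
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 4:
            raise DataFormatError(f"row {lineno}: expected 4 fields, got {row}")
        case, rater, signature, code = (c.strip() for c in row[:4])
        try:
            trace = trace_from_signature(chart, signature)
        except ValueError as exc:
            raise DataFormatError(f"row {lineno}: {exc}") from exc
        recorded = CODE_CATEGORY.get(int(code))
        implied = "unassessable" if trace.stuck else trace.terminal
        if recorded != implied:
            raise DataFormatError(
                f"row {lineno}: responses {signature!r} imply outcome "
                f"{implied!r} but file records {recorded!r}"
            )
        records.append(
            TraceRecord(case=_maybe_int(case), rater=rater, trace=trace)
        )
    return records


def write_traces(records: list[TraceRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case", "rater", "responses", "outcome"])
        for rec in records:
            outcome = "unassessable" if rec.trace.stuck else rec.trace.terminal
            writer.writerow([
                rec.case, rec.rater, path_signature(rec.trace),
                CATEGORY_CODE[outcome],
            ])


def outcome_distribution(assessments: pd.DataFrame, method: str) -> dict:
    """Per-rater and pooled category counts plus distribution deviations.

    The deviation of a rater is their own proportion per category minus the
    mean of all raters' proportion vectors; per rater the deviations sum to
    zero.
    """
    sub = assessments[assessments["method"] == method]
    counts = (
        sub.pivot_table(index="rater", columns="outcome", values="case",
                        aggfunc="count", fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    pooled = counts.sum(axis=0)
    pooled.name = "pooled"
    props = counts.div(counts.sum(axis=1), axis=0)
    deviations = props - props.mean(axis=0)
    return {"per_rater": counts, "pooled": pooled, "deviations": deviations}


def plot_distribution_deviation(deviations: pd.DataFrame, path) -> None:
    """Render the per-rater deviation profile to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = range(len(deviations.columns))
    for rater, row in deviations.iterrows():
        ax.plot(x, row.values, marker="o", label=f"rater {rater}")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(list(x), deviations.columns, rotation=30)
    ax.set_ylabel("proportion minus rater mean")
    ax.legend()
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)
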