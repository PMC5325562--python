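"""Question-level diagnostics of LCAT assessment traces.

Where the outcome-level statistics ask *whether* two raters agreed, these
diagnostics ask *where* in the flowchart they diverged: how often each
question was answered positively/negatively per rater, whether professional
groups (clinicians vs pharmacists) answer differently, which of the
theoretically possible paths actually occur, how far traces penetrate the
chart, and case-wise specific agreement per question.

Test selection for the response cross-tabulations follows the usual rule:
Pearson chi-square without continuity correction when all expected counts are
at least 5, otherwise the Fisher-Freeman-Halton exact test (computed here by
exhaustive enumeration over the fixed margins; SciPy provides the exact test
only for 2x2 tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .agreement import AgreementStatistic
from .flowchart import (
    NEGATIVE,
    POSITIVE,
    QUESTION_IDS,
    Flowchart,
    Trace,
    load_flowchart,
    path_signature,
    scripted_responder,
    evaluate,
)


@dataclass(frozen=True)
class TraceRecord:
    """One rater's traced LCAT assessment of one case."""

    case: object
    rater: object
    trace: Trace


@dataclass(frozen=True)
class RaterGroup:
    label: str
    members: tuple


class QuestionResponseTable:
    """Counts of positive/negative responses per question and rater."""

    def __init__(self, counts: pd.DataFrame):
        # columns: MultiIndex (response in {negative, positive}, rater)
        self.counts = counts

    @classmethod
    def from_records(cls, records: list[TraceRecord]) -> "QuestionResponseTable":
        raters = sorted({r.rater for r in records}, key=repr)
        cols = pd.MultiIndex.from_product([[NEGATIVE, POSITIVE], raters],
                                          names=["response", "rater"])
        counts = pd.DataFrame(0, index=list(QUESTION_IDS), columns=cols)
        for rec in records:
            for qid, resp in rec.trace.steps:
                if qid not in counts.index:
                    raise ValueError(f"unknown question {qid!r} in trace "
                                     f"(case {rec.case!r}, rater {rec.rater!r})")
                counts.loc[qid, (resp, rec.rater)] += 1
        return cls(counts)

    @property
    def raters(self) -> list:
        return list(self.counts[NEGATIVE].columns)

    def question_matrix(self, question: str, groups=None) -> pd.DataFrame:
        """2 x c table (rows negative/positive) by rater or by group."""
        neg = self.counts.loc[question, NEGATIVE]
        pos = self.counts.loc[question, POSITIVE]
        if groups is None:
            return pd.DataFrame([neg.values, pos.values],
                                index=[NEGATIVE, POSITIVE], columns=self.raters)
        data = {}
        for g in groups:
            data[g.label] = [sum(neg.get(m, 0) for m in g.members),
                             sum(pos.get(m, 0) for m in g.members)]
        return pd.DataFrame(data, index=[NEGATIVE, POSITIVE])


def question_response_counts(records: list[TraceRecord]) -> QuestionResponseTable:
    """Tally each rater's positive and negative responses per question."""
    return QuestionResponseTable.from_records(records)


def freeman_halton_exact(table) -> float:
    """Fisher-Freeman-Halton exact test for a 2 x c table.

    Enumerates all tables with the observed margins; the p-value is the total
    conditional probability of tables no more probable than the observed one.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("exact enumeration implemented for 2 x c tables")
    cols = table.sum(axis=0)
    rows = table.sum(axis=1)
    n = table.sum()
    if n == 0:
        raise ValueError("empty table")

    def log_prob(x: np.ndarray) -> float:
        # product of per-column binomials over the row-margin hypergeometric
        lp = -(gammaln(n + 1) - gammaln(rows[0] + 1) - gammaln(rows[1] + 1))
        for xj, cj in zip(x, cols):
            lp += gammaln(cj + 1) - gammaln(xj + 1) - gammaln(cj - xj + 1)
        return lp

    lp_obs = log_prob(table[0])
    total = 0.0
    c = len(cols)

    def enumerate_rows(j: int, remaining: int, prefix: list[int]) -> None:
        nonlocal total
        if j == c - 1:
            if 0 <= remaining <= cols[j]:
                lp = log_prob(np.array(prefix + [remaining]))
                if lp <= lp_obs + 1e-9:
                    total += math.exp(lp)
            return
        tail_cap = cols[j + 1:].sum()
        lo = max(0, remaining - tail_cap)
        hi = min(cols[j], remaining)
        for xj in range(lo, hi + 1):
            enumerate_rows(j + 1, remaining - xj, prefix + [xj])

    enumerate_rows(0, int(rows[0]), [])
    return min(total, 1.0)


def question_association_test(
    qtable: QuestionResponseTable,
    question: str,
    groups=None,
    yates: bool = False,
) -> AgreementStatistic:
    """Test whether response profiles differ across raters (or groups).

    Pearson chi-square when every expected count is >= 5, otherwise the exact
    test.  Raters (or groups) with no responses to the question are dropped;
    if fewer than two columns or one response row remain the statistic is
    undefined and flagged.
    """
    mat = qtable.question_matrix(question, groups=groups).to_numpy()
    mat = mat[:, mat.sum(axis=0) > 0]
    used_rows = mat.sum(axis=1) > 0
    if mat.shape[1] < 2 or used_rows.sum() < 2:
        return AgreementStatistic(
            name=f"association_{question}", estimate=math.nan,
            extra={"undefined": "degenerate response table"},
        )
    expected = np.outer(mat.sum(axis=1), mat.sum(axis=0)) / mat.sum()
    if (expected < 5).any():
        p = freeman_halton_exact(mat)
        test, estimate = "fisher_exact", math.nan
    else:
        chi2, p, _, _ = stats.chi2_contingency(mat, correction=yates)
        test, estimate = "chi_square", float(chi2)
    return AgreementStatistic(
        name=f"association_{question}",
        estimate=estimate,
        p_value=float(p),
        n_used=int(mat.sum()),
        extra={"test": test},
    )


def group_odds_ratio(
    qtable: QuestionResponseTable,
    question: str,
    groups: tuple[RaterGroup, RaterGroup],
) -> AgreementStatistic:
    """Odds ratio for a positive response from the first group vs the second.

    Woolf (logit) 95% CI; p-value from the grouped association test.  A zero
    cell triggers the 0.5 continuity correction, flagged in ``extra``.
    """
    g1, g2 = groups
    if set(g1.members) & set(g2.members):
        raise ValueError("rater groups must be disjoint")
    mat = qtable.question_matrix(question, groups=groups)
    a = mat.loc[POSITIVE, g1.label]
    b = mat.loc[NEGATIVE, g1.label]
    c = mat.loc[POSITIVE, g2.label]
    d = mat.loc[NEGATIVE, g2.label]
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("both groups must have responded to the question")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    p = question_association_test(qtable, question, groups=groups).p_value
    return AgreementStatistic(
        name=f"odds_ratio_{question}",
        estimate=float(or_),
        ci_low=float(math.exp(math.log(or_) - z * se)),
        ci_high=float(math.exp(math.log(or_) + z * se)),
        p_value=p,
        n_used=int(mat.to_numpy().sum()),
        extra={"groups": (g1.label, g2.label), "continuity_corrected": corrected},
    )


def _replay(chart: Flowchart, rec: TraceRecord) -> Trace:
    responses = rec.trace.responses()
    _, replayed = evaluate(chart, scripted_responder(responses))
    if replayed != rec.trace:
        raise ValueError(
            f"trace for case {rec.case!r}, rater {rec.rater!r} does not replay "
            "on the flowchart"
        )
    return replayed


def path_frequencies(
    records: list[TraceRecord], chart: Flowchart | None = None
) -> pd.DataFrame:
    """Distinct complete paths with counts, descending; stuck traces tallied
    under the signature they reached with outcome ``stuck``."""
    chart = chart or load_flowchart()
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        _replay(chart, rec)
        key = (path_signature(rec.trace), rec.trace.terminal)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"path": sig, "outcome": term, "count": k}
        for (sig, term), k in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["path", "outcome", "count"])
    return df.sort_values(["count", "path"], ascending=[False, True],
                          ignore_index=True)


def question_reach(
    records: list[TraceRecord],
    beyond_start: bool = False,
) -> pd.Series:
    """Fraction of traces that visit each question.

    With ``beyond_start=True`` the denominator is restricted to traces that
    answered the start question positively (i.e. proceeded beyond it).
    """
    if beyond_start:
        records = [
            r for r in records
            if r.trace.steps and r.trace.steps[0][1] == POSITIVE
        ]
    n = len(records)
    reach = pd.Series(0, index=list(QUESTION_IDS), dtype=float)
    for rec in records:
        for q in rec.trace.visited():
            reach[q] += 1
    return reach / n if n else reach


def question_specific_agreement(records: list[TraceRecord]) -> pd.DataFrame:
    """Case-wise specific agreement on each question's responses.

    For every case assessed by two raters, each question answered by both
    contributes one response pair.  Per question: Ps(positive) = 2a/(2a+b+c)
    and Ps(negative) = 2d/(2d+b+c) over the concordant (a, d) and discordant
    (b + c) pair counts; NaN where undefined.
    """
    by_case: dict[object, list[TraceRecord]] = {}
    for rec in records:
        by_case.setdefault(rec.case, []).append(rec)
    tallies = {q: [0, 0, 0] for q in QUESTION_IDS}  # both_pos, both_neg, discordant
    for case, recs in by_case.items():
        if len(recs) != 2:
            continue
        r1, r2 = (r.trace.responses() for r in recs)
        for q in QUESTION_IDS:
            if q in r1 and q in r2:
                if r1[q] == r2[q] == POSITIVE:
                    tallies[q][0] += 1
                elif r1[q] == r2[q] == NEGATIVE:
                    tallies[q][1] += 1
                else:
                    tallies[q][2] += 1
    rows = []
    for q, (a, d, bc) in tallies.items():
        n_pairs = a + d + bc
        ps_pos = 2 * a / (2 * a + bc) if (a + bc) else math.nan
        ps_neg = 2 * d / (2 * d + bc) if (d + bc) else math.nan
        rows.append({"question": q, "n_pairs": n_pairs,
                     "ps_positive": ps_pos, "ps_negative": ps_neg})
    return pd.DataFrame(rows).set_index("question")
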