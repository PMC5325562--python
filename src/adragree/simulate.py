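"""Synthetic rater simulation for two-arm agreement studies.

The generator emulates the statistical structure the analysis assumes: a
latent case truth shared by both assessment methods, raters who err around
that truth, and an incomplete randomised allocation.

* :class:`CaseTruth` holds a latent causality category (ordinal 1..4) and a
  per-question true state.  The two are kept consistent by construction: the
  question facts are sampled along a flowchart path whose outcome *is* the
  latent category, so an error-free LCAT rater reproduces it exactly, and a
  global-introspection rater is modelled as observing the same latent
  category through ordinal noise.  This shared truth is what correlates the
  two methods' ratings.
* :class:`RaterProfile` carries a category bias (log-space preference over
  the four ordinal outcomes, used to tilt which adjacent category an erring
  introspective rater picks), a per-question error rate, and per-question
  log-odds shifts used to model profession effects on the subjective
  questions (Q4a, Q4b).
* Uninformative cases carry an unknown fact at one reached question, so LCAT
  raters get stuck there and introspective raters declare the case
  unassessable.

All generators take explicit seeds and the study output carries its
generation metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import METHODS, ORDINAL_CATEGORIES, ORDINAL_RANK
from .design import Allocation, allocate, randomize_order
from .diagnostics import TraceRecord
from .flowchart import (
    NEGATIVE,
    POSITIVE,
    UNANSWERABLE,
    Flowchart,
    enumerate_paths,
    evaluate,
    load_flowchart,
)

#: Pooled assessable LCAT outcome distribution of the motivating study,
#: (definite, probable, possible, unlikely) = (3, 29, 25, 32) of 89 ratings.
DEFAULT_CATEGORY_MIX: tuple[float, ...] = (3 / 89, 29 / 89, 25 / 89, 32 / 89)

#: Marginal positive-response rates used for question facts that lie off the
#: sampled path (they never influence the error-free traversal).
DEFAULT_FACT_RATES: dict[str, float] = {
    "Q1": 0.65, "Q2a": 0.95, "Q2b": 0.3, "Q3a": 0.85, "Q3b": 0.75,
    "Q4a": 0.45, "Q4b": 0.3, "Q5a": 0.05, "Q5b": 0.06, "Q6": 0.95,
}

UNKNOWN = "unknown"


@dataclass
class CaseTruth:
    case: object
    latent_category: str
    facts: dict[str, str]
    informative: bool = True

    @property
    def latent_rank(self) -> int:
        return ORDINAL_RANK[self.latent_category]


@dataclass
class RaterProfile:
    rater: object
    profession: str = "clinician"
    #: log-space preference over the four ordinal categories; must sum to 0
    category_bias: np.ndarray = field(
        default_factory=lambda: np.zeros(len(ORDINAL_CATEGORIES))
    )
    #: probability of flipping a known question fact (and of rating an
    #: adjacent category instead of the latent one); 0 <= e <= 0.5
    error_rate: float = 0.15
    #: per-question overrides of the error rate
    question_error: dict[str, float] = field(default_factory=dict)
    #: per-question log-odds shifts on answering positive (profession effects)
    question_shift: dict[str, float] = field(default_factory=dict)
    #: ignore the truth entirely and respond at random (null calibration)
    uniform_random: bool = False

    def __post_init__(self) -> None:
        self.category_bias = np.asarray(self.category_bias, dtype=float)
        if abs(self.category_bias.sum()) > 1e-8:
            raise ValueError("category bias must sum to zero in log space")
        rates = [self.error_rate, *self.question_error.values()]
        if any(not 0 <= e <= 0.5 for e in rates):
            raise ValueError("error rates must lie in [0, 0.5]")

    def error_for(self, question: str) -> float:
        return self.question_error.get(question, self.error_rate)


def default_profiles(
    error_rate: float = 0.15,
    q4a_log_or: float = math.log(5.1),
    q4b_log_or: float = -math.log(3.0),
) -> list[RaterProfile]:
    """Four raters mirroring the motivating study's panel.

    Raters 1 and 4 are clinicians, 2 and 3 pharmacists.  Rater 2 leans toward
    'probable', rater 3 toward 'possible', rater 4 toward 'unlikely'.  The
    profession effect on Q4a/Q4b is split symmetrically between the groups so
    the clinician-vs-pharmacist log odds ratio equals the stated value.
    """
    def bias(k: int | None) -> np.ndarray:
        v = np.zeros(4)
        if k is not None:
            v[:] = -0.25
            v[k] = 0.75
        return v

    shifts = {"clinician": {"Q4a": q4a_log_or / 2, "Q4b": q4b_log_or / 2},
              "pharmacist": {"Q4a": -q4a_log_or / 2, "Q4b": -q4b_log_or / 2}}
    spec = [("1", "clinician", None), ("2", "pharmacist", 1),
            ("3", "pharmacist", 2), ("4", "clinician", 3)]
    return [
        RaterProfile(
            rater=r, profession=prof, category_bias=bias(k),
            error_rate=error_rate, question_shift=dict(shifts[prof]),
        )
        for r, prof, k in spec
    ]


def generate_cases(
    n: int,
    category_mix=DEFAULT_CATEGORY_MIX,
    p_uninformative: float = 0.08,
    seed: int = 0,
    chart: Flowchart | None = None,
) -> list[CaseTruth]:
    """Sample ``n`` latent case truths.

    Latent categories are multinomial over ``category_mix``; the question
    facts are taken from a uniformly chosen flowchart path whose outcome
    equals the latent category (off-path facts from marginal rates), so the
    consistency invariant holds by construction.  With probability
    ``p_uninformative`` one reached question's fact is replaced by "unknown".
    """
    mix = np.asarray(category_mix, dtype=float)
    if mix.shape != (len(ORDINAL_CATEGORIES),) or (mix < 0).any() or not math.isclose(
        mix.sum(), 1.0, abs_tol=1e-8
    ):
        raise ValueError("category_mix must be a probability vector over the "
                         "four ordinal categories")
    chart = chart or load_flowchart()
    rng = np.random.default_rng(seed)
    by_outcome: dict[str, list] = {c: [] for c in ORDINAL_CATEGORIES}
    for p in enumerate_paths(chart):
        by_outcome[p.terminal].append(p)
    cases = []
    for i in range(1, n + 1):
        cat = ORDINAL_CATEGORIES[rng.choice(len(mix), p=mix)]
        path = by_outcome[cat][rng.integers(len(by_outcome[cat]))]
        facts = {
            q: (POSITIVE if rng.random() < DEFAULT_FACT_RATES[q] else NEGATIVE)
            for q in chart.nodes
        }
        facts.update(dict(path.steps))
        informative = rng.random() >= p_uninformative
        if not informative:
            visited = path.visited()
            facts[visited[rng.integers(len(visited))]] = UNKNOWN
        cases.append(CaseTruth(case=i, latent_category=cat, facts=facts,
                               informative=informative))
    return cases


def rate_whoumc(
    case: CaseTruth,
    rater: RaterProfile,
    rng: np.random.Generator,
    p_unassessable: float = 1.0,
) -> str:
    """Global-introspection rating: ordinal confusion around the latent truth.

    The rater recovers the latent category with probability ``1 - e``;
    otherwise an adjacent category is chosen, tilted by the rater's category
    bias.  Uninformative cases are declared unassessable with probability
    ``p_unassessable``.
    """
    if rater.uniform_random:
        return ORDINAL_CATEGORIES[rng.integers(len(ORDINAL_CATEGORIES))]
    if not case.informative and rng.random() < p_unassessable:
        return "unassessable"
    t = case.latent_rank
    if rng.random() >= rater.error_rate:
        return ORDINAL_CATEGORIES[t - 1]
    neighbours = [r for r in (t - 1, t + 1) if 1 <= r <= 4]
    logw = np.array([rater.category_bias[r - 1] for r in neighbours])
    w = np.exp(logw - logw.max())
    pick = neighbours[rng.choice(len(neighbours), p=w / w.sum())]
    return ORDINAL_CATEGORIES[pick - 1]


def answer_lcat(
    case: CaseTruth, rater: RaterProfile, rng: np.random.Generator
):
    """Responder for the flowchart engine: noisy readout of the case facts.

    Each reached question is answered positive with probability ``1 - e`` if
    the true fact is positive and ``e`` otherwise, shifted on the log-odds
    scale by the rater's per-question shift (profession effect on Q4a/Q4b).
    Unknown facts are unanswerable, so the rater gets stuck.
    """

    def _logistic(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-x))

    def respond(question: str) -> str:
        if rater.uniform_random:
            return POSITIVE if rng.random() < 0.5 else NEGATIVE
        fact = case.facts.get(question, UNKNOWN)
        if fact == UNKNOWN:
            return UNANSWERABLE
        e = rater.error_for(question)
        p_pos = (1.0 - e) if fact == POSITIVE else e
        shift = rater.question_shift.get(question, 0.0)
        if shift:
            p_pos = min(max(p_pos, 1e-9), 1 - 1e-9)
            p_pos = _logistic(math.log(p_pos / (1 - p_pos)) + shift)
        return POSITIVE if rng.random() < p_pos else NEGATIVE

    return respond


@dataclass
class SimulatedStudy:
    assessments: pd.DataFrame
    trace_records: list[TraceRecord]
    allocation: Allocation
    cases: list[CaseTruth]
    metadata: dict


def generate_study(
    n_cases: int = 48,
    raters: list[RaterProfile] | None = None,
    seed: int = 0,
    category_mix=DEFAULT_CATEGORY_MIX,
    p_uninformative: float = 0.08,
    chart: Flowchart | None = None,
) -> SimulatedStudy:
    """End-to-end synthetic study under a fresh incomplete allocation.

    Every case receives two ratings per method (half the raters by each), in
    the assessment-file dialect, plus full LCAT traces.  Deterministic per
    seed.
    """
    raters = raters if raters is not None else default_profiles()
    if len(raters) % 2:
        raise ValueError("rater count must be even")
    chart = chart or load_flowchart()
    master = np.random.default_rng(seed)
    sub = lambda: int(master.integers(2**31))  # noqa: E731
    cases = generate_cases(n_cases, category_mix, p_uninformative, seed=sub(),
                           chart=chart)
    alloc = allocate([c.case for c in cases], [r.rater for r in raters],
                     METHODS, seed=sub())
    alloc = randomize_order(alloc, seed=sub())
    rng = np.random.default_rng(sub())
    profiles = {r.rater: r for r in raters}
    rows = []
    traces: list[TraceRecord] = []
    for case in cases:
        by_method = alloc.case_assignments[case.case]
        for rid in by_method["WHO-UMC"]:
            outcome = rate_whoumc(case, profiles[rid], rng)
            rows.append({"case": case.case, "rater": rid,
                         "method": "WHO-UMC", "outcome": outcome})
        for rid in by_method["LCAT"]:
            outcome, trace = evaluate(chart, answer_lcat(case, profiles[rid], rng))
            rows.append({"case": case.case, "rater": rid,
                         "method": "LCAT", "outcome": outcome})
            traces.append(TraceRecord(case=case.case, rater=rid, trace=trace))
    assessments = pd.DataFrame(rows)
    metadata = {
        "seed": seed,
        "n_cases": n_cases,
        "raters": [r.rater for r in raters],
        "category_mix": tuple(float(x) for x in np.asarray(category_mix)),
        "p_uninformative": p_uninformative,
        "rng": "numpy.random.default_rng(PCG64)",
    }
    return SimulatedStudy(assessments=assessments, trace_records=traces,
                          allocation=alloc, cases=cases, metadata=metadata)
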