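"""Decision-flowchart engine for the Liverpool ADR Causality Assessment Tool.

The LCAT arranges ten dichotomous questions into a flowchart that terminates
in one of four ordinal causality categories.  The chart is data, not code: it
is loaded from a small YAML definition (one block per question with its two
successors) and validated structurally.  A rater is modelled as a *responder*
function mapping a question to ``"positive"``, ``"negative"`` or
``"unanswerable"``; a responder who cannot answer a reached question "gets
stuck" and the assessment is coded ``unassessable``.

The engine also enumerates the complete unrolled decision tree, which is the
basis for structural diagnostics such as which questions can be bypassed and
through which answers a "definite" outcome can be reached.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import yaml

from .categories import ORDINAL_CATEGORIES

#: Canonical question identifiers, in the figure's reading order.  This order
#: is also the column order of the trace-file response strings.
QUESTION_IDS: tuple[str, ...] = (
    "Q1", "Q2a", "Q2b", "Q3a", "Q3b", "Q4a", "Q4b", "Q5a", "Q5b", "Q6",
)

POSITIVE = "positive"
NEGATIVE = "negative"
UNANSWERABLE = "unanswerable"
STUCK = "stuck"

Responder = Callable[[str], str]


class FlowchartError(ValueError):
    """Raised when a flowchart definition violates a structural invariant."""


@dataclass(frozen=True)
class FlowNode:
    """One decision node: a question and its two successors.

    A successor is either another question id or a terminal outcome category.
    ``positive_label`` / ``negative_label`` record which written responses are
    counted as positive/negative (e.g. "Yes / Unassessable" on Q3a, "Low" on
    Q4a).
    """

    question: str
    text: str
    on_positive: str
    on_negative: str
    positive_label: str = "Yes"
    negative_label: str = "No"

    def successor(self, response: str) -> str:
        if response == POSITIVE:
            return self.on_positive
        if response == NEGATIVE:
            return self.on_negative
        raise ValueError(f"not a binary response: {response!r}")

    def classify(self, answer: str) -> str:
        """Map a written answer to positive/negative using the node's labels."""
        token = answer.strip().lower()
        pos = {p.strip().lower() for p in self.positive_label.split("/")}
        neg = {n.strip().lower() for n in self.negative_label.split("/")}
        if token in pos:
            return POSITIVE
        if token in neg:
            return NEGATIVE
        raise ValueError(
            f"{self.question}: answer {answer!r} matches neither "
            f"{self.positive_label!r} nor {self.negative_label!r}"
        )


@dataclass(frozen=True)
class Trace:
    """One traversal: ordered (question, response) steps and a terminal.

    ``terminal`` is an outcome category, or :data:`STUCK` when the traversal
    halted at an unanswerable question (coded ``unassessable`` downstream).
    """

    steps: tuple[tuple[str, str], ...]
    terminal: str

    @property
    def stuck(self) -> bool:
        return self.terminal == STUCK

    def responses(self) -> dict[str, str]:
        return dict(self.steps)

    def visited(self) -> tuple[str, ...]:
        return tuple(q for q, _ in self.steps)


@dataclass(frozen=True)
class Flowchart:
    nodes: Mapping[str, FlowNode]
    start: str = "Q1"

    def __post_init__(self) -> None:
        _validate(self)

    def node(self, qid: str) -> FlowNode:
        return self.nodes[qid]


def _validate(chart: Flowchart) -> None:
    known = set(chart.nodes)
    missing = set(QUESTION_IDS) - known
    if missing:
        raise FlowchartError(f"missing node(s): {', '.join(sorted(missing))}")
    extra = known - set(QUESTION_IDS)
    if extra:
        raise FlowchartError(f"unknown question id(s): {', '.join(sorted(extra))}")
    if chart.start not in known:
        raise FlowchartError(f"start node {chart.start} is not defined")
    for qid, node in chart.nodes.items():
        for succ in (node.on_positive, node.on_negative):
            if succ not in known and succ not in ORDINAL_CATEGORIES:
                raise FlowchartError(
                    f"{qid}: dangling successor {succ!r} (neither a question "
                    f"nor one of {ORDINAL_CATEGORIES})"
                )
        if node.on_positive == node.on_negative:
            raise FlowchartError(f"{qid}: degenerate node, both branches lead to "
                                 f"{node.on_positive!r}")
    # Reachability from start.
    seen: set[str] = set()
    stack = [chart.start]
    while stack:
        qid = stack.pop()
        if qid in seen or qid in ORDINAL_CATEGORIES:
            continue
        seen.add(qid)
        node = chart.nodes[qid]
        stack.extend([node.on_positive, node.on_negative])
    unreachable = known - seen
    if unreachable:
        raise FlowchartError(f"unreachable node(s): {', '.join(sorted(unreachable))}")
    # Acyclicity via DFS colouring.
    state: dict[str, int] = {}

    def visit(qid: str) -> None:
        if qid in ORDINAL_CATEGORIES:
            return
        if state.get(qid) == 1:
            raise FlowchartError(f"cycle detected through {qid}")
        if state.get(qid) == 2:
            return
        state[qid] = 1
        node = chart.nodes[qid]
        visit(node.on_positive)
        visit(node.on_negative)
        state[qid] = 2

    visit(chart.start)


def load_flowchart(source: str | bytes | Mapping | None = None) -> Flowchart:
    """Load and validate a flowchart definition.

    ``source`` may be YAML text, a pre-parsed mapping, or ``None`` for the
    packaged LCAT definition.  Raises :class:`FlowchartError` for missing
    nodes, cycles, unreachable nodes or dangling successors.
    """
    if source is None:
        source = (
            importlib.resources.files("adragree") / "data" / "lcat.yaml"
        ).read_text()
    if isinstance(source, (str, bytes)):
        raw = yaml.safe_load(source)
    else:
        raw = source
    if not isinstance(raw, Mapping) or "nodes" not in raw:
        raise FlowchartError("flowchart definition must contain a 'nodes' mapping")
    nodes: dict[str, FlowNode] = {}
    for qid, block in raw["nodes"].items():
        kwargs = {
            "question": qid,
            "text": str(block.get("text", "")),
            "on_positive": str(block["on_positive"]),
            "on_negative": str(block["on_negative"]),
        }
        if "positive_label" in block:
            kwargs["positive_label"] = str(block["positive_label"])
        if "negative_label" in block:
            kwargs["negative_label"] = str(block["negative_label"])
        nodes[qid] = FlowNode(**kwargs)
    return Flowchart(nodes=nodes, start=str(raw.get("start", "Q1")))


def evaluate(chart: Flowchart, responder: Responder) -> tuple[str, Trace]:
    """Traverse the chart with a responder; return (outcome, trace).

    An ``"unanswerable"`` response at any reached node halts traversal: the
    outcome is ``unassessable`` and the trace's terminal is :data:`STUCK`.
    """
    steps: list[tuple[str, str]] = []
    current = chart.start
    while current not in ORDINAL_CATEGORIES:
        node = chart.node(current)
        response = responder(current)
        if response == UNANSWERABLE:
            return "unassessable", Trace(tuple(steps), STUCK)
        if response not in (POSITIVE, NEGATIVE):
            raise ValueError(f"responder returned {response!r} at {current}")
        steps.append((current, response))
        current = node.successor(response)
    return current, Trace(tuple(steps), current)


def scripted_responder(responses: Mapping[str, str]) -> Responder:
    """Responder that replays fixed responses; unanswerable where absent."""

    def _respond(qid: str) -> str:
        return responses.get(qid, UNANSWERABLE)

    return _respond


def enumerate_paths(chart: Flowchart) -> list[Trace]:
    """Every distinct root-to-outcome response sequence of the chart.

    The chart is acyclic so the unrolled decision tree is finite; each leaf is
    one complete path.  Returned traces replay exactly under :func:`evaluate`.
    """
    paths: list[Trace] = []

    def descend(qid: str, steps: tuple[tuple[str, str], ...]) -> None:
        if qid in ORDINAL_CATEGORIES:
            paths.append(Trace(steps, qid))
            return
        node = chart.node(qid)
        descend(node.on_positive, steps + ((qid, POSITIVE),))
        descend(node.on_negative, steps + ((qid, NEGATIVE),))

    descend(chart.start, ())
    return paths


@dataclass(frozen=True)
class TopologyReport:
    """Structural summary of a flowchart."""

    n_paths: int
    paths_per_outcome: dict[str, int]
    #: (question, response) edges that lead, possibly indirectly, to definite;
    #: restricted to the edges through which every definite path passes last.
    definite_gateways: frozenset[tuple[str, str]]
    #: questions that at least one complete path never visits
    bypassable: frozenset[str]
    definite_only_via: tuple[str, ...] = field(default=())

    def render(self) -> str:
        lines = [f"paths: {self.n_paths}"]
        for cat, k in sorted(self.paths_per_outcome.items()):
            lines.append(f"  {cat}: {k}")
        gw = ", ".join(f"{q}{'+' if r == POSITIVE else '-'}"
                       for q, r in sorted(self.definite_gateways))
        lines.append(f"definite reached only via: {gw}")
        lines.append("bypassable questions: " + ", ".join(sorted(self.bypassable)))
        return "\n".join(lines)


def validate_topology(chart: Flowchart) -> TopologyReport:
    """Report path counts, definite gateways and bypassable questions."""
    paths = enumerate_paths(chart)
    per_outcome: dict[str, int] = {c: 0 for c in ORDINAL_CATEGORIES}
    for p in paths:
        per_outcome[p.terminal] += 1
    gateways = frozenset(
        p.steps[-1] for p in paths if p.terminal == "definite"
    )
    visited_all = set(QUESTION_IDS)
    bypassable = {
        q for q in chart.nodes
        if any(q not in p.visited() for p in paths)
    } & visited_all
    return TopologyReport(
        n_paths=len(paths),
        paths_per_outcome=per_outcome,
        definite_gateways=gateways,
        bypassable=frozenset(bypassable),
        definite_only_via=tuple(sorted({q for q, _ in gateways})),
    )


def path_signature(trace: Trace) -> str:
    """Compact ten-character encoding of a trace over :data:`QUESTION_IDS`.

    ``+``/``-`` for answered questions, ``.`` for questions never reached.
    """
    responses = trace.responses()
    symbols = {POSITIVE: "+", NEGATIVE: "-"}
    return "".join(symbols.get(responses.get(q), ".") for q in QUESTION_IDS)


def trace_from_signature(
    chart: Flowchart, signature: str
) -> Trace:
    """Rebuild a trace by replaying a response string on the chart.

    The string follows :func:`path_signature`.  A ``.`` at a reached question
    reproduces a stuck traversal.
    """
    if len(signature) != len(QUESTION_IDS):
        raise ValueError(
            f"response string must have {len(QUESTION_IDS)} symbols, "
            f"got {len(signature)}"
        )
    mapping = {}
    for qid, sym in zip(QUESTION_IDS, signature):
        if sym == "+":
            mapping[qid] = POSITIVE
        elif sym == "-":
            mapping[qid] = NEGATIVE
        elif sym != ".":
            raise ValueError(f"bad response symbol {sym!r} for {qid}")
    _, trace = evaluate(chart, scripted_responder(mapping))
    return trace
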