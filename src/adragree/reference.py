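"""Fixtures of the motivating study's printed tables.

A published four-rater comparison of the LCAT against the WHO-UMC system on
48 adult drug-event pairs is the package's reference dataset.  Its printed
tables ship as small CSV fixtures:

* the pooled pairwise outcome cross-tabulations for each method (unordered
  rater pairs, pooled over the six pairs; upper triangle);
* the per-rater-pair agreement grid (n, agreement proportions, kappas);
* the per-question response counts with the published p-value column.

Because the study's deposited record-level file is not redistributed here,
:func:`reconstructed_assessments` rebuilds a record-level dataset *synthetic
in its rater assignment*: the multiset of outcome pairs per method is exactly
the printed cross-tabulation, and the rater pairs per case follow the printed
per-pair case counts (which are complementary across methods, as the
incomplete design requires), but which outcome pair belongs to which rater
pair is not printed and is assigned deterministically.  Every statistic that
depends only on the pooled tables (agreement proportions, specific agreement,
pooled-marginal global kappa, ICC) is invariant to that assignment.
"""

from __future__ import annotations

import importlib.resources
from io import StringIO

import numpy as np
import pandas as pd

from .agreement import PairedCrossTab
from .categories import CATEGORIES

CLINICIANS = ("1", "4")
PHARMACISTS = ("2", "3")


def _read(name: str) -> pd.DataFrame:
    text = (
        importlib.resources.files("adragree") / "data" / "reference" / name
    ).read_text()
    return pd.read_csv(StringIO(text))


def crosstab(method: str) -> PairedCrossTab:
    """The printed pooled cross-tabulation for ``"WHO-UMC"`` or ``"LCAT"``."""
    name = {
        "WHO-UMC": "table1_whoumc_crosstab.csv",
        "LCAT": "table2_lcat_crosstab.csv",
    }[method]
    df = _read(name).set_index("category")
    return PairedCrossTab(df.loc[list(CATEGORIES), list(CATEGORIES)].to_numpy(),
                          method=method)


def pairwise_grid() -> pd.DataFrame:
    """Printed per-rater-pair agreement statistics (both methods)."""
    df = _read("table3_pairwise.csv")
    df["rater_a"] = df["rater_a"].astype(str)
    df["rater_b"] = df["rater_b"].astype(str)
    return df


def question_responses() -> pd.DataFrame:
    """Printed per-question response counts per rater, with p-values."""
    return _read("table4_question_responses.csv").set_index("question")


def _pair_assignment() -> list[tuple[tuple[str, str], tuple[str, str], int]]:
    """Per-case rater pairs per method, consistent with the printed per-pair
    case counts.  The WHO-UMC pair determines the complementary LCAT pair."""
    grid = pairwise_grid()
    who = grid[grid["method"] == "WHO-UMC"]
    raters = {"1", "2", "3", "4"}
    blocks = []
    for _, row in who.iterrows():
        pair = (row["rater_a"], row["rater_b"])
        other = tuple(sorted(raters - set(pair)))
        blocks.append((pair, other, int(row["n"])))
    return blocks


def reconstructed_assessments() -> pd.DataFrame:
    """Record-level dataset in the assessment-file dialect (synthetic rater
    assignment; see module docstring).  48 cases x 2 methods x 2 raters.

    The outcome-pair multiset is dealt to the rater-pair blocks in a fixed
    interleaved order (seeded shuffle) so that every rater pair sees a
    representative spread of outcomes rather than runs of identical pairs;
    any such deal reproduces the pooled statistics exactly.
    """
    blocks = _pair_assignment()
    pairs = {m: _expand_pairs(crosstab(m)) for m in ("WHO-UMC", "LCAT")}
    rng = np.random.default_rng(20170224)
    for m in pairs:
        rng.shuffle(pairs[m])
    rows = []
    case = 0
    cursor = {m: 0 for m in pairs}
    for who_pair, lcat_pair, n in blocks:
        for _ in range(n):
            case += 1
            for method, rater_pair in (("WHO-UMC", who_pair), ("LCAT", lcat_pair)):
                a, b = pairs[method][cursor[method]]
                cursor[method] += 1
                rows.append({"case": case, "rater": rater_pair[0],
                             "method": method, "outcome": a})
                rows.append({"case": case, "rater": rater_pair[1],
                             "method": method, "outcome": b})
    return pd.DataFrame(rows)


def _expand_pairs(tab: PairedCrossTab) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for (a, b), c in sorted(tab.pair_counts().items()):
        out.extend([(a, b)] * c)
    return out


def agreement_indicators() -> dict[str, pd.Series]:
    """Per-case exact-agreement indicators for each method, from the
    reconstructed dataset (the marginal agreement counts are exact; the
    case-level pairing of the two indicators is synthetic)."""
    df = reconstructed_assessments()
    out = {}
    for method in ("WHO-UMC", "LCAT"):
        sub = df[df["method"] == method]
        agree = sub.groupby("case")["outcome"].nunique() == 1
        out[method] = agree.astype(int)
    return out
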