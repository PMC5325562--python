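"""Incomplete randomised allocation of raters and methods to cases.

The design removes the need for a washout period between the two assessment
methods: instead of every rater rating every case with every method, each case
is rated with one method by a random half of the raters and with the other
method by the remaining half.  Each rater therefore sees each case exactly
once.  Block randomisation keeps the rater-half x method combinations balanced
over consecutive cases, and each rater's assessment order is independently
permuted to dilute learning effects.

All randomness flows through a named, seeded :class:`numpy.random.Generator`
recorded in the allocation, so a design is reproducible from its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Allocation:
    """Per-case rater-to-method assignment plus per-rater assessment order."""

    methods: tuple[str, str]
    raters: tuple[str, ...]
    #: case id -> {method -> tuple of rater ids}
    case_assignments: dict[object, dict[str, tuple[str, ...]]]
    #: rater id -> ordered list of case ids
    rater_order: dict[str, list]
    seed: int | None = None
    rng_name: str = "numpy.random.default_rng(PCG64)"

    @property
    def cases(self) -> list:
        return list(self.case_assignments)

    def method_of(self, case, rater) -> str:
        for method, rs in self.case_assignments[case].items():
            if rater in rs:
                return method
        raise KeyError(f"rater {rater!r} not allocated to case {case!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long CSV dialect: case, method, rater, order index for that rater."""
        pos = {
            r: {c: i for i, c in enumerate(order)}
            for r, order in self.rater_order.items()
        }
        rows = [
            {"case": case, "method": m, "rater": r, "order": pos[r][case]}
            for case, by_method in self.case_assignments.items()
            for m, rs in by_method.items()
            for r in rs
        ]
        return pd.DataFrame(rows).sort_values(["case", "method", "rater"],
                                              ignore_index=True)

    def validate(self) -> None:
        full = set(self.raters)
        half = len(self.raters) // 2
        for case, by_method in self.case_assignments.items():
            sets = [set(rs) for rs in by_method.values()]
            if len(sets) != 2 or sets[0] & sets[1] or sets[0] | sets[1] != full:
                raise ValueError(f"case {case!r}: rater sets do not partition")
            if any(len(s) != half for s in sets):
                raise ValueError(f"case {case!r}: unequal method halves")
        for r in self.raters:
            if sorted(self.rater_order[r], key=repr) != sorted(self.cases, key=repr):
                raise ValueError(f"rater {r!r} order is not a permutation of cases")


def _half_method_combos(raters: tuple[str, ...], methods: tuple[str, str]):
    """All (half -> method) assignments: C(R, R/2) splits, both orientations
    counted once via assigning the half *containing the first rater*."""
    half = len(raters) // 2
    first = raters[0]
    combos = []
    for subset in itertools.combinations(raters, half):
        if first not in subset:
            continue  # complements handled by orientation
        other = tuple(r for r in raters if r not in subset)
        combos.append({methods[0]: subset, methods[1]: other})
        combos.append({methods[0]: other, methods[1]: subset})
    return combos


def allocate(cases, raters, methods, seed: int) -> Allocation:
    """Block-randomised incomplete allocation.

    Within each block of consecutive cases (block length = number of distinct
    rater-half x method combinations, 6 for four raters and two methods), every
    combination appears exactly once, in random order.  Deterministic per seed.
    """
    raters = tuple(raters)
    methods = tuple(methods)
    if len(raters) % 2:
        raise ValueError(f"rater count must be even, got {len(raters)}")
    if len(methods) != 2:
        raise ValueError("exactly two methods are required")
    rng = np.random.default_rng(seed)
    combos = _half_method_combos(raters, methods)
    assignments: dict[object, dict[str, tuple[str, ...]]] = {}
    cases = list(cases)
    if len(combos) <= 24:
        # balanced blocks of consecutive cases
        schedule: list[dict] = []
        while len(schedule) < len(cases):
            block = list(combos)
            rng.shuffle(block)
            schedule.extend(block)
        for case, combo in zip(cases, schedule):
            assignments[case] = {m: tuple(rs) for m, rs in combo.items()}
    else:
        # too many combinations to block: independent random halves
        for case in cases:
            half = rng.choice(len(combos))
            assignments[case] = {m: tuple(rs) for m, rs in combos[half].items()}
    order = {r: list(cases) for r in raters}
    alloc = Allocation(
        methods=methods,
        raters=raters,
        case_assignments=assignments,
        rater_order=order,
        seed=seed,
    )
    alloc.validate()
    return alloc


def randomize_order(alloc: Allocation, seed: int) -> Allocation:
    """Return a copy with each rater's case order uniformly permuted."""
    rng = np.random.default_rng(seed)
    new_order = {}
    for r in alloc.raters:
        cases = list(alloc.rater_order[r])
        rng.shuffle(cases)
        new_order[r] = cases
    return Allocation(
        methods=alloc.methods,
        raters=alloc.raters,
        case_assignments=alloc.case_assignments,
        rater_order=new_order,
        seed=alloc.seed,
    )


def sample_cases(population: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` unclustered drug-event pairs from a screened population.

    ``population`` has one row per (patient, admission, suspect drug).  At most
    one admission per patient enters the sample (chosen at random), and when an
    admission lists several suspect drugs one is chosen at random, yielding one
    drug-event pair per sampled patient.
    """
    required = {"patient", "admission", "drug"}
    if not required.issubset(population.columns):
        raise ValueError(f"population must have columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    patients = population["patient"].unique()
    if n > len(patients):
        raise ValueError(
            f"requested {n} cases but only {len(patients)} distinct patients"
        )
    chosen = rng.choice(patients, size=n, replace=False)
    rows = []
    for i, patient in enumerate(chosen, start=1):
        sub = population[population["patient"] == patient]
        admission = rng.choice(sub["admission"].unique())
        drugs = sub.loc[sub["admission"] == admission, "drug"].unique()
        drug = rng.choice(drugs)
        rows.append(
            {"case": i, "patient": patient, "admission": admission, "drug": drug}
        )
    return pd.DataFrame(rows)
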