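"""Interrater agreement statistics for two-arm causality assessment studies.

Implements the full comparison suite for ratings on the five-category scale
(four ordinal causality categories plus "unassessable"):

* agreement proportions — exact agreement, extreme disagreement (non-adjacent
  ordinal categories, or exactly one rating unassessable), and the proportion
  of specific agreement per category;
* pairwise Cohen kappa, unweighted on the full 5x5 table and linearly weighted
  on the 4x4 ordinal table after removing cases with any unassessable rating;
* the Stuart-Maxwell test of marginal homogeneity;
* a global kappa for incomplete designs (not every rater rates every case):
  observed agreement pooled over within-case rating pairs, chance agreement
  from rating marginals with raters treated as interchangeable, and a
  leave-one-case-out jackknife confidence interval.  Two chance-agreement
  variants are provided because the construction admits alternatives:
  ``pe="pooled"`` uses the pooled marginal distribution of all ratings, while
  ``pe="per_rater"`` averages products of per-rater marginals over co-rating
  rater pairs;
* ICC(1,1): one-way random-effects, absolute-agreement, single-measures
  intraclass correlation with the exact F-based confidence interval;
* paired comparisons between the two methods: difference in exact agreement
  with a McNemar test, and a paired t comparison of pairwise kappas;
* a sensitivity analysis treating "unassessable" ratings as missing.

Standard single-table statistics (Cohen kappa, Stuart-Maxwell, McNemar) are
delegated to :mod:`statsmodels`; the incomplete-design global kappa, the
agreement proportions and the ICC are computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats import inter_rater
from statsmodels.stats.contingency_tables import SquareTable, mcnemar

from .categories import (
    CATEGORIES,
    ORDINAL_CATEGORIES,
    ORDINAL_RANK,
    UNASSESSABLE,
    ordinal_distance,
)

K_ORDINAL = len(ORDINAL_CATEGORIES)


@dataclass
class JackknifeEstimate:
    """Leave-one-case-out jackknife: pseudo-values, SE and a t-based CI."""

    estimate: float
    pseudo_values: np.ndarray
    se: float
    ci_low: float
    ci_high: float

    @property
    def n(self) -> int:
        return len(self.pseudo_values)


@dataclass
class AgreementStatistic:
    """A named estimate with optional CI, p-value and bookkeeping fields."""

    name: str
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_used: int | None = None
    method: str | None = None
    jackknife: JackknifeEstimate | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and np.isfinite(self.estimate)
            and not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12)
        ):
            raise ValueError(
                f"{self.name}: estimate {self.estimate} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


class PairedCrossTab:
    """5x5 count table of two ratings per case for one method.

    Row/column order is the category order definite, probable, possible,
    unlikely, unassessable.  Printed study tables pool unordered rater pairs
    into one triangle; all statistics defined here are invariant to which
    triangle holds a pair, and marginals per category are taken over both
    ratings.
    """

    def __init__(self, counts, method: str | None = None):
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (5, 5) or (counts < 0).any():
            raise ValueError("counts must be a nonnegative 5x5 array")
        self.counts = counts
        self.method = method

    @classmethod
    def from_pairs(cls, pairs, method: str | None = None) -> "PairedCrossTab":
        """Build from an iterable of (category, category) label pairs."""
        counts = np.zeros((5, 5), dtype=int)
        idx = {c: i for i, c in enumerate(CATEGORIES)}
        for a, b in pairs:
            counts[idx[a], idx[b]] += 1
        return cls(counts, method=method)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def pair_counts(self) -> dict[tuple[str, str], int]:
        """Unordered pair multiset (upper-triangle pooled)."""
        out: dict[tuple[str, str], int] = {}
        for i, a in enumerate(CATEGORIES):
            for j, b in enumerate(CATEGORIES):
                c = int(self.counts[i, j])
                if not c:
                    continue
                key = (a, b) if i <= j else (b, a)
                out[key] = out.get(key, 0) + c
        return out

    def category_totals(self) -> pd.Series:
        """Ratings per category pooled over both raters (sums to 2n)."""
        totals = self.counts.sum(axis=0) + self.counts.sum(axis=1)
        return pd.Series(totals, index=list(CATEGORIES), name="ratings")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CATEGORIES),
                            columns=list(CATEGORIES))

    def drop_unassessable(self) -> "PairedCrossTab":
        """Remove all pairs in which either rating is unassessable (keeps the
        5x5 shape with an all-zero last row/column)."""
        counts = self.counts.copy()
        counts[4, :] = 0
        counts[:, 4] = 0
        return PairedCrossTab(counts, method=self.method)


def build_crosstab(
    assessments: pd.DataFrame,
    method: str | None = None,
    per_pair: bool = False,
):
    """Cross-tabulate the two ratings each case received under one method.

    ``assessments`` is long-format with columns ``case``, ``rater``,
    ``outcome`` (labels) and, if ``method`` is given, ``method``.  Every case
    must carry exactly two ratings.  With ``per_pair=True`` a dict keyed by
    the sorted rater pair is returned instead of one pooled table.
    """
    df = assessments
    if method is not None:
        df = df[df["method"] == method]
    tables: dict[tuple, list] = {}
    pooled: list[tuple[str, str]] = []
    for case, grp in df.groupby("case", sort=True):
        if len(grp) != 2:
            raise ValueError(
                f"case {case!r} has {len(grp)} ratings for this method; "
                "exactly two are required"
            )
        grp = grp.sort_values("rater")
        a, b = grp["outcome"].tolist()
        pooled.append((a, b))
        key = tuple(grp["rater"].tolist())
        tables.setdefault(key, []).append((a, b))
    if per_pair:
        return {
            k: PairedCrossTab.from_pairs(v, method=method)
            for k, v in tables.items()
        }
    return PairedCrossTab.from_pairs(pooled, method=method)


# ---------------------------------------------------------------------------
# agreement proportions


def exact_agreement(tab: PairedCrossTab) -> float:
    """Proportion of cases rated to the same category (unassessable included)."""
    if tab.n == 0:
        raise ValueError("empty table")
    return float(np.trace(tab.counts)) / tab.n


def extreme_disagreement(tab: PairedCrossTab) -> float:
    """Proportion of case-pairs in non-adjacent ordinal categories, plus pairs
    where exactly one rating is unassessable."""
    if tab.n == 0:
        raise ValueError("empty table")
    total = 0
    for (a, b), c in tab.pair_counts().items():
        one_sided = (a == UNASSESSABLE) != (b == UNASSESSABLE)
        dist = ordinal_distance(a, b)
        if one_sided or (dist is not None and dist >= 2):
            total += c
    return total / tab.n


def specific_agreement(tab: PairedCrossTab, category: str) -> float:
    """Ps(k) = 2 n_kk / (2 n_kk + sum of off-diagonal counts involving k).

    The probability that, given one rater chose ``category``, the other did
    too.  Returns NaN when the category was never used.
    """
    k = list(CATEGORIES).index(category)
    diag = int(tab.counts[k, k])
    off = int(tab.counts[k, :].sum() + tab.counts[:, k].sum() - 2 * diag)
    denom = 2 * diag + off
    if denom == 0:
        return math.nan
    return 2 * diag / denom


def specific_agreement_table(tab: PairedCrossTab) -> pd.Series:
    return pd.Series(
        {c: specific_agreement(tab, c) for c in CATEGORIES},
        name="specific_agreement",
    )


# ---------------------------------------------------------------------------
# kappas


def linear_weights(k: int = K_ORDINAL) -> np.ndarray:
    """w_ij = 1 - |i - j| / (k - 1) on the ordinal categories."""
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def cohen_kappa(tab: PairedCrossTab, weights: str | None = None) -> AgreementStatistic:
    """Pairwise Cohen kappa via :mod:`statsmodels`.

    ``weights=None`` uses the full 5x5 table; ``weights="linear"`` first drops
    every case with an unassessable rating and applies linear weights on the
    remaining 4x4 ordinal table.
    """
    if weights not in (None, "linear"):
        raise ValueError(f"weights must be None or 'linear', got {weights!r}")
    if weights == "linear":
        counts = tab.drop_unassessable().counts[:K_ORDINAL, :K_ORDINAL]
        name = "cohen_kappa_linear"
    else:
        counts = tab.counts
        name = "cohen_kappa"
    with np.errstate(divide="ignore", invalid="ignore"):
        res = inter_rater.cohens_kappa(
            counts, wt="linear" if weights == "linear" else None)
    n = int(counts.sum())
    if not np.isfinite(res.kappa):
        return AgreementStatistic(name=name, estimate=math.nan, n_used=n,
                                  method=tab.method,
                                  extra={"undefined": "degenerate marginals"})
    ci_low = ci_high = None
    if np.isfinite(res.kappa_low) and np.isfinite(res.kappa_upp):
        ci_low = float(min(res.kappa_low, res.kappa))
        ci_high = float(max(res.kappa_upp, res.kappa))
    return AgreementStatistic(
        name=name,
        estimate=float(res.kappa),
        ci_low=ci_low,
        ci_high=ci_high,
        n_used=n,
        method=tab.method,
    )


def stuart_maxwell(tab: PairedCrossTab) -> AgreementStatistic:
    """Stuart-Maxwell chi-square test of marginal homogeneity.

    Categories that neither rater ever used are dropped first so the
    covariance matrix stays non-singular.  On a 2x2 table the statistic
    reduces exactly to McNemar's (b - c)^2 / (b + c).
    """
    counts = tab.counts
    used = (counts.sum(axis=0) + counts.sum(axis=1)) > 0
    counts = counts[np.ix_(used, used)]
    k = counts.shape[0]
    if k < 2:
        raise ValueError("need at least two used categories")
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = SquareTable(counts, shift_zeros=False).homogeneity(
                method="stuart_maxwell")
    except np.linalg.LinAlgError:
        res = None
    if res is None or not np.isfinite(res.statistic):
        return AgreementStatistic(
            name="stuart_maxwell", estimate=math.nan,
            n_used=int(counts.sum()), method=tab.method,
            extra={"undefined": "singular covariance"},
        )
    return AgreementStatistic(
        name="stuart_maxwell",
        estimate=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=int(counts.sum()),
        method=tab.method,
        extra={"df": int(res.df), "k_used": k},
    )


# ---------------------------------------------------------------------------
# global kappa for the incomplete design


def _case_ratings(assessments: pd.DataFrame, weights: str | None):
    """Group ratings by case; for the weighted version drop cases containing
    any unassessable rating.  Returns (list of (case, [outcomes]), weight W)."""
    groups = []
    for case, grp in assessments.groupby("case", sort=True):
        outs = grp["outcome"].tolist()
        raters = grp["rater"].tolist()
        if len(outs) < 2:
            raise ValueError(f"case {case!r} has fewer than two ratings")
        if weights == "linear" and UNASSESSABLE in outs:
            continue
        groups.append((case, raters, outs))
    if weights == "linear":
        cats = list(ORDINAL_CATEGORIES)
        w = linear_weights(len(cats))
    else:
        cats = list(CATEGORIES)
        w = np.eye(len(cats))
    return groups, cats, w


def _kappa_from_groups(groups, cats, w, pe_variant: str) -> float:
    idx = {c: i for i, c in enumerate(cats)}
    # observed: mean pair weight, cases weighted equally
    po_terms = []
    for _case, _raters, outs in groups:
        pairs = list(itertools.combinations(outs, 2))
        po_terms.append(np.mean([w[idx[a], idx[b]] for a, b in pairs]))
    po = float(np.mean(po_terms))
    if pe_variant == "pooled":
        marg = np.zeros(len(cats))
        for _case, _raters, outs in groups:
            for o in outs:
                marg[idx[o]] += 1
        p = marg / marg.sum()
        pe = float(p @ w @ p)
    elif pe_variant == "per_rater":
        # average over co-rating rater pairs, weighted by cases shared
        per_rater: dict[object, np.ndarray] = {}
        for _case, raters, outs in groups:
            for r, o in zip(raters, outs):
                per_rater.setdefault(r, np.zeros(len(cats)))[idx[o]] += 1
        p_r = {r: v / v.sum() for r, v in per_rater.items()}
        pair_weight: dict[tuple, int] = {}
        for _case, raters, _outs in groups:
            for r, s in itertools.combinations(sorted(raters, key=repr), 2):
                pair_weight[(r, s)] = pair_weight.get((r, s), 0) + 1
        num = sum(
            wgt * float(p_r[r] @ w @ p_r[s]) for (r, s), wgt in pair_weight.items()
        )
        pe = num / sum(pair_weight.values())
    else:
        raise ValueError(f"unknown pe variant {pe_variant!r}")
    if pe >= 1.0:
        return math.nan
    return (po - pe) / (1.0 - pe)


def global_kappa(
    assessments: pd.DataFrame,
    weights: str | None = None,
    pe: str = "pooled",
    ci: bool = True,
    alpha: float = 0.05,
) -> AgreementStatistic:
    """Overall kappa over all rater pairs under an incomplete design.

    Observed agreement is the mean within-case pair agreement (pair weight for
    the linearly weighted version); chance agreement treats raters as
    interchangeable (``pe="pooled"``) or uses per-rater marginals averaged
    over co-rating pairs (``pe="per_rater"``).  The CI is
    ``estimate +/- t(n-1) * SE`` with the jackknife SE from leave-one-case-out
    pseudo-values.
    """
    groups, cats, w = _case_ratings(assessments, weights)
    n = len(groups)
    if n == 0:
        raise ValueError("no usable cases")
    theta = _kappa_from_groups(groups, cats, w, pe)
    name = "global_kappa" + ("_linear" if weights == "linear" else "")
    stat = AgreementStatistic(
        name=name, estimate=theta, n_used=n, extra={"pe_variant": pe}
    )
    if ci and n > 2 and np.isfinite(theta):
        loo = np.array([
            _kappa_from_groups(groups[:i] + groups[i + 1:], cats, w, pe)
            for i in range(n)
        ])
        pseudo = n * theta - (n - 1) * loo
        se = float(pseudo.std(ddof=1) / math.sqrt(n))
        tq = stats.t.ppf(1 - alpha / 2, n - 1)
        jk = JackknifeEstimate(
            estimate=theta,
            pseudo_values=pseudo,
            se=se,
            ci_low=theta - tq * se,
            ci_high=theta + tq * se,
        )
        stat.jackknife = jk
        stat.ci_low, stat.ci_high = jk.ci_low, jk.ci_high
    return stat


# ---------------------------------------------------------------------------
# ICC(1,1)


def icc_oneway(
    assessments: pd.DataFrame,
    coding: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> AgreementStatistic:
    """ICC(1,1): one-way random-effects, absolute agreement, single measures.

    Cases with any unassessable rating are excluded; the remaining ordinal
    categories are coded 1..4 (ICC is invariant to affine recoding).  The CI
    is the exact F-based interval for the one-way model.  Ratings may also be
    supplied pre-coded as numbers in an ``outcome`` column.
    """
    coding = coding or dict(ORDINAL_RANK)
    values: list[list[float]] = []
    for case, grp in assessments.groupby("case", sort=True):
        outs = grp["outcome"].tolist()
        if any(o == UNASSESSABLE for o in outs):
            continue
        row = [float(coding.get(o, o) if isinstance(o, str) else o) for o in outs]
        if len(row) < 2:
            raise ValueError(f"case {case!r} has fewer than two ratings")
        values.append(row)
    if not values:
        raise ValueError("no assessable cases")
    k_sizes = {len(v) for v in values}
    if len(k_sizes) != 1:
        raise ValueError("unequal ratings per case; one-way ICC needs a fixed k")
    k = k_sizes.pop()
    data = np.asarray(values, dtype=float)
    n = data.shape[0]
    grand = data.mean()
    case_means = data.mean(axis=1)
    msb = k * ((case_means - grand) ** 2).sum() / (n - 1)
    msw = ((data - case_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msb == 0:
        return AgreementStatistic(
            name="icc_1_1", estimate=math.nan, n_used=n,
            extra={"undefined": "zero between-case variance"},
        )
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if msw == 0:
        # perfect within-case agreement: the F-interval degenerates at 1
        ci_low = ci_high = 1.0
    else:
        f_obs = msb / msw
        df1, df2 = n - 1, n * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (f_l - 1) / (f_l + k - 1)
        ci_high = (f_u - 1) / (f_u + k - 1)
    return AgreementStatistic(
        name="icc_1_1",
        estimate=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_used=n,
        extra={"msb": float(msb), "msw": float(msw), "k": k},
    )


# ---------------------------------------------------------------------------
# method comparisons


def compare_exact_agreement(
    agree_a: pd.Series,
    agree_b: pd.Series,
    continuity: bool = False,
    ci_method: str = "wald_paired",
    alpha: float = 0.05,
) -> AgreementStatistic:
    """Difference in exact-agreement proportions on the same cases.

    ``agree_a``/``agree_b`` are per-case 0/1 indicators indexed by case id for
    the two methods.  Returns the paired difference with a Wald CI
    (``wald_paired`` by default, ``wald_independent`` behind the flag) and the
    McNemar chi-square p-value on the discordant counts (no continuity
    correction unless requested).
    """
    if set(agree_a.index) != set(agree_b.index):
        raise ValueError("the two indicators must cover the same cases")
    b_ = agree_b.reindex(agree_a.index)
    a = agree_a.astype(int)
    b_ = b_.astype(int)
    n = len(a)
    n10 = int(((a == 1) & (b_ == 0)).sum())
    n01 = int(((a == 0) & (b_ == 1)).sum())
    diff = (n10 - n01) / n
    if ci_method == "wald_paired":
        var = (n10 + n01) / n**2 - diff**2 / n
        se = math.sqrt(max(var, 0.0))
    elif ci_method == "wald_independent":
        pa, pb = a.mean(), b_.mean()
        se = math.sqrt(pa * (1 - pa) / n + pb * (1 - pb) / n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = stats.norm.ppf(1 - alpha / 2)
    table = [[int(((a == 1) & (b_ == 1)).sum()), n10],
             [n01, int(((a == 0) & (b_ == 0)).sum())]]
    if n10 + n01 == 0:
        p = 1.0
    else:
        p = float(mcnemar(table, exact=False, correction=continuity).pvalue)
    return AgreementStatistic(
        name="exact_agreement_difference",
        estimate=diff,
        ci_low=diff - z * se,
        ci_high=diff + z * se,
        p_value=p,
        n_used=n,
        extra={"discordant": (n10, n01), "ci_method": ci_method},
    )


def compare_pairwise_kappas(
    kappas_a, kappas_b, alpha: float = 0.05
) -> AgreementStatistic:
    """Paired t comparison of pairwise kappas matched by rater pair."""
    a = np.asarray(kappas_a, dtype=float)
    b = np.asarray(kappas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("kappa vectors must have equal length")
    d = a - b
    n = len(d)
    t_res = stats.ttest_rel(a, b)
    tq = stats.t.ppf(1 - alpha / 2, n - 1)
    se = d.std(ddof=1) / math.sqrt(n)

    def _mean_ci(x):
        m = x.mean()
        s = x.std(ddof=1) / math.sqrt(len(x))
        return m, m - tq * s, m + tq * s

    ma, la, ha = _mean_ci(a)
    mb, lb, hb = _mean_ci(b)
    return AgreementStatistic(
        name="pairwise_kappa_difference",
        estimate=float(d.mean()),
        ci_low=float(d.mean() - tq * se),
        ci_high=float(d.mean() + tq * se),
        p_value=float(t_res.pvalue),
        n_used=n,
        extra={
            "mean_a": (float(ma), float(la), float(ha)),
            "mean_b": (float(mb), float(lb), float(hb)),
        },
    )


# ---------------------------------------------------------------------------
# method-level suite and sensitivity analysis


def method_suite(
    assessments: pd.DataFrame, method: str, pe: str = "pooled"
) -> dict[str, object]:
    """All single-method statistics from long-format assessments."""
    sub = assessments[assessments["method"] == method]
    tab = build_crosstab(sub)
    tab.method = method
    out: dict[str, object] = {
        "crosstab": tab,
        "exact_agreement": exact_agreement(tab),
        "extreme_disagreement": extreme_disagreement(tab),
        "specific_agreement": specific_agreement_table(tab),
        "global_kappa": global_kappa(sub, pe=pe),
        "global_kappa_linear": global_kappa(sub, weights="linear", pe=pe),
        "icc_1_1": icc_oneway(sub),
    }
    per_pair = build_crosstab(sub, per_pair=True)
    rows = []
    for pair, ptab in sorted(per_pair.items()):
        try:
            sm_p = stuart_maxwell(ptab).p_value
        except ValueError:  # fewer than two used categories
            sm_p = math.nan
        row = {
            "pair": pair,
            "n": ptab.n,
            "exact_agreement": exact_agreement(ptab),
            "extreme_disagreement": extreme_disagreement(ptab),
            "kappa": cohen_kappa(ptab).estimate,
            "kappa_linear": cohen_kappa(ptab, weights="linear").estimate,
            "stuart_maxwell_p": sm_p,
        }
        rows.append(row)
    out["per_pair"] = pd.DataFrame(rows)
    return out


def sensitivity_unassessable_missing(
    assessments: pd.DataFrame, pe: str = "pooled"
) -> dict[str, dict[str, object]]:
    """Recompute the full suite treating unassessable ratings as missing.

    Unassessable ratings are dropped; any case left with fewer than two
    ratings for a method is excluded from that method's statistics.
    """
    kept = assessments[assessments["outcome"] != UNASSESSABLE]
    out = {}
    for method in kept["method"].unique():
        sub = kept[kept["method"] == method]
        counts = sub.groupby("case").size()
        ok = counts[counts >= 2].index
        out[method] = method_suite(sub[sub["case"].isin(ok)], method, pe=pe)
    return out
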