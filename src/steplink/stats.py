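"""Linkage-quality metrics and linked-vs-unlinked representativeness tests.

Quality against a known truth map is summarized as sensitivity (true pairs
recovered), positive predictive value (made links that are true) and their
harmonic mean. Representativeness of the linked subpopulation is assessed by
comparing linked and non-linked patients covariate by covariate, with the
Pearson chi-square test (no continuity correction) for categorical variables,
switching to the Fisher exact test when any expected cell count falls below
5, and the pooled two-sample Student t-test for continuous variables. The
three tests are implemented here from first principles; only the Student-t
tail probability is delegated to the standard incomplete-beta routine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .model import LinkResult, SourceRecord


# ---------------------------------------------------------------------------
# Linkage quality against ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkageQuality:
    sensitivity: float
    ppv: Optional[float]
    f1: Optional[float]
    ambiguity_rate: float
    n_links: int
    n_truth: int


def confusion_metrics(links: Mapping[str, str], truth: Mapping[str, str],
                      n_ambiguous: int = 0,
                      n_clinical: Optional[int] = None) -> LinkageQuality:
    """Sensitivity / PPV / F1 of a one-to-one link set against a truth map.

    A link is correct iff it equals a truth pair. With no links made, PPV (and
    hence F1) is undefined and reported as None.
    """
    if len(set(links.values())) != len(links):
        raise ValueError("links are not one-to-one")
    correct = sum(1 for c, s in links.items() if truth.get(c) == s)
    sens = correct / len(truth) if truth else 0.0
    ppv = correct / len(links) if links else None
    f1 = None
    if ppv is not None and (sens + ppv) > 0:
        f1 = 2 * sens * ppv / (sens + ppv)
    elif ppv is not None:
        f1 = 0.0
    denom = n_clinical if n_clinical else max(len(truth), 1)
    return LinkageQuality(sens, ppv, f1, n_ambiguous / denom,
                          len(links), len(truth))


# ---------------------------------------------------------------------------
# 2x2 tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = (non-linked, linked) and columns = (no, yes)."""

    a: int  # non-linked, no
    b: int  # non-linked, yes
    c: int  # linked, no
    d: int  # linked, yes

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> Tuple[float, float, float, float]:
        r1 = self.a + self.b
        r2 = self.c + self.d
        c1 = self.a + self.c
        c2 = self.b + self.d
        n = self.n
        return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


class DegenerateTableError(ValueError):
    """A margin of the table is zero; the test statistic is undefined."""


def pearson_chi2(t: ContingencyTable2x2) -> Tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    The p-value is the upper chi-square(1) tail, computed as
    ``erfc(sqrt(X/2))``.
    """
    exp = t.expected
    if any(e == 0 for e in exp):
        raise DegenerateTableError("zero margin: chi-square undefined")
    obs = (t.a, t.b, t.c, t.d)
    stat = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    p = math.erfc(math.sqrt(stat / 2.0))
    return stat, min(p, 1.0)


def _log_hyper(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(top-left cell = a) under fixed margins (hypergeometric)."""
    b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
    lg = math.lgamma
    return (lg(r1 + 1) + lg(r2 + 1) + lg(c1 + 1) + lg(r1 + r2 - c1 + 1)
            - lg(r1 + r2 + 1) - lg(a + 1) - lg(b + 1) - lg(c + 1) - lg(d + 1))


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Sums, over every table with the observed margins, the hypergeometric
    probabilities no larger than the observed table's (to a relative
    tolerance of 1e-7). A table with a zero margin admits a single
    configuration and yields p = 1.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if lo == hi:
        return 1.0
    logp_obs = _log_hyper(t.a, r1, r2, c1)
    total = 0.0
    for a in range(lo, hi + 1):
        lp = _log_hyper(a, r1, r2, c1)
        if lp <= logp_obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def student_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test.

    With zero pooled variance the statistic is degenerate: p = 1 for equal
    means, p = 0 otherwise (both flagged by a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        warnings.warn("zero pooled variance: degenerate t-test", stacklevel=2)
        return (0.0, 1.0) if diff == 0.0 else (math.inf, 0.0)
    stat = diff / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2.0 * special.stdtr(df, -abs(stat))
    return stat, float(p)


# ---------------------------------------------------------------------------
# Representativeness report (linked vs non-linked)
# ---------------------------------------------------------------------------


def records_to_covariates(records: Iterable[SourceRecord]) -> pd.DataFrame:
    """Derive the standard comparison covariates from patient records."""
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "sex_female": None if r.sex is None else int(r.sex.value == "F"),
            "birth_year": None if r.birth_date is None else float(r.birth_date.year),
            "surgery": int(r.has(6) or r.has(7)),
            "endoscopic_treatment": int(r.has(11)),
            "chemotherapy": int(r.has(9)),
            "radiotherapy": int(r.has(10)),
        })
    return pd.DataFrame(rows)


def representativeness_report(linked: pd.DataFrame, nonlinked: pd.DataFrame,
                              covariates: Mapping[str, str],
                              alpha: float = 0.05) -> pd.DataFrame:
    """Compare linked and non-linked populations covariate by covariate.

    ``covariates`` maps column name to kind ("binary" or "continuous").
    Binary covariates yield a 2x2 table tested by Pearson chi-square, or by
    Fisher exact when any expected cell is below 5; continuous covariates use
    the pooled t-test. Covariates absent from either frame are skipped with a
    warning. Returns one row per covariate with counts, the test used, the
    two-sided p and a significance flag at ``alpha``.
    """
    rows = []
    if len(nonlinked) == 0 or len(linked) == 0:
        warnings.warn("one comparison group is empty; report is empty",
                      stacklevel=2)
        return pd.DataFrame(columns=["covariate", "test", "statistic", "p",
                                     "significant"])
    for name, kind in covariates.items():
        if name not in linked.columns or name not in nonlinked.columns:
            warnings.warn(f"covariate {name!r} absent from records; skipped",
                          stacklevel=2)
            continue
        xl = linked[name].dropna()
        xn = nonlinked[name].dropna()
        if kind == "continuous":
            stat, p = student_t(xn.to_numpy(), xl.to_numpy())
            rows.append({"covariate": name, "test": "student_t",
                         "statistic": stat, "p": p,
                         "nonlinked_mean": float(xn.mean()),
                         "linked_mean": float(xl.mean()),
                         "significant": p < alpha})
            continue
        tab = ContingencyTable2x2(
            a=int((xn == 0).sum()), b=int((xn == 1).sum()),
            c=int((xl == 0).sum()), d=int((xl == 1).sum()))
        if min(tab.expected) < 5:
            p = fisher_exact(tab)
            rows.append({"covariate": name, "test": "fisher_exact",
                         "statistic": math.nan, "p": p,
                         "nonlinked_yes": tab.b, "linked_yes": tab.d,
                         "significant": p < alpha})
        else:
            stat, p = pearson_chi2(tab)
            rows.append({"covariate": name, "test": "pearson_chi2",
                         "statistic": stat, "p": p,
                         "nonlinked_yes": tab.b, "linked_yes": tab.d,
                         "significant": p < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Step summary
# ---------------------------------------------------------------------------


def round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def step_summary_table(step_counts: Sequence[Tuple[str, int]],
                       n_clinical: int) -> pd.DataFrame:
    """Per-substep link counts with cumulative percentage of the cohort.

    Percentages are 100 * running-sum / cohort size, rounded half-up to one
    decimal place (the convention of the published summary tables).
    """
    if n_clinical <= 0:
        raise ValueError("cohort size must be positive")
    rows = []
    running = 0
    for step_id, n in step_counts:
        running += n
        rows.append({"step": step_id, "n_linked": n,
                     "cumulative_linked": running,
                     "cumulative_pct": round_half_up_1dp(100.0 * running / n_clinical)})
    return pd.DataFrame(rows)


def summarize_result(result: LinkResult, n_clinical: int) -> pd.DataFrame:
    return step_summary_table(result.step_counts, n_clinical)
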