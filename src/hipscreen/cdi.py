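"""CFSE cell-division-index (CDI) analysis.

The CDI is the ratio of divided (CFSE-dim) CD4+ cells counted per 5,000
undivided (CFSE-bright) cells with antigen versus without antigen.  A CDI
of at least 3.0 is a positive proliferative response.  Cohorts (e.g. T1D
versus HLA-matched controls) are compared by responder fractions with a
one-tailed exact Mann-Whitney rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CdiSample",
    "compute_cdi",
    "samples_from_counts",
    "call_responders",
    "exact_rank_test",
    "cohort_heatmap_table",
]

DEFAULT_THRESHOLD = 3.0


@dataclass(frozen=True)
class CdiSample:
    subject: str
    group: str
    antigen: str
    dim_with: float  # divided cells with antigen, per 5,000 bright
    dim_without: float  # divided cells without antigen, per 5,000 bright
    cdi: float
    positive: bool
    zero_denominator: bool = False


def compute_cdi(dim_with: float, dim_without: float) -> tuple[float, bool]:
    """CDI = dim_with / dim_without.

    A zero denominator (no background division at all) is floored at 1 so
    the ratio stays defined; the flag keeps such samples auditable.
    Returns (cdi, zero_denominator_flag).
    """
    if dim_with < 0 or dim_without < 0:
        raise ValueError("cell counts must be non-negative")
    if dim_without == 0:
        return float(dim_with), True
    return dim_with / dim_without, False


def samples_from_counts(
    counts: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> list[CdiSample]:
    """Build CdiSamples from a counts table with columns
    ``subject, group, antigen, dim_with, dim_without``."""
    out = []
    for row in counts.itertuples(index=False):
        cdi, flagged = compute_cdi(row.dim_with, row.dim_without)
        out.append(
            CdiSample(
                subject=row.subject,
                group=row.group,
                antigen=row.antigen,
                dim_with=row.dim_with,
                dim_without=row.dim_without,
                cdi=cdi,
                positive=cdi >= threshold,
                zero_denominator=flagged,
            )
        )
    return out


def call_responders(
    samples: Sequence[CdiSample], threshold: float = DEFAULT_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(subject x antigen responder indicator matrix,
    per-antigen responder fraction per group).

    The threshold comparison is inclusive: CDI >= threshold is positive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rows = [
        {
            "subject": s.subject,
            "group": s.group,
            "antigen": s.antigen,
            "responder": s.cdi >= threshold,
        }
        for s in samples
    ]
    df = pd.DataFrame(rows)
    indicators = df.pivot_table(
        index=["group", "subject"], columns="antigen", values="responder", aggfunc="any"
    )
    fractions = (
        df.groupby(["group", "antigen"])["responder"].mean().unstack("antigen")
    )
    return indicators, fractions


def exact_rank_test(
    group_a: Sequence[float], group_b: Sequence[float], tail: str = "one"
) -> float:
    """Mann-Whitney rank-sum p-value; one-tailed alternative is that
    ``group_b`` tends larger than ``group_a``.

    The null is enumerated exactly (all assignments of the pooled values to
    the two groups, so ties are handled exactly) when the combined sample
    size is at most 20; larger samples use the normal approximation with
    tie correction.
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(a), len(b)
    if n + m <= 20:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        observed = ranks[:n].sum()
        idx = range(n + m)
        sums = np.array([ranks[list(c)].sum() for c in combinations(idx, n)])
        # alternative b > a <=> rank sum of a is small
        p_low = float((sums <= observed + 1e-9).mean())
        if tail == "one":
            return p_low
        p_high = float((sums >= observed - 1e-9).mean())
        return min(1.0, 2.0 * min(p_low, p_high))
    alternative = "less" if tail == "one" else "two-sided"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def cohort_heatmap_table(
    samples: Sequence[CdiSample],
    threshold: float = DEFAULT_THRESHOLD,
    masked: str = "",
    not_determined: str = "X",
) -> pd.DataFrame:
    """Subject x antigen CDI matrix for heat-map display: sub-threshold
    entries are masked, missing combinations marked not-determined."""
    if not samples:
        return pd.DataFrame()
    values: dict[tuple[str, str], float] = {}
    subjects, antigens = [], []
    for s in samples:
        values[(s.subject, s.antigen)] = s.cdi
        if s.subject not in subjects:
            subjects.append(s.subject)
        if s.antigen not in antigens:
            antigens.append(s.antigen)
    data = []
    for subj in subjects:
        row = []
        for ant in antigens:
            if (subj, ant) not in values:
                row.append(not_determined)
            elif values[(subj, ant)] < threshold:
                row.append(masked)
            else:
                row.append(values[(subj, ant)])
        data.append(row)
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject"), columns=antigens)
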