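"""Retrospective anti-dsDNA audit statistics.

A testing cascade is summarised from a request-level table: quantitative
ELIA results above the positivity threshold (strictly > 10 IU/mL by
default) are reflex-tested by the semi-quantitative CLIFT immunofluorescence
assay, read on an ordinal scale (0 negative, 1 weak positive, 2 positive,
3 strong positive). The module computes the cascade count/percentage
summary, 2x2 diagnostic metrics of either method against a clinical SLE
diagnosis, and the nonparametric group comparisons used on ordinal antibody
data (Kruskal-Wallis across CLIFT categories, Mann-Whitney U between two
groups).

Report percentages are rounded half-up to integers, matching how audit
figures are conventionally printed; full precision is kept internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_data import AuditTable

__all__ = [
    "CascadeSummary",
    "DiagnosticMetrics",
    "summarise_cascade",
    "diagnostic_metrics",
    "kruskal_wallis",
    "mann_whitney",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CascadeSummary:
    """Counts and integer percentages of the ELIA -> CLIFT cascade."""

    n_requests: int
    n_elia_pos: int
    pct_elia_pos: int              # of all requests
    n_clift_neg: int
    pct_clift_neg: int             # of ELIA-positives
    n_clift_pos: int
    pct_clift_pos: int             # of ELIA-positives
    category_counts: dict[int, int]   # {1: weak, 2: positive, 3: strong}
    category_pcts: dict[int, int]     # of CLIFT-positives
    n_dual_pos: int
    pct_dual_pos: int              # of all requests

    def __post_init__(self) -> None:
        if sum(self.category_counts.values()) != self.n_clift_pos:
            raise ValueError("category counts must sum to the CLIFT-positive count")


def _pct(num: int, den: int) -> int:
    return round_half_up(100.0 * num / den) if den else 0


def summarise_cascade(table: AuditTable,
                      elia_threshold: float = 10.0) -> CascadeSummary:
    """Cascade counts and integer percentages from a request-level table.

    ELIA positivity is strict (> threshold); CLIFT stages are summarised
    among ELIA-positives only.
    """
    df = table.data
    if len(df) == 0:
        raise ValueError("audit table is empty")
    elia_pos = df["elia_iuml"] > elia_threshold
    n_pos = int(elia_pos.sum())
    pos = df[elia_pos]
    cats = pos["clift_category"].dropna().astype(int)
    n_clift_neg = int((cats == 0).sum())
    n_clift_pos = int((cats >= 1).sum())
    cat_counts = {k: int((cats == k).sum()) for k in (1, 2, 3)}
    return CascadeSummary(
        n_requests=len(df),
        n_elia_pos=n_pos,
        pct_elia_pos=_pct(n_pos, len(df)),
        n_clift_neg=n_clift_neg,
        pct_clift_neg=_pct(n_clift_neg, n_pos),
        n_clift_pos=n_clift_pos,
        pct_clift_pos=_pct(n_clift_pos, n_pos),
        category_counts=cat_counts,
        category_pcts={k: _pct(v, n_clift_pos) for k, v in cat_counts.items()},
        n_dual_pos=n_clift_pos,
        pct_dual_pos=_pct(n_clift_pos, len(df)),
    )


@dataclass
class DiagnosticMetrics:
    """Percent diagnostic performance vs clinical diagnosis (NaN = undefined)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int


def _safe_pct(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      stacklevel=3)
        return math.nan
    return 100.0 * num / den


def diagnostic_metrics(table: AuditTable, method: str,
                       elia_threshold: float = 10.0,
                       include_overlap: bool = False) -> DiagnosticMetrics:
    """2x2 metrics of one detection method against diagnosis = SLE.

    ``method`` is ``"ELIA"`` (positive iff value > threshold) or ``"CLIFT"``
    (positive iff category >= 1; requests without a CLIFT result — the
    cascade was not triggered — count as test-negative). SLE-overlap
    syndromes count as non-SLE unless ``include_overlap`` is set.
    """
    df = table.data
    if len(df) == 0:
        raise ValueError("audit table is empty")
    if method.upper() == "ELIA":
        test_pos = (df["elia_iuml"] > elia_threshold).to_numpy()
    elif method.upper() == "CLIFT":
        test_pos = (df["clift_category"].fillna(0) >= 1).to_numpy()
    else:
        raise ValueError("method must be 'ELIA' or 'CLIFT'")
    disease_labels = {"SLE", "SLE-overlap"} if include_overlap else {"SLE"}
    diseased = df["diagnosis"].isin(disease_labels).to_numpy()
    tp = int((test_pos & diseased).sum())
    fp = int((test_pos & ~diseased).sum())
    fn = int((~test_pos & diseased).sum())
    tn = int((~test_pos & ~diseased).sum())
    return DiagnosticMetrics(
        sensitivity=_safe_pct(tp, tp + fn, "sensitivity"),
        specificity=_safe_pct(tn, tn + fp, "specificity"),
        ppv=_safe_pct(tp, tp + fp, "PPV"),
        npv=_safe_pct(tn, tn + fn, "NPV"),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def kruskal_wallis(table: AuditTable) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across CLIFT categories' ELIA values."""
    df = table.data.dropna(subset=["clift_category"])
    groups = [
        g["elia_iuml"].to_numpy(dtype=float)
        for _, g in df.groupby(df["clift_category"].astype(int))
        if len(g) >= 1
    ]
    if len(groups) < 2:
        raise ValueError("need ELIA values in at least 2 CLIFT categories")
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        return 0.0, 1.0          # total ties: no rank variation
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two value groups.

    Exact p-value for small samples (both n <= 8, no ties), normal
    approximation with tie correction otherwise. Returns (U of group A, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
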