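"""Cascade summaries, diagnostic metrics and nonparametric group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ramanclass as rc
from ramanclass.audit_clinical import round_half_up
from ramanclass.synthetic_data import AuditTable


def build_table(n_below, clift_neg, weak, positive, strong,
                diagnoses=None):
    """Audit table with exact counts per cascade stage."""
    rows = []
    for i in range(n_below):
        rows.append((5.0, None))
    for i in range(clift_neg):
        rows.append((50.0, 0))
    for cat, n in ((1, weak), (2, positive), (3, strong)):
        for i in range(n):
            rows.append((50.0 * cat + 20.0, cat))
    frame = pd.DataFrame(
        {
            "request_id": [f"r{i}" for i in range(len(rows))],
            "elia_iuml": [v for v, _ in rows],
            "clift_category": pd.array([c for _, c in rows], dtype="Float64"),
            "diagnosis": diagnoses or ["other"] * len(rows),
        }
    )
    return AuditTable(frame)


# -- cascade summary --------------------------------------------------------

def test_cascade_reproduces_printed_percentages():
    """600 requests, 128 ELIA-positive, 101 CLIFT-negative, 27 positive
    split 7/16/4: percentages 21, 79, 21, 26/59/15 and 5% dual positive."""
    t = build_table(n_below=472, clift_neg=101, weak=7, positive=16, strong=4)
    s = rc.summarise_cascade(t)
    assert s.n_requests == 600
    assert (s.n_elia_pos, s.pct_elia_pos) == (128, 21)
    assert (s.n_clift_neg, s.pct_clift_neg) == (101, 79)
    assert (s.n_clift_pos, s.pct_clift_pos) == (27, 21)
    assert s.category_counts == {1: 7, 2: 16, 3: 4}
    assert s.category_pcts == {1: 26, 2: 59, 3: 15}
    assert (s.n_dual_pos, s.pct_dual_pos) == (27, 5)


def test_cascade_all_below_threshold():
    s = rc.summarise_cascade(build_table(50, 0, 0, 0, 0))
    assert s.n_elia_pos == 0
    assert s.n_clift_pos == 0 and s.pct_clift_pos == 0


def test_cascade_empty_table_is_error():
    empty = AuditTable(pd.DataFrame(
        {"request_id": [], "elia_iuml": [], "clift_category": [],
         "diagnosis": []}))
    with pytest.raises(ValueError):
        rc.summarise_cascade(empty)


def test_cascade_percentages_self_consistent_on_random_tables():
    for seed in range(5):
        t = rc.generate_audit(300, seed=seed)
        s = rc.summarise_cascade(t)
        assert sum(s.category_counts.values()) == s.n_clift_pos
        assert s.n_clift_neg + s.n_clift_pos == s.n_elia_pos
        assert s.pct_elia_pos == round_half_up(100 * s.n_elia_pos / 300)
        if s.n_elia_pos:
            assert s.pct_clift_neg == round_half_up(
                100 * s.n_clift_neg / s.n_elia_pos)


def test_round_half_up():
    assert round_half_up(0.5) == 1
    assert round_half_up(20.5) == 21
    assert round_half_up(20.4999) == 20


# -- diagnostic metrics -----------------------------------------------------

def test_diagnostic_metrics_arithmetic():
    """TP=20, FN=5, FP=10, TN=65 by construction."""
    diagnoses = (["SLE"] * 20 + ["other"] * 10   # ELIA positive
                 + ["SLE"] * 5 + ["other"] * 65)  # ELIA negative
    t = build_table(n_below=70, clift_neg=30, weak=0, positive=0, strong=0,
                    diagnoses=["other"] * 100)
    frame = t.data.copy()
    order = list(frame.index)
    pos_rows = [i for i in order if frame.loc[i, "elia_iuml"] > 10]
    neg_rows = [i for i in order if frame.loc[i, "elia_iuml"] <= 10]
    for i, row in enumerate(pos_rows):
        frame.loc[row, "diagnosis"] = "SLE" if i < 20 else "other"
    for i, row in enumerate(neg_rows):
        frame.loc[row, "diagnosis"] = "SLE" if i < 5 else "other"
    m = rc.diagnostic_metrics(AuditTable(frame), "ELIA")
    assert m.sensitivity == pytest.approx(80.0)
    assert m.specificity == pytest.approx(100 * 65 / 75, abs=0.05)
    assert m.ppv == pytest.approx(100 * 20 / 30, abs=0.05)
    assert m.npv == pytest.approx(100 * 65 / 70, abs=0.05)


def test_diagnostic_metrics_perfect_test():
    t = build_table(n_below=10, clift_neg=0, weak=5, positive=0, strong=0)
    frame = t.data.copy()
    frame["diagnosis"] = ["other"] * 10 + ["SLE"] * 5
    m = rc.diagnostic_metrics(AuditTable(frame), "CLIFT")
    assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (100.0,) * 4


def test_diagnostic_metrics_row_scan_oracle():
    """Counts agree with an exhaustive per-row scan on a random table."""
    t = rc.generate_audit(400, seed=3)
    for method in ("ELIA", "CLIFT"):
        m = rc.diagnostic_metrics(t, method)
        tp = fp = tn = fn = 0
        for _, row in t.data.iterrows():
            if method == "ELIA":
                pos = row["elia_iuml"] > 10.0
            else:
                pos = (not pd.isna(row["clift_category"])
                       and row["clift_category"] >= 1)
            sle = row["diagnosis"] == "SLE"
            tp += pos and sle
            fp += pos and not sle
            fn += (not pos) and sle
            tn += (not pos) and not sle
        assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)


def test_diagnostic_metrics_row_order_invariant():
    t = rc.generate_audit(200, seed=4)
    shuffled = AuditTable(t.data.sample(frac=1.0, random_state=0)
                          .reset_index(drop=True))
    a = rc.diagnostic_metrics(t, "ELIA")
    b = rc.diagnostic_metrics(shuffled, "ELIA")
    assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)


def test_diagnostic_metrics_overlap_flag():
    t = rc.generate_audit(500, seed=6)
    excl = rc.diagnostic_metrics(t, "ELIA", include_overlap=False)
    incl = rc.diagnostic_metrics(t, "ELIA", include_overlap=True)
    n_overlap = int((t.data["diagnosis"] == "SLE-overlap").sum())
    assert (incl.tp + incl.fn) - (excl.tp + excl.fn) == n_overlap


def test_diagnostic_metrics_zero_denominator_warns_nan():
    t = build_table(n_below=5, clift_neg=0, weak=0, positive=0, strong=0)
    with pytest.warns(UserWarning, match="undefined"):
        m = rc.diagnostic_metrics(t, "ELIA")
    assert math.isnan(m.sensitivity)


# -- Kruskal-Wallis ---------------------------------------------------------

def test_kruskal_wallis_total_ties_h_zero():
    frame = pd.DataFrame({
        "request_id": [f"r{i}" for i in range(8)],
        "elia_iuml": [50.0] * 8,
        "clift_category": pd.array([0, 0, 1, 1, 2, 2, 3, 3], dtype="Float64"),
        "diagnosis": ["other"] * 8,
    })
    h, p = rc.kruskal_wallis(AuditTable(frame))
    assert h == 0.0 and p == pytest.approx(1.0)


def test_kruskal_wallis_two_groups_fully_separated():
    """n=3 per group with non-overlapping ranks; H matches the closed-form
    value and the p-value matches full permutation enumeration."""
    frame = pd.DataFrame({
        "request_id": [f"r{i}" for i in range(6)],
        "elia_iuml": [11.0, 12.0, 13.0, 101.0, 102.0, 103.0],
        "clift_category": pd.array([0, 0, 0, 2, 2, 2], dtype="Float64"),
        "diagnosis": ["other"] * 6,
    })
    h, p = rc.kruskal_wallis(AuditTable(frame))
    # ranks 1..6; H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2) = 3.857142...
    assert h == pytest.approx(12 / 42 * (3 * 1.5**2 * 2), abs=1e-9)
    # permutation enumeration of rank assignments
    ranks = np.arange(1, 7)
    count = 0
    total = 0
    for combo in itertools.combinations(range(6), 3):
        r1 = ranks[list(combo)]
        r2 = np.delete(ranks, list(combo))
        h_perm = 12 / 42 * (3 * (r1.mean() - 3.5) ** 2
                            + 3 * (r2.mean() - 3.5) ** 2)
        total += 1
        if h_perm >= h - 1e-12:
            count += 1
    assert count / total == pytest.approx(0.1)  # exact tail mass


def test_kruskal_wallis_tie_correction_matches_manual():
    """n=8 with ties: H equals the hand-computed tie-corrected statistic."""
    values = [10.0, 10.0, 20.0, 30.0, 30.0, 40.0, 50.0, 50.0]
    cats = [0, 0, 1, 1, 2, 2, 3, 3]
    frame = pd.DataFrame({
        "request_id": [f"r{i}" for i in range(8)],
        "elia_iuml": values,
        "clift_category": pd.array(cats, dtype="Float64"),
        "diagnosis": ["other"] * 8,
    })
    h, _ = rc.kruskal_wallis(AuditTable(frame))
    # mid-ranks: 1.5,1.5,3,4.5,4.5,6,7.5,7.5
    r = np.array([1.5, 1.5, 3, 4.5, 4.5, 6, 7.5, 7.5])
    groups = [r[0:2], r[2:4], r[4:6], r[6:8]]
    n = 8
    h_raw = 12 / (n * (n + 1)) * sum(
        len(g) * (g.mean() - (n + 1) / 2) ** 2 for g in groups)
    ties = 3 * (2**3 - 2)  # three tied pairs
    h_manual = h_raw / (1 - ties / (n**3 - n))
    assert h == pytest.approx(h_manual, abs=1e-10)


def test_kruskal_wallis_single_category_is_error():
    frame = pd.DataFrame({
        "request_id": ["a", "b"],
        "elia_iuml": [20.0, 30.0],
        "clift_category": pd.array([1, 1], dtype="Float64"),
        "diagnosis": ["other"] * 2,
    })
    with pytest.raises(ValueError):
        rc.kruskal_wallis(AuditTable(frame))


# -- Mann-Whitney -----------------------------------------------------------

def test_mann_whitney_identical_groups():
    _, p = rc.mann_whitney([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 4.5])
    assert p > 0.5


def test_mann_whitney_exact_enumeration():
    """A={1,2,3} vs B={10,11,12}: U=0 and the exact two-sided p equals
    2/C(6,3) = 0.1, verified by enumerating all 20 orderings."""
    u, p = rc.mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert u == 0.0
    values = [1, 2, 3, 10, 11, 12]
    extreme = 0
    total = 0
    for combo in itertools.combinations(range(6), 3):
        a = [values[i] for i in combo]
        b = [values[i] for i in range(6) if i not in combo]
        u_a = sum(1 for x in a for y in b if x > y)
        total += 1
        if min(u_a, 9 - u_a) <= 0:  # as or more extreme than observed
            extreme += 1
    assert p == pytest.approx(extreme / total)
    assert p == pytest.approx(0.1)


def test_mann_whitney_u_identity(rng):
    a = rng.normal(size=6)
    b = rng.normal(size=5)
    u_a, _ = rc.mann_whitney(a, b)
    u_b, _ = rc.mann_whitney(b, a)
    assert u_a + u_b == pytest.approx(len(a) * len(b))


def test_mann_whitney_empty_group_is_error():
    with pytest.raises(ValueError):
        rc.mann_whitney([], [1.0])


def test_kruskal_two_groups_monotone_in_mann_whitney(rng):
    """With two groups and no ties, H is a monotone transform of
    |U - nm/2|: orderings by the two statistics coincide."""
    hs, us = [], []
    for seed in range(8):
        local = np.random.default_rng(seed)
        a = local.normal(0, 1, 6)
        b = local.normal(seed * 0.3, 1, 6)
        frame = pd.DataFrame({
            "request_id": [f"r{i}" for i in range(12)],
            "elia_iuml": np.concatenate([a, b]) + 100,
            "clift_category": pd.array([0] * 6 + [2] * 6, dtype="Float64"),
            "diagnosis": ["other"] * 12,
        })
        h, _ = rc.kruskal_wallis(AuditTable(frame))
        u, _ = rc.mann_whitney(a, b)
        hs.append(h)
        us.append(abs(u - 18.0))
    assert np.argsort(hs).tolist() == np.argsort(us).tolist()
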