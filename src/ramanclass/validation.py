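"""Monte Carlo cross-validation, confusion tables, AC/SENS/SPEC metrics,
and score-level ANOVA / MANOVA.

Model validation follows the repeated random-split scheme common in
chemometrics: at each of ``n_iter`` iterations a stratified random 20% of
spectra is held out, the classifier (PCA-LDA or PLS-DA) is refit on the
remaining 80%, and the held-out spectra are predicted. Accuracy, per-class
sensitivity and specificity

    AC   = (TP + TN) / (TP + FP + TN + FN) * 100
    SENS = TP / (TP + FN) * 100
    SPEC = TN / (TN + FP) * 100

are averaged over iterations, together with the mean confusion table.
Splits default to spectrum level (replicates of one subject may straddle the
split, which flatters the estimate when replicates are highly correlated);
subject-level splitting is available and keeps all replicates of a subject
on one side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import chemometrics as chem
from .spectral_io import SpectraSet

__all__ = [
    "ConfusionTable",
    "PerformanceMetrics",
    "CVResult",
    "metrics",
    "monte_carlo_cv",
    "score_anova",
    "score_manova",
]


@dataclass
class ConfusionTable:
    """K x K table of counts; rows are true classes, columns predicted."""

    classes: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        K = len(self.classes)
        if self.table.shape != (K, K):
            raise ValueError(f"table must be {K}x{K}")
        if (self.table < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, true, predicted,
                         classes: tuple[str, ...]) -> "ConfusionTable":
        idx = {c: i for i, c in enumerate(classes)}
        t = np.zeros((len(classes), len(classes)))
        for a, b in zip(true, predicted, strict=True):
            t[idx[str(a)], idx[str(b)]] += 1
        return cls(classes=classes, table=t)

    def one_vs_rest(self, positive: str) -> tuple[float, float, float, float]:
        """(TP, FP, TN, FN) counts treating ``positive`` against the rest."""
        k = self.classes.index(positive)
        tp = self.table[k, k]
        fn = self.table[k].sum() - tp
        fp = self.table[:, k].sum() - tp
        tn = self.table.sum() - tp - fn - fp
        return float(tp), float(fp), float(tn), float(fn)


@dataclass
class PerformanceMetrics:
    """Percent metrics; undefined ratios (zero denominator) are NaN."""

    accuracy: float
    sensitivity: float           # positive class (binary) or class mean
    specificity: float
    per_class_sensitivity: dict[str, float]
    per_class_specificity: dict[str, float]


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def metrics(table: ConfusionTable,
            positive_class: str | None = None) -> PerformanceMetrics:
    """AC / SENS / SPEC from a confusion table.

    Binary tables report sensitivity for the positive class (default: the
    last class in sorted order, i.e. the disease class for HC/SLE) and
    specificity for the other. Multi-class tables report micro accuracy
    (trace over total) and unweighted class means of one-vs-rest
    sensitivity/specificity.
    """
    total = table.table.sum()
    if total == 0:
        raise ValueError("confusion table is all zero")
    accuracy = 100.0 * np.trace(table.table) / total
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    for c in table.classes:
        tp, fp, tn, fn = table.one_vs_rest(c)
        sens[c] = _ratio(tp, tp + fn)
        spec[c] = _ratio(tn, tn + fp)
    if len(table.classes) == 2:
        pos = positive_class or table.classes[1]
        neg = [c for c in table.classes if c != pos][0]
        return PerformanceMetrics(
            accuracy=accuracy, sensitivity=sens[pos], specificity=sens[neg],
            per_class_sensitivity=sens, per_class_specificity=spec,
        )
    mean_sens = float(np.nanmean(list(sens.values())))
    mean_spec = float(np.nanmean(list(spec.values())))
    return PerformanceMetrics(
        accuracy=accuracy, sensitivity=mean_sens, specificity=mean_spec,
        per_class_sensitivity=sens, per_class_specificity=spec,
    )


@dataclass
class CVResult:
    n_iterations: int
    test_fraction: float
    split_level: str
    classes: tuple[str, ...]
    accuracies: np.ndarray                 # (n_iter,)
    sensitivities: np.ndarray              # (n_iter, K) one-vs-rest
    specificities: np.ndarray              # (n_iter, K)
    mean_confusion: ConfusionTable

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_sensitivity(self) -> dict[str, float]:
        means = np.nanmean(self.sensitivities, axis=0)
        return dict(zip(self.classes, means.tolist()))

    @property
    def mean_specificity(self) -> dict[str, float]:
        means = np.nanmean(self.specificities, axis=0)
        return dict(zip(self.classes, means.tolist()))


def _stratified_split(spectra: SpectraSet, test_fraction: float,
                      split_level: str, rng: np.random.Generator):
    """Return (train_idx, test_idx); every class keeps >= 1 spectrum on
    each side."""
    test: list[int] = []
    if split_level == "spectrum":
        for c in spectra.classes:
            idx = spectra.class_indices(c)
            if idx.size < 2:
                raise ValueError(f"class {c!r} too small to stratify")
            n_test = min(max(1, round(test_fraction * idx.size)), idx.size - 1)
            test.extend(rng.permutation(idx)[:n_test].tolist())
    elif split_level == "subject":
        for c in spectra.classes:
            idx = spectra.class_indices(c)
            subjects = sorted({spectra.subject_ids[i] for i in idx})
            if len(subjects) < 2:
                raise ValueError(
                    f"class {c!r} has fewer than 2 subjects; cannot split "
                    "at subject level"
                )
            n_test = min(max(1, round(test_fraction * len(subjects))),
                         len(subjects) - 1)
            held = set(rng.permutation(subjects)[:n_test].tolist())
            test.extend(i for i in idx if spectra.subject_ids[i] in held)
    else:
        raise ValueError("split_level must be 'spectrum' or 'subject'")
    test_set = set(test)
    train = [i for i in range(spectra.n_spectra) if i not in test_set]
    return np.array(train), np.array(sorted(test_set))


def monte_carlo_cv(
    spectra: SpectraSet,
    model: str = "plsda",
    n_components: int = 6,
    n_iter: int = 1000,
    test_fraction: float = 0.2,
    split_level: str = "spectrum",
    seed: int | None = None,
) -> CVResult:
    """Repeated stratified random-split validation of a classifier.

    Each iteration leaves ``test_fraction`` of the data out, fits the chosen
    model (``"plsda"`` with ``n_components`` latent variables or ``"pcalda"``
    with ``n_components`` PCs) on the rest, and scores the held-out spectra.
    Reproducible for a fixed ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if model not in {"plsda", "pcalda"}:
        raise ValueError("model must be 'plsda' or 'pcalda'")
    rng = np.random.default_rng(seed)
    classes = tuple(spectra.classes)
    K = len(classes)
    X = spectra.intensities
    labels = np.array(spectra.class_labels)
    acc = np.empty(n_iter)
    sens = np.empty((n_iter, K))
    spec = np.empty((n_iter, K))
    table_sum = np.zeros((K, K))
    for it in range(n_iter):
        train, test = _stratified_split(spectra, test_fraction, split_level, rng)
        ytr = labels[train].tolist()
        if model == "plsda":
            fitted = chem.fit_plsda(X[train], ytr, n_lvs=n_components)
            predicted = chem.plsda_predict(fitted, X[test]).assigned_class
        else:
            fitted = chem.fit_pca_lda(X[train], ytr, n_pcs=n_components)
            predicted = chem.pca_lda_score(fitted, X[test]).assigned_class
        table = ConfusionTable.from_predictions(labels[test], predicted, classes)
        m = metrics(table)
        acc[it] = m.accuracy
        sens[it] = [m.per_class_sensitivity[c] for c in classes]
        spec[it] = [m.per_class_specificity[c] for c in classes]
        table_sum += table.table
    return CVResult(
        n_iterations=n_iter,
        test_fraction=test_fraction,
        split_level=split_level,
        classes=classes,
        accuracies=acc,
        sensitivities=sens,
        specificities=spec,
        mean_confusion=ConfusionTable(classes=classes, table=table_sum / n_iter),
    )


def score_anova(scores, labels) -> tuple[float, float]:
    """One-way ANOVA (F, p) of 1-D discriminant scores across groups."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = [str(l) for l in labels]
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for g in groups:
        s = scores[[l == g for l in labels]]
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples.append(s)
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return 0.0, 1.0
    f_stat, p = stats.f_oneway(*samples)
    return float(f_stat), float(p)


def score_manova(scores, labels) -> tuple[float, float]:
    """Wilks' lambda MANOVA of multi-axis scores across groups.

    Returns (lambda, p) using Rao's F approximation; with a single axis this
    reduces exactly to the one-way ANOVA F test. Identical groups give
    (1, 1).
    """
    Z = np.atleast_2d(np.asarray(scores, dtype=float))
    if Z.shape[0] == 1:
        Z = Z.T
    labels = [str(l) for l in labels]
    if Z.shape[0] != len(labels):
        raise ValueError("scores and labels disagree in length")
    groups = sorted(set(labels))
    K, p = len(groups), Z.shape[1]
    if K < 2:
        raise ValueError("need at least 2 groups")
    N = Z.shape[0]
    grand = Z.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        Zg = Z[[l == g for l in labels]]
        if Zg.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        mg = Zg.mean(axis=0)
        W += (Zg - mg).T @ (Zg - mg)
        d = (mg - grand)[:, None]
        B += Zg.shape[0] * (d @ d.T)
    T = W + B
    det_T = np.linalg.det(T)
    if det_T <= 0 or np.linalg.det(W) <= 0:
        if np.allclose(B, 0):
            return 1.0, 1.0
        raise ValueError("singular within-group scatter; MANOVA undefined")
    lam = float(np.linalg.det(W) / det_T)
    if np.allclose(B, 0):
        return 1.0, 1.0
    nu_h = K - 1
    nu_e = N - K
    denom = p**2 + nu_h**2 - 5
    t = math.sqrt((p**2 * nu_h**2 - 4) / denom) if denom > 0 else 1.0
    w_term = nu_e + nu_h - (p + nu_h + 1) / 2.0
    df1 = p * nu_h
    df2 = w_term * t - (p * nu_h - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f_stat = (1 - lam_t) / lam_t * df2 / df1
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return lam, p_value
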