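"""Cluster-vector discovery of discriminatory wavenumbers, plus peak ANOVA.

The cluster-vector approach builds a "loadings-like" spectrum for each
class: among the leading principal components, the three PCs whose 3-D score
projection best separates the class clusters are selected, and each class
vector is the sum of those three loading vectors weighted by the class
medians of the corresponding scores,

    v_k = sum_{j in triplet} median_j(class k) * loading_j .

The disease-minus-control difference of class vectors (the contrast vector)
localises the wavenumbers driving the separation; its largest local extrema
are reported as ranked peaks. A one-way ANOVA of pre-processed intensity at
each peak across classes supplies per-peak significance and the direction of
the disease-vs-control change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .chemometrics import PCAModel
from .spectral_io import SpectraSet

__all__ = [
    "Peak",
    "ClusterVectorResult",
    "PeakStat",
    "select_pc_triplet",
    "cluster_vectors",
    "top_peaks",
    "peak_stats",
]


@dataclass
class Peak:
    wavenumber: float
    magnitude: float        # |contrast| at the peak
    direction: str          # "up" if disease > control at this wavenumber


@dataclass
class ClusterVectorResult:
    pc_triplet: tuple[int, int, int]       # 0-based PC indices
    per_class_vectors: dict[str, np.ndarray]
    contrast_vector: np.ndarray            # disease minus control
    control_class: str
    disease_class: str


@dataclass
class PeakStat:
    wavenumber: float                      # nearest axis point used
    group_means: dict[str, float]
    group_sds: dict[str, float]
    f_statistic: float
    p_value: float
    direction: str


def _fisher_criterion(Z: np.ndarray, labels: list[str]) -> float:
    """Multivariate Fisher separation trace(Sw^-1 Sb) of a projection.

    Scale-invariant, so low-variance noise PCs cannot crowd out genuinely
    separating PCs."""
    classes = sorted(set(labels))
    d = Z.shape[1]
    grand = Z.mean(axis=0)
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for c in classes:
        Zc = Z[[l == c for l in labels]]
        mc = Zc.mean(axis=0)
        dm = (mc - grand)[:, None]
        Sb += Zc.shape[0] * (dm @ dm.T)
        Sw += (Zc - mc).T @ (Zc - mc)
    try:
        return float(np.trace(np.linalg.solve(Sw, Sb)))
    except np.linalg.LinAlgError:
        return np.inf if np.trace(Sb) > 0 else 0.0


def select_pc_triplet(pca: PCAModel, labels) -> tuple[int, int, int]:
    """Exhaustively pick the 3 PCs whose score projection maximises the
    Fisher separation criterion. Deterministic: ties keep the
    lexicographically first triplet.
    """
    labels = [str(l) for l in labels]
    if pca.n_pcs < 3:
        raise ValueError("need at least 3 principal components")
    if pca.scores.shape[0] != len(labels):
        raise ValueError("label count does not match the fitted scores")
    best: tuple[int, int, int] | None = None
    best_J = -np.inf
    for combo in itertools.combinations(range(pca.n_pcs), 3):
        J = _fisher_criterion(pca.scores[:, combo], labels)
        if J > best_J:
            best, best_J = combo, J
    assert best is not None
    return best


def cluster_vectors(
    pca: PCAModel,
    labels,
    triplet: tuple[int, int, int],
    control: str,
    disease: str | None = None,
) -> ClusterVectorResult:
    """Class median-weighted loading sums and their disease-control contrast.

    With two classes the disease class is inferred as the non-control one;
    with more, ``disease`` must be given.
    """
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    if control not in classes:
        raise ValueError(f"unknown control class {control!r}; have {classes}")
    if disease is None:
        others = [c for c in classes if c != control]
        if len(others) != 1:
            raise ValueError(
                "disease class is ambiguous with more than two classes; "
                "pass disease= explicitly"
            )
        disease = others[0]
    elif disease not in classes:
        raise ValueError(f"unknown disease class {disease!r}; have {classes}")
    triplet = tuple(int(j) for j in triplet)
    if len(set(triplet)) != 3 or not all(0 <= j < pca.n_pcs for j in triplet):
        raise ValueError(f"invalid PC triplet {triplet} for {pca.n_pcs} PCs")
    vectors: dict[str, np.ndarray] = {}
    for c in classes:
        rows = [l == c for l in labels]
        medians = np.median(pca.scores[rows][:, triplet], axis=0)
        vectors[c] = medians @ pca.loadings[list(triplet)]
    return ClusterVectorResult(
        pc_triplet=triplet,
        per_class_vectors=vectors,
        contrast_vector=vectors[disease] - vectors[control],
        control_class=control,
        disease_class=disease,
    )


def top_peaks(
    result: ClusterVectorResult,
    wavenumbers: np.ndarray,
    n: int = 12,
    min_separation: float = 10.0,
) -> list[Peak]:
    """Largest local extrema of |contrast|, greedily spaced.

    Extrema are ranked by |contrast| descending; a candidate closer than
    ``min_separation`` cm^-1 to an already-kept peak is dropped, so one broad
    band cannot occupy several slots. Returns at most ``n`` peaks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.asarray(wavenumbers, dtype=float)
    v = np.abs(result.contrast_vector)
    if w.shape != v.shape:
        raise ValueError("wavenumbers do not match the contrast vector")
    candidates, _ = signal.find_peaks(v)
    if candidates.size == 0:
        return []
    order = candidates[np.argsort(v[candidates], kind="stable")[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(w[idx] - w[j]) >= min_separation for j in kept):
            kept.append(idx)
        if len(kept) == n:
            break
    return [
        Peak(
            wavenumber=float(w[i]),
            magnitude=float(v[i]),
            direction="up" if result.contrast_vector[i] > 0 else "down",
        )
        for i in kept
    ]


def peak_stats(
    spectra: SpectraSet,
    peaks,
    control: str,
    disease: str | None = None,
) -> list[PeakStat]:
    """One-way ANOVA of pre-processed intensity at each peak across classes.

    ``peaks`` may be wavenumbers or :class:`Peak` objects; each is snapped to
    the nearest axis point. The direction is the sign of the
    disease-minus-control mean at that point.
    """
    classes = spectra.classes
    if control not in classes:
        raise ValueError(f"unknown control class {control!r}")
    if disease is None:
        others = [c for c in classes if c != control]
        if len(others) != 1:
            raise ValueError("pass disease= explicitly with >2 classes")
        disease = others[0]
    for c in classes:
        if spectra.class_labels.count(c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 spectra")
    groups_idx = {c: spectra.class_indices(c) for c in classes}
    out: list[PeakStat] = []
    for peak in peaks:
        target = peak.wavenumber if isinstance(peak, Peak) else float(peak)
        i = int(np.argmin(np.abs(spectra.wavenumbers - target)))
        col = spectra.intensities[:, i]
        samples = [col[groups_idx[c]] for c in classes]
        if all(np.ptp(s) == 0 for s in samples) and len(
            {s[0] for s in samples}
        ) == 1:
            f_stat, p = 0.0, 1.0     # all groups identical constants
        else:
            f_stat, p = stats.f_oneway(*samples)
        diff = col[groups_idx[disease]].mean() - col[groups_idx[control]].mean()
        out.append(
            PeakStat(
                wavenumber=float(spectra.wavenumbers[i]),
                group_means={c: float(col[groups_idx[c]].mean()) for c in classes},
                group_sds={c: float(col[groups_idx[c]].std(ddof=1)) for c in classes},
                f_statistic=float(f_stat),
                p_value=float(p),
                direction="up" if diff > 0 else "down",
            )
        )
    return out
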