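"""Spectral pre-processing: fingerprint cut, rubber-band baseline, vector norm.

The pipeline mirrors routine biofluid Raman practice: spectra are cut to the
biological fingerprint region (900-1800 cm^-1 by default), the broad
fluorescence background is removed by rubber-band baseline correction, and
each spectrum is scaled to unit Euclidean norm so only relative band
intensities remain.

The rubber band is the exact lower convex hull of the (wavenumber,
intensity) point set, linearly interpolated between hull vertices. By
construction the corrected spectrum is non-negative and zero at every hull
vertex, including both endpoints, and the correction is invariant to adding
any affine function of wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral_io import SpectraSet

__all__ = [
    "PreprocessConfig",
    "cut_region",
    "rubberband_baseline",
    "vector_normalise",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Settings for :func:`preprocess`.

    cut_low / cut_high
        Fingerprint window bounds in cm^-1 (defaults 900 and 1800).
    baseline_method
        Only ``"rubberband"`` is implemented.
    normalisation
        Only ``"vector"`` (unit 2-norm) is implemented.
    cut_first
        Cut before baselining (default). Cutting first avoids anchoring the
        hull on the silent high-wavenumber region; the opposite order is
        retained for comparison.
    """

    cut_low: float = 900.0
    cut_high: float = 1800.0
    baseline_method: str = "rubberband"
    normalisation: str = "vector"
    cut_first: bool = True

    def __post_init__(self) -> None:
        if self.cut_low >= self.cut_high:
            raise ValueError("cut_low must be strictly below cut_high")
        if self.baseline_method != "rubberband":
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")
        if self.normalisation != "vector":
            raise ValueError(f"unknown normalisation {self.normalisation!r}")


def cut_region(spectra: SpectraSet, low: float, high: float) -> SpectraSet:
    """Restrict the axis to the closed interval [low, high] cm^-1."""
    if low >= high:
        raise ValueError(f"invalid cut window [{low}, {high}]: low >= high")
    mask = (spectra.wavenumbers >= low) & (spectra.wavenumbers <= high)
    if not mask.any():
        raise ValueError(
            f"cut window [{low}, {high}] cm^-1 does not overlap the axis "
            f"[{spectra.wavenumbers[0]}, {spectra.wavenumbers[-1]}]"
        )
    return spectra.with_intensities(
        spectra.wavenumbers[mask], spectra.intensities[:, mask]
    )


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    # Monotone-chain lower hull over points sorted by x. Collinear middle
    # points are dropped; linear interpolation restores them exactly.
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (x[b] - x[a]) * (y[i] - y[a]) - (y[b] - y[a]) * (x[i] - x[a])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def rubberband_baseline(
    wavenumbers: np.ndarray, intensities: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Lower-convex-hull ("rubber band") baseline of one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = intensities -
    baseline``. The baseline is pointwise <= the spectrum and touches it at
    every hull vertex.
    """
    w = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if w.ndim != 1 or y.shape != w.shape:
        raise ValueError("wavenumbers and intensities must be equal-length 1-D")
    if w.size < 3:
        raise ValueError("rubber-band correction needs at least 3 points")
    if not (np.isfinite(w).all() and np.isfinite(y).all()):
        raise ValueError("rubber-band correction requires finite values")
    hull = _lower_hull_indices(w, y)
    baseline = np.interp(w, w[hull], y[hull])
    return baseline, y - baseline


def vector_normalise(intensities: np.ndarray) -> np.ndarray:
    """Scale a spectrum to unit Euclidean norm (direction preserved)."""
    y = np.asarray(intensities, dtype=float)
    norm = float(np.linalg.norm(y))
    if norm == 0.0:
        raise ValueError("cannot vector-normalise an all-zero spectrum")
    return y / norm


def preprocess(spectra: SpectraSet, cfg: PreprocessConfig | None = None) -> SpectraSet:
    """Cut to the fingerprint window, baseline-correct, and unit-normalise.

    Metadata is untouched; only axis and intensities change.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.cut_first:
        spectra = cut_region(spectra, cfg.cut_low, cfg.cut_high)
    corrected = np.empty_like(spectra.intensities)
    for i in range(spectra.n_spectra):
        _, corrected[i] = rubberband_baseline(
            spectra.wavenumbers, spectra.intensities[i]
        )
    spectra = spectra.with_intensities(spectra.wavenumbers, corrected)
    if not cfg.cut_first:
        spectra = cut_region(spectra, cfg.cut_low, cfg.cut_high)
    normalised = np.vstack(
        [vector_normalise(row) for row in spectra.intensities]
    )
    return spectra.with_intensities(spectra.wavenumbers, normalised)
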