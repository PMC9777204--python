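"""Reading, validating and writing sets of Raman spectra in plain-text formats.

A spectra set couples a single wavenumber axis (cm^-1) with an intensity
matrix (one row per spectrum) and per-spectrum metadata: a unique spectrum
id, a subject id grouping technical replicates, and a class label (e.g.
``HC`` vs ``SLE``, or the four serology-defined groups).

Two on-disk layouts are supported:

* a wide delimited matrix whose first column is ``wavenumber_cm1`` and whose
  remaining columns are spectra, one per spectrum id;
* a directory of two-column (wavenumber, intensity) text files, the file
  stem serving as the spectrum id.

Either way the metadata travels in a separate delimited table keyed by
spectrum id (columns ``spectrum_id,subject_id,class`` and optionally
``subgroup``), which keeps the numeric matrices purely numeric and mirrors
how blinded study identifiers are usually handled.

The canonical internal axis orientation is ascending cm^-1; files recorded
with a descending axis are flipped on read. Duplicate wavenumbers within one
file are a hard error rather than being silently averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "DatasetManifest",
    "read_spectra",
    "write_spectra",
    "summarise",
]

_METADATA_REQUIRED = ("spectrum_id", "subject_id", "class")


@dataclass
class SpectraSet:
    """A wavenumber axis plus an intensity matrix and per-spectrum metadata.

    Attributes
    ----------
    wavenumbers : (p,) array, strictly increasing, cm^-1
    intensities : (n, p) array, arbitrary counts (a.u.)
    spectrum_ids : n unique strings
    subject_ids : n strings (replicate grouping)
    class_labels : n strings
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    spectrum_ids: list[str]
    subject_ids: list[str]
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.spectrum_ids = [str(s) for s in self.spectrum_ids]
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.class_labels = [str(s) for s in self.class_labels]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumber axis must be one-dimensional")
        if self.wavenumbers.size and np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        n, p = self.intensities.shape
        if p != self.wavenumbers.size:
            raise ValueError(
                f"intensity matrix has {p} columns but the axis has "
                f"{self.wavenumbers.size} points"
            )
        for name, seq in (
            ("spectrum_ids", self.spectrum_ids),
            ("subject_ids", self.subject_ids),
            ("class_labels", self.class_labels),
        ):
            if len(seq) != n:
                raise ValueError(f"{name} has {len(seq)} entries for {n} spectra")
        if len(set(self.spectrum_ids)) != n:
            raise ValueError("spectrum ids must be unique")

    # -- conveniences -------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    @property
    def classes(self) -> list[str]:
        """Distinct class labels in sorted order (deterministic model order)."""
        return sorted(set(self.class_labels))

    def class_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.class_labels) if c == label])

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[idx].copy(),
            spectrum_ids=[self.spectrum_ids[i] for i in idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            class_labels=[self.class_labels[i] for i in idx],
        )

    def with_intensities(self, wavenumbers: np.ndarray,
                         intensities: np.ndarray) -> "SpectraSet":
        """Same metadata, new axis/matrix (used by preprocessing steps)."""
        return SpectraSet(
            wavenumbers=wavenumbers,
            intensities=intensities,
            spectrum_ids=list(self.spectrum_ids),
            subject_ids=list(self.subject_ids),
            class_labels=list(self.class_labels),
        )


@dataclass
class DatasetManifest:
    """Per-class and per-subject spectrum counts for a spectra set."""

    n_spectra: int
    class_counts: dict[str, int]
    subject_counts: dict[str, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != self.n_spectra:
            raise ValueError("class counts do not sum to the number of spectra")
        if sum(self.subject_counts.values()) != self.n_spectra:
            raise ValueError("subject counts do not sum to the number of spectra")
        if any(c < 1 for c in self.subject_counts.values()):
            raise ValueError("replicate counts must be >= 1")


def summarise(spectra: SpectraSet, provenance: str = "") -> DatasetManifest:
    """Count spectra per class label and per subject."""
    class_counts: dict[str, int] = {}
    subject_counts: dict[str, int] = {}
    for c in spectra.class_labels:
        class_counts[c] = class_counts.get(c, 0) + 1
    for s in spectra.subject_ids:
        subject_counts[s] = subject_counts.get(s, 0) + 1
    return DatasetManifest(
        n_spectra=spectra.n_spectra,
        class_counts=class_counts,
        subject_counts=subject_counts,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, dtype=str)
    missing = [c for c in _METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(
            f"metadata file {metadata_path} is missing required column(s) "
            f"{missing}; expected {list(_METADATA_REQUIRED)}"
        )
    if meta["spectrum_id"].duplicated().any():
        dup = meta.loc[meta["spectrum_id"].duplicated(), "spectrum_id"].iloc[0]
        raise ValueError(f"duplicate spectrum_id {dup!r} in metadata")
    return meta


def _coerce_numeric(frame: pd.DataFrame, source: str) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any():
        bad = np.argwhere(out.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {source} at row {bad[0] + 1}, "
            f"column {frame.columns[bad[1]]!r}"
        )
    return out


def _sorted_axis(wavenumbers: np.ndarray, matrix: np.ndarray,
                 source: str) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(wavenumbers, kind="stable")
    w = wavenumbers[order]
    if w.size >= 2 and np.any(np.diff(w) == 0):
        dup = w[np.flatnonzero(np.diff(w) == 0)[0]]
        raise ValueError(f"duplicate wavenumber {dup} cm^-1 in {source}")
    return w, matrix[:, order]


def _read_wide(path: Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: wide matrix needs a wavenumber column plus "
                         "at least one spectrum column")
    frame = _coerce_numeric(frame, str(path))
    wav = frame.iloc[:, 0].to_numpy(dtype=float)
    ids = [str(c) for c in frame.columns[1:]]
    matrix = frame.iloc[:, 1:].to_numpy(dtype=float).T  # spectra as rows
    wav, matrix = _sorted_axis(wav, matrix, str(path))
    return wav, matrix, ids


def _read_directory(path: Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and p.suffix.lower() in {".txt", ".csv", ".dat", ".tsv"}
    )
    if not files:
        raise ValueError(f"no spectrum files (*.txt/*.csv/*.dat/*.tsv) in {path}")
    axis: np.ndarray | None = None
    rows, ids = [], []
    for f in files:
        frame = pd.read_csv(f, sep=None, engine="python", header=None,
                            comment="#")
        if frame.shape[1] != 2:
            raise ValueError(f"{f}: expected two columns "
                             f"(wavenumber, intensity), found {frame.shape[1]}")
        frame = _coerce_numeric(frame, str(f))
        w = frame.iloc[:, 0].to_numpy(dtype=float)
        y = frame.iloc[:, 1].to_numpy(dtype=float)[None, :]
        w, y = _sorted_axis(w, y, str(f))
        if axis is None:
            axis = w
        elif w.shape != axis.shape or not np.allclose(w, axis):
            raise ValueError(f"{f}: wavenumber axis differs from {files[0]}")
        rows.append(y[0])
        ids.append(f.stem)
    assert axis is not None
    return axis, np.vstack(rows), ids


def read_spectra(path: str | Path, metadata_path: str | Path) -> SpectraSet:
    """Read a spectra set from a wide matrix file or a directory of
    two-column files, joined with its metadata table.

    The axis is returned ascending regardless of on-disk order; intensities
    are reordered consistently. Spectrum ids present in exactly one of the
    matrix and the metadata are a hard error.
    """
    path = Path(path)
    meta = _read_metadata(metadata_path)
    if path.is_dir():
        wav, matrix, ids = _read_directory(path)
    else:
        wav, matrix, ids = _read_wide(path)

    meta_ids = list(meta["spectrum_id"])
    if set(meta_ids) != set(ids):
        only_meta = sorted(set(meta_ids) - set(ids))
        only_data = sorted(set(ids) - set(meta_ids))
        raise ValueError(
            "metadata and spectra ids do not match: "
            f"only in metadata {only_meta[:5]}, only in data {only_data[:5]}"
        )
    lookup = meta.set_index("spectrum_id")
    return SpectraSet(
        wavenumbers=wav,
        intensities=matrix,
        spectrum_ids=ids,
        subject_ids=[lookup.loc[i, "subject_id"] for i in ids],
        class_labels=[lookup.loc[i, "class"] for i in ids],
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_spectra(spectra: SpectraSet, path: str | Path,
                  metadata_path: str | Path | None = None) -> Path:
    """Write a spectra set as a wide CSV (and optionally its metadata CSV).

    Round-trips with :func:`read_spectra` to numeric tolerance 1e-9.
    Empty sets and non-finite intensities are refused.
    """
    if spectra.n_spectra == 0 or spectra.n_wavenumbers == 0:
        raise ValueError("refusing to write an empty spectra set")
    bad = ~np.isfinite(spectra.intensities)
    if bad.any():
        offenders = sorted({spectra.spectrum_ids[i]
                            for i in np.unique(np.argwhere(bad)[:, 0])})
        raise ValueError(f"non-finite intensities in spectra {offenders}")
    path = Path(path)
    frame = pd.DataFrame(
        spectra.intensities.T, columns=spectra.spectrum_ids
    )
    frame.insert(0, "wavenumber_cm1", spectra.wavenumbers)
    frame.to_csv(path, index=False, float_format="%.12g")
    if metadata_path is not None:
        pd.DataFrame(
            {
                "spectrum_id": spectra.spectrum_ids,
                "subject_id": spectra.subject_ids,
                "class": spectra.class_labels,
            }
        ).to_csv(metadata_path, index=False)
    return path
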