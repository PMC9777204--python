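"""Synthetic serum-like Raman cohorts and anti-dsDNA audit tables.

The generator emulates the structure the analysis pipeline assumes, so every
stage is testable without instrument data:

* a fixed library of ~18 Gaussian serum bands across 850-1730 cm^-1
  (strong phenylalanine ring-breathing near 1002, CH2 deformation near 1452
  and amide I near 1655 cm^-1) on an exponentially decaying fluorescence
  background;
* a replicate design of 4 healthy-control subjects x 20 replicates and
  8 disease subjects with 17-20 replicates each (234 spectra in total,
  154 disease / 80 control), optionally split into three serology-defined
  disease subgroups of 40/37/77 spectra;
* class effects as multiplicative band-amplitude shifts at 12 disease-
  associated wavenumbers (11 increased, decreased at 1155 cm^-1), applied
  before normalisation so vector normalisation redistributes them the way
  relative-intensity analysis sees real shifts;
* noise at three levels: a per-subject global intensity factor and
  per-subject per-band amplitude jitter (between-subject variation);
  per-replicate per-band amplitude jitter plus a global gain (within-subject
  replicate noise, which in averaged biofluid spectra is dominated by
  coherent band-intensity fluctuation from drying/focus variation rather
  than white detector noise); and a small additive white-noise floor.

A companion generator produces clinical-audit tables (ELIA IU/mL value,
cascade CLIFT category, diagnosis flag) with configurable marginal rates.
All outputs are reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral_io import SpectraSet

__all__ = [
    "CohortDesign",
    "EffectSpec",
    "AuditRates",
    "AuditTable",
    "PLANTED_WAVENUMBERS",
    "PLANTED_DIRECTIONS",
    "BASE_BANDS",
    "generate_cohort",
    "default_two_class",
    "default_four_group",
    "generate_audit",
]

#: The 12 disease-discriminatory band centres (cm^-1) and their direction of
#: change in the disease group (+1 increased, -1 decreased).
PLANTED_WAVENUMBERS: tuple[float, ...] = (
    1002.0, 1070.0, 1113.0, 1155.0, 1286.0, 1346.0,
    1408.0, 1452.0, 1527.0, 1596.0, 1639.0, 1727.0,
)
PLANTED_DIRECTIONS: tuple[int, ...] = (
    +1, +1, +1, -1, +1, +1, +1, +1, +1, +1, +1, +1,
)

#: Serum band library: (centre cm^-1, Gaussian sigma cm^-1, amplitude a.u.).
#: Amplitudes are relative to the strongest band (phenylalanine, 1002).
#: Sharp resolved marker bands ride on two very broad concave components
#: modelling the unresolved envelope of overlapping protein/lipid bands that
#: dominates the total energy of baseline-corrected serum spectra; the
#: envelope keeps the 12 disease-marker bands a small share of the spectral
#: norm, as in real biofluid data.
BASE_BANDS: tuple[tuple[float, float, float], ...] = (
    (852.0, 7.0, 0.25),
    (940.0, 7.0, 0.18),
    (1002.0, 3.5, 1.00),
    (1031.0, 6.0, 0.28),
    (1070.0, 4.0, 0.45),
    (1113.0, 4.0, 0.45),
    (1155.0, 4.0, 0.45),
    (1210.0, 7.0, 0.18),
    (1286.0, 4.0, 0.45),
    (1320.0, 6.0, 0.22),
    (1346.0, 4.0, 0.45),
    (1408.0, 4.0, 0.45),
    (1452.0, 5.0, 0.85),
    (1527.0, 4.0, 0.45),
    (1596.0, 4.0, 0.45),
    (1639.0, 5.0, 0.50),
    (1655.0, 9.0, 0.45),
    (1727.0, 4.0, 0.45),
    (1300.0, 250.0, 2.20),
    (1560.0, 220.0, 2.20),
)

# Subject layout shared by the two-class and four-group designs: the three
# subjects with fewer than 20 replicates use 17/18/19 so group totals are
# 40 / 37 / 77 (80 control, 154 disease, 234 in all).
_HC_REPLICATES = (20, 20, 20, 20)
_SUBGROUP_REPLICATES = {
    "CLIFT-N/A": (20, 20),        # 40
    "CLIFT-Neg": (20, 17),        # 37
    "CLIFT-Pos": (20, 20, 18, 19),  # 77
}


@dataclass
class CohortDesign:
    """Groups as (label, replicate counts per subject) plus the axis."""

    groups: tuple[tuple[str, tuple[int, ...]], ...]
    axis_start: float = 400.0
    axis_stop: float = 1800.0
    axis_step: float = 2.0

    def __post_init__(self) -> None:
        if self.axis_step <= 0:
            raise ValueError("axis_step must be positive")
        for label, reps in self.groups:
            if len(reps) < 1 or any(r < 1 for r in reps):
                raise ValueError(
                    f"group {label!r}: need >= 1 subject, each with >= 1 replicate"
                )

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(self.axis_start, self.axis_stop + self.axis_step / 2,
                         self.axis_step)


@dataclass
class EffectSpec:
    """Band model, class effects and noise scales for the generator.

    ``planted_shifts`` maps class label -> {band centre: signed relative
    amplitude shift}; bands not listed are identical across classes.
    Noise scales are relative to the strongest base band (amplitude 1).
    """

    base_bands: tuple[tuple[float, float, float], ...] = BASE_BANDS
    planted_shifts: dict[str, dict[float, float]] = field(default_factory=dict)
    background_amplitude: float = 1.5
    background_decay: float = 700.0      # cm^-1 e-folding of the fluorescence
    subject_sd: float = 0.004            # per-subject per-band amplitude jitter
    subject_gain_sd: float = 0.05        # per-subject global intensity factor
    replicate_sd: float = 0.02           # per-replicate per-band amplitude jitter
    gain_sd: float = 0.02                # per-replicate multiplicative gain
    noise_floor_sd: float = 0.002        # additive white noise SD per point

    def __post_init__(self) -> None:
        for c, w, a in self.base_bands:
            if w <= 0:
                raise ValueError(f"band at {c} cm^-1 has non-positive width")
        for sd in (self.subject_sd, self.subject_gain_sd, self.replicate_sd,
                   self.gain_sd, self.noise_floor_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")


def _band_matrix(wavenumbers: np.ndarray,
                 bands: tuple[tuple[float, float, float], ...]) -> np.ndarray:
    """(n_bands, n_points) unit-amplitude Gaussian profiles."""
    w = wavenumbers[None, :]
    centres = np.array([b[0] for b in bands])[:, None]
    sigmas = np.array([b[1] for b in bands])[:, None]
    return np.exp(-0.5 * ((w - centres) / sigmas) ** 2)


def generate_cohort(design: CohortDesign, effects: EffectSpec,
                    seed: int | None = None) -> SpectraSet:
    """Simulate a replicate-structured cohort of serum-like spectra.

    Each spectrum is ``(background + sum of class-shifted Gaussian bands)``
    scaled by subject and replicate gains, plus additive noise. Subject and
    class identity are recorded in the metadata; output is byte-identical
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    w = design.wavenumbers
    profiles = _band_matrix(w, effects.base_bands)
    base_amps = np.array([b[2] for b in effects.base_bands])
    centres = np.array([b[0] for b in effects.base_bands])
    background = effects.background_amplitude * np.exp(
        -(w - w[0]) / effects.background_decay
    )

    shift_by_class: dict[str, np.ndarray] = {}
    for label, _ in design.groups:
        shifts = np.zeros_like(base_amps)
        for centre, rel in effects.planted_shifts.get(label, {}).items():
            matches = np.flatnonzero(np.abs(centres - centre) < 1e-6)
            if matches.size != 1:
                raise ValueError(
                    f"planted shift at {centre} cm^-1 does not match exactly "
                    "one library band"
                )
            shifts[matches[0]] += rel
        shift_by_class[label] = shifts

    rows, spectrum_ids, subject_ids, class_labels = [], [], [], []
    for label, reps in design.groups:
        for s_idx, n_reps in enumerate(reps):
            subject = f"{label}-s{s_idx + 1}"
            subj_gain = np.exp(rng.normal(0.0, effects.subject_gain_sd))
            band_jitter = rng.normal(0.0, effects.subject_sd, base_amps.size)
            amps = base_amps * (1.0 + band_jitter) * (1.0 + shift_by_class[label])
            for r in range(n_reps):
                rep_jitter = rng.normal(0.0, effects.replicate_sd, base_amps.size)
                signal = (amps * (1.0 + rep_jitter)) @ profiles + background
                gain = np.exp(rng.normal(0.0, effects.gain_sd))
                noise = rng.normal(0.0, effects.noise_floor_sd, w.size)
                rows.append(signal * subj_gain * gain + noise)
                spectrum_ids.append(f"{subject}-r{r + 1:02d}")
                subject_ids.append(subject)
                class_labels.append(label)
    return SpectraSet(
        wavenumbers=w,
        intensities=np.vstack(rows),
        spectrum_ids=spectrum_ids,
        subject_ids=subject_ids,
        class_labels=class_labels,
    )


def _disease_shifts(scale: float) -> dict[float, float]:
    return {
        wn: direction * scale
        for wn, direction in zip(PLANTED_WAVENUMBERS, PLANTED_DIRECTIONS)
    }


def default_two_class(seed: int | None = None,
                      shift_multiple: float = 3.0,
                      effects: EffectSpec | None = None) -> SpectraSet:
    """The standard two-class cohort: 80 HC and 154 SLE spectra with the 12
    disease band shifts planted at ``shift_multiple`` x the replicate noise
    SD (default 3x)."""
    effects = effects or EffectSpec()
    sle_reps = tuple(
        r for g in ("CLIFT-N/A", "CLIFT-Neg", "CLIFT-Pos")
        for r in _SUBGROUP_REPLICATES[g]
    )
    design = CohortDesign(groups=(("HC", _HC_REPLICATES), ("SLE", sle_reps)))
    effects.planted_shifts = {
        "SLE": _disease_shifts(shift_multiple * effects.replicate_sd)
    }
    return generate_cohort(design, effects, seed=seed)


# Subgroup-specific band modulations (relative sign pattern); scaled by
# 2x the replicate noise SD and added on top of the shared disease effect.
_SUBGROUP_MODULATIONS: dict[str, dict[float, float]] = {
    "CLIFT-N/A": {1070.0: +1.0, 1346.0: -1.0, 1596.0: +1.0},
    "CLIFT-Neg": {1113.0: +1.0, 1408.0: +1.0, 1727.0: -1.0},
    "CLIFT-Pos": {1286.0: -1.0, 1527.0: +1.0, 1639.0: +1.0},
}


def default_four_group(seed: int | None = None,
                       shift_multiple: float = 3.0,
                       subgroup_multiple: float = 2.0,
                       effects: EffectSpec | None = None) -> SpectraSet:
    """Four-group cohort (HC 80 / disease subgroups 40, 37, 77 spectra):
    the shared disease effect of :func:`default_two_class` plus smaller
    subgroup-specific band modulations at ``subgroup_multiple`` x the
    replicate noise SD."""
    effects = effects or EffectSpec()
    shared = _disease_shifts(shift_multiple * effects.replicate_sd)
    planted: dict[str, dict[float, float]] = {}
    for label, mods in _SUBGROUP_MODULATIONS.items():
        shifts = dict(shared)
        for wn, sign in mods.items():
            shifts[wn] = shifts.get(wn, 0.0) + (
                sign * subgroup_multiple * effects.replicate_sd
            )
        planted[label] = shifts
    effects.planted_shifts = planted
    design = CohortDesign(
        groups=(
            ("HC", _HC_REPLICATES),
            ("CLIFT-N/A", _SUBGROUP_REPLICATES["CLIFT-N/A"]),
            ("CLIFT-Neg", _SUBGROUP_REPLICATES["CLIFT-Neg"]),
            ("CLIFT-Pos", _SUBGROUP_REPLICATES["CLIFT-Pos"]),
        )
    )
    return generate_cohort(design, effects, seed=seed)


# ---------------------------------------------------------------------------
# clinical audit tables
# ---------------------------------------------------------------------------

@dataclass
class AuditRates:
    """Marginal rates of the simulated anti-dsDNA testing cascade.

    Defaults follow the audited cascade: 128/600 ELIA-positive, 27/128
    CLIFT-positive among those, category mix 7:16:4
    (weak/positive/strong), and diagnosis mixes per stratum
    (SLE, SLE-overlap, other).
    """

    elia_pos: float = 128.0 / 600.0
    clift_pos_given_elia: float = 27.0 / 128.0
    category_mix: tuple[float, float, float] = (7 / 27, 16 / 27, 4 / 27)
    diagnosis_dual_pos: tuple[float, float, float] = (0.85, 0.04, 0.11)
    diagnosis_elia_only: tuple[float, float, float] = (0.23, 0.075, 0.695)
    diagnosis_elia_neg: tuple[float, float, float] = (0.04, 0.01, 0.95)
    elia_threshold: float = 10.0

    def __post_init__(self) -> None:
        probs = [self.elia_pos, self.clift_pos_given_elia,
                 *self.category_mix, *self.diagnosis_dual_pos,
                 *self.diagnosis_elia_only, *self.diagnosis_elia_neg]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rates must lie in [0, 1]")


@dataclass
class AuditTable:
    """One row per anti-dsDNA request.

    Columns: ``request_id``, ``elia_iuml`` (IU/mL), ``clift_category``
    (ordinal 0 negative, 1 weak positive, 2 positive, 3 strong positive;
    missing where CLIFT was not performed), ``diagnosis``
    ({SLE, SLE-overlap, other}).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"request_id", "elia_iuml", "clift_category", "diagnosis"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"audit table is missing columns {sorted(missing)}")
        if (self.data["elia_iuml"].dropna() < 0).any():
            raise ValueError("ELIA values must be >= 0")
        cats = self.data["clift_category"].dropna()
        if not cats.isin([0, 1, 2, 3]).all():
            raise ValueError("CLIFT categories must be in {0, 1, 2, 3}")

    def __len__(self) -> int:
        return len(self.data)


_DIAGNOSES = ("SLE", "SLE-overlap", "other")


def _lognormal_cluster(rng: np.random.Generator, mean_iuml: float,
                       sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(mean_iuml), sigma, n))


def generate_audit(n_requests: int = 600,
                   rates: AuditRates | None = None,
                   seed: int | None = None) -> AuditTable:
    """Simulate an anti-dsDNA audit table with the cascade testing protocol.

    ELIA positivity (strict > threshold) triggers CLIFT; ELIA values are
    drawn log-normal per stratum, with CLIFT-positive values a 3-component
    mixture (low / mid-range 100-170 / high > 379 IU/mL) so that strong
    positives concentrate at the high end.
    """
    rates = rates or AuditRates()
    if n_requests < 1:
        raise ValueError("n_requests must be >= 1")
    rng = np.random.default_rng(seed)
    thr = rates.elia_threshold
    records = []
    for i in range(n_requests):
        elia_positive = rng.random() < rates.elia_pos
        if not elia_positive:
            value = min(np.exp(rng.normal(np.log(3.0), 0.7)), thr)
            category: float | None = None
            diag_mix = rates.diagnosis_elia_neg
        else:
            clift_positive = rng.random() < rates.clift_pos_given_elia
            if clift_positive:
                category = 1 + int(rng.choice(3, p=np.asarray(rates.category_mix)
                                              / sum(rates.category_mix)))
                # 3-component value mixture keyed by category strength
                if category == 1:
                    value = thr + _lognormal_cluster(rng, 15.0, 0.5, 1)[0]
                elif category == 2:
                    low = thr + _lognormal_cluster(rng, 20.0, 0.5, 1)[0]
                    mid = rng.uniform(100.0, 170.0)
                    high = 379.0 + _lognormal_cluster(rng, 80.0, 0.5, 1)[0]
                    value = rng.choice([low, mid, high], p=[0.4, 0.35, 0.25])
                else:
                    value = 250.0 + _lognormal_cluster(rng, 120.0, 0.6, 1)[0]
                diag_mix = rates.diagnosis_dual_pos
            else:
                category = 0
                value = thr + _lognormal_cluster(rng, 12.0, 0.8, 1)[0]
                diag_mix = rates.diagnosis_elia_only
        diag = _DIAGNOSES[rng.choice(3, p=np.asarray(diag_mix) / sum(diag_mix))]
        records.append(
            {
                "request_id": f"req{i + 1:04d}",
                "elia_iuml": float(value),
                "clift_category": category,
                "diagnosis": diag,
            }
        )
    frame = pd.DataFrame.from_records(records)
    frame["clift_category"] = frame["clift_category"].astype("Float64")
    return AuditTable(data=frame)
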