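"""Synthetic PPG cohorts with CapnoBase-like structure.

The real study data (41 pulse-oximeter recordings, 20 cardiovascular-disease
and 21 normal subjects, 144,000 samples each at 200 samples/s) is not
redistributable, so this module generates seeded surrogate cohorts with the
same shape and a tunable class difference.

Each beat is the sum of two Gaussian lobes — a systolic peak and a smaller,
later dicrotic wave — which is the standard two-lobe description of PPG pulse
morphology, riding on a constant perfusion baseline.  Disease is emulated by
damping the pulse amplitude and baseline (reduced peripheral perfusion),
damping the dicrotic wave further, broadening the systolic peak and raising
beat-interval variability, all in proportion to ``morphology_shift``; at
shift 0 the class templates coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CVD = "CVD"
NORMAL = "NORMAL"

__all__ = [
    "CVD",
    "NORMAL",
    "CohortSpec",
    "PPGRecord",
    "generate_cohort",
    "generate_feature_blobs",
    "write_cohort_csv",
]


@dataclass(frozen=True)
class PPGRecord:
    """One subject's raw signal, label and sampling rate."""

    subject_id: str
    signal: np.ndarray
    fs: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in (CVD, NORMAL):
            raise ValueError(f"label must be {CVD!r} or {NORMAL!r}, got {self.label!r}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"subject {self.subject_id}: signal has non-finite values")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the study dataset: 20 CVD + 21 normal subjects, 200
    samples/s, 720 s per subject (144,000 samples, i.e. 720 one-second
    segments of 200 samples).
    """

    n_cvd: int = 20
    n_normal: int = 21
    fs: float = 200.0
    duration: float = 720.0
    #: mean heart rate (beats/min) per class, (CVD, NORMAL)
    heart_rate_mean: tuple[float, float] = (76.0, 68.0)
    #: class separability knob in [0, 1]; 0 makes the classes identical
    morphology_shift: float = 0.5
    #: additive white-noise standard deviation, signal units
    noise_sd: float = 0.05
    #: motion-artifact bumps per minute
    artifact_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cvd < 0 or self.n_normal < 0:
            raise ValueError("subject counts must be non-negative")
        if not (0.0 <= self.morphology_shift <= 1.0):
            raise ValueError("morphology_shift must lie in [0, 1]")
        if self.noise_sd < 0 or self.artifact_rate < 0:
            raise ValueError("noise_sd and artifact_rate must be non-negative")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"fs*duration must be an integer number of samples, got {n!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


# Beat template constants (fractions of the beat interval / systolic amplitude).
_SYS_AMP = 1.0
_DIC_AMP = 0.45
_SYS_CENTER = 0.30
_DIC_CENTER = 0.62
_SYS_WIDTH = 0.085
_DIC_WIDTH = 0.12
# Coefficient of variation of beat intervals for a healthy subject.
_IBI_CV = 0.05
# Healthy perfusion baseline (DC level of the optical signal, signal units).
_BASELINE = 0.5


def _beat_params(label: str, shift: float) -> tuple[float, float, float, float]:
    """(systolic amp, dicrotic amp, systolic width, dicrotic width) fractions.

    Disease damps the whole pulse (reduced peripheral pulse amplitude), damps
    the dicrotic wave further, and broadens the systolic peak; all three
    effects scale with ``shift`` and vanish at shift 0.
    """
    if label == CVD:
        damp = 1.0 - 0.6 * shift
        return (
            _SYS_AMP * damp,
            _DIC_AMP * damp * (1.0 - 0.6 * shift),
            _SYS_WIDTH * (1.0 + 0.4 * shift),
            _DIC_WIDTH,
        )
    return _SYS_AMP, _DIC_AMP, _SYS_WIDTH, _DIC_WIDTH


def _render_subject(spec: CohortSpec, label: str, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_samples
    fs = spec.fs
    hr = spec.heart_rate_mean[0] if label == CVD else spec.heart_rate_mean[1]
    mean_ibi = 60.0 / hr
    # disease raises beat-interval variability in proportion to the shift
    cv = _IBI_CV * (1.0 + 0.5 * spec.morphology_shift) if label == CVD else _IBI_CV
    # Gamma-distributed beat intervals: positive and right-skewed.
    shape = 1.0 / cv**2
    scale = mean_ibi / shape
    n_beats = int(np.ceil(spec.duration / mean_ibi * 1.2)) + 4
    ibis = rng.gamma(shape, scale, size=n_beats)
    onsets = np.concatenate([[0.0], np.cumsum(ibis)])

    a1, a2, w1, w2 = _beat_params(label, spec.morphology_shift)
    # reduced peripheral perfusion lowers the DC level in the diseased class
    if label == CVD:
        baseline = _BASELINE * (1.0 - 0.5 * spec.morphology_shift)
    else:
        baseline = _BASELINE
    signal = np.full(n, baseline)
    t_all = np.arange(n) / fs
    for k in range(len(onsets) - 1):
        t0 = onsets[k]
        ibi = onsets[k + 1] - t0
        if t0 > spec.duration:
            break
        lo = int(np.floor(t0 * fs))
        hi = min(n, int(np.ceil((t0 + ibi) * fs)) + 1)
        if hi <= lo:
            continue
        u = (t_all[lo:hi] - t0) / ibi  # beat phase in [0, 1)
        beat = a1 * np.exp(-0.5 * ((u - _SYS_CENTER) / w1) ** 2)
        beat += a2 * np.exp(-0.5 * ((u - _DIC_CENTER) / w2) ** 2)
        signal[lo:hi] += beat

    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=n)
    if spec.artifact_rate > 0:
        n_events = rng.poisson(spec.artifact_rate * spec.duration / 60.0)
        for _ in range(n_events):
            center = rng.uniform(0.0, spec.duration)
            width = rng.uniform(0.15, 0.5)
            amp = rng.uniform(1.5, 3.0) * rng.choice([-1.0, 1.0])
            signal += amp * np.exp(-0.5 * ((t_all - center) / width) ** 2)
    return signal


def generate_cohort(spec: CohortSpec) -> list[PPGRecord]:
    """Generate a labeled cohort of synthetic PPG records.

    The same ``(spec, seed)`` always produces a bit-identical cohort; per
    subject streams are drawn from independent spawned generators so subject
    k's signal does not depend on how many subjects precede it in the other
    class.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [CVD] * spec.n_cvd + [NORMAL] * spec.n_normal
    children = rng.spawn(len(labels))
    records = []
    for i, (label, child) in enumerate(zip(labels, children)):
        sid = f"{'cvd' if label == CVD else 'norm'}{i + 1:02d}"
        records.append(
            PPGRecord(sid, _render_subject(spec, label, child), spec.fs, label)
        )
    return records


def _blob_direction(dim: int) -> np.ndarray:
    """Fixed unit direction for the class-mean offset.

    A sinusoidal pattern (rather than e.g. the all-ones vector) is used so the
    offset has within-vector structure: classifiers sensitive to the shape of
    a feature vector (detrended-fluctuation profiles, piecewise detrending)
    see the class difference, while for distance-based classifiers only the
    Euclidean separation matters.
    """
    i = np.arange(dim)
    cycles = max(1, dim // 16)
    u = np.sin(2.0 * np.pi * cycles * (i + 0.5) / dim)
    return u / np.linalg.norm(u)


def generate_feature_blobs(
    n_per_class: int, dim: int, separation: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian clouds with identity covariance and class means a fixed
    Euclidean distance apart; the unit-test workhorse for classifiers.

    Returns ``(X, y)`` with ``2 * n_per_class`` rows; the shifted class is
    labeled CVD.  Rows are deterministic given the seed.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    mu = separation * _blob_direction(dim)
    x_norm = rng.normal(size=(n_per_class, dim))
    x_cvd = mu + rng.normal(size=(n_per_class, dim))
    X = np.vstack([x_cvd, x_norm])
    y = np.array([CVD] * n_per_class + [NORMAL] * n_per_class)
    return X, y


def write_cohort_csv(records: list[PPGRecord], signals_path, labels_path) -> None:
    """Write a cohort as one CSV signal column per subject plus a JSON label
    sidecar ``{subject_id: label}``."""
    if not records:
        raise ValueError("empty cohort")
    lengths = {len(r.signal) for r in records}
    if len(lengths) != 1:
        raise ValueError("all subjects must have equal signal lengths")
    df = pd.DataFrame({r.subject_id: r.signal for r in records})
    df.to_csv(signals_path, index=False, float_format="%.10g")
    labels = {r.subject_id: r.label for r in records}
    Path(labels_path).write_text(json.dumps(labels, indent=1, sort_keys=True))
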