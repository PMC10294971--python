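"""Loading, validation, optional denoising and one-second segmentation.

Every downstream stage consumes ``SegmentMatrix`` objects: per subject, the
signal cut into contiguous non-overlapping one-second rows (200 samples each
at the study's 200 samples/s), a 720 x 200 matrix for a full-length record.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CVD, NORMAL, PPGRecord

logger = logging.getLogger(__name__)

__all__ = ["SegmentMatrix", "read_cohort", "segment", "concatenate", "denoise",
           "write_segments_csv"]


@dataclass(frozen=True)
class SegmentMatrix:
    """Per-subject matrix of one-second segments, rows in temporal order."""

    subject_id: str
    segments: np.ndarray  # [n_segments x segment_len]
    label: str
    fs: float

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_len(self) -> int:
        return self.segments.shape[1]


def read_cohort(signals_path, labels_path) -> list[PPGRecord]:
    """Read a cohort written by :func:`ppgcvd.synth.write_cohort_csv`.

    The CSV holds one signal column per subject (header = subject id); the
    JSON sidecar maps subject id to label.  A subject without a label, an
    unknown label, or a non-finite cell is a hard error naming the culprit.
    """
    df = pd.read_csv(signals_path)
    labels = json.loads(Path(labels_path).read_text())
    records = []
    for col in df.columns:
        sig = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(sig))
        if bad.size:
            raise ValueError(
                f"non-finite value in column {col!r} at row {int(bad[0])}"
            )
        if col not in labels:
            raise ValueError(f"subject {col!r} has no label in {labels_path}")
        if labels[col] not in (CVD, NORMAL):
            raise ValueError(f"subject {col!r}: unknown label {labels[col]!r}")
        records.append(PPGRecord(col, sig, _infer_fs(labels), labels[col]))
    extra = set(labels) - set(df.columns) - {"_fs"}
    if extra:
        warnings.warn(f"labels without signal columns ignored: {sorted(extra)}")
    return records


def _infer_fs(labels: dict) -> float:
    # The sidecar may carry an optional "_fs" entry; default to the study rate.
    return float(labels.get("_fs", 200.0))


def segment(record: PPGRecord) -> SegmentMatrix:
    """Cut a record into one-second segments.

    ``n_segments = floor(len(signal) / fs)``; a trailing remainder shorter
    than one segment is dropped (and logged), matching the study's exact
    720-segments-per-subject bookkeeping.
    """
    seg_len = int(round(record.fs))
    n = len(record.signal)
    if n < seg_len:
        raise ValueError(
            f"subject {record.subject_id}: signal shorter than one segment "
            f"({n} < {seg_len} samples)"
        )
    n_seg = n // seg_len
    dropped = n - n_seg * seg_len
    if dropped:
        logger.info("subject %s: dropped %d trailing samples", record.subject_id, dropped)
    mat = record.signal[: n_seg * seg_len].reshape(n_seg, seg_len)
    return SegmentMatrix(record.subject_id, mat, record.label, record.fs)


def concatenate(segments: SegmentMatrix) -> PPGRecord:
    """Inverse of :func:`segment` for signals that are a segment multiple."""
    return PPGRecord(
        segments.subject_id, segments.segments.reshape(-1).copy(),
        segments.fs, segments.label,
    )


def denoise(segments: SegmentMatrix, enabled: bool = False) -> SegmentMatrix:
    """Remove the most artifact-like component from a segment matrix.

    Single-channel recordings admit no true independent-component separation,
    so this treats the segment matrix as multivariate data with segments as
    variables (time samples as observations), whitens it, drops the component
    with the highest sample kurtosis — heavy-tailed components are the usual
    artifact proxy — and back-projects.  Shape is preserved.  Disabled (the
    default) it is the identity, keeping the main pipeline reproducible
    without this heuristic.
    """
    if not enabled:
        return segments
    X = segments.segments.T.astype(float)  # [n_obs=seg_len x n_vars=n_segments]
    if segments.n_segments < 2:
        raise ValueError("denoise requires at least 2 segments")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if s.size == 0 or s[0] <= 0 or np.sum(s > tol) < 2:
        warnings.warn("rank-deficient segment matrix; denoise falls back to identity")
        return segments
    scores = U * s  # component score series over time samples
    with np.errstate(invalid="ignore"):
        m2 = np.mean(scores**2, axis=0)
        kurt = np.mean(scores**4, axis=0) / np.where(m2 > 0, m2**2, 1.0)
    kurt[s <= tol] = -np.inf
    worst = int(np.argmax(kurt))
    s_kept = s.copy()
    s_kept[worst] = 0.0
    cleaned = (U * s_kept) @ Vt + mean
    return SegmentMatrix(segments.subject_id, cleaned.T, segments.label, segments.fs)


def write_segments_csv(segments: SegmentMatrix, path) -> None:
    """Export one subject's segments for inspection (1-based segment index)."""
    df = pd.DataFrame(
        segments.segments,
        index=pd.RangeIndex(1, segments.n_segments + 1, name="segment"),
    )
    df.to_csv(path, float_format="%.10g")
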