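"""Quantitative evaluation of extracted fetal ECG.

Two beat-consistency SNR measures operate on a matrix ``U`` (N samples ×
M beat-aligned segments, each column standardised):

* eigenvalue SNR — ``λ_max / (Σλ − λ_max)`` over the eigenvalues of
  ``UᵀU``; large when one common beat shape dominates the segments;
* cross-correlation SNR — ``η / (1 − η)`` where η is the mean pairwise
  Pearson correlation of the (unit-norm) standardised segments.

Beat-detection accuracy is scored by one-to-one matching of detected
against reference R-peaks within a tolerance (±50 ms default), giving
TP/FP/FN and the usual sensitivity / positive predictive accuracy / F1
percentages.  An Amari performance index is provided as a separation
oracle for tests with known mixing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .qrs import BeatAnnotations

__all__ = [
    "SegmentMatrix",
    "DetectionCounts",
    "build_segment_matrix",
    "snr_eig",
    "snr_rms",
    "match_beats",
    "detection_stats",
    "amari_index",
]

logger = logging.getLogger(__name__)

#: Default beat-matching tolerance (a common fetal-QRS convention).
DEFAULT_TOL_MS = 50.0


@dataclass
class SegmentMatrix:
    """N × M matrix of standardised beat-aligned segments (M ≥ 2 columns)."""

    U: np.ndarray

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 2 or self.U.shape[1] < 2:
            raise ValidationError("segment matrix must be N × M with M >= 2")
        if np.any(np.abs(self.U.mean(axis=0)) > 1e-8):
            raise ValidationError("segment columns must have zero mean")
        if np.any(np.abs(self.U.var(axis=0) - 1.0) > 1e-6):
            raise ValidationError("segment columns must have unit variance")

    @property
    def n_segments(self) -> int:
        return self.U.shape[1]


@dataclass
class DetectionCounts:
    """TP/FP/FN contingency of beat matching."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")

    @property
    def n_reference(self) -> int:
        return self.tp + self.fn

    @property
    def n_detected(self) -> int:
        return self.tp + self.fp


def build_segment_matrix(
    x: np.ndarray,
    beats: BeatAnnotations,
    pre_ms: float = 100.0,
    post_ms: float = 100.0,
) -> SegmentMatrix:
    """Cut beat-aligned windows ``[R − pre_ms, R + post_ms]`` into columns.

    Beats whose window falls outside the record, and zero-variance
    segments, are dropped (logged); fewer than 2 usable segments is a
    validation error.  Each kept column is standardised to zero mean and
    unit variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    pre = int(round(pre_ms * beats.fs / 1000.0))
    post = int(round(post_ms * beats.fs / 1000.0))
    cols = []
    n_dropped = 0
    for r in beats.samples:
        a, b = r - pre, r + post + 1
        if a < 0 or b > x.size:
            n_dropped += 1
            continue
        seg = x[a:b]
        sd = seg.std()
        if sd == 0:
            n_dropped += 1
            warnings.warn("dropping zero-variance beat segment", stacklevel=2)
            continue
        cols.append((seg - seg.mean()) / sd)
    if n_dropped:
        logger.info("build_segment_matrix: dropped %d unusable beats", n_dropped)
    if len(cols) < 2:
        raise ValidationError(
            f"need at least 2 usable beat segments, got {len(cols)}"
        )
    return SegmentMatrix(np.column_stack(cols))


def snr_eig(U: SegmentMatrix) -> float:
    """Eigenvalue SNR: ``λ_max / (Σλ − λ_max)`` over eigenvalues of UᵀU.

    Returns ``inf`` when the segments are rank one (all eigenvalue mass
    in λ_max, denominator below 1e-12).
    """
    lam = np.linalg.eigvalsh(U.U.T @ U.U)
    lam_max = lam[-1]
    denom = lam.sum() - lam_max
    if denom < 1e-12:
        return float("inf")
    return float(lam_max / denom)


def snr_rms(U: SegmentMatrix) -> float:
    """Cross-correlation SNR: ``η / (1 − η)``.

    η is the mean pairwise inner product of the unit-norm standardised
    columns, i.e. the mean pairwise Pearson correlation of the segments.
    η ≈ 1 returns ``inf``; a non-positive η is floored to SNR 0 (with a
    warning), as anti-correlated segments carry no common beat shape.
    """
    m = U.n_segments
    f = U.U / np.linalg.norm(U.U, axis=0)
    gram = f.T @ f
    eta = float((gram.sum() - np.trace(gram)) / (m * (m - 1)))
    if eta >= 1.0 - 1e-12:
        return float("inf")
    if eta <= 0.0:
        warnings.warn("mean segment correlation is non-positive; SNR floored to 0")
        return 0.0
    return float(eta / (1.0 - eta))


def match_beats(
    detected: BeatAnnotations,
    reference: BeatAnnotations,
    tol_ms: float = DEFAULT_TOL_MS,
) -> DetectionCounts:
    """Greedy nearest-neighbour one-to-one beat matching within ±tol_ms.

    Candidate pairs are considered in order of increasing time distance;
    each detected and each reference beat is matched at most once.
    Matched pairs count as TP, unmatched detections as FP, unmatched
    references as FN.
    """
    if detected.fs != reference.fs:
        raise ValidationError(
            f"sampling rates differ: {detected.fs} vs {reference.fs}"
        )
    tol = tol_ms * detected.fs / 1000.0
    det = detected.samples
    ref = reference.samples
    pairs = [
        (abs(int(d) - int(r)), i, j)
        for i, d in enumerate(det)
        for j, r in enumerate(ref)
        if abs(int(d) - int(r)) <= tol
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        tp += 1
    return DetectionCounts(tp=tp, fp=len(det) - tp, fn=len(ref) - tp)


def detection_stats(counts: DetectionCounts) -> tuple[float, float, float]:
    """Sensitivity, positive predictive accuracy and F1, as percentages.

    ``Sens = TP/(TP+FN)``, ``PPA = TP/(TP+FP)``,
    ``F1 = 2·TP/(2·TP+FN+FP)``, each ×100 and rounded to 2 decimals.
    With no detections at all (TP+FP = 0) PPA is reported as 0 with a
    warning.
    """
    if counts.n_reference == 0:
        raise ValidationError("detection_stats requires TP + FN > 0")
    sens = 100.0 * counts.tp / counts.n_reference
    if counts.n_detected == 0:
        warnings.warn("no detections: PPA reported as 0")
        ppa = 0.0
    else:
        ppa = 100.0 * counts.tp / counts.n_detected
    f1 = 100.0 * 2 * counts.tp / (2 * counts.tp + counts.fn + counts.fp)
    return round(sens, 2), round(ppa, 2), round(f1, 2)


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Amari performance index of ``P = W @ A``, normalised to [0, 1].

    Zero iff P is a scaled permutation, i.e. the unmixing ``W`` inverts
    the (whitened-coordinate) mixing ``A`` up to source order and scale.
    """
    W = np.asarray(W, dtype=float)
    A = np.asarray(A, dtype=float)
    if W.shape != A.shape or W.shape[0] != W.shape[1]:
        raise ValidationError("amari_index expects square matrices of equal size")
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValidationError("true mixing matrix is singular")
    P = np.abs(W @ A)
    d = P.shape[0]
    rows = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * d * (d - 1)))
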