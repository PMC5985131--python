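"""QRS detection with the Pan–Tompkins algorithm.

The classic stage chain: zero-phase band-pass → derivative → squaring →
moving-window integration → adaptive dual thresholds with search-back and
a refractory period.  Two parameter sets are provided: the classic adult
parameterisation (5–15 Hz band, 150 ms integration, 200 ms refractory)
and a ``fetal`` set with a narrower, faster QRS in mind (10–25 Hz, 80 ms,
150 ms).  The fetal set also lowers the search-back threshold (0.25·T1
instead of the classic 0.5·T1): after maternal-template cancellation,
fetal beats that coincided with a maternal QRS survive with reduced
amplitude, and the RR-gap-gated search-back is what recovers them.  All thresholds adapt to running signal/noise peak estimates, so
detection is invariant to amplitude scaling, and squaring makes it
insensitive to polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import ValidationError

__all__ = ["BeatAnnotations", "pan_tompkins", "PARAMETER_SETS"]

#: Stage parameters per detection mode.  band in Hz, windows in ms.
PARAMETER_SETS = {
    "adult": {"band": (5.0, 15.0), "mwi_ms": 150.0, "refractory_ms": 200.0,
              "searchback_factor": 0.5},
    "fetal": {"band": (10.0, 25.0), "mwi_ms": 80.0, "refractory_ms": 150.0,
              "searchback_factor": 0.25},
}

#: Half-width of the R-peak refinement window on the band-passed signal.
REFINE_MS = 40.0


@dataclass
class BeatAnnotations:
    """Ordered R-peak sample indices for one signal."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.samples.ndim != 1:
            raise ValidationError("beat samples must be a 1-D index array")
        if self.samples.size and np.any(np.diff(self.samples) <= 0):
            raise ValidationError("beat samples must be strictly increasing")
        if self.samples.size and self.samples[0] < 0:
            raise ValidationError("beat samples must be non-negative")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError("sampling rate must be positive")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.samples / self.fs

    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.samples) / self.fs

    def mean_rate_bpm(self) -> float:
        rr = self.rr_intervals_s()
        return float(60.0 / rr.mean()) if rr.size else float("nan")


def _moving_window_integral(x: np.ndarray, width: int) -> np.ndarray:
    # centered moving average, so the integrated peak stays aligned with R
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def pan_tompkins(x: np.ndarray, fs: float, mode: str = "adult") -> BeatAnnotations:
    """Detect R-peaks in a single-channel signal.

    Parameters
    ----------
    x
        Signal, at least 2 s long.
    fs
        Sampling rate, >= 100 Hz.
    mode
        ``'adult'`` (default) or ``'fetal'`` parameter set.

    Returns
    -------
    BeatAnnotations
        Detected R-peak indices, refined to the extremum of the absolute
        band-passed signal within ±40 ms, never closer than the
        refractory period.
    """
    x = np.asarray(x, dtype=float).ravel()
    if fs < 100:
        raise ValidationError(f"pan_tompkins requires fs >= 100 Hz, got {fs}")
    if x.size < 2 * fs:
        raise ValidationError("pan_tompkins requires at least 2 s of signal")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    if np.ptp(x) == 0:
        return BeatAnnotations(np.empty(0, dtype=np.int64), fs)
    try:
        params = PARAMETER_SETS[mode]
    except KeyError:
        raise ValidationError(f"unknown detection mode {mode!r}") from None

    lo, hi = params["band"]
    sos = sps.butter(2, (lo, hi), btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    squared = deriv**2
    mwi_width = max(1, int(round(params["mwi_ms"] * fs / 1000.0)))
    mwi = _moving_window_integral(squared, mwi_width)
    if mwi.max() <= 0:
        return BeatAnnotations(np.empty(0, dtype=np.int64), fs)

    refractory = int(round(params["refractory_ms"] * fs / 1000.0))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return BeatAnnotations(np.empty(0, dtype=np.int64), fs)

    # Adaptive dual thresholds (PT running estimates of signal/noise peaks),
    # learned from the first two seconds, with RR-driven search-back.
    learn = mwi[: int(2 * fs)]
    spki = 0.25 * learn.max()
    npki = 0.5 * learn.mean()
    detections: list[int] = []
    noise_cand: list[int] = []  # sub-threshold candidates for search-back

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    rr_history: list[float] = []

    def note_rr(idx: int) -> None:
        if detections:
            rr_history.append(idx - detections[-1])
            if len(rr_history) > 8:
                rr_history.pop(0)

    def search_back(up_to: int) -> None:
        # a long RR gap suggests a missed low-amplitude beat: re-examine
        # sub-threshold candidates in the gap against the lower threshold
        nonlocal spki, noise_cand
        while detections and rr_history:
            rr_avg = float(np.mean(rr_history))
            # rhythm gate: a missed beat should sit near the position the
            # running RR average predicts; peaks far from it are noise
            expected = detections[-1] + rr_avg
            gap = [c for c in noise_cand
                   if c <= up_to and c - detections[-1] >= refractory
                   and abs(c - expected) <= 0.35 * rr_avg
                   and mwi[c] > params["searchback_factor"] * threshold1()]
            if up_to - detections[-1] <= 1.66 * rr_avg or not gap:
                break
            best = int(min(gap, key=lambda c: abs(c - expected)))
            note_rr(best)
            detections.append(best)
            spki = 0.25 * mwi[best] + 0.75 * spki
            noise_cand = [c for c in noise_cand if c > best]

    for idx in cand:
        peak = mwi[idx]
        if peak > threshold1():
            search_back(int(idx))
            note_rr(int(idx))
            detections.append(int(idx))
            spki = 0.125 * peak + 0.875 * spki
            noise_cand = []
        else:
            noise_cand.append(int(idx))
            npki = 0.125 * peak + 0.875 * npki
            search_back(int(idx))
    search_back(x.size)

    if not detections:
        return BeatAnnotations(np.empty(0, dtype=np.int64), fs)

    # refine each detection to the local extremum of |band-passed| signal
    half = int(round(REFINE_MS * fs / 1000.0))
    abs_bp = np.abs(bp)
    refined = []
    for idx in detections:
        a, b = max(0, idx - half), min(x.size, idx + half + 1)
        refined.append(a + int(np.argmax(abs_bp[a:b])))
    refined.sort()

    # enforce the refractory period after refinement (keep the larger peak)
    kept: list[int] = []
    for idx in refined:
        if kept and idx - kept[-1] < refractory:
            if abs_bp[idx] > abs_bp[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    return BeatAnnotations(np.asarray(kept, dtype=np.int64), fs)
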