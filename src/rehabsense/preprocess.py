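"""Raw-recording preprocessing: windowing, denoising, gravity/body
separation, and autocorrelation-based repetition segmentation.

A recording is ten repetitions of one rehabilitation movement captured by a
wrist/torso triaxial accelerometer.  This module turns such a recording into
(a) fixed-size sliding windows ready for the networks and (b) single-
repetition segments for the evaluation model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "SignalRecording", "SensorWindow", "GravityBodyPair", "SegmentationResult",
    "sliding_windows", "denoise_normalize", "gravity_body_split",
    "autocorrelation", "autocorrelation_sequence", "segment_repetitions",
]


@dataclass
class SignalRecording:
    """Timestamped triaxial acceleration with action/quality labels.

    t is in seconds and strictly increasing; acc is (T, 3) in g-units.
    """

    t: np.ndarray
    acc: np.ndarray
    action_label: int = 0
    level_label: int = 0
    recording_id: str = ""
    subject: int = 0
    rep_boundaries: np.ndarray | None = None  # ground truth when synthetic

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if len(self.t) != len(self.acc):
            raise ValueError("t and acc must have equal length")
        if len(self.t) < 2:
            raise ValueError("recording must have at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be (T, 3)")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SensorWindow:
    """A (W, 3) slice of a recording; `origin` is (recording_id, start)."""

    values: np.ndarray
    origin: tuple[str, int] = ("", 0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("window values must be (W, 3)")

    @property
    def window_size(self) -> int:
        return self.values.shape[0]


@dataclass
class GravityBodyPair:
    """Low-frequency (gravitational) and residual (body-motion) components.

    gravity + body reconstructs the input exactly by construction.
    """

    gravity: np.ndarray
    body: np.ndarray


@dataclass
class SegmentationResult:
    boundaries: np.ndarray            # n_reps + 1 sample indices incl. 0 and T
    peaks: np.ndarray                 # candidate autocorrelation-peak lags
    segments: list[np.ndarray] = field(default_factory=list)

    @property
    def cut_points(self) -> np.ndarray:
        """Interior cut points (the chosen split indices)."""
        return self.boundaries[1:-1]


class RecordingTooShortError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


def sliding_windows(rec: SignalRecording, size: int = 80,
                    overlap: float = 0.5) -> list[SensorWindow]:
    """Tile a recording with fixed-size windows; stride = round(size*(1-overlap)).

    The trailing partial window is dropped.  Raises RecordingTooShortError
    for recordings shorter than one window.
    """
    if size < 2:
        raise ValueError("window size must be >= 2")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    T = len(rec)
    if T < size:
        raise RecordingTooShortError(
            f"recording of {T} samples is shorter than window size {size}")
    stride = int(round(size * (1.0 - overlap)))
    stride = max(stride, 1)
    starts = range(0, T - size + 1, stride)
    return [SensorWindow(rec.acc[s:s + size].copy(), (rec.recording_id, s))
            for s in starts]


def denoise_normalize(win: SensorWindow, median_size: int = 3) -> SensorWindow:
    """Per-axis median filter (edge-replicated) then min-max mapping to [0, 1].

    A constant axis maps to all 0.5 so downstream quantization stays finite.
    """
    if median_size % 2 == 0:
        raise ValueError("median filter size must be odd")
    v = ndimage.median_filter(win.values, size=(median_size, 1), mode="nearest")
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    out = np.empty_like(v)
    for a in range(3):
        if span[a] == 0:
            out[:, a] = 0.5
        else:
            out[:, a] = (v[:, a] - lo[a]) / span[a]
    return SensorWindow(out, win.origin)


def gravity_body_split(win: SensorWindow, cutoff: float = 0.3,
                       order: int = 3, fs: float = 32.0) -> GravityBodyPair:
    """Split each axis into gravity (zero-phase Butterworth low-pass) and
    body (residual) components."""
    if not (0.0 < cutoff < fs / 2.0):
        raise ValueError("cutoff must be in (0, fs/2)")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    # even reflection keeps the DC level at the edges; the cutoff is far
    # below the window length's Nyquist so transients would otherwise leak
    gravity = signal.sosfiltfilt(sos, win.values, axis=0, padtype="even",
                                 padlen=win.window_size - 1)
    body = win.values - gravity
    return GravityBodyPair(gravity=gravity, body=body)


def autocorrelation(X: np.ndarray, k: int) -> float:
    """Normalized sample autocorrelation at lag k.

    Numerator averages (X_t - mean)(X_{t+k} - mean) over the overlap,
    denominator is the full-series variance; the value is 1 at k = 0 and
    bounded by [-1, 1].  Raises on zero-variance input.
    """
    X = np.asarray(X, dtype=float)
    T = len(X)
    if not (0 <= k < T):
        raise ValueError("lag must satisfy 0 <= k < T")
    xc = X - X.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ZeroDivisionError("zero-variance series has no autocorrelation")
    num = float(np.dot(xc[: T - k], xc[k:]))
    return num / denom


def autocorrelation_sequence(X: np.ndarray) -> np.ndarray:
    """All lags 0..T-1 of `autocorrelation` in one FFT-free pass."""
    X = np.asarray(X, dtype=float)
    xc = X - X.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ZeroDivisionError("zero-variance series has no autocorrelation")
    full = np.correlate(xc, xc, mode="full")
    return full[len(X) - 1:] / denom


def _prune_close(cands: np.ndarray, heights: np.ndarray,
                 n_keep: int) -> np.ndarray:
    """Drop candidates closer to a neighbour than half the mean
    inter-candidate distance, removing the weaker peak of the closest pair
    first (sub-harmonic peaks sit close to true-period peaks but are
    lower).  Keeps at least n_keep when possible."""
    order = np.argsort(cands)
    cands = np.asarray(cands)[order]
    heights = np.asarray(heights)[order]
    while len(cands) > n_keep:
        gaps = np.diff(cands)
        close = np.where(gaps < 0.5 * gaps.mean())[0]
        if len(close) == 0:
            break
        i = close[np.argmin(gaps[close])]
        drop = i if heights[i] < heights[i + 1] else i + 1
        cands = np.delete(cands, drop)
        heights = np.delete(heights, drop)
    return cands


def segment_repetitions(rec: SignalRecording, n_reps: int = 10,
                        prominence_frac: float = 0.05) -> SegmentationResult:
    """Split a recording of `n_reps` repetitions into one segment each.

    Candidates are peaks of the autocorrelation of the per-sample vector
    magnitude (rotation-invariant).  The n_reps-1 interior cut points are the
    candidate subset minimizing the variance of consecutive inter-boundary
    gaps, with 0 and T fixed as outer boundaries — repetitions performed in a
    row at roughly constant pace give near-equal segments.
    """
    mag = np.linalg.norm(rec.acc, axis=1)
    try:
        r = autocorrelation_sequence(mag)
    except ZeroDivisionError as e:
        raise SegmentationError("constant signal has no repetitions") from e
    prom = prominence_frac * (r.max() - r.min())
    peaks, _ = signal.find_peaks(r, prominence=prom)
    T = len(rec)
    n_interior = n_reps - 1
    if len(peaks) < n_interior:
        raise SegmentationError(
            f"found {len(peaks)} autocorrelation peaks, need {n_interior} "
            f"interior cut points for {n_reps} repetitions")
    cands = _prune_close(peaks.astype(int), r[peaks], n_interior)
    if len(cands) < n_interior:
        raise SegmentationError(
            f"{len(cands)} candidates remain after pruning, need {n_interior}")

    def gap_var(interior: np.ndarray) -> float:
        b = np.concatenate(([0], interior, [T]))
        return float(np.var(np.diff(b)))

    if len(cands) == n_interior:
        best = cands
    elif len(cands) <= 20:
        best = min((np.array(c) for c in
                    itertools.combinations(cands, n_interior)), key=gap_var)
    else:
        # greedy: seed with the evenly spaced ideal, refine locally
        ideal = np.linspace(0, T, n_reps + 1)[1:-1]
        best = np.array(sorted(set(
            int(cands[np.argmin(np.abs(cands - x))]) for x in ideal)))
        pool = [c for c in cands if c not in set(best)]
        while len(best) < n_interior and pool:
            scored = [(gap_var(np.sort(np.append(best, c))), c) for c in pool]
            _, c = min(scored)
            best = np.sort(np.append(best, c))
            pool.remove(c)
        if len(best) < n_interior:
            raise SegmentationError("could not assemble enough cut points")

    boundaries = np.concatenate(([0], np.sort(best), [T])).astype(int)
    segments = [rec.acc[boundaries[i]:boundaries[i + 1]].copy()
                for i in range(n_reps)]
    return SegmentationResult(boundaries=boundaries, peaks=peaks.astype(int),
                              segments=segments)
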