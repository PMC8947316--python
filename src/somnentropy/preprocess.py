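"""RR-interval artifact handling applied to each analysis epoch.

Two passes, run in order on every constructed epoch:

1. **Spike correction.**  A beat is a spike when its deviation from the
   median of the five surrounding RR intervals, scaled by the global robust
   spread (1.483 x the median absolute deviation), exceeds a robust-z
   threshold.  Spikes are replaced by that local median (impulse-rejection
   filtering), so ectopic beats and missed-beat pauses do not contaminate
   the entropy estimates.
2. **Out-of-band removal.**  An interval is deleted when it lies strictly
   outside the epoch's global mean +/- k local standard deviations, where
   the SD is taken over a centered moving window (default 100 beats,
   shrunk at the series edges).  Deleted intervals leave a gap; surviving
   beats keep their original timestamps so spectral analysis can use the
   uneven sample times directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PreprocessConfig",
    "CleanRR",
    "detect_and_correct_spikes",
    "remove_outliers",
    "preprocess_rr",
]


@dataclass
class PreprocessConfig:
    """Parameters of the two artifact passes.

    spike_local_window : beats (odd, >= 3)
        Width of the local-median window used by the spike detector.
    spike_threshold : robust-z units
        Deviation-over-robust-spread ratio above which a beat is a spike.
    outlier_k : SD multiples
        Half-width of the acceptance band around the global epoch mean.
    outlier_window : beats
        Width of the centered moving-SD window.
    """

    spike_local_window: int = 5
    spike_threshold: float = 4.0
    outlier_k: float = 3.0
    outlier_window: int = 100

    def __post_init__(self) -> None:
        if self.spike_local_window < 3 or self.spike_local_window % 2 == 0:
            raise ValueError("spike_local_window must be odd and >= 3")
        if self.outlier_window < 2:
            raise ValueError("outlier_window must be >= 2")
        if self.outlier_k <= 0 or self.spike_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CleanRR:
    """A preprocessed RR series with provenance bookkeeping.

    ``rr`` holds the surviving intervals in original order; ``times`` their
    terminating R-peak times (same length, or empty when no timestamps were
    supplied).  Indices refer to the *input* series.
    """

    rr: np.ndarray
    times: np.ndarray
    corrected_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    removed_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_corrected(self) -> int:
        return len(self.corrected_idx)

    @property
    def n_removed(self) -> int:
        return len(self.removed_idx)

    def __len__(self) -> int:
        return len(self.rr)


def _local_median(x: np.ndarray, window: int) -> np.ndarray:
    """Median over a centered window, shrunk at the series edges."""
    n = len(x)
    half = window // 2
    out = np.empty(n)
    if n >= window:
        from numpy.lib.stride_tricks import sliding_window_view

        out[half : n - half] = np.median(sliding_window_view(x, window), axis=1)
        edge = range(half)
    else:
        edge = range(n)
    for i in list(edge) + [n - 1 - j for j in edge]:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def detect_and_correct_spikes(rr, cfg: PreprocessConfig | None = None):
    """Flag spike beats by robust z against the 5-beat local median and
    replace them by that median.

    Returns ``(corrected_series, corrected_indices)``.  All non-flagged
    values are bit-identical to the input.  A constant series has zero
    median absolute deviation; the robust z is then defined as 0 and
    nothing is flagged.
    """
    cfg = cfg or PreprocessConfig()
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 3:
        warnings.warn("series shorter than 3 beats; spike pass skipped")
        return rr.copy(), np.empty(0, dtype=int)
    med = _local_median(rr, cfg.spike_local_window)
    mad = np.median(np.abs(rr - np.median(rr)))
    if mad == 0.0:
        return rr.copy(), np.empty(0, dtype=int)
    z = np.abs(rr - med) / (1.483 * mad)
    idx = np.flatnonzero(z > cfg.spike_threshold)
    out = rr.copy()
    out[idx] = med[idx]
    return out, idx


def _moving_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Sample SD over a centered window of ~`window` beats, shrunk at edges."""
    n = len(x)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)
    lo = np.maximum(0, i - half)
    hi = np.minimum(n, i + half)
    hi = np.maximum(hi, lo + 2)  # guarantee >= 2 beats where possible
    hi = np.minimum(hi, n)
    cnt = (hi - lo).astype(float)
    s = csum[hi] - csum[lo]
    s2 = csum2[hi] - csum2[lo]
    var = (s2 - s * s / cnt) / np.maximum(cnt - 1, 1)
    return np.sqrt(np.maximum(var, 0.0))


def remove_outliers(rr, cfg: PreprocessConfig | None = None):
    """Delete intervals strictly outside global mean +/- k * moving SD.

    The mean is the global mean of the epoch's (spike-corrected) series; the
    SD is local, over a centered ``outlier_window``-beat window shrunk at
    the edges.  Returns ``(surviving_series, removed_indices)``; surviving
    values keep their input order.  With a constant series the local SD is
    zero and the strict inequality removes nothing.
    """
    cfg = cfg or PreprocessConfig()
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 2:
        warnings.warn("series shorter than 2 beats; outlier pass skipped")
        return rr.copy(), np.empty(0, dtype=int)
    mu = rr.mean()
    s = _moving_sd(rr, cfg.outlier_window)
    bad = (rr > mu + cfg.outlier_k * s) | (rr < mu - cfg.outlier_k * s)
    idx = np.flatnonzero(bad)
    return rr[~bad], idx


def preprocess_rr(rr, times=None, cfg: PreprocessConfig | None = None) -> CleanRR:
    """Spike correction followed by out-of-band removal.

    Deterministic and pure: the same input always yields bit-identical
    output.  ``times``, when given, must align with ``rr`` (terminating
    R-peak time per interval) and is filtered alongside it.
    """
    cfg = cfg or PreprocessConfig()
    rr = np.asarray(rr, dtype=float)
    times = (
        np.empty(0) if times is None else np.asarray(times, dtype=float)
    )
    if times.size and len(times) != len(rr):
        raise ValueError("times must align with rr")
    corrected, cidx = detect_and_correct_spikes(rr, cfg)
    survived, ridx = remove_outliers(corrected, cfg)
    keep = np.ones(len(rr), dtype=bool)
    keep[ridx] = False
    return CleanRR(
        rr=survived,
        times=times[keep] if times.size else times,
        corrected_idx=cidx,
        removed_idx=ridx,
    )
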