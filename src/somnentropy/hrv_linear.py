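"""The 17 linear HRV features: time-domain, Poincaré geometry, and
frequency-domain band powers.

Frequency analysis uses the Lomb-Scargle periodogram on the uneven beat
timestamps by default, which avoids resampling a gapped RR sequence; an
alternative path cubic-spline resamples the tachogram at 4 Hz and applies
Welch's method.  Band edges follow the HRV Task Force conventions:
VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz, all half-open
``[lo, hi)``; total power integrates 0.0033-0.4 Hz.  Normalized powers are
``nLF = 100 * LF / (LF + HF)`` (and its HF complement), so nLF + nHF = 100
by construction.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle, welch

__all__ = [
    "LINEAR_FEATURES",
    "time_domain_features",
    "poincare_features",
    "spectral_features",
    "linear_features",
]

LINEAR_FEATURES = (
    "mrr",
    "sdnn",
    "rmssd",
    "sdsd",
    "pnn50",
    "pnn30",
    "sd1",
    "sd2",
    "sd1_sd2",
    "s_area",
    "tp",
    "vlf",
    "lf",
    "hf",
    "nlf",
    "nhf",
    "lf_hf",
)

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

_TIME_KEYS = ("mrr", "sdnn", "rmssd", "sdsd", "pnn50", "pnn30")
_POINCARE_KEYS = ("sd1", "sd2", "sd1_sd2", "s_area")
_SPECTRAL_KEYS = ("tp", "vlf", "lf", "hf", "nlf", "nhf", "lf_hf")


def _nan_record(keys) -> Dict[str, float]:
    return {k: float("nan") for k in keys}


def time_domain_features(rr) -> Dict[str, float]:
    """mRR, SDNN, RMSSD, SDSD, pNN50, pNN30 (RR in seconds, pNN in %).

    SDNN and SDSD use the sample (N-1) standard deviation; pNNx counts
    successive differences strictly greater than x ms, as a percentage of
    the number of successive pairs.
    """
    rr = np.asarray(getattr(rr, "rr", rr), dtype=float)
    if len(rr) < 3:
        return _nan_record(_TIME_KEYS)
    d = np.diff(rr)
    return {
        "mrr": float(rr.mean()),
        "sdnn": float(rr.std(ddof=1)),
        "rmssd": float(np.sqrt(np.mean(d * d))),
        "sdsd": float(d.std(ddof=1)),
        "pnn50": float(100.0 * np.mean(np.abs(d) > 0.050)),
        "pnn30": float(100.0 * np.mean(np.abs(d) > 0.030)),
    }


def poincare_features(rr) -> Dict[str, float]:
    """Poincaré-plot descriptors SD1, SD2, SD1/SD2, and ellipse area S.

    SD1/SD2 are the sample SDs of ``(RR_i - RR_{i+1})/sqrt(2)`` and
    ``(RR_i + RR_{i+1})/sqrt(2)`` (spread perpendicular to and along the
    identity line); ``S = pi * SD1 * SD2``.  The ratio is NaN when SD2 = 0.
    """
    rr = np.asarray(getattr(rr, "rr", rr), dtype=float)
    if len(rr) < 3:
        return _nan_record(_POINCARE_KEYS)
    a, b = rr[:-1], rr[1:]
    sd1 = float(((a - b) / math.sqrt(2)).std(ddof=1))
    sd2 = float(((a + b) / math.sqrt(2)).std(ddof=1))
    return {
        "sd1": sd1,
        "sd2": sd2,
        "sd1_sd2": sd1 / sd2 if sd2 > 0 else float("nan"),
        "s_area": math.pi * sd1 * sd2,
    }


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over the half-open band [lo, hi)."""
    mask = (freqs >= lo) & (freqs < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def _lomb_psd(times: np.ndarray, rr: np.ndarray, f_max: float):
    span = times[-1] - times[0]
    df = 1.0 / (2.0 * span)  # ~2x oversampling of the natural resolution
    freqs = np.arange(df, f_max + df, df)
    y = rr - rr.mean()
    pgram = lombscargle(times, y, 2.0 * math.pi * freqs)
    # one-sided PSD scaling: a tone of amplitude A integrates to A^2/2
    psd = pgram * 2.0 * span / len(rr)
    return freqs, psd


def _welch_psd(times: np.ndarray, rr: np.ndarray, fs: float = 4.0):
    spline = CubicSpline(times, rr)
    t = np.arange(times[0], times[-1], 1.0 / fs)
    y = spline(t)
    y = y - y.mean()
    nperseg = min(len(y), 256 * int(fs))
    freqs, psd = welch(y, fs=fs, nperseg=nperseg)
    return freqs, psd


def spectral_features(times, rr, method: str = "lomb") -> Dict[str, float]:
    """Band powers of the unevenly sampled RR tachogram.

    ``times`` are the terminating R-peak times of the ``rr`` values.
    Absolute powers (s^2): TP over 0.0033-0.4 Hz, VLF/LF/HF over their
    bands.  VLF is NaN-flagged when the record is too short to resolve the
    band (span < 50 s); the remaining features are still computed.
    """
    times = np.asarray(times, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 30 or len(times) != len(rr):
        return _nan_record(_SPECTRAL_KEYS)
    span = times[-1] - times[0]
    if span < 60.0:
        return _nan_record(_SPECTRAL_KEYS)
    if method == "lomb":
        freqs, psd = _lomb_psd(times, rr, HF_BAND[1])
    elif method == "resample_welch":
        freqs, psd = _welch_psd(times, rr)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    vlf = _band_power(freqs, psd, *VLF_BAND)
    lf = _band_power(freqs, psd, *LF_BAND)
    hf = _band_power(freqs, psd, *HF_BAND)
    tp = _band_power(freqs, psd, VLF_BAND[0], HF_BAND[1])
    if span < 50.0:
        vlf = float("nan")
    denom = lf + hf
    return {
        "tp": tp,
        "vlf": vlf,
        "lf": lf,
        "hf": hf,
        "nlf": 100.0 * lf / denom if denom > 0 else float("nan"),
        "nhf": 100.0 * hf / denom if denom > 0 else float("nan"),
        "lf_hf": lf / hf if hf > 0 else float("nan"),
    }


def linear_features(clean, method: str = "lomb") -> Dict[str, float]:
    """All 17 linear features of one preprocessed epoch (CleanRR)."""
    out: Dict[str, float] = {}
    out.update(time_domain_features(clean.rr))
    out.update(poincare_features(clean.rr))
    out.update(spectral_features(clean.times, clean.rr, method=method))
    return out
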