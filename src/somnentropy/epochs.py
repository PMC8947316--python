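"""Sliding-window construction of labeled analysis epochs.

Two schemes build overlapping analysis windows that advance in 30-s steps
across the hypnogram:

* **270-s scheme** — nine 30-s sub-epochs per window (240-s overlap); the
  window is labeled with the stage of the *middle* (5th) sub-epoch, so a
  window may contain a stage transition.
* **300-s scheme** — ten sub-epochs per window (270-s overlap); the window
  is labeled with a stage only when at least ``majority_min`` (default 9)
  of the ten sub-epochs share it, and is otherwise excluded.  Labels are
  therefore purer, at the cost of dropped windows around transitions.

In both schemes a window covering any EXCLUDED sub-epoch is dropped, as is
a window whose preprocessed RR series is shorter than ``min_beats``.  RR
intervals belong to the window containing their *terminating* R-peak, with
half-open ``[t0, t1)`` boundaries so overlapping windows never dispute a
beat.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .io import BeatSeries, Hypnogram, SleepStage
from .preprocess import CleanRR, PreprocessConfig, preprocess_rr

__all__ = ["EpochScheme", "Epoch", "extract_epoch_rr", "build_epochs"]


@dataclass
class EpochScheme:
    """Windowing parameters.

    window_len : 270 or 300 seconds
    step : slide step, 30 s
    majority_min : minimum sub-epoch count for the 300-s majority label
    min_beats : minimum preprocessed RR count for a window to be retained
    """

    window_len: int = 300
    step: int = 30
    majority_min: int = 9
    min_beats: int = 100

    def __post_init__(self) -> None:
        if self.window_len not in (270, 300):
            raise ValueError("window_len must be 270 or 300")
        if self.window_len % self.step != 0:
            raise ValueError("window_len must be a multiple of step")
        if not (6 <= self.majority_min <= 10):
            raise ValueError("majority_min must lie in [6, 10]")

    @property
    def n_subepochs(self) -> int:
        return self.window_len // self.step


@dataclass
class Epoch:
    """One analysis window: label, retention flag, and its clean RR series."""

    subject_id: str
    start_time: float
    window_len: int
    stage: SleepStage
    rr: Optional[CleanRR]
    retained: bool


def extract_epoch_rr(beats: BeatSeries, t0: float, t1: float) -> Tuple[np.ndarray, np.ndarray]:
    """RR intervals whose terminating R-peak lies in ``[t0, t1)``.

    Returns ``(rr, times)`` in original order; both empty when the window
    holds no beats.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    t = beats.rr_times
    lo, hi = np.searchsorted(t, [t0, t1], side="left")
    return beats.rr[lo:hi].copy(), t[lo:hi].copy()


def _label_window(stages: List[SleepStage], scheme: EpochScheme) -> Tuple[SleepStage, bool]:
    """(stage, retained) for one window's sub-epoch stages."""
    if any(s is SleepStage.EXCLUDED for s in stages):
        return SleepStage.EXCLUDED, False
    if scheme.window_len == 270:
        return stages[len(stages) // 2], True
    top, count = Counter(stages).most_common(1)[0]
    if count >= scheme.majority_min:
        return top, True
    return SleepStage.EXCLUDED, False


def build_epochs(
    hyp: Hypnogram,
    beats: BeatSeries,
    scheme: EpochScheme | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
) -> List[Epoch]:
    """Slide the scheme's window across the hypnogram and label each epoch.

    Windows start at ``hyp.start_time + k * step``; with a complete
    hypnogram of n sub-epochs there are ``n - window_len/30 + 1`` windows.
    RR extraction and preprocessing run only for windows whose label
    survives the scheme's rules; a retained epoch additionally needs at
    least ``min_beats`` preprocessed intervals.
    """
    scheme = scheme or EpochScheme()
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    w = scheme.n_subepochs
    n = len(hyp.stages)
    if n < w:
        warnings.warn("hypnogram shorter than one window; no epochs built")
        return []
    out: List[Epoch] = []
    for k in range(n - w + 1):
        t0 = hyp.start_time + k * scheme.step
        t1 = t0 + scheme.window_len
        stage, retained = _label_window(hyp.stages[k : k + w], scheme)
        clean = None
        if retained:
            rr, times = extract_epoch_rr(beats, t0, t1)
            clean = preprocess_rr(rr, times, preprocess_cfg)
            if len(clean) < scheme.min_beats:
                retained = False
        out.append(
            Epoch(
                subject_id=beats.subject_id,
                start_time=t0,
                window_len=scheme.window_len,
                stage=stage,
                rr=clean,
                retained=retained,
            )
        )
    return out
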