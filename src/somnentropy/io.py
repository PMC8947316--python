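"""Reading and writing beat series, hypnograms, and feature tables.

CSV is the canonical interchange dialect (UTF-8, header row, ``.`` decimal
separator).  Beat files carry ``subject_id, peak_time_s[, rr_s]``; hypnogram
files carry ``epoch_start_s, stage`` at a fixed 30-s cadence.  PhysioNet/WFDB
annotation files are supported through an optional adapter that requires the
``wfdb`` package.

Stage vocabulary
----------------
Hypnograms use the five AASM stages W, N1, N2, N3, REM plus an EXCLUDED
sentinel for movement time, unscored epochs, and scoring gaps.  Recordings
scored under the older Rechtschaffen & Kales rules (stages 1-4) are mapped
with S3 and S4 merged into N3, matching the AASM merge of slow-wave sleep.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("somnentropy")

HYPNOGRAM_EPOCH_S = 30.0


class SleepStage(str, enum.Enum):
    """Closed set of sleep-stage labels (plus an exclusion sentinel)."""

    W = "W"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    REM = "REM"
    EXCLUDED = "EXCLUDED"


#: The five scorable stages, in depth order W -> N3 then REM.
SCORABLE_STAGES: Tuple[SleepStage, ...] = (
    SleepStage.W,
    SleepStage.N1,
    SleepStage.N2,
    SleepStage.N3,
    SleepStage.REM,
)

_RK_MAP = {
    "W": SleepStage.W,
    "1": SleepStage.N1,
    "2": SleepStage.N2,
    "3": SleepStage.N3,
    "4": SleepStage.N3,
    "R": SleepStage.REM,
}

_AASM_MAP = {s.value: s for s in SCORABLE_STAGES}


def map_stage_labels(native_label: str, scheme: str = "rk") -> SleepStage:
    """Map a recording-native stage label onto the package's stage set.

    Total function: any label outside the scheme's vocabulary (movement time
    ``MT``, unscored, artifacts, ...) maps to :data:`SleepStage.EXCLUDED`.

    Parameters
    ----------
    native_label : str
        Label as found in the recording (e.g. ``"4"``, ``"R"``, ``"MT"``).
    scheme : {"rk", "aasm"}
        ``"rk"`` maps Rechtschaffen & Kales stages (1-4, with 3 and 4 merged
        into N3); ``"aasm"`` is the identity on {W, N1, N2, N3, REM}.
    """
    label = str(native_label).strip()
    if scheme == "rk":
        return _RK_MAP.get(label, SleepStage.EXCLUDED)
    if scheme == "aasm":
        return _AASM_MAP.get(label, SleepStage.EXCLUDED)
    raise ValueError(f"unknown stage-label scheme {scheme!r}")


@dataclass
class BeatSeries:
    """A subject's annotated R-peak times and derived RR intervals.

    ``rr[i]`` is the interval terminated by ``peak_times[i + 1]``; the first
    beat carries no RR interval, so ``len(rr) == len(peak_times) - 1``.
    ``meta`` carries free-form provenance (the synthetic generator stores its
    ground-truth artifact indices there).
    """

    subject_id: str
    peak_times: np.ndarray
    rr: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        d = np.diff(self.peak_times)
        if (d <= 0).any():
            i = int(np.argmax(d <= 0)) + 1
            raise ValueError(f"peak times non-monotonic at index {i}")
        if len(self.rr) != len(self.peak_times) - 1:
            raise ValueError(
                f"rr length {len(self.rr)} != n_peaks - 1 = {len(self.peak_times) - 1}"
            )

    @property
    def rr_times(self) -> np.ndarray:
        """Terminating R-peak time of each RR interval."""
        return self.peak_times[1:]

    @property
    def duration(self) -> float:
        return float(self.peak_times[-1] - self.peak_times[0])


@dataclass
class Hypnogram:
    """Sleep-stage labels at a fixed 30-s cadence."""

    stages: list  # list[SleepStage]
    start_time: float = 0.0
    epoch_len: float = HYPNOGRAM_EPOCH_S

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("hypnogram has no stages")
        self.stages = [SleepStage(s) for s in self.stages]

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_len

    def stage_at(self, t: float) -> SleepStage:
        """Stage of the sub-epoch containing time ``t`` (EXCLUDED outside)."""
        k = int(np.floor((t - self.start_time) / self.epoch_len))
        if k < 0 or k >= len(self.stages):
            return SleepStage.EXCLUDED
        return self.stages[k]


def read_beats(path, format: str = "csv", subject_id: Optional[str] = None) -> BeatSeries:
    """Read a beat-annotation file into a :class:`BeatSeries`.

    CSV files need a ``peak_time_s`` column; ``rr_s`` is recomputed from
    successive peaks when absent.  ``format="wfdb_annotation"`` reads a
    PhysioNet beat-annotation file and requires the optional ``wfdb``
    package.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"{path}: empty beat file")
        if "peak_time_s" not in df.columns:
            raise ValueError(f"{path}: missing required column peak_time_s")
        times = df["peak_time_s"].to_numpy(dtype=float)
        d = np.diff(times)
        if (d <= 0).any():
            i = int(np.argmax(d <= 0)) + 1
            raise ValueError(f"{path}: non-monotonic at index {i}")
        if "rr_s" in df.columns:
            rr = df["rr_s"].to_numpy(dtype=float)[1:]
        else:
            rr = d
        if subject_id is None:
            if "subject_id" in df.columns:
                subject_id = str(df["subject_id"].iloc[0])
            else:
                subject_id = path.stem
        return BeatSeries(subject_id=subject_id, peak_times=times, rr=rr)
    if format == "wfdb_annotation":
        return _read_beats_wfdb(path, subject_id)
    raise ValueError(f"unknown beat format {format!r}")


def _read_beats_wfdb(path, subject_id):  # pragma: no cover - optional adapter
    try:
        import wfdb
    except ImportError as exc:
        raise ImportError(
            "reading WFDB annotations requires the optional 'wfdb' package "
            "(pip install somnentropy[wfdb]); use the CSV dialect otherwise"
        ) from exc
    path = Path(path)
    ann = wfdb.rdann(str(path.with_suffix("")), path.suffix.lstrip("."))
    times = np.asarray(ann.sample, dtype=float) / float(ann.fs)
    return BeatSeries(
        subject_id=subject_id or path.stem,
        peak_times=times,
        rr=np.diff(times),
    )


def read_hypnogram(path, format: str = "csv", scheme: str = "rk") -> Hypnogram:
    """Read a 30-s hypnogram, mapping native labels through the stage map.

    Rows must sit on a 30-s grid; grid gaps are filled with EXCLUDED, and any
    off-grid cadence is a hard error.  Unknown labels map to EXCLUDED with a
    logged warning.
    """
    if format == "wfdb_annotation":  # pragma: no cover - optional adapter
        return _read_hypnogram_wfdb(path, scheme)
    if format != "csv":
        raise ValueError(f"unknown hypnogram format {format!r}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty hypnogram")
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    rel = starts - starts[0]
    if not np.allclose(rel % HYPNOGRAM_EPOCH_S, 0.0, atol=1e-9):
        raise ValueError(f"{path}: hypnogram cadence is not a 30-s grid")
    d = np.diff(starts)
    if (d <= 0).any():
        raise ValueError(f"{path}: hypnogram epochs out of order")
    n = int(round(rel[-1] / HYPNOGRAM_EPOCH_S)) + 1
    stages = [SleepStage.EXCLUDED] * n
    for s, lab in zip(starts, df["stage"]):
        k = int(round((s - starts[0]) / HYPNOGRAM_EPOCH_S))
        mapped = map_stage_labels(lab, scheme)
        if mapped is SleepStage.EXCLUDED and str(lab).strip() not in ("EXCLUDED",):
            logger.warning("unknown stage label %r mapped to EXCLUDED", lab)
        stages[k] = mapped
    return Hypnogram(stages=stages, start_time=float(starts[0]))


def _read_hypnogram_wfdb(path, scheme):  # pragma: no cover - optional adapter
    try:
        import wfdb
    except ImportError as exc:
        raise ImportError(
            "reading WFDB annotations requires the optional 'wfdb' package"
        ) from exc
    path = Path(path)
    ann = wfdb.rdann(str(path.with_suffix("")), path.suffix.lstrip("."))
    # slpdb convention: stage letter is the first token of aux_note per 30 s
    starts = np.asarray(ann.sample, dtype=float) / float(ann.fs)
    labels = [str(a).strip().split(" ")[0] for a in ann.aux_note]
    stages = [map_stage_labels(lab, scheme) for lab in labels]
    return Hypnogram(stages=stages, start_time=float(starts[0]))


def merge_records(
    a: Tuple[BeatSeries, Hypnogram],
    b: Tuple[BeatSeries, Hypnogram],
    gap_s: float = 0.0,
) -> Tuple[BeatSeries, Hypnogram]:
    """Concatenate two same-subject recordings (e.g. slp01a + slp01b).

    ``b``'s clock is shifted so that its hypnogram starts ``gap_s`` seconds
    after ``a``'s hypnogram ends; the gap (a multiple of 30 s) is filled with
    EXCLUDED sub-epochs so downstream windows spanning it are dropped.
    """
    beats_a, hyp_a = a
    beats_b, hyp_b = b
    if beats_a.subject_id != beats_b.subject_id:
        raise ValueError(
            f"cannot merge records of different subjects "
            f"({beats_a.subject_id!r} vs {beats_b.subject_id!r})"
        )
    if gap_s < 0 or abs(gap_s % HYPNOGRAM_EPOCH_S) > 1e-9:
        raise ValueError("gap must be a non-negative multiple of 30 s")
    n_gap = int(round(gap_s / HYPNOGRAM_EPOCH_S))
    a_end = hyp_a.start_time + hyp_a.duration
    offset = a_end + gap_s - hyp_b.start_time
    times_b = beats_b.peak_times + offset
    if times_b[0] <= beats_a.peak_times[-1]:
        raise ValueError("record b does not follow record a in time")
    merged_beats = BeatSeries(
        subject_id=beats_a.subject_id,
        peak_times=np.concatenate([beats_a.peak_times, times_b]),
        rr=np.concatenate(
            [beats_a.rr, [times_b[0] - beats_a.peak_times[-1]], beats_b.rr]
        ),
    )
    stages = list(hyp_a.stages) + [SleepStage.EXCLUDED] * n_gap + list(hyp_b.stages)
    return merged_beats, Hypnogram(stages=stages, start_time=hyp_a.start_time)


def write_beats(beats: BeatSeries, path) -> None:
    """Write a beat series in the canonical CSV dialect."""
    rr = np.concatenate([[np.nan], beats.rr])
    pd.DataFrame(
        {
            "subject_id": beats.subject_id,
            "peak_time_s": beats.peak_times,
            "rr_s": rr,
        }
    ).to_csv(path, index=False)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    starts = hyp.start_time + HYPNOGRAM_EPOCH_S * np.arange(len(hyp.stages))
    pd.DataFrame(
        {"epoch_start_s": starts, "stage": [s.value for s in hyp.stages]}
    ).to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table to CSV, round-tripping floats losslessly.

    One row per retained epoch; NaN features are serialized as empty fields
    and the row is kept (the ``has_nan`` flag column marks it).
    """
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "has_nan" in df.columns:
        df["has_nan"] = df["has_nan"].astype(bool)
    return df
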