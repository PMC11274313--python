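"""Domain types: Doppler signals, heart-rate traces, recordings, segments, windows.

Conventions: DUS amplitude is dimensionless in [-1, 1) at 1 kHz; heart-rate
traces are bpm at 4 Hz with NaN as the missing-value sentinel; time is
0-based seconds and intervals are half-open [start, end).  The 4 Hz and
1 kHz tracks share their start time, so trace sample i covers DUS samples
[250*i, 250*(i+1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .config import DUS_RATE_HZ, TRACE_RATE_HZ

#: source-annotation codes, per DUS sample
FETAL, VESSEL, ARTIFACT, SILENT = 0, 1, 2, 3
SOURCE_NAMES = {FETAL: "fetal", VESSEL: "vessel", ARTIFACT: "artifact", SILENT: "silent"}
SOURCE_CODES = {v: k for k, v in SOURCE_NAMES.items()}

#: segment / window labels
LABEL_FETAL = "fetal"
LABEL_VESSEL = "vessel"
LABEL_ND = "not_determinable"
LABEL_UNLABELED = "unlabeled"
BINARY_LABELS = (LABEL_FETAL, LABEL_VESSEL)


@dataclass
class DusSignal:
    """Raw Doppler-ultrasound amplitude sequence at 1 kHz."""

    samples: np.ndarray
    sample_rate_hz: int = DUS_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate_hz != DUS_RATE_HZ:
            raise ValueError(f"DUS sample rate is fixed at {DUS_RATE_HZ} Hz")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class HeartRateTrace:
    """4 Hz heart-rate series in bpm; NaN marks samples with no reading."""

    values_bpm: np.ndarray
    kind: str  # "FHR" or "MHR"
    sample_rate_hz: int = TRACE_RATE_HZ

    def __post_init__(self) -> None:
        if self.kind not in ("FHR", "MHR"):
            raise ValueError(f"trace kind must be 'FHR' or 'MHR', got {self.kind!r}")
        self.values_bpm = np.asarray(self.values_bpm, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return len(self.values_bpm) / self.sample_rate_hz

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values_bpm)

    def __len__(self) -> int:
        return len(self.values_bpm)


@dataclass
class SourceAnnotation:
    """Per-sample ground-truth source track at 1 kHz (synthetic data only)."""

    codes: np.ndarray  # uint8, values in {FETAL, VESSEL, ARTIFACT, SILENT}

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.size and self.codes.max() > SILENT:
            raise ValueError("annotation contains an unknown source code")

    def __len__(self) -> int:
        return len(self.codes)

    def to_runs(self) -> List[dict]:
        """Run-length encoding: [{start_sample, end_sample, source}, ...]."""
        runs = []
        if len(self.codes) == 0:
            return runs
        change = np.flatnonzero(np.diff(self.codes)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(self.codes)]))
        for s, e in zip(starts, ends):
            runs.append(
                {"start_sample": int(s), "end_sample": int(e), "source": SOURCE_NAMES[int(self.codes[s])]}
            )
        return runs

    @classmethod
    def from_runs(cls, runs: List[dict]) -> "SourceAnnotation":
        n = max(r["end_sample"] for r in runs) if runs else 0
        codes = np.zeros(n, dtype=np.uint8)
        for r in runs:
            codes[r["start_sample"]:r["end_sample"]] = SOURCE_CODES[r["source"]]
        return cls(codes)


@dataclass
class Recording:
    """A monitored episode: DUS plus displayed-FHR and (optional) MHR traces."""

    id: str
    dus: DusSignal
    fhr: HeartRateTrace
    mhr: Optional[HeartRateTrace] = None
    annotation: Optional[SourceAnnotation] = None

    def __post_init__(self) -> None:
        if abs(self.dus.duration_s - self.fhr.duration_s) > 1.0 / TRACE_RATE_HZ:
            raise ValueError(
                f"DUS duration {self.dus.duration_s} s and FHR duration "
                f"{self.fhr.duration_s} s disagree beyond one trace sample"
            )
        if self.annotation is not None and len(self.annotation) != len(self.dus):
            raise ValueError("annotation length must equal DUS length")

    @property
    def duration_s(self) -> float:
        return self.dus.duration_s


@dataclass
class LabeledSegment:
    """A 10-s slice of a recording with a source label."""

    recording_id: str
    start_s: float
    dus: np.ndarray          # 10,000 samples for the standard 10-s segment
    fhr: np.ndarray          # 40 bpm samples
    mhr: Optional[np.ndarray]
    label: str = LABEL_UNLABELED

    def __post_init__(self) -> None:
        self.dus = np.asarray(self.dus, dtype=np.float64)
        self.fhr = np.asarray(self.fhr, dtype=np.float64)
        if self.mhr is not None:
            self.mhr = np.asarray(self.mhr, dtype=np.float64)
        if self.label not in (LABEL_FETAL, LABEL_VESSEL, LABEL_ND, LABEL_UNLABELED):
            raise ValueError(f"unknown segment label {self.label!r}")

    @property
    def id(self) -> str:
        return f"{self.recording_id}:{self.start_s:g}"

    @property
    def duration_s(self) -> float:
        return len(self.dus) / DUS_RATE_HZ


@dataclass
class Window:
    """A 2-s (2000-sample) classifier input extracted from a segment."""

    samples: np.ndarray
    label: str
    parent_segment_id: str = ""
    offset_ms: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.samples)


def as_window_matrix(windows) -> np.ndarray:
    """Stack Window objects or array-likes into an (n, length) float32 matrix."""
    rows = [w.samples if isinstance(w, Window) else np.asarray(w) for w in windows]
    return np.stack(rows).astype(np.float32)
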