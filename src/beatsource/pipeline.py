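"""Segmentation, coincidence selection, window augmentation and splits.

The candidate-selection chain: recordings are cut into non-overlapping 10-s
segments; a segment is a candidate for labelling when its displayed FHR and
the simultaneously monitored MHR differ by less than 5 bpm for at least 6
consecutive seconds (that is when a maternal masquerade is plausible).
Labelled segments are expanded into 2-s windows shifted every 100 ms (80
windows per 10-s segment), the minority class is duplicated to balance, and
windows are pooled and split 92/8 into train/validation after a per-class
random test allocation of 2/27 of the segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DUS_RATE_HZ, TRACE_RATE_HZ, PipelineConfig
from .signals import (
    ARTIFACT,
    FETAL,
    SILENT,
    VESSEL,
    BINARY_LABELS,
    LABEL_FETAL,
    LABEL_ND,
    LABEL_UNLABELED,
    LABEL_VESSEL,
    LabeledSegment,
    Recording,
    Window,
)


class MissingTraceError(ValueError):
    """Raised when a segment has no MHR trace (not simultaneously monitored)."""


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero-free: always up."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# segmentation


def segment_count(duration_s: float, segment_s: float = 10.0) -> int:
    """Number of whole segments obtained from a recording duration."""
    return int(duration_s // segment_s)


def _label_from_annotation(codes: np.ndarray) -> str:
    if np.any(codes == ARTIFACT) or np.any(codes == SILENT):
        return LABEL_ND
    if np.all(codes == FETAL):
        return LABEL_FETAL
    if np.all(codes == VESSEL):
        return LABEL_VESSEL
    return LABEL_ND  # mixed fetal/vessel within one segment


def segment_recording(rec: Recording, segment_s: float = 10.0) -> List[LabeledSegment]:
    """Divide a recording into consecutive ``segment_s`` slices from t=0.

    The trailing remainder shorter than one segment is discarded.  When the
    recording carries a ground-truth annotation, labels are assigned from
    it: pure-fetal segments are fetal, pure-vessel segments vessel, and any
    segment overlapping an artifact or dropout episode (or mixing sources)
    is not_determinable.  Without annotation all segments are unlabeled.
    """
    n_seg = segment_count(rec.duration_s, segment_s)
    if n_seg < 1:
        raise ValueError(f"recording shorter than one {segment_s}-s segment")
    dus_per_seg = int(round(segment_s * DUS_RATE_HZ))
    trace_per_seg = int(round(segment_s * TRACE_RATE_HZ))
    segments = []
    for i in range(n_seg):
        dsl = slice(i * dus_per_seg, (i + 1) * dus_per_seg)
        tsl = slice(i * trace_per_seg, (i + 1) * trace_per_seg)
        if rec.annotation is not None:
            label = _label_from_annotation(rec.annotation.codes[dsl])
        else:
            label = LABEL_UNLABELED
        segments.append(
            LabeledSegment(
                recording_id=rec.id,
                start_s=i * segment_s,
                dus=rec.dus.samples[dsl],
                fhr=rec.fhr.values_bpm[tsl],
                mhr=None if rec.mhr is None else rec.mhr.values_bpm[tsl],
                label=label,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# coincidence filter


def coincidence_filter(seg: LabeledSegment, threshold_bpm: float = 5.0,
                       min_duration_s: float = 6.0) -> bool:
    """True iff |FHR - MHR| < threshold holds on a long-enough consecutive run.

    The run must span at least ``min_duration_s`` of consecutive 4 Hz
    samples (24 samples for the default 6 s) on which both traces are
    non-missing; a missing sample breaks the run.  The inequality is strict.
    """
    if seg.mhr is None:
        raise MissingTraceError(
            f"segment {seg.id} has no MHR trace: not simultaneously monitored"
        )
    fhr, mhr = seg.fhr, seg.mhr
    if len(fhr) != len(mhr):
        raise ValueError("FHR and MHR traces differ in length")
    ok = np.isfinite(fhr) & np.isfinite(mhr) & (np.abs(fhr - mhr) < threshold_bpm)
    need = int(round(min_duration_s * TRACE_RATE_HZ))
    run = 0
    for flag in ok:
        run = run + 1 if flag else 0
        if run >= need:
            return True
    return False


# ---------------------------------------------------------------------------
# window augmentation


def window_count(duration_ms: int, window_ms: int = 2000, stride_ms: int = 100) -> int:
    """Number of windows extracted from a segment: max(1, floor((T-W)/S))."""
    if duration_ms < window_ms:
        raise ValueError("segment shorter than window")
    return max(1, (duration_ms - window_ms) // stride_ms)


def window_segment(seg: LabeledSegment, window_s: float = 2.0,
                   stride_ms: int = 100) -> List[Window]:
    """Extract sliding windows of ``window_s`` every ``stride_ms``.

    A 10-s segment yields 80 windows at offsets 0, 100, ..., 7900 ms; each
    window is the half-open sample range [start, start + W).  Labels are
    inherited from the segment.
    """
    w_samples = int(round(window_s * DUS_RATE_HZ))
    t_ms = int(round(len(seg.dus) / DUS_RATE_HZ * 1000))
    n = window_count(t_ms, w_samples, stride_ms)  # 1 kHz: 1 sample == 1 ms
    stride_samples = stride_ms  # at 1 kHz
    return [
        Window(
            samples=seg.dus[k * stride_samples: k * stride_samples + w_samples],
            label=seg.label,
            parent_segment_id=seg.id,
            offset_ms=k * stride_ms,
        )
        for k in range(n)
    ]


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SplitDataset:
    """Window-level train/validation/test split with provenance.

    Window contents are stored implicitly: ``segment_data`` holds the raw
    segment samples and each split table references (segment index,
    offset_ms).  Oversampling duplicates table rows, never array contents.
    """

    segment_data: np.ndarray            # (n_segments, segment_samples) float32
    segment_labels: np.ndarray          # (n_segments,) object: 'fetal'/'vessel'
    segment_ids: List[str]
    tables: Dict[str, pd.DataFrame]     # split -> columns seg_idx, offset_ms, label
    window_samples: int
    seed: int

    SPLITS = ("train", "validation", "test")

    def counts(self) -> Dict[str, Dict[str, int]]:
        return {
            split: {
                str(k): int(v)
                for k, v in self.tables[split]["label"].value_counts().items()
            }
            for split in self.SPLITS
        }

    def parent_segments(self, split: str) -> set:
        return {self.segment_ids[i] for i in self.tables[split]["seg_idx"].unique()}

    def window_array(self, split: str) -> Tuple[np.ndarray, np.ndarray]:
        """Materialise (X, y) for a split; y encodes fetal=0, vessel=1."""
        tab = self.tables[split]
        n, w = len(tab), self.window_samples
        x = np.empty((n, w), dtype=np.float32)
        seg_idx = tab["seg_idx"].to_numpy()
        offsets = tab["offset_ms"].to_numpy()  # 1 ms == 1 sample at 1 kHz
        for i in range(n):
            x[i] = self.segment_data[seg_idx[i], offsets[i]: offsets[i] + w]
        y = (tab["label"].to_numpy() == LABEL_VESSEL).astype(np.int64)
        return x, y

    def manifest(self) -> pd.DataFrame:
        frames = []
        for split in self.SPLITS:
            tab = self.tables[split].copy()
            tab["split"] = split
            tab["parent_segment"] = [self.segment_ids[i] for i in tab["seg_idx"]]
            tab["id"] = [
                f"{p}+{o}ms#{c}"
                for p, o, c in zip(tab["parent_segment"], tab["offset_ms"], tab["copy"])
            ]
            frames.append(tab[["id", "parent_segment", "offset_ms", "label", "split"]])
        return pd.concat(frames, ignore_index=True)


def auto_oversample_factor(majority_windows: int, minority_windows: int) -> int:
    """Balancing duplication factor: round(majority / minority), at least 1."""
    if minority_windows <= 0:
        raise ValueError("minority class has no windows")
    return max(1, round_half_up(majority_windows / minority_windows))


def heldout_allocation(n_class: int, ratio: Tuple[int, int, int] = (23, 2, 2)) -> int:
    """Per-class number of test segments: round(n_class * test_share)."""
    share = ratio[2] / sum(ratio)
    return round_half_up(n_class * share)


def build_splits(segments: Sequence[LabeledSegment],
                 cfg: Optional[PipelineConfig] = None,
                 seed: int = 0) -> SplitDataset:
    """Assemble the train/validation/test window dataset from labelled segments.

    Per class, ``round(n * 2/27)`` segments are drawn at random into the
    test set; the rest are windowed, the minority class is duplicated by the
    auto (or given) factor, and the pooled train+validation windows are
    split 92/8 uniformly at random at the window level.  Test windows are
    never duplicated, and no segment contributes windows to both the test
    set and any other split.
    """
    cfg = (cfg or PipelineConfig()).validate()
    labels = [s.label for s in segments]
    bad = sorted({l for l in labels if l not in BINARY_LABELS})
    if bad:
        raise ValueError(f"build_splits accepts only fetal/vessel segments, got {bad}")
    by_class = {
        lab: [i for i, l in enumerate(labels) if l == lab] for lab in BINARY_LABELS
    }
    for lab, idxs in by_class.items():
        if not idxs:
            raise ValueError(f"class {lab!r} has no segments; cannot build a split")

    rng = np.random.default_rng([seed, 101])
    test_idx: Dict[str, np.ndarray] = {}
    trainval_idx: Dict[str, np.ndarray] = {}
    for lab, idxs in by_class.items():
        n_test = heldout_allocation(len(idxs), cfg.ratio)
        if n_test < 1:
            raise ValueError(
                f"class {lab!r} has only {len(idxs)} segments; its test "
                "allocation rounds to zero, so no held-out evaluation is possible"
            )
        if n_test >= len(idxs):
            raise ValueError(
                f"class {lab!r} has {len(idxs)} segments, fewer than its "
                f"test allocation of {n_test} plus one"
            )
        chosen = rng.choice(len(idxs), size=n_test, replace=False)
        mask = np.zeros(len(idxs), dtype=bool)
        mask[chosen] = True
        arr = np.asarray(idxs)
        test_idx[lab] = arr[mask]
        trainval_idx[lab] = arr[~mask]

    window_samples = int(round(cfg.window_s * DUS_RATE_HZ))

    def rows_for(seg_indices: np.ndarray) -> pd.DataFrame:
        recs = []
        for si in seg_indices:
            seg = segments[si]
            t_ms = int(round(len(seg.dus) / DUS_RATE_HZ * 1000))
            for k in range(window_count(t_ms, window_samples, cfg.stride_ms)):
                recs.append((si, k * cfg.stride_ms, seg.label, 0))
        return pd.DataFrame(recs, columns=["seg_idx", "offset_ms", "label", "copy"])

    test_tab = pd.concat(
        [rows_for(test_idx[lab]) for lab in BINARY_LABELS], ignore_index=True
    )
    tv_tabs = {lab: rows_for(trainval_idx[lab]) for lab in BINARY_LABELS}

    n_by_class = {lab: len(t) for lab, t in tv_tabs.items()}
    minority = min(n_by_class, key=n_by_class.get)
    majority = max(n_by_class, key=n_by_class.get)
    if cfg.oversample == "auto":
        k = auto_oversample_factor(n_by_class[majority], n_by_class[minority])
    else:
        k = int(cfg.oversample)
    if k > 1:
        copies = [tv_tabs[minority]]
        for c in range(1, k):
            dup = tv_tabs[minority].copy()
            dup["copy"] = c
            copies.append(dup)
        tv_tabs[minority] = pd.concat(copies, ignore_index=True)

    pool = pd.concat([tv_tabs[lab] for lab in BINARY_LABELS], ignore_index=True)
    split_rng = np.random.default_rng([seed, 102])
    if cfg.segment_level_split:
        # leakage-free variant: segments (not windows) are assigned 92/8
        seg_ids = pool["seg_idx"].unique()
        perm = split_rng.permutation(len(seg_ids))
        n_train_seg = round_half_up(cfg.trainval_split * len(seg_ids))
        train_segs = set(seg_ids[perm[:n_train_seg]])
        is_train = pool["seg_idx"].isin(train_segs).to_numpy()
        train_tab = pool[is_train].reset_index(drop=True)
        val_tab = pool[~is_train].reset_index(drop=True)
    else:
        perm = split_rng.permutation(len(pool))
        n_train = round_half_up(cfg.trainval_split * len(pool))
        train_tab = pool.iloc[perm[:n_train]].reset_index(drop=True)
        val_tab = pool.iloc[perm[n_train:]].reset_index(drop=True)

    seg_data = np.stack([s.dus for s in segments]).astype(np.float32)
    return SplitDataset(
        segment_data=seg_data,
        segment_labels=np.asarray(labels, dtype=object),
        segment_ids=[s.id for s in segments],
        tables={"train": train_tab, "validation": val_tab, "test": test_tab},
        window_samples=window_samples,
        seed=seed,
    )
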