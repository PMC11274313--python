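"""Independent brute-force oracles used by the test suite.

Each function here is deliberately written from first principles, without
reusing any implementation path from the package, so that agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, hilbert


def envelope_peak_count(samples: np.ndarray, fs: int = 1000,
                        smooth_ms: float = 20.0) -> int:
    """Count amplitude bursts via the smoothed analytic-signal envelope."""
    env = np.abs(hilbert(np.asarray(samples, dtype=np.float64)))
    env = gaussian_filter1d(env, smooth_ms * fs / 1000.0)
    peaks, _ = find_peaks(env, height=0.3 * env.max(), distance=int(0.08 * fs))
    return len(peaks)


def longest_true_run(mask) -> int:
    """Length of the longest run of consecutive True values."""
    best = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def coincidence_oracle(fhr: np.ndarray, mhr: np.ndarray,
                       threshold: float = 5.0, need: int = 24) -> bool:
    """Enumerate every consecutive run on the 40-sample coincidence mask."""
    ok = np.isfinite(fhr) & np.isfinite(mhr) & (np.abs(fhr - mhr) < threshold)
    return longest_true_run(ok) >= need


def pairwise_auc(labels, scores, positive) -> float:
    """Mann-Whitney AUC by exhaustive pairwise comparison (ties count half)."""
    pos = [s for l, s in zip(labels, scores) if l == positive]
    neg = [s for l, s in zip(labels, scores) if l != positive]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1.0
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / total


def metric_formulas(tp: int, tn: int, fp: int, fn: int):
    """Direct textbook evaluation of accuracy/precision/recall/F1 in %."""
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    prec = 100.0 * tp / (tp + fp) if tp + fp else None
    rec = 100.0 * tp / (tp + fn) if tp + fn else None
    if prec is None or rec is None or prec + rec == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    return acc, prec, rec, f1


def valid_window_starts(duration_ms: int, window_ms: int, stride_ms: int):
    """All start offsets under the adopted rule: a window is taken at every
    stride-grid position that still leaves at least one full stride before
    the end of the covered span (this excludes the final flush-with-the-end
    start, giving 80 for a 10-s segment); a segment exactly one window long
    yields the single flush window."""
    starts = [
        s for s in range(0, duration_ms - window_ms + 1, stride_ms)
        if s + window_ms + stride_ms <= duration_ms
    ]
    if not starts and window_ms <= duration_ms:
        starts = [0]
    return starts
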