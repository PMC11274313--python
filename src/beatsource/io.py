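"""Readers and writers for recordings and derived artefacts.

On disk a recording ``<id>`` is three files in one directory:

* ``<id>.wav`` — DUS as PCM 16-bit mono WAV at 1000 Hz (amplitudes are
  quantized to the 16-bit grid only here; in memory they stay float);
* ``<id>.traces.csv`` — 4 Hz rows ``time_s,fhr_bpm,mhr_bpm``; missing
  readings are empty cells, never zero;
* ``<id>.annotation.json`` — optional run-length-encoded ground truth.

Reading validates the format strictly: wrong sample rate, bit depth or
channel count is rejected, never silently resampled; non-missing heart
rates must respect the device range [50, 240] bpm.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .config import BPM_MAX, BPM_MIN, DUS_RATE_HZ, TRACE_RATE_HZ
from .signals import DusSignal, HeartRateTrace, Recording, SourceAnnotation

_QUANT = 32768  # 16-bit full scale; grid step 2**-15 of full scale


def quantize16(x: np.ndarray) -> np.ndarray:
    """Map float amplitudes in [-1, 1) onto the int16 grid."""
    return np.clip(np.round(np.asarray(x) * _QUANT), -_QUANT, _QUANT - 1).astype(np.int16)


def dequantize16(q: np.ndarray) -> np.ndarray:
    return np.asarray(q, dtype=np.float64) / _QUANT


def write_recording(rec: Recording, directory: Union[str, Path]) -> Path:
    """Write WAV + trace CSV (+ annotation JSON when present); returns the dir."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wavfile.write(directory / f"{rec.id}.wav", DUS_RATE_HZ, quantize16(rec.dus.samples))

    n = len(rec.fhr)
    mhr = rec.mhr.values_bpm if rec.mhr is not None else np.full(n, np.nan)
    frame = pd.DataFrame(
        {
            "time_s": np.arange(n) / TRACE_RATE_HZ,
            "fhr_bpm": rec.fhr.values_bpm,
            "mhr_bpm": mhr,
        }
    )
    frame.to_csv(directory / f"{rec.id}.traces.csv", index=False, na_rep="")

    if rec.annotation is not None:
        (directory / f"{rec.id}.annotation.json").write_text(
            json.dumps(rec.annotation.to_runs())
        )
    return directory


def _validate_trace(values: np.ndarray, name: str) -> None:
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < BPM_MIN or finite.max() > BPM_MAX):
        raise ValueError(
            f"{name} contains values outside the device range "
            f"[{BPM_MIN:g}, {BPM_MAX:g}] bpm"
        )


def read_recording(directory: Union[str, Path], rec_id: str) -> Recording:
    """Read a recording written by :func:`write_recording`.

    The round trip is lossless up to 16-bit quantization (max absolute
    amplitude error 2**-16 of full scale).
    """
    directory = Path(directory)
    rate, data = wavfile.read(directory / f"{rec_id}.wav")
    if rate != DUS_RATE_HZ:
        raise ValueError(f"expected {DUS_RATE_HZ} Hz WAV, got {rate} Hz; refusing to resample")
    if data.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM, got dtype {data.dtype}")
    if data.ndim != 1:
        raise ValueError(f"expected mono WAV, got {data.shape[1]} channels")
    dus = DusSignal(dequantize16(data))

    frame = pd.read_csv(directory / f"{rec_id}.traces.csv")
    for col in ("time_s", "fhr_bpm", "mhr_bpm"):
        if col not in frame.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    fhr_values = frame["fhr_bpm"].to_numpy(dtype=np.float64)
    mhr_values = frame["mhr_bpm"].to_numpy(dtype=np.float64)
    _validate_trace(fhr_values, "fhr_bpm")
    _validate_trace(mhr_values, "mhr_bpm")
    if abs(len(dus) / DUS_RATE_HZ - len(frame) / TRACE_RATE_HZ) > 1.0 / TRACE_RATE_HZ:
        raise ValueError("DUS and trace durations disagree beyond one trace sample")

    fhr = HeartRateTrace(fhr_values, kind="FHR")
    mhr = None if np.all(np.isnan(mhr_values)) else HeartRateTrace(mhr_values, kind="MHR")

    ann_path = directory / f"{rec_id}.annotation.json"
    annotation = None
    if ann_path.exists():
        annotation = SourceAnnotation.from_runs(json.loads(ann_path.read_text()))
    return Recording(id=rec_id, dus=dus, fhr=fhr, mhr=mhr, annotation=annotation)


def write_split_dataset(data, directory: Union[str, Path]) -> Path:
    """Persist a SplitDataset as window tensors (npz) plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for split in data.SPLITS:
        x, y = data.window_array(split)
        arrays[f"x_{split}"] = x
        arrays[f"y_{split}"] = y
    np.savez_compressed(directory / "windows.npz", **arrays)
    manifest = data.manifest()
    manifest.to_json(directory / "manifest.json", orient="records", indent=2)
    return directory


def read_split_arrays(directory: Union[str, Path]) -> dict:
    """Load the window tensors written by :func:`write_split_dataset`."""
    with np.load(Path(directory) / "windows.npz") as z:
        return {k: z[k] for k in z.files}
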