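"""Synthetic Doppler-ultrasound recording generator.

Emulates intrapartum CTG monitoring data: a 1 kHz DUS amplitude signal plus
4 Hz FHR/MHR traces.  A fetal beat train carries TWO Gaussian-envelope
bursts per beat (the "galloping horse" of the two valve sounds); a maternal
vessel train carries ONE wider burst per beat.  Bursts modulate a narrowband
carrier whose centre frequency wanders slowly, emulating the speckle-like,
band-limited character of device-filtered Doppler audio.  Loudness is
normalised to a fixed RMS, emulating the monitor's automatic gain control.

Episode types composed into a recording:

* crossing episodes — the transducer locks onto a maternal vessel: the DUS
  switches to the vessel train and the displayed FHR follows the MHR;
* coincidence episodes — maternal tachycardia pulls the MHR to within
  ~2 bpm of the (still fetal) FHR;
* dropout episodes — signal amplitude collapses to <= 1% of nominal;
* artifact episodes — broadband high-amplitude noise (fetal movement).

All randomness is drawn from streams derived from ``cfg.seed``, so identical
configs yield bit-identical recordings.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import signal as sps

from .config import DUS_RATE_HZ, TRACE_RATE_HZ, BPM_MIN, BPM_MAX, SynthConfig
from .signals import (
    ARTIFACT,
    FETAL,
    SILENT,
    VESSEL,
    DusSignal,
    HeartRateTrace,
    Recording,
    SourceAnnotation,
)

# fixed relative amplitude of the second valve sound within a fetal beat
SECOND_BURST_GAIN = 0.85
# hard ceiling applied after gain normalisation so |amplitude| < 1 pre-noise
PEAK_CEILING = 0.98
# low-pass cutoff of the carrier-frequency wander: slower than the burst
# bandwidths, so each burst keeps a near-constant, transform-limited carrier
WANDER_CUTOFF_HZ = 1.0

_STREAMS = {
    "fetal_hr": 11,
    "maternal_hr": 12,
    "fetal": 21,
    "vessel": 22,
    "noise": 31,
    "artifact": 32,
}


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# heart-rate traces


def make_heart_rate_trace(kind: str, cfg: SynthConfig) -> HeartRateTrace:
    """Generate a 4 Hz heart-rate trace.

    ``kind='fetal'`` gives baseline plus band-limited short-term variability
    (a sum of slow sinusoids, peak deviation = ``fetal_variability_bpm``);
    ``kind='maternal'`` gives baseline plus one slow sinusoidal drift of
    amplitude ``maternal_drift_bpm``.  Values are clipped to the device
    range [50, 240] bpm.
    """
    cfg.validate()
    if cfg.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = round(TRACE_RATE_HZ * cfg.duration_s)
    t = np.arange(n) / TRACE_RATE_HZ
    if kind == "fetal":
        rng = _rng(cfg, "fetal_hr")
        dev = np.zeros(n)
        if cfg.fetal_variability_bpm > 0:
            # band-limited variability: slow sinusoids at 0.02-0.15 Hz
            freqs = np.geomspace(0.02, 0.15, 8)
            amps = rng.uniform(0.3, 1.0, size=freqs.size)
            phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
            for f, a, p in zip(freqs, amps, phases):
                dev += a * np.sin(2 * np.pi * f * t + p)
            peak = np.max(np.abs(dev))
            if peak > 0:
                dev *= cfg.fetal_variability_bpm / peak
        values = cfg.fetal_baseline_bpm + dev
        trace_kind = "FHR"
    elif kind == "maternal":
        rng = _rng(cfg, "maternal_hr")
        phase = rng.uniform(0, 2 * np.pi)
        values = cfg.maternal_baseline_bpm + cfg.maternal_drift_bpm * np.sin(
            2 * np.pi * t / 60.0 + phase
        )
        trace_kind = "MHR"
    else:
        raise ValueError(f"kind must be 'fetal' or 'maternal', got {kind!r}")
    return HeartRateTrace(np.clip(values, BPM_MIN, BPM_MAX), kind=trace_kind)


# ---------------------------------------------------------------------------
# beat trains


def _beat_onsets(hr_bpm: np.ndarray, duration_s: float, rng: np.random.Generator,
                 jitter_ms: float) -> Tuple[np.ndarray, np.ndarray]:
    """Beat onset times under piecewise-constant instantaneous rate.

    Returns (onsets, periods); onsets carry Gaussian timing jitter.
    """
    hr = np.array(hr_bpm, dtype=np.float64)
    if np.isnan(hr).any():
        # forward-fill missing readings; fail only if nothing precedes
        idx = np.where(np.isnan(hr), 0, np.arange(len(hr)))
        np.maximum.accumulate(idx, out=idx)
        hr = hr[idx]
        if np.isnan(hr[0]):
            raise ValueError("heart-rate trace starts with missing values")
    if (hr <= 0).any():
        raise ValueError("heart-rate sample <= 0")
    onsets, periods = [], []
    t = 0.15 * 60.0 / hr[0]  # fixed small phase so whole beats fit the duration
    while t < duration_s:
        rate = hr[min(int(t * TRACE_RATE_HZ), len(hr) - 1)]
        period = 60.0 / rate
        onsets.append(t + rng.normal(0.0, jitter_ms / 1000.0))
        periods.append(period)
        t += period
    return np.asarray(onsets), np.asarray(periods)


def _carrier_phase(n: int, cfg: SynthConfig, spread_hz: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Phase of a carrier whose frequency wanders around the centre.

    The instantaneous frequency is the carrier centre plus low-pass-filtered
    Gaussian noise (std ``spread_hz``), clipped inside the Nyquist band.
    The wander models the Doppler velocity spread of the insonated motion;
    cardiac motion is broader-band than laminar vessel flow.
    """
    freq = np.full(n, cfg.burst_carrier_hz)
    if spread_hz > 0:
        white = rng.standard_normal(n)
        sos = sps.butter(2, WANDER_CUTOFF_HZ, btype="low", fs=DUS_RATE_HZ, output="sos")
        wander = sps.sosfilt(sos, white)
        std = wander.std()
        if std > 0:
            wander *= spread_hz / std
        freq = np.clip(freq + wander, 20.0, DUS_RATE_HZ / 2 - 20.0)
    phase0 = rng.uniform(0, 2 * np.pi)
    return phase0 + 2 * np.pi * np.cumsum(freq) / DUS_RATE_HZ


def synth_beat_train(hr: HeartRateTrace, source: str, cfg: SynthConfig,
                     rng: np.random.Generator | None = None) -> DusSignal:
    """Render a noiseless beat train at 1 kHz driven by a heart-rate trace.

    Fetal beats contribute two Gaussian-envelope bursts separated by
    ``intra_beat_gap_fraction`` of the beat period; vessel beats one wider
    burst.  Burst amplitudes are jittered with CV ``amplitude_jitter_cv``;
    loudness is normalised to ``target_rms`` and the peak capped below 1.
    """
    cfg.validate()
    if len(hr) == 0:
        raise ValueError("heart-rate trace is empty")
    if source not in ("fetal", "vessel"):
        raise ValueError(f"source must be 'fetal' or 'vessel', got {source!r}")
    if rng is None:
        rng = _rng(cfg, source)

    duration_s = len(hr) / TRACE_RATE_HZ
    n = round(duration_s * DUS_RATE_HZ)
    onsets, periods = _beat_onsets(hr.values_bpm, duration_s, rng, cfg.timing_jitter_ms)

    # burst events: (centre_s, relative_amplitude, width_s)
    if source == "fetal":
        sigma = cfg.fetal_burst_width_ms / 1000.0
        centres = np.concatenate([onsets, onsets + cfg.intra_beat_gap_fraction * periods])
        gains = np.concatenate([np.ones_like(onsets), SECOND_BURST_GAIN * np.ones_like(onsets)])
        order = np.argsort(centres)
        centres, gains = centres[order], gains[order]
    else:
        sigma = cfg.vessel_burst_width_ms / 1000.0
        centres, gains = onsets, np.ones_like(onsets)

    envelope = np.zeros(n)
    t_axis = np.arange(n) / DUS_RATE_HZ
    half_support = 4.0 * sigma
    for c, g in zip(centres, gains):
        a = g * max(0.1, 1.0 + cfg.amplitude_jitter_cv * rng.standard_normal())
        lo = max(0, int((c - half_support) * DUS_RATE_HZ))
        hi = min(n, int((c + half_support) * DUS_RATE_HZ) + 1)
        if hi <= lo:
            continue
        envelope[lo:hi] += a * np.exp(-0.5 * ((t_axis[lo:hi] - c) / sigma) ** 2)

    spread = cfg.fetal_spread_hz if source == "fetal" else cfg.vessel_spread_hz
    samples = envelope * np.sin(_carrier_phase(n, cfg, spread, rng))

    # recording-level automatic gain: loudness equalised to target_rms, as
    # the monitor normalises its audio output; peak capped below full scale
    rms = np.sqrt(np.mean(samples**2))
    if rms > 0:
        samples *= cfg.target_rms / rms
    peak = np.max(np.abs(samples))
    if peak > PEAK_CEILING:
        samples *= PEAK_CEILING / peak
    return DusSignal(samples)


# ---------------------------------------------------------------------------
# full recordings


def _sample_slice(start_s: float, end_s: float, rate: int) -> slice:
    return slice(int(round(start_s * rate)), int(round(end_s * rate)))


def _reject_cross_overlaps(cfg: SynthConfig) -> None:
    cats = {
        "crossing": cfg.crossing_episodes,
        "dropout": cfg.dropout_episodes,
        "artifact": cfg.artifact_episodes,
    }
    names = list(cats)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for s1, e1 in cats[a]:
                for s2, e2 in cats[b]:
                    if s1 < e2 and s2 < e1:
                        raise ValueError(
                            f"overlapping {a} episode ({s1}, {e1}) and "
                            f"{b} episode ({s2}, {e2})"
                        )


def make_recording(cfg: SynthConfig) -> Tuple[Recording, SourceAnnotation]:
    """Compose a full synthetic recording with ground-truth annotation.

    The DUS equals the fetal beat train outside crossing episodes and a
    vessel train driven by the MHR inside them; the displayed FHR likewise
    follows the true fetal trace outside and the MHR inside.  Dropouts scale
    the signal to <= 1% of nominal, artifacts replace it with broadband
    noise, and white noise is added at ``snr_db``.
    """
    cfg.validate()
    _reject_cross_overlaps(cfg)

    fhr_true = make_heart_rate_trace("fetal", cfg)
    mhr = make_heart_rate_trace("maternal", cfg)

    # maternal tachycardia episodes: MHR pulled to within ~2 bpm of the FHR
    for start_s, end_s in cfg.coincidence_episodes:
        sl = _sample_slice(start_s, end_s, TRACE_RATE_HZ)
        t = np.arange(sl.stop - sl.start) / TRACE_RATE_HZ
        mhr.values_bpm[sl] = fhr_true.values_bpm[sl] + 2.0 * np.sin(2 * np.pi * t / 20.0)

    fetal_train = synth_beat_train(fhr_true, "fetal", cfg)
    vessel_train = synth_beat_train(mhr, "vessel", cfg)

    dus = fetal_train.samples.copy()
    n = len(dus)
    annotation = np.full(n, FETAL, dtype=np.uint8)
    fhr_shown = fhr_true.values_bpm.copy()

    for start_s, end_s in cfg.crossing_episodes:
        sl = _sample_slice(start_s, end_s, DUS_RATE_HZ)
        dus[sl] = vessel_train.samples[sl]
        annotation[sl] = VESSEL
        tsl = _sample_slice(start_s, end_s, TRACE_RATE_HZ)
        fhr_shown[tsl] = mhr.values_bpm[tsl]

    for start_s, end_s in cfg.dropout_episodes:
        sl = _sample_slice(start_s, end_s, DUS_RATE_HZ)
        dus[sl] *= 0.005
        annotation[sl] = SILENT

    art_rng = _rng(cfg, "artifact")
    for start_s, end_s in cfg.artifact_episodes:
        sl = _sample_slice(start_s, end_s, DUS_RATE_HZ)
        dus[sl] = np.clip(
            art_rng.standard_normal(sl.stop - sl.start) * 2.0 * cfg.target_rms,
            -PEAK_CEILING,
            PEAK_CEILING,
        )
        annotation[sl] = ARTIFACT

    if cfg.snr_db is not None and np.isfinite(cfg.snr_db):
        noise_std = cfg.target_rms * 10.0 ** (-cfg.snr_db / 20.0)
        dus = dus + _rng(cfg, "noise").normal(0.0, noise_std, size=n)
        np.clip(dus, -1.0, 1.0 - 2.0**-15, out=dus)

    rec = Recording(
        id=f"synth-{cfg.seed}",
        dus=DusSignal(dus),
        fhr=HeartRateTrace(fhr_shown, kind="FHR"),
        mhr=mhr,
        annotation=SourceAnnotation(annotation),
    )
    return rec, rec.annotation
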