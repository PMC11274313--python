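import numpy as np
import pytest

from beatsource import CnnConfig, PipelineConfig, RunConfig, SynthConfig
from beatsource.signals import HeartRateTrace, LabeledSegment


def tiny_run_config(seed: int = 0, epochs: int = 1) -> RunConfig:
    """A scaled-down end-to-end study that runs in seconds: 4 recordings of
    80 s, one crossing and one coincidence episode each, a narrow CNN."""
    return RunConfig(
        synth=SynthConfig(duration_s=80.0, crossing_episodes=((10.0, 30.0),),
                          coincidence_episodes=((40.0, 60.0),), seed=seed),
        pipeline=PipelineConfig(),
        cnn=CnnConfig(channels=(4, 4, 8, 8), epochs=epochs, seed=seed),
        n_recordings=4,
        seed=seed,
    )


@pytest.fixture
def quiet_cfg():
    """A short noiseless config with no episodes."""
    return SynthConfig(duration_s=10.0, snr_db=None, seed=3)


def constant_trace(bpm: float, duration_s: float, kind: str = "FHR") -> HeartRateTrace:
    return HeartRateTrace(np.full(round(4 * duration_s), float(bpm)), kind=kind)


def make_segment(label="fetal", fhr=None, mhr=None, dus=None, rec="r0", start=0.0):
    """A 10-s segment with synthetic-or-given contents."""
    rng = np.random.default_rng(0)
    return LabeledSegment(
        recording_id=rec,
        start_s=start,
        dus=rng.normal(0, 0.1, 10_000) if dus is None else dus,
        fhr=np.full(40, 140.0) if fhr is None else np.asarray(fhr, dtype=float),
        mhr=mhr if mhr is None else np.asarray(mhr, dtype=float),
        label=label,
    )
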