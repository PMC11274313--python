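"""Colour-bar quality timeline: flag vessel-contaminated stretches.

Trains a small model, then classifies consecutive 2-s windows of a fresh
recording that contains a crossing episode at 30-50 s.  Blue means the
classifier sees fetal-heart signal, red a maternal vessel; a run of red
under a plausible-looking FHR trace is exactly the failure mode the method
is designed to expose.
"""

from beatsource import (
    CnnConfig, PipelineConfig, RunConfig, SynthConfig,
    make_recording, quality_timeline, run_pipeline,
)

study = RunConfig(
    synth=SynthConfig(duration_s=80.0, crossing_episodes=((10.0, 30.0),),
                      coincidence_episodes=((40.0, 60.0),), seed=5),
    pipeline=PipelineConfig(),
    cnn=CnnConfig(channels=(4, 4, 8, 8), epochs=6, seed=5),
    n_recordings=4,
    seed=5,
)
_, trained = run_pipeline(study)

rec, _ = make_recording(SynthConfig(duration_s=120.0,
                                    crossing_episodes=((30.0, 50.0),), seed=99))
timeline = quality_timeline(rec, trained, stride_s=2.0)

bar = "".join("R" if c == "red" else "." for c in timeline.color)
print(f"one character per 2-s window ('.' fetal, 'R' vessel):\n{bar}")
n_red = sum(c == "red" for c in timeline.color)
print(f"{n_red} of {len(timeline.color)} windows flagged red; "
      "the red block should cover the 30-50 s crossing episode")
timeline.to_csv("timeline.csv")
print("timeline written to timeline.csv (start_s, p_fetal, p_vessel, color)")
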