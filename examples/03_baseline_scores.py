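"""Score fetal and vessel windows with the four classical discriminators.

Peak amplitude, average amplitude, central frequency intensity (power at
the spectral fundamental) and half-power bandwidth are each a single number
per 2-s window; their per-class medians show which carry class information
on synthetic data.
"""

import numpy as np

from beatsource import SynthConfig, make_heart_rate_trace, synth_beat_train
from beatsource.baselines import score_matrix

cfg = SynthConfig(duration_s=60.0, seed=3)
windows = {}
for source, kind in (("fetal", "fetal"), ("vessel", "maternal")):
    hr = make_heart_rate_trace(kind, cfg)
    sig = synth_beat_train(hr, source, cfg).samples
    windows[source] = np.stack([sig[k * 2000:(k + 1) * 2000] for k in range(29)])

print(f"{'score':>28} {'fetal median':>14} {'vessel median':>14}")
for col, name in (("peak", "peak amplitude"), ("avg", "average amplitude"),
                  ("cfi", "central freq. intensity"), ("hpbw", "half-power bandwidth (Hz)")):
    f = score_matrix(windows["fetal"])[col].median()
    v = score_matrix(windows["vessel"])[col].median()
    print(f"{name:>28} {f:14.4f} {v:14.4f}")
# Average amplitude separates the classes best (two short bursts vs one
# wide burst per beat at different rates -> different envelope duty cycle);
# central frequency intensity is nearly identical because loudness
# normalisation equalises spectral peak density.
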