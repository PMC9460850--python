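"""Show the spectral signature that distinguishes snoring from normal breath.

A snoring epoch keeps the slow breath envelope but is attenuated and
carries a fast vibration during exhalation; its spectrum grows a secondary
peak at the vibration frequency that a normal epoch lacks.
"""

import numpy as np
import scipy.fft

from respstage import SleepStage, default_stage_models, synth_epoch, \
    synth_snoring_epoch

model = default_stage_models()[SleepStage.N2]
normal = synth_epoch(model, duration=30.0, dt=0.017, seed=5)
snore = synth_snoring_epoch(model, vib_freq=8.0, vib_depth=0.5,
                            duration=30.0, dt=0.017, seed=5, attenuation=0.6)


def magnitude_near(trace, freq, half_width=0.5):
    x = trace.samples - trace.samples.mean()
    mag = np.abs(scipy.fft.rfft(x))
    fr = scipy.fft.rfftfreq(len(x), trace.dt)
    sel = (fr >= freq - half_width) & (fr <= freq + half_width)
    return mag[sel].max()


print(f"max voltage      normal {normal.samples.max():5.2f} V   "
      f"snoring {snore.samples.max():5.2f} V")
print(f"8 Hz spectral peak  normal {magnitude_near(normal, 8.0):7.1f}     "
      f"snoring {magnitude_near(snore, 8.0):7.1f}")
print("\nSnoring attenuates the breath amplitude (reduced tidal volume) and "
      "adds a vibration peak near 8 Hz absent from quiet breathing — the "
      "cue a snore detector would threshold on.")
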