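"""Simulate a short synthetic night of mask-sensor respiration voltage.

Builds a five-stage hypnogram (2 minutes per stage), generates the voltage
trace with acquisition offset and noise, and prints per-stage signal
statistics.  Non-REM amplitudes shrink with sleep depth while REM breathes
at awake-like amplitude but irregularly.
"""

import numpy as np

from respstage import (AcquisitionModel, SleepStage, default_stage_models,
                       synth_session)

hypnogram = [(stage, 120.0) for stage in SleepStage]
session = synth_session(hypnogram, models=default_stage_models(),
                        acq=AcquisitionModel(dc_offset=1.2, noise_sd=0.05),
                        dt=0.017, seed=0)

print(f"simulated {len(session)} epochs, "
      f"{session.concatenated().duration:.0f} s total, "
      f"{len(session.concatenated())} samples at dt = 0.017 s\n")
print(f"{'stage':<6} {'max V':>7} {'mean V':>7}")
for stage, trace in session.epochs:
    print(f"{stage.name:<6} {trace.samples.max():>7.2f} "
          f"{trace.samples.mean():>7.2f}")
print("\nMax voltage tracks breath amplitude: it drops from AWAKE through "
      "N3 and recovers in REM.  Every sample also carries the 1.2 V "
      "acquisition DC offset, which the preprocessing later removes.")
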