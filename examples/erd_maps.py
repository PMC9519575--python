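"""ERD/ERS time-frequency map and band-power time course.

Builds a low-noise session with a 50% mu/beta amplitude drop during motor
imagery and a 20% post-task rebound, pools the motor-imagery trials, and
prints the baseline-referenced power changes an analyst would read off the
time-frequency map and the 8-30 Hz ERD/ERS curve.
"""

import numpy as np

from strokebci import (SimConfig, epoch_session, erd_ers_curve,
                       generate_session, time_frequency_map)

config = SimConfig(seed=3, erd_depth_left=0.5, erd_depth_right=0.5,
                   background_rms_uv=1.0, sensor_noise_sd=0.2)
recording = generate_session(config)
epochs = epoch_session(recording, (-2.0, 5.0))
mi = epochs.select_trials(np.flatnonzero(epochs.labels == 1))
print(f"pooled motor-imagery trials: {mi.n_trials}")

tf = time_frequency_map(mi, "C3", window_s=1.0, step_s=0.1)
mu_rows = (tf.freqs >= 9) & (tf.freqs <= 11)
task_cols = (tf.times >= 1.0) & (tf.times <= 3.5)
print(f"time-frequency map: {tf.values.shape[0]} windows x "
      f"{tf.values.shape[1]} frequencies")
print(f"mu-band (9-11 Hz) change during the task: "
      f"{tf.values[np.ix_(task_cols, mu_rows)].mean():+.1f}% "
      "(analytic oscillator-only value: -75.0%)")

curve = erd_ers_curve(mi, "C3", band=(8.0, 30.0))
erd = curve.values[(curve.times >= 1.0) & (curve.times <= 3.5)].mean()
ers = curve.values[(curve.times >= 4.2) & (curve.times <= 4.8)].mean()
print(f"8-30 Hz ERD during [1.0, 3.5] s: {erd:+.1f}%")
print(f"8-30 Hz ERS rebound in [4.2, 4.8] s: {ers:+.1f}% "
      "(analytic: +44% for a 1.2x amplitude overshoot)")

# Negative values are event-related desynchronization (power suppression
# during imagery); the positive rebound after the task end is the ERS.
# The residual 1/f background dilutes both toward zero relative to the
# oscillator-only analytic values.
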