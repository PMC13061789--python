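"""Stimulus-onset lag and vibration-ramp analysis of a synthetic session.

Generates a 200-trial timing session (700-ms trials, stimuli nominally at
300 ms, per-channel hardware lags, ramped vibration), detects physical
onsets from the waveforms, and reproduces the three analyses: onset lag vs
the trigger, marker lag vs the detected onset, and the regression of
visual-vibration asynchrony on the ramp period.
"""

import numpy as np

from multitact.synthetic_data import SessionGenConfig, gen_session_recording
from multitact.timing_analysis import (
    OnsetDetectorConfig,
    detect_onsets,
    filter_spurious_onsets,
    lag_summary,
    match_markers_to_onsets,
    regress_asynchrony_on_ramp,
)

cfg = SessionGenConfig(n_trials=200, sample_rate=8000.0, seed=0)
det = OnsetDetectorConfig(frame=512, hop=128)
recordings, events, truth = gen_session_recording(cfg)

onsets = {}
print("onset lag vs trigger (ms):")
print("channel        mean    sd     p25    p50    p75      n")
for ch in ("light", "sound", "vibration_mic"):
    detected = filter_spurious_onsets(detect_onsets(recordings[ch], det))
    onsets[ch] = np.array([o.time for o in detected if o.accepted])
    t = lag_summary(onsets[ch] - events.stimulus_onsets, ch)
    print(f"{ch:<13} {t.mean:6.1f} {t.sd:5.1f}  {t.p25:6.1f} {t.p50:6.1f} {t.p75:6.1f} {t.n_events:6d}")

matches, unmatched = match_markers_to_onsets(
    events.device_markers["vibration_mic"], onsets["vibration_mic"]
)
marker_lag = lag_summary(matches["lag"].to_numpy(), "vibration marker lag")
print(f"\nvibration marker lag (ramp to trigger threshold): "
      f"{marker_lag.mean:.1f} ms (SD {marker_lag.sd:.1f}, {unmatched.size} unmatched)")

asynchrony = (events.device_markers["vibration_mic"] - onsets["light"]) * 1000.0
res = regress_asynchrony_on_ramp(matches["lag"].to_numpy() * 1000.0, asynchrony)
print(f"asynchrony ~ ramp: slope {res.slope:.3f} (SE {res.slope_se:.3f}), "
      f"intercept {res.intercept:.2f} ms, R^2 = {res.r_squared:.3f}, "
      f"F({res.df1}, {res.df2}) = {res.f_value:.1f}")
print("\nThe vibration channel trails the others because its amplitude ramps up;")
print("the regression shows the ramp period predicts the visual-vibration asynchrony,")
print("with a residual intercept lag even at zero ramp.")
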