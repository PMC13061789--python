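"""Stimulus-onset timing analysis from session audio recordings.

Given a mono recording of one stimulus channel (photodiode-style light
trace, tone, or vibration picked up by a microphone) together with the
browser trigger stream and device threshold markers, this module measures:

* physical stimulus onsets, via a normalized RMS-envelope threshold
  detector (pluggable, so an external detector such as a trained
  onset-detection network can be substituted) with optional sub-sample
  refinement using the analytic-signal (Hilbert) envelope;
* marker lag — the delay of each device marker behind its matched physical
  onset (for ramped vibration this is the ramp period up to the marker
  threshold);
* onset lag relative to the trigger (accuracy) and its SD (precision),
  summarized as mean/SD/min/quartiles/max tables in milliseconds;
* cross-modal asynchrony relative to a reference (visual) channel, and an
  OLS regression of asynchrony on ramp/marker lag.

Internal computation is in seconds at full sample resolution; tables are
reported in milliseconds.  Percentiles use linear interpolation between
order statistics; SDs use the n-1 denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.io import wavfile
from scipy.signal import hilbert

__all__ = [
    "Recording",
    "EventMarkers",
    "OnsetEstimate",
    "OnsetDetectorConfig",
    "LagTable",
    "RegressionResult",
    "read_wav",
    "write_wav",
    "read_events_json",
    "write_events_json",
    "rms_envelope",
    "detect_onsets",
    "filter_spurious_onsets",
    "match_markers_to_onsets",
    "lag_summary",
    "asynchrony_summary",
    "regress_asynchrony_on_ramp",
]

CHANNEL_LABELS = ("light", "sound", "vibration_mic")


@dataclass(frozen=True)
class Recording:
    samples: np.ndarray
    sample_rate: float
    channel_label: str = "sound"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class EventMarkers:
    """Trigger streams (seconds) plus per-channel device threshold markers."""

    trial_onsets: np.ndarray
    stimulus_onsets: np.ndarray
    trial_offsets: np.ndarray
    device_markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("trial_onsets", "stimulus_onsets", "trial_offsets"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        object.__setattr__(
            self,
            "device_markers",
            {k: np.asarray(v, dtype=float) for k, v in self.device_markers.items()},
        )
        n = self.stimulus_onsets.size
        if self.trial_onsets.size == n and self.trial_offsets.size == n:
            if np.any(self.stimulus_onsets < self.trial_onsets) or np.any(
                self.stimulus_onsets > self.trial_offsets
            ):
                raise ValueError("stimulus onsets must lie within their trials")


@dataclass(frozen=True)
class OnsetEstimate:
    time: float
    envelope_at_onset: float
    accepted: bool = True


@dataclass(frozen=True)
class OnsetDetectorConfig:
    """Envelope-threshold detector settings.

    ``threshold`` is on the peak-normalized RMS envelope; ``refractory_s``
    suppresses re-triggering within one stimulus;  with ``refine`` the
    frame-level crossing is sharpened to sub-sample precision by finding
    the linear-interpolated crossing of ``threshold`` x local peak on the
    Hilbert amplitude envelope around the frame.
    """

    threshold: float = 0.05
    refractory_s: float = 0.1
    frame: int = 2048
    hop: int = 512
    refine: bool = True
    refine_lookahead_s: float = 0.06


def rms_envelope(recording: Recording, frame: int = 2048, hop: int = 512):
    """Peak-normalized per-frame RMS envelope and frame-center times.

    Returns ``(envelope, times)``; an all-zero signal keeps an all-zero
    envelope.
    """
    x = recording.samples
    if x.size < frame:
        raise ValueError(f"recording shorter than one frame ({x.size} < {frame})")
    n_frames = 1 + (x.size - frame) // hop
    starts = np.arange(n_frames) * hop
    # O(n) framing via a cumulative sum of squares (long sessions stay cheap)
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    rms = np.sqrt((csum[starts + frame] - csum[starts]) / frame)
    peak = rms.max()
    if peak > 0:
        rms = rms / peak
    times = (starts + frame / 2.0) / recording.sample_rate
    return rms, times


def _refine_onset(
    x: np.ndarray, sr: float, start_idx: int, cfg: OnsetDetectorConfig
) -> float:
    """Sub-sample onset via the Hilbert envelope around the crossing frame."""
    margin = 256  # discarded on both sides: FFT wrap-around leakage decays ~1/k
    w0 = max(0, start_idx - cfg.frame)
    w1 = min(x.size, start_idx + cfg.frame + int(cfg.refine_lookahead_s * sr))
    seg = x[max(0, w0 - margin): min(x.size, w1 + margin)]
    env = np.abs(hilbert(seg))[w0 - max(0, w0 - margin): w1 - max(0, w0 - margin)]
    level = cfg.threshold * env.max()
    above = env >= level
    if not above.any():
        return start_idx / sr
    j = int(np.argmax(above))
    if j == 0:
        return w0 / sr
    frac = (level - env[j - 1]) / (env[j] - env[j - 1])
    return (w0 + j - 1 + frac) / sr


def _threshold_detector(recording: Recording, cfg: OnsetDetectorConfig) -> list[OnsetEstimate]:
    env, times = rms_envelope(recording, cfg.frame, cfg.hop)
    sr = recording.sample_rate
    half = cfg.frame / (2.0 * sr)
    onsets: list[OnsetEstimate] = []
    last = -np.inf
    crossing = (env >= cfg.threshold) & np.concatenate(([True], env[:-1] < cfg.threshold))
    for i in np.flatnonzero(crossing):
        t_coarse = times[i] - half  # first sample of the crossing frame
        if t_coarse - last < cfg.refractory_s:
            continue
        t = t_coarse
        if cfg.refine:
            t = _refine_onset(recording.samples, sr, int(round(t_coarse * sr)), cfg)
        # pre-onset amplitude: last frame lying wholly before the crossing frame
        pre = i - max(1, cfg.frame // cfg.hop)
        pre_env = float(env[pre]) if pre >= 0 else 0.0
        onsets.append(OnsetEstimate(time=float(t), envelope_at_onset=pre_env))
        last = t_coarse
    return onsets


def detect_onsets(
    recording: Recording,
    config: OnsetDetectorConfig | None = None,
    detector=None,
) -> list[OnsetEstimate]:
    """Detect stimulus onsets; ``detector(recording, config)`` may be swapped in.

    The default detector reports the first upward crossing of the
    normalized RMS envelope above ``config.threshold`` after a refractory
    interval.  Each onset carries the envelope value of the last frame
    lying wholly before the crossing frame — the amplitude already present
    before the onset — which is what the spurious-onset rule inspects
    (slow-attack stimuli would otherwise contaminate the pre-onset frame
    with their own ramp).
    """
    if config is None:
        config = OnsetDetectorConfig()
    if detector is None:
        detector = _threshold_detector
    return detector(recording, config)


def filter_spurious_onsets(onsets, max_envelope: float = 0.01) -> list[OnsetEstimate]:
    """Flag onsets sitting on amplitude already above ``max_envelope`` as spurious.

    An onset whose pre-onset normalized RMS strictly exceeds the limit is
    marked rejected (a real onset rises out of silence); the boundary value
    itself is accepted.
    """
    return [replace(o, accepted=o.envelope_at_onset <= max_envelope) for o in onsets]


def match_markers_to_onsets(markers, onsets, max_gap: float = 0.150):
    """Pair each marker with its nearest accepted onset within ``max_gap`` s.

    Returns ``(matches, unmatched)``: matches is a DataFrame with columns
    marker, onset, lag (= marker - onset, positive when the marker trails
    the physical onset); unmatched holds markers with no onset in range.
    """
    markers = np.asarray(markers, dtype=float)
    if len(onsets) and isinstance(onsets[0], OnsetEstimate):
        times = np.array([o.time for o in onsets if o.accepted])
    else:
        times = np.asarray(onsets, dtype=float)
    if times.size == 0:
        return (
            pd.DataFrame(columns=["marker", "onset", "lag"]),
            markers.copy(),
        )
    pos = np.searchsorted(times, markers)
    left = np.clip(pos - 1, 0, times.size - 1)
    right = np.clip(pos, 0, times.size - 1)
    nearest = np.where(
        np.abs(markers - times[left]) <= np.abs(markers - times[right]), left, right
    )
    gap = np.abs(markers - times[nearest])
    ok = gap <= max_gap
    matches = pd.DataFrame(
        {
            "marker": markers[ok],
            "onset": times[nearest[ok]],
            "lag": markers[ok] - times[nearest[ok]],
        }
    )
    return matches, markers[~ok]


@dataclass(frozen=True)
class LagTable:
    """Mean/SD/min/quartiles/max of a lag distribution, in milliseconds."""

    event_label: str
    mean: float
    sd: float
    min: float
    p25: float
    p50: float
    p75: float
    max: float
    n_events: int


def lag_summary(lags_s, label: str) -> LagTable:
    """Summarize lags (seconds in, milliseconds out)."""
    lags = np.asarray(lags_s, dtype=float) * 1000.0
    if lags.size == 0:
        raise ValueError("no lags to summarize")
    q25, q50, q75 = np.percentile(lags, [25, 50, 75])
    return LagTable(
        event_label=label,
        mean=float(lags.mean()),
        sd=float(lags.std(ddof=1)) if lags.size > 1 else 0.0,
        min=float(lags.min()),
        p25=float(q25),
        p50=float(q50),
        p75=float(q75),
        max=float(lags.max()),
        n_events=int(lags.size),
    )


def asynchrony_summary(channel_onsets_s, reference_onsets_s, label: str) -> LagTable:
    """Per-trial asynchrony (channel minus reference/visual onset), as a LagTable."""
    ch = np.asarray(channel_onsets_s, dtype=float)
    ref = np.asarray(reference_onsets_s, dtype=float)
    if ch.shape != ref.shape:
        raise ValueError("channel and reference onset lists must align per trial")
    return lag_summary(ch - ref, label)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    slope_se: float
    slope_t: float
    slope_p: float
    slope_ci95: tuple
    intercept: float
    intercept_se: float
    intercept_t: float
    intercept_p: float
    intercept_ci95: tuple
    r_squared: float
    f_value: float
    df1: int
    df2: int


def regress_asynchrony_on_ramp(ramp_lags_ms, asynchronies_ms) -> RegressionResult:
    """OLS of asynchrony on ramp period (both ms), with classical inference."""
    x = np.asarray(ramp_lags_ms, dtype=float)
    y = np.asarray(asynchronies_ms, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of at least 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor; fit is degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        slope_t=float(model.tvalues[1]),
        slope_p=float(model.pvalues[1]),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        intercept_t=float(model.tvalues[0]),
        intercept_p=float(model.pvalues[0]),
        intercept_ci95=(float(ci[0][0]), float(ci[0][1])),
        r_squared=float(model.rsquared),
        f_value=float(model.fvalue),
        df1=int(model.df_model),
        df2=int(model.df_resid),
    )


# ---------------------------------------------------------------------------
# I/O: 16-bit PCM mono WAV and the events JSON schema


def write_wav(path, recording: Recording) -> None:
    x = np.clip(recording.samples, -1.0, 1.0)
    wavfile.write(str(path), int(recording.sample_rate), (x * 32767).astype(np.int16))


def read_wav(path, channel_label: str = "sound") -> Recording:
    sr, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return Recording(samples=data, sample_rate=float(sr), channel_label=channel_label)


def write_events_json(path, events: EventMarkers) -> None:
    payload = {
        "trial_onsets": events.trial_onsets.tolist(),
        "stimulus_onsets": events.stimulus_onsets.tolist(),
        "trial_offsets": events.trial_offsets.tolist(),
        "device_markers": {k: v.tolist() for k, v in events.device_markers.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_events_json(path) -> EventMarkers:
    payload = json.loads(Path(path).read_text())
    return EventMarkers(
        trial_onsets=payload["trial_onsets"],
        stimulus_onsets=payload["stimulus_onsets"],
        trial_offsets=payload["trial_offsets"],
        device_markers=payload.get("device_markers", {}),
    )
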