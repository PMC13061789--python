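"""Synthetic inputs with ground truth for every pipeline stage.

Two generators emulate the experimental designs the analysis code targets:

* :func:`gen_rte_trials` — trial tables for the redundant-target reaction
  time task: per participant, 30 catch trials plus 10 trials in each of the
  seven target conditions (100 total), with participant condition means
  drawn from a correlated multivariate normal around configurable group
  means, plus anticipations, slow outliers, and misses at configurable
  rates.

* :func:`gen_session_recording` — timing-benchmark sessions: 700-ms trials
  (300-ms foreperiod, 200-ms stimulus) with trigger streams at 0/300/700 ms
  per trial; a light (photodiode-proxy) channel, a 440-Hz tone channel, and
  a vibration-microphone channel whose amplitude ramps up over a sampled
  ramp duration; device markers are the closed-form times at which each
  channel's amplitude envelope crosses the marker threshold, emulating a
  sound-level trigger box.  All per-trial lags, ramps, onsets, and marker
  times are returned as ground truth.

Every generator is deterministic under a fixed seed.

The staircase observer harness lives in :mod:`multitact.staircase_matching`
and is re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .staircase_matching import SimulatedObserver, run_simulated_staircase  # noqa: F401 (re-export)
from .timing_analysis import EventMarkers, Recording

__all__ = [
    "RTEGenConfig",
    "SessionGenConfig",
    "gen_rte_trials",
    "gen_session_recording",
    "marker_crossing_delay",
    "SimulatedObserver",
    "run_simulated_staircase",
]

# group-level per-condition mean/SD of participant mean RTs (seconds); the
# defaults describe a plausible multisensory detection sample in which
# redundant targets are faster than single targets
DEFAULT_CONDITION_MEANS = {
    "V": 0.476, "A": 0.514, "T": 0.478,
    "AV": 0.431, "VT": 0.412, "AT": 0.432, "AVT": 0.403,
}
DEFAULT_CONDITION_SDS = {
    "V": 0.093, "A": 0.140, "T": 0.097,
    "AV": 0.100, "VT": 0.092, "AT": 0.113, "AVT": 0.114,
}


@dataclass(frozen=True)
class RTEGenConfig:
    """Reaction-time table generator settings (times in seconds)."""

    n_participants: int = 32
    n_none_trials: int = 30
    n_trials_per_target: int = 10
    condition_means: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_MEANS))
    condition_sds: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_SDS))
    within_subject_corr: float = 0.8
    trial_sd: float = 0.08
    anticipation_rate: float = 0.02
    slow_outlier_rate: float = 0.02
    miss_rate: float = 0.02
    response_window: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.anticipation_rate, self.slow_outlier_rate, self.miss_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if set(self.condition_means) != set(self.condition_sds):
            raise ValueError("condition_means and condition_sds must cover the same conditions")
        if not -1 < self.within_subject_corr < 1:
            raise ValueError("within_subject_corr must be in (-1, 1)")


def gen_rte_trials(config: RTEGenConfig, rng: np.random.Generator | None = None):
    """Generate a trial table and its ground truth.

    Returns ``(trials, truth)`` where ``trials`` has columns participant,
    condition, rt, responded and ``truth`` carries the participant-level
    true condition means plus contamination bookkeeping.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    conds = list(config.condition_means)
    k = len(conds)
    sds = np.array([config.condition_sds[c] for c in conds])
    means = np.array([config.condition_means[c] for c in conds])
    r = np.full((k, k), config.within_subject_corr)
    np.fill_diagonal(r, 1.0)
    cov = r * np.outer(sds, sds)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded by corr bound
        raise ValueError("infeasible condition covariance") from e
    pmeans = rng.multivariate_normal(means, cov, size=config.n_participants, method="cholesky")

    rows = []
    contamination = {"anticipations": 0, "slow_outliers": 0, "misses": 0}
    for i in range(config.n_participants):
        pid = f"p{i+1:02d}"
        for _ in range(config.n_none_trials):
            rows.append((pid, "none", np.nan, False))
        for j, cond in enumerate(conds):
            for _ in range(config.n_trials_per_target):
                u = rng.random()
                if u < config.miss_rate:
                    rows.append((pid, cond, np.nan, False))
                    contamination["misses"] += 1
                elif u < config.miss_rate + config.anticipation_rate:
                    rows.append((pid, cond, rng.uniform(0.02, 0.095), True))
                    contamination["anticipations"] += 1
                elif u < config.miss_rate + config.anticipation_rate + config.slow_outlier_rate:
                    hi = min(1.6, config.response_window)
                    rows.append((pid, cond, rng.uniform(1.05, hi), True))
                    contamination["slow_outliers"] += 1
                else:
                    rt = rng.normal(pmeans[i, j], config.trial_sd)
                    rt = min(max(rt, 0.0), config.response_window)
                    rows.append((pid, cond, rt, True))
    trials = pd.DataFrame(rows, columns=["participant", "condition", "rt", "responded"])
    truth = {
        "participant_means": pd.DataFrame(
            pmeans, columns=conds, index=[f"p{i+1:02d}" for i in range(config.n_participants)]
        ),
        "configured_means": dict(zip(conds, means)),
        "configured_sds": dict(zip(conds, sds)),
        "contamination": contamination,
    }
    return trials, truth


@dataclass(frozen=True)
class SessionGenConfig:
    """Timing-session generator settings.

    Lags and ramps are (mean, sd) in milliseconds; channels carry a tone at
    the given frequency whose amplitude envelope ramps up over the channel's
    ramp duration (linear by default, optionally exponential) and holds
    until stimulus offset.  ``marker_threshold`` is the fraction of peak
    amplitude at which the emulated trigger box fires.
    """

    n_trials: int = 1000
    block_size: int = 250
    trial_length_s: float = 0.700
    foreperiod_s: float = 0.300
    stimulus_duration_s: float = 0.200
    sample_rate: float = 44100.0
    light_lag_ms: tuple = (35.9, 4.3)
    sound_lag_ms: tuple = (40.9, 3.4)
    vibration_lag_ms: tuple = (48.1, 3.0)
    light_ramp_ms: tuple = (3.0, 0.0)
    sound_ramp_ms: tuple = (5.0, 0.0)
    vibration_ramp_ms: tuple = (30.46, 5.28)
    light_freq_hz: float = 400.0
    tone_freq_hz: float = 440.0
    vibration_freq_hz: float = 180.0
    amplitude: float = 0.8
    noise_floor: float = 0.004
    marker_threshold: float = 0.4
    ramp_shape: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.foreperiod_s + self.stimulus_duration_s > self.trial_length_s:
            raise ValueError("foreperiod + stimulus duration must fit inside the trial")
        if self.ramp_shape not in ("linear", "exponential"):
            raise ValueError("ramp_shape must be 'linear' or 'exponential'")
        if not 0 < self.marker_threshold < 1:
            raise ValueError("marker_threshold must be in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def marker_crossing_delay(ramp_s, frac: float, shape: str = "linear"):
    """Closed-form delay from physical onset to the envelope crossing ``frac`` of peak.

    Linear ramp of duration tau: delay = frac * tau.  Exponential ramp
    (time constant tau/3, ~95% of peak at tau): delay = -(tau/3) ln(1-frac).
    """
    ramp_s = np.asarray(ramp_s, dtype=float)
    if shape == "linear":
        return frac * ramp_s
    return -(ramp_s / 3.0) * np.log1p(-frac)


def _ramp_envelope(t_rel: np.ndarray, tau: float, shape: str) -> np.ndarray:
    if tau <= 0:
        return np.ones_like(t_rel)
    if shape == "linear":
        return np.clip(t_rel / tau, 0.0, 1.0)
    return 1.0 - np.exp(-3.0 * t_rel / tau)


_CHANNELS = (
    ("light", "light_lag_ms", "light_ramp_ms", "light_freq_hz"),
    ("sound", "sound_lag_ms", "sound_ramp_ms", "tone_freq_hz"),
    ("vibration_mic", "vibration_lag_ms", "vibration_ramp_ms", "vibration_freq_hz"),
)


def gen_session_recording(config: SessionGenConfig, rng: np.random.Generator | None = None):
    """Generate per-channel recordings, trigger/marker events, and ground truth.

    Returns ``(recordings, events, truth)``: recordings maps channel label
    to :class:`Recording`; events holds the three trigger streams plus
    per-channel device markers (closed-form envelope threshold crossings);
    truth maps channel label to per-trial physical onsets, lags (ms), ramp
    durations (ms), and marker times (s).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sr = config.sample_rate
    n = config.n_trials
    t0 = np.arange(n) * config.trial_length_s
    stim_nominal = t0 + config.foreperiod_s
    total_samples = int(np.ceil((n * config.trial_length_s + 0.1) * sr))
    t_axis = np.arange(total_samples) / sr

    recordings: dict[str, Recording] = {}
    device_markers: dict[str, np.ndarray] = {}
    truth: dict[str, dict] = {}
    for label, lag_attr, ramp_attr, freq_attr in _CHANNELS:
        lag_mean, lag_sd = getattr(config, lag_attr)
        ramp_mean, ramp_sd = getattr(config, ramp_attr)
        freq = getattr(config, freq_attr)
        lags_ms = rng.normal(lag_mean, lag_sd, size=n)
        ramps_ms = np.maximum(rng.normal(ramp_mean, ramp_sd, size=n), 0.0) if ramp_sd > 0 \
            else np.full(n, ramp_mean)
        onsets = stim_nominal + lags_ms / 1000.0
        if np.any(onsets + config.stimulus_duration_s > t0 + config.trial_length_s):
            raise ValueError("a stimulus burst overlaps the next trial; reduce lags or duration")

        x = rng.normal(0.0, config.noise_floor * config.amplitude, size=total_samples)
        for i in range(n):
            a = int(np.ceil(onsets[i] * sr))
            b = min(int((onsets[i] + config.stimulus_duration_s) * sr), total_samples)
            tt = t_axis[a:b] - onsets[i]
            env = _ramp_envelope(tt, ramps_ms[i] / 1000.0, config.ramp_shape)
            x[a:b] += config.amplitude * env * np.sin(2 * np.pi * freq * tt)
        recordings[label] = Recording(samples=x, sample_rate=sr, channel_label=label)

        delay = marker_crossing_delay(ramps_ms / 1000.0, config.marker_threshold, config.ramp_shape)
        markers = onsets + delay
        device_markers[label] = markers
        truth[label] = {
            "physical_onsets_s": onsets,
            "lags_ms": lags_ms,
            "ramps_ms": ramps_ms,
            "marker_times_s": markers,
            "marker_delays_ms": delay * 1000.0,
        }

    events = EventMarkers(
        trial_onsets=t0,
        stimulus_onsets=stim_nominal,
        trial_offsets=t0 + config.trial_length_s,
        device_markers=device_markers,
    )
    return recordings, events, truth
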