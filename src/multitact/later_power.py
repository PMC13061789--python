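"""Monte Carlo power analysis under the LATER reaction-time model.

The LATER (Linear Approach to Threshold with Ergodic Rate) model treats each
trial's decision signal as rising linearly at a rate ``v`` drawn from a
normal distribution truncated at zero; the reaction time is ``RT = 1/v``.
A slowing manipulation is modeled as a decrement ``delta_mu`` of the mean
rise rate in the experimental condition.  Trial-to-trial jitter in the
physical stimulus onset ("onset noise") is modeled as zero-mean Gaussian
noise added to every simulated RT.

For a hierarchical population of participants the module simulates whole
experiments (participants x trials x 2 conditions), tests the paired
per-participant mean RTs with a two-sided Wilcoxon signed-rank test, and
maps out empirical power over a grid of effect sizes, interpolating to the
smallest effect reaching a target power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._wilcoxon import wilcoxon_pvalues

__all__ = [
    "LATERPopulation",
    "ParticipantParams",
    "PowerDesign",
    "PowerPoint",
    "PowerCurve",
    "DegenerateEffectError",
    "PowerRangeError",
    "draw_participants",
    "simulate_condition_means",
    "wilcoxon_two_sided",
    "estimate_power",
    "power_curve",
    "min_effect_at_power",
    "delta_mu_to_rt_shift",
]

DEFAULT_DELTA_MU_GRID = tuple(np.round(np.arange(0.0, 0.0801, 0.005), 6))


class DegenerateEffectError(ValueError):
    """The requested effect would push a participant's mean rate to <= 0."""


class PowerRangeError(ValueError):
    """The target power is not bracketed by the estimated power curve."""


@dataclass(frozen=True)
class LATERPopulation:
    """Hierarchical drift-rate population (all rates in 1/s).

    ``mu_base``/``sigma_mu`` parameterize the normal distribution of
    participant mean rates; ``sigma_base``/``sigma_sigma`` that of the
    participant rate SDs (taken as absolute values of normal draws).
    """

    mu_base: float = 2.5
    sigma_mu: float = 0.3
    sigma_base: float = 0.4
    sigma_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.mu_base <= 0:
            raise ValueError("mu_base must be > 0")
        if self.sigma_mu < 0 or self.sigma_sigma < 0:
            raise ValueError("hyperprior SDs must be >= 0")
        if self.sigma_base <= 0:
            raise ValueError("sigma_base must be > 0")


@dataclass(frozen=True)
class ParticipantParams:
    """Per-participant rate mean and SD (1/s)."""

    mu_i: float
    sigma_i: float

    def __post_init__(self) -> None:
        if self.sigma_i < 0:
            raise ValueError("sigma_i must be >= 0")


@dataclass(frozen=True)
class PowerDesign:
    """Design of one Monte Carlo power run.

    ``onset_noise_sd`` is in milliseconds; rates are 1/s; RTs in seconds.
    """

    n_participants: int = 20
    n_trials: int = 100
    onset_noise_sd: float = 0.0
    delta_mu_grid: tuple = DEFAULT_DELTA_MU_GRID
    n_reps: int = 10_000
    alpha: float = 0.05
    power_target: float = 0.8
    seed: int = 0
    population: LATERPopulation = field(default_factory=LATERPopulation)

    def __post_init__(self) -> None:
        grid = np.asarray(self.delta_mu_grid, dtype=float)
        if grid.size < 1 or np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("delta_mu_grid must be strictly increasing and >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("n_participants and n_trials must be >= 1")
        if self.onset_noise_sd < 0:
            raise ValueError("onset_noise_sd must be >= 0")


@dataclass(frozen=True)
class PowerPoint:
    delta_mu: float
    power: float
    mc_se: float


@dataclass(frozen=True)
class PowerCurve:
    points: tuple
    design: PowerDesign

    @property
    def delta_mus(self) -> np.ndarray:
        return np.array([p.delta_mu for p in self.points])

    @property
    def powers(self) -> np.ndarray:
        return np.array([p.power for p in self.points])


def draw_participants(pop: LATERPopulation, n: int, rng: np.random.Generator) -> list[ParticipantParams]:
    """Draw ``n`` participants: mu_i ~ N(mu_base, sigma_mu), sigma_i = |N(sigma_base, sigma_sigma)|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mu = rng.normal(pop.mu_base, pop.sigma_mu, size=n)
    sigma = np.abs(rng.normal(pop.sigma_base, pop.sigma_sigma, size=n))
    return [ParticipantParams(m, s) for m, s in zip(mu, sigma)]


def _truncated_rates(mu: np.ndarray, sigma: np.ndarray, shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Per-trial rates v ~ N(mu, sigma) truncated at zero by rejection (redraw)."""
    v = rng.normal(mu, sigma, size=shape)
    bad = v <= 0.0
    # with mu ~6 sigma above zero this loop essentially never iterates
    while bad.any():
        v[bad] = rng.normal(np.broadcast_to(mu, shape)[bad], np.broadcast_to(sigma, shape)[bad])
        bad = v <= 0.0
    return v


def _condition_means(
    mu: np.ndarray,
    sigma: np.ndarray,
    delta_mu: float,
    onset_noise_sd_ms: float,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean RT per participant for control and experimental conditions.

    ``mu``/``sigma`` may be 1-D (participants) or 2-D (replicates x
    participants); one trailing trial axis is added.
    """
    if np.any(mu - delta_mu <= 0):
        raise DegenerateEffectError(
            f"delta_mu={delta_mu} drives a participant mean rate to <= 0"
        )
    shape = mu.shape + (n_trials,)
    mu_t = mu[..., None]
    sig_t = sigma[..., None]
    v_ctrl = _truncated_rates(mu_t, sig_t, shape, rng)
    v_exp = _truncated_rates(mu_t - delta_mu, sig_t, shape, rng)
    rt_ctrl = 1.0 / v_ctrl
    rt_exp = 1.0 / v_exp
    if onset_noise_sd_ms > 0:
        sd_s = onset_noise_sd_ms / 1000.0
        rt_ctrl = rt_ctrl + rng.normal(0.0, sd_s, size=shape)
        rt_exp = rt_exp + rng.normal(0.0, sd_s, size=shape)
    return rt_ctrl.mean(axis=-1), rt_exp.mean(axis=-1)


def simulate_condition_means(
    participants: list[ParticipantParams],
    delta_mu: float,
    onset_noise_sd: float,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one experiment; return (control, experimental) mean RT (s) per participant.

    Per trial the rate is drawn from the participant's truncated normal
    (mean mu_i for control, mu_i - delta_mu for experimental), RT = 1/v, and
    zero-mean Gaussian onset noise (SD in ms) is added to every trial of
    both conditions.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if onset_noise_sd < 0:
        raise ValueError("onset_noise_sd must be >= 0")
    mu = np.array([p.mu_i for p in participants])
    sigma = np.array([p.sigma_i for p in participants])
    return _condition_means(mu, sigma, delta_mu, onset_noise_sd, n_trials, rng)


def wilcoxon_two_sided(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact distribution for n <= 25, normal approximation with continuity
    correction above; zero differences dropped (Wilcoxon's convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    if np.all(d == 0):
        return 1.0
    n = np.count_nonzero(d)
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(
        x, y, alternative="two-sided", zero_method="wilcox", method=method, correction=True
    )
    return float(res.pvalue)


def estimate_power(
    design: PowerDesign,
    delta_mu: float,
    rng: np.random.Generator | None = None,
    _chunk: int = 1000,
) -> tuple[float, float]:
    """Empirical power (and Monte Carlo SE) at one effect size.

    Runs ``design.n_reps`` replicate experiments, drawing fresh participants
    each replicate, and returns the fraction with Wilcoxon p < alpha.
    """
    if delta_mu < 0:
        raise ValueError("delta_mu must be >= 0")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    pop = design.population
    n_rej = 0
    done = 0
    while done < design.n_reps:
        r = min(_chunk, design.n_reps - done)
        mu = rng.normal(pop.mu_base, pop.sigma_mu, size=(r, design.n_participants))
        sigma = np.abs(rng.normal(pop.sigma_base, pop.sigma_sigma, size=(r, design.n_participants)))
        ctrl, exp = _condition_means(
            mu, sigma, delta_mu, design.onset_noise_sd, design.n_trials, rng
        )
        pvals = wilcoxon_pvalues(ctrl - exp)
        n_rej += int(np.sum(pvals < design.alpha))
        done += r
    p = n_rej / design.n_reps
    se = float(np.sqrt(p * (1.0 - p) / design.n_reps))
    return p, se


def power_curve(design: PowerDesign) -> PowerCurve:
    """Power at every grid point, with independent RNG substreams per point."""
    children = np.random.SeedSequence(design.seed).spawn(len(design.delta_mu_grid))
    points = []
    for dm, child in zip(design.delta_mu_grid, children):
        p, se = estimate_power(design, float(dm), rng=np.random.default_rng(child))
        points.append(PowerPoint(float(dm), p, se))
    return PowerCurve(tuple(points), design)


def min_effect_at_power(curve: PowerCurve, target: float | None = None) -> float:
    """Smallest delta_mu reaching the target power, by linear interpolation.

    Uses the first adjacent grid pair bracketing the target; an exact grid
    hit returns that grid value.
    """
    if target is None:
        target = curve.design.power_target
    dms = curve.delta_mus
    pows = curve.powers
    if dms.size < 2:
        raise PowerRangeError("need at least 2 curve points")
    for i in range(dms.size):
        if pows[i] == target:
            return float(dms[i])
        if i + 1 < dms.size and pows[i] < target <= pows[i + 1]:
            frac = (target - pows[i]) / (pows[i + 1] - pows[i])
            return float(dms[i] + frac * (dms[i + 1] - dms[i]))
    raise PowerRangeError(
        f"target power {target} not bracketed; achieved range "
        f"[{pows.min():.3f}, {pows.max():.3f}]"
    )


def delta_mu_to_rt_shift(mu_base: float, delta_mu: float) -> float:
    """Approximate RT slowdown (ms) for a drift-rate decrement: |1/mu - 1/(mu-dmu)| * 1000."""
    if mu_base <= 0:
        raise ValueError("mu_base must be > 0")
    if not 0 <= delta_mu < mu_base:
        raise ValueError("require 0 <= delta_mu < mu_base")
    return abs(1.0 / mu_base - 1.0 / (mu_base - delta_mu)) * 1000.0


def reduced(design: PowerDesign, n_reps: int) -> PowerDesign:
    """Copy of ``design`` with a smaller replicate count (for quick runs)."""
    return replace(design, n_reps=n_reps)
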