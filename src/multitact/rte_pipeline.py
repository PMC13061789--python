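"""Redundant-target-effect (RTE) reaction-time analysis pipeline.

Takes trial-level simple-RT tables from a multisensory detection task with
seven target conditions (V, A, T, AV, AT, VT, AVT) plus catch ("none")
trials, applies the standard outlier filters, summarizes conditions at the
participant level, and runs a one-way repeated-measures ANOVA with
Greenhouse-Geisser sphericity correction and Holm-adjusted pairwise paired
t-tests.

Filtering is two-stage and order-fixed: an absolute range filter
(100-1000 ms) first, then a 2.5-SD filter applied once per
participant x condition cell on the survivors (sample SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CONDITIONS",
    "TARGET_CONDITIONS",
    "FilterReport",
    "ConditionSummary",
    "AnovaResult",
    "apply_rt_filters",
    "condition_summary",
    "rm_anova_gg",
    "holm_pairwise",
    "means_matrix",
]

TARGET_CONDITIONS = ("V", "A", "T", "AV", "AT", "VT", "AVT")
CONDITIONS = TARGET_CONDITIONS + ("none",)

RT_MIN_S = 0.100
RT_MAX_S = 1.000
SD_CRITERION = 2.5


@dataclass(frozen=True)
class FilterReport:
    """Per-cell exclusion counts; ``cells`` is indexed by (participant, condition)."""

    n_input: int
    n_no_response: int
    n_no_target: int
    n_removed_fast: int
    n_removed_slow: int
    n_removed_sd: int
    n_retained: int
    cells: pd.DataFrame
    warnings: tuple = ()


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n: int
    mean: float
    sd: float
    se: float


@dataclass(frozen=True)
class AnovaResult:
    f_value: float
    df_effect: float
    df_error: float
    df_effect_gg: float
    df_error_gg: float
    epsilon_gg: float
    p_value: float
    p_value_gg: float
    eta_squared: float
    partial_eta_squared: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: float
    mauchly_p: float
    pairwise: pd.DataFrame | None = None


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "condition", "rt", "responded"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    bad = set(trials["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    return trials


def apply_rt_filters(trials: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Two-stage RT exclusion; returns retained target trials and a report.

    Misses (no response) and catch trials are tabulated but excluded from
    the RT analysis before the range filter.  Stage 1 drops RT < 100 ms or
    > 1000 ms; stage 2 drops trials deviating more than 2.5 sample SDs from
    their participant x condition mean, in a single pass over the stage-1
    survivors.
    """
    trials = _validate_trials(trials)
    n_input = len(trials)
    is_target = trials["condition"] != "none"
    responded = trials["responded"].astype(bool) & trials["rt"].notna()
    n_no_target = int((~is_target).sum())
    n_no_response = int((is_target & ~responded).sum())
    rt_trials = trials[is_target & responded].copy()

    fast = rt_trials["rt"] < RT_MIN_S
    slow = rt_trials["rt"] > RT_MAX_S
    stage1 = rt_trials[~(fast | slow)].copy()

    warnings: list[str] = []
    keep = pd.Series(True, index=stage1.index)
    for (pp, cond), cell in stage1.groupby(["participant", "condition"], sort=False):
        if len(cell) < 2:
            warnings.append(f"cell ({pp}, {cond}): <2 trials after range filter; SD filter skipped")
            continue
        m = cell["rt"].mean()
        sd = cell["rt"].std(ddof=1)
        if sd == 0:
            continue
        keep.loc[cell.index[(cell["rt"] - m).abs() > SD_CRITERION * sd]] = False
    retained = stage1[keep]

    removed_sd = stage1[~keep]
    cells = (
        pd.DataFrame(
            {
                "n_input": rt_trials.groupby(["participant", "condition"]).size(),
                "n_removed_fast": rt_trials[fast].groupby(["participant", "condition"]).size(),
                "n_removed_slow": rt_trials[slow].groupby(["participant", "condition"]).size(),
                "n_removed_sd": removed_sd.groupby(["participant", "condition"]).size(),
                "n_retained": retained.groupby(["participant", "condition"]).size(),
            }
        )
        .fillna(0)
        .astype(int)
    )
    report = FilterReport(
        n_input=n_input,
        n_no_response=n_no_response,
        n_no_target=n_no_target,
        n_removed_fast=int(fast.sum()),
        n_removed_slow=int(slow.sum()),
        n_removed_sd=int(len(removed_sd)),
        n_retained=int(len(retained)),
        cells=cells,
        warnings=tuple(warnings),
    )
    return retained, report


def condition_summary(retained: pd.DataFrame, conditions=TARGET_CONDITIONS) -> list[ConditionSummary]:
    """Group-level summary over participant means (N = participants per condition)."""
    out = []
    for cond in conditions:
        sub = retained[retained["condition"] == cond]
        if sub.empty:
            continue
        pmeans = sub.groupby("participant")["rt"].mean()
        n = len(pmeans)
        sd = float(pmeans.std(ddof=1)) if n > 1 else float("nan")
        out.append(
            ConditionSummary(
                condition=cond,
                n=n,
                mean=float(pmeans.mean()),
                sd=sd,
                se=sd / np.sqrt(n) if n > 1 else float("nan"),
            )
        )
    return out


def means_matrix(retained: pd.DataFrame, conditions=TARGET_CONDITIONS) -> pd.DataFrame:
    """Participants x conditions matrix of mean RTs (listwise-complete rows only)."""
    mat = (
        retained.groupby(["participant", "condition"])["rt"]
        .mean()
        .unstack("condition")
        .reindex(columns=list(conditions))
    )
    return mat.dropna(axis=0, how="any")


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the k x k condition covariance matrix."""
    k = cov.shape[0]
    c = np.eye(k) - np.full((k, k), 1.0 / k)
    s = c @ cov @ c
    tr = np.trace(s)
    return float(tr**2 / ((k - 1) * np.sum(s**2)))


def _mauchly(cov: np.ndarray, n: int) -> tuple[float, float, float, float]:
    """Mauchly's sphericity test (W, chi2, df, p) via the centered covariance."""
    k = cov.shape[0]
    p = k - 1
    # orthonormal contrast basis (columns sum to zero, span orthogonal to 1)
    c = np.linalg.qr(np.eye(k)[:, 1:] - 1.0 / k)[0][:, :p]
    s = c.T @ cov @ c
    eig = np.linalg.eigvalsh(s)
    if eig.max() <= 1e-12 * max(1.0, float(np.abs(cov).max())):
        # no between-condition variance: sphericity holds trivially
        return 1.0, 0.0, p * (p + 1) / 2.0 - 1.0, 1.0
    eig = np.clip(eig, 1e-300, None)
    w = float(np.prod(eig) / (eig.mean() ** p))
    d = 1.0 - (2 * p**2 + p + 2) / (6.0 * p * (n - 1))
    chi2 = -(n - 1) * d * np.log(w)
    df = p * (p + 1) / 2.0 - 1.0
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return w, float(chi2), df, pval


def rm_anova_gg(matrix, include_pairwise: bool = True) -> AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is participants x conditions (DataFrame or array), complete.
    Classical sums of squares partition the total into subject, condition,
    and residual terms; epsilon comes from the sample covariance of the
    condition columns; p-values are reported both uncorrected and at the
    GG-corrected degrees of freedom.  Both classical and partial eta-squared
    are returned.
    """
    if isinstance(matrix, pd.DataFrame):
        x = matrix.to_numpy(dtype=float)
        labels = list(matrix.columns)
    else:
        x = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(x.shape[1])]
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (participants x conditions)")
    if np.isnan(x).any():
        raise ValueError("matrix has missing cells; apply listwise deletion upstream")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 participants and >= 2 conditions")

    grand = x.mean()
    ss_total = float(np.sum((x - grand) ** 2))
    ss_subj = float(k * np.sum((x.mean(axis=1) - grand) ** 2))
    ss_cond = float(n * np.sum((x.mean(axis=0) - grand) ** 2))
    ss_err = ss_total - ss_subj - ss_cond

    df_effect = k - 1.0
    df_error = (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    f = ms_cond / ms_err if ms_err > 0 else 0.0 if ms_cond == 0 else np.inf

    cov = np.cov(x, rowvar=False, ddof=1)
    eps = 1.0 if k == 2 else _gg_epsilon(cov)
    df_e_gg = eps * df_effect
    df_r_gg = eps * df_error
    p_unc = float(stats.f.sf(f, df_effect, df_error))
    p_gg = float(stats.f.sf(f, df_e_gg, df_r_gg))

    w, chi2, mdf, mp = _mauchly(cov, n) if k > 2 else (1.0, 0.0, 0.0, 1.0)

    pairwise = holm_pairwise(pd.DataFrame(x, columns=labels)) if include_pairwise else None
    return AnovaResult(
        f_value=float(f),
        df_effect=df_effect,
        df_error=df_error,
        df_effect_gg=float(df_e_gg),
        df_error_gg=float(df_r_gg),
        epsilon_gg=float(eps),
        p_value=p_unc,
        p_value_gg=p_gg,
        eta_squared=ss_cond / ss_total if ss_total > 0 else 0.0,
        partial_eta_squared=ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0,
        mauchly_w=w,
        mauchly_chi2=chi2,
        mauchly_df=mdf,
        mauchly_p=mp,
        pairwise=pairwise,
    )


def holm_pairwise(matrix) -> pd.DataFrame:
    """All pairwise paired t-tests between conditions, Holm step-down adjusted."""
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    if matrix.isna().any().any():
        raise ValueError("matrix has missing cells; apply listwise deletion upstream")
    rows = []
    for a, b in combinations(matrix.columns, 2):
        t, p = stats.ttest_rel(matrix[a], matrix[b])
        rows.append(
            {
                "pair": f"{a}-{b}",
                "mean_diff": float(matrix[a].mean() - matrix[b].mean()),
                "t": float(t),
                "p_raw": float(p),
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = multipletests(table["p_raw"], method="holm")[1]
    return table
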