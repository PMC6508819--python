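"""Two-stage growth analysis.

Stage 1 fits a three-parameter logistic H(t) = A / (1 + exp(-r (t -
t_half))) to each replicate's height series by least squares and derives
the time from half to three-quarters of the asymptote (ln 3 / r).
Stage 2 treats the per-replicate parameter estimates as responses in a
one-way between-group comparison (classic or Welch ANOVA), one
parameter at a time — the stated alternative to a full nonlinear mixed
model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateFitError, InputError

PARAMETERS = ("A", "t_half", "dt_half_to_3q")


@dataclass
class GrowthTrajectory:
    """Weekly height series for one plant."""

    plant_id: str
    genotype: str
    vernalization_weeks: int
    times: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.shape != self.heights.shape or self.times.ndim != 1:
            raise InputError("times and heights must be 1-D arrays of equal length")
        if len(self.times) < 5:
            raise InputError("need >= 5 observations to fit a logistic curve")
        if not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")
        if (self.heights < 0).any():
            raise InputError("heights must be non-negative")

    @property
    def group(self) -> str:
        return f"{self.genotype}:v{self.vernalization_weeks}"


@dataclass(frozen=True)
class GrowthFit:
    plant_id: str
    genotype: str
    vernalization_weeks: int
    A: float
    r: float
    t_half: float
    dt_half_to_3q: float
    r2: float
    converged: bool
    message: str = ""

    @property
    def group(self) -> str:
        return f"{self.genotype}:v{self.vernalization_weeks}"


def logistic(t, A, r, t_half):
    return A / (1.0 + np.exp(-r * (t - t_half)))


def _initial_guess(t: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    a0 = 1.05 * h.max()
    half = a0 / 2.0
    above = np.flatnonzero(h >= half)
    t0 = t[above[0]] if above.size else float(np.median(t))
    frac = np.clip(h / a0, 1e-6, 1.0 - 1e-6)
    slope, intercept = np.polyfit(t, np.log(frac / (1.0 - frac)), 1)
    r0 = slope if slope > 1e-3 else 0.5
    return a0, r0, float(t0)


def fit_logistic(traj: GrowthTrajectory) -> GrowthFit:
    """Least-squares logistic fit of one trajectory.

    Raises :class:`DegenerateFitError` on a flat series (no growth
    signal). Non-convergence is reported via ``converged=False`` rather
    than raised.
    """
    t, h = traj.times, traj.heights
    if h.max() <= 0 or np.ptp(h) < 1e-9 * max(h.max(), 1.0):
        raise DegenerateFitError(
            f"{traj.plant_id}: flat height series, logistic fit is undefined"
        )

    p0 = _initial_guess(t, h)
    converged, message = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                logistic, t, h, p0=p0,
                bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                ftol=1e-8, xtol=1e-12, maxfev=500 * 4,
            )
    except RuntimeError as exc:  # exceeded maxfev without converging
        converged, message = False, str(exc)
        popt = np.asarray(p0, dtype=float)

    A, r, t_half = (float(v) for v in popt)
    resid = h - logistic(t, *popt)
    sse = float(resid @ resid)
    sst = float(((h - h.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")

    return GrowthFit(
        plant_id=traj.plant_id, genotype=traj.genotype,
        vernalization_weeks=traj.vernalization_weeks,
        A=A, r=r, t_half=t_half, dt_half_to_3q=math.log(3.0) / r,
        r2=r2, converged=converged, message=message,
    )


@dataclass(frozen=True)
class ParameterComparison:
    parameter: str
    group_means: dict
    group_sds: dict
    group_ns: dict
    statistic: float
    p: float


@dataclass(frozen=True)
class StageTwoResult:
    comparisons: dict  # parameter -> ParameterComparison
    excluded_groups: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for param, comp in self.comparisons.items():
            for grp in comp.group_means:
                rows.append({
                    "parameter": param, "group": grp,
                    "mean": comp.group_means[grp], "sd": comp.group_sds[grp],
                    "n": comp.group_ns[grp], "statistic": comp.statistic,
                    "p": comp.p,
                })
        return pd.DataFrame(rows)


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    vars_ = np.array([g.var(ddof=1) for g in groups])
    if np.ptp(means) == 0:
        return 0.0, 1.0
    if (vars_ <= 0).any():
        return float("inf"), 0.0
    w = ns / vars_
    mw = (w * means).sum() / w.sum()
    f_num = ((w * (means - mw) ** 2).sum()) / (k - 1)
    lam = (3.0 * ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()) / (k**2 - 1)
    f_stat = f_num / (1 + 2 * lam * (k - 2) / 3)
    df2 = 1.0 / lam
    return float(f_stat), float(stats.f.sf(f_stat, k - 1, df2))


def _oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    scale = float((all_vals**2).sum())
    if ssb <= 1e-12 * max(scale, 1e-300):
        return 0.0, 1.0  # no between-group signal beyond float noise
    if ssw <= 0:
        return float("inf"), 0.0
    f_stat = (ssb / df1) / (ssw / df2)
    return float(f_stat), float(stats.f.sf(f_stat, df1, df2))


def stage_two(fits: Sequence[GrowthFit], groups: Optional[Sequence[str]] = None,
              welch: bool = False) -> StageTwoResult:
    """Per-parameter one-way comparison of stage-1 estimates across groups.

    Non-converged fits are dropped; groups left with fewer than two fits
    are excluded with a warning. Each parameter (A, t_half,
    dt_half_to_3q) is analyzed independently.
    """
    if groups is None:
        groups = [f.group for f in fits]
    if len(groups) != len(fits):
        raise InputError("group labels must align with fits")

    by_group: dict[str, list[GrowthFit]] = {}
    for fit, grp in zip(fits, groups):
        if fit.converged:
            by_group.setdefault(grp, []).append(fit)

    excluded = tuple(g for g, fs in by_group.items() if len(fs) < 2)
    for g in excluded:
        warnings.warn(f"group {g!r} has < 2 converged fits; excluded", stacklevel=2)
        del by_group[g]
    if len(by_group) < 2:
        raise InputError("need >= 2 groups with >= 2 converged fits each")

    comparisons = {}
    for param in PARAMETERS:
        vals = {g: np.array([getattr(f, param) for f in fs]) for g, fs in by_group.items()}
        arrays = list(vals.values())
        if welch:
            stat, p = _welch_anova(arrays)
        else:
            stat, p = _oneway(arrays)
        comparisons[param] = ParameterComparison(
            parameter=param,
            group_means={g: float(v.mean()) for g, v in vals.items()},
            group_sds={g: float(v.std(ddof=1)) for g, v in vals.items()},
            group_ns={g: int(v.size) for g, v in vals.items()},
            statistic=stat, p=p,
        )
    return StageTwoResult(comparisons=comparisons, excluded_groups=excluded)


# --- tabular I/O -----------------------------------------------------------

TRAJECTORY_COLUMNS = ["plant_id", "genotype", "weeks_vernalized", "week", "height_cm"]


def trajectories_from_frame(df: pd.DataFrame) -> list[GrowthTrajectory]:
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"trajectory table missing columns {sorted(missing)}")
    out = []
    for (pid, geno, vern), sub in df.groupby(
        ["plant_id", "genotype", "weeks_vernalized"], sort=False
    ):
        sub = sub.sort_values("week")
        out.append(GrowthTrajectory(
            plant_id=str(pid), genotype=str(geno), vernalization_weeks=int(vern),
            times=sub["week"].to_numpy(float), heights=sub["height_cm"].to_numpy(float),
        ))
    return out


def trajectories_to_frame(trajs: Sequence[GrowthTrajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajs:
        for t, h in zip(tr.times, tr.heights):
            rows.append({
                "plant_id": tr.plant_id, "genotype": tr.genotype,
                "weeks_vernalized": tr.vernalization_weeks,
                "week": t, "height_cm": h,
            })
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def fits_to_frame(fits: Sequence[GrowthFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "plant_id": f.plant_id, "genotype": f.genotype,
        "weeks_vernalized": f.vernalization_weeks, "A": f.A, "r": f.r,
        "t_half": f.t_half, "dt_half_to_3q": f.dt_half_to_3q, "r2": f.r2,
        "converged": f.converged,
    } for f in fits])
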