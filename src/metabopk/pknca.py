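"""Non-compartmental pharmacokinetic analysis (NCA).

Estimates the standard single-dose parameters — AUC0-t, Cmax, Tmax, the
terminal elimination rate constant Kel and the half-life T1/2 = ln2/Kel —
directly from a subject's concentration–time profile, without assuming any
compartment model.

The terminal phase is found by a best-fit search: ordinary least squares of
ln(concentration) on time over every window of at least three positive
observations that starts strictly after Tmax and ends at the last
measurable observation, keeping the window with the highest adjusted R²
and preferring more points whenever adjusted R² values are within 1e-4.
Anchoring the window at the last observation is the standard NCA "best
fit" rule; a free-floating window search is badly behaved under assay
noise (short interior windows win by luck and, because only negative
slopes qualify, bias Kel upward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationProfile",
    "PKParameters",
    "KelFit",
    "compute_auc",
    "estimate_kel",
    "compute_pk_profile",
    "compute_pk_table",
]

PK_PARAMETER_NAMES = ("auc0t", "cmax", "tmax", "kel", "t_half")


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject's plasma concentration–time series.

    Times in hours, sorted ascending and unique; concentrations in µg/mL,
    non-negative, same length; at least three observations.
    """

    subject_id: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t.size < 3:
            raise ValueError("a profile needs at least 3 observations")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing (sorted, unique)")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass
class PKParameters:
    """Per-subject NCA estimates; kel/t_half are NaN when undefined."""

    subject_id: str
    auc0t: float
    cmax: float
    tmax: float
    kel: float
    t_half: float
    n_terminal_points: int
    terminal_r2: float


class KelFit(NamedTuple):
    kel: float
    n_terminal_points: int
    terminal_r2: float


def compute_auc(profile: ConcentrationProfile, method: str = "linear") -> float:
    """AUC from t=0 to the last measurable time by the trapezoidal rule.

    ``method='linear'`` is the plain trapezoid; ``'linlog'`` uses the
    logarithmic trapezoid on strictly declining positive segments (the
    lin-up/log-down convention) and the linear rule elsewhere. All observed
    points enter the sum (a terminal zero closes the curve at zero area
    beyond it); the below-quantification-limit trimming applies only to the
    terminal log-linear fit.
    """
    t, c = profile.times, profile.concentrations
    if t.size < 2:
        raise ValueError(
            f"AUC undefined for subject {profile.subject_id!r}: fewer than 2 points"
        )
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    linear = dt * (c1 + c2) / 2.0
    if method == "linear":
        return float(np.sum(linear))
    if method == "linlog":
        declining = (c1 > 0) & (c2 > 0) & (c2 < c1)
        seg = linear.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            loglog = dt * (c1 - c2) / np.log(c1 / c2)
        seg[declining] = loglog[declining]
        return float(np.sum(seg))
    raise ValueError(f"unknown AUC method: {method!r}")


def _measurable(profile: ConcentrationProfile) -> tuple[np.ndarray, np.ndarray]:
    """Trim values below the quantification limit (trailing zeros).

    Zeros after the last positive observation are treated as missing; zeros
    before/at Tmax (pre-absorption) are kept as true zeros.
    """
    c = profile.concentrations
    pos = np.nonzero(c > 0)[0]
    if pos.size == 0:
        return profile.times, c
    last = pos[-1]
    return profile.times[: last + 1], c[: last + 1]


def estimate_kel(profile: ConcentrationProfile) -> KelFit:
    """Terminal elimination rate constant by best-adjusted-R² log-linear fit.

    Windows start strictly after Tmax and end at the last measurable
    observation. Returns ``KelFit(nan, 0, nan)`` (flagged, not fatal) when
    fewer than three positive points lie strictly after Tmax or no window
    yields a negative slope.
    """
    t, c = _measurable(profile)
    if t.size == 0 or np.all(c <= 0):
        return KelFit(np.nan, 0, np.nan)
    i_tmax = int(np.argmax(c))
    cand = np.nonzero((np.arange(t.size) > i_tmax) & (c > 0))[0]
    if cand.size < 3:
        return KelFit(np.nan, 0, np.nan)
    # candidate indices are not necessarily contiguous in the raw profile
    # (interior zeros break them); windows are contiguous in candidate order
    # and always end at the last measurable point.
    tt, lc = t[cand], np.log(c[cand])
    best: tuple[float, int] | None = None  # (adj_r2, n)
    best_fit = (np.nan, 0, np.nan)
    m = cand.size
    for n in range(3, m + 1):
        xs, ys = tt[m - n :], lc[m - n :]
        slope, r2 = _ols_slope_r2(xs, ys)
        if not slope < 0:
            continue
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or _better((adj, n), best):
            best = (adj, n)
            best_fit = (-slope, n, r2)
    if best is None:
        return KelFit(np.nan, 0, np.nan)
    return KelFit(float(best_fit[0]), int(best_fit[1]), float(best_fit[2]))


def _better(key: tuple[float, int], best: tuple[float, int]) -> bool:
    # higher adjusted R² wins; near-ties (1e-4, the conventional NCA
    # tolerance) prefer the window with more points.
    if key[0] > best[0] + 1e-4:
        return True
    if key[0] < best[0] - 1e-4:
        return False
    return key[1] > best[1]


def _ols_slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x - x.mean(), y - y.mean()
    sxx = float(xm @ xm)
    syy = float(ym @ ym)
    sxy = float(xm @ ym)
    if sxx == 0.0:
        return 0.0, 0.0
    slope = sxy / sxx
    r2 = 1.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    return slope, r2


def compute_pk_profile(
    profile: ConcentrationProfile, auc_method: str = "linear"
) -> PKParameters:
    """All NCA parameters for one profile."""
    c = profile.concentrations
    i = int(np.argmax(c))
    cmax = float(c[i])
    tmax = float(profile.times[i])
    auc = compute_auc(profile, method=auc_method)
    fit = estimate_kel(profile)
    t_half = float(np.log(2) / fit.kel) if np.isfinite(fit.kel) else np.nan
    return PKParameters(
        subject_id=profile.subject_id,
        auc0t=auc,
        cmax=cmax,
        tmax=tmax,
        kel=fit.kel,
        t_half=t_half,
        n_terminal_points=fit.n_terminal_points,
        terminal_r2=fit.terminal_r2,
    )


def compute_pk_table(
    profiles: Sequence[ConcentrationProfile], auc_method: str = "linear"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject NCA table plus an arithmetic mean (SD) cohort summary.

    Subjects with an undefined Kel carry NaN for kel/t_half and are excluded
    pairwise from the summary of those columns.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    rows = [compute_pk_profile(p, auc_method=auc_method) for p in profiles]
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "auc0t": [r.auc0t for r in rows],
            "cmax": [r.cmax for r in rows],
            "tmax": [r.tmax for r in rows],
            "kel": [r.kel for r in rows],
            "t_half": [r.t_half for r in rows],
            "n_terminal_points": [r.n_terminal_points for r in rows],
            "terminal_r2": [r.terminal_r2 for r in rows],
        }
    )
    params = list(PK_PARAMETER_NAMES)
    summary = pd.DataFrame(
        {
            "mean": table[params].mean(skipna=True),
            "sd": table[params].std(ddof=1, skipna=True),
            "n": table[params].count(),
        }
    )
    return table, summary


def read_concentrations_csv(path) -> list[ConcentrationProfile]:
    """Read a long-format concentrations CSV (subject,time_h,conc_ug_per_ml)."""
    df = pd.read_csv(path)
    profiles = []
    for sid, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("time_h")
        profiles.append(
            ConcentrationProfile(
                subject_id=str(sid),
                times=grp["time_h"].to_numpy(float),
                concentrations=grp["conc_ug_per_ml"].to_numpy(float),
            )
        )
    return profiles
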