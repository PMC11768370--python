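"""Pre- vs post-dose differential abundance with empirical-Bayes moderation.

Each subject contributes one within-subject difference (post − pre) per
feature, which makes the participant blocking exact: the paired design
collapses to a one-sample regression of the differences on an intercept
plus (centered) subject-level covariates — sex, age, BMI and the study
period. The intercept is then the covariate-adjusted mean paired difference.

Per-feature residual variances are shrunk toward a pooled prior estimated by
the closed-form method of moments on log sample variances (the scaled
inverse-chi-square hierarchical model): s̃² = (d0·s0² + d·s²)/(d0 + d), with
the moderated t referred to a t distribution on d0 + d degrees of freedom.
Multiplicity is handled by Benjamini–Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureMatrix

__all__ = [
    "DesignSpec",
    "PairedFit",
    "paired_design_fit",
    "eb_moderate",
    "bh_adjust",
    "select_features",
]

DEFAULT_COVARIATES = ("sex", "age", "bmi", "period")


@dataclass(frozen=True)
class DesignSpec:
    """Paired pre/post contrast with subject blocking and covariates."""

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    block: str = "subject_id"
    contrast: tuple[str, str] = ("pre", "post")


@dataclass
class PairedFit:
    """Per-feature OLS results on within-subject differences."""

    feature_ids: list[str]
    estimate: np.ndarray  # adjusted mean paired difference
    sigma2: np.ndarray  # residual variance
    df_resid: int
    se_unit: np.ndarray  # unscaled SE of the intercept (same for all features)
    n_subjects: int = 0
    subjects: list[str] = field(default_factory=list)


def paired_differences(
    fm: FeatureMatrix, design: DesignSpec = DesignSpec()
) -> pd.DataFrame:
    """Subjects × features table of (post − pre) differences.

    Subjects lacking either timepoint are dropped with a warning.
    """
    pre_tp, post_tp = design.contrast
    pre = fm.subject_matrix(pre_tp)
    post = fm.subject_matrix(post_tp)
    common = pre.index.intersection(post.index)
    dropped = set(pre.index).symmetric_difference(post.index)
    if dropped:
        warnings.warn(
            f"dropping subjects without both timepoints: {sorted(dropped)}",
            stacklevel=2,
        )
    return post.loc[common] - pre.loc[common]


def paired_design_fit(
    fm: FeatureMatrix,
    traits: pd.DataFrame | None = None,
    design: DesignSpec = DesignSpec(),
) -> PairedFit:
    """Fit per-feature difference models with covariate adjustment.

    ``traits`` (indexed by subject id) supplies the covariate columns;
    covariates are mean-centered so the intercept remains the adjusted mean
    paired difference. The study ``period`` covariate, being an injection
    property, is read from the feature-matrix metadata when absent from
    ``traits``. Raises on a singular (collinear) design.
    """
    diffs = paired_differences(fm, design)
    if diffs.shape[0] < 3:
        raise ValueError("need at least 3 complete subject pairs")
    subjects = list(diffs.index)

    cov_cols = []
    names = []
    for cov in design.covariates:
        if traits is not None and cov in traits.columns:
            col = traits.loc[subjects, cov].to_numpy(float)
        elif cov == "period":
            meta = fm.metadata
            per = (
                meta[meta["timepoint"] != "QC"]
                .drop_duplicates("subject_id")
                .set_index("subject_id")["period"]
            )
            col = pd.to_numeric(per.loc[subjects], errors="coerce").to_numpy(float)
        else:
            raise KeyError(f"covariate {cov!r} not found in traits")
        cov_cols.append(col - np.mean(col))
        names.append(cov)

    X = np.column_stack([np.ones(len(subjects))] + cov_cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, ["intercept"] + names)
        raise ValueError(f"singular covariate design; collinear columns: {collinear}")

    Y = diffs.to_numpy(float)  # subjects × features
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df_resid = n - p
    sigma2 = (resid**2).sum(axis=0) / df_resid
    se_unit = float(np.sqrt(xtx_inv[0, 0]))
    return PairedFit(
        feature_ids=list(diffs.columns),
        estimate=beta[0],
        sigma2=sigma2,
        df_resid=df_resid,
        se_unit=np.full(Y.shape[1], se_unit),
        n_subjects=n,
        subjects=subjects,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    out = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            out.append(names[j])
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimation of (d0, s0²) from log sample variances.

    Models s² ~ s0²·F(d, d0); returns d0 = inf (complete shrinkage) when the
    spread of log variances is no more than expected under a common variance.
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    s0 = float(
        np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0


def squeeze_variances(
    sigma2: np.ndarray, df: float, prior_df: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Posterior variances s̃² = (d0·s0² + d·s²)/(d0 + d)."""
    if prior_df is None:
        d0, s0 = fit_variance_prior(sigma2, df)
    elif prior_df == 0:
        return np.asarray(sigma2, float), 0.0, float("nan")
    else:
        d0 = float(prior_df)
        _, s0 = fit_variance_prior(sigma2, df)
    if np.isinf(d0):
        return np.full_like(np.asarray(sigma2, float), s0), d0, s0
    post = (d0 * s0 + df * np.asarray(sigma2, float)) / (d0 + df)
    return post, d0, s0


def eb_moderate(
    fit: PairedFit, alpha: float = 0.05, prior_df: float | None = None
) -> pd.DataFrame:
    """Moderated t-tests for every feature; returns the results table.

    ``prior_df=0`` forces the no-shrinkage limit (ordinary t). When every
    residual variance is zero the function falls back to the ordinary t with
    a warning (t = ±inf for nonzero estimates).
    """
    if len(fit.feature_ids) < 10 and prior_df is None:
        raise ValueError("variance-prior estimation needs at least 10 features")
    sigma2 = np.asarray(fit.sigma2, float)
    if np.all(sigma2 == 0):
        warnings.warn(
            "all residual variances are zero; falling back to ordinary t",
            stacklevel=2,
        )
        post, d0 = sigma2, 0.0
    else:
        post, d0, _ = squeeze_variances(sigma2, fit.df_resid, prior_df=prior_df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.estimate / (np.sqrt(post) * fit.se_unit)
    df_total = fit.df_resid + (0.0 if not np.isfinite(d0) else d0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isnan(t), np.nan, p)
    p = np.where(np.isinf(t), 0.0, p)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "feature_id": fit.feature_ids,
            "estimate": fit.estimate,
            "t_mod": t,
            "p": p,
            "q": q,
            "selected": q <= alpha,
        }
    )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN p propagate as NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q_ok, _, _ = multipletests(p[ok], method="fdr_bh")
    q[ok] = q_ok
    return q


def select_features(results: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Feature ids with q ≤ alpha, in stable (input) order."""
    if len(results) == 0:
        return []
    mask = results["q"].to_numpy() <= alpha
    return list(results.loc[mask, "feature_id"])
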