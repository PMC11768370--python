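"""QC-anchored drift correction and feature-table preprocessing.

The chain, in fixed order, is the standard untargeted-LC-MS recipe:

1. ``drift_correct`` — divide each feature by a smooth curve fit to its pooled-QC
   intensities versus injection order (LOESS by default), normalized to mean
   one over the QC injections.
2. ``impute_zeros`` — replace zeros by half the smallest positive value of the
   original (matrix-global) dataset.
3. ``iqr_filter`` — drop the lowest 10% of features by interquartile range
   across study injections (near-constant features).
4. ``rsd_filter`` — drop features whose QC relative standard deviation
   exceeds 20%.
5. ``transform_scale`` — log10 then Pareto scaling (center, divide by the
   square root of the standard deviation), statistics taken over study
   injections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "FeatureMatrix",
    "PreprocessReport",
    "qc_rsd",
    "drift_correct",
    "impute_zeros",
    "iqr_filter",
    "rsd_filter",
    "transform_scale",
    "preprocess_pipeline",
]

QC_LABEL = "QC"


@dataclass
class FeatureMatrix:
    """Features × injections intensity table with injection metadata.

    ``intensities``: DataFrame, rows = feature ids, columns = injection ids.
    ``metadata``: DataFrame indexed by injection id with columns
    ``subject_id`` (empty/NaN for QC), ``timepoint`` in {pre, post, QC},
    ``injection_order`` (unique positive ints) and ``period``.
    ``analysis_scale`` flips to True after transform_scale; the pipeline uses
    it to refuse a second transform.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    analysis_scale: bool = False

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.metadata.index):
            raise ValueError("intensity columns must match metadata injection ids")
        required = {"subject_id", "timepoint", "injection_order", "period"}
        missing = required - set(self.metadata.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        order = self.metadata["injection_order"]
        if order.duplicated().any():
            raise ValueError("injection_order values must be unique")
        bad = set(self.metadata["timepoint"]) - {"pre", "post", QC_LABEL}
        if bad:
            raise ValueError(f"unknown timepoint labels: {sorted(bad)}")
        if not self.analysis_scale and (self.intensities.to_numpy() < 0).any():
            raise ValueError("raw intensities must be non-negative")

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def qc_ids(self) -> list[str]:
        return list(self.metadata.index[self.metadata["timepoint"] == QC_LABEL])

    @property
    def study_ids(self) -> list[str]:
        return list(self.metadata.index[self.metadata["timepoint"] != QC_LABEL])

    def copy(self, intensities: pd.DataFrame | None = None) -> "FeatureMatrix":
        return FeatureMatrix(
            intensities=(
                self.intensities.copy() if intensities is None else intensities
            ),
            metadata=self.metadata.copy(),
            analysis_scale=self.analysis_scale,
        )

    def subject_matrix(self, timepoint: str) -> pd.DataFrame:
        """Subjects × features table for one study timepoint."""
        mask = self.metadata["timepoint"] == timepoint
        ids = self.metadata.index[mask]
        sub = self.intensities[ids].T
        sub.index = self.metadata.loc[ids, "subject_id"].to_numpy()
        return sub.sort_index()

    # -- I/O in the simulate module's CSV dialect --------------------------
    def to_csv(self, matrix_path, metadata_path) -> None:
        self.intensities.to_csv(matrix_path, float_format="%.10g")
        self.metadata.to_csv(metadata_path, index_label="injection_id")

    @classmethod
    def from_csv(cls, matrix_path, metadata_path) -> "FeatureMatrix":
        intensities = pd.read_csv(matrix_path, index_col=0)
        metadata = pd.read_csv(metadata_path, index_col="injection_id")
        return cls(intensities=intensities, metadata=metadata)


@dataclass
class PreprocessReport:
    """Feature bookkeeping through the chain; counts are non-increasing."""

    n_input_features: int = 0
    n_after_iqr: int = 0
    n_after_rsd: int = 0
    removed_iqr: list = field(default_factory=list)
    removed_rsd: list = field(default_factory=list)
    flagged_constant: list = field(default_factory=list)
    qc_rsd_before: pd.Series | None = None
    qc_rsd_after: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "n_input_features": self.n_input_features,
            "n_after_iqr": self.n_after_iqr,
            "n_after_rsd": self.n_after_rsd,
            "removed_iqr": list(self.removed_iqr),
            "removed_rsd": list(self.removed_rsd),
            "flagged_constant": list(self.flagged_constant),
            "median_qc_rsd_before": (
                float(self.qc_rsd_before.median())
                if self.qc_rsd_before is not None
                else None
            ),
            "median_qc_rsd_after": (
                float(self.qc_rsd_after.median())
                if self.qc_rsd_after is not None
                else None
            ),
        }


def qc_rsd(fm: FeatureMatrix) -> pd.Series:
    """Per-feature RSD (%) over QC injections: 100·sd/mean, sample SD (n−1).

    NaN where the QC mean is zero.
    """
    qc = fm.intensities[fm.qc_ids]
    if qc.shape[1] < 2:
        raise ValueError("need at least 2 QC injections for RSD")
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    rsd[mean == 0] = np.nan
    return rsd


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------


def _loess_curve(order: np.ndarray, y: np.ndarray, span: float, grid: np.ndarray):
    fit = lowess(y, order, frac=span, it=0, return_sorted=True)
    return np.interp(grid, fit[:, 0], fit[:, 1])


def _select_span(
    qc_order: np.ndarray, qc_mat: np.ndarray, spans: tuple[float, ...]
) -> float:
    """Leave-one-out CV of the LOESS span, pooled over (a subsample of) features."""
    n_qc = qc_order.size
    rng = np.random.default_rng(0)
    rows = np.arange(qc_mat.shape[0])
    if rows.size > 200:
        rows = rng.choice(rows, size=200, replace=False)
    best_span, best_err = spans[0], np.inf
    for span in spans:
        err = 0.0
        for i in rows:
            y = qc_mat[i]
            if np.allclose(y, y[0]):
                continue
            scale = np.mean(y)
            if scale <= 0:
                continue
            for j in range(n_qc):
                keep = np.arange(n_qc) != j
                pred = _loess_curve(
                    qc_order[keep], y[keep], span, qc_order[j : j + 1]
                )[0]
                err += ((pred - y[j]) / scale) ** 2
        if err < best_err:
            best_err, best_span = err, span
    return best_span


def drift_correct(
    fm: FeatureMatrix,
    method: str = "loess",
    spans: tuple[float, ...] = (0.6, 0.8, 1.0),
    min_qc: int = 5,
) -> FeatureMatrix:
    """Remove smooth injection-order signal drift using the pooled QCs.

    Per feature, a curve is fit to QC intensity vs injection order
    (``loess`` — local regression with a cross-validated span shared across
    features; ``median-ratio`` — per-QC-injection median ratio to the QC
    mean, interpolated; ``rf`` — random-forest regression on order) and,
    after normalizing the curve to mean one over the QC injections, divides
    every injection. All-zero features pass through unchanged.
    """
    if fm.analysis_scale:
        raise ValueError("drift correction must run on raw intensities")
    qc_ids = fm.qc_ids
    if len(qc_ids) < min_qc:
        raise ValueError(f"need at least {min_qc} QC injections, got {len(qc_ids)}")
    order_all = fm.metadata["injection_order"].to_numpy(float)
    qc_order = fm.metadata.loc[qc_ids, "injection_order"].to_numpy(float)
    X = fm.intensities.to_numpy(float)
    qc_mat = fm.intensities[qc_ids].to_numpy(float)
    qc_sort = np.argsort(qc_order)
    qc_order_s = qc_order[qc_sort]
    qc_mat_s = qc_mat[:, qc_sort]

    factors = np.ones_like(X)
    if method == "loess":
        span = _select_span(qc_order_s, qc_mat_s, spans)
        for i in range(X.shape[0]):
            y = qc_mat_s[i]
            if np.all(y == 0) or np.allclose(y, y[0]):
                continue  # flat fit → unit factor
            curve = _loess_curve(qc_order_s, y, span, order_all)
            qc_curve = np.interp(qc_order_s, order_all, curve)
            mean_qc = qc_curve.mean()
            if mean_qc <= 0:
                continue
            f = curve / mean_qc
            factors[i] = np.clip(f, 1e-6, None)
    elif method == "median-ratio":
        ref = qc_mat_s.mean(axis=1, keepdims=True)
        ok = ref[:, 0] > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(ok[:, None], qc_mat_s / ref, np.nan)
        inj_factor = np.nanmedian(ratios, axis=0)
        curve = np.interp(order_all, qc_order_s, inj_factor)
        curve = np.clip(curve / np.interp(qc_order_s, order_all, curve).mean(), 1e-6, None)
        factors[:] = curve[None, :]
    elif method == "rf":
        from sklearn.ensemble import RandomForestRegressor

        for i in range(X.shape[0]):
            y = qc_mat_s[i]
            if np.all(y == 0) or np.allclose(y, y[0]):
                continue
            rf = RandomForestRegressor(
                n_estimators=100, min_samples_leaf=2, random_state=0
            )
            rf.fit(qc_order_s[:, None], y)
            curve = rf.predict(order_all[:, None])
            mean_qc = rf.predict(qc_order_s[:, None]).mean()
            if mean_qc <= 0:
                continue
            factors[i] = np.clip(curve / mean_qc, 1e-6, None)
    else:
        raise ValueError(f"unknown drift method: {method!r}")

    corrected = pd.DataFrame(
        X / factors, index=fm.intensities.index, columns=fm.intensities.columns
    )
    return fm.copy(intensities=corrected)


# ---------------------------------------------------------------------------
# imputation, filters, scaling
# ---------------------------------------------------------------------------


def impute_zeros(fm: FeatureMatrix) -> FeatureMatrix:
    """Replace zeros by half the smallest positive value of the whole matrix."""
    X = fm.intensities.to_numpy(float)
    positive = X[X > 0]
    if positive.size == 0:
        raise ValueError("all-zero matrix: nothing to anchor the imputation")
    half_min = positive.min() / 2.0
    out = fm.intensities.mask(fm.intensities == 0, half_min)
    return fm.copy(intensities=out)


def iqr_filter(
    fm: FeatureMatrix, fraction: float = 0.10
) -> tuple[FeatureMatrix, list[str]]:
    """Drop the ``floor(fraction·n)`` features with the lowest IQR.

    IQR is computed across study (non-QC) injections; ties resolved by
    feature-id (row) order.
    """
    study = fm.intensities[fm.study_ids]
    if study.shape[0] < 10:
        raise ValueError("IQR filter needs at least 10 features")
    q75 = study.quantile(0.75, axis=1)
    q25 = study.quantile(0.25, axis=1)
    iqr = (q75 - q25).to_numpy()
    n_drop = int(np.floor(fraction * len(iqr)))
    # stable sort keeps feature order among exact ties
    ranked = np.argsort(iqr, kind="stable")
    drop_idx = ranked[:n_drop]
    removed = [fm.feature_ids[i] for i in sorted(drop_idx)]
    kept = fm.intensities.drop(index=removed)
    return fm.copy(intensities=kept), removed


def rsd_filter(
    fm: FeatureMatrix, threshold: float = 20.0
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features whose QC RSD exceeds ``threshold`` percent.

    Features with zero QC mean (RSD undefined) are removed as well.
    """
    rsd = qc_rsd(fm)
    bad = rsd.isna() | (rsd > threshold)
    removed = list(rsd.index[bad])
    kept = fm.intensities.drop(index=removed)
    return fm.copy(intensities=kept), removed


def transform_scale(fm: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """log10 then Pareto scaling: x' = (log10 x − mean)/sqrt(sd).

    Mean and SD are taken over study injections (QC columns are scaled with
    the study statistics). Constant features come out all-zero and are
    flagged. Requires a strictly positive matrix (run after imputation).
    """
    if fm.analysis_scale:
        raise ValueError("matrix is already on the analysis scale")
    X = fm.intensities
    nonpos = X <= 0
    if nonpos.to_numpy().any():
        r, c = np.argwhere(nonpos.to_numpy())[0]
        raise ValueError(
            f"non-positive intensity at feature {X.index[r]!r}, "
            f"injection {X.columns[c]!r}; impute zeros first"
        )
    logged = np.log10(X)
    study = logged[fm.study_ids]
    mean = study.mean(axis=1)
    sd = study.std(axis=1, ddof=1)
    flagged = list(sd.index[sd == 0])
    denom = np.sqrt(sd.where(sd > 0, 1.0))
    scaled = logged.sub(mean, axis=0).div(denom, axis=0)
    scaled.loc[flagged] = 0.0
    out = FeatureMatrix(
        intensities=scaled, metadata=fm.metadata.copy(), analysis_scale=True
    )
    return out, flagged


def preprocess_pipeline(
    fm: FeatureMatrix,
    drift_method: str = "loess",
    iqr_fraction: float = 0.10,
    rsd_threshold: float = 20.0,
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Full chain: drift → impute → IQR filter → RSD filter → log+Pareto."""
    report = PreprocessReport(n_input_features=len(fm.feature_ids))
    report.qc_rsd_before = qc_rsd(fm)
    fm = drift_correct(fm, method=drift_method)
    report.qc_rsd_after = qc_rsd(fm)
    fm = impute_zeros(fm)
    fm, report.removed_iqr = iqr_filter(fm, fraction=iqr_fraction)
    report.n_after_iqr = len(fm.feature_ids)
    fm, report.removed_rsd = rsd_filter(fm, threshold=rsd_threshold)
    report.n_after_rsd = len(fm.feature_ids)
    fm, report.flagged_constant = transform_scale(fm)
    return fm, report
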