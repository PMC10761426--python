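"""Per-platform cleanup of untargeted metabolomics feature matrices.

The fixed pipeline order is: kNN imputation -> QC coefficient-of-variation
filter -> QC-based support-vector-regression drift correction (QC-SVRC) ->
internal-standard normalization -> (log10 +) PCA / Hotelling T2 outlier
screening.  Each step is also available as a standalone operation.

QC-SVRC models each feature's QC intensity as a smooth function of injection
order with an epsilon-insensitive RBF support vector regression and divides
every sample by the predicted trend (ratio to the QC median), removing
gain-like intra-batch drift.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .data_model import FeatureMatrix

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass
class PreprocessReport:
    """What a preprocessing step did to one platform's matrix."""

    platform_id: str
    step: str
    params: dict = dataclasses.field(default_factory=dict)
    cv_before: pd.Series | None = None       # per-feature QC CV, percent
    cv_after: pd.Series | None = None
    dropped_features: dict[str, str] = dataclasses.field(default_factory=dict)
    fallback_features: list[str] = dataclasses.field(default_factory=list)
    outliers: pd.DataFrame | None = None     # sample, t2, flagged

    def validate(self) -> None:
        for s in (self.cv_before, self.cv_after):
            if s is not None and (s.dropna() < 0).any():
                raise PreprocessError("negative CV")
        bad = set(self.dropped_features.values()) - {"cv_filter", "all_missing"}
        if bad:
            raise PreprocessError(f"unknown drop reasons {bad}")


def qc_cv(values: pd.DataFrame) -> pd.Series:
    """Percent coefficient of variation per feature (sample sd, n-1)."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    return cv


# ---------------------------------------------------------------------------
# kNN imputation
# ---------------------------------------------------------------------------

def impute_knn(m: FeatureMatrix, k: int = 5) -> FeatureMatrix:
    """Replace missing entries by the mean over the k nearest samples.

    Nearness is Euclidean distance computed over the features observed in
    both samples, after standardizing each feature (observed mean / sd over
    all samples).  The neighbour pool for a missing entry is restricted to
    samples where that feature is observed; if fewer than k exist, all are
    used.  Features missing in every sample are dropped.
    """
    if k < 1:
        raise PreprocessError("k must be >= 1")
    if m.n_samples < k + 1:
        raise PreprocessError(f"need at least {k + 1} samples for k={k}")
    X = m.values.to_numpy(dtype=float)
    if np.isnan(X).all():
        raise PreprocessError(f"{m.platform_id}: all entries missing")
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        dropped = list(m.values.columns[all_missing])
        log.warning("%s: dropping all-missing features %s", m.platform_id, dropped)
        m = m.drop_features(dropped)
        X = m.values.to_numpy(dtype=float)
    if not np.isnan(X).any():
        return m

    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    Z = (X - mean) / sd

    out = X.copy()
    n = X.shape[0]
    obs = ~np.isnan(X)
    for i in range(n):
        miss_j = np.flatnonzero(~obs[i])
        if miss_j.size == 0:
            continue
        # distances from sample i to every other sample over co-observed features
        d = np.full(n, np.inf)
        for t in range(n):
            if t == i:
                continue
            shared = obs[i] & obs[t]
            if shared.any():
                diff = Z[i, shared] - Z[t, shared]
                d[t] = float(np.sqrt(np.sum(diff * diff)))
        for j in miss_j:
            donors = np.flatnonzero(obs[:, j] & np.isfinite(d))
            if donors.size == 0:
                raise PreprocessError(
                    f"{m.platform_id}: no donor for feature "
                    f"{m.values.columns[j]!r} in sample {m.values.index[i]!r}")
            order = donors[np.argsort(d[donors], kind="stable")]
            out[i, j] = float(np.mean(X[order[:k], j]))
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(values)


# ---------------------------------------------------------------------------
# QC CV filter
# ---------------------------------------------------------------------------

def qc_cv_filter(m: FeatureMatrix, max_cv_pct: float = 30.0
                 ) -> tuple[FeatureMatrix, PreprocessReport]:
    """Keep features whose QC coefficient of variation is below ``max_cv_pct``.

    Internal-standard features are always kept.  Features with QC mean 0 (CV
    undefined) are dropped.
    """
    qcs = m.qc_values()
    if len(qcs) < 3:
        raise PreprocessError(
            f"{m.platform_id}: need >= 3 QC samples, have {len(qcs)}")
    cv = qc_cv(qcs)
    dropped: dict[str, str] = {}
    keep = []
    for f in m.feature_ids:
        if f in m.is_features:
            keep.append(f)
            continue
        c = cv[f]
        if np.isfinite(c) and abs(c) < max_cv_pct:
            keep.append(f)
        else:
            dropped[f] = "cv_filter"
    report = PreprocessReport(
        platform_id=m.platform_id, step="qc_cv_filter",
        params={"max_cv_pct": max_cv_pct},
        cv_before=cv.abs(), dropped_features=dropped)
    report.validate()
    return m.select_features(keep), report


# ---------------------------------------------------------------------------
# QC-SVRC drift correction
# ---------------------------------------------------------------------------

def qc_svrc_correct(m: FeatureMatrix,
                    C: float | str = "auto",
                    epsilon: float | str = "auto",
                    gamma: float | str = "auto"
                    ) -> tuple[FeatureMatrix, PreprocessReport]:
    """Remove injection-order drift with QC-based support vector regression.

    Per feature, an RBF-kernel epsilon-SVR of QC intensity against injection
    order is fitted; every sample's value is multiplied by
    ``median(QC) / predicted trend`` at its own injection order.  Scale-aware
    defaults: C = QC range, epsilon = a robust noise estimate (scaled MAD of
    the linearly detrended QC trace — the spread of the raw QC intensities
    would absorb the very drift being corrected),
    gamma = 1 / (injection-order range)^2.  Features whose fit fails fall
    back to no correction and are logged.
    """
    qc_mask = (m.sample_roles == "qc").to_numpy()
    qc_orders = m.injection_order.to_numpy()[qc_mask]
    if len(np.unique(qc_orders)) < 5:
        raise PreprocessError(
            f"{m.platform_id}: need >= 5 QCs with distinct injection orders")
    orders_all = m.injection_order.to_numpy(dtype=float)[:, None]
    order_range = float(qc_orders.max() - qc_orders.min())
    gamma_val = 1.0 / order_range ** 2 if gamma == "auto" else float(gamma)

    X = m.values.to_numpy(dtype=float)
    out = X.copy()
    qc_X = X[qc_mask]
    cv_before = qc_cv(m.qc_values())
    fallback: list[str] = []
    for j, feat in enumerate(m.feature_ids):
        y = qc_X[:, j]
        ok = np.isfinite(y)
        if ok.sum() < 5:
            fallback.append(feat)
            continue
        y_ok = y[ok]
        ord_ok = qc_orders[ok]
        med = float(np.median(y_ok))
        c_val = float(y_ok.max() - y_ok.min()) if C == "auto" else float(C)
        if epsilon == "auto":
            # tube width ~ 2 robust SDs of the QC noise, estimated after
            # removing a low-order polynomial trend so the width reflects
            # measurement noise rather than the drift being corrected
            deg = min(2, int(ok.sum()) - 2)
            coef = np.polyfit(ord_ok.astype(float), y_ok, deg)
            resid = y_ok - np.polyval(coef, ord_ok.astype(float))
            eps_val = float(2 * 1.4826 * np.median(
                np.abs(resid - np.median(resid))))
        else:
            eps_val = float(epsilon)
        if c_val <= 0:
            continue  # constant QC trace: nothing to correct
        try:
            svr = SVR(kernel="rbf", C=c_val, epsilon=max(eps_val, 1e-12),
                      gamma=gamma_val)
            svr.fit(qc_orders[ok].reshape(-1, 1).astype(float), y_ok)
            pred = svr.predict(orders_all)
        except Exception:  # pragma: no cover - defensive
            fallback.append(feat)
            continue
        pred = np.maximum(pred, 1e-6 * med)
        # reference level = median of the fitted trend over the QC orders:
        # a flat trend then yields an exact identity (no fit-level offset)
        ref = float(np.median(pred[qc_mask]))
        col = X[:, j]
        obs = np.isfinite(col)
        out[obs, j] = col[obs] * ref / pred[obs]
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    corrected = m.with_values(values)
    report = PreprocessReport(
        platform_id=m.platform_id, step="qc_svrc_correct",
        params={"C": C, "epsilon": epsilon, "gamma": gamma},
        cv_before=cv_before.abs(), cv_after=qc_cv(corrected.qc_values()).abs(),
        fallback_features=fallback)
    if fallback:
        log.warning("%s: SVRC fallback (no correction) for %d features",
                    m.platform_id, len(fallback))
    report.validate()
    return corrected, report


# ---------------------------------------------------------------------------
# internal-standard normalization
# ---------------------------------------------------------------------------

def normalize_internal_standard(m: FeatureMatrix, is_feature: str
                                ) -> FeatureMatrix:
    """Divide every sample by its IS response ratio; remove the IS channel.

    The per-sample factor is ``IS_s / median(IS over study samples)`` so the
    typical study sample is left on its original scale.
    """
    if is_feature not in m.feature_ids:
        raise PreprocessError(f"{m.platform_id}: IS feature {is_feature!r} absent")
    is_col = m.values[is_feature]
    bad = is_col.index[~(is_col > 0) | is_col.isna()]
    if len(bad):
        raise PreprocessError(
            f"{m.platform_id}: non-positive or missing IS value in sample "
            f"{bad[0]!r}")
    ref = float(is_col.loc[m.sample_roles == "study"].median())
    factors = is_col / ref
    values = m.values.div(factors, axis=0).drop(columns=[is_feature])
    return m.with_values(values)


# ---------------------------------------------------------------------------
# PCA / Hotelling T2 outlier screen
# ---------------------------------------------------------------------------

def pca_outlier_screen(m: FeatureMatrix, n_components: int = 2,
                       alpha: float = 0.05, log10: bool = False
                       ) -> PreprocessReport:
    """Flag analytical outliers outside the Hotelling T2 ellipse.

    PCA on mean-centred (optionally log10-transformed) study + QC samples;
    a sample is flagged iff its T2 on the first 2 score dimensions exceeds
    the F-based limit ``(2(n-1)/(n-2)) F(1-alpha; 2, n-2)``.  Flagging only;
    removal is a separate, explicit decision.
    """
    if n_components != 2:
        raise PreprocessError("outlier screen is defined on 2 components")
    mask = m.sample_roles.isin(["study", "qc"])
    X = m.values.loc[mask].to_numpy(dtype=float)
    ids = m.values.index[mask]
    n = X.shape[0]
    if n <= 3:
        raise PreprocessError("need more than 3 samples")
    if np.isnan(X).any():
        raise PreprocessError("outlier screen requires complete data (impute first)")
    if log10:
        if (X <= 0).any():
            raise PreprocessError("log10 requested but non-positive values present")
        X = np.log10(X)
    Xc = X - X.mean(axis=0)
    # scores on the first two principal components
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    T = Xc @ vt[:2].T
    lam = (s[:2] ** 2) / (n - 1)
    lam = np.maximum(lam, np.finfo(float).tiny)
    t2 = np.sum(T ** 2 / lam, axis=1)
    crit = (2.0 * (n - 1) / (n - 2)) * stats.f.ppf(1 - alpha, 2, n - 2)
    flagged = t2 > crit
    outliers = pd.DataFrame({"sample_id": ids, "t2": t2, "flagged": flagged})
    report = PreprocessReport(
        platform_id=m.platform_id, step="pca_outlier_screen",
        params={"n_components": 2, "alpha": alpha, "log10": log10,
                "t2_crit": float(crit)},
        outliers=outliers)
    report.validate()
    return report


# ---------------------------------------------------------------------------
# full per-platform pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PreprocessParams:
    knn_k: int = 5
    max_cv_pct: float = 30.0
    svrc_C: float | str = "auto"
    svrc_epsilon: float | str = "auto"
    svrc_gamma: float | str = "auto"
    outlier_alpha: float = 0.05
    outlier_log10: bool = True
    drop_outliers: bool = False


def preprocess_platform(m: FeatureMatrix,
                        params: PreprocessParams | None = None
                        ) -> tuple[FeatureMatrix, list[PreprocessReport]]:
    """Run the fixed pipeline: impute -> CV filter -> SVRC -> IS -> screen."""
    params = params or PreprocessParams()
    reports: list[PreprocessReport] = []
    m = impute_knn(m, k=params.knn_k)
    m, rep_svrc = qc_svrc_correct(m, C=params.svrc_C,
                                  epsilon=params.svrc_epsilon,
                                  gamma=params.svrc_gamma)
    reports.append(rep_svrc)
    m, rep_cv = qc_cv_filter(m, max_cv_pct=params.max_cv_pct)
    reports.append(rep_cv)
    for is_feat in m.is_features:
        m = normalize_internal_standard(m, is_feat)
    rep_out = pca_outlier_screen(m, alpha=params.outlier_alpha,
                                 log10=params.outlier_log10)
    reports.append(rep_out)
    if params.drop_outliers:
        flagged = rep_out.outliers.loc[rep_out.outliers["flagged"], "sample_id"]
        keep = [s for s in m.sample_ids if s not in set(flagged)]
        m = m.select_samples(keep)
        log.info("%s: dropped %d flagged outliers", m.platform_id, len(flagged))
    return m, reports
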